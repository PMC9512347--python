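"""Train the combined classifier on a small cohort and vote on held-out
patients.

Uses the combined segment+position network with brain-anatomical
normalization (CAS-B); each slice of a structure casts one vote and the
structure receives the plurality label (ties count as misclassification).
A small cohort and short run keep this demo around two minutes; the
reference study uses 60 patients.
"""

import contourclass as cc

cohort = cc.generate_cohort(cc.PhantomSpec(), n_patients=20, seed=1)
train_c, test_c = cohort.split(0.8, seed=101)

samples = cc.cohort_samples(train_c, "ANAT_BRAIN", multi_slice=True)
model = cc.build_network("CAS-B", grid=(128, 128), seed=1)
history = cc.train(model, samples, cc.TrainConfig(epochs=5, seed=1))
print(history.to_string(index=False))

report, cm, table = cc.evaluate_cohort_voting(model, test_c)
print(
    f"\nheld-out voting: total accuracy {report.total_accuracy:.1%}, "
    f"mean accuracy per class {report.mean_accuracy_per_class:.1%}, "
    f"{report.n_errors} errors (of which {report.n_ties} ties) "
    f"in {report.n_items} structures"
)
wrong = table[~table.correct]
if len(wrong):
    print("misclassified structures (thin ones dominate):")
    print(wrong[["truth", "winner", "n_slices"]].to_string(index=False))
# Expect roughly 80-90% structure-level accuracy at this reduced training
# size (the 60-patient reference study reaches >=90%); failures concentrate
# in structures with few slices, where a handful of bad votes flips the
# plurality.
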