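"""Metrics, confusion matrices, guess baselines, and the missing-slice
robustness harness.

Two accuracy summaries are reported throughout:

* **total accuracy** — the fraction of all classified items (slices or
  structures) that are correct;
* **mean accuracy per class** — the unweighted mean of per-class accuracies
  (per-class recall), insensitive to the heavy class imbalance of axial
  slice data.  Classes with zero support are excluded from the mean rather
  than counted as zero, so the metric stays defined on small cohorts.

Confusion matrices are oriented with **columns = true class** (rows =
predicted), so column-normalizing each column to sum 1 turns columns into
per-class recall profiles.  TIE decisions count as errors but are excluded
from the predicted axis of the matrix and tracked in a side count, since a
17x17 matrix has no tie row.

Printed percentages: clinical reports in this area typically show one
decimal; both a truncating and a rounding formatter are provided because
published tables mix the two conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierModel, make_samples
from .normalize import build_frame
from .phantom import PhantomCohort, drop_slice
from .vocabulary import VOCAB, ClassVocabulary
from .vote import TIE, StructureDecision, classify_structure

#: Per-class axial slice counts of a 446-patient clinical head-and-neck
#: training cohort; the reference class distribution for the
#: proportional-guess baseline.
CLINICAL_TRAIN_SLICE_COUNTS: dict[str, int] = {
    "Eye_L": 4788,
    "Eye_R": 4738,
    "Cochlea_L": 161,
    "Cochlea_R": 158,
    "Larynx": 5750,
    "Lens_L": 1504,
    "Lens_R": 1494,
    "Chiasm": 810,
    "OpticNerve_L": 1125,
    "OpticNerve_R": 1086,
    "Brainstem": 11536,
    "Brain": 25590,
    "Esophagus": 20832,
    "SpinalCord": 21746,
    "Parotid_L": 10031,
    "Parotid_R": 9879,
    "Pituitary": 1357,
}


def pct_truncated(fraction: float, decimals: int = 1) -> float:
    """Percentage with the trailing digits truncated (0.0588 -> 5.8)."""
    scale = 10.0**decimals
    return math.floor(fraction * 100.0 * scale) / scale


def pct_rounded(fraction: float, decimals: int = 1) -> float:
    """Percentage rounded half-to-even (0.97871 -> 97.9)."""
    return round(fraction * 100.0, decimals)


@dataclass
class ConfusionMatrix:
    """17x17 counts with entry (predicted i, true j), plus tie side-counts."""

    counts: np.ndarray
    tie_counts: np.ndarray  # per true class
    vocab: ClassVocabulary = field(default_factory=lambda: VOCAB)

    @property
    def normalized(self) -> np.ndarray:
        """Each column divided by its column sum (ties live outside the
        matrix); columns with zero support are NaN."""
        support = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(support > 0, self.counts / support, np.nan)

    @property
    def log10_view(self) -> np.ndarray:
        """Elementwise log10 of the normalized matrix; zeros/NaN masked."""
        norm = self.normalized
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log10(norm)
        out[~np.isfinite(out)] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.vocab.labels, columns=self.vocab.labels
        )


@dataclass
class EvalReport:
    total_accuracy: float
    mean_accuracy_per_class: float
    per_class: dict[str, float]
    failure_histogram: dict[int, int]
    n_items: int
    n_errors: int
    n_ties: int

    def to_dict(self) -> dict:
        return {
            "total_accuracy": self.total_accuracy,
            "mean_accuracy_per_class": self.mean_accuracy_per_class,
            "per_class": dict(self.per_class),
            "failure_histogram": {str(k): v for k, v in self.failure_histogram.items()},
            "n_items": self.n_items,
            "n_errors": self.n_errors,
            "n_ties": self.n_ties,
        }


def score(
    truths: list[str],
    predictions: list[str],
    n_slices: list[int] | None = None,
    vocab: ClassVocabulary = VOCAB,
) -> tuple[EvalReport, ConfusionMatrix]:
    """Score (truth, predicted-or-TIE) pairs.

    ``n_slices``, when given, feeds the failure histogram: for every
    misclassified item its slice count is binned (bin = the count itself).
    """
    if not truths:
        raise ValueError("cannot score an empty decision list")
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    k = len(vocab)
    counts = np.zeros((k, k), dtype=int)
    ties = np.zeros(k, dtype=int)
    hist: dict[int, int] = {}
    n_err = 0
    for i, (t, p) in enumerate(zip(truths, predictions)):
        j = vocab.index(t)
        if p == TIE:
            ties[j] += 1
        else:
            counts[vocab.index(p), j] += 1
        if p != t:
            n_err += 1
            if n_slices is not None:
                hist[n_slices[i]] = hist.get(n_slices[i], 0) + 1

    support = counts.sum(axis=0) + ties
    per_class = {
        vocab.label(j): counts[j, j] / support[j]
        for j in range(k)
        if support[j] > 0
    }
    n = len(truths)
    return (
        EvalReport(
            total_accuracy=(n - n_err) / n,
            mean_accuracy_per_class=float(np.mean(list(per_class.values()))),
            per_class=per_class,
            failure_histogram=dict(sorted(hist.items())),
            n_items=n,
            n_errors=n_err,
            n_ties=int(ties.sum()),
        ),
        ConfusionMatrix(counts=counts, tie_counts=ties, vocab=vocab),
    )


def score_decisions(
    decisions: list[tuple[str, StructureDecision]],
    n_slices: list[int] | None = None,
    vocab: ClassVocabulary = VOCAB,
) -> tuple[EvalReport, ConfusionMatrix]:
    truths = [t for t, _ in decisions]
    preds = [d.winner for _, d in decisions]
    return score(truths, preds, n_slices=n_slices, vocab=vocab)


# ---------------------------------------------------------------------------
# Random-guess baselines
# ---------------------------------------------------------------------------


def uniform_baseline(k: int) -> float:
    """Expected accuracy of guessing uniformly among ``k`` classes: 1/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 / k


def proportional_baseline(class_counts: dict[str, int]) -> float:
    """Expected accuracy of guessing with probability proportional to class
    frequency, evaluated on that same distribution: sum_i (n_i/N)^2."""
    counts = np.array(list(class_counts.values()), dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("class counts sum to zero")
    p = counts / n
    return float((p**2).sum())


# ---------------------------------------------------------------------------
# Structure-level cohort evaluation
# ---------------------------------------------------------------------------


def evaluate_cohort_voting(
    model: ClassifierModel, cohort: PhantomCohort
) -> tuple[EvalReport, ConfusionMatrix, pd.DataFrame]:
    """Vote-classify every structure of a cohort against its truth labels.

    Returns the report, the confusion matrix, and a per-structure table
    (patient_id, structure_index, truth, winner, n_slices, correct).
    """
    rows = []
    for sset in cohort.structure_sets:
        frame = build_frame(model.spec.frame_scheme, sset)
        for i, st in enumerate(sset.structures):
            truth = cohort.truth.get((sset.patient_id, i))
            if truth is None:
                continue
            dec = classify_structure(model, st, sset, frame, truth=truth)
            rows.append(
                {
                    "patient_id": sset.patient_id,
                    "structure_index": i,
                    "truth": truth,
                    "winner": dec.winner,
                    "n_slices": st.slice_count,
                    "correct": bool(dec.correct),
                }
            )
    table = pd.DataFrame(rows)
    report, cm = score(
        list(table.truth), list(table.winner), n_slices=list(table.n_slices),
        vocab=model.vocab,
    )
    return report, cm, table


def evaluate_cohort_slices(
    model: ClassifierModel, cohort: PhantomCohort
) -> tuple[EvalReport, ConfusionMatrix]:
    """Slice-by-slice evaluation of a cohort (no voting)."""
    from .classify import cohort_samples  # local import to avoid cycle noise

    samples = cohort_samples(cohort, model.spec.frame_scheme, model.spec.multi_slice,
                             vocab=model.vocab)
    preds = model.predict_batch(samples)
    truths = [model.vocab.label(s.label) for s in samples]
    labels = [model.vocab.label(p.argmax) for p in preds]
    return score(truths, labels, vocab=model.vocab)


# ---------------------------------------------------------------------------
# Missing-slice robustness harness
# ---------------------------------------------------------------------------


def robustness_test(
    model: ClassifierModel,
    cohort: PhantomCohort,
    per_class: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-classify structures after deleting a single random slice.

    Each organ class is selected exactly ``per_class`` times (structures
    with >=2 slices, drawn without replacement across patients).  For every
    selected structure the intact and the degraded (one seeded-random slice
    removed; zero channels stand in for the missing neighbour data) versions
    are vote-classified.  Returns one row per selected structure with both
    decisions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B57]))
    by_class: dict[str, list[tuple]] = {lab: [] for lab in model.vocab.labels}
    for sset in cohort.structure_sets:
        for i, st in enumerate(sset.structures):
            truth = cohort.truth.get((sset.patient_id, i))
            if truth in by_class and st.slice_count >= 2:
                by_class[truth].append((sset, i, st))

    rows = []
    for lab in model.vocab.labels:
        pool = by_class[lab]
        if len(pool) < per_class:
            raise ValueError(
                f"cohort has only {len(pool)} structures of class {lab!r} "
                f"with >=2 slices; {per_class} required"
            )
        picks = rng.choice(len(pool), size=per_class, replace=False)
        for p in picks:
            sset, i, st = pool[p]
            frame = build_frame(model.spec.frame_scheme, sset)
            intact = classify_structure(model, st, sset, frame, truth=lab)
            idxs = st.nonempty_slice_indices()
            removed = int(idxs[rng.integers(len(idxs))])
            degraded_struct = drop_slice(st, removed)
            degraded = classify_structure(model, degraded_struct, sset, frame, truth=lab)
            rows.append(
                {
                    "patient_id": sset.patient_id,
                    "structure_index": i,
                    "truth": lab,
                    "n_slices": st.slice_count,
                    "removed_slice": removed,
                    "intact_winner": intact.winner,
                    "intact_correct": bool(intact.correct),
                    "degraded_winner": degraded.winner,
                    "degraded_correct": bool(degraded.correct),
                }
            )
    return pd.DataFrame(rows)


def plot_confusion(cm: ConfusionMatrix, path, log10: bool = False) -> None:
    """Heatmap of the column-normalized (or log10) confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = cm.log10_view if log10 else cm.normalized
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(data, cmap="viridis")
    ax.set_xticks(range(len(cm.vocab)), cm.vocab.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.vocab)), cm.vocab.labels, fontsize=7)
    ax.set_xlabel("true class")
    ax.set_ylabel("predicted class")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
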