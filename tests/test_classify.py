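"""Sample construction, network architecture, and the training loop."""

import numpy as np
import pytest

import contourclass as cc
from contourclass.classify import NETWORKS, Family, patient_split, resolve_network


@pytest.fixture(scope="module")
def tiny_cohort():
    return cc.generate_cohort(cc.PhantomSpec(), 4, seed=19)


@pytest.fixture(scope="module")
def tiny_samples(tiny_cohort):
    return cc.cohort_samples(tiny_cohort, "ANAT_BRAIN", True)


class TestMakeSamples:
    def test_multi_slice_channel_stacking(self, square_set):
        frame = cc.frame_unnormalized()
        samples = cc.make_samples(square_set, frame, multi_slice=True)
        three = [s for s in samples if s.structure_index == 0]
        assert len(three) == 3
        first, middle, last = sorted(three, key=lambda s: s.slice_index)
        assert not first.channels[0].any()  # no preceding slice: red zero
        assert first.channels[2].any()
        assert all(c.any() for c in middle.channels)
        assert not last.channels[2].any()  # no succeeding slice: blue zero

    def test_single_slice_mode_zeroes_neighbours(self, square_set):
        samples = cc.make_samples(square_set, cc.frame_unnormalized(), multi_slice=False)
        assert all(
            not s.channels[0].any() and not s.channels[2].any() for s in samples
        )
        assert all(s.channels[1].any() for s in samples)

    def test_one_sample_per_nonempty_slice_with_count_feature(self, tiny_cohort):
        sset = tiny_cohort.structure_sets[0]
        frame = cc.build_frame("ANAT_BRAIN", sset)
        samples = cc.make_samples(sset, frame, True)
        for i, st in enumerate(sset.structures):
            mine = [s for s in samples if s.structure_index == i]
            assert len(mine) == st.slice_count
            assert all(s.n_slices_feature == st.slice_count for s in mine)

    def test_labels_attached_from_map(self, square_set):
        samples = cc.make_samples(
            square_set, cc.frame_unnormalized(), False, labels={0: 11}
        )
        by_struct = {s.structure_index: s.label for s in samples}
        assert by_struct[0] == 11 and by_struct[1] is None


class TestBuildNetwork:
    def test_position_net_without_hidden_has_51_params(self):
        m = cc.build_network("PU", grid=(64, 64), seed=0)
        assert m.n_params == 2 * 17 + 17

    def test_position_net_with_hidden_param_count(self):
        m = cc.build_network("PN-32", grid=(64, 64), seed=0)
        assert m.n_params == (2 * 32 + 32) + (32 * 17 + 17)

    def test_table2_registry_families(self):
        assert resolve_network("PU").family is Family.POSITION
        assert resolve_network("SM").multi_slice
        assert not resolve_network("SS").multi_slice
        assert resolve_network("CNV") is resolve_network("CNS")
        assert resolve_network("CAV-B").frame_scheme is cc.Scheme.ANAT_BRAIN

    def test_seeded_builds_identical(self):
        a = cc.build_network("CAS-B", grid=(64, 64), seed=5)
        b = cc.build_network("CAS-B", grid=(64, 64), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cc.NetworkSpec("bad", Family.COMBINED, cc.Scheme.NONANAT, backbone=None).validate()
        with pytest.raises(ValueError):
            cc.NetworkSpec("bad", Family.POSITION, cc.Scheme.NONANAT, hidden_nodes=64).validate()

    def test_combined_forward_probabilities(self, tiny_samples):
        m = cc.build_network("CAS-B", grid=(128, 128), seed=0)
        pred = m.predict_slice(tiny_samples[0])
        assert pred.probs.shape == (17,)
        assert pred.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.argmax == int(pred.probs.argmax())

    def test_zeroed_output_layer_gives_uniform_probs(self, tiny_samples):
        m = cc.build_network("PA-32Z", grid=(128, 128), seed=0)
        final = m.head.layers[-1]
        final.W.value[...] = 0.0
        final.b.value[...] = 0.0
        pred = m.predict_slice(tiny_samples[0])
        np.testing.assert_allclose(pred.probs, np.full(17, 1 / 17), atol=1e-12)

    def test_grid_mismatch_raises(self, tiny_samples):
        m = cc.build_network("SM", grid=(64, 64), seed=0)
        with pytest.raises(ValueError, match="grid"):
            m.predict_slice(tiny_samples[0])


class TestTraining:
    def test_patient_split_disjoint(self, tiny_samples):
        tr, va = patient_split(tiny_samples, 0.8, seed=0)
        a = {tiny_samples[i].patient_id for i in tr}
        b = {tiny_samples[i].patient_id for i in va}
        assert not (a & b) and a and b

    def test_training_is_seeded_deterministic(self, tiny_samples):
        accs = []
        for _ in range(2):
            m = cc.build_network("PA-32Z", grid=(128, 128), seed=4)
            h = cc.train(m, tiny_samples, cc.TrainConfig(epochs=2, seed=4))
            accs.append(h.val_total_acc.iloc[-1])
        assert accs[0] == accs[1]

    def test_lr_decays_each_epoch(self, tiny_samples):
        m = cc.build_network("PN-32Z", grid=(128, 128), seed=0)
        h = cc.train(m, tiny_samples, cc.TrainConfig(epochs=3, seed=0))
        np.testing.assert_allclose(h.lr, [0.1, 0.05, 0.025])

    def test_training_improves_over_init(self, tiny_samples):
        m = cc.build_network("PA-32Z", grid=(128, 128), seed=1)
        h = cc.train(m, tiny_samples, cc.TrainConfig(epochs=3, seed=1))
        assert h.val_total_acc.iloc[-1] > 2 * (1 / 17)

    def test_single_class_rejected(self, tiny_samples):
        one = [s for s in tiny_samples if s.label == 11]
        m = cc.build_network("PA-32Z", grid=(128, 128), seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            cc.train(m, one, cc.TrainConfig(epochs=1, seed=0))

    def test_empty_sample_list_rejected(self):
        m = cc.build_network("PA-32Z", grid=(128, 128), seed=0)
        with pytest.raises(ValueError):
            cc.train(m, [], cc.TrainConfig(epochs=1, seed=0))


class TestPredictionDeterminism:
    def test_identical_samples_identical_predictions(self, tiny_samples):
        m = cc.build_network("CAS-B", grid=(128, 128), seed=2)
        p1 = m.predict_slice(tiny_samples[3])
        p2 = m.predict_slice(tiny_samples[3])
        np.testing.assert_array_equal(p1.probs, p2.probs)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tiny_samples, tmp_path):
        m = cc.build_network("CAS-B", grid=(128, 128), seed=0)
        cc.train(m, tiny_samples, cc.TrainConfig(epochs=1, seed=0))
        p = tmp_path / "model.npz"
        cc.save_checkpoint(m, p)
        back = cc.load_checkpoint(p)
        assert back.spec == m.spec
        assert back.grid == m.grid
        for s in tiny_samples[:5]:
            np.testing.assert_array_equal(
                m.predict_slice(s).probs, back.predict_slice(s).probs
            )
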