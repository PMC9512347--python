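"""Coordinate-normalization frames: anchor exactness, affinity, symmetry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import contourclass as cc
from contourclass.normalize import Scheme, apply


def _brain_on_slices(lo, hi, grid=(64, 64)):
    """Minimal brain structure spanning slices lo..hi."""
    sq = cc.ContourPolygon(
        np.array([[20.0, 20.0], [44.0, 20.0], [44.0, 44.0], [20.0, 44.0]])
    )
    return cc.Structure("Brain", {z: [sq] for z in range(lo, hi + 1)})


class TestNonanatomicalFrame:
    def test_grid_extremes_map_to_unit_interval(self):
        f = cc.frame_nonanatomical((512, 512), _brain_on_slices(40, 80))
        p0 = apply(f, (0.0, 0.0), 40)
        p1 = apply(f, (511.0, 511.0), 80)
        assert (p0.x, p0.y, p0.z) == (-1.0, -1.0, 0.0)
        assert (p1.x, p1.y, p1.z) == (1.0, 1.0, 1.0)

    def test_midpoints(self):
        f = cc.frame_nonanatomical((512, 512), _brain_on_slices(40, 80))
        p = apply(f, (255.5, 255.5), 60)
        assert p.x == pytest.approx(0.0, abs=1e-12)
        assert p.z == pytest.approx(0.5, abs=1e-12)

    def test_empty_brain_raises(self):
        with pytest.raises(cc.MissingReferenceError):
            cc.frame_nonanatomical((64, 64), cc.Structure("Brain", {}))


class TestAnatomicalBrainFrame:
    def test_extremes_map_to_plus_minus_one(self, rigid_patient):
        sset, _ = rigid_patient
        f = cc.frame_anatomical_brain(sset)
        assert apply(f, (f.x_ref[1], 0.0), 0).x == pytest.approx(1.0, abs=1e-12)
        assert apply(f, (f.x_ref[0], 0.0), 0).x == pytest.approx(-1.0, abs=1e-12)
        mid = (f.x_ref[0] + f.x_ref[1]) / 2
        assert apply(f, (mid, 0.0), 0).x == pytest.approx(0.0, abs=1e-12)

    def test_extrapolation_beyond_reference(self):
        f = cc.Frame(Scheme.ANAT_BRAIN, (100.0, 400.0), (0.0, 511.0), (0.0, 10.0), (-1.0, 1.0))
        x_beyond = 400.0 + 0.1 * 300.0
        assert apply(f, (x_beyond, 0.0), 0).x > 1.0  # no clamping

    def test_missing_brain_names_roi(self):
        s = cc.StructureSet("X", (64, 64), 2.5, 10, [])
        with pytest.raises(cc.MissingReferenceError, match="Brain"):
            cc.frame_anatomical_brain(s)

    def test_mirror_negates_normalized_x(self, rigid_patient):
        sset, _ = rigid_patient
        rows, cols = sset.grid
        mirrored = cc.StructureSet(
            "M",
            sset.grid,
            sset.slice_thickness,
            sset.n_slices,
            [
                cc.Structure(
                    st.label,
                    {
                        z: [
                            cc.ContourPolygon(
                                np.column_stack(
                                    [(cols - 1) - p.vertices[:, 0], p.vertices[:, 1]]
                                )
                            )
                            for p in polys
                        ]
                        for z, polys in st.slices.items()
                    },
                )
                for st in sset.structures
            ],
        )
        f = cc.frame_anatomical_brain(sset)
        fm = cc.frame_anatomical_brain(mirrored)
        for x in (60.0, 75.5, 90.0):
            a = apply(f, (x, 30.0), 5).x
            b = apply(fm, ((cols - 1) - x, 30.0), 5).x
            assert b == pytest.approx(-a, abs=1e-9)


class TestEyesBrainstemFrame:
    def test_lateral_extremes_from_eyes(self, rigid_patient):
        sset, _ = rigid_patient
        f = cc.frame_anatomical_eyes_brainstem(sset)
        eye_masks = {}
        for lab in ("Eye_L", "Eye_R"):
            eye_masks.update(
                {(lab, z): m for z, m in cc.rasterize_structure(sset.find(lab), sset.grid).items()}
            )
        cols = [np.nonzero(m)[1] for m in eye_masks.values()]
        assert f.x_ref[0] == min(c.min() for c in cols)
        assert f.x_ref[1] == max(c.max() for c in cols)
        assert apply(f, (f.x_ref[1], 0.0), 0).x == pytest.approx(1.0, abs=1e-12)

    def test_z_extremes_from_eyes_and_brainstem(self, rigid_patient):
        sset, _ = rigid_patient
        f = cc.frame_anatomical_eyes_brainstem(sset)
        idx = (
            sset.find("Eye_L").nonempty_slice_indices()
            + sset.find("Eye_R").nonempty_slice_indices()
            + sset.find("Brainstem").nonempty_slice_indices()
        )
        assert f.z_ref == (min(idx), max(idx))
        assert apply(f, (0.0, 0.0), min(idx)).z == pytest.approx(-1.0, abs=1e-12)

    def test_degenerate_z_span_rejected(self):
        eye = cc.Structure("Eye_L", {5: [_sq := cc.ContourPolygon(np.array([[1.0, 1.0], [5.0, 1.0], [5.0, 5.0], [1.0, 5.0]]))]})
        eye_r = cc.Structure("Eye_R", {5: [_sq]})
        bstem = cc.Structure("Brainstem", {5: [_sq]})
        s = cc.StructureSet("D", (16, 16), 2.5, 10, [eye, eye_r, bstem])
        with pytest.raises(cc.MissingReferenceError):
            cc.frame_anatomical_eyes_brainstem(s)

    def test_missing_eye_names_roi(self, rigid_patient):
        sset, _ = rigid_patient
        pruned = cc.StructureSet(
            sset.patient_id,
            sset.grid,
            sset.slice_thickness,
            sset.n_slices,
            [st for st in sset.structures if st.label != "Eye_R"],
        )
        with pytest.raises(cc.MissingReferenceError, match="Eye_R"):
            cc.frame_anatomical_eyes_brainstem(pruned)


class TestApply:
    def test_unnormalized_identity(self):
        f = cc.frame_unnormalized()
        p = apply(f, (100.0, 200.0), 30)
        assert (p.x, p.y, p.z) == (100.0, 200.0, 30.0)

    @given(
        lam=st.floats(0.0, 1.0),
        ax=st.floats(-50.0, 550.0),
        bx=st.floats(-50.0, 550.0),
    )
    def test_apply_is_affine_per_axis(self, lam, ax, bx):
        f = cc.Frame(Scheme.ANAT_BRAIN, (100.0, 400.0), (50.0, 450.0), (10.0, 90.0), (-1.0, 1.0))
        mix = lam * ax + (1 - lam) * bx
        got = apply(f, (mix, 0.0), 0).x
        want = lam * apply(f, (ax, 0.0), 0).x + (1 - lam) * apply(f, (bx, 0.0), 0).x
        assert got == pytest.approx(want, abs=1e-9)

    def test_frame_serialization_roundtrip(self, rigid_patient):
        sset, _ = rigid_patient
        for scheme in Scheme:
            f = cc.build_frame(scheme, sset)
            assert cc.Frame.from_dict(f.to_dict()) == f

    def test_invalid_reference_ordering_rejected(self):
        with pytest.raises(cc.MissingReferenceError):
            cc.Frame(Scheme.NONANAT, (10.0, 10.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0))
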