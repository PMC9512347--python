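"""Structure-set domain types, JSON round-trips, and the RTSTRUCT adapter."""

import numpy as np
import pytest

import contourclass as cc
from contourclass.model import read_mask_archive, write_mask_archive
from contourclass.rtstruct import GridGeometry, import_rtstruct


class TestVocabulary:
    def test_has_17_distinct_labels(self):
        assert len(cc.VOCAB) == 17
        assert len(set(cc.VOCAB.labels)) == 17

    def test_index_label_bijection(self):
        for i in range(17):
            assert cc.VOCAB.index(cc.VOCAB.label(i)) == i

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            cc.VOCAB.index("Femur_L")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            cc.ClassVocabulary(("Brain", "Brain"))


class TestJsonRoundTrip:
    def test_read_write_identity(self, square_set, tmp_path):
        p = cc.write_structure_set(square_set, tmp_path / "s.json")
        assert cc.read_structure_set(p) == square_set

    def test_write_is_deterministic(self, square_set, tmp_path):
        p1 = cc.write_structure_set(square_set, tmp_path / "a.json")
        p2 = cc.write_structure_set(square_set, tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_structure_list(self, tmp_path):
        s = cc.StructureSet("E", (16, 16), 2.5, 4, [])
        p = cc.write_structure_set(s, tmp_path / "e.json")
        assert cc.read_structure_set(p).structures == []

    def test_unknown_labels_preserved(self, square_set, tmp_path):
        p = cc.write_structure_set(square_set, tmp_path / "s.json")
        assert cc.read_structure_set(p).structures[1].label == "odd name"

    def test_phantom_roundtrip(self, small_cohort, tmp_path):
        s = small_cohort.structure_sets[0]
        p = cc.write_structure_set(s, tmp_path / "p.json")
        back = cc.read_structure_set(p)
        assert back == s
        assert len(back.structures) == 17

    def test_malformed_json_names_field(self, tmp_path):
        f = tmp_path / "bad.json"
        f.write_text('{"patient_id": "x"}')
        with pytest.raises(cc.ParseError, match="grid"):
            cc.read_structure_set(f)


class TestValidation:
    def test_slice_out_of_range_rejected(self, square_set, tmp_path):
        square_set.structures[0].slices[99] = square_set.structures[0].slices[3]
        with pytest.raises(cc.ValidationError, match="slice 99"):
            square_set.validate()

    @pytest.mark.parametrize(
        "field,value",
        [("grid", (0, 32)), ("slice_thickness", 0.0), ("n_slices", 0)],
    )
    def test_bad_scalars_rejected(self, field, value):
        s = cc.StructureSet("X", (32, 32), 2.5, 10, [])
        setattr(s, field, value)
        with pytest.raises(cc.ValidationError):
            s.validate()

    def test_nonfinite_vertices_rejected(self):
        with pytest.raises(cc.ValidationError):
            cc.ContourPolygon(np.array([[0.0, 0.0], [1.0, np.nan], [1.0, 1.0]]))


class TestMaskArchive:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        masks = {
            (0, 4): (rng.random((16, 16)) > 0.5).astype(np.uint8),
            (2, 7): np.ones((16, 16), dtype=np.uint8),
        }
        p = write_mask_archive(masks, tmp_path / "m.npz")
        back = read_mask_archive(p)
        assert set(back) == set(masks)
        for k in masks:
            np.testing.assert_array_equal(back[k], masks[k])


class TestRtstructImport:
    @staticmethod
    def _build_rtstruct(rois):
        """Synthetic in-memory RTSTRUCT with the given {name: (z_mm, pts)}."""
        from pydicom.dataset import Dataset

        ds = Dataset()
        ds.PatientID = "RT1"
        ds.StructureSetROISequence = []
        ds.ROIContourSequence = []
        for num, (name, contours) in enumerate(rois.items(), start=1):
            roi = Dataset()
            roi.ROINumber = num
            roi.ROIName = name
            ds.StructureSetROISequence.append(roi)
            rc = Dataset()
            rc.ReferencedROINumber = num
            rc.ContourSequence = []
            for z_mm, pts in contours:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.ContourData = [v for (x, y) in pts for v in (x, y, z_mm)]
                rc.ContourSequence.append(c)
            ds.ROIContourSequence.append(rc)
        return ds

    @staticmethod
    def _write(ds, path):
        import pydicom
        from pydicom.uid import ImplicitVRLittleEndian

        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ImplicitVRLittleEndian
        pydicom.dcmwrite(str(path), ds, enforce_file_format=False)

    def test_square_roi_identity_geometry(self, tmp_path):
        # spacing 1 mm, origin 0: patient coords equal pixel coords
        pts = [(10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)]
        ds = self._build_rtstruct({"Brain": [(5.0, pts)]})
        f = tmp_path / "rt.dcm"
        self._write(ds, f)
        geo = GridGeometry((0, 0, 0), (1.0, 1.0), 2.5, (64, 64), 20)
        sset = import_rtstruct(f, geo)
        assert len(sset.structures) == 1
        st = sset.structures[0]
        assert st.label == "Brain"
        assert list(st.slices) == [2]  # z=5mm / 2.5mm
        np.testing.assert_allclose(st.slices[2][0].vertices, np.array(pts))

    def test_mm_to_pixel_scaling(self, tmp_path):
        pts = [(10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)]
        ds = self._build_rtstruct({"R": [(0.0, pts)]})
        f = tmp_path / "rt.dcm"
        self._write(ds, f)
        geo = GridGeometry((-5.0, -5.0, 0.0), (2.0, 2.0), 2.5, (64, 64), 20)
        sset = import_rtstruct(f, geo)
        v = sset.structures[0].slices[0][0].vertices
        np.testing.assert_allclose(v[0], [(10 + 5) / 2, (10 + 5) / 2])

    def test_zero_rois_gives_empty_set(self, tmp_path):
        ds = self._build_rtstruct({})
        f = tmp_path / "rt.dcm"
        self._write(ds, f)
        geo = GridGeometry((0, 0, 0), (1, 1), 2.5, (64, 64), 20)
        assert import_rtstruct(f, geo).structures == []

    def test_non_axial_contour_rejected(self, tmp_path):
        from pydicom.dataset import Dataset

        ds = self._build_rtstruct({"X": []})
        rc = ds.ROIContourSequence[0]
        c = Dataset()
        c.ContourGeometricType = "CLOSED_PLANAR"
        c.ContourData = [0, 0, 0, 10, 0, 5, 10, 10, 0]  # z varies
        rc.ContourSequence = [c]
        f = tmp_path / "rt.dcm"
        self._write(ds, f)
        geo = GridGeometry((0, 0, 0), (1, 1), 2.5, (64, 64), 20)
        with pytest.raises(cc.ParseError, match="non-axial"):
            import_rtstruct(f, geo)
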