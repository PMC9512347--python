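"""Seeded synthetic head-and-neck phantom generator.

Produces labeled structure sets with the geometric regularities the
classifiers rely on: 17 organs at risk built from geometric primitives
(spheres, ellipsoids, elliptic tubes), placed at anatomically plausible
relative positions with left/right mirror symmetry for paired organs, and
per-organ axial extents that reproduce the characteristic ordering of organ
slice counts in clinical head-and-neck structure sets (brain > spinal cord >
esophagus > brainstem >> lenses/pituitary > cochleae).

Randomness is explicit and fully seeded: a patient is a jittered realization
of the organ templates (global head scale, global positioning shift, and
independent per-organ position/scale jitter, all uniform with documented
bounds so organs provably stay inside the grid).  Identical (spec, seed)
pairs generate identical cohorts.

The generator can also emit "raw label" variants — messy non-standard names
for each organ — to exercise the classification use case end to end, since
the whole point of contour classification is that input labels are
unreliable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ContourPolygon, Structure, StructureSet
from .vocabulary import VOCAB, ClassVocabulary


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class OrganTemplate:
    """One organ's primitive: an ellipsoid or elliptic tube in fractional
    head coordinates.

    ``fx, fy`` — center as fractions of (n_cols-1, n_rows-1); ``rx, ry`` —
    in-plane semi-axes as fractions of the grid; ``z_lo_f, z_hi_f`` — axial
    extent as fractions of (n_slices-1).  ``tube`` keeps the cross-section
    constant along z; otherwise the in-plane radii taper as an ellipsoid.
    """

    name: str
    fx: float
    fy: float
    rx: float
    ry: float
    z_lo_f: float
    z_hi_f: float
    tube: bool = False


def _mirror(t: OrganTemplate, name: str) -> OrganTemplate:
    return replace(t, name=name, fx=1.0 - t.fx)


def default_templates() -> dict[str, OrganTemplate]:
    """Default 17-organ template set (paired organs mirrored about midline)."""
    lefts = [
        OrganTemplate("Brain", 0.50, 0.47, 0.300, 0.360, 0.40, 0.90),
        OrganTemplate("SpinalCord", 0.50, 0.62, 0.035, 0.035, 0.04, 0.45, tube=True),
        OrganTemplate("Esophagus", 0.47, 0.55, 0.040, 0.030, 0.04, 0.38, tube=True),
        OrganTemplate("Brainstem", 0.50, 0.55, 0.045, 0.050, 0.42, 0.64, tube=True),
        OrganTemplate("Larynx", 0.50, 0.48, 0.090, 0.070, 0.10, 0.24, tube=True),
        OrganTemplate("Parotid_L", 0.70, 0.52, 0.070, 0.090, 0.46, 0.62),
        OrganTemplate("Eye_L", 0.63, 0.30, 0.055, 0.055, 0.70, 0.80),
        OrganTemplate("OpticNerve_L", 0.57, 0.38, 0.020, 0.020, 0.72, 0.78, tube=True),
        OrganTemplate("Lens_L", 0.63, 0.255, 0.018, 0.018, 0.735, 0.765),
        OrganTemplate("Chiasm", 0.50, 0.42, 0.050, 0.020, 0.73, 0.76),
        OrganTemplate("Pituitary", 0.50, 0.45, 0.020, 0.020, 0.695, 0.73),
        OrganTemplate("Cochlea_L", 0.68, 0.55, 0.015, 0.015, 0.657, 0.670),
    ]
    out = {t.name: t for t in lefts}
    for left, right in [
        ("Parotid_L", "Parotid_R"),
        ("Eye_L", "Eye_R"),
        ("OpticNerve_L", "OpticNerve_R"),
        ("Lens_L", "Lens_R"),
        ("Cochlea_L", "Cochlea_R"),
    ]:
        out[right] = _mirror(out[left], right)
    return out


#: Messy real-world-style label variants, for the mislabeled-input use case.
RAW_LABEL_VARIANTS: dict[str, tuple[str, ...]] = {
    "Eye_L": ("L Eye", "EYE_LT", "lt orbit"),
    "Eye_R": ("R Eye", "EYE_RT", "rt orbit"),
    "Cochlea_L": ("L Cochlea", "cochlea left"),
    "Cochlea_R": ("R Cochlea", "cochlea right"),
    "Larynx": ("larynx", "LARYNX_PTV"),
    "Lens_L": ("L Lens", "lens lt"),
    "Lens_R": ("R Lens", "lens rt"),
    "Chiasm": ("optic chiasm", "CHIASM"),
    "OpticNerve_L": ("L Optic Nerve", "opt nrv l"),
    "OpticNerve_R": ("R Optic Nerve", "opt nrv r"),
    "Brainstem": ("Brain Stem", "BSTEM"),
    "Brain": ("brain", "WHOLE BRAIN"),
    "Esophagus": ("esophagus", "ESO"),
    "SpinalCord": ("Spinal Cord", "cord", "SC"),
    "Parotid_L": ("Left Parotid", "Parotidl"),
    "Parotid_R": ("Right Parotid", "Parotidr"),
    "Pituitary": ("pituitary gland", "PIT"),
}


@dataclass
class PhantomSpec:
    """Generation parameters for one synthetic cohort.

    Defaults: 128x128 grid (configurable up to 512x512), 2.5 mm slices, 64
    axial slices, uniform jitter bounds chosen so every organ provably stays
    inside the grid.
    """

    grid: tuple[int, int] = (128, 128)
    slice_thickness: float = 2.5
    n_slices: int = 64
    templates: dict[str, OrganTemplate] = field(default_factory=default_templates)
    #: uniform in-plane center jitter, pixels (per organ, each axis).  Kept
    #: small relative to the global head transform: adjacent organs move
    #: together in real anatomy, so independent per-organ displacement is a
    #: minor effect compared with head size/positioning variance.
    xy_jitter: float = 1.0
    #: integer axial shift per organ, slices (uniform on [-z_jitter, z_jitter])
    z_jitter: int = 1
    #: per-organ in-plane scale factor, uniform on [1-s, 1+s]
    scale_jitter: float = 0.08
    #: global head scale about grid center, uniform on [1-s, 1+s]
    head_scale_jitter: float = 0.05
    #: global in-plane positioning shift, pixels
    head_xy_shift: float = 4.0
    #: global axial positioning shift, slices (integer)
    head_z_shift: int = 2
    #: per-slice contour jitter, pixels (hand-drawn contours vary slice to slice)
    slice_xy_jitter: float = 0.6
    #: per-slice in-plane scale factor, uniform on [1-s, 1+s]
    slice_scale_jitter: float = 0.08
    #: axial drift amplitude for tubular organs, pixels (organs curve through
    #: the neck rather than running straight)
    drift_amp: float = 2.0
    #: minimum in-plane polygon radius, pixels (guarantees nonempty masks)
    min_radius_px: float = 1.2
    #: vertices per contour polygon
    n_vertices: int = 24
    vocab: ClassVocabulary = field(default_factory=lambda: VOCAB)

    def validate(self) -> "PhantomSpec":
        missing = [lab for lab in self.vocab.labels if lab not in self.templates]
        if missing:
            raise GenerationError(f"templates missing for organs: {missing}")
        return self


@dataclass
class PhantomCohort:
    """A generated cohort: structure sets plus ground truth.

    ``truth`` maps (patient_id, structure index within the set) to the
    TG-263 class name; ``manifest`` tabulates what was generated.
    """

    structure_sets: list[StructureSet]
    truth: dict[tuple[str, int], str]
    manifest: pd.DataFrame

    def split(self, train_fraction: float, seed: int):
        """Seeded patient-level split into (train, test) cohorts."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.structure_sets))
        n_train = int(round(train_fraction * len(order)))
        return self.subset(order[:n_train]), self.subset(order[n_train:])

    def subset(self, indices) -> "PhantomCohort":
        sets = [self.structure_sets[i] for i in indices]
        ids = {s.patient_id for s in sets}
        truth = {k: v for k, v in self.truth.items() if k[0] in ids}
        manifest = self.manifest[self.manifest.patient_id.isin(ids)].reset_index(
            drop=True
        )
        return PhantomCohort(sets, truth, manifest)


def _ellipse_polygon(
    cx: float, cy: float, rx: float, ry: float, n: int
) -> ContourPolygon:
    theta = 2.0 * np.pi * np.arange(n) / n
    verts = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
    return ContourPolygon(verts)


def _realize_organ(
    t: OrganTemplate,
    spec: PhantomSpec,
    head_scale: float,
    head_dx: float,
    head_dy: float,
    head_dz: int,
    rng: np.random.Generator,
) -> Structure:
    rows, cols = spec.grid
    cx0, cy0 = (cols - 1) / 2.0, (rows - 1) / 2.0

    # global head transform (scale about grid center + shift), then organ jitter
    cx = cx0 + head_scale * (t.fx * (cols - 1) - cx0) + head_dx
    cy = cy0 + head_scale * (t.fy * (rows - 1) - cy0) + head_dy
    cx += rng.uniform(-spec.xy_jitter, spec.xy_jitter)
    cy += rng.uniform(-spec.xy_jitter, spec.xy_jitter)
    s = head_scale * rng.uniform(1 - spec.scale_jitter, 1 + spec.scale_jitter)
    rx = t.rx * (cols - 1) * s
    ry = t.ry * (rows - 1) * s

    z_lo = int(round(t.z_lo_f * (spec.n_slices - 1)))
    z_hi = int(round(t.z_hi_f * (spec.n_slices - 1)))
    dz = head_dz + int(rng.integers(-spec.z_jitter, spec.z_jitter + 1))
    z_lo, z_hi = z_lo + dz, z_hi + dz
    if z_lo < 0 or z_hi >= spec.n_slices:
        raise GenerationError(
            f"organ {t.name!r} axial extent [{z_lo}, {z_hi}] leaves the "
            f"slice range [0, {spec.n_slices})"
        )

    zc, rz = (z_lo + z_hi) / 2.0, max((z_hi - z_lo) / 2.0, 0.5)
    # tubular organs wander slowly along z (e.g. the esophagus curving
    # through the neck); the drift is a seeded sinusoid per organ
    if t.tube and spec.drift_amp > 0:
        amp_x = rng.uniform(0, spec.drift_amp)
        amp_y = rng.uniform(0, spec.drift_amp)
        phase_x = rng.uniform(0, 2 * np.pi)
        phase_y = rng.uniform(0, 2 * np.pi)
    else:
        amp_x = amp_y = phase_x = phase_y = 0.0
    span = max(z_hi - z_lo, 1)

    slices: dict[int, list[ContourPolygon]] = {}
    for z in range(z_lo, z_hi + 1):
        if t.tube:
            taper = 1.0
        else:
            taper = float(np.sqrt(max(0.0, 1.0 - ((z - zc) / rz) ** 2)))
        u = 2 * np.pi * (z - z_lo) / span
        czx = cx + amp_x * np.sin(u + phase_x)
        czy = cy + amp_y * np.sin(u + phase_y)
        czx += rng.uniform(-spec.slice_xy_jitter, spec.slice_xy_jitter)
        czy += rng.uniform(-spec.slice_xy_jitter, spec.slice_xy_jitter)
        sz = rng.uniform(1 - spec.slice_scale_jitter, 1 + spec.slice_scale_jitter)
        rxz = max(rx * taper * sz, spec.min_radius_px)
        ryz = max(ry * taper * sz, spec.min_radius_px)
        if not (
            0 <= czx - rxz and czx + rxz <= cols - 1 and 0 <= czy - ryz and czy + ryz <= rows - 1
        ):
            raise GenerationError(
                f"organ {t.name!r} extends outside the {rows}x{cols} grid "
                f"on slice {z}"
            )
        slices[z] = [_ellipse_polygon(czx, czy, rxz, ryz, spec.n_vertices)]
    return Structure(label=t.name, slices=slices)


def generate_patient(
    spec: PhantomSpec,
    rng: np.random.Generator,
    patient_id: str = "P0",
    raw_labels: bool = False,
) -> tuple[StructureSet, dict[int, str]]:
    """One jittered phantom patient; returns the set and structure-index truth.

    Structures are emitted in vocabulary order.  With ``raw_labels`` the
    emitted label is a messy variant while the truth map keeps the TG-263
    name.
    """
    spec.validate()
    head_scale = rng.uniform(1 - spec.head_scale_jitter, 1 + spec.head_scale_jitter)
    head_dx = rng.uniform(-spec.head_xy_shift, spec.head_xy_shift)
    head_dy = rng.uniform(-spec.head_xy_shift, spec.head_xy_shift)
    head_dz = int(rng.integers(-spec.head_z_shift, spec.head_z_shift + 1))

    structures: list[Structure] = []
    truth: dict[int, str] = {}
    for i, name in enumerate(spec.vocab.labels):
        st = _realize_organ(
            spec.templates[name], spec, head_scale, head_dx, head_dy, head_dz, rng
        )
        if raw_labels:
            variants = RAW_LABEL_VARIANTS.get(name, (name,))
            st.label = str(variants[int(rng.integers(len(variants)))])
        structures.append(st)
        truth[i] = name

    sset = StructureSet(
        patient_id=patient_id,
        grid=spec.grid,
        slice_thickness=spec.slice_thickness,
        n_slices=spec.n_slices,
        structures=structures,
    ).validate()
    return sset, truth


def generate_cohort(
    spec: PhantomSpec,
    n_patients: int,
    seed: int,
    raw_labels: bool = False,
) -> PhantomCohort:
    """Generate ``n_patients`` independent phantoms from a seeded stream."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    spec.validate()
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    sets: list[StructureSet] = []
    truth: dict[tuple[str, int], str] = {}
    rows = []
    for p, ss in enumerate(streams):
        pid = f"P{p:04d}"
        rng = np.random.default_rng(ss)
        sset, pt_truth = generate_patient(spec, rng, patient_id=pid, raw_labels=raw_labels)
        sets.append(sset)
        for i, lab in pt_truth.items():
            truth[(pid, i)] = lab
            st = sset.structures[i]
            idxs = st.nonempty_slice_indices()
            rows.append(
                {
                    "patient_id": pid,
                    "structure_index": i,
                    "label_raw": st.label,
                    "tg263_label": lab,
                    "slice_count": st.slice_count,
                    "z_lo": idxs[0],
                    "z_hi": idxs[-1],
                }
            )
    return PhantomCohort(sets, truth, pd.DataFrame(rows))


def save_cohort(cohort: PhantomCohort, out_dir) -> None:
    """Write one JSON structure-set file per patient plus ``truth.csv``."""
    from pathlib import Path

    from .model import write_structure_set

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sset in cohort.structure_sets:
        write_structure_set(sset, out / f"{sset.patient_id}.json")
    cohort.manifest.to_csv(out / "truth.csv", index=False)


def load_cohort(in_dir) -> PhantomCohort:
    """Read a cohort directory written by :func:`save_cohort`."""
    from pathlib import Path

    from .model import read_structure_set

    d = Path(in_dir)
    manifest = pd.read_csv(d / "truth.csv")
    sets = [read_structure_set(p) for p in sorted(d.glob("*.json"))]
    truth = {
        (r.patient_id, int(r.structure_index)): r.tg263_label
        for r in manifest.itertuples()
    }
    return PhantomCohort(sets, truth, manifest)


def drop_slice(s: Structure, slice_index: int) -> Structure:
    """Copy of ``s`` with one slice's polygons removed.

    Dropping the only slice leaves a valid empty structure.  An absent index
    is an error.
    """
    if slice_index not in s.slices:
        raise KeyError(f"structure {s.label!r} has no slice {slice_index}")
    out = copy.deepcopy(s)
    del out.slices[slice_index]
    return out
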