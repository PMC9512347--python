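"""The three classifier families: position-only, segment-only, combined.

The unit of classification is a :class:`SliceSample`: a 3-channel binary
mask stack (channel 1 — "green" — the slice to classify, channel 0 —
"red" — the preceding slice, channel 2 — "blue" — the succeeding slice,
zeros where a neighbour does not exist), the normalized center of mass of
the green channel, and the parent structure's total slice count.

* POSITION nets see only the normalized coordinates (2-D or 3-D), with an
  optional 32-node hidden layer.
* SEGMENT nets see only the mask stack, through a convolutional backbone
  whose classification layer is replaced by a hidden layer plus a
  17-way output.
* COMBINED nets concatenate the backbone features with
  ``(x, y, z, n_slices)`` and pass them through dropout -> 64-node hidden
  layer -> dropout -> output, the configuration that wins on clinical data.

The backbone contract is any map from a (B, 3, H, W) stack to a fixed-length
feature vector.  The built-in desk-scale backbone is a small four-block
strided convolutional net trained from scratch, grid-size agnostic via a
fixed input pooling and global average pooling.  Training is plain SGD with
per-epoch learning-rate decay and class-weighted cross-entropy; the
train/validation split is at patient level, so no patient contributes to
both groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .model import StructureSet
from .normalize import Frame, NormalizedPosition, Scheme, apply, build_frame
from .phantom import PhantomCohort
from .rasterize import center_of_mass, rasterize_structure
from .vocabulary import VOCAB, ClassVocabulary

log = logging.getLogger(__name__)


class Family(str, Enum):
    POSITION = "POSITION"
    SEGMENT = "SEGMENT"
    COMBINED = "COMBINED"


@dataclass
class SliceSample:
    """One classifiable slice of one structure."""

    channels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (red, green, blue)
    position: NormalizedPosition
    n_slices_feature: int
    label: int | None
    patient_id: str
    structure_index: int
    slice_index: int

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError(f"channel grids differ: {shapes}")
        if not self.channels[1].any():
            raise ValueError("center (green) channel must be nonempty")
        if self.n_slices_feature < 1:
            raise ValueError("n_slices_feature must be >= 1")

    @property
    def grid(self) -> tuple[int, int]:
        return self.channels[1].shape


@dataclass(frozen=True)
class Prediction:
    """A 17-class probability vector and its argmax."""

    probs: np.ndarray
    argmax: int

    def __post_init__(self) -> None:
        if abs(float(self.probs.sum()) - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture selector for one classifier."""

    name: str
    family: Family
    frame_scheme: Scheme
    position_dims: int = 3  # 2 -> (x, y); 3 -> (x, y, z)
    hidden_nodes: int = 64
    multi_slice: bool = True
    backbone: str | None = "small-conv"

    def validate(self) -> "NetworkSpec":
        if self.family is Family.POSITION:
            if self.hidden_nodes not in (0, 32):
                raise ValueError("POSITION nets use hidden_nodes in {0, 32}")
            if self.position_dims not in (2, 3):
                raise ValueError("position_dims must be 2 or 3")
        else:
            if not self.backbone:
                raise ValueError(f"{self.family.value} nets require a backbone")
        if self.family is Family.COMBINED and self.hidden_nodes != 64:
            raise ValueError("COMBINED nets use the 64-node hidden layer")
        return self

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "family": self.family.value,
            "frame_scheme": self.frame_scheme.value,
            "position_dims": self.position_dims,
            "hidden_nodes": self.hidden_nodes,
            "multi_slice": self.multi_slice,
            "backbone": self.backbone,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            name=d["name"],
            family=Family(d["family"]),
            frame_scheme=Scheme(d["frame_scheme"]),
            position_dims=d["position_dims"],
            hidden_nodes=d["hidden_nodes"],
            multi_slice=d["multi_slice"],
            backbone=d["backbone"],
        ).validate()


#: Named network configurations (the standard ablation ladder).  The
#: voting-mode names (CNV, CAV-B, CAV-E) denote the same trained networks as
#: their slice-mode counterparts, evaluated after vote aggregation.
NETWORKS: dict[str, NetworkSpec] = {
    s.name: s.validate()
    for s in [
        NetworkSpec("PU", Family.POSITION, Scheme.UNNORM, 2, 0, False, None),
        NetworkSpec("PU-32", Family.POSITION, Scheme.UNNORM, 2, 32, False, None),
        NetworkSpec("PN", Family.POSITION, Scheme.NONANAT, 2, 0, False, None),
        NetworkSpec("PN-32", Family.POSITION, Scheme.NONANAT, 2, 32, False, None),
        NetworkSpec("PN-32Z", Family.POSITION, Scheme.NONANAT, 3, 32, False, None),
        NetworkSpec("PA-32Z", Family.POSITION, Scheme.ANAT_BRAIN, 3, 32, False, None),
        NetworkSpec("SS", Family.SEGMENT, Scheme.NONANAT, 3, 64, False),
        NetworkSpec("SM", Family.SEGMENT, Scheme.NONANAT, 3, 64, True),
        NetworkSpec("CNS", Family.COMBINED, Scheme.NONANAT),
        NetworkSpec("CAS-B", Family.COMBINED, Scheme.ANAT_BRAIN),
        NetworkSpec("CAS-E", Family.COMBINED, Scheme.ANAT_EYES_BSTEM),
    ]
}

VOTING_ALIASES = {"CNV": "CNS", "CAV-B": "CAS-B", "CAV-E": "CAS-E"}


def resolve_network(name: str) -> NetworkSpec:
    return NETWORKS[VOTING_ALIASES.get(name, name)]


@dataclass
class TrainConfig:
    """Training hyperparameters (the tuned clinical-run values by default)."""

    batch_size: int = 12
    learning_rate: float = 0.1
    lr_decay: float = 0.5
    weight_decay: float = 0.0
    dropout1: float = 0.6  # concatenated features -> hidden layer
    dropout2: float = 0.2  # hidden layer -> output
    hidden: int = 64
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Cochlea_L": 10.0,
            "Cochlea_R": 10.0,
            "Pituitary": 10.0,
        }
    )
    epochs: int = 5
    split_fraction: float = 0.8
    seed: int = 0

    def weight_vector(self, vocab: ClassVocabulary) -> np.ndarray:
        return np.array([self.class_weights.get(lab, 1.0) for lab in vocab.labels])

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "lr_decay": self.lr_decay,
            "weight_decay": self.weight_decay,
            "dropout1": self.dropout1,
            "dropout2": self.dropout2,
            "hidden": self.hidden,
            "class_weights": dict(self.class_weights),
            "epochs": self.epochs,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Sample construction
# ---------------------------------------------------------------------------


def make_samples(
    s: StructureSet,
    frame: Frame,
    multi_slice: bool,
    labels: dict[int, int] | None = None,
) -> list[SliceSample]:
    """One sample per (structure, nonempty slice) of a structure set.

    ``labels`` maps structure index -> class index; unlabeled structures get
    ``label=None``.  In single-slice mode the red and blue channels are
    all-zero; in multi-slice mode they hold the structure's adjacent slices
    where those exist.  Empty structures yield no samples.
    """
    out: list[SliceSample] = []
    zeros = np.zeros(s.grid, dtype=np.uint8)
    for i, st in enumerate(s.structures):
        masks = rasterize_structure(st, s.grid)
        if not masks:
            log.warning(
                "structure %r of patient %s has no rasterizable slice; skipped",
                st.label,
                s.patient_id,
            )
            continue
        n_feat = st.slice_count
        lab = labels.get(i) if labels else None
        for z, green in masks.items():
            if multi_slice:
                red = masks.get(z - 1, zeros)
                blue = masks.get(z + 1, zeros)
            else:
                red = blue = zeros
            com = center_of_mass(green)
            out.append(
                SliceSample(
                    channels=(red, green, blue),
                    position=apply(frame, com, z),
                    n_slices_feature=n_feat,
                    label=lab,
                    patient_id=s.patient_id,
                    structure_index=i,
                    slice_index=z,
                )
            )
    return out


def cohort_samples(
    cohort: PhantomCohort,
    scheme: Scheme | str,
    multi_slice: bool,
    vocab: ClassVocabulary = VOCAB,
) -> list[SliceSample]:
    """Labeled samples for a whole cohort, one frame per patient."""
    samples: list[SliceSample] = []
    for sset in cohort.structure_sets:
        frame = build_frame(scheme, sset)
        labels = {
            i: vocab.index(lab)
            for (pid, i), lab in cohort.truth.items()
            if pid == sset.patient_id
        }
        samples.extend(make_samples(sset, frame, multi_slice, labels))
    return samples


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


#: Fixed standardization of the slice-count input to the combined head: the
#: count stays linear in ROI length but is scaled so typical values (2-60
#: slices) share the O(1) dynamic range of the normalized coordinates —
#: otherwise its gradients dominate the concatenated feature vector.
N_SLICES_SCALE = 1.0 / 32.0


class SmallConvBackbone(nn.Module):
    """Desk-scale backbone: fixed input pooling to <=32 px, four 3x3
    stride-2 conv blocks, global moment pooling.  Output: 192 features
    (per-channel mean activation plus first spatial moments, so the
    features keep coarse frame position as a deep full-frame backbone
    would)."""

    channels = (8, 16, 32, 64)
    pool_to = 32

    def __init__(self, grid: tuple[int, int], rng: np.random.Generator):
        h, w = grid
        factor = max(1, h // self.pool_to)
        if h != w or (factor > 1 and h % self.pool_to):
            raise ValueError(f"backbone expects a square grid divisible by {self.pool_to}, got {grid}")
        layers: list[nn.Module] = [nn.AvgPool2d(factor)]
        c_in = 3
        for c_out in self.channels:
            layers += [nn.Conv2d(c_in, c_out, rng, stride=2), nn.ReLU()]
            c_in = c_out
        layers.append(nn.GlobalMomentPool())
        self.net = nn.Sequential(*layers)
        self.out_features = 3 * self.channels[-1]

    def parameters(self):
        return self.net.parameters()

    def forward(self, x, train=False):
        return self.net.forward(np.asarray(x, dtype=np.float64), train=train)

    def backward(self, dout):
        return self.net.backward(dout)


class ClassifierModel:
    """A classifier of any family, with batch assembly and prediction."""

    def __init__(
        self,
        spec: NetworkSpec,
        vocab: ClassVocabulary,
        cfg: TrainConfig,
        grid: tuple[int, int],
        seed: int,
    ):
        spec.validate()
        self.spec = spec
        self.vocab = vocab
        self.cfg = cfg
        self.grid = tuple(grid)
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n_classes = len(vocab)

        self.backbone: SmallConvBackbone | None = None
        if spec.family is Family.POSITION:
            if spec.hidden_nodes:
                self.head = nn.Sequential(
                    nn.Linear(spec.position_dims, spec.hidden_nodes, rng),
                    nn.ReLU(),
                    nn.Linear(spec.hidden_nodes, n_classes, rng),
                )
            else:
                self.head = nn.Sequential(nn.Linear(spec.position_dims, n_classes, rng))
        elif spec.family is Family.SEGMENT:
            # the two dropouts are defined positionally (backbone output ->
            # hidden, hidden -> output); segment heads have the same
            # junctions, so they get the same dropouts as the combined head
            self.backbone = SmallConvBackbone(self.grid, rng)
            self.head = nn.Sequential(
                nn.Dropout(cfg.dropout1, rng),
                nn.Linear(self.backbone.out_features, spec.hidden_nodes, rng),
                nn.ReLU(),
                nn.Dropout(cfg.dropout2, rng),
                nn.Linear(spec.hidden_nodes, n_classes, rng),
            )
        else:  # COMBINED
            self.backbone = SmallConvBackbone(self.grid, rng)
            self._aux_dim = 4  # x, y, z, n_slices
            self.head = nn.Sequential(
                nn.Dropout(cfg.dropout1, rng),
                nn.Linear(self.backbone.out_features + self._aux_dim, cfg.hidden, rng),
                nn.ReLU(),
                nn.Linear(cfg.hidden, n_classes, rng),
            )
            # dropout2 sits between hidden and output
            self.head.layers.insert(3, nn.Dropout(cfg.dropout2, rng))

    # -- plumbing ----------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        out = [] if self.backbone is None else list(self.backbone.parameters())
        return out + self.head.parameters()

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def _aux(self, samples: list[SliceSample]) -> np.ndarray:
        if self.spec.family is Family.POSITION:
            cols = [[s.position.x, s.position.y, s.position.z][: self.spec.position_dims] for s in samples]
        else:
            cols = [
                [
                    s.position.x,
                    s.position.y,
                    s.position.z,
                    s.n_slices_feature * N_SLICES_SCALE,
                ]
                for s in samples
            ]
        return np.asarray(cols, dtype=float)

    def _images(self, samples: list[SliceSample]) -> np.ndarray:
        for s in samples:
            if s.grid != self.grid:
                raise ValueError(
                    f"sample grid {s.grid} does not match model grid {self.grid}"
                )
        return np.stack([np.stack(s.channels) for s in samples]).astype(np.float64)

    # -- forward/backward --------------------------------------------------

    def forward(self, samples: list[SliceSample], train: bool = False) -> np.ndarray:
        """Logits for a batch of samples."""
        if self.spec.family is Family.POSITION:
            return self.head.forward(self._aux(samples), train=train)
        feats = self.backbone.forward(self._images(samples), train=train)
        if self.spec.family is Family.SEGMENT:
            return self.head.forward(feats, train=train)
        x = np.concatenate([feats, self._aux(samples)], axis=1)
        return self.head.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        if self.spec.family is Family.POSITION:
            return
        if self.spec.family is Family.COMBINED:
            dx = dx[:, : self.backbone.out_features]
        self.backbone.backward(dx)

    # -- prediction --------------------------------------------------------

    def predict_batch(self, samples: list[SliceSample]) -> list[Prediction]:
        """Deterministic eval-mode predictions (dropout disabled)."""
        preds: list[Prediction] = []
        for i in range(0, len(samples), 64):
            chunk = samples[i : i + 64]
            probs = nn.softmax(self.forward(chunk, train=False))
            preds.extend(
                Prediction(probs=p, argmax=int(p.argmax())) for p in probs
            )
        return preds

    def predict_slice(self, sample: SliceSample) -> Prediction:
        return self.predict_batch([sample])[0]


def build_network(
    spec: NetworkSpec | str,
    vocab: ClassVocabulary = VOCAB,
    cfg: TrainConfig | None = None,
    grid: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> ClassifierModel:
    """Construct a seeded, untrained classifier from a spec or Table-2 name."""
    if isinstance(spec, str):
        spec = resolve_network(spec)
    return ClassifierModel(spec, vocab, cfg or TrainConfig(), grid, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def patient_split(
    samples: list[SliceSample], fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Seeded patient-level split of sample indices (no patient in both)."""
    patients = sorted({s.patient_id for s in samples})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B117]))
    order = rng.permutation(len(patients))
    n_train = int(round(fraction * len(patients)))
    train_p = {patients[i] for i in order[:n_train]}
    tr = [i for i, s in enumerate(samples) if s.patient_id in train_p]
    va = [i for i, s in enumerate(samples) if s.patient_id not in train_p]
    return tr, va


def _accuracy(model: ClassifierModel, samples: list[SliceSample]) -> float:
    if not samples:
        return float("nan")
    preds = model.predict_batch(samples)
    hits = sum(p.argmax == s.label for p, s in zip(preds, samples))
    return hits / len(samples)


def train(
    model: ClassifierModel,
    samples: list[SliceSample],
    cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train in place; returns the per-epoch history.

    Class-weighted cross-entropy, plain SGD, learning rate multiplied by
    ``lr_decay`` after each epoch, seeded patient-level 80/20 split.
    History columns: epoch, lr, train_total_acc (running, over the epoch's
    weight updates), val_total_acc.
    """
    cfg = cfg or model.cfg
    labeled = [s for s in samples if s.label is not None]
    if not labeled:
        raise ValueError("no labeled samples to train on")
    if len({s.label for s in labeled}) < 2:
        raise ValueError("training requires samples from at least 2 classes")

    tr_idx, va_idx = patient_split(labeled, cfg.split_fraction, cfg.seed)
    train_set = [labeled[i] for i in tr_idx]
    val_set = [labeled[i] for i in va_idx]
    weights = cfg.weight_vector(model.vocab)
    opt = nn.SGD(model.parameters(), cfg.learning_rate, cfg.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xE90C4]))

    rows = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(train_set))
        hits = 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[lo : lo + cfg.batch_size]]
            y = np.array([s.label for s in batch])
            logits = model.forward(batch, train=True)
            loss, dlogits = nn.weighted_cross_entropy(logits, y, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {lo} "
                    f"(lr={opt.lr:g}); training aborted"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            hits += int((logits.argmax(axis=1) == y).sum())
        rows.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_total_acc": hits / len(train_set),
                "val_total_acc": _accuracy(model, val_set),
            }
        )
        opt.lr *= cfg.lr_decay
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: ClassifierModel, path: str | Path) -> Path:
    """Single-archive bundle: parameters + spec + config + vocabulary + grid."""
    path = Path(path)
    meta = {
        "network": model.spec.to_dict(),
        "train_config": model.cfg.to_dict(),
        "vocab": list(model.vocab.labels),
        "grid": list(model.grid),
        "seed": model.seed,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    with open(path, "wb") as f:
        np.savez_compressed(f, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> ClassifierModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        spec = NetworkSpec.from_dict(meta["network"])
        cfgd = dict(meta["train_config"])
        cfg = TrainConfig(**cfgd)
        vocab = ClassVocabulary(tuple(meta["vocab"]))
        model = ClassifierModel(spec, vocab, cfg, tuple(meta["grid"]), meta["seed"])
        for i, p in enumerate(model.parameters()):
            p.value[...] = z[f"param_{i}"]
    return model
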