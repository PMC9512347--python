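"""First-past-the-post aggregation of per-slice predictions.

Each classified slice of a structure casts one vote — the argmax class of
its prediction — and the structure receives the label with the most votes.
A tied maximum is reported as ``TIE`` and never broken (by probability mass
or otherwise): ties count as misclassification in every downstream metric,
so silently breaking them would change the metric's meaning.  Votes are hard
argmaxes, not summed probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import ClassifierModel, Prediction, make_samples
from .model import Structure, StructureSet
from .normalize import Frame
from .vocabulary import VOCAB, ClassVocabulary

#: Sentinel decision for a tied maximal vote count.
TIE = "TIE"


@dataclass(frozen=True)
class VoteTally:
    """Per-class vote counts for one structure."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("a tally needs at least one vote")
        bad = [k for k, v in self.counts.items() if v < 0]
        if bad:
            raise ValueError(f"negative vote counts for {bad}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class StructureDecision:
    """The resolved label of one structure (or TIE), with its tally."""

    winner: str
    tally: VoteTally
    correct: bool | None = None  # None when truth is unknown

    @property
    def is_tie(self) -> bool:
        return self.winner == TIE


def tally(preds: list[Prediction], vocab: ClassVocabulary = VOCAB) -> VoteTally:
    """Count argmax votes over a structure's slice predictions."""
    if not preds:
        raise ValueError("cannot tally an empty prediction list")
    counts: dict[str, int] = {}
    for p in preds:
        lab = vocab.label(p.argmax)
        counts[lab] = counts.get(lab, 0) + 1
    return VoteTally(counts)


def decide(t: VoteTally, truth: str | None = None) -> StructureDecision:
    """Resolve a tally: unique maximal count wins, shared maximum is TIE."""
    best = max(t.counts.values())
    leaders = [lab for lab, c in t.counts.items() if c == best]
    winner = leaders[0] if len(leaders) == 1 else TIE
    correct = None if truth is None else (winner == truth)
    return StructureDecision(winner=winner, tally=t, correct=correct)


def classify_structure(
    model: ClassifierModel,
    s: Structure,
    sset: StructureSet,
    frame: Frame,
    truth: str | None = None,
) -> StructureDecision:
    """Classify every nonempty slice of ``s`` and vote.

    Deterministic for a fixed model (eval mode).  A structure with zero
    rasterizable slices is an error — there is nothing to vote on.
    """
    one = StructureSet(
        patient_id=sset.patient_id,
        grid=sset.grid,
        slice_thickness=sset.slice_thickness,
        n_slices=sset.n_slices,
        structures=[s],
    )
    samples = make_samples(one, frame, model.spec.multi_slice)
    if not samples:
        raise ValueError(f"structure {s.label!r} has no classifiable slices")
    preds = model.predict_batch(samples)
    return decide(tally(preds, model.vocab), truth=truth)
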