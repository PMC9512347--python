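"""The fixed 17-class TG-263 vocabulary for head-and-neck organs at risk.

Network output index ``i`` always means ``TG263_LABELS[i]``; the order is
fixed and part of every trained checkpoint's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TG263_LABELS: tuple[str, ...] = (
    "Eye_L",
    "Eye_R",
    "Cochlea_L",
    "Cochlea_R",
    "Larynx",
    "Lens_L",
    "Lens_R",
    "Chiasm",
    "OpticNerve_L",
    "OpticNerve_R",
    "Brainstem",
    "Brain",
    "Esophagus",
    "SpinalCord",
    "Parotid_L",
    "Parotid_R",
    "Pituitary",
)


@dataclass(frozen=True)
class ClassVocabulary:
    """Bijection between TG-263 structure names and class indices 0..16."""

    labels: tuple[str, ...] = TG263_LABELS
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("vocabulary labels must be distinct")
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"label {label!r} is not in the vocabulary") from None

    def label(self, i: int) -> str:
        return self.labels[i]


#: The default 17-organ head-and-neck vocabulary.
VOCAB = ClassVocabulary()
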