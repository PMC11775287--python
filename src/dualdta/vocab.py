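"""Token vocabularies and the token-sequence container.

Drugs are tokenized at atom level (every heavy atom is one token; ring
digits, bonds and branch parentheses are their own tokens), proteins at
residue level (one single-letter token per residue).  Both sequences end in a
special ``[EOS]`` token whose encoder feature later seeds the fusion graph's
virtual node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PAD = "<pad>"
EOS = "[EOS]"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Atom tokens the fragment grammar can emit, plus the standard organic-subset
# SMILES symbols; fixed at build time — anything else is rejected, not UNK'd.
_DRUG_ATOM_TOKENS = [
    "B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I",
    "b", "c", "n", "o", "p", "s",
    "[nH]", "[N+]", "[O-]", "[NH+]", "[NH2+]", "[NH3+]", "[S+]",
]
_DRUG_OTHER_TOKENS = list("123456789()=#-/\\")


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {tok: i for i, tok in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        return self.index[token]

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        toks = [line for line in Path(path).read_text().splitlines() if line]
        return cls(tuple(toks))


def drug_vocabulary() -> Vocabulary:
    return Vocabulary(tuple([PAD, EOS] + _DRUG_ATOM_TOKENS + _DRUG_OTHER_TOKENS))


def protein_vocabulary() -> Vocabulary:
    return Vocabulary(tuple([PAD, EOS] + list(AMINO_ACIDS) + ["X"]))


@dataclass
class TokenSeq:
    """Integer token ids with padding mask and EOS bookkeeping.

    ``atom_map`` (drugs only) maps molecular-graph atom index -> position of
    that atom's token in ``ids``.
    """

    ids: np.ndarray
    mask: np.ndarray
    eos_index: int
    tokens: list[str]
    atom_map: dict[int, int] | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.ids) != len(self.mask):
            raise ValueError("ids and mask must have equal length")
        if not self.mask[self.eos_index]:
            raise ValueError("EOS position must be unmasked")

    def __len__(self) -> int:
        return len(self.ids)
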