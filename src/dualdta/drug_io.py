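"""Atom-level SMILES tokenization and drug molecular-graph construction.

The guarantee this module provides is the token<->atom correspondence: RDKit
keeps atom indices in the order atoms appear in the input SMILES, and the
regex tokenizer emits atom tokens in string order, so the k-th atom token is
graph atom k.  Both sides are cross-checked on every call and any mismatch is
rejected rather than silently misaligned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .vocab import EOS, TokenSeq, Vocabulary, drug_vocabulary

RDLogger.DisableLog("rdApp.*")

# Bracket atoms first, then two-letter elements, then everything single-char.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|[BCNOPSFI]|[bcnops]|%\d{2}|\d|[()=#\-+/\\.@*])"
)
_ATOM_RE = re.compile(r"^(\[[^\]]+\]|Br|Cl|[BCNOPSFI]|[bcnops])$")


@dataclass
class MolGraph:
    """Heavy-atom molecular graph: nodes in RDKit (input-SMILES) atom order,
    one undirected edge per bond, stored once with i < j."""

    n_atoms: int
    elements: list[str]
    edges: list[tuple[int, int]]

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loop in molecular graph")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError("edge index out of range")


def _parse_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into lexical tokens; reject unknown spans."""
    tokens, pos = [], 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise ValueError(
                f"unparseable SMILES span at position {pos}: {smiles[pos:pos+4]!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def is_atom_token(token: str) -> bool:
    if token == EOS:  # the EOS special is bracketed but is not an atom
        return False
    return bool(_ATOM_RE.match(token))


def tokenize_smiles(smiles: str, vocab: Vocabulary | None = None) -> TokenSeq:
    """Tokenize a SMILES string at atom level and append an EOS token.

    Every heavy atom yields exactly one token; ``atom_map`` aligns molecular
    graph atom indices with token positions.  Tokens outside the fixed
    vocabulary are rejected.
    """
    vocab = vocab or drug_vocabulary()
    mol = _parse_mol(smiles)
    tokens = split_smiles(smiles)
    for tok in tokens:
        if tok not in vocab:
            raise ValueError(f"token {tok!r} not in drug vocabulary")
    atom_positions = [i for i, tok in enumerate(tokens) if is_atom_token(tok)]
    if len(atom_positions) != mol.GetNumAtoms():
        raise ValueError(
            f"tokenizer/graph desync for {smiles!r}: "
            f"{len(atom_positions)} atom tokens vs {mol.GetNumAtoms()} atoms"
        )
    tokens = tokens + [EOS]
    ids = np.array([vocab[t] for t in tokens], dtype=np.int64)
    mask = np.ones(len(tokens), dtype=bool)
    atom_map = {k: p for k, p in enumerate(atom_positions)}
    return TokenSeq(
        ids=ids, mask=mask, eos_index=len(tokens) - 1, tokens=tokens, atom_map=atom_map
    )


def detokenize(seq: TokenSeq) -> str:
    """Inverse of :func:`tokenize_smiles` up to the appended EOS."""
    return "".join(t for t in seq.tokens if t != EOS)


def smiles_to_graph(smiles: str) -> MolGraph:
    """Build the heavy-atom bond graph in the parser's native atom order."""
    mol = _parse_mol(smiles)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
    return MolGraph(n_atoms=mol.GetNumAtoms(), elements=elements, edges=sorted(edges))


def element_counts(smiles: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for el in smiles_to_graph(smiles).elements:
        counts[el] = counts.get(el, 0) + 1
    return counts
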