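"""Protein-side inputs: residue tokenization, structure parsing, contact
maps, binding ranges, and the binding-site-restricted residue graph.

Distances are measured between residue representative atoms: the beta carbon,
with the alpha carbon substituting for glycine (which has no CB).  A residue
pair is in contact when its distance is strictly below the threshold
(default 8 angstrom).  Binding annotations use the UniProt convention
(1-based inclusive intervals); everything internal is 0-based half-open, and
the two conventions meet only in :func:`binding_range` and the TSV reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .vocab import AMINO_ACIDS, EOS, TokenSeq, Vocabulary, protein_vocabulary

DEFAULT_CONTACT_THRESHOLD = 8.0
DEFAULT_RANGE_CAP = 300


class RangeSource(Enum):
    ANNOTATION_UNION = "annotation_union"
    FULL_SEQUENCE_FALLBACK = "full_sequence_fallback"


@dataclass
class ContactMap:
    matrix: np.ndarray
    threshold_angstrom: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact map must be square")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class BindingRange:
    """Half-open 0-based residue interval [start, end)."""

    start: int
    end: int
    source: RangeSource

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("binding range must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, residue: int) -> bool:
        return self.start <= residue < self.end


@dataclass
class TargetGraph:
    n_residues: int
    residue_offsets: np.ndarray  # node index -> original sequence position
    edges: list[tuple[int, int]]

    def __post_init__(self):
        self.residue_offsets = np.asarray(self.residue_offsets, dtype=np.int64)
        if np.any(np.diff(self.residue_offsets) <= 0):
            raise ValueError("residue_offsets must be strictly increasing")


def tokenize_protein(sequence: str, vocab: Vocabulary | None = None) -> TokenSeq:
    """One token per residue plus EOS; rejects characters outside the 20
    standard amino acids (and X)."""
    vocab = vocab or protein_vocabulary()
    if not sequence:
        raise ValueError("empty protein sequence")
    allowed = set(AMINO_ACIDS) | {"X"}
    for pos, aa in enumerate(sequence):
        if aa not in allowed:
            raise ValueError(f"illegal residue {aa!r} at position {pos}")
    tokens = list(sequence) + [EOS]
    ids = np.array([vocab[t] for t in tokens], dtype=np.int64)
    return TokenSeq(
        ids=ids,
        mask=np.ones(len(tokens), dtype=bool),
        eos_index=len(tokens) - 1,
        tokens=tokens,
    )


# --------------------------------------------------------------------------
# Structures


def load_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _representative_atom(residue: gemmi.Residue) -> gemmi.Atom:
    cb = residue.find_atom("CB", "*")
    if cb is not None:
        return cb
    ca = residue.find_atom("CA", "*")
    if ca is not None:
        return ca
    raise ValueError(
        f"residue {residue.name} {residue.seqid.num} has neither CB nor CA"
    )


def residue_coordinates(
    structure: gemmi.Structure, chain: str | None = None
) -> np.ndarray:
    """Representative-atom (CB, CA for glycine) coordinates of one chain."""
    model = structure[0]
    chains = list(model)
    if chain is None:
        if len(chains) != 1:
            names = [c.name for c in chains]
            raise ValueError(f"multi-chain structure; select one of {names}")
        selected = chains[0]
    else:
        selected = model.find_chain(chain)
        if selected is None:
            raise ValueError(f"chain {chain!r} not found")
    coords = []
    for residue in selected:
        atom = _representative_atom(residue)
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError("selected chain has no residues")
    return np.asarray(coords, dtype=float)


def residue_distance_matrix(
    structure: gemmi.Structure, chain: str | None = None
) -> np.ndarray:
    """Pairwise Euclidean distances between residue representative atoms."""
    coords = residue_coordinates(structure, chain)
    return distance_matrix_from_coords(coords)


def distance_matrix_from_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def contact_map(
    dist: np.ndarray, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> ContactMap:
    """Binary contact map: 1 where distance is strictly below the threshold."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    return ContactMap(matrix=(dist < threshold).astype(np.int8), threshold_angstrom=threshold)


# --------------------------------------------------------------------------
# Binding ranges and target graphs


def binding_range(
    annotations: list[tuple[int, int]],
    seq_len: int,
    cap: int = DEFAULT_RANGE_CAP,
) -> BindingRange:
    """Contiguous envelope of the union of annotated sites.

    ``annotations`` are 1-based inclusive intervals.  An empty list falls back
    to the full sequence.  A result longer than ``cap`` is truncated
    symmetrically around its center.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be positive")
    if not annotations:
        start, end = 0, seq_len
        source = RangeSource.FULL_SEQUENCE_FALLBACK
    else:
        for a, b in annotations:
            if not (1 <= a <= b <= seq_len):
                raise ValueError(
                    f"annotation ({a}, {b}) outside sequence of length {seq_len}"
                )
        start = min(a for a, _ in annotations) - 1
        end = max(b for _, b in annotations)
        source = RangeSource.ANNOTATION_UNION
    if end - start > cap:
        excess = (end - start) - cap
        start += excess // 2
        end -= excess - excess // 2
    return BindingRange(start=start, end=end, source=source)


def target_graph(cmap: ContactMap, brange: BindingRange) -> TargetGraph:
    """Residue graph over the binding range: nodes are residues in
    [start, end); edges are the contacts within the slice (diagonal
    self-contacts are not emitted)."""
    if brange.end > cmap.length:
        raise ValueError("binding range exceeds contact-map length")
    sub = cmap.matrix[brange.start : brange.end, brange.start : brange.end]
    ii, jj = np.nonzero(np.triu(sub, k=1))
    edges = [(int(i), int(j)) for i, j in zip(ii, jj)]
    return TargetGraph(
        n_residues=brange.end - brange.start,
        residue_offsets=np.arange(brange.start, brange.end),
        edges=edges,
    )


# --------------------------------------------------------------------------
# File interfaces


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_binding_sites(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """TSV with columns target_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    sites: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        sites.setdefault(str(row.target_id), []).append((int(row.start), int(row.end)))
    return sites


def write_contact_map_csv(cmap: ContactMap, path: str | Path) -> None:
    np.savetxt(path, cmap.matrix, fmt="%d", delimiter=",")


def write_contact_edges_tsv(cmap: ContactMap, path: str | Path) -> None:
    ii, jj = np.nonzero(np.triu(cmap.matrix, k=1))
    pd.DataFrame({"i": ii, "j": jj}).to_csv(path, sep="\t", index=False)
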