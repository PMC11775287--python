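"""Synthetic study generator: molecules, protein sequences with plausible
backbones, binding-site annotations, and affinities with a planted signal.

The generator exists so the full pipeline is testable without downloads.  Its
design choices mirror the statistics that matter downstream, not physics:

* molecules come from a fragment grammar (concatenation-safe SMILES pieces),
  which guarantees chemical validity without a valence-model rabbit hole;
* backbones are self-avoiding 3D random walks with ~3.8 angstrom steps, which
  is enough to give 8-angstrom contact maps that are sparse but non-trivial;
* binding-site residues are drawn from a composition-biased alphabet
  (enriched in H/W/Y/F/C/D), emulating the compositional distinctness of real
  pockets;
* the affinity label is linear in drug element counts and binding-range
  residue counts plus Gaussian noise, so it depends only on residues inside
  the binding range and is exactly recoverable at zero noise.

All randomness flows through one explicit integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem

from .drug_io import element_counts
from .target_io import binding_range
from .vocab import AMINO_ACIDS

# --------------------------------------------------------------------------
# Types


@dataclass
class SyntheticTarget:
    target_id: str
    sequence: str
    coords_cb: np.ndarray  # (L, 3) representative-atom coordinates, angstrom
    binding_sites: list[tuple[int, int]]  # 1-based inclusive intervals

    def __post_init__(self):
        self.coords_cb = np.asarray(self.coords_cb, dtype=float)
        if len(self.coords_cb) != len(self.sequence):
            raise ValueError("one coordinate triplet per residue required")
        for a, b in self.binding_sites:
            if not (1 <= a <= b <= len(self.sequence)):
                raise ValueError("binding interval outside sequence bounds")


@dataclass
class PlantedAffinityModel:
    """Ground-truth affinity function: linear in drug element counts and
    binding-range residue counts, plus N(0, noise_sd^2) noise."""

    drug_weights: dict[str, float] = field(
        default_factory=lambda: {
            "C": 0.04, "N": 0.12, "O": 0.10, "S": 0.08,
            "F": 0.18, "Cl": 0.18, "Br": 0.18,
        }
    )
    target_weights: dict[str, float] = field(
        default_factory=lambda: {
            "H": 0.07, "W": 0.09, "Y": 0.05, "F": 0.04, "C": 0.04, "D": 0.06,
        }
    )
    intercept: float = 4.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    smiles: str
    target_id: str
    affinity: float


@dataclass
class SyntheticDataset:
    records: list[AffinityRecord]
    drugs: dict[str, str]  # drug_id -> SMILES
    targets: dict[str, SyntheticTarget]

    def __len__(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------------
# Molecules

# Fragments are written so plain string concatenation stays valid SMILES:
# the first and the last atom of each middle fragment tolerate one extra
# single bond on each side; enders need only one attachment point.
_MIDDLE_FRAGMENTS = [
    "C", "CC", "CCC", "CO", "CN", "COC", "CNC", "CSC",
    "C(C)C", "C(F)C", "C(Cl)C", "C(=O)C", "C(=O)N", "C(=O)NC",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "C1CCOCC1",
]
_END_FRAGMENTS = [
    "C", "F", "Cl", "Br", "O", "N", "S", "C#N", "C(=O)O", "C(F)(F)F",
    "c1ccccc1", "c1ccncc1",
]

MIN_HEAVY_ATOMS = 5
MAX_HEAVY_ATOMS = 40


def _assemble_smiles(rng: np.random.Generator) -> str:
    n_mid = int(rng.integers(1, 6))
    parts = [str(rng.choice(_MIDDLE_FRAGMENTS)) for _ in range(n_mid)]
    parts.append(str(rng.choice(_END_FRAGMENTS)))
    return "".join(parts)


def gen_molecules(n: int, seed: int) -> list[str]:
    """Generate ``n`` valid, connected SMILES of 5-40 heavy atoms."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        smiles = _assemble_smiles(rng)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue  # grammar slipped; resample
        n_heavy = mol.GetNumAtoms()
        if not (MIN_HEAVY_ATOMS <= n_heavy <= MAX_HEAVY_ATOMS):
            continue
        if len(Chem.GetMolFrags(mol)) != 1:
            continue
        out.append(smiles)
    return out


# --------------------------------------------------------------------------
# Targets

# Pocket alphabet: binding-site residues are enriched in these six types.
POCKET_RESIDUES = "HWYFCD"
_POCKET_P = np.array(
    [0.10 if aa in POCKET_RESIDUES else 0.4 / 14 for aa in AMINO_ACIDS]
)
_POCKET_P /= _POCKET_P.sum()

_STEP_LENGTH = 3.8  # consecutive-residue spacing, angstrom
_MIN_SEPARATION = 4.0  # self-avoidance radius for non-adjacent residues


def _self_avoiding_walk(length: int, rng: np.random.Generator) -> np.ndarray:
    """3D walk with ~3.8 angstrom steps, mild direction persistence, and a
    4 angstrom exclusion radius against non-adjacent residues."""
    coords = np.zeros((length, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, length):
        placed = False
        for _ in range(40):
            proposal = 0.6 * direction + rng.normal(size=3)
            proposal /= np.linalg.norm(proposal)
            step = _STEP_LENGTH + rng.normal(0.0, 0.05)
            candidate = coords[i - 1] + step * proposal
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if d.min() < _MIN_SEPARATION:
                    continue
            coords[i] = candidate
            direction = proposal
            placed = True
            break
        if not placed:  # rare dead end: step straight on regardless
            coords[i] = coords[i - 1] + _STEP_LENGTH * direction
    return coords


def _sample_binding_sites(
    length: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """1-3 non-overlapping intervals whose envelope stays within 280
    residues (so downstream range capping never cuts into the signal)."""
    n_sites = int(rng.integers(1, 4))
    window = min(length, 280)
    w0 = int(rng.integers(0, length - window + 1))
    sites: list[tuple[int, int]] = []
    for _ in range(n_sites):
        for _ in range(20):
            size = int(rng.integers(8, 29))
            start = w0 + int(rng.integers(0, max(window - size, 1)))
            end = min(start + size - 1, length - 1)
            interval = (start + 1, end + 1)  # to 1-based inclusive
            if all(interval[1] < a or interval[0] > b for a, b in sites):
                sites.append(interval)
                break
    return sorted(sites)


def gen_targets(
    n: int,
    length_range: tuple[int, int] = (50, 150),
    seed: int = 0,
) -> list[SyntheticTarget]:
    """Generate targets: sequence, walk-derived coordinates, binding sites."""
    lo, hi = length_range
    if not (50 <= lo <= hi <= 600):
        raise ValueError("length_range must lie within [50, 600]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    targets = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aa, size=length)
        sites = _sample_binding_sites(length, rng)
        for a, b in sites:
            seq[a - 1 : b] = rng.choice(aa, size=b - a + 1, p=_POCKET_P)
        coords = _self_avoiding_walk(length, rng)
        targets.append(
            SyntheticTarget(
                target_id=f"T{k:04d}",
                sequence="".join(seq),
                coords_cb=coords,
                binding_sites=sites,
            )
        )
    return targets


# --------------------------------------------------------------------------
# Affinities


def planted_affinity_components(
    smiles: str, target: SyntheticTarget, model: PlantedAffinityModel
) -> float:
    """Noise-free planted affinity (intercept + drug term + range term)."""
    value = model.intercept
    counts = element_counts(smiles)
    for element, weight in model.drug_weights.items():
        value += weight * counts.get(element, 0)
    env = binding_range(target.binding_sites, len(target.sequence))
    segment = target.sequence[env.start : env.end]
    for residue, weight in model.target_weights.items():
        value += weight * segment.count(residue)
    return value


def gen_affinity(
    smiles: str,
    target: SyntheticTarget,
    model: PlantedAffinityModel,
    seed: int,
) -> float:
    value = planted_affinity_components(smiles, target, model)
    if model.noise_sd > 0:
        value += np.random.default_rng(seed).normal(0.0, model.noise_sd)
    return float(value)


def gen_dataset(
    n_drugs: int,
    n_targets: int,
    density: float,
    model: PlantedAffinityModel | None = None,
    seed: int = 0,
    length_range: tuple[int, int] = (50, 150),
) -> SyntheticDataset:
    """Sample drug-target pairs without replacement up to
    ``density * n_drugs * n_targets`` records."""
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    model = model or PlantedAffinityModel()
    rng = np.random.default_rng(seed)
    smiles_list = gen_molecules(n_drugs, seed=int(rng.integers(2**31)))
    targets = gen_targets(n_targets, length_range, seed=int(rng.integers(2**31)))
    drugs = {f"D{i:04d}": s for i, s in enumerate(smiles_list)}
    target_map = {t.target_id: t for t in targets}
    n_pairs = int(round(density * n_drugs * n_targets))
    grid = [(d, t) for d in sorted(drugs) for t in sorted(target_map)]
    chosen = rng.choice(len(grid), size=n_pairs, replace=False)
    records = []
    for idx in sorted(int(i) for i in chosen):
        drug_id, target_id = grid[idx]
        y = gen_affinity(
            drugs[drug_id],
            target_map[target_id],
            model,
            seed=int(rng.integers(2**31)),
        )
        records.append(
            AffinityRecord(
                drug_id=drug_id,
                smiles=drugs[drug_id],
                target_id=target_id,
                affinity=y,
            )
        )
    return SyntheticDataset(records=records, drugs=drugs, targets=target_map)


# --------------------------------------------------------------------------
# File round trips

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_records_csv(records: list[AffinityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "smiles": r.smiles,
                "target_id": r.target_id,
                "affinity": r.affinity,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[AffinityRecord]:
    df = pd.read_csv(path)
    return [
        AffinityRecord(
            drug_id=str(r.drug_id),
            smiles=str(r.smiles),
            target_id=str(r.target_id),
            affinity=float(r.affinity),
        )
        for r in df.itertuples(index=False)
    ]


def write_target_pdb(target: SyntheticTarget, path: str | Path) -> None:
    """One residue per position with a single representative atom
    (CB; CA for glycine, which has no beta carbon)."""
    st = gemmi.Structure()
    st.name = target.target_id
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (aa, xyz) in enumerate(zip(target.sequence, target.coords_cb)):
        res = gemmi.Residue()
        res.name = _THREE_LETTER.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA" if aa == "G" else "CB"
        atom.pos = gemmi.Position(*xyz)
        atom.element = gemmi.Element("C")
        res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


def write_targets(
    targets: list[SyntheticTarget], out_dir: str | Path
) -> None:
    """FASTA of sequences, one PDB per target, and a binding-site TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "targets.fasta", "w") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n{t.sequence}\n")
    rows = []
    for t in targets:
        write_target_pdb(t, out_dir / f"{t.target_id}.pdb")
        for a, b in t.binding_sites:
            rows.append({"target_id": t.target_id, "start": a, "end": b})
    pd.DataFrame(rows).to_csv(out_dir / "binding_sites.tsv", sep="\t", index=False)


def read_targets(target_dir: str | Path) -> dict[str, SyntheticTarget]:
    """Inverse of :func:`write_targets`: FASTA + per-target PDB + site TSV."""
    from .target_io import load_structure, read_binding_sites, read_fasta, residue_coordinates

    target_dir = Path(target_dir)
    sequences = read_fasta(target_dir / "targets.fasta")
    sites_path = target_dir / "binding_sites.tsv"
    sites = read_binding_sites(sites_path) if sites_path.exists() else {}
    out = {}
    for tid, seq in sequences.items():
        coords = residue_coordinates(load_structure(target_dir / f"{tid}.pdb"))
        out[tid] = SyntheticTarget(
            target_id=tid,
            sequence=seq,
            coords_cb=coords,
            binding_sites=sorted(sites.get(tid, [])),
        )
    return out
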