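"""Virtual-node fusion graph.

The joint graph keeps the target residue graph and the drug molecular graph
intact and couples them through a single virtual node adjacent to every other
node; there are no direct target-drug edges.  Node order is fixed globally:
target residues first, then the virtual node, then drug atoms.  Node features
are the sequence encoder's per-token features (so both node kinds live in the
same feature space); the virtual node receives the mean of the two EOS-token
features, and a 3-channel one-hot source type (target / virtual / drug) is
appended last.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .drug_io import MolGraph
from .seq_encoder import SeqOutput
from .target_io import TargetGraph


@dataclass
class FusionGraph:
    n_target: int
    n_drug: int
    edges: list[tuple[int, int]]  # undirected, each stored once
    virtual_self_loop: bool = False
    node_features: np.ndarray | None = None  # (N, D) or (N, D+3)
    has_source_features: bool = False

    @property
    def n_nodes(self) -> int:
        return self.n_target + 1 + self.n_drug

    @property
    def virtual_index(self) -> int:
        return self.n_target

    def node_kinds(self) -> np.ndarray:
        """0 = target residue, 1 = virtual, 2 = drug atom, in node order."""
        return np.array(
            [0] * self.n_target + [1] + [2] * self.n_drug, dtype=np.int64
        )

    def to_dense_adjacency(self) -> np.ndarray:
        """Dense block adjacency: residue contacts, bond graph, one-coupling
        rows/columns for the virtual node (and its optional self-loop)."""
        n = self.n_nodes
        adj = np.zeros((n, n), dtype=np.int8)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = 1
        if self.virtual_self_loop:
            adj[self.virtual_index, self.virtual_index] = 1
        return adj


def build_fusion_adjacency(
    target: TargetGraph, drug: MolGraph, virtual_self_loop: bool = False
) -> FusionGraph:
    """Assemble the fusion edge set: target edges, drug edges (shifted past
    the virtual node), and one virtual-node link to every other node."""
    if target.n_residues == 0 or drug.n_atoms == 0:
        raise ValueError("fusion graph requires non-empty target and drug graphs")
    nt = target.n_residues
    v = nt
    offset = nt + 1
    edges: list[tuple[int, int]] = []
    edges.extend((int(i), int(j)) for i, j in target.edges)
    edges.extend((offset + i, offset + j) for i, j in drug.edges)
    edges.extend((min(v, u), max(v, u)) for u in range(nt + 1 + drug.n_atoms) if u != v)
    return FusionGraph(
        n_target=nt,
        n_drug=drug.n_atoms,
        edges=sorted(set(edges)),
        virtual_self_loop=virtual_self_loop,
    )


def virtual_node_feature(seq_out: SeqOutput, sample: int = 0) -> np.ndarray:
    """Elementwise mean of the target and drug EOS-token features."""
    eos_t = int(seq_out.eos_target[sample])
    eos_d = int(seq_out.eos_drug[sample])
    if not seq_out.target_mask[sample, eos_t] or not seq_out.drug_mask[sample, eos_d]:
        raise ValueError("EOS token missing or masked")
    ft = seq_out.f_target.data[sample, eos_t]
    fd = seq_out.f_drug.data[sample, eos_d]
    return 0.5 * (ft + fd)


def assign_node_features(
    fg: FusionGraph,
    seq_out: SeqOutput,
    atom_map: dict[int, int],
    residue_offsets: np.ndarray,
    sample: int = 0,
) -> FusionGraph:
    """Endow every node with its sequence-derived feature row.

    Residue node i reads the full-sequence feature at position
    ``residue_offsets[i]``; drug atom node j reads the drug feature at its
    atom token's position ``atom_map[j]``; the virtual node gets the averaged
    EOS feature.
    """
    residue_offsets = np.asarray(residue_offsets, dtype=np.int64)
    if len(residue_offsets) != fg.n_target:
        raise ValueError("residue_offsets length must equal n_target")
    if len(atom_map) != fg.n_drug:
        raise ValueError(
            "atom_map does not cover every drug node (tokenizer/graph desync)"
        )
    f_t = seq_out.f_target.data[sample]
    f_d = seq_out.f_drug.data[sample]
    if residue_offsets.max() >= f_t.shape[0]:
        raise ValueError("residue offset outside encoded sequence")
    feats = np.empty((fg.n_nodes, f_t.shape[1]))
    feats[: fg.n_target] = f_t[residue_offsets]
    feats[fg.virtual_index] = virtual_node_feature(seq_out, sample)
    for j in range(fg.n_drug):
        feats[fg.virtual_index + 1 + j] = f_d[atom_map[j]]
    fg.node_features = feats
    fg.has_source_features = False
    return fg


def append_source_features(fg: FusionGraph) -> FusionGraph:
    """Append the one-hot (target, virtual, drug) source channels."""
    if fg.node_features is None:
        raise ValueError("assign node features before appending source channels")
    if fg.has_source_features:
        raise ValueError("source channels already appended")
    onehot = np.eye(3)[fg.node_kinds()]
    fg.node_features = np.concatenate([fg.node_features, onehot], axis=1)
    fg.has_source_features = True
    return fg


def export_fusion_graph(fg: FusionGraph, out_dir: str | Path, name: str) -> None:
    """Debug export: edge-list TSV, node-feature array, node-metadata TSV."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fg.edges, columns=["i", "j"]).to_csv(
        out / f"{name}.edges.tsv", sep="\t", index=False
    )
    kinds = fg.node_kinds()
    original = np.concatenate(
        [np.arange(fg.n_target), [-1], np.arange(fg.n_drug)]
    )
    kind_names = ["target", "virtual", "drug"]
    pd.DataFrame(
        {"kind": [kind_names[k] for k in kinds], "original_index": original}
    ).to_csv(out / f"{name}.nodes.tsv", sep="\t", index=False)
    if fg.node_features is not None:
        np.savetxt(out / f"{name}.features.csv", fg.node_features, delimiter=",")
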