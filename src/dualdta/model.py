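"""The full dual-modality affinity regressor.

``DTAModel`` wires the sequence encoder, the virtual-node fusion graph, the
GIN stack, and the fusion prediction head together, and implements the
component ablations (group enhancement off, link attention -> masked mean
pooling, virtual node -> two independent graph encoders with summed outputs,
source channels off, sequence-only, graph-only).

Batches of drug-target pairs are encoded as one block-diagonal fusion graph:
per-pair graphs are concatenated with node offsets and pooled back per graph,
which keeps message passing a single vectorized pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .drug_io import MolGraph, smiles_to_graph, tokenize_smiles
from .gnn_encoder import GnnConfig, MGNN
from .nn import Linear, MLP, Module, Tensor, concat, gather_rows, no_grad
from .seq_encoder import EncoderConfig, SeqEncoder, SeqOutput, pad_batch
from .synthetic import SyntheticDataset, SyntheticTarget
from .target_io import (
    BindingRange,
    TargetGraph,
    binding_range,
    contact_map,
    distance_matrix_from_coords,
    target_graph,
    tokenize_protein,
)
from .vocab import TokenSeq, drug_vocabulary, protein_vocabulary


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    gnn: GnnConfig = field(default_factory=GnnConfig)
    head_hidden: int = 256
    use_gem: bool = True
    use_link_attention: bool = True
    use_virtual_node: bool = True
    use_source_feature: bool = True
    virtual_self_loop: bool = False
    seq_only: bool = False  # drop the graph branch entirely
    graph_only: bool = False  # drop the sequence branch (embeddings only)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder"] = EncoderConfig(**d.get("encoder", {}))
        d["gnn"] = GnnConfig(**d.get("gnn", {}))
        return cls(**d)


# --------------------------------------------------------------------------
# Pre-encoded entities


@dataclass
class DrugEntry:
    drug_id: str
    smiles: str
    tokens: TokenSeq
    graph: MolGraph


@dataclass
class TargetEntry:
    target_id: str
    sequence: str
    tokens: TokenSeq
    graph: TargetGraph
    brange: BindingRange
    binding_sites: list[tuple[int, int]]


@dataclass
class Pair:
    drug: DrugEntry
    target: TargetEntry
    affinity: float


def encode_target(target: SyntheticTarget, cap: int = 300) -> TargetEntry:
    """Tokenize, build the contact map from coordinates, slice the range."""
    dist = distance_matrix_from_coords(target.coords_cb)
    cmap = contact_map(dist)
    brange = binding_range(target.binding_sites, len(target.sequence), cap=cap)
    return TargetEntry(
        target_id=target.target_id,
        sequence=target.sequence,
        tokens=tokenize_protein(target.sequence),
        graph=target_graph(cmap, brange),
        brange=brange,
        binding_sites=list(target.binding_sites),
    )


def prepare_pairs(dataset: SyntheticDataset, cap: int = 300) -> list[Pair]:
    drugs = {
        did: DrugEntry(did, s, tokenize_smiles(s), smiles_to_graph(s))
        for did, s in dataset.drugs.items()
    }
    targets = {tid: encode_target(t, cap) for tid, t in dataset.targets.items()}
    return [
        Pair(drugs[r.drug_id], targets[r.target_id], r.affinity)
        for r in dataset.records
    ]


# --------------------------------------------------------------------------
# Model


class DTAModel(Module):
    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        self.seq = SeqEncoder(
            cfg.encoder,
            seed=int(rng.integers(2**31)),
            use_gem=cfg.use_gem,
            use_link_attention=cfg.use_link_attention,
        )
        node_dim = cfg.encoder.embed_dim + (3 if cfg.use_source_feature else 0)
        if not cfg.seq_only:
            self.mgnn = MGNN(node_dim, cfg.gnn, seed=int(rng.integers(2**31)))
            if not cfg.use_virtual_node:
                self.mgnn_drug = MGNN(
                    node_dim, cfg.gnn, seed=int(rng.integers(2**31))
                )
        # Warm-up head: scalar readout of out_seq; doubles as the
        # sequence-only model.
        self.warm_head = Linear(self.seq.out_dim, 1, rng)
        head_in = self._head_in_dim()
        self.head = MLP([head_in, cfg.head_hidden, 1], rng)
        self._pad_t = protein_vocabulary().pad_id
        self._pad_d = drug_vocabulary().pad_id
        # Additive label offset (train-set mean), set by the training loop so
        # the network regresses centered labels.
        self.y_offset = 0.0

    def _collect_buffers(self, out: dict, path: str) -> None:
        out[path + "y_offset"] = np.array([self.y_offset])

    def _load_buffers(self, state: dict, path: str) -> None:
        if path + "y_offset" in state:
            self.y_offset = float(state[path + "y_offset"][0])

    def _head_in_dim(self) -> int:
        cfg = self.config
        if cfg.seq_only:
            return self.seq.out_dim
        if cfg.graph_only:
            return cfg.gnn.hidden_dim
        return cfg.gnn.hidden_dim + self.seq.out_dim

    # -- spec surface ------------------------------------------------------
    def predict_affinity(self, out_seq: Tensor, out_str: Tensor) -> Tensor:
        """Fusion head: yhat = FFN(concat(out_str, out_seq))."""
        if out_str.shape[1] + out_seq.shape[1] != self._head_in_dim():
            raise ValueError("feature width does not match the trained head")
        return self.head(concat([out_str, out_seq], axis=1))

    # -- batched forward ----------------------------------------------------
    def _encode_sequences(self, pairs: list[Pair]) -> SeqOutput:
        t_ids, t_mask, t_eos = pad_batch(
            [p.target.tokens for p in pairs], self._pad_t
        )
        d_ids, d_mask, d_eos = pad_batch([p.drug.tokens for p in pairs], self._pad_d)
        if self.config.graph_only:
            # Sequence branch ablated: nodes read raw embedded features.
            f_t = self.seq.target_enc.fc(self.seq.target_enc.embedding(t_ids))
            f_d = self.seq.drug_enc.fc(self.seq.drug_enc.embedding(d_ids))
            zeros = Tensor(np.zeros((len(pairs), 1)))
            return SeqOutput(
                f_target=f_t, f_drug=f_d,
                pooled_target=zeros, pooled_drug=zeros, pooled_cat=zeros,
                attn_target=zeros, attn_drug=zeros, attn_cat=zeros,
                out_seq=zeros,
                target_mask=t_mask, drug_mask=d_mask,
                eos_target=t_eos, eos_drug=d_eos,
            )
        return self.seq(t_ids, t_mask, d_ids, d_mask, t_eos, d_eos)

    def _batched_graph_features(self, pairs: list[Pair], seq_out: SeqOutput):
        """Gather node features for the block-diagonal fusion graph.

        Sources: flattened per-token target features, per-token drug
        features, and the per-pair averaged EOS (virtual) features.
        """
        b = len(pairs)
        lt = seq_out.f_target.shape[1]
        ld = seq_out.f_drug.shape[1]
        d = seq_out.f_target.shape[2]
        flat_t = seq_out.f_target.reshape(b * lt, d)
        flat_d = seq_out.f_drug.reshape(b * ld, d)
        use_virtual = self.config.use_virtual_node
        eos_t_idx = np.arange(b) * lt + seq_out.eos_target
        eos_d_idx = np.arange(b) * ld + seq_out.eos_drug
        virt = (gather_rows(flat_t, eos_t_idx) + gather_rows(flat_d, eos_d_idx)) * 0.5
        source = concat([flat_t, flat_d, virt], axis=0)
        base_d = b * lt
        base_v = b * lt + b * ld

        gather_idx: list[np.ndarray] = []
        kinds: list[np.ndarray] = []
        edges: list[np.ndarray] = []
        graph_ids: list[np.ndarray] = []
        virtual_nodes: list[int] = []
        offset = 0
        for i, p in enumerate(pairs):
            nt, nd = p.target.graph.n_residues, p.drug.graph.n_atoms
            res_idx = i * lt + p.target.graph.residue_offsets
            atom_idx = base_d + i * ld + np.array(
                [p.drug.tokens.atom_map[k] for k in range(nd)], dtype=np.int64
            )
            t_edges = np.asarray(p.target.graph.edges, dtype=np.int64).reshape(-1, 2)
            d_edges = np.asarray(p.drug.graph.edges, dtype=np.int64).reshape(-1, 2)
            if use_virtual:
                n_i = nt + 1 + nd
                gather_idx.extend([res_idx, [base_v + i], atom_idx])
                kinds.append(np.array([0] * nt + [1] + [2] * nd))
                v = offset + nt
                virtual_nodes.append(v)
                e = [t_edges + offset, d_edges + offset + nt + 1]
                others = np.concatenate(
                    [np.arange(offset, v), np.arange(v + 1, offset + n_i)]
                )
                e.append(np.stack([np.full(n_i - 1, v), others], axis=1))
                edges.append(np.concatenate(e, axis=0))
            else:
                n_i = nt + nd
                gather_idx.extend([res_idx, atom_idx])
                kinds.append(np.array([0] * nt + [2] * nd))
                edges.append(
                    np.concatenate([t_edges + offset, d_edges + offset + nt], axis=0)
                )
            graph_ids.append(np.full(n_i, i, dtype=np.intp))
            offset += n_i
        node_idx = np.concatenate([np.asarray(g, dtype=np.int64) for g in gather_idx])
        feats = gather_rows(source, node_idx)
        kinds_arr = np.concatenate(kinds)
        if self.config.use_source_feature:
            onehot = np.eye(3)[kinds_arr]
            feats = concat([feats, Tensor(onehot)], axis=1)
        return (
            feats,
            np.concatenate(edges, axis=0),
            np.concatenate(graph_ids),
            kinds_arr,
            np.array(virtual_nodes, dtype=np.intp),
        )

    def forward(self, pairs: list[Pair]) -> tuple[Tensor, SeqOutput]:
        """Predict affinities for a batch of pairs; returns (B,) predictions
        and the sequence-branch output (for attention extraction)."""
        b = len(pairs)
        seq_out = self._encode_sequences(pairs)
        if self.config.seq_only:
            pred = self.warm_head(seq_out.out_seq)
            return pred.reshape(b), seq_out
        feats, edges, graph_ids, kinds, vnodes = self._batched_graph_features(
            pairs, seq_out
        )
        loops = vnodes if (self.config.virtual_self_loop and len(vnodes)) else None
        if self.config.use_virtual_node:
            out_str = self.mgnn(feats, edges, graph_ids, b, self_loop_nodes=loops)
        else:
            # Two independent graph encoders over the disjoint node sets;
            # their pooled outputs are summed.  Without the virtual node no
            # edge crosses kinds, so each edge belongs to exactly one subset.
            n_total = len(kinds)
            remap = np.full(n_total, -1, dtype=np.int64)
            out_parts = []
            for kind, encoder in ((0, self.mgnn), (2, self.mgnn_drug)):
                idx = np.where(kinds == kind)[0]
                remap[idx] = np.arange(len(idx))
                sel = kinds[edges[:, 0]] == kind
                sub_edges = remap[edges[sel]]
                out_parts.append(
                    encoder(feats[idx], sub_edges, graph_ids[idx], b)
                )
            out_str = out_parts[0] + out_parts[1]
        if self.config.graph_only:
            pred = self.head(out_str)
        else:
            pred = self.predict_affinity(seq_out.out_seq, out_str)
        return pred.reshape(b), seq_out

    def predict(self, pairs: list[Pair], batch_size: int = 64) -> np.ndarray:
        """Deterministic eval-mode predictions (on the label scale)."""
        self.eval()
        preds = []
        with no_grad():
            for lo in range(0, len(pairs), batch_size):
                out, _ = self.forward(pairs[lo : lo + batch_size])
                preds.append(out.data.copy())
        return np.concatenate(preds) + self.y_offset

    def seq_predict(self, pairs: list[Pair], batch_size: int = 64) -> np.ndarray:
        """Predictions of the warm-up (sequence-only) scalar head."""
        self.eval()
        preds = []
        with no_grad():
            for lo in range(0, len(pairs), batch_size):
                seq_out = self._encode_sequences(pairs[lo : lo + batch_size])
                out = self.warm_head(seq_out.out_seq)
                preds.append(out.data[:, 0].copy())
        return np.concatenate(preds) + self.y_offset

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "DTAModel":
        with np.load(path, allow_pickle=False) as data:
            state = {k: data[k] for k in data.files}
        cfg = ModelConfig.from_dict(
            json.loads(state.pop("__config__").tobytes().decode())
        )
        model = cls(cfg)
        model.load_state_dict(state)
        return model.eval()
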