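"""Graph-modality encoder: stacked GIN convolutions with batch
normalization over the fusion graph, sum-pooled to a graph-level vector.

Two GIN variants are provided.  The default applies an MLP to each neighbor
inside the aggregation sum and a second MLP outside:

    out_i = outer_mlp( x_i + sum_{j in N(i)} inner_mlp(x_j) )

``standard_gin`` is the textbook form, (1 + eps) * x_i + sum of raw neighbor
features followed by a single MLP.  The two differ on small examples and the
default is pinned by a regression test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm1d, MLP, Module, Parameter, Tensor, scatter_sum

VARIANTS = ("paper_eq16", "standard_gin")


@dataclass
class GnnConfig:
    n_layers: int = 3
    hidden_dim: int = 128
    mlp_depth: int = 2
    variant: str = "paper_eq16"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def _directed_pairs(
    edges, n_nodes: int, self_loop_nodes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Expand an undirected edge list to both directions; validate indices."""
    if len(edges) == 0:
        src = np.zeros(0, dtype=np.intp)
        dst = np.zeros(0, dtype=np.intp)
    else:
        e = np.asarray(edges, dtype=np.intp)
        if e.min() < 0 or e.max() >= n_nodes:
            raise ValueError("dangling edge index")
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
    if self_loop_nodes is not None and len(self_loop_nodes):
        src = np.concatenate([src, self_loop_nodes])
        dst = np.concatenate([dst, self_loop_nodes])
    return src, dst


def gin_conv(
    x: Tensor,
    edges,
    inner_mlp,
    outer_mlp,
    n_nodes: int | None = None,
    self_loop_nodes: np.ndarray | None = None,
) -> Tensor:
    """One default-variant GIN convolution; ``inner_mlp``/``outer_mlp`` are
    callables on tensors (identity is allowed for testing)."""
    n = n_nodes or x.shape[0]
    src, dst = _directed_pairs(edges, n, self_loop_nodes)
    messages = inner_mlp(x)
    agg = scatter_sum(messages, src, dst, n)
    return outer_mlp(x + agg)


def gin_conv_standard(
    x: Tensor,
    edges,
    mlp,
    eps: Tensor,
    n_nodes: int | None = None,
    self_loop_nodes: np.ndarray | None = None,
) -> Tensor:
    n = n_nodes or x.shape[0]
    src, dst = _directed_pairs(edges, n, self_loop_nodes)
    agg = scatter_sum(x, src, dst, n)
    return mlp(x * (eps + 1.0) + agg)


class GinLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, cfg: GnnConfig, rng):
        super().__init__()
        self.variant = cfg.variant
        dims_inner = [in_dim] + [in_dim] * (cfg.mlp_depth - 1) + [in_dim]
        dims_outer = [in_dim] + [out_dim] * (cfg.mlp_depth - 1) + [out_dim]
        if cfg.variant == "paper_eq16":
            self.inner = MLP(dims_inner, rng)
            self.outer = MLP(dims_outer, rng)
        else:
            self.eps = Parameter(np.zeros(1))
            self.mlp = MLP(dims_outer, rng)
        self.norm = BatchNorm1d(out_dim)

    def forward(self, x: Tensor, edges, n_nodes=None, self_loop_nodes=None) -> Tensor:
        if self.variant == "paper_eq16":
            out = gin_conv(x, edges, self.inner, self.outer, n_nodes, self_loop_nodes)
        else:
            out = gin_conv_standard(
                x, edges, self.mlp, self.eps, n_nodes, self_loop_nodes
            )
        return self.norm(out)


class MGNN(Module):
    """L stacked GIN + batch-norm layers followed by sum pooling over all
    nodes (the virtual node included)."""

    def __init__(self, in_dim: int, config: GnnConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = config or GnnConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.in_dim = in_dim
        dims = [in_dim] + [cfg.hidden_dim] * cfg.n_layers
        for i in range(cfg.n_layers):
            setattr(self, f"layer{i}", GinLayer(dims[i], dims[i + 1], cfg, rng))

    @property
    def out_dim(self) -> int:
        return self.config.hidden_dim

    def forward(
        self,
        node_features: Tensor,
        edges,
        graph_ids: np.ndarray | None = None,
        n_graphs: int = 1,
        self_loop_nodes: np.ndarray | None = None,
    ) -> Tensor:
        """Encode a (possibly batched, block-diagonal) graph.

        ``graph_ids`` maps each node to its graph for sum pooling; omitted it
        defaults to a single graph.  Returns (n_graphs, hidden_dim).
        """
        n = node_features.shape[0]
        if graph_ids is None:
            graph_ids = np.zeros(n, dtype=np.intp)
        x = node_features
        for i in range(self.config.n_layers):
            x = getattr(self, f"layer{i}")(x, edges, n, self_loop_nodes)
        return scatter_sum(x, np.arange(n, dtype=np.intp), graph_ids, n_graphs)


def mgnn_forward(mgnn: MGNN, fg) -> np.ndarray:
    """Encode one featured fusion graph to its ``Out_str`` vector."""
    if fg.node_features is None:
        raise ValueError("fusion graph has no node features")
    loops = (
        np.array([fg.virtual_index], dtype=np.intp)
        if fg.virtual_self_loop
        else None
    )
    out = mgnn(Tensor(fg.node_features), fg.edges, self_loop_nodes=loops)
    return out.data[0]
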