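"""Sequence-modality feature extractor.

Pipeline per entity (drug / target): token embedding + affine map -> group
enhancement (channel-group gating) -> stacked BiLSTM.  The two per-token
feature streams are then pooled three ways by masked multi-head link
attention (target alone, drug alone, and their concatenation), the pooled
blocks are concatenated head-major, and a residual feed-forward layer
produces the flat sequence representation ``out_seq``.

Link attention is query-only pooling attention: a linear map scores each
position per head, masked positions are shielded with a large negative
constant before the softmax, and the attention distribution is multiplied
with the raw per-token features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BiLSTM,
    Dropout,
    Embedding,
    Linear,
    Module,
    Parameter,
    Tensor,
    concat,
)
from .vocab import TokenSeq, drug_vocabulary, protein_vocabulary

NEG_INF = 1e9  # realization of -inf in masked attention scores


@dataclass
class EncoderConfig:
    embed_dim: int = 128
    lstm_layers: int = 2
    heads: int = 8
    gem_groups: int = 8
    gem_epsilon: float = 1e-5
    max_len_target: int = 600
    max_len_drug: int = 150
    dropout: float = 0.1

    def __post_init__(self):
        if self.embed_dim % self.gem_groups:
            raise ValueError("embed_dim must be divisible by gem_groups")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.gem_epsilon <= 0:
            raise ValueError("gem_epsilon must be > 0")
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even (BiLSTM halves)")


@dataclass
class SeqOutput:
    """Per-token features, the three attention maps, pooled blocks, and the
    flat sequence representation.  All tensors are batched (leading B)."""

    f_target: Tensor  # (B, Lt, D)
    f_drug: Tensor  # (B, Ld, D)
    pooled_target: Tensor  # (B, H, D)
    pooled_drug: Tensor  # (B, H, D)
    pooled_cat: Tensor  # (B, H, D)
    attn_target: Tensor  # (B, H, Lt)
    attn_drug: Tensor  # (B, H, Ld)
    attn_cat: Tensor  # (B, H, Lt+Ld)
    out_seq: Tensor  # (B, 3*H*D)
    target_mask: np.ndarray
    drug_mask: np.ndarray
    eos_target: np.ndarray  # (B,) EOS position per sample
    eos_drug: np.ndarray


class GroupEnhance(Module):
    """Group Enhance Module: splits channels into G groups, scores each
    position by its similarity to the group's channel-mean, normalizes the
    scores over (unmasked) positions, and gates the features with a sigmoid
    of the affinely mapped normalized scores."""

    def __init__(self, dim: int, groups: int, epsilon: float):
        super().__init__()
        if dim % groups:
            raise ValueError("dim must be divisible by groups")
        self.groups = groups
        self.epsilon = epsilon
        self.weight = Parameter(np.ones(groups))
        self.bias = Parameter(np.zeros(groups))

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        b, length, dim = x.shape
        if length == 0:
            raise ValueError("zero-length sequence")
        g = self.groups
        dg = dim // g
        xg = x.reshape(b, length, g, dg)
        xm = xg.mean(axis=3, keepdims=True)
        t = (xg * xm).sum(axis=3)  # (B, L, G)
        m = Tensor(mask.astype(np.float64)[:, :, None])  # (B, L, 1)
        count = mask.sum(axis=1).astype(np.float64)[:, None, None]
        mean_t = (t * m).sum(axis=1, keepdims=True) * (1.0 / count)
        tc = t - mean_t
        var = ((tc * tc) * m).sum(axis=1, keepdims=True) * (1.0 / count)
        t_norm = tc * ((var.sqrt() + self.epsilon) ** -1.0)
        gate = (t_norm * self.weight + self.bias).sigmoid()  # (B, L, G)
        out = xg * gate.reshape(b, length, g, 1)
        return out.reshape(b, length, dim)


class LinkAttention(Module):
    """Masked multi-head query-only pooling attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.heads = heads
        self.query = Linear(dim, heads, rng)

    def forward(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """x: (B, L, D); mask: (B, L) or (B, H, L) booleans (True = valid).
        Returns pooled (B, H, D) and attention (B, H, L)."""
        single = x.ndim == 2
        if single:
            x = x.reshape(1, *x.shape)
            mask = np.asarray(mask)
            if mask.ndim == 1:
                mask = mask[None, :]
            else:
                mask = mask[None, :, :]
        b, length, _ = x.shape
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = np.broadcast_to(mask[:, None, :], (b, self.heads, length))
        if not mask.any(axis=2).all():
            raise ValueError("a head has every position masked; softmax undefined")
        scores = self.query(x).transpose(0, 2, 1)  # (B, H, L)
        shield = Tensor(np.where(mask, 0.0, -NEG_INF))
        attn = (scores + shield).softmax(axis=2)
        # exp(-1e9 - max) underflows to exactly 0; the multiply makes the
        # exact-zero guarantee explicit and independent of the score scale.
        attn = attn * Tensor(mask.astype(np.float64))
        pooled = attn @ x  # (B, H, D)
        if single:
            return (
                pooled.reshape(*pooled.shape[1:]),
                attn.reshape(*attn.shape[1:]),
            )
        return pooled, attn


class _EntityEncoder(Module):
    """Embedding + FC + group enhancement + stacked BiLSTM for one entity."""

    def __init__(self, vocab_size: int, cfg: EncoderConfig, rng, use_gem: bool):
        super().__init__()
        d = cfg.embed_dim
        self.embedding = Embedding(vocab_size, d, rng)
        self.fc = Linear(d, d, rng)
        self.use_gem = use_gem
        if use_gem:
            self.gem = GroupEnhance(d, cfg.gem_groups, cfg.gem_epsilon)
        self.n_layers = cfg.lstm_layers
        for i in range(cfg.lstm_layers):
            setattr(self, f"bilstm{i}", BiLSTM(d, d, rng))
        self.drop = Dropout(cfg.dropout, rng)

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        x = self.fc(self.embedding(ids))
        if self.use_gem:
            x = self.gem(x, mask)
        x = self.drop(x)
        for i in range(self.n_layers):
            y = getattr(self, f"bilstm{i}")(x, mask)
            x = self.drop(y) if i < self.n_layers - 1 else y
        return x


class SeqEncoder(Module):
    def __init__(
        self,
        config: EncoderConfig | None = None,
        seed: int = 0,
        use_gem: bool = True,
        use_link_attention: bool = True,
        drug_vocab_size: int | None = None,
        target_vocab_size: int | None = None,
    ):
        super().__init__()
        cfg = config or EncoderConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.use_link_attention = use_link_attention
        dv = drug_vocab_size or len(drug_vocabulary())
        tv = target_vocab_size or len(protein_vocabulary())
        self.target_enc = _EntityEncoder(tv, cfg, rng, use_gem)
        self.drug_enc = _EntityEncoder(dv, cfg, rng, use_gem)
        self.attn_target = LinkAttention(cfg.embed_dim, cfg.heads, rng)
        self.attn_drug = LinkAttention(cfg.embed_dim, cfg.heads, rng)
        self.attn_cat = LinkAttention(cfg.embed_dim, cfg.heads, rng)
        width = 3 * cfg.heads * cfg.embed_dim
        self.ffn = Linear(width, width, rng)

    @property
    def out_dim(self) -> int:
        return 3 * self.config.heads * self.config.embed_dim

    def _pool(self, attn: LinkAttention, x: Tensor, mask: np.ndarray):
        if self.use_link_attention:
            return attn(x, mask)
        # Ablation: masked mean pooling replicated across heads.
        b, length, d = x.shape
        h = self.config.heads
        m = mask.astype(np.float64)
        w = m / m.sum(axis=1, keepdims=True)
        attn_w = np.broadcast_to(w[:, None, :], (b, h, length)).copy()
        weights = Tensor(attn_w)
        return weights @ x, weights

    def forward(
        self,
        target_ids: np.ndarray,
        target_mask: np.ndarray,
        drug_ids: np.ndarray,
        drug_mask: np.ndarray,
        eos_target: np.ndarray,
        eos_drug: np.ndarray,
    ) -> SeqOutput:
        b = target_ids.shape[0]
        h, d = self.config.heads, self.config.embed_dim
        f_t = self.target_enc(target_ids, target_mask)
        f_d = self.drug_enc(drug_ids, drug_mask)
        pooled_t, a_t = self._pool(self.attn_target, f_t, target_mask)
        pooled_d, a_d = self._pool(self.attn_drug, f_d, drug_mask)
        f_cat = concat([f_t, f_d], axis=1)
        mask_cat = np.concatenate([target_mask, drug_mask], axis=1)
        pooled_c, a_c = self._pool(self.attn_cat, f_cat, mask_cat)
        r_seq = concat(
            [
                pooled_t.reshape(b, h * d),
                pooled_d.reshape(b, h * d),
                pooled_c.reshape(b, h * d),
            ],
            axis=1,
        )
        out_seq = self.ffn(r_seq).relu() + r_seq
        return SeqOutput(
            f_target=f_t,
            f_drug=f_d,
            pooled_target=pooled_t,
            pooled_drug=pooled_d,
            pooled_cat=pooled_c,
            attn_target=a_t,
            attn_drug=a_d,
            attn_cat=a_c,
            out_seq=out_seq,
            target_mask=np.asarray(target_mask, dtype=bool),
            drug_mask=np.asarray(drug_mask, dtype=bool),
            eos_target=np.asarray(eos_target),
            eos_drug=np.asarray(eos_drug),
        )


def pad_batch(seqs: list[TokenSeq], pad_id: int, max_len: int | None = None):
    """Pad token sequences to a common length; returns (ids, mask, eos)."""
    length = max(len(s) for s in seqs)
    if max_len is not None and length > max_len:
        raise ValueError("sequence exceeds configured maximum length")
    ids = np.full((len(seqs), length), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), length), dtype=bool)
    eos = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s.ids
        mask[i, : len(s)] = s.mask
        eos[i] = s.eos_index
    return ids, mask, eos


def seq_forward(
    encoder: SeqEncoder, drug_tokens: TokenSeq, target_tokens: TokenSeq
) -> SeqOutput:
    """Single-pair convenience wrapper (batch of one)."""
    t_ids, t_mask, t_eos = pad_batch([target_tokens], protein_vocabulary().pad_id)
    d_ids, d_mask, d_eos = pad_batch([drug_tokens], drug_vocabulary().pad_id)
    return encoder(t_ids, t_mask, d_ids, d_mask, t_eos, d_eos)
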