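"""Attention-based interpretation.

Per-residue and per-atom importances are read off the sequence-side link
attention maps (head-averaged).  Region statistics partition every residue of
a target into three disjoint buckets — inside an annotated binding site,
inside the binding range but outside any site, and outside the range — and
compare attention levels between buckets with Welch t-tests.  The range
analysis uses the sequence-side target attention because it is the only map
that spans residues outside the binding range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seq_encoder import SeqOutput
from .target_io import BindingRange
from .vocab import TokenSeq

REGIONS = ("binding_site", "binding_range", "outside")


@dataclass
class AttentionReport:
    per_residue: np.ndarray
    per_atom: np.ndarray
    region_means: dict


def extract_attention(
    seq_out: SeqOutput,
    target_tokens: TokenSeq,
    drug_tokens: TokenSeq,
    sample: int = 0,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Head-averaged per-residue and per-atom attention weights.

    Residue weights are the target attention at residue token positions (the
    EOS token is dropped); atom weights are the drug attention mapped back
    through ``atom_map``.  With ``standardize`` the weights are z-scored per
    sequence, giving signed values centered at zero.
    """
    a_t = seq_out.attn_target.data[sample].mean(axis=0)  # (Lt,)
    a_d = seq_out.attn_drug.data[sample].mean(axis=0)
    n_res = len(target_tokens) - 1  # residues precede the EOS token
    per_residue = a_t[:n_res].copy()
    atom_map = drug_tokens.atom_map or {}
    per_atom = np.array([a_d[atom_map[k]] for k in sorted(atom_map)])
    if standardize:
        per_residue = _zscore(per_residue)
        per_atom = _zscore(per_atom)
    return per_residue, per_atom


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def region_labels(
    n_residues: int,
    site_intervals: list[tuple[int, int]],
    brange: BindingRange,
) -> np.ndarray:
    """Disjoint exhaustive partition of residues (0-based) into
    binding_site / binding_range (range minus sites) / outside."""
    labels = np.full(n_residues, "outside", dtype=object)
    labels[brange.start : min(brange.end, n_residues)] = "binding_range"
    for a, b in site_intervals:  # 1-based inclusive
        labels[a - 1 : b] = "binding_site"
    return labels


def region_stats(
    weights: np.ndarray,
    site_intervals: list[tuple[int, int]],
    brange: BindingRange,
) -> dict:
    """Mean/std/n of attention per region plus Welch t-tests between the
    region pairs (empty buckets are reported as undefined and skipped)."""
    weights = np.asarray(weights, dtype=float)
    labels = region_labels(len(weights), site_intervals, brange)
    buckets = {r: weights[labels == r] for r in REGIONS}
    out: dict = {"regions": {}, "tests": {}}
    for region, vals in buckets.items():
        if vals.size:
            out["regions"][region] = {
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        else:
            out["regions"][region] = {"mean": None, "std": None, "n": 0}
    for i, ra in enumerate(REGIONS):
        for rb in REGIONS[i + 1 :]:
            a, b = buckets[ra], buckets[rb]
            if a.size < 2 or b.size < 2:
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            t1, p1 = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            out["tests"][f"{ra}_vs_{rb}"] = {
                "t": float(t),
                "p_two_sided": float(p),
                "p_greater": float(p1),
            }
    return out
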