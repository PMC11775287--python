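"""Training protocols and dataset splitting.

Training follows a two-stage schedule: a warm-up stage fits the sequence
encoder alone (through a temporary scalar head on ``out_seq``), after which
the whole model — sequence encoder, fusion graph, GIN stack, fusion head — is
optimized jointly.  Both stages minimize mean squared error with Adam.  Joint
training early-stops on validation MSE and returns the best-validation
checkpoint.

Splits implement the 5-fold 7:1:2 protocol and the three cold-start modes:
``unseen_drug`` (no test/val drug occurs in any training pair),
``unseen_target`` (same over targets) and ``all_unseen`` (both constraints;
pairs straddling the entity partitions are discarded).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .metrics import MetricReport, report
from .model import DTAModel, Pair
from .nn import Adam, Tensor

SPLIT_MODES = ("random_cv", "unseen_drug", "unseen_target", "all_unseen")


@dataclass
class TrainConfig:
    warmup_epochs: int = 20
    joint_epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 128
    seed: int = 0
    patience: int = 20

    def __post_init__(self):
        if min(self.joint_epochs, self.lr, self.batch_size, self.patience) <= 0:
            raise ValueError("joint_epochs, lr, batch_size, patience must be > 0")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")


@dataclass
class SplitSpec:
    mode: str = "random_cv"
    fold_count: int = 5
    ratios: tuple[int, int, int] = (7, 1, 2)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"mode must be one of {SPLIT_MODES}")


@dataclass
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def _chunk(perm: np.ndarray, k: int) -> list[np.ndarray]:
    return [np.sort(c) for c in np.array_split(perm, k)]


def _train_val(remaining: np.ndarray, rng: np.random.Generator) -> tuple:
    """Split the non-test portion 7:1 (train:val)."""
    perm = rng.permutation(remaining)
    n_val = max(1, round(len(perm) / 8))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def make_splits(records, spec: SplitSpec) -> list[Fold]:
    """Per-fold (train, val, test) index sets over ``records``.

    ``records`` only needs ``drug_id`` / ``target_id`` attributes (both
    ``AffinityRecord`` and prepared ``Pair`` objects qualify).
    """
    n = len(records)
    drug_of = np.array([_drug_id(r) for r in records])
    target_of = np.array([_target_id(r) for r in records])
    rng = np.random.default_rng(spec.seed)
    k = spec.fold_count
    folds: list[Fold] = []

    if spec.mode == "random_cv":
        if n < k:
            raise ValueError(f"need >= {k} records, got {n}")
        chunks = _chunk(rng.permutation(n), k)
        for i in range(k):
            test = chunks[i]
            rest = np.concatenate([c for j, c in enumerate(chunks) if j != i])
            train, val = _train_val(rest, rng)
            folds.append(Fold(train=train, val=val, test=test))
        return folds

    def entity_folds(values: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        uniq = np.unique(values)
        if len(uniq) < k:
            raise ValueError(
                f"{spec.mode} needs >= {k} distinct entities, got {len(uniq)}"
            )
        return uniq, _chunk(rng.permutation(len(uniq)), k)

    if spec.mode in ("unseen_drug", "unseen_target"):
        values = drug_of if spec.mode == "unseen_drug" else target_of
        uniq, chunks = entity_folds(values)
        for i in range(k):
            test_entities = set(uniq[chunks[i]])
            rest = np.concatenate([c for j, c in enumerate(chunks) if j != i])
            tr_e, va_e = _train_val(rest, rng)
            train_entities, val_entities = set(uniq[tr_e]), set(uniq[va_e])
            folds.append(
                Fold(
                    train=np.where([v in train_entities for v in values])[0],
                    val=np.where([v in val_entities for v in values])[0],
                    test=np.where([v in test_entities for v in values])[0],
                )
            )
        return folds

    # all_unseen: partition drugs and targets independently; keep only pairs
    # whose two entities land in the same split.
    d_uniq, d_chunks = entity_folds(drug_of)
    t_uniq, t_chunks = entity_folds(target_of)
    for i in range(k):
        d_test, t_test = set(d_uniq[d_chunks[i]]), set(t_uniq[t_chunks[i]])
        d_rest = np.concatenate([c for j, c in enumerate(d_chunks) if j != i])
        t_rest = np.concatenate([c for j, c in enumerate(t_chunks) if j != i])
        d_tr, d_va = _train_val(d_rest, rng)
        t_tr, t_va = _train_val(t_rest, rng)
        sets = {
            "train": (set(d_uniq[d_tr]), set(t_uniq[t_tr])),
            "val": (set(d_uniq[d_va]), set(t_uniq[t_va])),
            "test": (d_test, t_test),
        }
        idx = {
            name: np.where(
                [d in ds and t in ts for d, t in zip(drug_of, target_of)]
            )[0]
            for name, (ds, ts) in sets.items()
        }
        folds.append(Fold(train=idx["train"], val=idx["val"], test=idx["test"]))
    return folds


def _drug_id(r) -> str:
    return r.drug_id if hasattr(r, "drug_id") else r.drug.drug_id


def _target_id(r) -> str:
    return r.target_id if hasattr(r, "target_id") else r.target.target_id


# --------------------------------------------------------------------------
# Training loops


def _epoch(model: DTAModel, pairs, opt, rng, batch_size, seq_head_only=False):
    order = rng.permutation(len(pairs))
    total, count = 0.0, 0
    for lo in range(0, len(order), batch_size):
        batch = [pairs[i] for i in order[lo : lo + batch_size]]
        y = Tensor(np.array([p.affinity for p in batch]) - model.y_offset)
        if seq_head_only:
            seq_out = model._encode_sequences(batch)
            pred = model.warm_head(seq_out.out_seq).reshape(len(batch))
        else:
            pred, _ = model.forward(batch)
        diff = pred - y
        loss = (diff * diff).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        total += float(loss.data) * len(batch)
        count += len(batch)
    return total / count


def train_warmup(
    model: DTAModel, train_pairs: list[Pair], config: TrainConfig
) -> list[float]:
    """Stage 1: fit the sequence encoder with a temporary scalar head.

    With ``warmup_epochs == 0`` the weights are left at initialization
    (this is also the "no warm-up" ablation).  Returns per-epoch train MSE.
    """
    model.y_offset = float(np.mean([p.affinity for p in train_pairs]))
    if config.warmup_epochs == 0 or model.config.graph_only:
        # nothing to warm up without a sequence branch
        return []
    rng = np.random.default_rng(config.seed + 1)
    params = list(model.seq.parameters()) + list(model.warm_head.parameters())
    opt = Adam(params, lr=config.lr)
    model.train()
    return [
        _epoch(model, train_pairs, opt, rng, config.batch_size, seq_head_only=True)
        for _ in range(config.warmup_epochs)
    ]


def train_joint(
    model: DTAModel,
    train_pairs: list[Pair],
    val_pairs: list[Pair],
    config: TrainConfig,
) -> dict:
    """Stage 2: end-to-end optimization of all modules under MSE.

    Early-stops when validation MSE has not improved for ``patience`` epochs
    and restores the best-validation checkpoint.
    """
    model.y_offset = float(np.mean([p.affinity for p in train_pairs]))
    rng = np.random.default_rng(config.seed + 2)
    opt = Adam(list(model.parameters()), lr=config.lr)
    history = {"train_mse": [], "val_mse": []}
    best_val, best_state, since_best = np.inf, None, 0
    for _ in range(config.joint_epochs):
        model.train()
        tr = _epoch(model, train_pairs, opt, rng, config.batch_size)
        val_pred = model.predict(val_pairs, config.batch_size)
        val_mse = float(
            np.mean((val_pred - np.array([p.affinity for p in val_pairs])) ** 2)
        )
        history["train_mse"].append(tr)
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val, since_best = val_mse, 0
            best_state = copy.deepcopy(model.state_dict())
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_val_mse"] = best_val
    model.eval()
    return history


def train_model(
    model: DTAModel,
    train_pairs: list[Pair],
    val_pairs: list[Pair],
    config: TrainConfig,
) -> dict:
    """Warm-up (unless disabled) followed by joint training."""
    warm = train_warmup(model, train_pairs, config)
    history = train_joint(model, train_pairs, val_pairs, config)
    history["warmup_mse"] = warm
    return history


def evaluate(model: DTAModel, pairs: list[Pair], batch_size: int = 64) -> MetricReport:
    pred = model.predict(pairs, batch_size)
    y = np.array([p.affinity for p in pairs])
    return report(y, pred)
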