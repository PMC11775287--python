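"""Regression metrics: MSE, concordance index, and the rm2 coefficient.

Conventions (fixed, and cross-checked against brute-force oracles in tests):

* CI counts all pairs with y_i > y_j; a correctly ordered prediction scores
  1, a tied prediction 0.5, a reversed one 0.
* rm2 is the Roy regression-toward-the-mean coefficient in its
  single-direction form: rm2 = r^2 * (1 - sqrt(|r^2 - r0^2|)), with r^2 the
  squared Pearson correlation of (y, yhat) and r0^2 the coefficient of
  determination of the best through-origin fit y ~ k * yhat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricReport:
    mse: float
    ci: float
    rm2: float
    n: int

    def as_dict(self) -> dict:
        return {"mse": self.mse, "ci": self.ci, "rm2": self.rm2, "n": self.n}


def _check(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length non-empty vectors")
    return y, yhat


def mse(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def concordance_index(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    if y.size < 2:
        raise ValueError("CI needs at least two observations")
    diff_y = y[:, None] - y[None, :]
    comparable = diff_y > 0  # ordered pairs (i, j) with y_i > y_j
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("CI undefined: all labels tied")
    diff_p = yhat[:, None] - yhat[None, :]
    credit = np.where(diff_p > 0, 1.0, np.where(diff_p == 0, 0.5, 0.0))
    return float(credit[comparable].sum() / n_pairs)


def rm_squared(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    if y.size < 3:
        raise ValueError("rm2 needs at least three observations")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("rm2 undefined for zero-variance inputs")
    r = np.corrcoef(y, yhat)[0, 1]
    r2 = r**2
    k = float(np.sum(y * yhat) / np.sum(yhat**2))
    ss_res0 = float(np.sum((y - k * yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r0_2 = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r0_2))))


def report(y, yhat) -> MetricReport:
    y, yhat = _check(y, yhat)
    return MetricReport(
        mse=mse(y, yhat),
        ci=concordance_index(y, yhat),
        rm2=rm_squared(y, yhat),
        n=int(y.size),
    )
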