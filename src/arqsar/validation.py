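"""Internal and external validation metrics for MLR QSAR models.

Internal: coefficient of determination R2, training RMSE, leave-one-out
Q2 (computed with the hat-matrix shortcut e_i/(1-h_ii), which is algebraically
identical to refitting without each compound), leave-many-out Q2, and
Y-scrambling (response permutation) as a chance-correlation control.

External (prediction-set) predictivity, three reference-variance conventions:

    Q2_F1 = 1 - SS_ext / sum((y_ext - mean(y_train))^2)
    Q2_F2 = 1 - SS_ext / sum((y_ext - mean(y_ext))^2)
    Q2_F3 = 1 - (SS_ext / n_ext) / (sum((y_train - mean(y_train))^2) / n_train)

with SS_ext = sum((y_ext - yhat_ext)^2), plus Lin's concordance correlation
coefficient (CCC), which measures agreement with the identity line rather than
mere linear association.

RMSE uses the 1/n convention throughout (no degrees-of-freedom correction).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateLOOError
from .gamlr import fit_ols
from .tables import DescriptorTable

__all__ = [
    "MetricsReport",
    "r_squared",
    "rmse",
    "q2_loo",
    "q2_lmo",
    "q2_f1",
    "q2_f2",
    "q2_f3",
    "ccc",
    "y_scramble",
    "external_metrics",
]


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of internal/external validation statistics for one model."""

    r2: float
    rmse_train: float
    q2_loo: float
    q2_lmo: float | None = None
    q2_f1: float | None = None
    q2_f2: float | None = None
    q2_f3: float | None = None
    ccc: float | None = None
    rmse_prediction: float | None = None
    y_scramble_mean_r2: float | None = None
    y_scramble_mean_q2: float | None = None
    lmo_config: dict | None = None
    scramble_config: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(y: Sequence[float], yhat: Sequence[float], min_len: int = 1):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ConfigError("y and yhat must be 1-D and equal length")
    if len(y) < min_len:
        raise ConfigError(f"need at least {min_len} observations")
    return y, yhat


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """1 - SS_res / SS_tot about the mean of y."""
    y, yhat = _as_arrays(y, yhat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigError("y is constant: R2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean squared error, 1/n convention."""
    y, yhat = _as_arrays(y, yhat, min_len=1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def q2_loo(table: DescriptorTable, y: Sequence[float]) -> float:
    """Leave-one-out cross-validated Q2 = 1 - PRESS / SS_tot.

    Uses the exact hat-matrix identity: the LOO residual of compound i equals
    e_i / (1 - h_ii) for an OLS fit, so no refitting loop is needed. Raises
    :class:`DegenerateLOOError` if any training point has leverage 1.
    """
    y = np.asarray(y, dtype=float)
    fit = fit_ols(table, y)
    design = np.column_stack([np.ones(table.n_compounds), table.values])
    # hat diagonal via the normal-equations inverse
    xtx_inv = np.linalg.inv(design.T @ design)
    h = np.einsum("ij,jk,ik->i", design, xtx_inv, design)
    if np.any(h >= 1.0 - 1e-12):
        raise DegenerateLOOError("a training point has leverage 1; LOO undefined")
    press = float(np.sum((fit.residuals / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigError("y is constant: Q2 undefined")
    return 1.0 - press / ss_tot


def q2_loo_refit(table: DescriptorTable, y: Sequence[float]) -> float:
    """Brute-force LOO Q2 by explicit n refits (reference implementation)."""
    y = np.asarray(y, dtype=float)
    n = table.n_compounds
    press = 0.0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = table.select_compounds([table.compound_ids[j] for j in keep])
        fit = fit_ols(sub, y[keep])
        pred = fit.model.intercept + float(
            np.dot(fit.model.coefficients, table.values[i, :])
        )
        press += (y[i] - pred) ** 2
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def q2_lmo(
    table: DescriptorTable,
    y: Sequence[float],
    leave_out_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int = 0,
    aggregation: str = "mean",
) -> float:
    """Leave-many-out Q2 over random withheld subsets.

    Each iteration withholds ``round(n * fraction)`` compounds (at least 1),
    refits on the rest, and scores the withheld block against the mean of the
    kept responses. ``aggregation="mean"`` (default) averages the
    per-iteration Q2 values; ``"pooled"`` pools numerator and denominator
    sums across iterations before forming the ratio, which is stable even for
    single-compound out-groups (where it converges to the LOO statistic).
    """
    y = np.asarray(y, dtype=float)
    n = table.n_compounds
    n_out = max(1, int(round(n * leave_out_fraction)))
    n_kept = n - n_out
    if n_kept <= table.n_descriptors + 2:
        raise ConfigError(
            f"leave_out_fraction {leave_out_fraction} keeps only {n_kept} compounds"
        )
    if aggregation not in ("mean", "pooled"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    rng = np.random.default_rng(seed)
    scores = np.empty(iterations)
    ss_out_total = 0.0
    ss_ref_total = 0.0
    ids = np.arange(n)
    for it in range(iterations):
        out = rng.choice(ids, size=n_out, replace=False)
        keep = np.setdiff1d(ids, out)
        sub = table.select_compounds([table.compound_ids[j] for j in keep])
        fit = fit_ols(sub, y[keep])
        preds = fit.model.intercept + table.values[out, :] @ np.asarray(
            fit.model.coefficients
        )
        ss_out = float(np.sum((y[out] - preds) ** 2))
        ss_ref = float(np.sum((y[out] - y[keep].mean()) ** 2))
        ss_out_total += ss_out
        ss_ref_total += ss_ref
        scores[it] = 1.0 - ss_out / ss_ref if ss_ref > 0 else np.nan
    if aggregation == "pooled":
        return 1.0 - ss_out_total / ss_ref_total
    return float(np.nanmean(scores))


def q2_f1(y_ext: Sequence[float], yhat_ext: Sequence[float], ybar_train: float) -> float:
    y, yhat = _as_arrays(y_ext, yhat_ext, min_len=2)
    denom = float(np.sum((y - ybar_train) ** 2))
    if denom == 0.0:
        raise ConfigError("external responses all equal the training mean")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def q2_f2(y_ext: Sequence[float], yhat_ext: Sequence[float]) -> float:
    y, yhat = _as_arrays(y_ext, yhat_ext, min_len=2)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ConfigError("external responses are constant")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def q2_f3(
    y_ext: Sequence[float], yhat_ext: Sequence[float], y_train: Sequence[float]
) -> float:
    y, yhat = _as_arrays(y_ext, yhat_ext, min_len=1)
    y_train = np.asarray(y_train, dtype=float)
    denom = float(np.mean((y_train - y_train.mean()) ** 2))
    if denom == 0.0:
        raise ConfigError("training responses are constant")
    return 1.0 - float(np.mean((y - yhat) ** 2)) / denom


def ccc(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (agreement with y = x)."""
    y, yhat = _as_arrays(y, yhat, min_len=2)
    ybar, pbar = y.mean(), yhat.mean()
    sy = float(np.sum((y - ybar) ** 2))
    sp = float(np.sum((yhat - pbar) ** 2))
    cross = float(np.sum((y - ybar) * (yhat - pbar)))
    denom = sy + sp + len(y) * (ybar - pbar) ** 2
    if denom == 0.0:
        raise ConfigError("both sequences constant: CCC undefined")
    return 2.0 * cross / denom


def external_metrics(
    y_ext: Sequence[float],
    yhat_ext: Sequence[float],
    y_train: Sequence[float],
) -> dict[str, float]:
    """All four external predictivity statistics plus prediction RMSE."""
    y_train = np.asarray(y_train, dtype=float)
    return {
        "q2_f1": q2_f1(y_ext, yhat_ext, float(y_train.mean())),
        "q2_f2": q2_f2(y_ext, yhat_ext),
        "q2_f3": q2_f3(y_ext, yhat_ext, y_train),
        "ccc": ccc(y_ext, yhat_ext),
        "rmse_prediction": rmse(y_ext, yhat_ext),
    }


def y_scramble(
    table: DescriptorTable,
    y: Sequence[float],
    iterations: int = 5000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Response-permutation control: refit the same descriptor subset against
    randomly permuted activities.

    Returns (mean scrambled R2, mean scrambled Q2_LOO, R2 array, Q2 array).
    A real structure-activity relationship shows unscrambled R2 well above the
    scrambled distribution.
    """
    y = np.asarray(y, dtype=float)
    if iterations < 1:
        raise ConfigError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    r2s = np.empty(iterations)
    q2s = np.empty(iterations)
    for it in range(iterations):
        perm = rng.permutation(y)
        fit = fit_ols(table, perm)
        yhat = perm - fit.residuals
        r2s[it] = r_squared(perm, yhat)
        try:
            q2s[it] = q2_loo(table, perm)
        except DegenerateLOOError:
            q2s[it] = np.nan
    return float(r2s.mean()), float(np.nanmean(q2s)), r2s, q2s
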