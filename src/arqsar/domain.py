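"""Leverage-based applicability domain (Williams plot / Insubria graph data).

The applicability domain of an MLR QSAR model is defined in the space of its
selected descriptors through the leverage (hat value)

    h_i = x~_i (X~' X~)^(-1) x~_i'

where X~ is the training design matrix with an intercept column and x~_i the
intercept-augmented descriptor row of a query compound. Training leverages are
the hat-matrix diagonal, so they sum to p + 1. A query with h above the cutoff
h* = 3 (p + 1) / n sits outside the structural domain and its prediction is an
extrapolation.

For compounds with measured activity the domain check pairs leverage with the
standardized cross-validated residual (Williams plot; |residual| > 2.5 flags a
response outlier). For screening compounds without measurements, leverage is
plotted against the predicted activity instead (Insubria graph).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .tables import DescriptorTable, ModelSpec

__all__ = [
    "LeverageReport",
    "leverage_cutoff",
    "leverages",
    "standardized_residuals",
    "williams_points",
    "insubria_points",
]

RESIDUAL_SIGMA_THRESHOLD = 2.5


@dataclass(frozen=True)
class LeverageRecord:
    compound_id: str
    h: float
    inside_ad: bool
    standardized_residual: float | None = None
    residual_flag: bool | None = None
    predicted: float | None = None


@dataclass(frozen=True)
class LeverageReport:
    h_star: float
    records: tuple[LeverageRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def leverage_cutoff(p: int, n: int) -> float:
    """Warning leverage h* = 3 (p + 1) / n for p descriptors, n training rows."""
    if p < 1:
        raise ConfigError("p must be >= 1")
    if n <= p + 1:
        raise ConfigError(f"need n > p + 1 (got n={n}, p={p})")
    return 3.0 * (p + 1) / n


def _augment(values: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(values.shape[0]), values])


def leverages(x_train: DescriptorTable, x_query: DescriptorTable) -> np.ndarray:
    """Hat values of query rows against the training design (with intercept).

    Querying the training table itself returns the hat-matrix diagonal.
    """
    if x_query.descriptor_names != x_train.descriptor_names:
        raise DomainError(
            "query descriptor columns do not match training columns "
            f"({x_query.descriptor_names} vs {x_train.descriptor_names})"
        )
    design = _augment(x_train.values)
    gram = design.T @ design
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        raise DomainError("training design X~'X~ is singular") from None
    q = _augment(x_query.values)
    return np.einsum("ij,jk,ik->i", q, gram_inv, q)


def standardized_residuals(
    y: Sequence[float], yhat: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals divided by the sample SD (ddof=1) of the training residuals.

    Returns (standardized residuals, boolean flags for |value| > 2.5).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ConfigError("y and yhat must have equal length")
    resid = y - yhat
    s = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    if s == 0.0:
        raise DomainError("zero residual variance: standardized residuals undefined")
    std = resid / s
    return std, np.abs(std) > RESIDUAL_SIGMA_THRESHOLD


def _predict(model: ModelSpec, table: DescriptorTable) -> np.ndarray:
    sub = table.select_descriptors(model.descriptor_names)
    return model.intercept + sub.values @ np.asarray(model.coefficients)


def williams_points(
    model: ModelSpec,
    x_train: DescriptorTable,
    y_train: Sequence[float],
    x_ext: DescriptorTable | None = None,
    y_ext: Sequence[float] | None = None,
) -> LeverageReport:
    """Leverage vs standardized residual for labelled compounds.

    Residuals of both training and external compounds are standardized by the
    training residual SD, so external rows are judged on the training scale.
    """
    x_train = x_train.select_descriptors(model.descriptor_names)
    y_train = np.asarray(y_train, dtype=float)
    h_star = leverage_cutoff(model.p, x_train.n_compounds)
    h_train = leverages(x_train, x_train)
    yhat_train = _predict(model, x_train)
    resid_train = y_train - yhat_train
    s = float(np.std(resid_train, ddof=1))
    if s == 0.0:
        raise DomainError("zero training residual variance")

    records = []

    def add(ids, h, resid):
        std = resid / s
        for cid, hv, sv in zip(ids, h, std):
            records.append(
                LeverageRecord(
                    compound_id=cid,
                    h=float(hv),
                    inside_ad=bool(hv <= h_star),
                    standardized_residual=float(sv),
                    residual_flag=bool(abs(sv) > RESIDUAL_SIGMA_THRESHOLD),
                )
            )

    add(x_train.compound_ids, h_train, resid_train)
    if x_ext is not None:
        if y_ext is None:
            raise ConfigError("external table given without external activities")
        x_ext = x_ext.select_descriptors(model.descriptor_names)
        y_ext = np.asarray(y_ext, dtype=float)
        h_ext = leverages(x_train, x_ext)
        add(x_ext.compound_ids, h_ext, y_ext - _predict(model, x_ext))
    return LeverageReport(h_star=h_star, records=tuple(records))


def insubria_points(
    model: ModelSpec,
    x_train: DescriptorTable,
    x_screen: DescriptorTable | None,
) -> LeverageReport:
    """Leverage vs predicted activity for unlabelled screening compounds."""
    x_train = x_train.select_descriptors(model.descriptor_names)
    h_star = leverage_cutoff(model.p, x_train.n_compounds)
    if x_screen is None or x_screen.n_compounds == 0:
        return LeverageReport(h_star=h_star, records=())
    x_screen = x_screen.select_descriptors(model.descriptor_names)
    h = leverages(x_train, x_screen)
    preds = _predict(model, x_screen)
    records = tuple(
        LeverageRecord(
            compound_id=cid,
            h=float(hv),
            inside_ad=bool(hv <= h_star),
            predicted=float(pv),
        )
        for cid, hv, pv in zip(x_screen.compound_ids, h, preds)
    )
    return LeverageReport(h_star=h_star, records=records)
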