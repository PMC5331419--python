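"""Virtual screening with a frozen MLR model.

Applies a :class:`~arqsar.tables.ModelSpec` to a screening descriptor table,
attaches leverage-based applicability-domain flags (Y = inside the structural
domain, N = outside), and ranks compounds by descending predicted activity.
Predictions for compounds outside the domain are extrapolations and are
reported but flagged, mirroring how screening hits are triaged in practice:
the best in-domain compound is the defensible nomination, while high-scoring
out-of-domain compounds are leads worth a second look.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .domain import leverage_cutoff, leverages
from .errors import ConfigError, MissingValueError
from .tables import DescriptorTable, ModelSpec

__all__ = ["ScreenResult", "predict", "screen", "results_from_predictions", "top_hits"]


@dataclass(frozen=True)
class ScreenResult:
    compound_id: str
    predicted_pic50: float
    ad_flag: str  # "Y" inside the structural domain, "N" outside
    rank: int     # 1 = highest predicted activity
    h: float | None = None


def predict(model: ModelSpec, table: DescriptorTable) -> np.ndarray:
    """yhat = intercept + sum(coefficient * descriptor), matched by exact name."""
    missing = [n for n in model.descriptor_names if n not in table.descriptor_names]
    if missing:
        raise MissingValueError(f"table lacks model descriptor columns: {missing}")
    sub = table.select_descriptors(model.descriptor_names)
    return model.intercept + sub.values @ np.asarray(model.coefficients)


def _ranked(
    ids: Sequence[str],
    preds: Sequence[float],
    flags: Sequence[str],
    hs: Sequence[float | None],
) -> list[ScreenResult]:
    # descending prediction, ties broken by ascending compound id
    order = sorted(range(len(ids)), key=lambda i: (-preds[i], ids[i]))
    return [
        ScreenResult(
            compound_id=ids[i],
            predicted_pic50=float(preds[i]),
            ad_flag=flags[i],
            rank=rank,
            h=hs[i],
        )
        for rank, i in enumerate(order, start=1)
    ]


def screen(
    model: ModelSpec,
    x_train: DescriptorTable,
    x_screen: DescriptorTable,
    threshold: float | None = None,
) -> list[ScreenResult]:
    """Predict, flag against the training-set leverage domain, and rank.

    ``threshold``, when given, drops results with predicted activity below it
    (after ranking, so ranks reflect the full screen).
    """
    x_train = x_train.select_descriptors(model.descriptor_names)
    preds = predict(model, x_screen)
    x_screen_sub = x_screen.select_descriptors(model.descriptor_names)
    h = leverages(x_train, x_screen_sub)
    h_star = leverage_cutoff(model.p, x_train.n_compounds)
    flags = ["Y" if hv <= h_star else "N" for hv in h]
    results = _ranked(list(x_screen.compound_ids), preds, flags, [float(v) for v in h])
    if threshold is not None:
        results = [r for r in results if r.predicted_pic50 >= threshold]
    return results


def results_from_predictions(
    ids: Sequence[str], predictions: Sequence[float], ad_flags: Sequence[str]
) -> list[ScreenResult]:
    """Build ranked results from precomputed predictions and Y/N flags.

    Used when the descriptor values behind a published screen are unavailable
    but its predictions and domain flags are, so ranking and reporting still
    run on the printed numbers.
    """
    if not (len(ids) == len(predictions) == len(ad_flags)):
        raise ConfigError("ids, predictions and ad_flags must have equal length")
    bad = sorted({f for f in ad_flags} - {"Y", "N"})
    if bad:
        raise ConfigError(f"AD flags must be 'Y' or 'N', got {bad}")
    return _ranked(list(ids), list(map(float, predictions)), list(ad_flags), [None] * len(ids))


@dataclass(frozen=True)
class TopHits:
    best_overall: tuple[ScreenResult, ...]
    best_inside_ad: ScreenResult | None
    inside_ad: tuple[ScreenResult, ...]
    outside_ad: tuple[ScreenResult, ...]


def top_hits(
    results: Sequence[ScreenResult],
    k: int | None = None,
    activity_cutoff: float | None = None,
) -> TopHits:
    """Best-k compounds overall plus the best compound inside the domain.

    ``activity_cutoff`` restricts the overall list (not the partitions) to
    predictions at or above the cutoff.
    """
    if len(results) == 0:
        raise ConfigError("top_hits needs a non-empty result list")
    ordered = sorted(results, key=lambda r: r.rank)
    overall = ordered
    if activity_cutoff is not None:
        overall = [r for r in overall if r.predicted_pic50 >= activity_cutoff]
    if k is not None:
        overall = overall[: max(k, 0)]
    inside = tuple(r for r in ordered if r.ad_flag == "Y")
    outside = tuple(r for r in ordered if r.ad_flag == "N")
    return TopHits(
        best_overall=tuple(overall),
        best_inside_ad=inside[0] if inside else None,
        inside_ad=inside,
        outside_ad=outside,
    )


def results_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "predicted_pIC50": r.predicted_pic50,
                "h": r.h,
                "AD": r.ad_flag,
                "rank": r.rank,
            }
            for r in results
        ]
    )
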