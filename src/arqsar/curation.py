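"""Descriptor pre-selection filters.

Two standard QSAR curation steps, applied before any variable selection:

1. drop constant and near-constant descriptor columns (they carry no
   between-compound information and destabilise regression);
2. greedily prune pairwise-correlated descriptors until no surviving pair has
   |Pearson r| above a cutoff (default 0.98): among the worst-offending pair,
   the member with the larger mean absolute correlation to all other surviving
   columns is dropped, ties broken by dropping the later column in table
   order. The rule is applied iteratively, so the survivor set is guaranteed
   free of above-cutoff pairs.

Both filters preserve the input column order among survivors and report every
removal, keeping curation auditable and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CurationError
from .tables import DescriptorTable

__all__ = ["CurationReport", "remove_constant", "prune_correlated"]


@dataclass(frozen=True)
class CurationReport:
    """Audit trail of a curation step; removed + kept partition the input."""

    removed_constant: tuple[str, ...]
    removed_near_constant: tuple[str, ...]
    removed_correlated: tuple[tuple[str, str, float], ...]  # (dropped, partner, r)
    kept: tuple[str, ...]

    @property
    def removed(self) -> tuple[str, ...]:
        return (
            self.removed_constant
            + self.removed_near_constant
            + tuple(d for d, _, _ in self.removed_correlated)
        )

    def to_dict(self) -> dict:
        return {
            "removed_constant": list(self.removed_constant),
            "removed_near_constant": list(self.removed_near_constant),
            "removed_correlated": [
                {"dropped": d, "partner": p, "r": r} for d, p, r in self.removed_correlated
            ],
            "kept": list(self.kept),
        }


def remove_constant(
    table: DescriptorTable, near_constant_sd_fraction: float = 1e-4
) -> tuple[DescriptorTable, CurationReport]:
    """Drop zero-variance columns and columns with tiny relative spread.

    A column is *constant* when its sample standard deviation is exactly zero
    and *near-constant* when its standard deviation, divided by the largest
    column standard deviation in the table, falls below
    ``near_constant_sd_fraction``.
    """
    if near_constant_sd_fraction < 0:
        raise CurationError("near_constant_sd_fraction must be >= 0")
    sds = np.std(table.values, axis=0, ddof=1) if table.n_compounds > 1 else np.zeros(
        table.n_descriptors
    )
    max_sd = float(sds.max())
    removed_constant = []
    removed_near_constant = []
    kept = []
    for name, sd in zip(table.descriptor_names, sds):
        if sd == 0.0:
            removed_constant.append(name)
        elif max_sd > 0 and sd / max_sd < near_constant_sd_fraction:
            removed_near_constant.append(name)
        else:
            kept.append(name)
    if not kept:
        raise CurationError("curation removed every descriptor column")
    report = CurationReport(
        removed_constant=tuple(removed_constant),
        removed_near_constant=tuple(removed_near_constant),
        removed_correlated=(),
        kept=tuple(kept),
    )
    return table.select_descriptors(kept), report


def prune_correlated(
    table: DescriptorTable, r_cutoff: float = 0.98
) -> tuple[DescriptorTable, CurationReport]:
    """Iteratively remove one member of every descriptor pair with |r| > cutoff.

    Requires all columns to vary (run :func:`remove_constant` first).
    """
    if not (0.0 < r_cutoff <= 1.0):
        raise CurationError("r_cutoff must be in (0, 1]")
    if table.n_descriptors < 2:
        raise CurationError("need at least two descriptor columns to prune")
    sds = np.std(table.values, axis=0)
    if np.any(sds == 0.0):
        flat = [n for n, s in zip(table.descriptor_names, sds) if s == 0.0]
        raise CurationError(f"zero-variance columns present (run remove_constant first): {flat}")

    corr = np.corrcoef(table.values, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    alive = list(range(table.n_descriptors))
    dropped: list[tuple[str, str, float]] = []

    while True:
        sub = np.abs(corr[np.ix_(alive, alive)])
        if sub.max() <= r_cutoff:
            break
        # worst-offending pair; argmax scans row-major so ties resolve to the
        # earliest (i, j) pair, keeping the procedure deterministic
        flat = int(np.argmax(sub))
        ai, aj = divmod(flat, len(alive))
        i, j = alive[ai], alive[aj]
        if i > j:
            i, j = j, i
        # mean |r| of each member against all *other* surviving columns
        others = [k for k in alive if k not in (i, j)]
        if others:
            mean_i = float(np.mean(np.abs(corr[i, others])))
            mean_j = float(np.mean(np.abs(corr[j, others])))
        else:
            mean_i = mean_j = 0.0
        if mean_i > mean_j:
            drop, keep = i, j
        elif mean_j > mean_i:
            drop, keep = j, i
        else:  # tie: drop the later column in table order
            drop, keep = j, i
        dropped.append(
            (
                table.descriptor_names[drop],
                table.descriptor_names[keep],
                float(corr[drop, keep]),
            )
        )
        alive.remove(drop)
        if len(alive) < 2:
            break

    kept = tuple(table.descriptor_names[k] for k in alive)
    if not kept:
        raise CurationError("correlation pruning removed every column")
    report = CurationReport(
        removed_constant=(),
        removed_near_constant=(),
        removed_correlated=tuple(dropped),
        kept=kept,
    )
    return table.select_descriptors(kept), report
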