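"""MM/GBSA energy-term bookkeeping.

Composes binding free energies from precomputed per-complex energy terms
(exported by MD post-processing tools) under the single-trajectory MM/GBSA
decomposition:

    dE_MM   = dE_val + dE_ele + dE_vdw          (gas-phase molecular mechanics)
    dG_sol  = dG_p + dG_np                      (polar GB + nonpolar SASA term)
    dE_bind = dE_MM + dG_sol                    (enthalpic estimate)
    dG_bind = dE_bind + (-T dS)                 (entropy-corrected)

The nonpolar solvation term follows the linear SASA model
dG_np = gamma * SASA + beta with gamma = 0.0072 kcal mol^-1 A^-2 and
beta = 0.92 kcal mol^-1. The entropy column is stored as -T*dS (the sign as
tabulated), so every composition above is a plain sum — no hidden negation.

No trajectory processing happens here: this module is bookkeeping and
reporting over term tables, plus per-residue decomposition filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingValueError

__all__ = [
    "EnergyTerms",
    "ResidueContribution",
    "nonpolar_solvation",
    "binding_free_energy",
    "rank_complexes",
    "key_residues",
    "read_energy_table",
]

GAMMA_SASA = 0.0072  # kcal mol^-1 A^-2, surface-tension proportionality
BETA_SASA = 0.92     # kcal mol^-1, point-solute offset
KEY_RESIDUE_THRESHOLD = 1.5  # kcal mol^-1


@dataclass(frozen=True)
class EnergyTerms:
    """Per-complex MM/GBSA terms in kcal/mol; derived fields may be None."""

    complex_id: str
    dE_ele: float
    dE_vdw: float
    dG_p: float
    dG_np: float
    minus_TdS: float
    dE_val: float = 0.0  # single-trajectory convention: internal terms cancel
    dE_MM: float | None = None
    dG_sol: float | None = None
    dE_bind: float | None = None
    dG_bind: float | None = None


@dataclass(frozen=True)
class ResidueContribution:
    """Per-residue decomposition entry in kcal/mol (total = vdw + ele + solv)."""

    complex_id: str
    residue: str  # e.g. "L704"
    vdw: float
    ele: float
    solvation: float
    total: float


def nonpolar_solvation(sasa: float, gamma: float = GAMMA_SASA, beta: float = BETA_SASA) -> float:
    """Nonpolar solvation free energy gamma * SASA + beta (SASA in A^2)."""
    if sasa < 0:
        raise ValueError("SASA cannot be negative")
    return gamma * sasa + beta


def binding_free_energy(terms: EnergyTerms) -> EnergyTerms:
    """Populate the derived fields from the primitive terms.

    When ``dE_MM`` or ``dG_sol`` is already present (for example copied from a
    published table whose intermediate sums were rounded independently), the
    given value is kept and only the missing compositions are computed; the
    higher-level sums always follow dE_bind = dE_MM + dG_sol and
    dG_bind = dE_bind + (-T dS).
    """
    for name in ("dE_ele", "dE_vdw", "dG_p", "dG_np", "minus_TdS", "dE_val"):
        value = getattr(terms, name)
        if value is None or not np.isfinite(value):
            raise MissingValueError(f"{terms.complex_id}: missing or non-finite {name}")
    dE_MM = terms.dE_MM if terms.dE_MM is not None else (
        terms.dE_val + terms.dE_ele + terms.dE_vdw
    )
    dG_sol = terms.dG_sol if terms.dG_sol is not None else terms.dG_p + terms.dG_np
    dE_bind = dE_MM + dG_sol
    dG_bind = dE_bind + terms.minus_TdS
    return replace(terms, dE_MM=dE_MM, dG_sol=dG_sol, dE_bind=dE_bind, dG_bind=dG_bind)


def rank_complexes(terms: Sequence[EnergyTerms]) -> list[EnergyTerms]:
    """Stable sort by ascending dG_bind (most favourable binder first)."""
    if len(terms) == 0:
        raise MissingValueError("rank_complexes needs at least one complex")
    composed = [t if t.dG_bind is not None else binding_free_energy(t) for t in terms]
    return sorted(composed, key=lambda t: t.dG_bind)  # sorted() is stable


def key_residues(
    contributions: Sequence[ResidueContribution],
    threshold: float = KEY_RESIDUE_THRESHOLD,
) -> dict[str, list[ResidueContribution]]:
    """Per complex, the residues with |total contribution| >= threshold,
    sorted by descending magnitude."""
    out: dict[str, list[ResidueContribution]] = {}
    for contrib in contributions:
        if abs(contrib.total) >= threshold:
            out.setdefault(contrib.complex_id, []).append(contrib)
    for complex_id in out:
        out[complex_id].sort(key=lambda c: -abs(c.total))
    return out


def read_energy_table(path) -> list[EnergyTerms]:
    """Read a per-complex term CSV; recomposes and keeps any derived columns."""
    frame = pd.read_csv(path)
    required = {"complex_id", "dE_ele", "dE_vdw", "dG_p", "dG_np", "minus_TdS"}
    if not required <= set(frame.columns):
        raise MissingValueError(f"{path}: expected columns {sorted(required)}")
    rows = []
    for _, row in frame.iterrows():
        terms = EnergyTerms(
            complex_id=str(row["complex_id"]),
            dE_ele=float(row["dE_ele"]),
            dE_vdw=float(row["dE_vdw"]),
            dG_p=float(row["dG_p"]),
            dG_np=float(row["dG_np"]),
            minus_TdS=float(row["minus_TdS"]),
            dE_val=float(row["dE_val"]) if "dE_val" in frame.columns else 0.0,
            dE_MM=float(row["dE_MM"]) if "dE_MM" in frame.columns else None,
            dG_sol=float(row["dG_sol"]) if "dG_sol" in frame.columns else None,
        )
        rows.append(binding_free_energy(terms))
    return rows


def energy_frame(terms: Sequence[EnergyTerms]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in terms])
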