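"""Synthetic descriptor/activity data with the structure the pipeline assumes.

Real DRAGON-style descriptor matrices are proprietary, so testing the whole
workflow needs simulated data that reproduces the *statistical* shape the
method relies on: a wide numeric descriptor matrix (defaults mirror the published data shape:
29 training compounds, 7 external, 110 screening candidates, 358 curated
columns), a small planted linear signal (4 true descriptors plus intercept
with Gaussian noise on the pIC50 scale), near-duplicate column pairs
(|r| > 0.98) to exercise correlation pruning, and screening rows constructed
inside and outside the training leverage domain.

Descriptor marginals are standard Gaussians: the pipeline's algebra only
assumes numeric full-rank columns, not descriptor semantics. Ground truth
(true column names, coefficients, intercept, noise level) is returned — and
written as sidecar JSON by the CLI — so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .domain import leverage_cutoff, leverages
from .errors import ConfigError
from .tables import ActivityTable, DescriptorTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_screen_outliers"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults mirror the published data shape."""

    n_train: int = 29
    n_ext: int = 7
    n_screen: int = 110
    n_descriptors: int = 358
    n_true_descriptors: int = 4
    true_coefficients: tuple[float, ...] = (0.60, -0.55, 0.50, -0.65)
    intercept: float = 6.5          # midpoint of the pIC50 activity scale
    noise_sd: float = 0.2           # pIC50 units
    n_correlated_pairs: int = 0
    correlated_noise_sd: float = 0.05   # gives pairwise |r| ~ 0.999
    n_outlier_screen: int = 0
    activity_range: tuple[float, float] = (5.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_train, self.n_descriptors) < 1 or self.n_ext < 0 or self.n_screen < 0:
            raise ConfigError("sample and descriptor counts must be positive")
        if self.n_true_descriptors < 1 or self.n_true_descriptors > self.n_descriptors:
            raise ConfigError("n_true_descriptors outside [1, n_descriptors]")
        if len(self.true_coefficients) != self.n_true_descriptors:
            raise ConfigError("true_coefficients length must equal n_true_descriptors")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        n_decoys = self.n_descriptors - self.n_true_descriptors
        if 2 * self.n_correlated_pairs > n_decoys:
            raise ConfigError(
                f"{self.n_correlated_pairs} correlated pairs need "
                f"{2 * self.n_correlated_pairs} decoy columns, only {n_decoys} available"
            )
        if self.n_outlier_screen > self.n_screen:
            raise ConfigError("n_outlier_screen exceeds n_screen")
        if self.n_train <= self.n_true_descriptors + 1:
            raise ConfigError("n_train must exceed n_true_descriptors + 1")


@dataclass(frozen=True)
class GroundTruth:
    true_descriptor_indices: tuple[int, ...]
    true_descriptor_names: tuple[str, ...]
    true_coefficients: tuple[float, ...]
    intercept: float
    noise_sd: float
    correlated_pairs: tuple[tuple[str, str], ...]
    outlier_screen_ids: tuple[str, ...]
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _descriptor_names(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"D{i:0{width}d}" for i in range(n))


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, ActivityTable, GroundTruth]:
    """Draw a full synthetic dataset (train + external + screen).

    The first ``n_true_descriptors`` columns in a random position carry the
    planted signal; ``n_correlated_pairs`` decoy pairs are near-duplicates;
    ``n_outlier_screen`` screening rows are pushed outside the training
    leverage domain of the true-descriptor design (and the remaining screen
    rows are rejection-sampled to stay inside it).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_train + spec.n_ext + spec.n_screen
    names = _descriptor_names(spec.n_descriptors)
    X = rng.standard_normal((n_total, spec.n_descriptors))

    # choose true columns; decoy pairs are earmarked now but tied together
    # only after the screening rows are finalised, so row resampling cannot
    # dilute the planted pairwise correlation
    perm = rng.permutation(spec.n_descriptors)
    true_idx = tuple(sorted(int(i) for i in perm[: spec.n_true_descriptors]))
    decoys = [int(i) for i in perm[spec.n_true_descriptors:]]
    pair_index = [
        (decoys[2 * k], decoys[2 * k + 1]) for k in range(spec.n_correlated_pairs)
    ]
    pairs = [(names[a], names[b]) for a, b in pair_index]

    beta = np.asarray(spec.true_coefficients, dtype=float)
    y = spec.intercept + X[:, list(true_idx)] @ beta + spec.noise_sd * rng.standard_normal(n_total)

    ids = tuple(f"S{i + 1:04d}" for i in range(n_total))
    splits = (
        ["train"] * spec.n_train + ["pred_a"] * spec.n_ext + ["screen"] * spec.n_screen
    )
    table = DescriptorTable(ids, names, X)

    outlier_ids: tuple[str, ...] = ()
    if spec.n_screen > 0:
        true_names = tuple(names[i] for i in true_idx)
        train_sub = table.select_compounds(ids[: spec.n_train]).select_descriptors(true_names)
        h_star = leverage_cutoff(len(true_idx), spec.n_train)
        screen_slice = slice(spec.n_train + spec.n_ext, n_total)
        screen_rows = X[screen_slice, :]
        n_inside = spec.n_screen - spec.n_outlier_screen

        # keep the inside rows inside: rejection-sample rows whose leverage
        # (on the true-descriptor design) exceeds the cutoff
        for attempt in range(200):
            probe = DescriptorTable(
                tuple(f"q{i}" for i in range(spec.n_screen)),
                true_names,
                screen_rows[:, list(true_idx)],
            )
            h = leverages(train_sub, probe)
            bad = np.nonzero(h[:n_inside] > h_star)[0]
            if len(bad) == 0:
                break
            screen_rows[bad, :] = rng.standard_normal((len(bad), spec.n_descriptors))
        else:
            raise ConfigError("could not sample inside-domain screening rows")

        if spec.n_outlier_screen > 0:
            out_rows = _outlier_rows(
                rng, train_sub, spec.n_outlier_screen, spec.n_descriptors, true_idx
            )
            screen_rows[n_inside:, :] = out_rows
        X[screen_slice, :] = screen_rows
        outlier_ids = ids[spec.n_train + spec.n_ext + n_inside :]

    for a, b in pair_index:
        X[:, b] = X[:, a] + spec.correlated_noise_sd * rng.standard_normal(n_total)
    table = DescriptorTable(ids, names, X)

    y = np.asarray(y, dtype=float)
    y_out = y.copy()
    y_out[spec.n_train + spec.n_ext :] = np.nan  # screen rows carry no activity
    activities = ActivityTable(ids, y_out, tuple(splits))
    truth = GroundTruth(
        true_descriptor_indices=true_idx,
        true_descriptor_names=tuple(names[i] for i in true_idx),
        true_coefficients=tuple(beta),
        intercept=spec.intercept,
        noise_sd=spec.noise_sd,
        correlated_pairs=tuple(pairs),
        outlier_screen_ids=outlier_ids,
        seed=spec.seed,
    )
    return table, activities, truth


def _outlier_rows(
    rng: np.random.Generator,
    train_sub: DescriptorTable,
    count: int,
    n_descriptors: int,
    true_idx: tuple[int, ...],
    max_iter: int = 60,
) -> np.ndarray:
    """Rows whose leverage on the true-descriptor design exceeds the cutoff.

    Each row starts at the training centroid plus a random direction and is
    scaled outward until its hat value crosses h*; leverage grows
    monotonically with the distance from the centroid, so this terminates.
    """
    p = train_sub.n_descriptors
    h_star = leverage_cutoff(p, train_sub.n_compounds)
    centroid = train_sub.values.mean(axis=0)
    rows = np.empty((count, n_descriptors))
    for i in range(count):
        direction = rng.standard_normal(p)
        direction /= np.linalg.norm(direction)
        scale = 1.0
        for _ in range(max_iter):
            candidate = centroid + scale * direction
            probe = DescriptorTable(("q",), train_sub.descriptor_names, candidate[None, :])
            if leverages(train_sub, probe)[0] > h_star:
                break
            scale *= 1.6
        else:
            raise ConfigError("could not push a screening row outside the domain")
        rows[i, :] = rng.standard_normal(n_descriptors)
        rows[i, list(true_idx)] = candidate
    return rows


def generate_screen_outliers(
    spec: SyntheticSpec,
    train_table: DescriptorTable,
    descriptor_names: tuple[str, ...] | None = None,
) -> DescriptorTable:
    """Standalone outlier construction against an existing training table.

    ``descriptor_names`` selects the model columns defining the leverage
    domain (defaults to all columns of ``train_table``). Returns
    ``spec.n_outlier_screen`` rows, each verified to have h > h*; a zero
    request yields a zero-row table.
    """
    rng = np.random.default_rng(spec.seed)
    names = descriptor_names or train_table.descriptor_names
    train_sub = train_table.select_descriptors(names)
    count = spec.n_outlier_screen
    ids = tuple(f"OUT{i + 1:04d}" for i in range(count))
    if count == 0:
        return DescriptorTable(ids, names, np.empty((0, len(names))))
    true_idx = tuple(range(len(names)))
    rows = _outlier_rows(rng, train_sub, count, len(names), true_idx)
    out = DescriptorTable(ids, names, rows[:, : len(names)])
    h = leverages(train_sub, out)
    h_star = leverage_cutoff(train_sub.n_descriptors, train_sub.n_compounds)
    if not np.all(h > h_star):
        raise ConfigError("outlier construction failed verification")
    return out
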