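"""Ranking of merged PSM sets and per-threshold count curves.

The merged modified + unmodified PSM population is sorted in ascending order
of score: rank 1 is the worst match, rank N the best. All per-threshold
statistics count PSMs with rank >= r ("at or above the threshold"); this
boundary convention is used everywhere in the package. Counts only change
around ranks held by decoy PSMs, so the default threshold grid is the set of
decoy ranks, the ranks one past each decoy (where the cumulative decoy
counts change), and both range ends.

The gamma parameter is the proportion of modified PSMs among all false
identifications; its decoy-based estimate D_k(r)/D(r) becomes unstable where
decoys are scarce, which is quantified by Poisson error propagation
sigma = (x/y) * sqrt(1/x + 1/y) on the cumulative counts x = D_k, y = D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import GammaEstimationError
from .records import PSMRecord

#: Subset labels in the target/decoy x modified/unmodified partition.
SUBSET_LABELS = (
    "target-unmodified", "target-modified", "decoy-unmodified", "decoy-modified",
)


@dataclass
class RankedPSMSet:
    """Merged PSMs with ranks (1 = worst score) and the four subset labels."""

    records: list[PSMRecord]
    ranks: np.ndarray          # rank of records[i], values are a bijection onto 1..N
    scores: np.ndarray
    is_decoy: np.ndarray
    is_modified: np.ndarray

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        td = np.where(self.is_decoy, "decoy", "target")
        mu = np.where(self.is_modified, "modified", "unmodified")
        return np.char.add(np.char.add(td, "-"), mu)

    def by_rank(self) -> np.ndarray:
        """Indices into ``records`` ordered by ascending rank."""
        return np.argsort(self.ranks)


def rank_psms(merged: Sequence[PSMRecord]) -> RankedPSMSet:
    """Sort merged PSMs ascending by score and assign ranks 1..N.

    Ties are broken by stable input order (the earlier record gets the lower
    rank). Non-finite scores are rejected with the offending record index.
    """
    if len(merged) == 0:
        raise ValueError("cannot rank an empty PSM set")
    scores = np.array([r.score for r in merged], dtype=float)
    bad = np.flatnonzero(~np.isfinite(scores))
    if bad.size:
        raise ValueError(f"non-finite score at record index {int(bad[0])}")
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(merged), dtype=np.int64)
    ranks[order] = np.arange(1, len(merged) + 1)
    return RankedPSMSet(
        records=list(merged),
        ranks=ranks,
        scores=scores,
        is_decoy=np.array([r.is_decoy for r in merged], dtype=bool),
        is_modified=np.array([r.is_modified for r in merged], dtype=bool),
    )


@dataclass
class CountCurves:
    """Cumulative counts over rank thresholds (rank >= r).

    ``n_unmod``: target-unmodified count N(r); ``n_mod``: target-modified
    count N_k(r); ``d_total``: decoy count D(r); ``d_mod``: decoy-modified
    count D_k(r); ``t_total``: all targets T(r); ``fdr``: global FDR
    D(r)/T(r) (optionally (D(r)+1)/T(r)). ``undefined`` flags thresholds
    where T(r)=0 while D(r)>0.
    """

    thresholds: np.ndarray
    n_unmod: np.ndarray
    n_mod: np.ndarray
    d_total: np.ndarray
    d_mod: np.ndarray
    t_total: np.ndarray
    fdr: np.ndarray
    undefined: np.ndarray
    pseudocount: bool = False

    @property
    def n_total_psms(self) -> int:
        return int(self.t_total[0] + self.d_total[0]) if len(self.thresholds) else 0


def _default_grid(ranked: RankedPSMSet) -> np.ndarray:
    # Under the rank >= r convention decoy counts change at (decoy rank + 1);
    # include both the decoy ranks and those change points, plus the range ends.
    decoy_ranks = np.unique(ranked.ranks[ranked.is_decoy])
    after = np.minimum(decoy_ranks + 1, ranked.n)
    ends = np.array([1, ranked.n], dtype=np.int64)
    return np.unique(np.concatenate([decoy_ranks, after, ends]))


def count_curves(
    ranked: RankedPSMSet,
    grid: np.ndarray | str | None = None,
    pseudocount: bool = False,
    max_grid: int | None = None,
) -> CountCurves:
    """Compute the four subset count curves and the global FDR over a grid.

    ``grid`` may be ``None``/"decoy" (every rank held by a decoy plus both
    range ends — counts only change there), "all" (every rank), or an
    explicit increasing array of ranks within 1..N. ``max_grid`` uniformly
    subsamples very large grids (range ends always kept).
    """
    if grid is None or (isinstance(grid, str) and grid == "decoy"):
        thresholds = _default_grid(ranked)
    elif isinstance(grid, str) and grid == "all":
        thresholds = np.arange(1, ranked.n + 1, dtype=np.int64)
    else:
        thresholds = np.asarray(grid, dtype=np.int64)
        if thresholds.size == 0 or thresholds.min() < 1 or thresholds.max() > ranked.n:
            raise ValueError(f"grid must lie within 1..{ranked.n}")
        thresholds = np.unique(thresholds)
    if max_grid is not None and thresholds.size > max_grid:
        keep = np.unique(np.linspace(0, thresholds.size - 1, max_grid).round().astype(int))
        thresholds = thresholds[keep]

    # suffix counts via prefix cumulative sums in rank order
    order = ranked.by_rank()
    dec = ranked.is_decoy[order]
    mod = ranked.is_modified[order]

    def suffix(mask: np.ndarray) -> np.ndarray:
        csum = np.concatenate([[0], np.cumsum(mask)])
        total = csum[-1]
        return total - csum[thresholds - 1]

    d_total = suffix(dec)
    d_mod = suffix(dec & mod)
    t_total = suffix(~dec)
    n_mod = suffix(~dec & mod)
    n_unmod = t_total - n_mod

    numer = d_total + 1 if pseudocount else d_total
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(t_total > 0, numer / np.maximum(t_total, 1), np.nan)
    fdr = np.where((t_total == 0) & (d_total == 0), 0.0, fdr)
    undefined = (t_total == 0) & (d_total > 0)
    return CountCurves(
        thresholds=thresholds, n_unmod=n_unmod, n_mod=n_mod, d_total=d_total,
        d_mod=d_mod, t_total=t_total, fdr=fdr, undefined=undefined,
        pseudocount=pseudocount,
    )


def error_propagation(x, y):
    """Poisson error propagation of the ratio x/y: (x/y)*sqrt(1/x + 1/y).

    x is the modified-decoy count, y the total decoy count (cumulative, above
    a threshold). Undefined (NaN) where x < 1 or y < 1, signalling too few
    decoys at that threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x > y):
        raise ValueError("modified-decoy count x cannot exceed total decoy count y")
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = (x / y) * np.sqrt(1.0 / x + 1.0 / y)
    sigma = np.where((x < 1) | (y < 1), np.nan, sigma)
    return float(sigma) if sigma.ndim == 0 else sigma


@dataclass
class GammaCurve:
    """Decoy-based gamma estimate with its stability mask.

    ``gamma_hat(r) = D_k(r)/D(r)`` where D(r) > 0; ``sigma`` is the Poisson
    error propagation; ``stable`` marks grid points with sigma <= cutoff.
    The stable mask is computed, never assumed contiguous.
    """

    thresholds: np.ndarray
    gamma_hat: np.ndarray
    sigma: np.ndarray
    stable: np.ndarray
    sigma_cutoff: float = 0.01

    @property
    def n_stable(self) -> int:
        return int(self.stable.sum())

    def stable_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.thresholds[self.stable], self.gamma_hat[self.stable]


def estimate_gamma_curve(curves: CountCurves, sigma_cutoff: float = 0.01) -> GammaCurve:
    """Estimate gamma(r) = D_k(r)/D(r) with its error-propagation mask."""
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma_hat = np.where(curves.d_total > 0,
                             curves.d_mod / np.maximum(curves.d_total, 1), np.nan)
    sigma = error_propagation(curves.d_mod, curves.d_total)
    stable = np.isfinite(sigma) & (sigma <= sigma_cutoff) & (curves.d_total > 0)
    if not stable.any():
        raise GammaEstimationError(
            "no threshold passes the error-propagation filter "
            f"(sigma <= {sigma_cutoff}); add decoys, e.g. by appending random "
            "(entrapment) proteins to the search database"
        )
    return GammaCurve(thresholds=curves.thresholds, gamma_hat=gamma_hat,
                      sigma=sigma, stable=stable, sigma_cutoff=sigma_cutoff)


def decoy_target_ratio(curves: CountCurves) -> np.ndarray:
    """Ratio rho(r) = D(r)/T(r); NaN where T(r) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(curves.t_total > 0,
                        curves.d_total / np.maximum(curves.t_total, 1), np.nan)
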