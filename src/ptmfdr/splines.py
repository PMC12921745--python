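"""Inflection-point detection and (spline-)linear regression of gamma.

The gamma curve is fitted over its stable region with a continuous piecewise
linear least-squares model (a linear spline). One interior knot is anchored
at the inflection rank: the global minimum of the Gaussian-smoothed first
derivative of the decoy/target ratio rho(r) = D(r)/T(r). Beyond the last
node the last segment extrapolates gamma for high-rank thresholds where the
decoy-based estimate is unstable; evaluated gamma is clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .curves import GammaCurve
from .exceptions import FitError

#: Default Gaussian kernel width for derivative smoothing, as a fraction of
#: the grid's rank span.
DEFAULT_SMOOTHING_FRACTION = 0.02


def find_inflection_rank(
    thresholds: np.ndarray,
    ratio: np.ndarray,
    smoothing_sigma: float | None = None,
) -> float:
    """Anchor rank: global minimum of the smoothed derivative of D/T.

    The first derivative is taken by central finite differences on the
    (possibly non-uniform) rank grid and convolved with a Gaussian kernel of
    width ``smoothing_sigma`` (in rank units; default 2% of the grid span),
    with reflect padding at the boundaries. Ties go to the smallest rank.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    keep = np.isfinite(ratio)
    t, y = thresholds[keep], ratio[keep]
    if t.size < 5:
        raise ValueError(f"inflection undefined: need >= 5 ratio points, got {t.size}")
    if smoothing_sigma is None:
        smoothing_sigma = DEFAULT_SMOOTHING_FRACTION * (t[-1] - t[0])
    deriv = np.gradient(y, t)
    spacing = np.mean(np.diff(t))
    sigma_pts = smoothing_sigma / spacing if spacing > 0 else 0.0
    smoothed = gaussian_filter1d(deriv, sigma_pts, mode="reflect") if sigma_pts > 0 else deriv
    # smallest rank on the global-minimum plateau; the tolerance absorbs the
    # ~1e-16 jitter Gaussian smoothing leaves on exactly constant segments
    smin = smoothed.min()
    tol = 1e-9 * (abs(smin) + np.ptp(smoothed) + 1e-300)
    return float(t[int(np.flatnonzero(smoothed <= smin + tol)[0])])


class LinearFit(NamedTuple):
    a: float        # intercept
    b: float        # slope per rank
    r_squared: float
    rmse: float


def _diagnostics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return r2, float(np.sqrt(ss_res / y.size))


def fit_linear_gamma(curve: GammaCurve) -> LinearFit:
    """Ordinary least squares of gamma_hat on rank over the stable points."""
    x, y = curve.stable_points()
    if x.size < 2:
        raise FitError(f"linear gamma fit needs >= 2 stable points, got {x.size}")
    design = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r2, rmse = _diagnostics(y, design @ coef)
    return LinearFit(a=float(coef[0]), b=float(coef[1]), r_squared=r2, rmse=rmse)


@dataclass
class SplineLinearModel:
    """Continuous piecewise-linear model gamma(r) = a_i + b_i * r on [x_{i-1}, x_i].

    ``nodes`` are the knot ranks x_0 < ... < x_n (boundary nodes at the ends
    of the stable range); ``coefficients[i]`` is the (a, b) pair of the
    segment [nodes[i], nodes[i+1]]. Evaluation beyond x_n extrapolates the
    last segment; below x_0, the first.
    """

    nodes: np.ndarray
    coefficients: list[tuple[float, float]]
    anchor_node: float | None
    anchored: bool
    r_squared: float
    rmse: float
    n_stable: int

    @property
    def n_segments(self) -> int:
        return len(self.coefficients)

    def evaluate(self, r, clip: bool = True) -> np.ndarray | float:
        """Evaluate gamma at rank(s) r; clipped to [0, 1] unless ``clip=False``."""
        r_arr = np.asarray(r, dtype=float)
        seg = np.searchsorted(self.nodes, r_arr, side="right") - 1
        seg = np.clip(seg, 0, self.n_segments - 1)
        a = np.array([c[0] for c in self.coefficients])
        b = np.array([c[1] for c in self.coefficients])
        val = a[seg] + b[seg] * r_arr
        if clip:
            val = np.clip(val, 0.0, 1.0)
        return float(val) if val.ndim == 0 else val


def evaluate_gamma(model: SplineLinearModel, r, clip: bool = True):
    """Functional alias for :meth:`SplineLinearModel.evaluate`."""
    return model.evaluate(r, clip=clip)


def _segment_counts(x: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Points per segment; each interval [nodes[i], nodes[i+1]) (last closed)."""
    idx = np.searchsorted(nodes, x, side="right") - 1
    idx = np.clip(idx, 0, len(nodes) - 2)
    return np.bincount(idx, minlength=len(nodes) - 1)


def fit_spline_linear_gamma(
    curve: GammaCurve,
    anchor: float | None,
    n_interior_knots: int = 3,
) -> SplineLinearModel:
    """Fit a continuous linear spline to gamma over the stable region.

    The interior knot set is ``n_interior_knots`` equally spaced ranks over
    the stable range, with the anchor (inflection rank) replacing its nearest
    spaced knot; so the anchor counts as one of the interior knots. If the
    anchor lies outside the stable range the fit falls back to the spaced
    knots and is flagged ``anchored=False``. Interior knots whose segments
    hold fewer than 2 stable points are dropped with a warning.
    """
    x, y = curve.stable_points()
    x = x.astype(float)
    if x.size < n_interior_knots + 2:
        raise FitError(
            f"spline fit with {n_interior_knots} interior knots needs >= "
            f"{n_interior_knots + 2} stable points, got {x.size}"
        )
    lo, hi = float(x.min()), float(x.max())

    anchored = False
    anchor_node: float | None = None
    if n_interior_knots > 0:
        knots = list(np.linspace(lo, hi, n_interior_knots + 2)[1:-1])
        if anchor is not None and lo < anchor < hi:
            nearest = int(np.argmin([abs(k - anchor) for k in knots]))
            knots[nearest] = float(anchor)
            anchored = True
            anchor_node = float(anchor)
        elif anchor is not None:
            warnings.warn(
                f"anchor rank {anchor} outside the stable range [{lo}, {hi}]; "
                "falling back to equally spaced knots", stacklevel=2,
            )
        knots = sorted(set(knots))
    else:
        knots = []

    # drop knots bounding degenerate (< 2 point) segments, keeping the anchor last
    while knots:
        nodes = np.array([lo, *knots, hi])
        counts = _segment_counts(x, nodes)
        if counts.min() >= 2:
            break
        seg = int(np.argmin(counts))
        # candidate interior knots bounding this segment
        bounding = [k for k in (nodes[seg], nodes[seg + 1]) if k in knots]
        drop = next((k for k in bounding if k != anchor_node), bounding[0])
        if drop == anchor_node:
            anchored = False
            anchor_node = None
        knots.remove(drop)
        warnings.warn(f"dropping knot {drop}: segment with < 2 stable points", stacklevel=2)

    nodes = np.array([lo, *knots, hi])
    # hinge basis: gamma(r) = c0 + c1 r + sum_j d_j max(0, r - k_j) is
    # continuous piecewise linear with breaks exactly at the knots
    cols = [np.ones_like(x), x] + [np.maximum(0.0, x - k) for k in knots]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r2, rmse = _diagnostics(y, design @ coef)

    coefficients: list[tuple[float, float]] = []
    for i in range(len(nodes) - 1):
        active = [j for j, k in enumerate(knots) if k <= nodes[i]]
        b = coef[1] + sum(coef[2 + j] for j in active)
        a = coef[0] - sum(coef[2 + j] * knots[j] for j in active)
        coefficients.append((float(a), float(b)))

    return SplineLinearModel(
        nodes=nodes, coefficients=coefficients, anchor_node=anchor_node,
        anchored=anchored, r_squared=r2, rmse=rmse, n_stable=int(x.size),
    )
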