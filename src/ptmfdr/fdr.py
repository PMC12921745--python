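"""Group-specific FDR estimation for modified PSMs.

Two estimators are provided for the FDR within the group of PSMs carrying
one specific PTM:

* **separate FDR** — the classical target-decoy ratio restricted to the
  modified subset, D_k(r) / T_k(r). Simple but unstable when modified decoys
  are scarce.
* **transferred FDR** — the global FDR rescaled into the modified group:

      FDRhat_k(r) = [N(r) / N_k(r)] * gamma(r) * FDR(r)

  where N(r) counts unmodified target PSMs at rank >= r, N_k(r) modified
  target PSMs, FDR(r) = D(r)/T(r) is the global FDR, and gamma(r) is the
  modified fraction among false identifications, modelled by a spline-linear
  (or plain linear) regression of the decoy proportion D_k/D over the stable
  rank region and extrapolated from the last spline segment at high ranks.

The user-facing entry point is the :class:`TransferredFDR` model whose
``fit()`` returns a :class:`TransferredFDRResults` object carrying per-PSM
annotations, the fitted gamma model, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .curves import (
    CountCurves,
    GammaCurve,
    RankedPSMSet,
    count_curves,
    decoy_target_ratio,
    estimate_gamma_curve,
    rank_psms,
)
from .records import PSMRecord, format_modifications
from .splines import (
    SplineLinearModel,
    find_inflection_rank,
    fit_linear_gamma,
    fit_spline_linear_gamma,
)

Method = Literal["spline_transferred", "linear_transferred", "separate"]


def transferred_fdr_curve(
    curves: CountCurves,
    model: SplineLinearModel,
    n_definition: str = "unmodified",
) -> np.ndarray:
    """Transferred FDR over the threshold grid.

    ``n_definition`` selects the numerator count N(r): "unmodified" (target
    PSMs without the PTM) or "all_targets" (every target PSM). Thresholds
    with N_k(r) = 0 are NaN (skipped: no modified targets to accept there).
    Values are not truncated before q-value monotonization.
    """
    if n_definition == "unmodified":
        numer = curves.n_unmod
    elif n_definition == "all_targets":
        numer = curves.t_total
    else:
        raise ValueError(f"unknown n_definition {n_definition!r}")
    gamma = model.evaluate(curves.thresholds, clip=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_k = (numer / np.where(curves.n_mod > 0, curves.n_mod, np.nan)) * gamma * curves.fdr
    return fdr_k


def qvalues_and_threshold(
    thresholds: np.ndarray,
    fdr_values: np.ndarray,
    alpha: float = 0.01,
) -> tuple[np.ndarray, float | None]:
    """Monotonize an FDR curve into q-values and find the rank threshold.

    The q-value of a threshold r is the minimal estimated FDR over the
    thresholds that accept everything r accepts or more — i.e. the running
    minimum of FDR over r' <= r along ascending rank. q is therefore
    non-increasing with rank (better PSMs never have larger q). NaN
    thresholds (no modified targets) are skipped and stay NaN. Returns the
    q array (aligned with ``thresholds``) and the minimal accepting rank
    (smallest r with q <= alpha), or None if no rank accepts.
    """
    fdr_values = np.asarray(fdr_values, dtype=float)
    q = np.full_like(fdr_values, np.nan)
    finite = np.isfinite(fdr_values)
    if finite.any():
        q[finite] = np.minimum.accumulate(fdr_values[finite])
    accept = finite & (q <= alpha)
    threshold_rank = float(thresholds[accept][0]) if accept.any() else None
    return q, threshold_rank


@dataclass
class SeparateFDRResult:
    """Subset-only target-decoy q-values for the modified PSM population."""

    indices: np.ndarray        # positions in the input record list (modified PSMs, by rank)
    ranks: np.ndarray
    is_decoy: np.ndarray
    fdr: np.ndarray
    q: np.ndarray
    low_confidence: bool = False


def separate_fdr_curve(ranked: RankedPSMSet) -> SeparateFDRResult:
    """Separate FDR: D_k(r)/T_k(r) within the modified subset only.

    q-values are the minimal subset FDR over the thresholds accepting each
    PSM. With no modified decoys the q-values are identically 0 and flagged
    low-confidence.
    """
    mod_idx = np.flatnonzero(ranked.is_modified)
    if mod_idx.size == 0 or not (~ranked.is_decoy[mod_idx]).any():
        # no modified targets: nothing to assign a q-value to
        empty = np.array([], dtype=float)
        return SeparateFDRResult(
            indices=np.array([], dtype=int), ranks=empty, is_decoy=np.array([], dtype=bool),
            fdr=empty, q=empty, low_confidence=True,
        )
    order = mod_idx[np.argsort(ranked.ranks[mod_idx])]
    dec = ranked.is_decoy[order]
    # suffix counts at each modified PSM's own rank
    d_k = np.cumsum(dec[::-1])[::-1]
    t_k = np.cumsum((~dec)[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(t_k > 0, d_k / np.maximum(t_k, 1), np.nan)
    q, _ = qvalues_and_threshold(ranked.ranks[order], fdr)
    low_conf = not dec.any()
    if low_conf:
        warnings.warn(
            "no modified decoys: separate FDR q-values are identically 0 "
            "and should be treated as low-confidence", stacklevel=2,
        )
    return SeparateFDRResult(
        indices=order, ranks=ranked.ranks[order].astype(float), is_decoy=dec,
        fdr=fdr, q=q, low_confidence=low_conf,
    )


def _grid_lookup(grid: np.ndarray, values: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Value at the largest grid threshold <= rank.

    That threshold accepts the PSM; on a grid containing all decoy-count
    change points the curve is exact there.
    """
    idx = np.searchsorted(grid, ranks, side="right") - 1
    idx = np.clip(idx, 0, len(grid) - 1)
    return values[idx]


class TransferredFDR:
    """Model for PTM-group-specific FDR on a merged PSM population.

    Parameters
    ----------
    records
        Merged modified + unmodified PSMs (targets and decoys), e.g. the
        union of a standard-search table and one PTM search table.
    method
        "spline_transferred" (default), "linear_transferred" or "separate".
    alpha
        Acceptance level (default 0.01, i.e. 1% FDR).
    sigma_cutoff
        Error-propagation stability cutoff for gamma estimation.
    smoothing_sigma
        Gaussian kernel width (rank units) for the inflection-point search;
        default 2% of the grid span.
    n_interior_knots
        Interior knots of the linear spline, the anchor included.
    n_definition
        Numerator count in the transfer formula: "unmodified" or "all_targets".
    pseudocount
        Use (D+1)/T for the global FDR instead of D/T.
    grid
        Threshold grid spec passed to :func:`count_curves`.
    """

    def __init__(
        self,
        records: Sequence[PSMRecord],
        *,
        method: Method = "spline_transferred",
        alpha: float = 0.01,
        sigma_cutoff: float = 0.01,
        smoothing_sigma: float | None = None,
        n_interior_knots: int = 3,
        n_definition: str = "unmodified",
        pseudocount: bool = False,
        grid: np.ndarray | str | None = None,
        max_grid: int | None = None,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if method not in ("spline_transferred", "linear_transferred", "separate"):
            raise ValueError(f"unknown method {method!r}")
        self.records = list(records)
        self.method = method
        self.alpha = alpha
        self.sigma_cutoff = sigma_cutoff
        self.smoothing_sigma = smoothing_sigma
        self.n_interior_knots = n_interior_knots
        self.n_definition = n_definition
        self.pseudocount = pseudocount
        self.grid = grid
        self.max_grid = max_grid

    @classmethod
    def from_tables(
        cls,
        standard_path: str | os.PathLike,
        modified_path: str | os.PathLike,
        dialect=None,
        exclude_standard_keys: bool = False,
        key_profile: Sequence[str] = ("file", "scan"),
        **kwargs,
    ) -> "TransferredFDR":
        """Build the merged population from a standard and a PTM search table.

        Unmodified PSMs come from the standard table, modified PSMs from the
        PTM table. With ``exclude_standard_keys`` the PTM table additionally
        drops spectra already explained by the standard search (key-based
        equivalent of removing those spectra upstream).
        """
        from .io import read_psm_table

        standard = read_psm_table(standard_path, dialect)
        ptm = read_psm_table(modified_path, dialect)
        unmod = [r for r in standard if not r.is_modified]
        mod = [r for r in ptm if r.is_modified]
        if exclude_standard_keys:
            seen = {r.key.project(key_profile) for r in standard}
            mod = [r for r in mod if r.key.project(key_profile) not in seen]
        return cls(unmod + mod, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dialect=None, **kwargs) -> "TransferredFDR":
        """Build from a DataFrame in the neutral table dialect (via a temp-free path)."""
        from .io import DEFAULT_DIALECT, read_psm_table
        import io as _io

        dialect = dialect or DEFAULT_DIALECT
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return cls(read_psm_table(buf, dialect), **kwargs)

    def fit(self) -> "TransferredFDRResults":
        ranked = rank_psms(self.records)
        curves = count_curves(ranked, grid=self.grid, pseudocount=self.pseudocount,
                              max_grid=self.max_grid)
        separate = separate_fdr_curve(ranked)

        gamma_curve = anchor = gamma_model = None
        fdr_k = q_grid = None
        threshold_rank = None
        if self.method == "separate":
            sep_target = ~separate.is_decoy
            accept = sep_target & (separate.q <= self.alpha)
            threshold_rank = float(separate.ranks[accept].min()) if accept.any() else None
        else:
            gamma_curve = estimate_gamma_curve(curves, self.sigma_cutoff)
            rho = decoy_target_ratio(curves)
            try:
                anchor = find_inflection_rank(curves.thresholds, rho, self.smoothing_sigma)
            except ValueError:
                anchor = None
            n_knots = 0 if self.method == "linear_transferred" else self.n_interior_knots
            gamma_model = fit_spline_linear_gamma(gamma_curve, anchor, n_interior_knots=n_knots)
            fdr_k = transferred_fdr_curve(curves, gamma_model, self.n_definition)
            q_grid, threshold_rank = qvalues_and_threshold(
                curves.thresholds, fdr_k, self.alpha)

        return TransferredFDRResults(
            model=self, ranked=ranked, curves=curves, gamma_curve=gamma_curve,
            gamma_model=gamma_model, anchor_rank=anchor, separate=separate,
            transferred_grid=fdr_k, q_grid=q_grid, threshold_rank=threshold_rank,
        )


@dataclass
class TransferredFDRResults:
    """Fitted group-specific FDR estimates and per-PSM annotations."""

    model: TransferredFDR
    ranked: RankedPSMSet
    curves: CountCurves
    gamma_curve: GammaCurve | None
    gamma_model: SplineLinearModel | None
    anchor_rank: float | None
    separate: SeparateFDRResult
    transferred_grid: np.ndarray | None
    q_grid: np.ndarray | None
    threshold_rank: float | None
    _annotations: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def annotations(self) -> pd.DataFrame:
        """Per modified-target-PSM annotation table (best scores first)."""
        if self._annotations is None:
            self._annotations = self._build_annotations()
        return self._annotations

    def _build_annotations(self) -> pd.DataFrame:
        ranked = self.ranked
        sep_q = np.full(ranked.n, np.nan)
        sep_q[self.separate.indices] = self.separate.q
        idx = np.flatnonzero(ranked.is_modified & ~ranked.is_decoy)
        idx = idx[np.argsort(-ranked.ranks[idx])]  # best first
        rows = []
        for i in idx:
            rec = ranked.records[i]
            rank = int(ranked.ranks[i])
            if self.model.method == "separate":
                tfdr = np.nan
                q = sep_q[i]
            else:
                tfdr = float(_grid_lookup(self.curves.thresholds, self.transferred_grid,
                                          np.array([rank]))[0])
                q = float(_grid_lookup(self.curves.thresholds, self.q_grid,
                                       np.array([rank]))[0])
            rows.append({
                "file": rec.key.file_name,
                "scan": rec.key.scan_number,
                "peptide": rec.peptide,
                "modifications": format_modifications(rec.modifications, rec.peptide),
                "charge": rec.charge,
                "score": rec.score,
                "rank": rank,
                "transferred_fdr": tfdr,
                "q_value": q,
                "separate_q": sep_q[i],
                "accepted": bool(np.isfinite(q) and q <= self.alpha),
                "proteins": ";".join(rec.proteins),
            })
        return pd.DataFrame(rows, columns=[
            "file", "scan", "peptide", "modifications", "charge", "score", "rank",
            "transferred_fdr", "q_value", "separate_q", "accepted", "proteins",
        ])

    @property
    def n_accepted(self) -> int:
        return int(self.annotations["accepted"].sum())

    def accepted_records(self) -> list[PSMRecord]:
        """Modified target PSMs passing the acceptance level, best first."""
        ann = self.annotations
        ranked = self.ranked
        by_rank = {int(ranked.ranks[i]): ranked.records[i]
                   for i in np.flatnonzero(ranked.is_modified & ~ranked.is_decoy)}
        return [by_rank[r] for r in ann.loc[ann["accepted"], "rank"]]

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        ranked, curves = self.ranked, self.curves
        lab, cnt = np.unique(ranked.labels, return_counts=True)
        counts = dict(zip(lab.tolist(), cnt.tolist()))
        lines = [
            "Group-specific FDR fit",
            "=" * 62,
            f"method:            {self.model.method}",
            f"alpha:             {self.alpha:g}",
            f"PSMs (merged):     {ranked.n}",
        ]
        for name in ("target-unmodified", "target-modified",
                     "decoy-unmodified", "decoy-modified"):
            lines.append(f"  {name:<18} {counts.get(name, 0)}")
        lines.append(f"threshold grid:    {len(curves.thresholds)} points")
        if self.gamma_curve is not None:
            lines.append(f"stable thresholds: {self.gamma_curve.n_stable} "
                         f"(sigma <= {self.gamma_curve.sigma_cutoff:g})")
        if self.anchor_rank is not None:
            lines.append(f"anchor rank:       {self.anchor_rank:.0f} (inflection of D/T)")
        m = self.gamma_model
        if m is not None:
            lines.append(f"gamma model:       {m.n_segments} segment(s), "
                         f"R^2 = {m.r_squared:.4f}, RMSE = {m.rmse:.4g}")
            lines.append(f"  nodes: {np.array2string(m.nodes, precision=1)}")
            for i, (a, b) in enumerate(m.coefficients):
                lines.append(f"  segment {i}: gamma = {a:.4g} + {b:.4g} * rank")
        thr = "none" if self.threshold_rank is None else f"{self.threshold_rank:.0f}"
        lines.append(f"rank threshold:    {thr}")
        lines.append(f"accepted PSMs:     {self.n_accepted}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def model_table(self) -> pd.DataFrame:
        """Knots and per-segment coefficients with fit diagnostics."""
        m = self.gamma_model
        if m is None:
            return pd.DataFrame(columns=["segment", "x_left", "x_right", "a", "b",
                                         "r_squared", "rmse"])
        rows = [{"segment": i, "x_left": m.nodes[i], "x_right": m.nodes[i + 1],
                 "a": a, "b": b, "r_squared": m.r_squared, "rmse": m.rmse}
                for i, (a, b) in enumerate(m.coefficients)]
        return pd.DataFrame(rows)

    def curve_table(self) -> pd.DataFrame:
        """Per-threshold counts, gamma estimate and stability mask."""
        c = self.curves
        df = pd.DataFrame({
            "threshold": c.thresholds, "N": c.n_unmod, "N_k": c.n_mod,
            "D": c.d_total, "D_k": c.d_mod, "T": c.t_total, "global_fdr": c.fdr,
        })
        if self.gamma_curve is not None:
            df["gamma_hat"] = self.gamma_curve.gamma_hat
            df["sigma"] = self.gamma_curve.sigma
            df["stable"] = self.gamma_curve.stable
        if self.transferred_grid is not None:
            df["transferred_fdr"] = self.transferred_grid
            df["q_value"] = self.q_grid
        return df

    def to_tables(self, output_dir: str | os.PathLike, prefix: str = "ptm") -> dict[str, Path]:
        """Write annotation, model and curve TSVs; returns the paths."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations": out / f"{prefix}_psms.tsv",
            "model": out / f"{prefix}_gamma_model.tsv",
            "curves": out / f"{prefix}_curves.tsv",
        }
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.model_table().to_csv(paths["model"], sep="\t", index=False)
        self.curve_table().to_csv(paths["curves"], sep="\t", index=False)
        return paths

    # -- plotting ----------------------------------------------------------

    def plot_gamma(self, ax=None):
        """Gamma estimates vs rank with the fitted model and the anchor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        gc = self.gamma_curve
        if gc is not None:
            ax.plot(gc.thresholds[~gc.stable], gc.gamma_hat[~gc.stable], ".",
                    color="0.7", ms=3, label="gamma (unstable)")
            ax.plot(gc.thresholds[gc.stable], gc.gamma_hat[gc.stable], ".",
                    color="tab:blue", ms=3, label="gamma (stable)")
        if self.gamma_model is not None:
            grid = np.linspace(self.curves.thresholds.min(),
                               self.curves.thresholds.max(), 400)
            ax.plot(grid, self.gamma_model.evaluate(grid), "-", color="tab:red",
                    label="spline-linear fit")
        if self.anchor_rank is not None:
            ax.axvline(self.anchor_rank, ls=":", color="tab:green", label="anchor")
        ax.set_xlabel("rank threshold")
        ax.set_ylabel("gamma")
        ax.legend(fontsize=8)
        return ax

    def plot_fdr(self, ax=None):
        """Transferred FDR and q-values over the threshold grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        if self.transferred_grid is not None:
            ax.plot(self.curves.thresholds, self.transferred_grid, ".",
                    ms=3, label="transferred FDR")
            ax.plot(self.curves.thresholds, self.q_grid, "-", label="q-value")
        ax.axhline(self.alpha, ls="--", color="0.5", label=f"alpha = {self.alpha:g}")
        if self.threshold_rank is not None:
            ax.axvline(self.threshold_rank, ls=":", color="tab:green")
        ax.set_xlabel("rank threshold")
        ax.set_ylabel("FDR")
        ax.set_yscale("log")
        ax.legend(fontsize=8)
        return ax
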