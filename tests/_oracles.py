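"""Independent brute-force oracles for per-threshold statistics.

These recompute every curve by explicit recounting at each threshold,
deliberately avoiding the cumulative-sum path used by the implementation.
"""

from __future__ import annotations

import numpy as np


def oracle_counts(ranks, is_decoy, is_modified, thresholds):
    """Per-threshold recount over {rank >= r} by direct boolean reduction."""
    ranks = np.asarray(ranks)
    dec = np.asarray(is_decoy, dtype=bool)
    mod = np.asarray(is_modified, dtype=bool)
    out = {k: [] for k in ("N", "N_k", "D", "D_k", "T")}
    for r in thresholds:
        above = ranks >= r
        out["D"].append(int(np.sum(above & dec)))
        out["D_k"].append(int(np.sum(above & dec & mod)))
        out["T"].append(int(np.sum(above & ~dec)))
        out["N_k"].append(int(np.sum(above & ~dec & mod)))
        out["N"].append(int(np.sum(above & ~dec & ~mod)))
    return {k: np.array(v) for k, v in out.items()}


def oracle_gamma(counts):
    """gamma = D_k/D where D > 0, else NaN."""
    d, dk = counts["D"], counts["D_k"]
    return np.where(d > 0, dk / np.maximum(d, 1), np.nan)


def oracle_global_fdr(counts):
    d, t = counts["D"], counts["T"]
    fdr = np.where(t > 0, d / np.maximum(t, 1), np.nan)
    return np.where((t == 0) & (d == 0), 0.0, fdr)


def oracle_piecewise_eval(nodes, coefficients, r):
    """Segment-search evaluation of the linear spline (clipped to [0, 1])."""
    vals = []
    for x in np.atleast_1d(np.asarray(r, dtype=float)):
        seg = 0
        for i in range(len(nodes) - 1):
            if x >= nodes[i]:
                seg = i
        a, b = coefficients[seg]
        vals.append(min(1.0, max(0.0, a + b * x)))
    return np.array(vals)


def oracle_transferred(counts, thresholds, nodes, coefficients, n_definition="unmodified"):
    """Direct product N/N_k * gamma * FDR with explicit piecewise gamma."""
    numer = counts["N"] if n_definition == "unmodified" else counts["T"]
    fdr = oracle_global_fdr(counts)
    gamma = oracle_piecewise_eval(nodes, coefficients, np.asarray(thresholds, dtype=float))
    out = []
    for i in range(len(fdr)):
        if counts["N_k"][i] == 0:
            out.append(np.nan)
        else:
            out.append(numer[i] / counts["N_k"][i] * gamma[i] * fdr[i])
    return np.array(out)


def oracle_separate_q(ranks, is_decoy, is_modified):
    """Subset-only target-decoy q-values by explicit per-PSM recount.

    Returns (indices sorted by rank, fdr, q) for modified PSMs; the q-value
    of each PSM is the minimum subset FDR over the thresholds at or below
    its own rank (thresholds = modified PSM ranks).
    """
    ranks = np.asarray(ranks)
    mod_idx = [i for i in range(len(ranks)) if is_modified[i]]
    mod_idx.sort(key=lambda i: ranks[i])
    fdr = []
    for i in mod_idx:
        r = ranks[i]
        dk = sum(1 for j in mod_idx if ranks[j] >= r and is_decoy[j])
        tk = sum(1 for j in mod_idx if ranks[j] >= r and not is_decoy[j])
        fdr.append(dk / tk if tk > 0 else np.nan)
    q, best = [], np.inf
    for v in fdr:
        if np.isfinite(v):
            best = min(best, v)
            q.append(best)
        else:
            q.append(np.nan)
    return np.array(mod_idx), np.array(fdr), np.array(q)
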