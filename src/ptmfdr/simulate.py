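"""Synthetic merged PSM populations with ground-truth correctness labels.

The simulator emulates the merged modified/unmodified PSM population that
the FDR estimators consume, with a hidden correct/incorrect label per PSM so
calibration (empirical false-discovery proportion) is measurable:

* correct target matches score from a right-shifted distribution;
* incorrect targets and decoys score i.i.d. from the same null distribution
  (the equal-chance assumption behind target-decoy estimation), with one
  decoy drawn per incorrect target;
* the modified/unmodified membership of false matches follows a
  score-quantile-dependent profile, so the modified fraction gamma among
  decoys varies with rank the way it does in real data.

Score distributions are Gumbel location-scale families by default: a
right-skewed null mimicking hyperscore shape. Rank-based estimators are
invariant to the exact family; it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .curves import GammaCurve, error_propagation
from .exceptions import ConfigurationError
from .records import AMINO_ACIDS, Modification, PSMRecord, SpectrumKey


# -- gamma profiles (functions of the null score quantile q in [0, 1]) ------

@dataclass(frozen=True)
class ConstantGamma:
    value: float = 0.2

    def __call__(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.value)


@dataclass(frozen=True)
class LogisticGamma:
    """Smooth rise of the modified fraction with score quantile."""

    low: float = 0.05
    high: float = 0.35
    midpoint: float = 0.6
    steepness: float = 10.0

    def __call__(self, q):
        q = np.asarray(q, dtype=float)
        return self.low + (self.high - self.low) / (
            1.0 + np.exp(-self.steepness * (q - self.midpoint)))


@dataclass(frozen=True)
class PiecewiseLinearGamma:
    """Piecewise-linear profile through (quantile, gamma) points."""

    quantiles: tuple[float, ...] = (0.0, 0.6, 1.0)
    values: tuple[float, ...] = (0.05, 0.1, 0.4)

    def __call__(self, q):
        return np.interp(np.asarray(q, dtype=float), self.quantiles, self.values)


GammaProfile = Callable[[np.ndarray], np.ndarray]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated merged PSM set.

    ``frac_incorrect_targets`` is the incorrect fraction among targets (the
    pi0 of the target population); one decoy is generated per incorrect
    target so the decoy count estimates the incorrect-target count
    unbiasedly. ``frac_modified_targets`` is the modified fraction among
    *correct* targets. Null scores ~ Gumbel(mu0, s0); correct scores ~
    Gumbel(mu1, s1), right-shifted (mu1 > mu0).
    """

    n_total: int = 20_000
    frac_modified_targets: float = 0.10
    frac_incorrect_targets: float = 0.30
    gamma_profile: GammaProfile = field(default_factory=LogisticGamma)
    mu0: float = 15.0
    s0: float = 3.0
    mu1: float = 27.0
    s1: float = 4.0
    seed: int = 0
    ptm_name: str = "phospho"
    ptm_residue: str = "S"
    ptm_delta: float = 79.96633
    file_name: str = "sim.mgf"

    def validate(self) -> None:
        for name in ("frac_modified_targets", "frac_incorrect_targets"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.mu1 <= self.mu0:
            raise ConfigurationError("correct-score mean mu1 must exceed null mean mu0")
        if self.n_total < 2:
            raise ConfigurationError("n_total must be >= 2")
        if self.frac_modified_targets == 0.0:
            probe = np.asarray(self.gamma_profile(np.linspace(0, 1, 11)))
            if not (np.all(probe == probe[0]) and probe[0] == 0.0):
                raise ConfigurationError(
                    "frac_modified_targets=0 with a non-zero gamma profile would "
                    "produce modified decoys with no modified target population"
                )


@dataclass(frozen=True)
class GroundTruthPSM:
    """A PSMRecord plus its hidden correctness label.

    ``is_correct`` is never visible to the estimators; decoys are incorrect
    by construction.
    """

    record: PSMRecord
    is_correct: bool


def _null_quantile(scores: np.ndarray, mu0: float, s0: float) -> np.ndarray:
    # Gumbel CDF; theoretical quantile of each score within the null family
    return np.exp(-np.exp(-(scores - mu0) / s0))


def _random_peptide(rng: np.random.Generator, residue: str, modified: bool) -> tuple[str, int]:
    length = int(rng.integers(7, 21))
    seq = rng.choice(list(AMINO_ACIDS), size=length)
    pos = int(rng.integers(1, length + 1))
    if modified:
        seq[pos - 1] = residue
    return "".join(seq), pos


def simulate_psm_set(config: SimulationConfig) -> list[GroundTruthPSM]:
    """Draw one merged PSM population; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_targets = int(round(config.n_total / (1.0 + config.frac_incorrect_targets)))
    n_decoys = config.n_total - n_targets
    n_incorrect = min(n_decoys, n_targets) if config.frac_incorrect_targets > 0 else 0
    n_correct = n_targets - n_incorrect

    # scores
    correct_scores = rng.gumbel(config.mu1, config.s1, size=n_correct)
    null_scores = rng.gumbel(config.mu0, config.s0, size=n_incorrect + n_decoys)
    incorrect_scores = null_scores[:n_incorrect]
    decoy_scores = null_scores[n_incorrect:]

    # modification membership
    correct_mod = rng.random(n_correct) < config.frac_modified_targets
    g_incorrect = np.asarray(config.gamma_profile(
        _null_quantile(incorrect_scores, config.mu0, config.s0)))
    incorrect_mod = rng.random(n_incorrect) < g_incorrect
    g_decoy = np.asarray(config.gamma_profile(
        _null_quantile(decoy_scores, config.mu0, config.s0)))
    decoy_mod = rng.random(n_decoys) < g_decoy

    out: list[GroundTruthPSM] = []
    counter = 0

    def emit(score: float, is_decoy: bool, is_modified: bool, is_correct: bool) -> None:
        nonlocal counter
        counter += 1
        peptide, pos = _random_peptide(rng, config.ptm_residue, is_modified)
        mods = (Modification(pos, config.ptm_name, config.ptm_delta),) if is_modified else ()
        accession = ("DECOY_" if is_decoy else "") + f"SYNP{counter:06d}"
        rec = PSMRecord(
            key=SpectrumKey(file_name=config.file_name, scan_number=counter, charge=2,
                            peptide=None),
            peptide=peptide, modifications=mods, charge=2, score=float(score),
            is_decoy=is_decoy, is_modified=is_modified, proteins=(accession,),
        )
        from dataclasses import replace
        rec = replace(rec, key=replace(rec.key, peptide=rec.annotated_peptide))
        out.append(GroundTruthPSM(record=rec, is_correct=is_correct))

    for s, m in zip(correct_scores, correct_mod):
        emit(s, is_decoy=False, is_modified=bool(m), is_correct=True)
    for s, m in zip(incorrect_scores, incorrect_mod):
        emit(s, is_decoy=False, is_modified=bool(m), is_correct=False)
    for s, m in zip(decoy_scores, decoy_mod):
        emit(s, is_decoy=True, is_modified=bool(m), is_correct=False)
    return out


def records_of(simulated: Sequence[GroundTruthPSM]) -> list[PSMRecord]:
    """The estimator-visible records, ground truth stripped."""
    return [g.record for g in simulated]


@dataclass(frozen=True)
class FDPResult:
    """Empirical false-discovery proportion of an accepted set."""

    value: float
    n_accepted: int

    @property
    def empty(self) -> bool:
        return self.n_accepted == 0


def empirical_fdp(accepted: Sequence[GroundTruthPSM]) -> FDPResult:
    """(# accepted incorrect) / max(1, # accepted)."""
    n = len(accepted)
    n_false = sum(1 for g in accepted if not g.is_correct)
    return FDPResult(value=n_false / max(1, n), n_accepted=n)


@dataclass
class GammaSimulation:
    """Binomially noised gamma observations with the generating truth."""

    curve: GammaCurve
    gamma_true: np.ndarray


def simulate_gamma_observations(
    profile: Callable[[np.ndarray], np.ndarray],
    n_thresholds: int,
    decoy_counts: np.ndarray | Sequence[int],
    seed: int,
    sigma_cutoff: float = 0.01,
) -> GammaSimulation:
    """Gamma-curve-shaped data with known truth, for recovery tests.

    ``profile`` maps the threshold's position in [0, 1] (rank fraction) to
    the true gamma; observed D_k(r) ~ Binomial(D(r), gamma_true(r)).
    ``decoy_counts`` must be positive and non-increasing (cumulative counts
    shrink as the threshold rises).
    """
    d = np.asarray(decoy_counts, dtype=int)
    if d.shape != (n_thresholds,):
        raise ValueError(f"decoy_counts must have length {n_thresholds}")
    if np.any(d <= 0) or np.any(np.diff(d) > 0):
        raise ValueError("decoy_counts must be positive and non-increasing")
    rng = np.random.default_rng(seed)
    thresholds = np.arange(1, n_thresholds + 1, dtype=float)
    frac = (thresholds - 1) / max(n_thresholds - 1, 1)
    gamma_true = np.clip(np.asarray(profile(frac), dtype=float), 0.0, 1.0)
    d_mod = rng.binomial(d, gamma_true)
    gamma_hat = d_mod / d
    sigma = error_propagation(d_mod, d)
    stable = np.isfinite(sigma) & (sigma <= sigma_cutoff)
    curve = GammaCurve(thresholds=thresholds, gamma_hat=gamma_hat, sigma=sigma,
                       stable=stable, sigma_cutoff=sigma_cutoff)
    return GammaSimulation(curve=curve, gamma_true=gamma_true)
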