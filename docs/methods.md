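# Methods

This note documents the statistical model, its tunable parameters, the
synthetic data the tests run on, and the numerical conventions the package
holds fixed. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Ranking and counting conventions

All merged PSMs (modified + unmodified, targets + decoys) are sorted in
ascending order of the search-engine score; rank 1 is the worst match and
rank N the best. Scores are used *only* through ranks, so engines with
different score scales are comparable. Ties are broken by stable input
order. Every per-threshold statistic counts PSMs with **rank ≥ r**
(at-or-above); this boundary convention is used everywhere.

Counts only change at finitely many ranks, so curves are evaluated on a
threshold grid: by default every rank held by a decoy PSM, every rank one
past a decoy (where cumulative decoy counts actually change under the
at-or-above convention), and both range ends. A uniform subsample
(`max_grid`) is available for very large sets. Per-PSM values are looked up
at the largest grid threshold at or below the PSM's rank — the threshold
that accepts it.

## The transferred FDR

For a modification group k,

    FDRhat_k(r) = [N(r) / N_k(r)] * gamma_k(r) * FDR(r)

with `N` unmodified-target counts, `N_k` modified-target counts,
`FDR = D/T` the global decoy/target ratio, and `gamma_k` the modified
fraction among false identifications. Two switches exist because the
literature varies:

* `n_definition` — `"unmodified"` (default) counts only unmodified targets
  in `N(r)`; `"all_targets"` uses `T(r)` (the original transferred-FDR
  formulation). The default is the less conservative of the two whenever
  modified targets are a minority.
* `pseudocount` — global FDR as `(D+1)/T` instead of `D/T` (off by default).

Thresholds with `N_k(r) = 0` carry no modified target to accept and are
skipped (NaN), not assigned 0 or infinity.

### q-values

The q-value of a threshold (and of the PSMs it accepts) is the minimal
estimated FDR over all thresholds that accept at least as much — the
running minimum of `FDRhat_k` along ascending rank. This is the standard
target-decoy q-value; it is non-increasing with rank, so the accepted set
at level α is always a top segment of the ranking, reported as the minimal
accepting rank. (Monotonizing in the opposite direction — over *stricter*
thresholds — degenerates as soon as the estimated FDR reaches zero above
the best decoy: every PSM would inherit q = 0.)

### Gamma estimation and stabilization

`gamma_hat(r) = D_k(r)/D(r)` on the grid, with Poisson error propagation

    sigma(r) = (x/y) * sqrt(1/x + 1/y),  x = D_k(r), y = D(r)

on the cumulative counts. Grid points with `sigma > sigma_cutoff`
(default 0.01) or with `D_k < 1` are excluded from the regression; the
stable set is taken as-is (no contiguity is imposed, since noise can make
sigma locally non-monotone). If no point is stable, estimation aborts with
advice to enlarge the decoy population (that is what the 5000 random
entrapment proteins in the database builder are for).

The stable points are fitted with a continuous piecewise-linear model
(linear spline) by least squares on a hinge basis, so continuity at the
knots holds by construction. Knots: `n_interior_knots` (default 3) equally
spaced ranks over the stable range, one of them replaced by the **anchor**
— the inflection rank of the decoy/target ratio `rho(r) = D/T`, detected as
the global minimum of the Gaussian-smoothed central-difference derivative
of rho (kernel width `smoothing_sigma`, default 2% of the grid span;
reflect padding; ties resolved to the smallest rank on the minimum plateau,
with a 1e-9 relative tolerance absorbing smoothing round-off). With zero
interior knots the model reduces exactly to ordinary least squares (tested
to 1e-9). An anchor outside the stable range triggers a flagged fallback to
the spaced knots; a knot whose segment holds fewer than two stable points
is dropped with a warning.

Beyond the last knot gamma is extrapolated from the last segment's affine
form, and evaluated gamma is clipped to [0, 1].

### Known behavior of the extrapolation

When the true cumulative gamma saturates at high ranks (it is a proportion;
it must), a linear extrapolation from the stable region overshoots it. The
effect is conservative: the estimated `FDRhat_k` is inflated at high ranks,
the acceptance threshold moves up, and calibration holds while power is
lost. In the calibration simulations below the mean empirical FDP at
α = 0.01 is ≈ 0.018 — inside the nominal band, on its conservative-power
side. Under extreme decoy scarcity (D_k ≈ 1–5) the opposite artifact
appears: `gamma_hat = 1/D(r)` passes the absolute sigma cutoff while
overshooting a tiny true gamma, so the transferred and separate methods
trade single-PSM differences; across 20-seed batches the transferred
estimator accepts at least as many PSMs as the separate estimator in
roughly 60–95% of seeds depending on the seed batch, with ties dominating
and occasional larger losses when a late surviving modified decoy drags the
fitted gamma tail upward. The conditioning artifact behind this: once the
cumulative modified-decoy count reaches 1, the estimate `1/D(r)` keeps
rising with rank regardless of the true gamma, and the stability filter
(being an absolute cutoff) admits those points down to `D ≈ 100`.

## Separate FDR

For comparison and for the scarce-group baseline: `D_k(r)/T_k(r)`
restricted to the modified subset, q-values as above. With zero modified
decoys the q-values are identically zero and flagged low-confidence. One
test cross-checks these q-values against `pyteomics.auxiliary.qvalues`.

## Synthetic PSM populations

The simulator generates the merged population the estimators consume, with
a hidden correctness label per PSM:

* Correct targets score from a right-shifted Gumbel(μ₁ = 27, s₁ = 4);
  incorrect targets and decoys score i.i.d. Gumbel(μ₀ = 15, s₀ = 3) — a
  right-skewed null mimicking hyperscore shape. Rank-based statistics are
  invariant to the exact families; both are configurable.
* One decoy is drawn per incorrect target (the equal-chance assumption of
  target-decoy estimation), so `D(r)` estimates the incorrect-target count
  unbiasedly; a two-sample test in the suite confirms exchangeability.
* Modified/unmodified membership of *false* matches follows a profile
  `gamma(q)` of the null score quantile (constant, logistic — default low
  0.05, high 0.35, midpoint 0.6, steepness 10 — or piecewise linear), so
  the modified-decoy fraction varies with rank as in real data. Correct
  targets are modified with probability `frac_modified_targets`.
* Default study conditions: 20,000 PSMs, 10% modified (correct) targets,
  30% incorrect targets, logistic gamma.

What this emulates: the four-subset structure, score-dependent decoy
composition, and decoy/incorrect exchangeability. What it does not: spectra
and fragment evidence, mass-accuracy structure, shared peptides between
proteins, score miscalibration across charge states, and correlated
duplicate spectra. Passing calibration here therefore validates the
*statistics* under the stated sampling assumptions, not the behavior of any
search engine on real spectra.

Problem sizes in the test suite (50 × 1,000 PSM oracle sets; 20 × 20,000
calibration sets; 20 × 26,000 scarcity sets; 50 × 120-point gamma curves;
one 10,008-entry database) keep the full suite around a minute on one CPU
while leaving every count regime (dense to single-decoy) exercised.

## Database builder

Per PTM: annotated real proteins (UniProt-flat and dbPTM-style annotation
sources normalized through a packaged vocabulary; custom lists always
included), plus `n_random` = 5000 random proteins, their 5000 reverses, and
one reversal decoy per real protein. Random sequences draw lengths from
the proteome's empirical length distribution and residues i.i.d. from its
amino-acid composition, keeping entrapment peptide masses realistic; a
chi-square goodness-of-fit on the generated composition is part of the
acceptance suite. Forward/reverse random pairs mirror the target/decoy
construction. Random-protein hits are stripped from results only *after*
the FDR threshold is fixed (a PSM is removed only if *every* protein
assignment is a random entry), and the operation is idempotent.

The default of 5000 random sequences follows the observation that smaller
search spaces distort the q-value distribution while larger ones only cost
time; the sizing harness (`search_space_experiment`, CLI `sizing`) exposes
the comparison for any set of database sizes.

## Pipeline conventions

Each PTM is filtered independently against the same standard-search
unmodified background at `alpha` (default 0.01); no cross-PTM multiplicity
correction is applied beyond the per-group FDR. Only singly-modified
peptides are in scope; methionine oxidation may co-occur and is ignored for
grouping, and carbamidomethylation/oxidation never enter the site tables.
Protein coverage is exact substring matching, counting every occurrence,
union over peptides; isoform ambiguity is reported (all mapped accessions
are counted), not resolved. Two PSM key profiles are provided — (file,
scan, modified peptide) for core/unique partitions of the sizing harness
and (file, scan, charge, modified peptide) for cross-engine intersection —
and every intersection call names its profile explicitly.

## Numerical choices

* Least squares via `numpy.linalg.lstsq`; R² defined as 1 − SS_res/SS_tot,
  with the SS_tot = 0 degenerate case mapped to 1 (perfect) or 0.
* Gamma clipped to [0, 1] after evaluation; transferred FDR values are not
  truncated before q-value monotonization.
* `FDR(r)` with `T(r) = 0`: 0 if also `D(r) = 0`, otherwise flagged
  undefined (NaN) and excluded downstream.
* Determinism: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); identical configs produce byte-identical
  output files.
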