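# Methods

## Physical setting

`relkin` models the cumulative release R(t), in percent of total drug
load, of a hydrophobic drug (the built-in scenarios use paclitaxel)
from spherical nanocarriers: a porous Fe-BTC metal–organic framework
(MOF) releasing by surface-diffusion desorption, and mPEG-PCL polymer
nanoparticles (with or without MOF-adsorbed drug inside) releasing by
diffusion through the polymer matrix.  Hydrolytic matrix erosion is
excluded as a release mechanism: at physiological pH/temperature it
removes well under 1 wt% over the study horizon, which is what the
weight-loss arithmetic in `formulation` quantifies.

## Release models

**Exact sphere series.**  Desorption limited by surface diffusion in a
sphere of radius r obeys the transient diffusion equation, whose
solution is

    R(t) = 100 · (1 − (6/π²) Σ_{i≥1} exp(−D i² π² t / r²) / i²),

with D the surface diffusion coefficient (m²/s).  The series is summed
adaptively: terms are added until the remaining tail cannot change the
sum by `rel_tol` (default 1e-10) relative, using the rigorous tail
bound Σ_{j>i} exp(−a j²)/j² < term_i · i, with a hard cap of 10,000
terms.  t = 0 short-circuits to exactly 0 because any finite truncation
of the full series (which sums to π²/6) would report a spurious
positive release.  The adaptive sum agrees with an independent
10,000-term brute-force sum to better than 1e-8 release-% over
dimensionless times D·t/r² from 1e-4 to 10.

**Single-term approximation.**  Keeping one exponential and letting
both its amplitude and rate float gives R(t) = 100·(1 − A e^(−kt)),
A ∈ (0, 1], k > 0 (d⁻¹).  With A = 6/π² and k = Dπ²/r² this is exactly
the first series term.  Its structural defect is the initial burst:
whenever A < 1 it starts from a spurious positive intercept
100(1 − A) with a shallow early slope, while the exact solution starts
at 0 with unbounded initial slope.  (Note the exact series is *below*
the A = 6/π² first term in value at all t > 0 — the burst failure is a
matter of intercept and slope, not of one curve exceeding the other.)

**Bimodal two-population model.**  Two sub-populations of drug
molecules, fractions φ and 1 − φ, release with distinct first-order
rate constants:

    R(t) = 100 · [φ(1 − e^(−K1 t)) + (1 − φ)(1 − e^(−K2 t))].

The triple (φ, K1, K2) is only identified up to the relabelling
(1 − φ, K2, K1); `canonicalize` resolves this by fixing K1 ≥ K2
(fast mode first).  When the data are genuinely single-exponential the
model is degenerate (φ at a boundary or K1 ≈ K2); this is reported
as-is, not raised as an error.

**Rate ↔ diffusivity.**  The linear-driving-force approximation for a
sphere links a first-order rate constant to a diffusivity through
K = 15 D / r²; the geometric factor 15 is taken as given from the
standard lumped-kinetics literature.  All public rates are in d⁻¹ and
diffusivities in SI m²/s; the 86,400 s/day factor is applied only
inside `diffusivity_from_rate` / `rate_from_diffusivity`.  The particle
radius is by convention half the DLS-average size — this convention is
validated by reproducing the published diffusivities (3.7e-21,
1.46e-22, 6.9e-21, 4.84e-22 m²/s) from the published rate constants
and sizes (138 and 143 nm) to within 1 %.

## Fitting

Fit quality is the root-mean-square deviation in release-% over the N
non-trivial points,

    S = sqrt( Σ (R_model − R_exp)² / N ),     non-trivial: R < 99 %,

applied uniformly before every fit (threshold configurable).  Points on
the exhaustion plateau carry no kinetic information but would dominate
an unweighted criterion; t = 0 points are retained because they anchor
the burst.  S is both the reported statistic and the model-selection
score; no information criterion is layered on top.

Optimisation is bounded trust-region least squares in the parameters'
natural units (box constraints, no sigmoid/log reparameterisations, so
reported values are the physical ones).  Because diffusivities live
around 1e-22 m²/s and scipy's trust-region code silently clamps
unscaled iterates below ~1e-10 onto an absolute feasibility margin,
each local solve is performed in per-start scaled units u = x/|x0|;
this is a linear change of units, not a reparameterisation.

Starts form a deterministic grid — φ ∈ {0.1, 0.3, 0.5, 0.7, 0.9},
rates log-spaced over 1e-3…10 d⁻¹ (5 values, ordered pairs K1 ≥ K2),
amplitudes {0.2,…,1.0} for the single-term model, and 11 log-spaced
decades 1e-26…1e-16 m²/s for the series model.  The grid is screened
by initial residual sum of squares and local optimisation runs from the
best `n_best_starts` (default 12) points; the best converged optimum
wins, with ties (within 1e-9 relative SSE) broken by the smaller fast
rate.  The screen-then-polish design keeps the 150-fit recovery sweeps
to seconds while retaining multi-start robustness — the 1-D series fit,
for instance, reaches the same optimum from starts up to six decades
away.  Identical curve + options give bit-identical results; the
`seed` option is provenance echo only.

`compare_models` fits every applicable model (series requires a radius)
on the identically filtered curve and ranks by S; per-model failures
are collected, not fatal.  `fast_slow_diffusivities` converts a
canonical bimodal fit to (D_fast, D_slow) and
`diffusivity_percent_change` reports 100·(D_b/D_a − 1) between two
formulations, each with its own radius.

## Synthetic data

The study's experimental dissolution profiles exist only as published
figures, so the test surface is synthetic: forward model on a sampling
schedule plus i.i.d. additive Gaussian noise on cumulative release,
clipped to [0, 102] % (the ceiling tolerates the over-100 excursions
real assays produce; clipping is flagged per point).  Additive noise on
the cumulative percentage is the simplest mechanism consistent with the
unweighted S criterion; it permits mildly non-monotone curves, as real
cumulative data show.  An isotonic post-step (scikit-learn's
`IsotonicRegression`) can restore monotonicity but is off by default.

Three named scenarios emulate the study's modelled formulations, with
bimodal parameters at the published fits, noise at the published fit
deviations, sub-daily schedules starting at the t = 0 assay origin, and
fixed seeds:

| scenario             | φ     | K1 (d⁻¹) | K2 (d⁻¹) | horizon | σ (%) |
|----------------------|-------|----------|----------|---------|-------|
| Fe-BTC-PTX           | 0.665 | 4.98     | 0.547    | 4 d     | 2.8   |
| mPEG-PCL-PTX         | 0.254 | 1.0      | 0.04     | 15 d    | 1.1   |
| mPEG-PCL-Fe-BTC-PTX  | 0.29  | 1.74     | 0.123    | 15 d    | 1.65  |

The Fe-BTC rates are derived from the published diffusivities
(6e-22 and 6.6e-23 m²/s) with r = 12.5 nm, the midpoint of the 20–30 nm
TEM size range for the bare MOF particles (no radius is published for
this formulation); the resulting noiseless curve reproduces the
reported profile (≈89 % at 2 d, ≈96 % at 4 d).  The mPEG-PCL scenario
plateaus near 59 % at 15 d — that deficiency is kinetic (K2·t = 0.6 at
the horizon), matching the reported behaviour of that formulation.

What the generator does *not* emulate: sink-condition violations,
inter-replicate variability of the underlying kinetics, heteroscedastic
assay error, or autocorrelated drift.  Passing recovery tests therefore
demonstrate estimator correctness under the assumed noise model, not
robustness to all real-assay pathologies.

## Validation results and a known estimator limit

On noiseless scenario curves the bimodal fit recovers (φ, K1, K2) to
better than 1e-4 relative.  Under σ = 2 % noise, 50 seeded replicates
per scenario give median absolute relative errors ≤ 0.10 for φ and K2
everywhere and for K1 in the desorption scenario, but ≈ 0.21 / 0.17 for
K1 in the two polymer scenarios.  That limit is statistical, not
algorithmic: the fit attains the global optimum on every replicate
(fitted SSE ≤ SSE at the true parameters, 50/50), the linearized
Cramér–Rao bound already implies a median K1 error around 0.12 under
these conditions (the fast mode carries only ~25 % of the signal and is
exhausted within ~2 days of a 15-day schedule), and nonlinear curvature
inflates the realized spread by ~1.7×.  Sub-15 % K1 recovery in those
scenarios would require denser early sampling or lower noise than the
scenarios specify.

On desorption-like synthetic data the fitted S values rank
bimodal < series < single-term (typically ≈2.5 / 4.5 / 7), the same
qualitative ordering and similar magnitudes as the published fits
(2.8 / 4.8 / 8.3).  The published fitted constants themselves derive
from figure-only data and are treated as narrative anchors, not test
fixtures.

## Formulation arithmetic

Single-point intrinsic viscosity uses the Solomon–Ciuta form
[η] = sqrt(2(t/t₀ − ln(t/t₀) − 1))/c (standard grouping), admitting
t = t₀ as the zero-viscosity limit.  The Mark–Houwink–Sakurada weight
is Mv = ([η]/k)^(1/a); with the stated mPEG-PCL/chloroform constants
(k = 1.09e-3 dL/g, a = 0.6021) and [η] = 0.68 dL/g it gives
43,876 g/mol vs the published 43,629 (0.6 %, within rounding of the
printed inputs).  Mv is a molar mass; a concentration-like unit
sometimes seen in print for it is a typographical slip that does not
affect the number.  Yield, drug loading and entrapment efficiency are
the three standard mass ratios ×100; the published percentage table
cannot be recomputed because the underlying weighings are not printed,
so those values serve as format examples only.

## Pore-passage screen

A rigid triaxial-ellipsoid guest (full axes a1 ≤ a2 ≤ a3, Å)
translating along its longest axis presents an a1 × a2 elliptical
cross-section, which clears a circular window of diameter d iff
a2 ≤ d.  The tiers PASSES_FREELY (a2 ≤ d), PASSES_ORIENTED
(a1 ≤ d < a2), MARGINALLY_BLOCKED (d < a1 ≤ d + tol) and BLOCKED
partition every case; the default marginal tolerance of 1.0 Å encodes
"marginally too small" for deficits like paclitaxel's 0.6 Å at the
5-membered window.  These are deliberate heuristics: guest flexibility,
tilted trajectories and host–guest energetics are out of scope.
Cavity occupancy uses the cruder a3 ≤ cavity-diameter test.

## Numerical and interface choices

- Time is days in every file and public signature; radii are nm at the
  CLI (DLS convention) and SI metres internally; unit conversion
  happens only in the two conversion operations and at the CLI
  boundary.
- Release CSVs are written with pandas' shortest-repr float output and
  read with the `round_trip` parser, so write→read is bit-exact;
  unsorted or duplicated times are rejected, never silently fixed.
- Fit reports echo the input curve and options, so every reported
  number can be recomputed from the report alone.
- CLI exit codes: 0 success, 2 validation failure, 3 fit
  non-convergence.
- Problem sizes used by the validation scripts: 13-point dimensionless
  time grid for the series oracle, 50 seeds × 3 scenarios × 31-or-17
  point curves for recovery, single seeded curves for ranking.
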