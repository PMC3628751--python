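# Methods

## Model

The MilkBot model writes daily milk yield as
`Y(t) = a·G(t)·D(t)` with growth `G(t) = 1 − exp((c − t)/b)/2` and
death `D(t) = exp(−d t)`, `t` in days in milk (DIM, `t = 1` at
parturition). `G` is the integral of a right-sided Laplace growth-rate
density `C(t) = exp((c − t)/b)/(2b)` (defined for `t > c`, unit half
mass), so `G(c) = 1/2` by construction — the offset `c` is *defined* as
the growth midpoint — and `G → 1` as `t` grows. `G` is the analytic
continuation below `c` as well; it can drop below 1/2 (even below 0 for
`t ≪ c`) and is deliberately not clamped, since fitted offsets near
calving keep observations on the right branch.

Closed forms used throughout:

* peak day `t_peak = c − b·ln(2bd/(1 + bd))` (stationary point of `Y`);
  for `bd > 1` this falls before parturition and is returned untruncated
  with a `pre_parturition_peak` diagnostic rather than clipped.
* peak milk `y_peak = Y(t_peak)`; algebraically
  `a·e^{−dc}(2bd/(1+bd))^{bd}/(1+bd)`, always `< a`.
* persistency `0.693/d`. The constant is kept at the conventional
  rounded 0.693 rather than ln 2 = 0.693147…; the difference is
  < 0.03% and the rounded form matches the definition in field use.
* cumulative yield: the antiderivative of `Y` is
  `−a·e^{−dt}/d + (ab/(2(1+bd)))·e^{c/b}·e^{−t(1/b+d)}`; M305 is the
  `[0, 305]` integral. The lower bound is 0 (not 1): the closed form of
  M305 in field use evaluates the antiderivative at 0, and the yield
  below DIM 1 contributes a fraction of one day's milk.
* peak-to-M305 multiplier: the closed-form "extra kg of M305 per unit
  increase of scale". Because M305 is linear in `a`, the formula reduces
  exactly to `m305/scale` (verified to 1e-9 in the tests). The analogous
  sensitivity per unit of *peak milk* is simply `m305/peak_milk`
  (also linear in `a`); both are provided by composition.

Degenerate decay: all formulas dividing by `d` switch to their analytic
`d → 0` limit below `d = 1e-12 /day` (flat-curve branch, first term
`a·t`). Exponent arguments are clamped at ±700 before exponentiation so
extreme `ramp → 0` probes overflow gracefully; clamping is logged at
debug level and surfaced as a `clamped_exponent` diagnostic on fits.

## Fitting

Both engines minimize over `x = (ln a, ln b, [c], ln d)` — logs enforce
the positivity of scale, ramp and decay smoothly, offset stays natural —
with analytic Jacobians. Defaults fix `c = 0` because monthly test
intervals cannot identify it (a free-offset policy is available, and a
`fixed_value` policy for a nonzero constant). Convergence: relative
objective change below 1e-10 or 200 iterations; non-convergence is a
flagged result, never an exception.

The least-squares engine runs unconstrained Levenberg–Marquardt first
with a short evaluation budget (80): well-posed fits converge in ~20
evaluations, while fits walking a parameter to a sign boundary (about
10–15% of realistic first-parity lactations have their constrained ML
at `d ≈ 0`) exhaust the budget, come back flagged, and are finished by
a bounded trust-region solve over the plausibility box
scale ∈ [1e-3, 1e4] kg/day, ramp ∈ [1e-2, 1e3] d, decay ∈ [1e-8, 1] /day
(offset ∈ [−305, 305] d when free). Boundary-pinned solutions carry a
`boundary_active` flag. Log-coordinates are clipped at ±600 before
exponentiation so the Jacobian stays finite when the optimizer probes
`ramp → 0` (the `b²` in the ramp partial otherwise underflows and
produces NaNs that stall MINPACK). Initialization is data-driven
(`a₀ = 1.1·max(milk)`, `b₀ = 25 d`, `d₀ = 0.002 /day`, `c₀ = 0`) with
population-mean fallback starts tried whenever the first solution is
worse than the best constant curve; across 200 random noisy monthly
lactations the returned SSE never exceeds the SSE at the generating
parameters.

RMSE uses divisor `n`, not `n − 4`: no degrees-of-freedom correction is
applied, matching RMSE's use here as a per-lactation consistency
measure and the worked outlier example's arithmetic.

The MAP engine maximizes a Gaussian log-likelihood with fixed residual
SD (default 4.0 kg/day, between the typical first-parity ≈3.7 and
mature-cow ≈4.65 fitted RMSE) plus independent Gaussian log-priors on
the *natural* parameters, implemented as an extended residual vector in
the same LM core. With zero observations the posterior mode is exactly
the prior mean vector and is returned directly (bit-exact); with
prior SDs → ∞ the solution matches least squares to ~1e-4 relative.
Shipped default priors per parity group come from a published
21-herd survey of Holstein-dominated US DHIA herds:
P1 (38.66, 31.43, −0.5, 0.000974) with SDs (5.87, 2.67, 0, 0.000605);
P2+ (53.65, 26.13, −0.37, 0.002213) with SDs (9.3, 7.66, 0.39,
0.000858). An offset prior SD of 0 means "offset fixed at the prior
mean". This engine is an openly specified prior-anchored fitter; it is
not claimed to replicate any proprietary fitting product numerically.
Note that MAP shrinkage is toward the prior in *distance* per
parameter, but coordinate-wise betweenness between prior mean and the
LS solution can fail for ramp through the ramp–decay correlation; the
tests assert the distance property.

Study filters: test days past 305 DIM are dropped first, then
lactations with fewer than 7 remaining tests are rejected — in that
order, so late tests cannot rescue a short lactation — with both
actions counted in an exclusion log.

## Group comparison

Per (herd, parity) group and metric (scale, ramp, offset, decay, RMSE,
M305, peak day, peak milk): mean, SD (n−1), quartiles by linear
interpolation between order statistics (numpy's default convention; no
convention is canonical here), full range, and a Z-based 95% CI
half-width `1.96·sd/√n`. Pairwise comparisons use a two-sample Z-test
with unpooled (Welch-style) variance and a standard normal reference —
appropriate at n = 50 per group — and **no multiple-testing
correction**, deliberately: with 21 groups each group has 20 peers, so
under the null each group is expected to diverge from one peer at
p < .05, and that expectation of ~1 is the design's own calibration
device. The divergence score is the count of same-parity peers with
p < .05; it is invariant under herd relabeling and under common affine
rescaling of a metric.

Calibration in practice: the Monte-Carlo null mean score is expected
slightly above 1.0 rather than exactly at it. Two small inflations
stack: the normal reference versus the implicit Welch-t (≈0.053
rejection instead of 0.050 at n = 50), and right-skew in least-squares
scale estimates from decay–scale confounding at monthly sampling with
~3.7 kg noise. Replicate mean scores are also strongly over-dispersed
(pairwise tests share groups), so 200-replicate averages scatter
noticeably across seeds. Both effects are properties of Z-tests on
fitted parameters at these study conditions, not implementation
artifacts; the acceptance script reports the realized value for its
seed.

## Synthetic cohorts

The generator emulates a DHIA-style recording structure: 21 herds × 2
parity groups × 50 lactations by default; per-cow parameters drawn as
population mean + herd effect + cow deviation, truncated by resampling
to the sign constraints; first test uniform on 5–35 DIM, subsequent
tests every 30 ± 3 d (uniform jitter), truncated at 305 DIM with at
least 7 tests by construction; additive homoskedastic Gaussian noise on
each milk weight (SD 3.7 kg P1 / 4.65 kg P2+, the scale of typical
fitted RMSE), floored at 0 with flooring counted. Herd effects default
to 0.5× the within-group SD per parameter — a deliberately free knob,
since the survey reports within-group SDs only; null experiments set it
to 0. Parameters are drawn independently by default (a correlation
matrix hook exists but defaults to none): the fitted-offset/ramp
correlation seen in real monthly data is a fitting artifact, and no
generative correlations are established. Every lactation's generating
parameters, noise SD and injected effects are recorded in a truth
table keyed by lactation id.

What the generator does *not* emulate — and therefore what passing
tests cannot certify about real data: culling-driven late-lactation
selection, seasonal and calving-date effects, heteroskedastic or
non-Gaussian measurement error, breed structure, and any cross-herd
correlation in management. Truncation also shifts the realized decay
mean slightly above its nominal value for P1 (the nominal mean is ~1.6
SDs above zero).

## Problem sizes and numerical choices

The Monte-Carlo null calibration uses 200 replicates of the full
21 × 50 design (1,050 LM fits per replicate, ~10 minutes on one CPU);
recovery regressions use 200 replicates of single lactations. Frozen
regression thresholds for noisy monthly recovery at the P1 population
point (median relative error over 200 replicates: scale ≤ 0.12,
ramp ≤ 0.65, decay ≤ 0.65) were calibrated once and sit ~30% above the
measured medians (0.09/0.50/0.49); the information (Cramér–Rao) bound
at this design already implies median errors of roughly 0.14/0.7/0.7,
so materially tighter recovery is not attainable from 10 monthly tests
at 3.7 kg noise. Closed forms are verified against adaptive quadrature
at 1e-6 relative and against numeric maximization of the peak at
0.01 day. Ties and degeneracies: reversed integration bounds and
singleton parity strata raise; zero-variance Z-tests return p = 1 for
equal means and p = 0 (with a warning) otherwise.

## Files and interfaces

Test-day CSV: `lactation_id, herd_id, parity_group, dim, milk_kg`, one
row per milk weight, header required; parity accepts aliases ("1" → P1,
"2+"/"2plus"/any integer ≥ 2 → P2plus); DIM is real-valued with the
1-at-calving convention; milk is kg (an `--units lb` read-time
conversion multiplies by 0.45359237 — unit changes touch scale only).
Parameter CSV: ids, the four parameters, RMSE, n_tests, M305, peak day,
peak milk, persistency and diagnostic flags, written at 10 significant
digits so files round-trip losslessly. Every CLI run writes a JSON
manifest (argv, seed, config, SHA-256 of inputs, library versions)
sufficient to reproduce its outputs exactly.
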