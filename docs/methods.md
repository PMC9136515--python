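# Methods

## The problem

Under chronic sub-lethal DNA damage, *E. coli* populations split into two
phenotypic classes: most cells keep a low level of SOS induction and divide
normally, while a small subpopulation reaches high SOS expression, induces
the division inhibitor SulA, filaments, and all but stops dividing. The
size of that high-SOS subpopulation in an expanding culture is set not by
the induction rate alone but by the competition between induction and the
division-rate gap between the two classes. `sosswitch` implements the
quantitative machinery for this picture: inference of the switching rate
from censored single-cell lineages, inference of the population growth
rate from interdivision times, the two-state population model that
combines them, and snapshot statistics for validation against batch data.

## Two-state model

States 1 (low SOS) and 2 (high SOS) carry division rates λ₁ > λ₂ (per
hour) and switching rates α (1→2) and β (2→1). Counts in an expanding
culture obey

    dn₁/dt = (λ₁ − α) n₁ + β n₂
    dn₂/dt = α n₁ + (λ₂ − β) n₂.

The steady-state high-SOS fraction f₂ is read off the dominant
eigenvector (`f2_exact`). Two standard approximations are exposed because
they are what practitioners quote: f₂ ≈ α/λ₁ when high-SOS divisions are
negligible (`f2_simple`), and f₂ ≈ α/(λ₁ − λ₂) when they are not
(`f2_corrected`). With β = 0 and λ₁ − α > λ₂ the corrected form is exact,
and the package asserts this identity rather than assuming it. Reversion
is supported throughout (the eigen and ODE routes take any β ≥ 0) but
defaults to 0: in the mother-machine data this model describes, reversion
events are rare enough to neglect.

A regime flag marks λ₁ − α ≤ λ₂, where the high state dominates and the
ratio approximations are meaningless.

`two_state_ode_solve` evaluates the same linear system by matrix
exponentials (exact up to floating point) and exists mainly as an
independent oracle for the eigen route; the stochastic branching
simulator (below) is the third, fully independent route. Tests require
eigen/ODE agreement to 1e-6 and eigen/simulation agreement within
Monte-Carlo error. The model-level analysis is deliberately *not*
implemented via the simulator: simulation validates, algebra predicts.

## Switching-rate inference

Along each mother lineage the first frame whose GFP concentration reaches
the threshold θ (default 5 a.u./area) is the event; lineages that never
reach θ contribute their full observation span as right-censored
exposure; lineages already at or above θ at their first frame are
excluded and counted. The exposure clock runs from the first observed
frame, not from cell birth: the mother position is a single renewing unit
and α is a per-lineage, per-hour rate. With exponential waiting times the
censored likelihood L(α) = α^k exp(−αT) is maximized at α̂ = k/T.

Confidence intervals are percentile bootstrap over lineages (default 2000
resamples, seeded) rather than the χ² censored-exponential interval, so
they remain valid with heterogeneous exposures. With k = 0 the MLE sits
on the boundary; the one-sided exact upper bound −ln(0.05)/T is reported
with a flag.

Numerical caveats, stated rather than hidden:

* crossing times are frame-quantized (no sub-frame interpolation), so
  each event's exposure is overstated by up to one frame interval; at the
  default geometries this biases α̂ downward by well under 1% and shows up
  in the CI-calibration study as a mean z-score of ≈ −0.14 at coverage
  93.5% (200 replicates, nominal 95%);
* no GFP smoothing is applied before thresholding by default, so the
  exponential oracle holds exactly when the generator's rise time is 0; a
  3-frame median filter is the obvious extension for noisy real data and
  is intentionally not applied inside the estimator.

A threshold sweep (default 5…20 a.u./area, step 1) repeats the estimate
per θ; when the high-state plateau lies above the whole grid the curve is
flat, and a faster-switching condition stays above a slower one at every
threshold.

## Growth-rate inference

Single-cell route: interdivision times τᵢ from complete (non-censored)
cycles of the mother lineages enter the discrete Euler–Lotka condition
(2/N)Σᵢ exp(−λτᵢ) = 1, solved by bisection on [ln2/max τ, ln2/min τ]
(the bracket is guaranteed: each endpoint bounds every term by 1/2 from
one side) to relative tolerance 1e-10. Censored cycles are excluded —
they carry no τ — which tilts the estimate toward the normally dividing
low-SOS subpopulation. That is the λ₁ the two-state model wants, so the
exclusion is a feature, not a correction to apologize for; the censored
count is still reported. No lineage-tree reweighting is applied: the
estimate reproduces the plain discrete Euler–Lotka of the observed
mother-lineage τ distribution, and a weighting hook would slot in at the
single function that collects τᵢ.

A subtlety worth stating precisely: for the generator's gamma
interdivision law with mean ln2/λ₁ and CV c, the implied Euler–Lotka rate
has the closed form λ = λ₁ (2^{c²} − 1)/(c² ln2), which is ≈ 1.4% above
λ₁ at c = 0.2. Division-time variability makes a population grow slightly
faster than ln2 over the mean interdivision time. Parameter-recovery
tests therefore target this exact implied rate
(`simulate.lineage_growth_rate`), not λ₁ itself — at n = 2000 the ≈1.4%
offset is several bootstrap standard errors wide, so conflating the two
would be a real error, not a rounding choice.

Batch route: OLS on ln(OD600) or ln(CFU/ml) against time within an
exponential-phase window (≥ 3 points), slope in 1/h, doubling rate =
slope/ln2 (λ = µ ln2 throughout).

## Replication-fork arithmetic

Under the Cooper–Helmstetter cell-cycle model (replication period C,
post-replication period D, doubling time τ), a round destined for the
division n generations ahead is initiated at age (n+1)τ − (C+D) —
possibly in an ancestor — runs for C minutes with 2ⁿ⁺¹ forks, and the
steady-state age distribution is φ(a) = (2 ln2/τ)·2^{−a/τ}. Averaging the
instantaneous fork count over φ gives the closed form
F = 2(2^{(C+D)/τ} − 2^{D/τ}). The package carries both the closed form
(implementation) and the piecewise-constant integrand (`forks_at_age`,
oracle); tests integrate the latter numerically and require agreement to
1e-9. With C = 40 min, D = 20 min: F ≈ 4.83 (≈ 5 forks) at τ = 30 min and
F ≈ 0.36 at τ = 180 min.

## Synthetic-data generators

The generators define the study conditions for every inference stage;
they emulate statistical structure, not images.

**Mother machine** (`simulate_mother_machine`). A fixed number of
lineages, each a continuous-time history sampled at the frame interval:

* low state: interdivision times gamma with mean ln2/λ₁ and CV 0.2
  (default) — a timer per cycle, independent across cycles, no
  mother-daughter correlation, because the inference stack consumes only
  the τ marginal; exponential elongation at rate λ₁; at division the
  proximal half is retained;
* switching: Poisson with rate α per lineage; after a switch, divisions
  become exponential at λ₂, and the elongation rate relaxes toward
  0.05 h⁻¹ (filamentation without full arrest) with the same time
  constant as the GFP ramp;
* GFP: per-lineage low/high plateaus drawn once (means 1.4 and 9.0
  a.u./area by default, so the 5 a.u./area threshold cleanly separates
  them), exponential ramp with time constant `gfp_rise_time` (default
  0.5 h; 0 for exact-exponential oracles); multiplicative lognormal
  measurement noise on GFP and mKate;
* right-censoring at the experiment duration; frames/durations per
  condition follow the imaging protocol (12 min/42 h for M9-gly,
  10 min/24 h for M9-glu, 5 min/16 h for M9-glu+aa).

Per-lineage RNG substreams are spawned from the master seed by spawn-key,
so enlarging `n_lineages` appends lineages without reshuffling existing
ones, and a fixed seed reproduces the table byte-for-byte. The result
object carries the generative ground truth (true switch and division
times) for oracle tests; inference code never touches it.

What the generator does *not* emulate — hence what passing tests do not
show about real data: segmentation/tracking errors, autofluorescence
background, cell-age and cell-size correlations, mother-daughter
covariance, GFP bleaching, partial reversion with asymmetric division,
and channel-geometry artifacts.

**Condition presets.** The per-condition (α, λ₁) pairs are not printed
anywhere as inputs; the presets back-derive them from the model's own
printed outputs (first-order fractions 7.81/5.92/5.25%, corrected
fractions ≈15%/≈7.1%, and a 0.98 dbl/h mother-machine doubling rate in
the rich condition), giving α = 0.0163/0.0357/0.0357 h⁻¹ and
λ₁ = 0.208/0.603/0.679 h⁻¹ with λ₂ = 0.1 h⁻¹ everywhere. These preserve
the two orderings that matter: switching is faster in rich media, yet the
predicted and simulated high-SOS fraction is larger in poor media —
because λ₁ grows with nutrient quality much faster than α does.

**Branching population** (`simulate_branching_population`). Exact
Gillespie simulation on aggregated propensities (n₁λ₁, n₁α, n₂λ₂, n₂β) —
exact for this linear model, no per-cell agents needed. Above the
population cap, hypergeometric thinning back to the cap preserves state
proportions without bias and accumulates the discarded log growth factor
so the absolute trajectory can be reconstructed.

**Snapshots** (`simulate_snapshot`). Two-component lognormal mixture with
high-component weight f₂, split across replicate labels — the main peak
plus high shoulder structure of batch fluorescence distributions.

## Snapshot statistics

Thresholded fractions (strict `>`, ties to the lower class), nearest-rank
percentile slices (top 1% of 100 cells is exactly 1 cell), geometric-bin
histograms normalized per replicate, and rescaling by a reference-strain
mean. Error bars are always mean ± SEM across biological replicates,
never across cells; with one replicate the SEM is reported as 0 with an
explicit flag.

The two-component Gaussian mixture is fit by hand-written EM, by default
on log intensities (distributions are log-binned, and the components are
closer to lognormal than normal): means initialized at the 15th/85th
percentiles with weights 0.85/0.15, tolerance 1e-8 on the log-likelihood,
max 500 iterations, monotone log-likelihood asserted every iteration, a
variance floor against component collapse, components ordered by mean,
and a `collapsed` flag when the means end within one pooled standard
deviation. A cross-check test compares against scikit-learn's
`GaussianMixture` with five initializations; notably sklearn's default
single k-means initialization finds a worse local optimum on the
realistic (weight-0.15 shoulder) mixture, which is exactly why the
percentile initialization is built in.

## Problem sizes and tolerances in the test suite

Stochastic checks run at sizes chosen to make their error bars decisive:
switching-rate recovery at 1000 lineages × 40 h with a 200-replicate CI
calibration study; Euler–Lotka recovery at 2000 interdivision times;
branching-vs-analytic comparisons at caps of 2000 with 5–12 replicate
runs judged in units of the replicate standard error (2–3 se as stated
per test); mixture recovery at n = 20000 (means within 5%, weights
within 0.03). All randomness is seeded; the suite is deterministic.

## Known limitations

* No tree-bias correction for mother-machine sampling beyond the stated
  exclusion argument; for strongly asymmetric or correlated division-time
  structures the Euler–Lotka estimate would need reweighting.
* β is never *estimated* — only supported generatively; reversion in data
  is ignored after the first crossing.
* Frame-quantized crossings understate α slightly (documented above);
  sub-frame interpolation is deliberately out of scope.
* The EM fit assumes exactly two components; model selection between one
  and two populations is reported only via the `collapsed` flag, not a
  likelihood-ratio test.
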