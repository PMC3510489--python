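# Methods

This note records the models implemented in `helimodal`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one defensible option
existed.

## Model selection: uninormal vs binormal

Each univariate ensemble is fitted with a single Gaussian (closed-form MLE;
the variance uses divisor *n*, consistent with maximum likelihood rather
than the unbiased estimator) and with a two-component mixture. Models are
compared by BIC = −2 ln L + k ln n with k = 2 for the Gaussian (μ, σ) and
k = 5 for the mixture (μ₁, σ₁, μ₂, σ₂, p). Mixtures with three or more
components are deliberately not fitted: sparse experimental ensembles
over-fit quickly, and the downstream elastic machinery is two-state.

The BIC difference is mapped to an approximate Bayes factor,
F = exp((BIC₁ − BIC₂)/2), and to p(M2|data) = F/(1+F) under equal prior
odds. This is the unit-information-prior approximation to the marginal
likelihood ratio; no exact marginal likelihoods are computed. The posterior
is evaluated as a logistic in log space, so arbitrarily large BIC gaps
saturate at 0 or 1 without overflow. Evidence labels use strict
inequalities — M2 above 0.95, M1 below 0.05, IE otherwise — so the
boundary values themselves fall in IE. No multiple-testing correction is
applied across grid cells: each (step, parameter, origin) cell is an
independent classification against fixed thresholds, and the report states
this.

### EM details

The mixture likelihood is maximized by expectation–maximization with
deterministic, seeded restarts:

- restart 0 splits the sample at the median and uses half-sample moments;
- one additional start places both components on the pooled mean and SD —
  this is exactly the nested single-Gaussian solution, which guarantees the
  fitted mixture log-likelihood never falls below the Gaussian fit's;
- restarts 1..R (default R = 4) perturb the two starting means with seeded
  Gaussian noise of one sample SD.

Responsibilities are computed as a logistic of the log-density difference
(numerically safe for extreme points). Component collapse is prevented by a
σ floor of 10⁻³ × sample SD and clamping p to [10⁻³, 1−10⁻³]. Iteration
stops when the log-likelihood improves by less than 10⁻⁸ or after 500
iterations; the best restart wins and components are reported in
ascending-mean order, which removes label-switching ambiguity everywhere
downstream (state 1 is always the low-value state). An optional fit window
restricts the sample to a closed interval before fitting, for parameters
whose far tails mix in unrelated structure; no truncation is applied by
default.

## Modality: the generalized de Helguero criterion

Whether a binormal density actually has two peaks is decided in closed
form. With variance ratio r = max(σ₁², σ₂²)/min(σ₁², σ₂²) (defined ≥ 1 so
that a single algebraic branch suffices; the test suite enforces symmetry
under argument swap) the separation factor is

    S(r) = sqrt(−2 + 3r + 3r² − 2r³ + 2(1 − r + r²)^{3/2}) / (sqrt(r)(1 + sqrt(r)))

and the mixture is unimodal for **every** proportion p iff
|μ₂ − μ₁| ≤ S(r)(σ₁ + σ₂). S(1) = 1 recovers the classical equal-variance
2σ bound.

Two independent numerical oracles validate the closed form:

1. `count_modes_numeric` evaluates the density on a 4096-point grid
   spanning ±6·max σ beyond the means, merges plateaus, and counts strict
   local maxima. It is exact for mode separations ≳ 0.05σ but can miss the
   razor-thin second mode that exists only just above the threshold.
2. `bimodal_proportion_interval` does exact root analysis of g′: every
   critical point lies strictly between the means, where g′(x) = 0
   rearranges to p/(1−p) = h(x) with h the ratio of the component slope
   magnitudes. h falls from +∞ at μ₁ to 0 at μ₂; it is monotone exactly
   when no proportion gives two modes, and when it has interior extrema
   (h_lo, h_hi) the mixture is bimodal precisely for p/(1−p) strictly
   inside that interval. This yields the full set of bimodal proportions,
   not just a count, and resolves near-threshold geometry that defeats any
   fixed grid.

A subtlety worth recording: the Helguero condition quantifies over all
proportions. Just above the threshold the bimodal proportion window can be
narrow and need not contain p = 0.5 (e.g. σ₂/σ₁ = 1.03 at 2% above the
bound is unimodal at p = 0.5 but bimodal near p ≈ 0.48). Agreement between
the label and the oracles is therefore tested as: B ⟺ the proportion
interval is non-empty; U ⟹ unimodal at every proportion.

The pipeline evaluates modality only for M2 cells; M1 cells are unimodal
by definition and IE cells receive no modality call. For M2/U cells the
mixture is collapsed to its weighted mean and SD (exact moment formulas),
under which a single harmonic description remains serviceable.

## Elastic models

`stiffness_from_covariance` estimates a harmonic well from a joint
ensemble: x₀ is the sample mean and K = kT × inverse sample covariance,
giving both diagonal and coupling force constants. The estimator demands
n > 10·d and raises a rank error naming the most collinear coordinate pair
when the correlation matrix's condition number exceeds 10¹² — inverting a
near-singular covariance would otherwise produce huge, meaningless
stiffnesses. Energies are kept in kT; the kcal/mol conversion (0.593 at
298 K) is applied only when reporting.

The two-state model holds two wells with independent stiffness matrices
plus an offset ΔG_ij, estimated by Boltzmann inversion of the fitted
mixture weights (−kT ln of the minor/major population ratio; the mixture
weights are the only internally available population estimate). Snapshots
are split between states by hard posterior responsibility on the splitting
coordinate, ties going to the low-mean state — the simplest deterministic
rule, and at 8σ mode separation it is indistinguishable from the Bayes
boundary.

The smooth surface is the lower branch of the 2×2 secular problem,
E = ½(E_i + E_j) − ½√((E_i − E_j)² + 4ε²). It equals min(E_i, E_j) − ε at
crossings, lies within ε below the hard minimum everywhere, and has
continuous first derivatives. ε defaults to 0.25 kT: small enough that
barrier shapes are preserved (the barrier-top depression is at most ε),
large enough that gradients stay well-scaled for optimization. The limit
ε → 0⁺ recovers the kinked two-branch minimum, which is retained as a
separate function for simple energy evaluations. With n bimodal
coordinates in one step the number of required state models is 2^(n−1);
the multi-state container enforces that count.

`unimodal_error_profile` tabulates the energy error made by forcing a
single harmonic fit onto a two-well landscape. Its sign conventions: the
difference column is E_bimodal − E_unimodal, positive where the unimodal
model underestimates the true energy — maximal at the unimodal minimum,
which for a genuinely bimodal parameter is actually a barrier top, and
positive again in the far tails because bimodality inflates the unimodal
σ and hence underestimates the tail stiffness kT/σ².

## Kinetics

Frames of a uniform-timestep series (relative tolerance 10⁻⁶) are assigned
to the mixture component with the larger posterior responsibility — hard,
frame-wise assignment with no hidden-Markov smoothing, mirroring direct
threshold reading of a twist trace. The recorded boundary is the crossing
point of the two weighted component densities between the means; a frame
exactly on it goes to state 1. Transitions are counted in both directions
and reported as transitions/ns = changes / (dt·(len−1)). Mean residence
times average completed dwells only; the first and last dwell are censored
by the observation window and excluded, which removes the length-bias of
truncated dwells. An optional minimum-dwell filter (in frames, default
off) merges fast recrossings into the surrounding dwell before counting,
since instrument-free hard assignment inflates counts when emissions
overlap.

`convergence_profile` recomputes occupancy and rate on ascending prefix
windows (a short window over-represents the initial state when switching
is slow relative to the window — the standard burn-in signature) and on
consecutive equal blocks, reporting the largest block-to-mean relative
rate deviation as a stationarity diagnostic.

## Synthetic generators

The generators produce data with exactly the structure the estimators
assume, so estimator recovery can be tested against known ground truth.

- `sample_binormal`: i.i.d. mixture draws, component chosen Bernoulli(p).
- `sample_telegraph`: a discrete-time two-state Markov chain with exact
  exponential per-step switch probabilities 1 − exp(−rate·dt), started
  from its stationary distribution, with state-conditional Gaussian
  emissions. The discretization matches the snapshot structure of MD
  output; a warning fires when dt·(k₁₂+k₂₁) > 0.2, where fast recrossings
  begin to alias. Ground-truth state sequences are always returned.
- `sample_harmonic`: multivariate Gaussian draws with covariance kT·K⁻¹
  for a given symmetric positive-definite stiffness K (Cholesky sampling).

Preset scenarios bundle plausible magnitudes: the CpG-twist-like preset
puts the minor mode at 25° (the literature-anchored low-twist value) with
the major mode at 35°, widths 3–4° and minor weight 0.25; the
ApG/CpC-slide-like preset puts the minor mode at −1.5 Å (likewise
anchored) against a major mode at 0 Å. All other preset numbers are
plausible-scale choices, not measurements. The telegraph preset uses
symmetric 2.75/ns rates at 1 ps sampling, giving sub-ns residence times of
the right order for fast twist switching.

What the generators do **not** emulate: force-field-specific sequence
effects, tetranucleotide context dependence, autocorrelation within a
state (emissions are white given the state), anharmonic tails, and
protein-induced distortions. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not force-field realism.

## Curation defaults

The outlier filter removes records farther than 3 SD from the ensemble
mean, with moments computed once on the input (a single pass — re-applying
the filter to its own output would iterate to a different, unintended
fixed point, so the one-pass contract is tested explicitly). It is applied
per parameter, univariately, matching the univariate statistical analysis
downstream, and by default only to the X-ray origins — experimental
anomalies are curation targets, while extreme MD frames are data; a
per-origin switch exposes the choice. Subsampling is uniform without
replacement, seeded, order-preserving (so subsampled time series keep
increasing timestamps), and clamps to the full ensemble when m ≥ n. The
subsample size is configuration, not a constant; a two-seed stability
comparison is available through the config rather than hard-wired.

Angles are plain reals in degrees throughout: B-DNA parameter
fluctuations span far less than a full turn, so linear moments are valid
and circular statistics would add nothing.

## Problem sizes used in the tests

The test and benchmark suites size their simulations to make each check
statistically decisive: n = 10⁴–10⁵ for distributional recovery (SE-based
4σ bands), 10⁵ joint samples for the 6×6 stiffness round-trip (5%
elementwise), 10³ ns at 1 ps for kinetics (≈5×10³ dwells, supporting a 5%
residence-time check), a 50×50 random sweep for the modality oracle
agreement, and a 2500-cell lattice for the label/oracle consistency
benchmark. The tiny-n EM oracle check (n = 12) uses an equal-σ lattice
search, which is an independent optimizer rather than a reimplementation
of EM; EM may only match or beat it.

## Known limitations

- The Bayes posterior inherits the BIC approximation; for very small n the
  unit-information prior can be a poor stand-in for a considered prior.
- Hard state assignment underestimates residence times when emission
  distributions overlap appreciably; the minimum-dwell filter mitigates
  but does not remove this bias.
- The Helguero criterion addresses the fitted binormal model, not the raw
  sample; it says nothing about modality of data the mixture fits badly.
- ΔG from mixture weights assumes the two fitted components are the two
  physical states; if the mixture is soaking up skewness rather than
  genuine two-state structure, the inferred ΔG is not a free energy.
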