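# Methods

## The design

A multiple baseline factorial design (MBFD) extends the multiple baseline
design of single-case research to two interventions. Sequences are rows of
a condition grid over periods; each begins with at least one control
period, switches to one single intervention (A or B), and ends on the
sequentially delivered combination AB, never reverting. The standard
layout has six sequences (three A-first, three B-first) over five periods,
with the single-intervention phase starting at periods 2, 3 and 4 and
lasting exactly one period. The published figure for this design does not
pin the start periods numerically; the 2/3/4 stagger is the minimal layout
consistent with five periods, a one-period single-intervention phase, and
every sequence reaching the combination — combined-phase durations are
then 3, 2 and 1 periods. `build_extended_design` generalizes the stagger
gap, single-phase length and exit policy (`common_exit` versus a fixed
combined-phase duration with staggered exits).

Randomization is individual and balanced: group sizes differ by at most
one, and when the number of participants is not a multiple of the number
of sequences, the sequences receiving an extra participant are chosen
uniformly at random (seeded).

## Data-generating model

Outcomes follow the multi-arm parameterization

Y_ij = u + β_T·j + β_A·Z_A + β_B·Z_B + β_C·Z_C + α_i + ε_ij,

with α_i ~ N(0, τ²) drawn once per participant and ε_ij ~ N(0, σ²) i.i.d.,
giving a compound-symmetric marginal covariance σ²I + τ²J and intraclass
correlation τ²/(τ² + σ²). Defaults mirror the study conditions: u = 0,
β_T = 1, σ = 1, ICC ∈ {0.05, 0.10, 0.30} (τ ≈ 0.23, 0.33, 0.65), effect
vectors (β_A, β_B, β_C) of (0,0,0), (0.8,0.8,1.6) and (0.8,0.8,2.0) —
null, additive, and interaction (β_I = 0.4). Time enters as the raw period
index j = 1…J; with u = 0 and no centering only the intercept is affected.
Interaction scenarios are expressed through β_C with β_I derived
(β_I = β_C − β_A − β_B), so one generator serves all three analysis
models. The generator produces no missing data, dropout, random slopes or
serial correlation; conclusions from passing tests therefore speak to the
correctly specified random-intercept world, not to robustness against
richer real-data structure (the motivation for preferring GEE in
practice).

Randomness: each Monte Carlo replicate owns a `SeedSequence` substream
spawned from the master seed, so any replicate is reproducible in
isolation and parallel execution equals serial execution exactly.

## REML estimation

The mixed model is estimated by profiling the restricted likelihood over
the variance ratio λ = τ²/σ²: for fixed λ, the GLS coefficients and σ²
are closed-form via the Sherman–Morrison identity
(I + λ11')⁻¹ = I − λ/(1+nλ)·11', and the per-cluster sufficient
statistics (cross-products plus cluster sums) make each criterion
evaluation O(p²). A bounded 1-D search over log λ (absolute tolerance
1e-10) is compared against the λ = 0 boundary, so negative
variance-component estimates are truncated at zero as in standard mixed
software. On a fixed N = 30 dataset the coefficients, standard errors and
restricted log-likelihood agree with an independent dense-matrix
restricted-likelihood maximizer to below 1e-6 (test-suite oracle).

Satterthwaite degrees of freedom for a contrast c use
df = 2(c'Vc)² / Var(c'Vc), with Var(c'Vc) from the delta method: the
gradient of c'V(θ)c in θ = (τ², σ²) by central differences (relative step
1e-5) against the inverse observed REML information (central-difference
Hessian, relative step 1e-4). Because the restricted score vanishes at an
interior optimum, this is invariant to smooth reparameterizations of θ.
df is clamped to [1, NJ − p]. At the τ² = 0 boundary only σ² remains free
and the formula collapses to the residual df NJ − p, which is returned
directly; a singular information matrix falls back to df = N − p (the GEE
convention) with a warning, and the simulation engine counts fallback
replicates.

## GEE estimation

Identity-link Gaussian GEE with exchangeable working correlation,
initialized at OLS: coefficient steps alternate with moment updates of the
scale φ (denominator Σnᵢ − p) and working correlation α (all
within-cluster residual pairs, denominator #pairs − p), until the max
coefficient change is below 1e-8 (cap 50 iterations; non-convergence is
flagged, and α is clipped to its admissible range (−1/(J−1), 1) with a
warning). These conventions match common GEE software — the test suite
confirms agreement of coefficients, α and robust standard errors with an
independent implementation to ~1e-6 — and are fixed here so results are
reproducible to the Monte Carlo level.

Variances: model-based φ(X'V⁻¹X)⁻¹; robust Liang–Zeger sandwich; and the
Mancl–DeRouen correction, which pre-multiplies each cluster's residual
vector by (I − Hᵢ)⁻¹ with Hᵢ = Xᵢ(X'V⁻¹X)⁻¹Xᵢ'Vᵢ⁻¹ before forming the
meat — implemented from the original formula, not a scalar multiplier.
MD standard errors dominate the uncorrected robust ones in small samples
and converge to them as N grows (both asserted empirically).

## Hypothesis testing conventions

Per-coefficient two-sided Wald tests at Bonferroni-adjusted levels:
0.05/2 (additive model), 0.05/3 (interaction and multi-arm models). The
references are:

* LMM — t with Satterthwaite df;
* GEE (uncorrected robust variance) — the large-sample normal reference,
  i.e. the default Wald test reported by standard GEE software;
* GEE-MD — t with df = N − p.

The pairing for the uncorrected-GEE case reproduces the published
small-sample inflation (e.g. type I error ≈ 0.047 at N = 30 against a
nominal 0.025); pairing it with the t(N − p) reference instead yields
≈ 0.037 and is available through `gee_test`'s `df` argument, which is also
its default for direct use.

## Monte Carlo engine

Each replicate simulates one trial and analyzes the same dataset with
every requested estimator (common random numbers), so estimator contrasts
are paired. Reported measures: mean estimate and bias
(mean of β̂ − β), per-coefficient rejection rate, the disjunctive
("at least one") rejection rate, and Monte Carlo standard errors
(√(r(1−r)/n_sim) for rates). The published grids report per-coefficient
columns, so table reproduction uses per-coefficient rates; the
disjunctive rate — the study's verbal definition of power — is reported
alongside. Non-converged fits exclude the replicate from that estimator's
denominator and are counted in metadata, with a hard warning above 5%.

The replication count of the original study is not stated; the package
default is 5000 (binomial SE ≤ 0.007), which the acceptance script uses.
The test suite runs its end-to-end scenario checks at 2000 replicates with
tolerances sized for the combined Monte Carlo error of both studies
(about ±0.012–0.015 on type-I-error rates, ±0.03–0.045 on powers and
means), and smaller property checks at a few hundred replicates.

## Known limitations

* Carryover/sequence effects are absent from the generator and the models;
  the multi-arm β_C is interpreted as an order-averaged effect.
* Only the MD small-sample correction is implemented (no Kenward–Roger or
  Kauermann–Carroll), and only exchangeable working correlation.
* Continuous Gaussian outcomes only; no missing data.
* The Satterthwaite variant of any particular mixed-model package is not
  targeted; agreement is asserted against this package's own
  Richardson-extrapolated numerical oracle.
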