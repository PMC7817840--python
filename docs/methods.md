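# Methods

This note documents the models, estimators, and numerical choices behind
`infoscale`, and what its synthetic-data experiments do and do not show.

## Linear Fisher information for coarse discriminations

For a discrimination between stimulus angles θ₁ and θ₂ (δθ = θ₂ − θ₁, in
radians), the linearly decodable information in a population response r is

    I = f′ᵀ Σ⁻¹ f′,      f′ = (f(θ₂) − f(θ₁)) / δθ,

where f(θ) is the vector of mean responses and Σ the noise covariance.  This
equals (d′/δθ)² and reduces to classical Fisher information as δθ → 0.  It
depends only on the first two moments of the response distribution, is
invariant under invertible linear recoding of the population, and is additive
across uncorrelated subpopulations.  All information values are rad⁻²; angles
cross the API in degrees and are converted internally.

### Estimation from finite data

With T trials per condition, f̂′ uses the condition means and Σ̂ is the
**average** of the two per-condition sample covariances (2T − 2 pooled
degrees of freedom).  The plug-in estimate is biased upward; the corrected
estimator

    Î_bc = Î_naive (2T − N − 3)/(2T − 2) − 2N/(T δθ²)

is exactly unbiased under the Gaussian sampling model.  This follows from the
sampling distribution of the plug-in statistic: with m = Tδθ²/2, m·Î_naive is
a Hotelling T², i.e. a scaled noncentral F(N, 2T − N − 1; λ = mI).  The same
distribution yields the closed-form estimator variance

    Var(Î_bc) = 2[(N + mI)² + (N + 2mI)(2T − N − 3)] / (m² (2T − N − 5)),

evaluated at the plug-in λ̂ = m·max(Î_bc, 0).  This is the default variance
backend; a nonparametric bootstrap over trials (500 resamples by default) is
available as an alternative.  Both are validated against the empirical
variance across replicate synthetic datasets (calibration within 15%).
Requirements: N ≤ 2T − 4 for the correction, N ≤ 2T − 6 for the variance.
Solves use Cholesky factorizations, never explicit inverses; a condition
number above 10¹⁰ triggers a warning.

Information converts to ideal-observer units via
P(correct) = Φ(Δθ √(I/2)) and the 80%-correct threshold
Δθ = Φ⁻¹(0.8) √(2/I) (reported in degrees).

## Scaling curves from independent increments

Information estimates at nested population sizes share data and are strongly
correlated, but the increments ΔÎ_N = Î_N − Î_{N−1} are uncorrelated across
N.  Curves are therefore summarized by across-ordering increment moments
(μ_N, σ²_N), obtained by bootstrapping random neuron orderings (default 10⁴;
tests and presets scale this down to 10²–10³).  Orderings are permutations
drawn without replacement within an ordering and with replacement across
orderings; the small negative across-ordering correlations this induces are
ignored, which only overestimates uncertainty.  Within one ordering, all
prefix informations come from a single Cholesky factorization of the permuted
covariance (the leading k×k block of the factor is the factor of the leading
principal submatrix), so a full curve costs one O(N³/3) factorization.

Per-ordering increments telescope exactly (to 10⁻¹²) to that ordering's
full-population estimate.  Cumulative moments are running sums of increment
moments.

Greedy ("most informative first") orderings rank candidates by naive
information gain — an N-dependent bias correction would distort the ranking —
with ties broken toward the lowest neuron index; fixed-ordering curves apply
no bias correction and obtain uncertainty by parametric bootstrap of Gaussian
increments (re-summed to curves), following the same no-correction convention.

Two hypothesis tests operate on Gaussian summaries of information estimates:
a difference test p = pr(A − B < 0), and a K-sample equality test comparing
TS_H1 = Σ(I_k − μ_k)² against TS_H0 = Σ(I_k − μ̄)² over independent bootstrap
sample sets (10⁵ each).  The raw tail pr(TS_H1 − TS_H0 < 0) approaches 1, not
0, under strong inequality, so the reported p-value is the two-sided tail
2·min(p, 1−p).  Degenerate zero-variance comparisons return 0.5 by
convention.

## Information-scaling models and inference

Three nested models describe information growth with population size:

| family | I_N | parameters |
|---|---|---|
| unlim  | cN | c |
| lim    | 1/(1/(cN) + 1/I∞) | c, I∞ |
| limexp | as lim with I₀,N = c(N + τ(e^{−N/τ} − 1)) | c, I∞, τ |

c is the non-limiting information per neuron (rad⁻² per neuron), I∞ the
asymptotic information (rad⁻²), τ the extent of initial supralinearity
(neurons).  unlim = lim(I∞ = ∞); limexp → lim as τ → 0 (both exact in code).

The likelihood treats measured increment means as independent Gaussians
around model increments with the measured increment variances (floored at
10⁻¹² × max(1, max σ²) for numerical safety).  Priors are Student-t (df = 1,
i.e. Cauchy) densities truncated to [0, ∞) and renormalized, centered on
empirical scales: c on ⟨μ_n⟩ with scale 10(⟨μ_n⟩ + 0.5); I∞ on ⟨Î_N⟩ with
scale 10·max(1, ⟨Î_N⟩); τ on 0 with scale N.  ("Variance" in the St₁
notation is read as squared scale — a df-1 t has no variance.)

Sampling is univariate slice sampling cycled in fixed coordinate order
(c, I∞, τ), initialized at the maximum-likelihood fit (L-BFGS-B, multiple
starts).  Interval search uses Neal's doubling procedure (cap 100 doublings)
with the doubling-consistency back-test during shrinkage: doubling reaches
the heavy upper tail of I∞ — essentially unbounded when the data show no
saturation — in logarithmically many density evaluations, where fixed-width
stepping out would need thousands.  Initial widths: (⟨μ_n⟩ + 0.5)/2 for c,
max(1, ⟨Î_N⟩)/5 for I∞, 10 for τ.  Four chains; the full preset runs 10⁵
iterations per chain after 100 burn-in, thinned by 10 (10⁴ kept per chain);
the test preset uses 10⁴ iterations.  Pooled fits across discriminations
share a single parameter vector (product of likelihoods); prior scales are
averaged across the pooled curves.

Convergence is monitored with the Gelman–Rubin PSRF, computed per parameter
from the kept samples and clamped at 1.0 from below (so exactly duplicated
chains report 1.0); values above 1.1 warn.  Model comparison uses WAIC on
the deviance scale, −2(lppd − p_WAIC) with p_WAIC = Σᵢ var(log pᵢ); smaller
is better, negative values are expected when pointwise densities exceed one,
and values are comparable only across fits to the same curve(s).

Derived quantities are per-sample transforms marginalized over the pooled
chains: N_f = (f/(1−f))·I∞/c (N₉₅ = 19·I∞/c), summarized by median, 50% and
90% credible intervals.  An independent cross-check regresses 1/Î_N on 1/N
by weighted least squares (delta-method moments ⟨1/I⟩ ≈ 1/⟨I⟩,
var(1/I) ≈ var(I)/⟨I⟩⁴; weights 1/var): under the lim model the slope is 1/c
and the intercept 1/I∞, with a one-sided positivity test on the intercept.
Sizes with nonpositive ⟨Î_N⟩ (possible at small N after bias correction) are
dropped; if fewer than three usable points remain the fit is skipped.

## Subspace decomposition

Trials are split into disjoint random halves per condition (10 splits; an
odd trial drops one at random).  The train half defines the principal noise
dimensions Q (eigenvectors of the pooled covariance, descending); the test
half provides independent moments.  Per dimension: noise variance
q_nᵀΣ_test q_n, signal alignment cos²(α_n) = (q_nᵀf′)²/(f′ᵀf′), and
cumulative information I_n from the projected test moments (prefix-Cholesky,
as above).  Completeness holds by construction: Σcos² = 1 and I_N equals the
full test-moment information.  The fractions of dimensions needed to reach a
level (default 90%) of total variance / alignment / information threshold
the across-split mean curves; per-split fractions are also reported.  No
bias correction is applied inside these plug-in formulas.

## Tuning classification

Three nested models are fit per neuron to all trials by multi-start
trust-region least squares (8 preferred-angle starts spanning the period;
best RSS kept, ties to the first start): a two-lobe von Mises (direction,
5 parameters, shared concentration with opposite-sign cosine arguments), a
single doubled-angle von Mises (orientation, 4), and a constant (analytic
grand mean).  Nesting (RSS_constant ≥ RSS_orientation ≥ RSS_direction) is
checked to 10⁻⁶ and violations flag the fit.  Classification cascades nested
F-tests at Bonferroni-corrected level α/n_tests (the denominator is
config-exposed; the pipeline uses 2 × number of neurons): direction if f₁
significantly beats f₂, else orientation if f₂ beats f₃, else untuned.
RSS improvements below a round-off floor (10⁻⁹ × the data's sum of squares)
count as no improvement, so perfectly constant data never classify as tuned.
The coefficient of variation is computed per condition and averaged over
conditions with mean above 10⁻⁶ (a preferred-condition-only mode exists).

## Synthetic populations

The generator draws heterogeneous tuning (18% direction / 48% orientation /
34% untuned by default, matching the recorded mixture), log-normal
baselines, amplitudes, and concentrations, and builds the noise covariance

    Σ = Σ₀ + f′f′ᵀ / I∞,

whose rank-one differential-correlation term caps the decodable information
at I∞ (exactly; the Sherman–Morrison identity 1/I = 1/I₀ + 1/I∞ gives the
closed-form oracle on any neuron subset).  Σ₀ options: limited-range
correlations decaying with preferred-angle distance (default, ρ_max = 0.25,
length 40°), diagonal heterogeneous variances, or low-rank-plus-diagonal.
Indefinite constructions are repaired by eigenvalue flooring at 10⁻⁶ × the
largest eigenvalue.  Per-neuron noise standard deviation equals the CV
(default 1.0, the value typical of deconvolved calcium responses) times the
mean response; default amplitudes put per-neuron information at
O(10⁻²–10⁻¹) rad⁻².  Trials are multivariate Gaussian — the estimator only
uses first and second moments — with optional rectification at zero (off by
default, since rectification perturbs the moments).  Multi-condition
sessions draw each condition with the differential term aligned to the local
analytic tuning derivative, so every extracted discrimination carries
approximately limited information; pair datasets use the exact
finite-difference f′ of the pair, for which the closed-form oracle is exact.
A single master seed drives all sub-streams deterministically.

What the generator does **not** emulate: non-Gaussian (skewed, zero-
inflated) deconvolved activity, indicator saturation, eye-movement or
arousal nonstationarities, and trial-to-trial gain fluctuations.  Passing
tests therefore certify the estimation and inference machinery under the
moment assumptions the estimators are built on — not robustness of the
scientific conclusions to real calcium-imaging artifacts.

## Validation experiment design

Problem sizes are chosen so the full suite runs on one CPU in minutes.
Parameter recovery uses 300-neuron diagonal-Σ₀ populations with I∞ = 15
rad⁻² and T = 310 (saturation clearly visible: I₃₀₀/I∞ ≈ 0.6 for every
seed, comfortably above the 0.5 the recovery guarantee conditions on), 10³
orderings, and the test MCMC preset; with diagonal Σ₀ the lim scaling law is
the exact generative model, making this a parameter-recovery check rather
than a robustness check.  Model selection uses 150-neuron populations
(I∞ = 10, T = 300 = 2N) and their trial-shuffled counterparts at 4 × 10³
MCMC iterations.  Estimator calibration uses N = 50, T = 200 over 2000
replicates; subspace experiments use 80 neurons, T = 400, default
limited-range correlations.

## Known limitations

- The analytic estimator variance assumes a shared Gaussian noise covariance
  across the two conditions; strong condition-dependence of Σ shifts its
  calibration (the bootstrap backend does not share this assumption).
- I∞ posteriors are honest but extremely wide when the recorded population
  shows little saturation; the package reports the credible intervals rather
  than warning thresholds.
- The greedy ordering is a heuristic: it maximizes one-step gains and holds
  no global optimality guarantee beyond the diagonal-covariance case.
- Session-level synthetic data limit information per discrimination only
  approximately (local-derivative differential correlations); exact
  ground-truth checks use pair datasets.
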