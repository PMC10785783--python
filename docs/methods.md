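# Methods

## Equilibrium model

All equilibrium constants are association (protonation) constants and
are carried as base-10 logarithms throughout; natural logarithms appear
nowhere in the public interface. For an n-protic ligand L the stepwise
macroconstants K₁…Kₙ are defined on macrospecies HᵢL grouped by bound
proton count, and the cumulative constants are βᵢ = ∏ⱼ≤ᵢ Kⱼ, i.e.
log βᵢ = Σⱼ≤ᵢ log Kⱼ.

For a mirror-symmetric diprotic compound the two sites are chemically
identical, so the four site-specific microconstants collapse to two
distinct values tied exactly to the macroconstants by statistical
factors of 2:

    log k_first  = log K₁ − log 2        (other site unprotonated)
    log k_second = log K₂ + log 2        (other site protonated)

These shifts are exact constants, so standard errors pass through
unchanged (`se_first = se(log K₁)` etc.). The pair-interactivity
parameter log ε = log k_first − log k_second = log K₁ − log K₂ − 2 log 2
quantifies the anticooperative coupling of the two sites. Cooperative
inputs (log ε < 0) are accepted with a `CooperativityWarning` rather
than rejected: cooperativity is rare in small molecules but not
impossible, and the algebra is unaffected.

A model compound (methyl ester, amide, O-methyl ether, S-methyl
thioether) mimics the microspecies whose substituted site is in its
protonated/blocked state; its single protonation constant is therefore
an estimate of log k_second of the parent, and the correction factor

    corr = log K_model − log k_second

is the signed bias of that deductive estimate. Derived-quantity errors
use first-order Gaussian propagation, sqrt(Σ (∂f/∂xᵢ · seᵢ)²); for the
differences involved here all derivatives are ±1.

The package deliberately does not implement a general 2^N microspecies
lattice: only the symmetric diprotic case (plus monoprotic models) has
assumption-free microconstants, which is the point of the analysis.

## Titration forward models and fitting

**NMR-pH.** The exchange-averaged chemical shift of a nucleus is the
population-weighted mean of the limiting shifts of the macrospecies,
δ(pH) = (δ_L + Σᵢ δ_HᵢL βᵢ[H⁺]ⁱ)/(1 + Σᵢ βᵢ[H⁺]ⁱ) with [H⁺] = 10^(−pH)
(activity corrections are out of scope; the reference experiments run at
fixed 0.15 mol/L ionic strength with calibrated pH). Species weights are
evaluated in log10 space with max-subtraction, so extreme pH cannot
overflow, and the prediction is always a convex combination of the
limiting shifts.

**Potentiometric difference titration.** Subtracting a blank strong
acid–strong base titration from the sample titration leaves the KOH
volume consumed by deprotonating the titrand. We parametrize this as
ΔV(pH) = A·n̄(pH) + D, where n̄(pH) = Σ i·βᵢ[H⁺]ⁱ/(1+Σ βᵢ[H⁺]ⁱ) is the
Bjerrum average-protonation function, A is the KOH volume per unit of
deprotonation fixed by mass balance (A = c_titrand·V₀/c_KOH; 0.2 mL for
10 mmol/L titrand in 2 mL against 0.1 mol/L KOH) and D is an
experimental correction offset. An equivalent parametrization replaces
A·n̄ by A·(n − n̄), which only relabels A·n into D; the choice used here
is recorded by the parameter names in the results.

**Fitting.** Both models are fitted by Levenberg–Marquardt damped least
squares (lmfit/MINPACK) with unit weights, tight tolerances (xtol = ftol
= 1e-14, ≤ 20000 evaluations), parameters on the stepwise log K scale
for conditioning, and standard errors from the covariance at the
optimum. Cumulative-constant errors use the full covariance of the
stepwise estimates. Multi-nucleus NMR data are fitted jointly: one
shared set of constants, per-nucleus limiting shifts — one constant set
per compound. Starting values need no user input: plateau levels come
from the mean signal in the extreme-pH deciles, log Kᵢ from the pH at
which the normalized titration progress crosses (i − ½)/n, A from the
observed range, D from the basic-limit signal. Fits with fewer points
than parameters raise; fewer than 3× parameters warns. For replicated
potentiometric titrations each replicate is fitted separately and the
reported constants are replicate means with SD (ddof = 1) across
replicates as the standard error — the convention for repeated
titrations; single titrations report regression SEs.

## Synthetic data

The generator emulates the two experimental designs the analysis
consumes: ~40-point pH grids spanning the transitions (log K ± 2 where
feasible), homoscedastic additive Gaussian noise on the signal, and, for
potentiometry, independent replicate titrations spawned from a single
seed (`numpy` Generator.spawn). Defaults are a malonic-acid-like truth
(log K = 5.22, 2.70), noise of 0.002 ppm (NMR) and 0.002 mL
(potentiometric) — chosen to reproduce the order of magnitude of the
reference tables' standard errors (~0.01 log units) — and the reference
concentrations (5–10 mmol/L titrand, 0.1 mol/L titrants, 2 mL initial
volume, 298.15 K, 0.15 mol/L ionic strength). Simulated-then-fitted
constants at these settings have empirical replicate SD within ~5% of
the mean reported SE.

What the generator does *not* emulate: NMR lineshapes and peak overlap,
in-situ indicator pH calculation, electrode drift or junction
potentials, D₂O isotope effects, carbonate contamination, and any
heteroscedasticity of real detectors. Passing recovery tests therefore
demonstrates the estimator is correct and calibrated under the stated
noise model, not that real titrations are free of systematic error — the
method-comparison analysis exists precisely because the two real
methods disagree systematically at the extremes of the pH scale.

The registry generator places synthetic parents at uniformly drawn
interactivities and second microconstants, and positions each model
compound so the correction factor follows corr = b0 + b1·ln ε plus
additive Gaussian noise (default scatter 0.1 log units, comparable to
the observed O-methyl residuals), giving downstream regression tests an
exact ground truth.

## Bias statistics

**Error decomposition.** Per model type, MSE = (1/n)Σcᵢ², bias² =
((1/n)Σcᵢ)², Var = (1/(n−1))Σ(cᵢ − c̄)²; MSE = bias² + (n−1)/n·Var holds
exactly. This denominator pairing (n for MSE, n−1 for variance) is the
only one consistent with the reference decompositions and is asserted by
a property test. NMR and potentiometric determinations of the same
compound are pooled as separate records.

**Correction-vs-interactivity regression.** The correction factor is
itself the base-10 logarithm of the multiplicative bias factor
k_model/k_second, so the fitted law corr = b0 + b1·ln ε states that the
bias factor is a power law in ε. The model is estimated by weighted
linear least squares with weights proportional to log ε (observation
variance inversely proportional to log ε), which keeps the estimator
linear on the correction scale and hence admits the negative observed
corrections that a log-transformed response could not. A direct
nonlinear fit of corr = exp(b0 + b1·log ε) was evaluated and rejected:
for a group whose corrections cluster around zero with a few large
positive values at high ε (the O-methyl pattern), its global optimum is
a degenerate spike that interpolates the high-ε points and calls
everything else zero, under every weighting — a statistically
meaningless estimate. Records with log ε ≤ 0 are excluded from the
regression (their weight is undefined) with a warning; S-methyl records
are summarized but excluded from regression by default because three
points cannot support a two-parameter weighted fit worth reporting. The
95% prediction band uses the t distribution with n − 2 df and the
weighted prediction variance s²(x₀ᵀ(XᵀWX)⁻¹x₀ + 1/w(x₀)).

**Method comparison.** Bland–Altman analysis of compounds determined by
both methods: difference (NMR − potentiometry) against the pair mean,
bias, 1.96·SD limits of agreement, and the OLS difference-vs-mean trend
slope. The method effect is additionally tested with a linear mixed
model, log K ~ method with a random intercept per parent compound
(statsmodels MixedLM, REML), reporting a Wald F with containment
denominator df = n_obs − n_groups − 1; in the balanced one-constant
case this reduces exactly to the paired-t test, and simulation shows the
test holds its nominal 5% size (observed 3% over 200 null replicates).
Both stepwise constants of a compound enter as observations sharing that
compound's random intercept, which makes the test conservative when the
K₁–K₂ spread is large relative to the method difference; the df
convention is part of the reported result because mixed-model F tests
are convention-dependent.

## Problem sizes and determinism

Statistical calibration tests use 200 seeded replicates for titration
recovery and method-test size, and 50 for regression recovery; every
stochastic test and the CLI derive all randomness from explicit integer
seeds, so reruns are bit-reproducible. The packaged reference table
(19 parent determinations, 26 model records) drives all
reference-reproduction tests and the acceptance script.

## Known limitations

* Only symmetric diprotic parents and monoprotic models; no general
  microspeciation lattices or cluster-expansion constraints.
* [H⁺] = 10^(−pH) operationally; no activity or electrode-calibration
  modeling.
* The exact estimator behind the published regression coefficients for
  the reference data is not fully specified upstream; this package's
  weighted linear estimator reproduces their slopes to ~2% and their
  group ordering, but intercepts differ because a random-intercept term
  is not included in the package's fixed-effects fit.
* The method-effect F statistic depends on the denominator-df
  convention; only its qualitative conclusion (no significant method
  effect) is asserted.
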