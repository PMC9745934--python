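# Methods

This note documents the statistical models, the numerical choices behind
them, and the simulation design, in enough detail to reproduce or audit any
number the package computes.

## Data model and zero-event studies

A meta-analysis is K independent two-arm studies; study k contributes the
2×2 table (y_kT, n_kT, y_kC, n_kC).  A *single-zero* study has zero events
in exactly one arm, a *double-zero* study in both.  Policies differ by
estimator, and the differences are substantive, not cosmetic:

- Beta-binomial and mixed-logistic models use the full likelihood and need
  no continuity correction; double-zero studies stay in the likelihood.
- Inverse-variance methods (DSL, HKSJ) use per-study log effects with the
  Woolf/delta-method variances.  Any study with a zero *cell* gets 0.5
  added to all four cells; double-zero studies are excluded.  The
  correction is keyed on zero cells rather than zero event counts because
  a study with y = n in an arm leaves the variance undefined in exactly
  the same way as y = 0.
- Mantel–Haenszel drops studies with any zero cell (a configuration switch
  `drop_zero_cell_studies=False` restores the conventional behaviour of
  keeping them); Peto includes single-zero studies by construction and
  drops only zero-variance studies; the collapsed table corrects the
  pooled table by +0.5 per cell only when it has a zero cell.

## Beta-binomial models

Arm-level counts are beta-binomial: y ~ BetaBin(n; α, β) with mean
μ = α/(α+β) and intraclass correlation ρ = 1/(α+β+1).  The log pmf is
evaluated as log C(n,y) + ln B(y+α, n−y+β) − ln B(α, β), which equals the
nine-log-gamma expansion identically (tested to 1e-10).

**BBST** assumes one ρ for both arm groups (equivalently α_C+β_C =
α_T+β_T) and parameterizes (b0, b_T, logit ρ) with μ_C = g⁻¹(b0),
μ_T = g⁻¹(b0 + b_T); g is logit for the OR and log for the RR.  Under the
log link, parameter points implying μ ≥ 1 receive a large finite penalty
so the optimizer can retreat.  Estimation is quasi-Newton (L-BFGS-B on the
transformed parameters) followed by a bounded Nelder–Mead polish; starting
values are pooled event-rate moments with ρ started at 0.1.  The SE of
b_T is read from the inverse observed information in this parameterization
(no delta method needed); the Hessian is a central finite difference with
relative step 1e-3, chosen because the log-gamma evaluations carry ~1e-9
cancellation noise when α+β is large and smaller steps amplify it.

**BBFR** adds a study-level random treatment effect γ_k ~ N(0, σ²) on the
link scale.  The treatment-arm likelihood is marginalised by adaptive
Gauss–Hermite quadrature centred at the per-study mode (one node — the
Laplace approximation — is the working default; the node count is
configurable).  Because α+β is constant in γ under the common-ρ
constraint, the derivatives of the integrand reduce to digamma/trigamma
differences, and the mode search is an exact Newton iteration; this makes
the marginal likelihood smooth to machine precision, which the
finite-difference information matrix requires.

**BBCB1** shares β across arms: y_ki ~ BetaBin(n_ki; α_i, β).  It is
parameterized as (x1, x2, x3) = (log α_C/β, log α_T/β, log β), in which
the treatment effect is exactly b_T = x2 − x1 (because logit μ_i =
log α_i/β) and the no-overdispersion degeneracy is confined to x3 → ∞.
The SE is the delta-method variance of the contrast x2 − x1.  OR only.

**BBCB2** conditions on each study's event total m_k: y_kT | m_k ~
BetaBin(m_k; n_kT e^{b0+b_T}, n_kC e^{b0}), the two-arm reduction of the
fixed-effects negative-binomial panel likelihood with arm sizes as
exposure offsets.  b0 enters only through the dispersion scale, so
b0 → +∞ is this model's no-overdispersion boundary.  OR only.

Confidence intervals for all four use the t distribution with df = 2K−2
(default; the better performer) or K−1.

### Boundary handling and the convergence rule

A fit is *converged* when the optimizer succeeds, the observed information
over the free parameters is positive definite, and the resulting SE is
finite and positive.  Variance-type parameters sitting on their box bound
(ρ → 0, σ² → 0, τ² → 0, β → ∞, BBCB2's b0 → ∞) are profiled out of the
information matrix — the SE is then conditional on the variance being at
its boundary, the standard mixed-model convention.  An *effect* (or an
informative intercept) on a bound is counted as non-convergence.  In GLFR,
intercepts of double-zero (or all-event) studies diverge to the boundary
where those studies carry no information about θ; they are profiled out
exactly rather than failing the whole fit.

## Mixed logistic models

**GLFR**: g(π_ki) = γ_k + i·θ + i·ε_k with fixed study intercepts and
ε_k ~ N(0, τ²).  **GLRRI** additionally draws γ_k ~ N(γ, σ²_int),
independent of ε_k.  Random effects are integrated out per study by the
Laplace approximation (one adaptive quadrature node; more nodes give
adaptive Gauss–Hermite, and for GLRRI a product rule over the 2-D random
effect).  Inner modes are found by damped Newton iterations with analytic
binomial derivatives (step-halving, clipped steps, tolerance 1e-9).  GLFR
supplies the analytic gradient of the Laplace objective — envelope theorem
for the mode value plus implicit differentiation for the log-determinant
term — so the outer optimization and the information matrix (finite
difference of the exact gradient) are fast and noise-free.  τ² and σ²_int
are optimized as logs with a floor of 1e-10 treated as zero.  Wald 95%
intervals use the normal quantile 1.96 exactly.

## Inverse-variance and classical methods

Fixed-effect weights are 1/σ²_k; Cochran's Q and the DerSimonian–Laird
moment estimator τ²_DSL = max{0, (Q−(K−1))/(Σw − Σw²/Σw)} follow directly.
The Paule–Mandel τ² solves the generalised Q statistic equal to K−1; since
Q(τ²) is strictly decreasing, the root is bracketed by geometric doubling
and found by Brent's method (tolerance 1e-8), with τ² = 0 when Q(0) ≤ K−1.
The HKSJ interval is θ̂ ± t_{K−1,0.975}·√q·σ̂ with q the weighted mean
squared deviation; when that interval is narrower than the DSL interval
computed on the same data, it is recomputed with q* = max{1, q} (the
ad-hoc modification, applied conditionally as a DSL-based sensitivity
rule).  Mantel–Haenszel uses the ratio form Σ(a_k d_k/n_k)/Σ(b_k c_k/n_k)
with the Robins–Breslow–Greenland variance (the de-facto standard SE,
which the source description omits).  Peto uses O−E and the
hypergeometric variance; the collapsed table uses the Woolf SE.

## Fleishman power-method generator

Non-normal variates are generated as cubics Y = a + bZ + cZ² + dZ³ of a
standard normal Z, with (b, c, d) solving the classical three-moment
system for zero mean, unit variance, target skewness and excess kurtosis
(Newton from the near-normal start, multi-start fallback; residual
tolerance 1e-8).  "Kurtosis 3.68" for the effect-size distribution is
read as *excess* kurtosis: the raw reading (excess 0.68) lies outside the
feasible region for |skew| = 1.28, so the excess reading is forced.  The
quadratic feasibility boundary −1.2264489 + 1.6410373·skew² is treated as
advisory (it is slightly conservative; the classic pair (1.75, 3.75) lies
below it yet has the textbook solution), and a feasibility error is
raised only when no solution exists.  The effect-size cubic is monotone
increasing over |z| ≤ 6, so the median of exp(μ + σY) is exp(μ + σa);
the heterogeneity cubic (skew −0.55, excess kurtosis 0 by default — the
kurtosis is unstated in the design and exposed as a parameter) has c, d <
0 and turns over near z ≈ 2.75, so no quantile identity is used for τ².

## Simulation design

Per meta-analysis: π_C ~ Beta(0.42, 1.43); τ² = exp(−1.47 + 1.65·Y_τ);
θ = 0 under H0 and −0.59 + 0.61·Y_eff under H1 (log OR and log RR reuse
the same distribution).  Per study: n_k = round(LogNormal(4.615, 1.1)),
redrawn while n_k < 8; n_kT ~ Binomial(n_k, ½) redrawn while an arm would
be empty; y_kC ~ Binomial(n_kC, π_C); δ_k ~ N(0, τ²); π_kT =
expit(logit(π_C) + θ + δ_k) for the OR and min(1−10⁻¹², exp(log(π_C) + θ +
δ_k)) for the RR; y_kT ~ Binomial(n_kT, π_kT).  One RNG stream is spawned
per replication from the scenario seed, so the simulated data are
identical whatever subset of methods is requested.

**Double-zero policy.**  The reference study conditions this design
emulates contained *no* double-zero studies, while single-zero studies
appeared in 36% (K=2) to 58% (K=10) of meta-analyses.  The unconditioned
generator contradicts all of those observables (double-zero studies in
22–36% of meta-analyses).  The default policy therefore redraws a study's
event counts until at least one arm has an event — which reproduces the
reported single-zero rates almost exactly (36.5% / 56.9% measured) —
using vectorised rejection sampling with an exact rare-event-limit
fallback (importance resampling of δ, single event placed with odds
n_C·π_C : n_T·π_T) for control risks so small that rejection is
impractical.  `double_zero_policy="keep"` restores the literal generator.

**Known discrepancy (effect sizes).**  The construction
exp(μ + σ·FleishmanY) reproduces the design's printed τ² summary
quartiles to every digit (0.079 / 0.273 / 0.802, mean 0.621), validating
both the construction and the solver.  The printed effect-size summaries
(OR quartiles 0.527 / 0.694 / 0.838) are *not* reproducible from the
stated parameters — indeed no monotone Fleishman cubic is consistent with
that quartile triple, because Y(z)+Y(−z) = 2a+2cz² together with a = −c
forces Q1+Q3 = 1.09·median on the Y scale, while the printed row implies
0.595 versus 0.402.  The package generates from the stated parameters
(median OR ≈ 0.614).  Consequently the simulated H1 effects sit somewhat
farther from the null than the reference distribution's, and all power
figures run a few points higher than the reference values; H0 quantities
are unaffected.

## Performance measures

All measures are computed over R, the converged replications of a method:
bias θ̂−θ on the log scale; percentage bias (H1 only, undefined when
|θ| < 10⁻¹²); coverage = % of 95% CIs containing θ; CI length on the log
scale; power = % of CIs excluding 0 (H1 only).  Quartiles use linear
interpolation (type 7) throughout.  The sensitivity subset keeps
replications with Cochran-Q p > 0.05.  Under H0, power ≡ 100 − coverage
by construction, which the tests assert exactly.

## Problem sizes

Test-suite and acceptance runs use 1,000–2,000 replications per scenario
(the reference figures used 10,000), sized so the full pipeline completes
in minutes on one CPU; comparisons use ±3 Monte-Carlo standard errors
(binomial for proportions, order-statistic bands for medians).

## Limitations

Only 1:1 randomisation and two-arm studies are supported.  The generator
shares one π_C across all control arms of a meta-analysis, so the BBST's
common-ρ assumption is misspecified by design (as in the reference
conditions); ρ frequently estimates at its zero boundary for K = 2.  The
exact likelihoods behind the reference implementation's common-beta
models (SAS COUNTREG) are not documented there; the two adopted
likelihoods are isolated in their own classes so alternates can be
swapped in.  RR fits with the log link fail to converge for large
baseline risks (π_C > 0.5), matching the reference behaviour.
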