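# Methods

## Model

Per-cell γ-H2AX foci counts are modelled as a K-component Poisson mixture.
Conditional on dose d (Gy) and post-irradiation time t (h), a cell drawn from
component k (probability ω_k) has a Poisson count with mean

    λ_k(d, t) = c_k t^u_k + a_k t^{v_k} d .

The two terms separate spontaneous foci (level c_k, kinetics t^u_k) from
radiation-induced foci (yield a_k per gray, kinetics t^{v_k}); foci repair
over time corresponds to negative exponents. The mixture captures the
overdispersion of foci data, attributed to leukocyte sub-populations with
different radiosensitivity. A "shared-u" variant constrains the spontaneous
kinetics to be common across components; the free-parameter count is
(K−1) + 3K + (1 or K), e.g. 16 for K = 4 with shared u.

At fixed t the population mean is affine in dose, μ(d|t) = α_t + β_t d with
α_t = Σ ω_k c_k t^u_k and β_t = Σ ω_k a_k t^{v_k}; the pair (α_t, β_t) is the
calibration line used for inverse regression.

**Assumptions.** Cells are conditionally independent given (d, t); the same
mixture weights apply at every condition; dose–response is linear at fixed
time over the calibrated range (0–3 Gy, low-LET photon exposure, acute
whole-body irradiation). None of high-LET kinetics, chronic exposure, or
partial-body dose gradients is modelled.

## Priors and fitting

Weights get a Perks prior, the symmetric Dirichlet with concentration 1/K;
surface coefficients get flat box priors. Inference is performed in an
unconstrained space: additive log-ratio for ω (last component as reference),
log for a_k and c_k, identity for the exponents. Default boxes are
log a, log c ∈ [−10, 5] and u, v ∈ [−5, 2] — generous enough for any
plausible foci kinetics (means from ~5·10⁻⁵ to ~150 foci per cell over
0.5–24 h) and user-overridable.

The posterior mode is found by multi-start L-BFGS-B (default 20 starts;
starts are built from a single-component Poisson-surface fit, jittered
multiplicatively by up to ±70% per component, with Dirichlet-random weights).
Mixture likelihoods are multimodal up to label permutation; fitted components
are reported in canonical order, ascending in the dose slope a_k, which is
the coefficient most likely to separate radiosensitivity subsets. Because
the Perks prior density diverges as any weight approaches zero, the
optimizer additionally caps the weight log-ratios at ±12 (weights ≳ 6·10⁻⁶)
so a superfluous component cannot drag the search onto that boundary ridge;
with well-supported components the interior mode is unaffected.

Likelihood evaluation aggregates the data over unique (dose, time, count)
triples, so its cost scales with the number of distinct triples (a few
hundred for a 25-condition design) rather than the number of cells, and uses
log-sum-exp for the inner mixture sum (component means reach ~25–30 foci at
high dose / short time, where direct pmf products underflow).

## Laplace approximation

The posterior is approximated as N_p(mode, Σ) with Σ the inverse negative
Hessian of the unconstrained log posterior at the mode. The Hessian is
computed by central finite differences with per-coordinate steps
1e−4·(1+|x_j|) and symmetrized; a non-negative-definite Hessian raises an
error naming the offending eigendirections (this is also how degenerate
designs — e.g. a single time point, where t^u confounds with c — surface).
Condition numbers above 1e10 are flagged in diagnostics. Model order is
selected by AIC = 2p − 2·loglik at the mode, matching the MAP under the flat
coefficient priors.

The calibration output file carries the mode, the full p×p covariance, the
parametrization descriptor and the AIC, and is the complete handoff between
the calibrating and the estimating laboratory (16 + 136 = 152 numbers for
the K = 4 shared-u structure).

An adaptive random-walk Metropolis-within-Gibbs sampler over the same
unconstrained space (coordinate-wise proposals, scales adapted toward ~40%
acceptance during burn-in, draws relabelled to canonical order) serves as an
independent cross-check of the Laplace approximation; it is deliberately not
the production path.

## Delta method for (α_t, β_t)

The bivariate posterior of (α_t, β_t) at any t is obtained by first-order
propagation: mean g(mode), covariance J Σ Jᵀ, with the Jacobian J of
g = (α_t, β_t) computed analytically through the softmax/log transforms
(finite-difference-verified in tests). The approximation is deliberately
first-order only; its residual against a Monte-Carlo pushforward of the
Laplace posterior is the quadratic term 0.5·tr(∇²g Σ) — a relative ~0.3–0.4%
on α_t at the default study size — which the test suite verifies explicitly.

## Dose estimation

The patient's expected foci count is modelled nonparametrically as
μ ~ N(x̄, s²/n) from the aggregate summary (x̄, s, n), independent of the
calibration posterior. Conditional on t, the dose d = (μ − α_t)/β_t is a
ratio of correlated normals: numerator μ − α_t ~ N(x̄ − α̂_t, s²/n + var α_t),
denominator β_t, covariance −cov(α_t, β_t). Time-since-exposure uncertainty
enters through a prior π(t), uniform or scaled symmetric Beta
(t_lo + (t_hi−t_lo)·Beta(a, a)) on an interval.

Two routes to the marginal dose posterior:

* **Simulation** — repeat m ≥ 10,000 times (default 10,000): draw t* from
  π(t), (α, β) from the delta-method bivariate normal at t*, μ* from
  N(x̄, s²/n), record d* = (μ* − α)/β. Fully vectorized; deterministic given
  the seed.
* **Integration** — Gauss–Legendre quadrature (64 nodes) of the exact
  conditional ratio density (Hinkley's closed form) against π(t), normalized
  on an automatically bracketed dose grid (801 points, centred on the
  conditional ratio means ± 10 first-order SDs); a normalization defect
  above 1% raises an error rather than silently renormalizing a clipped
  density. The Hinkley exponent is evaluated in the algebraically
  equivalent cancellation-free form −(μ₂r − μ₁)²/(2σ₁²σ₂²a(r)²), since the
  naive b² − c·a² difference loses all precision when the denominator's
  coefficient of variation is small — which is the typical biodosimetry
  regime (β_t estimated to ~1%).

Negative dose draws are retained in the raw sample (the ratio produces them
when μ* < α_t, i.e. counts at or below background); summaries can optionally
be truncated at 0 via a switch. Summaries report mean, median and an
equal-tailed credible interval, default level 0.95 (the level is a
convention, user-overridable); both mean and median are reported since
either may be quoted as "the" estimate.

## Synthetic data

The generator emulates the calibration design: full crossing of doses
{0, 0.5, 1, 2, 3} Gy with times {0.5, 1, 2, 4, 24} h, 500 cells per
condition (12,500 cells), counts drawn from the generative mixture. The
default test fixture is a two-component model — ω = (0.6, 0.4),
a = (3.0, 6.0), c = (0.4, 0.8), shared u = −0.3, v = (−0.5, −0.9) — chosen
to give ~0.5–1 spontaneous foci and ~22–25 foci at 3 Gy / 0.5 h, the
magnitudes seen in real γ-H2AX calibration experiments; these are fixture
values, not estimates from any dataset. Patient samples are generated the
same way at a true (dose, time), returning both raw counts and the
aggregate summary, so the aggregate-only interface of the estimating
laboratory is testable as a boundary.

What the generator does **not** emulate: donor-to-donor variability,
foci-scoring error (manual vs automatic), image-analysis artefacts, and any
misspecification of the power-law kinetics. Passing recovery and coverage
tests therefore demonstrate internal consistency of the inference under the
model, not robustness to real-data misspecification.

## Numerical choices and test scale

* Hessian steps 1e−4·(1+|x_j|), central differences; covariance symmetrized,
  positive-definiteness enforced (tiny jitter flagged in diagnostics).
* Optimizer tolerances: L-BFGS-B ftol 1e−11, gtol 1e−7, bounds kept 1e−6
  inside the prior box so finite differences stay valid.
* Ties and degenerate inputs: a zero Laplace covariance yields point-mass
  (α, β) posteriors and, with s = 0 and a point-like time prior, a
  zero-width dose interval; β_t = 0 in the inverse ratio is an invalid draw,
  counted and warned about above a 1% share.
* Test problem sizes: the recovery and coverage checks run the full 500
  cells-per-condition design with a K = 2 truth (50 and 25 replicates), the
  simulation/integration cross-checks use 10⁵ draws, and the MCMC
  cross-check uses 4,000 iterations of the coordinate sampler — sizes at
  which the whole suite completes in a few minutes on one core while the
  Monte-Carlo error stays well below the tolerances being asserted.

## Known limitations

* The Laplace and delta-method approximations are asymptotic; with far
  smaller calibration studies (few conditions or few cells) the Gaussian
  approximation degrades and the MCMC cross-check is the honest reference.
* MAP with a Dirichlet(1/K) prior is ill-posed at the simplex boundary when
  K exceeds the number of supported components; the optimizer cap makes the
  fit usable for AIC comparison, but the reported covariance for such
  overspecified models should not be trusted (the condition-number
  diagnostic flags this).
* The time priors are fixed families on an interval; arbitrary user-supplied
  π(t) densities are not implemented.
* Calibration and patient data are assumed to come from the same scoring
  protocol; no transfer/recalibration between laboratories is modelled.
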