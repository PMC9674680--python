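# biodose

Bayesian radiation biodosimetry from γ-H2AX foci counts, with uncertainty on
the time since exposure.

## The problem

After a radiological accident, the absorbed dose of an exposed person can be
estimated from biological markers. Ionising radiation causes DNA double-strand
breaks; at each break the histone H2AX is phosphorylated (γ-H2AX) and becomes
visible under the microscope as a focus. The number of foci per blood cell
grows with dose — but it also decays over the hours after exposure as the cell
repairs the damage, and in a real accident the exact exposure time is not
known. `biodose` implements a calibration-and-estimation pipeline that treats
both dose *and* time-since-exposure as uncertain.

## The model

Foci counts per cell are overdispersed (blood is a mixture of leukocyte
subsets with different radiosensitivity), so a K-component Poisson mixture is
used. Component k has mean surface

    λ_k(d, t) = c_k · t^u + a_k · t^{v_k} · d

with dose d (Gy) and post-irradiation time t (h); `c_k t^u` is the spontaneous
focus level and `a_k t^{v_k}` the per-gray yield, each with its own repair
kinetics. At fixed t the expected count is affine in dose,

    μ(d | t) = α_t + β_t d,   α_t = Σ_k ω_k c_k t^u,   β_t = Σ_k ω_k a_k t^{v_k}.

**Calibration** (done once, by a calibration laboratory): the posterior over
weights ω and surface coefficients — under a Perks (symmetric Dirichlet 1/K)
prior on ω and flat box priors on the coefficients — is maximized to find the
mode and approximated by a Gaussian via Laplace's method (inverse negative
Hessian at the mode). K is chosen by AIC. The shipped "calibration file"
contains the mode and its full covariance; for the K = 4 shared-u model that
is 16 coefficients + 136 covariance values = 152 numbers.

**Estimation** (by any laboratory, from aggregate data only): given a
patient's mean foci count x̄, its SD s over n cells, the patient's expected
count is modelled as μ ~ N(x̄, s²/n), and the dose at a known time is the
inverse-regression ratio d = (μ − α_t)/β_t — a ratio of correlated normals,
since (α_t, β_t) carry the calibration posterior pushed through the delta
method. Uncertainty about t enters through a prior (uniform or scaled
symmetric Beta on an interval); the marginal dose posterior is computed either
by Monte-Carlo simulation of the chain t* → (α, β) → μ* → d*, or by
Gauss–Legendre quadrature of the exact Hinkley ratio density over the time
prior. Both routes agree to well under 0.01 Gy.

## Worked example

```bash
# 1. simulate a calibration study: doses 0-3 Gy, times 0.5-24 h, 500 cells each
biodose simulate --seed 3 --out calibration.csv

# 2. calibrate: AIC model selection over K, Laplace posterior to file
biodose calibrate --data calibration.csv --k-grid 1,2,3 --seed 1 \
    --out calibration.json

# 3. estimate a patient scored at 1.52 foci/cell (SD 1.27, 500 cells),
#    exposed an estimated 3-5 hours ago
biodose estimate --calibration calibration.json \
    --mean 1.516 --sd 1.270 --n-cells 500 \
    --time-prior uniform --t-lo 3 --t-hi 5 \
    --method simulate --draws 100000 --seed 9
```

The last command prints

```
method,mean,median,ci_lo,ci_hi,level,n_draws,seed
simulate,0.718346779850623,0.718319787909078,0.563709900058102,0.880330487649864,0.95,100000,9
```

read as: posterior mean dose 0.72 Gy, median 0.72 Gy, and a 95% equal-tailed
credible interval of (0.56, 0.88) Gy — the patient summary was itself
simulated from a true exposure of 0.75 Gy at 4 h. `--method integrate`
computes the same
posterior by numerical integration instead of simulation; `--density-out`
dumps the full density curve. With a tighter time prior (e.g.
`--time-prior beta --beta-a 100 --beta-b 100`) the interval narrows.

As a library, the same pipeline is four calls:

```python
from biodose import *

params = paper_like_params()                       # synthetic truth (K=2)
data = generate_calibration_data(params, seed=3)   # 12,500 cells
fit = map_fit(data, MixtureSpec(K=2, shared_u=True), seed=1)
laplace = laplace_approx(fit, data)

patient, _ = generate_patient_sample(params, true_dose=0.75, true_time=4.0, seed=11)
post = simulate_dose_posterior(laplace, patient, TimePrior("uniform", 3, 5),
                               m=100000, seed=9)
print(post.summarize())
# PosteriorSummary(mean=0.7183..., median=0.7183..., ci_lo=0.5637..., ci_hi=0.8803..., level=0.95)
```

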