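# ppdesign

Optimal experiment design for Bayesian model selection in biochemical
networks — and for any other setting where competing parametric models must
be told apart with scarce data.

When several model topologies describe the available measurements equally
well, the question becomes *which new experiment would discriminate between
them*. `ppdesign` answers it by comparing the models' **posterior predictive
distributions** (PPDs): for each candidate experiment (which observable,
which time point, which stimulus condition — singly or in combination) it
estimates the Jensen–Shannon divergence (JSD) between the joint predictive
densities of each model pair,

    D_JS = Σ_i p(M_i) · D_KL( p(y | M_i) ‖ Σ_j p(M_j) p(y | M_j) ),

with equal model weights, base-2 logarithms, and `K = 2` models compared at
a time, so `D_JS ∈ [0, 1]` bits. A value near 1 means the models predict
essentially disjoint outcomes — performing that experiment will settle the
comparison; a value near 0 means the experiment cannot help. Because only
samples of the PPDs are available, the divergence is estimated from
k-nearest-neighbor densities: the density at a point is `(k/N) / (ρ_k^d v_d)`
where `ρ_k` is the Euclidean distance to the k-th nearest neighbor (found by
exact k-d tree search, within and across the two samples) and `v_d` the unit
d-ball volume. The default `k = 10`.

The criterion is validated against the quantity it is meant to predict: the
expected change in log10 **Bayes factor** toward the true model after the
candidate measurement is actually (virtually) performed. For linear
basis-function models both the posterior and the marginal likelihood are
analytic, which makes an overarching Monte-Carlo validation feasible; for
nonlinear ODE models posteriors are sampled by population MCMC over a
power-posterior temperature ladder `T_n = (n/N_T)^4`, which also yields the
marginal likelihood by thermodynamic integration.

## What is in the box

| module | contents |
| --- | --- |
| `ppdesign.models` | linear basis-function and ODE model objects, priors (gamma / Gaussian / half-normal), Gaussian error model, steady-state simulation, synthetic data generation, dataset CSV I/O |
| `ppdesign.inference` | analytic conjugate posteriors, population MCMC with exchange moves, posterior-propriety profiling, thinning, HDF5 persistence |
| `ppdesign.evidence` | analytic and thermodynamic-integration marginal likelihoods, Bayes factors with Jeffreys labels, expected Bayes-factor updates for candidate experiments |
| `ppdesign.ppd` | posterior predictive sampling for arbitrary candidates (noise included), candidate-grid enumeration |
| `ppdesign.divergence` | the kNN-JSD estimator, a quadrature / Monte-Carlo oracle, k-sensitivity sweep |
| `ppdesign.design` | design matrices over candidate pairs, ranking across model pairs, greedy augmentation |
| `ppdesign.studies` | the linear regression quartet, random model-pair generator, the feedback-motif ODE quartet, and the two packaged validation studies |

## A worked example

Four nested regression models `y(t) = θ₁t (+ θ₂t² (+ θ₃sin(15t)/3 (+ θ₄sin(2t)·t)))`
compete; M3 generated the data. Measurements were taken at times spaced
exactly one period of the sine apart, so the oscillation is aliased — all
four models fit the window, the sine coefficient keeps its prior
uncertainty, and model selection stalls:

```python
import numpy as np
from ppdesign import studies, knn_jsd
from ppdesign.models import ParameterVector, generate_data, regular_design, DesignPoint
from ppdesign.inference import analytic_posterior
from ppdesign.evidence import analytic_log_evidence, bayes_factor, expected_bf_update
from ppdesign.ppd import build_column_source, CandidateExperiment

m1, m2, m3, m4 = studies.linear_quartet()
theta = ParameterVector({"theta_1": 0.5, "theta_2": 0.3, "theta_3": 1.0})
times = 2.0 + np.arange(10) * 2 * np.pi / 15
data = generate_data(m3, theta, regular_design("y", times, 1), sigma=0.2, seed=0)

sigma, xi = 0.2, 1.0
for alt in (m1, m2):
    b = bayes_factor(analytic_log_evidence(m3, data, sigma, xi),
                     analytic_log_evidence(alt, data, sigma, xi))
    print(f"initial log10 B(M3:{alt.name}) = {b.log10_bf:.2f} ({b.label})")

grid = [DesignPoint("y", t) for t in (1.0, 3.5, 7.0)]
rng = np.random.default_rng(1)
src3 = build_column_source(analytic_posterior(m3, data, sigma, xi), m3, grid,
                           sigma=sigma, seed=rng, n=5000)
src2 = build_column_source(analytic_posterior(m2, data, sigma, xi), m2, grid,
                           sigma=sigma, seed=rng, n=5000)
for i, t in enumerate((1.0, 3.5, 7.0)):
    est = knn_jsd(src3.columns([i], rng), src2.columns([i], rng), k=10)
    upd = expected_bf_update((m3, m2), data, CandidateExperiment(points=(grid[i],)),
                             sigma, xi, n_rep=100, seed=2, generating_model=m3)
    print(f"candidate t={t:>4}: JSD = {est.jsd_bits:5.3f} bits   "
          f"E[dlog10 B(M3:M2)] = {upd.mean:+.3f}")
```

prints

```
initial log10 B(M3:M1) = 90.89 (decisive)
initial log10 B(M3:M2) = 0.01 (barely worth mentioning)
candidate t= 1.0: JSD = 0.158 bits   E[dlog10 B(M3:M2)] = +0.424
candidate t= 3.5: JSD = 0.271 bits   E[dlog10 B(M3:M2)] = +1.352
candidate t= 7.0: JSD = 0.012 bits   E[dlog10 B(M3:M2)] = +0.013
```

The straight line M1 is already rejected (`log10 B = 90.9`), but M3 and M2
are indistinguishable on the current data (`log10 B = 0.01`). Among the
three candidate measurement times, the divergence ranks `t = 3.5` (a
quarter-period off the sampling phase, where the aliased oscillation would
become visible) far above `t = 7.0` (beyond the window, where polynomial
extrapolation uncertainty swamps the sine) — and the Monte-Carlo expected
Bayes-factor updates (+1.35 vs +0.01 in log10 units) agree with that
ranking.
That agreement, summarized as a Spearman rank correlation across candidates
and averaged over many randomly generated model pairs, is the package's
headline validation statistic (≈ 0.91).

The nonlinear counterpart — four ODE feedback-motif variants fit by
population MCMC, with design matrices over all combinations of two
measurements — runs end to end via

```bash
ppdesign study-motif --temps 20 --samples 4000 --ppd-size 1000 --seed 1 --out out/
```

## Command-line interface

`ppdesign` installs a console script with subcommands `infer` (population
MCMC → HDF5 chains), `evidence` (thermodynamic integration), `bf`, `jsd`,
`study-linear` and `study-motif`. Each is a thin wrapper over the library
functions above. See `ppdesign --help`.
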