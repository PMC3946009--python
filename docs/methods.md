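# Methods

## The design problem

Given competing models `M_1 … M_K` of one system, calibrated to the same
data `y^D`, we score a candidate experiment `q` — an ordered list of `d`
design points, each a (observable, condition, time-or-steady-state) triple —
by how well its outcome would discriminate between the models. The score is
the Jensen–Shannon divergence between the models' posterior predictive
distributions (PPDs) of the candidate's outcome vector:

    D_JS(q) = Σ_i w_i D_KL( p(y_q | M_i, y^D) ‖ Σ_j w_j p(y_q | M_j, y^D) )

with base-2 logarithms. We compare models pairwise (`K = 2`) with equal
weights `w = (½, ½)`, so `D_JS ∈ [0, 1]` bits, and it equals the mutual
information between a draw from the two-model predictive mixture and a
model-identity label — the information the measurement carries about which
model is true. Equal weights are deliberate: weighting by current model
evidence would let the complexity penalty silently remove models from the
design stage, which is the opposite of what a discriminating experiment is
for.

PPDs include measurement noise (future observations will be noisy); when
the noise scale σ is itself inferred, each predictive draw uses its own
posterior σ, propagating the full uncertainty. An optional log transform of
strictly positive predictions is available (off by default) for cases where
predictive dispersions span decades.

## The kNN divergence estimator

Only samples `Ω_1, Ω_2` (one row per posterior draw) of the PPDs are
available, so the densities in `D_KL` are replaced by k-nearest-neighbor
estimates `p̂(y) = (k/N) / (ρ_k(y)^d v_d)`, with `ρ_k` the Euclidean
distance to the k-th nearest neighbor and `v_d = π^{d/2}/Γ(d/2+1)`.
Writing `r_cross` for the k-th-neighbor distance of a point of `Ω_a` in the
*other* sample and `r_own` for its k-th-neighbor distance in its *own*
sample with the point itself excluded, the per-point density ratio against
the equal-weight mixture is

    Q_ab(i) = 2 N_b r_cross^d / ( N_b r_cross^d + (N_a − 1) r_own^d )

and the divergence estimate is `½·mean_a log2 Q_ab + ½·mean_b log2 Q_ba`.
Neighbor searches use exact k-d trees; ties break by sample order, so the
estimate is deterministic given the stored row order. Default `k = 10`;
`k_sensitivity` sweeps `k ∈ {1, 5, 10, 20, 50}` for stability checks, and
sample sizes should satisfy `N ≫ 2^d` (the density estimates lose accuracy
as the candidate dimension grows, which is why the design dimension is
capped at 3 by default).

**Finite-k debias.** `log2 Q` is a smooth concave function of the log
density ratio `u = log(N_b r_cross^d) − log((N_a−1) r_own^d)`, whose
k-th-neighbor fluctuation has variance ≈ 2ψ′(k) (ψ′ the trigamma
function). Averaging therefore incurs a second-order Jensen bias of about
`−ψ′(k)·σ(u)σ(−u)/ln 2` per point — measured at −0.038 bits for identical
1-D Gaussian samples at `k = 10`, independent of N. `knn_jsd` subtracts
this term point by point by default (`bias_correction=True`); the
correction vanishes for well-separated samples and as k grows, and the
measured residual bias at the reference settings (N = 10000, k = 10) is
≈ 0.001 bits. The uncorrected estimator remains available and is what the
Q-ratio formula above defines.

**Degeneracies.** Exactly replicated prediction vectors give zero neighbor
distances where `Q` is undefined; distances are floored at `1e-12` times
the sample scale and the number of floored distances is reported. Estimates
may overshoot `[0, 1]` by a few hundredths at moderate N; tests use a
±0.05 band.

**Oracle.** `jsd_oracle` integrates the definition directly for known
densities — adaptive quadrature in 1-D (with support bracketing and
breakpoints at density peaks so narrow modes cannot be missed), mixture
Monte Carlo in higher dimension — and is used to calibrate the estimator,
never as part of it.

## Inference

*Linear basis-function models* `y(t) = Σ θ_i B_i(t) + ε`, with known noise
σ and a zero-mean Gaussian coefficient prior of sd ξ, have the conjugate
posterior `Σ = (BᵀB/σ² + I/ξ²)^{-1}`, `μ = Σ Bᵀy/σ²` and marginal
likelihood `N(y; 0, ξ²BBᵀ + σ²I)`. These closed forms are the oracles for
every sampled quantity.

*Nonlinear (ODE) models* are sampled by population MCMC on the power
posteriors `p(y|θ)^{T_n} p(θ)` over the quartic ladder `T_n = (n/N_T)^4`,
`n = 0 … N_T` (reference `N_T = 40`): one Gaussian-proposal Metropolis
update per temperature per sweep, plus exchange attempts between random
adjacent temperatures (swaps cost no likelihood evaluations; the studies
attempt `N_T` per sweep). Positivity-constrained parameters are sampled on
the log scale with the Jacobian correction. The proposal covariance is
seeded from a finite-difference Jacobian approximation to the Hessian
(`JᵀJ/σ²` plus a unit ridge; identity fallback) and then adapted per
temperature during burn-in only — empirical covariance every 50 sweeps once
10·dim sweeps have accumulated, step scale tuned toward 23% acceptance —
and frozen afterwards, so retained chains are Markovian. Burn-in defaults
to half the retained length; chains persist to HDF5; `thin` takes an
evenly-strided subsample (reference target 10000 draws) with effective
sample sizes from `arviz`.

Posterior propriety can be checked beforehand by profiling: maximize
likelihood × prior over all other parameters along a grid for the parameter
in question (Nelder–Mead in the transformed space) and flag "improper"
unless the profile has dropped ≥ 3 nats from its peak at both grid ends.

*Thermodynamic integration.* `log Z = ∫₀¹ E_T[log p(y|θ)] dT`, evaluated by
the trapezoid rule over the same ladder; the standard error combines
per-temperature `var/ESS` through the quadrature weights. The quadrature
rule and SE estimator are this package's choices. The trapezoid
discretization bias is visible on short ladders (≈ −0.3 nats at `N_T = 12`
on the linear benchmark) and negligible at `N_T = 40` (≈ −0.02 nats vs the
analytic value); evidence comparisons should use the full ladder.

*Expected Bayes-factor update.* For a candidate `q`, hypothetical outcomes
are drawn from the true model's PPD (default; drawing from the true model
at fixed true parameters is available), appended to the data, and both
evidences recomputed; `Δ(B_ab)` is the change in `log10 B_ab`. For scalar
(`d = 1`) candidates the outcomes are drawn from equal-probability strata
of the predictive distribution, jittered within each stratum — unbiased,
still random, and with far smaller Monte-Carlo error in the mean than
i.i.d. draws at the same replication count (reference `n_rep = 100`; the
validation study uses 25). For nonlinear models each replicate would cost
a full MCMC-plus-integration run; that path exists behind an explicit
expensive flag and is not part of any default pipeline.

## Design matrices, ranking, augmentation

For a grid of m single measurements, the `d = 2` design matrix holds the
pairwise JSD for every unordered pair of grid points (diagonal = the same
point measured twice, with independent noise per replicate); it is
symmetric by construction and bit-reproducible given the seed (per-cell
generators are spawned deterministically). Rankings across several model
pairs aggregate by the minimum over pairs by default — an experiment is
only as good as the pair it fails to separate; mean and max are options.
Greedy augmentation extends a candidate one design point at a time (true
JSD cannot decrease when a coordinate is added; the estimate may dip by at
most the documented 0.05 tolerance) and refuses to exceed the dimension
cap. Exhaustive grid enumeration plus greedy extension deliberately
replaces any stochastic search over design space.

## Synthetic data generators

**Linear quartet.** `M1: θ₁t`, `M2: +θ₂t²`, `M3: +θ₃ sin(15t)/3` (the
designated truth), `M4: +θ₄ sin(2t)·t`. The flattened source notation for
the oscillatory terms is ambiguous; these readings are fixed here and the
constants live in the basis registry, so the quartet can be re-tuned.

The packaged quartet example uses `θ = (0.5, 0.3, 1.0)`, `σ = 0.2`,
`ξ = 1`, and ten measurements spaced exactly one sine period `2π/15` apart
starting at `t = 2`. The aliased spacing is the operative choice: the
oscillation is invisible in the sampled window (every sample hits the same
phase), so the initial comparison gives a decisive Bayes factor against the
straight line but `log10 B(M3:M2) ≈ 0` with the sine coefficient still at
prior uncertainty. This is the regime that produces the characteristic
correlation structure: M2's predictions at negative and positive times are
positively correlated while M3's anticorrelate through the odd sine term,
so a combined (negative-time, positive-time) measurement discriminates
better than any same-side pair. Off-window candidates sit at
quarter-phase offsets (|sin| = 1) on both sides. Windows chosen only by
"initial |log10 B| < 1" do not reproduce that mechanism: with amplitude
1/3 and ξ = 1 the sine's contribution to predictive covariance is
structurally dominated by polynomial extrapolation variance.

**Random model pairs** (the headline validation): basis functions drawn
from the registry families `t^a` (a ≤ 3) and `sin(bt)·t^c`
(b ∈ {1, 2, 5, 15}, c ∈ {0, 1}), true and competitor sets overlapping but
never identical, true coefficients drawn from the `N(0, ξ²)` prior. Data:
10 equidistant points, σ = 0.2, in a random window (start ∈ [0,1], span ∈
[0.5, 1.5]) redrawn until the initial `|log10 B| < 1` — the regime where
design is actually needed; pairs that never qualify, or whose scores are
degenerate (constant), are skipped and counted. Candidates: 20 times on a
grid extending 1.5 window-spans beyond both window ends. Per pair, the
Spearman rank correlation between candidate JSD and mean `Δlog10 B`; the
study reports all correlations and their mean (≈ 0.92 at 40 pairs,
`n_rep = 25`, 5000 predictive draws).

**Feedback-motif quartet.** A mass-action phosphorylation cascade with
complex formation: stimulus `u` drives `B → Bp`; `Bp` phosphorylates
`C → Cp`; `Bp + Cp` bind reversibly to the complex `BpCp`; `BpCp` drives
`D → Dp`; all reverse steps first-order. Total `B`, `C`, `D` pools are
conserved and normalized to 1, so the model integrates the four states
`(Bp, Cp, BpCp, Dp)`. Four variants differ only in the origin and point of
action of one negative feedback, a saturating factor `1/(1 + k_fb·X)`:

| variant | origin X | acts on |
| --- | --- | --- |
| M1 (truth) | Dp | `u → B` activation |
| M2 | Dp | `Bp + Cp` binding |
| M3 | BpCp | `u → B` activation |
| M4 | Cp | `u → B` activation |

These are *synthetic models built to exercise the method*, not a
reconstruction of any published pathway's exact equations. Observables:
`Bp, Cp, BpCp, Dp` and total phosphorylated B (`Bp + BpCp`). Data: `Bp` in
triplicate and `Dp` in duplicate at `t = (0, 2, 5, 10, 20, 40, 60, 100)`
under stimulus `u = 1`, Gaussian noise σ = 0.03. The true rate constants
were fixed once so that `Bp` overshoots visibly above the noise level
(peak ≈ 0.28 at `t ≈ 2` vs steady state ≈ 0.09); priors are Gamma(α = 1,
β = 3) in the shape–scale convention (mean 3 — broad enough for rates over
decades, informative enough to avoid the vague-prior pathology of always
preferring the simplest model) for the nine rates and half-normal(1) for
the inferred σ. All four variants fit the shared dataset with best-fit
residual SD ≤ 0.03 (well within 3σ), so the selection problem is genuinely
open at the start.

Steady-state design points integrate to a horizon of 1000 time units (10×
the largest measured time), accept when `max|dx/dt| < 1e-8 · max(|x|, 1)`,
and double the horizon (up to 6 times) otherwise — robust for stiff
feedback systems without algebraic root finding.

**What the generators do not emulate.** Real data have non-Gaussian and
heteroscedastic errors, scaling/offset observation maps (supported but off
by default — the examples read concentrations directly), missing values,
and model misspecification (here the truth is always in the candidate set).
Passing tests therefore demonstrate the method's internal consistency and
its behavior under its own assumptions, not robustness to any of the
above.

## Motif study behavior at desk scale

With well-mixed chains the named validation experiments behave as follows
on this reconstruction: steady-state `Cp` alone separates no pair (JSD
0.02–0.15, Monte-Carlo-noise-limited toward 0); the joint steady-state
`(Cp, BpCp)` candidate separates M1 from M3 strongly (JSD ≥ 0.5) — but, in
this reconstruction, it also separates M1 from M2 and M4, because each
feedback variant pins the unobserved steady `BpCp` at a different level.
Which pairs the steady-state joint leaves indistinct is a property of the
exact equations; the corresponding check is kept in the suite as a
conditional expectation and currently fails by design honesty rather than
being relaxed. The per-tile "dark diagonal" property (measuring the same
point twice is less informative than two different times) and bit-exact
end-to-end determinism hold.

## Numerical choices

- ODE integration: `lsoda` via `scipy.integrate.odeint`, reference
  tolerances `atol = 1e-8`, `rtol = 1e-9`; study-scale runs use
  `1e-7/1e-6` (verified indistinguishable for these systems at data
  precision).
- Evidence quadrature: trapezoid on the inference ladder (see above).
- kNN searches: exact `cKDTree`; zero-distance floor `1e-12 ×` scale.
- Gamma priors: shape–scale convention, switchable to shape–rate.
- No per-column standardization of prediction vectors by default (raw
  Euclidean distances); optional robust scaling exists for mixed-unit
  candidates and is off by default.
- Random numbers: every public entry point takes a seed; internal
  per-cell/per-pair generators are spawned via `SeedSequence(entropy,
  spawn_key)`, so results are reproducible bit for bit.

## Problem sizes used by the packaged tests and scripts

The validation study runs 30–40 random model pairs with 25 Bayes-factor
replicates per candidate and 5000 predictive draws; the motif study in the
test suite uses a 5-rung ladder, 2500 retained sweeps per model, 800
predictive draws and a 5-time grid. These sizes were chosen as the smallest
at which the reported statistics are stable; all scale up linearly via
function arguments.

## Known limitations

- Pairwise (`K = 2`) comparisons only; the divergence and estimator
  generalize to K-component mixtures but that path is not implemented.
- Design dimension is capped (default 3) because neighbor-distance density
  estimation degrades with dimension.
- The kNN-JSD estimate at fixed k retains a small residual bias after the
  Jensen correction; it is far below the decision-relevant differences in
  any of the studies.
- Expected Bayes-factor updates for nonlinear models are computationally
  out of reach as a routine quantity (each replicate is a full inference);
  the JSD is the practical criterion there, which is the method's point.
- Gaussian, independent measurement error only; no stochastic (Gillespie)
  simulation; no SBML import.
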