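"""Posterior sampling: conjugate closed forms and population MCMC.

Linear basis-function models with known noise and Gaussian coefficient
priors admit an analytic Gaussian posterior, used throughout as an oracle.
Nonlinear (ODE) models are sampled by population MCMC: a ladder of chains
targeting the power posteriors p(y|theta)^T p(theta) with T running from 0
(the prior) to 1 (the posterior), Metropolis updates within each chain and
exchange (swap) moves between adjacent temperatures.  The per-temperature
expected log likelihoods are exactly what thermodynamic integration needs
for the marginal likelihood, so evidence estimation comes for free.

Positivity-constrained parameters (gamma/half-normal priors) are sampled on
the log scale with the appropriate Jacobian correction, since kinetic rates
under a broad gamma prior span decades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .models import (
    Dataset,
    LinearBasisModel,
    ParameterVector,
    PriorSpec,
    _predict_points,
)

__all__ = [
    "GaussianPosterior",
    "TemperedChains",
    "PosteriorSample",
    "ProfileReport",
    "FlatPrior",
    "analytic_posterior",
    "temperature_schedule",
    "population_mcmc",
    "check_propriety",
    "thin",
]


# ---------------------------------------------------------------------------
# analytic conjugate posterior
# ---------------------------------------------------------------------------


@dataclass
class GaussianPosterior:
    """Gaussian posterior over linear-model coefficients."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        # Cholesky doubles as the positive-definiteness check
        self._chol = np.linalg.cholesky(self.cov)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, len(self.mean)))
        return self.mean + z @ self._chol.T


def analytic_posterior(
    model: LinearBasisModel,
    data: Dataset,
    sigma: float,
    xi: float,
) -> GaussianPosterior:
    """Conjugate Gaussian posterior for a linear model with known noise.

    With design matrix B (rows = data points), noise sd ``sigma`` and a
    zero-mean coefficient prior of sd ``xi``:

        Sigma = (B'B / sigma^2 + I / xi^2)^{-1},   mu = Sigma B'y / sigma^2

    An empty dataset returns the prior (mean 0, covariance xi^2 I).
    """
    if sigma <= 0 or xi <= 0:
        raise ValueError("sigma and xi must be positive")
    L = model.n_params
    if len(data) == 0:
        return GaussianPosterior(np.zeros(L), xi**2 * np.eye(L))
    times = data.frame["time"].to_numpy(dtype=float)
    if data.frame["steady"].any():
        raise ValueError("linear basis models have no steady state")
    B = model.design_matrix(times)
    y = data.values
    precision = B.T @ B / sigma**2 + np.eye(L) / xi**2
    cov = np.linalg.inv(precision)
    cov = 0.5 * (cov + cov.T)
    mean = cov @ (B.T @ y) / sigma**2
    return GaussianPosterior(mean, cov)


# ---------------------------------------------------------------------------
# temperature ladder
# ---------------------------------------------------------------------------


def temperature_schedule(n_temps: int, exponent: float = 4.0) -> np.ndarray:
    """Power-law ladder T_n = (n / N_T)^exponent for n = 0 .. N_T.

    The default quartic spacing concentrates temperatures near the prior
    end, where the integrand of the thermodynamic identity varies fastest.
    """
    if n_temps < 2:
        raise ValueError("need at least 2 temperatures")
    return (np.arange(n_temps + 1) / n_temps) ** exponent


# ---------------------------------------------------------------------------
# target density plumbing
# ---------------------------------------------------------------------------


class _Target:
    """Log likelihood / log prior of a model-dataset pair as functions of a
    flat parameter vector, with positive parameters on the log scale."""

    def __init__(self, model, data: Dataset, prior: PriorSpec, sigma=None,
                 atol=1e-8, rtol=1e-9):
        self.model = model
        self.data = data
        self.prior = prior
        self.names = list(prior.names)
        self.positive = prior.positive_mask(self.names)
        self.fixed_sigma = sigma
        self.infer_sigma = "sigma" in self.names
        if not self.infer_sigma and sigma is None:
            raise ValueError("provide sigma or include 'sigma' in the prior")
        self.atol, self.rtol = atol, rtol
        self._y = data.values
        if isinstance(model, LinearBasisModel):
            self._B = model.design_matrix(data.frame["time"].to_numpy(dtype=float))
        else:
            self._points = data.design_points()
            # deduplicate simulation work: map data rows to unique points
            uniq: dict[tuple, int] = {}
            self._row_to_point = []
            self._uniq_points = []
            for p in self._points:
                key = (p.observable, p.condition, p.time)
                if key not in uniq:
                    uniq[key] = len(self._uniq_points)
                    self._uniq_points.append(p)
                self._row_to_point.append(uniq[key])
            self._row_to_point = np.asarray(self._row_to_point)

    # -- transforms ---------------------------------------------------------
    def to_z(self, theta: np.ndarray) -> np.ndarray:
        z = np.array(theta, dtype=float)
        z[self.positive] = np.log(z[self.positive])
        return z

    def to_theta(self, z: np.ndarray) -> np.ndarray:
        th = np.array(z, dtype=float)
        th[self.positive] = np.exp(th[self.positive])
        return th

    def log_jacobian(self, z: np.ndarray) -> float:
        # d theta / d z = theta for log-transformed entries
        return float(np.sum(z[self.positive]))

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, theta))

    # -- densities ----------------------------------------------------------
    def predictions(self, theta: np.ndarray) -> np.ndarray:
        if isinstance(self.model, LinearBasisModel):
            coef = np.array(
                [theta[self.names.index(n)] for n in self.model.parameter_names]
            )
            return self._B @ coef
        td = self.theta_dict(theta)
        preds = _predict_points(
            self.model, td, self._uniq_points, atol=self.atol, rtol=self.rtol
        )
        vals = np.array(
            [preds[(p.observable, p.condition, p.time)] for p in self._uniq_points]
        )
        return vals[self._row_to_point]

    def sigma_of(self, theta: np.ndarray) -> float:
        if self.infer_sigma:
            return float(theta[self.names.index("sigma")])
        return float(self.fixed_sigma)

    def loglik(self, theta: np.ndarray) -> float:
        sig = self.sigma_of(theta)
        if sig <= 0:
            return -np.inf
        try:
            pred = self.predictions(theta)
        except Exception:
            return -np.inf
        resid = self._y - pred
        n = len(resid)
        return float(
            -0.5 * np.sum((resid / sig) ** 2) - n * np.log(sig) - 0.5 * n * np.log(2 * np.pi)
        )

    def logprior(self, theta: np.ndarray) -> float:
        return self.prior.log_prior(self.theta_dict(theta))


# ---------------------------------------------------------------------------
# population MCMC
# ---------------------------------------------------------------------------


@dataclass
class TemperedChains:
    """Per-temperature chains from a population MCMC run.

    ``draws`` has shape (n_temps+1, n_kept, n_params) on the natural
    parameter scale; ``logliks``/``logpriors`` are the matching traces.
    """

    temperatures: np.ndarray
    param_names: list[str]
    draws: np.ndarray
    logliks: np.ndarray
    logpriors: np.ndarray
    acceptance: np.ndarray
    swap_acceptance: float
    seed: int
    model_name: str = "model"

    def chain_at_one(self) -> np.ndarray:
        return self.draws[-1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("temperatures", data=self.temperatures)
            f.create_dataset("draws", data=self.draws)
            f.create_dataset("logliks", data=self.logliks)
            f.create_dataset("logpriors", data=self.logpriors)
            f.create_dataset("acceptance", data=self.acceptance)
            f.attrs["swap_acceptance"] = self.swap_acceptance
            f.attrs["seed"] = self.seed
            f.attrs["model_name"] = self.model_name
            f.attrs["param_names"] = json.dumps(self.param_names)

    @classmethod
    def from_hdf5(cls, path) -> "TemperedChains":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                temperatures=f["temperatures"][...],
                param_names=json.loads(f.attrs["param_names"]),
                draws=f["draws"][...],
                logliks=f["logliks"][...],
                logpriors=f["logpriors"][...],
                acceptance=f["acceptance"][...],
                swap_acceptance=float(f.attrs["swap_acceptance"]),
                seed=int(f.attrs["seed"]),
                model_name=str(f.attrs["model_name"]),
            )


def _initial_point(target: _Target, rng: np.random.Generator, n_tries: int = 30):
    best, best_lp = None, -np.inf
    for _ in range(n_tries):
        theta = target.prior.sample(rng).as_array(target.names)
        lp = target.loglik(theta) + target.logprior(theta)
        if np.isfinite(lp) and lp > best_lp:
            best, best_lp = theta, lp
    if best is None:
        raise RuntimeError(
            "could not find a finite-posterior starting point from the prior; "
            "check the model/data/prior combination"
        )
    return best


def _proposal_chol(target: _Target, theta0: np.ndarray) -> np.ndarray:
    """Base proposal covariance from an approximate Hessian.

    Finite-difference Jacobian J of the model predictions with respect to
    the (log-transformed) parameters gives H ~ J'J / sigma^2 plus a unit
    prior precision; the proposal covariance is H^{-1}.  Falls back to the
    identity (prior-scale steps in z-space) when the approximation is not
    positive definite or the predictions fail.
    """
    n_p = len(theta0)
    z0 = target.to_z(theta0)
    try:
        f0 = target.predictions(theta0)
        sig = max(target.sigma_of(theta0), 1e-6)
        J = np.empty((len(f0), n_p))
        h = 1e-4
        for i in range(n_p):
            z = z0.copy()
            z[i] += h
            J[:, i] = (target.predictions(target.to_theta(z)) - f0) / h
        H = J.T @ J / sig**2 + np.eye(n_p)
        cov = np.linalg.inv(H)
        return np.linalg.cholesky(0.5 * (cov + cov.T))
    except Exception:
        return np.eye(n_p)


def population_mcmc(
    model,
    data: Dataset,
    prior: PriorSpec,
    n_temps: int = 40,
    n_samples: int = 10_000,
    seed: int = 0,
    sigma: float | None = None,
    burn_in: int | None = None,
    adapt_interval: int = 50,
    target_acceptance: float = 0.23,
    schedule_exponent: float = 4.0,
    swaps_per_sweep: int = 1,
    adapt_covariance: bool = True,
    atol: float = 1e-8,
    rtol: float = 1e-9,
) -> TemperedChains:
    """Population MCMC over the power-posterior ladder.

    Each sweep performs one Gaussian-proposal Metropolis update per
    temperature followed by ``swaps_per_sweep`` exchange attempts between
    random adjacent temperature pairs (exchange moves cost no likelihood
    evaluations).  The proposal covariance is seeded from an approximate
    Hessian and, with ``adapt_covariance``, replaced per temperature by
    the chain's own empirical covariance during burn-in; per-temperature
    step scaling is tuned toward ``target_acceptance`` at the same time.
    All adaptation is frozen after burn-in, so the retained chains are
    Markovian.  ``n_samples`` sweeps are retained after ``burn_in``
    (default: ``n_samples // 2``).  Reproducible given ``seed``.
    """
    if n_temps < 2:
        raise ValueError("n_temps must be >= 2")
    rng = np.random.default_rng(seed)
    target = _Target(model, data, prior, sigma=sigma, atol=atol, rtol=rtol)
    temps = temperature_schedule(n_temps, exponent=schedule_exponent)
    n_chains = len(temps)
    n_p = len(target.names)
    burn = n_samples // 2 if burn_in is None else burn_in

    theta0 = _initial_point(target, rng)
    chol = _proposal_chol(target, theta0)

    z = np.tile(target.to_z(theta0), (n_chains, 1))
    z += 0.01 * rng.standard_normal(z.shape)
    ll = np.empty(n_chains)
    lp = np.empty(n_chains)
    for c in range(n_chains):
        th = target.to_theta(z[c])
        ll[c] = target.loglik(th)
        lp[c] = target.logprior(th) + target.log_jacobian(z[c])
    if not np.all(np.isfinite(lp)):
        raise RuntimeError("non-finite posterior at initialization")

    chols = [chol.copy() for _ in range(n_chains)]
    scales = np.full(n_chains, 2.38 / np.sqrt(n_p))
    acc = np.zeros(n_chains)
    acc_window = np.zeros(n_chains)
    swap_acc = 0
    swap_tries = 0

    kept_draws = np.empty((n_chains, n_samples, n_p))
    kept_ll = np.empty((n_chains, n_samples))
    kept_lp = np.empty((n_chains, n_samples))
    burn_hist = np.empty((n_chains, burn, n_p)) if burn > 0 else None

    total = burn + n_samples
    stall = 0
    for it in range(total):
        # Metropolis-within-temperature
        steps = rng.standard_normal((n_chains, n_p))
        logu = np.log(rng.random(n_chains))
        accepted_any = False
        for c in range(n_chains):
            z_new = z[c] + scales[c] * (chols[c] @ steps[c])
            th_new = target.to_theta(z_new)
            lp_new = target.logprior(th_new) + target.log_jacobian(z_new)
            if not np.isfinite(lp_new):
                continue
            ll_new = target.loglik(th_new)
            log_alpha = temps[c] * (ll_new - ll[c]) + (lp_new - lp[c])
            if logu[c] < log_alpha:
                z[c], ll[c], lp[c] = z_new, ll_new, lp_new
                acc[c] += 1
                acc_window[c] += 1
                accepted_any = True
        stall = 0 if accepted_any else stall + 1
        if stall > 500:
            raise RuntimeError(
                "sampler stalled: 500 consecutive all-rejection sweeps; "
                f"last state {target.theta_dict(target.to_theta(z[-1]))}"
            )

        # exchange moves between random adjacent pairs
        for _ in range(max(swaps_per_sweep, 0)):
            j = int(rng.integers(0, n_chains - 1))
            log_alpha = (temps[j + 1] - temps[j]) * (ll[j] - ll[j + 1])
            swap_tries += 1
            if np.log(rng.random()) < log_alpha:
                z[[j, j + 1]] = z[[j + 1, j]]
                ll[[j, j + 1]] = ll[[j + 1, j]]
                lp[[j, j + 1]] = lp[[j + 1, j]]
                swap_acc += 1

        # adaptation, burn-in only
        if it < burn:
            burn_hist[:, it] = z
            if (it + 1) % adapt_interval == 0:
                rates = acc_window / adapt_interval
                scales *= np.exp(0.66 * (rates - target_acceptance))
                acc_window[:] = 0.0
                if adapt_covariance and it + 1 >= max(10 * n_p, 200):
                    lo = max(0, it + 1 - 2000)
                    for c in range(n_chains):
                        emp = np.cov(burn_hist[c, lo : it + 1].T)
                        emp = np.atleast_2d(emp) + 1e-8 * np.eye(n_p)
                        try:
                            chols[c] = np.linalg.cholesky(emp)
                        except np.linalg.LinAlgError:
                            pass

        if it >= burn:
            k = it - burn
            th_all = z.copy()
            th_all[:, target.positive] = np.exp(th_all[:, target.positive])
            kept_draws[:, k] = th_all
            kept_ll[:, k] = ll
            # lp holds log prior + log Jacobian; strip the Jacobian back off
            kept_lp[:, k] = lp - z[:, target.positive].sum(axis=1)

    return TemperedChains(
        temperatures=temps,
        param_names=target.names,
        draws=kept_draws,
        logliks=kept_ll,
        logpriors=kept_lp,
        acceptance=acc / total,
        swap_acceptance=swap_acc / max(swap_tries, 1),
        seed=seed,
        model_name=getattr(model, "name", "model"),
    )


# ---------------------------------------------------------------------------
# posterior sample / thinning
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """Thinned draws from the temperature-1 chain."""

    draws: np.ndarray
    param_names: list[str]
    model_name: str = "model"
    ess: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def as_parameter_vectors(self) -> list[ParameterVector]:
        return [
            ParameterVector(dict(zip(self.param_names, row))) for row in self.draws
        ]


def thin(chains: TemperedChains, target: int = 10_000) -> PosteriorSample:
    """Evenly-strided subsample of exactly ``target`` draws from the
    temperature-1 chain."""
    full = chains.chain_at_one()
    n = full.shape[0]
    if n < target:
        raise ValueError(
            f"chain has {n} post-burn-in draws; need at least {target} "
            f"(run n_samples >= {target})"
        )
    idx = np.floor(np.linspace(0, n - 1, target)).astype(int)
    draws = full[idx]
    ess = {}
    try:
        import arviz as az

        for i, name in enumerate(chains.param_names):
            ess[name] = float(az.ess(draws[:, i][None, :]))
    except Exception:
        pass
    return PosteriorSample(
        draws=draws,
        param_names=list(chains.param_names),
        model_name=chains.model_name,
        ess=ess,
    )


# ---------------------------------------------------------------------------
# propriety check
# ---------------------------------------------------------------------------


class FlatPrior:
    """Improper flat prior (log density 0 everywhere); only meaningful
    inside the propriety check."""

    positive = False

    def logpdf(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def sample(self, rng, size=None):
        raise NotImplementedError("improper prior cannot be sampled")

    mean = 0.0
    variance = np.inf


@dataclass
class ProfileReport:
    """Profile of likelihood x prior along one parameter."""

    parameter: str
    grid: np.ndarray
    log_profile: np.ndarray
    flag: str  # "proper" | "improper"
    n_failed: int = 0

    @property
    def proper(self) -> bool:
        return self.flag == "proper"


def check_propriety(
    model,
    data: Dataset,
    prior: PriorSpec,
    parameter: str,
    grid,
    sigma: float | None = None,
    drop_threshold: float = 3.0,
) -> ProfileReport:
    """Profile likelihood x prior along one parameter before sampling.

    At each grid value the named parameter is fixed and the log of
    likelihood times prior is maximized over the remaining parameters
    (Nelder-Mead in the transformed space).  The posterior is flagged
    proper when the profile has dropped by at least ``drop_threshold``
    nats from its maximum at both grid ends -- a flat tail signals an
    improper (unnormalizable) direction.
    """
    target = _Target(model, data, prior, sigma=sigma)
    idx = target.names.index(parameter)
    others = [i for i in range(len(target.names)) if i != idx]

    try:
        theta0 = _initial_point(target, np.random.default_rng(0))
    except (NotImplementedError, RuntimeError):
        means = []
        for n in target.names:
            m = getattr(prior.priors[n], "mean", 1.0)
            means.append(1.0 if not np.isfinite(m) else max(m, 1e-3))
        theta0 = np.array(means, dtype=float)
    z0 = target.to_z(theta0)

    grid = np.asarray(grid, dtype=float)
    prof = np.full(len(grid), np.nan)
    n_failed = 0
    for gi, gval in enumerate(grid):
        theta_fix = theta0.copy()
        theta_fix[idx] = gval
        if not others:
            val = target.loglik(theta_fix) + target.logprior(theta_fix)
            prof[gi] = val
            continue

        def neg(z_free):
            z = z0.copy()
            z[others] = z_free
            th = target.to_theta(z)
            th[idx] = gval
            v = target.loglik(th) + target.logprior(th)
            return -v if np.isfinite(v) else 1e12

        try:
            res = optimize.minimize(neg, z0[others], method="Nelder-Mead",
                                    options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-7})
            prof[gi] = -res.fun
        except Exception:
            n_failed += 1
    finite = np.isfinite(prof)
    if finite.sum() < 3:
        return ProfileReport(parameter, grid, prof, "improper", n_failed)
    peak = np.nanmax(prof[finite])
    left = prof[finite][0]
    right = prof[finite][-1]
    flag = "proper" if (peak - left >= drop_threshold and peak - right >= drop_threshold) else "improper"
    return ProfileReport(parameter, grid, prof, flag, n_failed)
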