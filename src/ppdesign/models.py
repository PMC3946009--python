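"""Simulable model objects and synthetic data generation.

Two model families are supported:

* :class:`LinearBasisModel` -- regression models ``y(t) = sum_i theta_i B_i(t) + eps``
  with Gaussian noise, for which posteriors and marginal likelihoods are
  available in closed form.
* :class:`OdeModel` -- systems of ODEs ``dx/dt = f(x, u, p)`` with a
  piecewise-constant input ``u`` per experimental condition and an
  observation map ``g`` producing named observables.

Both share the independent-Gaussian error model: the likelihood of a
dataset factorizes over time series and time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import odeint

__all__ = [
    "STEADY_STATE",
    "ParameterVector",
    "DesignPoint",
    "Dataset",
    "GammaPrior",
    "GaussianPrior",
    "HalfNormalPrior",
    "PriorSpec",
    "LinearBasisModel",
    "OdeModel",
    "BASIS_REGISTRY",
    "make_basis",
    "simulate_linear",
    "simulate_ode",
    "steady_state",
    "log_likelihood",
    "log_prior",
    "generate_data",
]

#: Sentinel for "measure after the system has relaxed to steady state".
STEADY_STATE = "steady-state"

#: Encoding of the steady-state sentinel in tabular/CSV form.
_STEADY_TIME_CODE = -1.0


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------


@dataclass
class ParameterVector:
    """Named parameter set: everything needed to simulate a model.

    ``values`` maps parameter names (kinetic rates ``p``, observation
    scaling/offset ``r``, initial conditions ``x0`` and optionally the
    noise scale ``sigma``) to real numbers.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {name!r} is not finite: {v}")

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.values]
        if missing:
            raise KeyError(f"missing parameters: {missing}")
        return np.array([self.values[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)


class GammaPrior:
    """Gamma prior for positive-constrained parameters.

    The shape--scale convention is the default: ``alpha=1, beta=3`` is an
    exponential with mean 3, a weakly informative choice that admits
    rates spanning several decades without being so vague that the
    simplest model always wins the evidence comparison (Lindley's
    paradox).  Set ``rate_convention=True`` to read ``beta`` as a rate.
    """

    positive = True

    def __init__(self, alpha: float = 1.0, beta: float = 3.0, rate_convention: bool = False):
        if alpha <= 0 or beta <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.scale = 1.0 / beta if rate_convention else beta
        self._dist = stats.gamma(a=alpha, scale=self.scale)
        self._lognorm = math.lgamma(alpha) + alpha * math.log(self.scale)

    def logpdf(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (self.alpha - 1.0) * np.log(x) - x / self.scale - self._lognorm
        return np.where(x > 0, lp, -np.inf)

    def sample(self, rng: np.random.Generator, size=None):
        return self._dist.rvs(size=size, random_state=rng)

    @property
    def variance(self) -> float:
        return self._dist.var()

    @property
    def mean(self) -> float:
        return self._dist.mean()


class GaussianPrior:
    """Zero-mean Gaussian prior with standard deviation ``xi`` (linear-model
    coefficients)."""

    positive = False

    def __init__(self, xi: float = 1.0):
        if xi <= 0:
            raise ValueError("prior standard deviation must be positive")
        self.xi = float(xi)
        self._dist = stats.norm(scale=xi)
        self._lognorm = math.log(xi) + 0.5 * math.log(2 * math.pi)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return -0.5 * (x / self.xi) ** 2 - self._lognorm

    def sample(self, rng, size=None):
        return self._dist.rvs(size=size, random_state=rng)

    @property
    def variance(self) -> float:
        return self.xi**2

    @property
    def mean(self) -> float:
        return 0.0


class HalfNormalPrior:
    """Broad positive-scale prior, used by default for an inferred noise
    sigma."""

    positive = True

    def __init__(self, scale: float = 1.0):
        if scale <= 0:
            raise ValueError("half-normal scale must be positive")
        self.scale_param = float(scale)
        self._dist = stats.halfnorm(scale=scale)
        self._lognorm = 0.5 * math.log(2.0 / math.pi) - math.log(scale)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        lp = self._lognorm - 0.5 * (x / self.scale_param) ** 2
        return np.where(x > 0, lp, -np.inf)

    def sample(self, rng, size=None):
        return self._dist.rvs(size=size, random_state=rng)

    @property
    def variance(self) -> float:
        return self._dist.var()

    @property
    def mean(self) -> float:
        return self._dist.mean()


@dataclass
class PriorSpec:
    """Per-parameter independent prior distributions.

    ``priors`` maps each parameter name to a distribution object exposing
    ``logpdf``, ``sample``, ``mean``, ``variance`` and a ``positive``
    support flag.
    """

    priors: dict[str, object]

    @property
    def names(self) -> list[str]:
        return list(self.priors)

    def log_prior(self, theta: ParameterVector | Mapping[str, float]) -> float:
        values = theta.values if isinstance(theta, ParameterVector) else theta
        total = 0.0
        for name, prior in self.priors.items():
            lp = float(prior.logpdf(values[name]))
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def sample(self, rng: np.random.Generator) -> ParameterVector:
        return ParameterVector({n: float(p.sample(rng)) for n, p in self.priors.items()})

    def positive_mask(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.priors[n].positive for n in names], dtype=bool)


def log_prior(theta: ParameterVector | Mapping[str, float], prior: PriorSpec) -> float:
    """Sum of per-parameter log prior densities; ``-inf`` outside support."""
    return prior.log_prior(theta)


# ---------------------------------------------------------------------------
# design points and datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignPoint:
    """One candidate observation: which observable, when, under which
    condition (stimulus level)."""

    observable: str
    time: float | str
    condition: str = "1"

    def __post_init__(self):
        if self.time != STEADY_STATE:
            t = float(self.time)
            if not np.isfinite(t):
                raise ValueError(f"time must be finite or {STEADY_STATE!r}, got {t}")
            # negative times are legal for regression-style models where time
            # is just a covariate; ODE simulation enforces t >= 0 itself
            object.__setattr__(self, "time", t)

    @property
    def is_steady(self) -> bool:
        return self.time == STEADY_STATE

    @property
    def label(self) -> str:
        t = "ss" if self.is_steady else f"t={self.time:g}"
        return f"{self.observable}|u{self.condition}|{t}"


class Dataset:
    """Tabular time-series measurements.

    Wraps a :class:`pandas.DataFrame` with columns ``observable``,
    ``condition``, ``time``, ``steady``, ``replicate`` and ``value``.
    Steady-state measurements carry ``steady=True`` and are encoded with
    ``time=-1`` on disk.
    """

    COLUMNS = ["observable", "condition", "time", "steady", "replicate", "value"]

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if len(df) == 0:
            df = pd.DataFrame(
                {
                    "observable": pd.Series(dtype=str),
                    "condition": pd.Series(dtype=str),
                    "time": pd.Series(dtype=float),
                    "steady": pd.Series(dtype=bool),
                    "replicate": pd.Series(dtype=int),
                    "value": pd.Series(dtype=float),
                }
            )
        if "steady" not in df.columns:
            df["steady"] = False
        if "condition" not in df.columns:
            df["condition"] = "1"
        df["condition"] = df["condition"].astype(str)
        df = df[self.COLUMNS]
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("dataset contains non-finite values")
        key = df[["observable", "condition", "time", "steady", "replicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (observable, condition, time, replicate) records")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Dataset":
        """Records of (observable, condition, time, replicate, value); time may
        be the steady-state sentinel."""
        rows = []
        for obs, cond, time, rep, value in records:
            steady = time == STEADY_STATE
            rows.append(
                {
                    "observable": obs,
                    "condition": str(cond),
                    "time": _STEADY_TIME_CODE if steady else float(time),
                    "steady": steady,
                    "replicate": int(rep),
                    "value": float(value),
                }
            )
        return cls(pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    def design_points(self) -> list[DesignPoint]:
        pts = []
        for _, row in self.frame.iterrows():
            t = STEADY_STATE if row["steady"] else float(row["time"])
            pts.append(DesignPoint(row["observable"], t, row["condition"]))
        return pts

    def concat(self, other: "Dataset") -> "Dataset":
        a, b = self.frame, other.frame.copy()
        # shift replicate indices so the merged key set stays unique
        key_cols = ["observable", "condition", "time", "steady"]
        shift = a.groupby(key_cols)["replicate"].max().rename("r0")
        b = b.merge(shift, on=key_cols, how="left")
        b["replicate"] = b["replicate"] + b["r0"].fillna(-1) + 1
        b = b.drop(columns="r0")
        return Dataset(pd.concat([a, b], ignore_index=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        if "steady" in df.columns:
            df["steady"] = df["steady"].astype(bool)
        else:
            df["steady"] = df["time"] == _STEADY_TIME_CODE
        return cls(df)


# ---------------------------------------------------------------------------
# linear basis-function models
# ---------------------------------------------------------------------------


def _poly(a: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.asarray(t, dtype=float) ** a


def _sin_scaled(b: float, s: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.sin(b * np.asarray(t, dtype=float)) / s


def _sin_poly(b: float, c: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.sin(b * np.asarray(t, dtype=float)) * np.asarray(t, dtype=float) ** c


#: Registry of basis-function constructors for declarative model configs.
#: ``poly(a)`` is t^a, ``sin_scaled(b, s)`` is sin(b t)/s and
#: ``sin_poly(b, c)`` is sin(b t) * t^c.
BASIS_REGISTRY: dict[str, Callable[..., Callable]] = {
    "poly": _poly,
    "sin_scaled": _sin_scaled,
    "sin_poly": _sin_poly,
}


def make_basis(kind: str, *args: float) -> tuple[str, Callable]:
    """Instantiate a named basis function from the registry."""
    if kind not in BASIS_REGISTRY:
        raise KeyError(f"unknown basis kind {kind!r}; known: {sorted(BASIS_REGISTRY)}")
    label = f"{kind}({', '.join(f'{a:g}' for a in args)})"
    return label, BASIS_REGISTRY[kind](*args)


@dataclass
class LinearBasisModel:
    """``y(t) = sum_i theta_i B_i(t) + eps`` with L basis functions."""

    basis: list[tuple[str, Callable]]
    name: str = "linear"
    observable: str = "y"

    def __post_init__(self):
        if len(self.basis) < 1:
            raise ValueError("need at least one basis function")

    @property
    def n_params(self) -> int:
        return len(self.basis)

    @property
    def parameter_names(self) -> list[str]:
        return [f"theta_{i + 1}" for i in range(len(self.basis))]

    def design_matrix(self, times: Sequence[float]) -> np.ndarray:
        """Evaluate all basis functions at ``times``; rows = time points."""
        t = np.asarray(times, dtype=float)
        cols = []
        for i, (label, fn) in enumerate(self.basis):
            with np.errstate(all="ignore"):
                v = np.asarray(fn(t), dtype=float)
            if not np.isfinite(v).all():
                bad = t[~np.isfinite(v)][0]
                raise FloatingPointError(
                    f"basis {i + 1} ({label}) is non-finite at t={bad}"
                )
            cols.append(np.broadcast_to(v, t.shape))
        return np.column_stack(cols)

    def default_prior(self, xi: float = 1.0) -> PriorSpec:
        return PriorSpec({n: GaussianPrior(xi) for n in self.parameter_names})


def simulate_linear(
    model: LinearBasisModel,
    theta: ParameterVector | Sequence[float],
    times: Sequence[float],
) -> np.ndarray:
    """Noise-free predicted means ``sum_i theta_i B_i(t)`` at each requested time."""
    if isinstance(theta, ParameterVector):
        coef = theta.as_array(model.parameter_names)
    else:
        coef = np.asarray(theta, dtype=float)
    if coef.shape != (model.n_params,):
        raise ValueError(
            f"expected {model.n_params} coefficients, got shape {coef.shape}"
        )
    return model.design_matrix(times) @ coef


# ---------------------------------------------------------------------------
# ODE models
# ---------------------------------------------------------------------------


class SimulationError(RuntimeError):
    """Integrator failure; carries the offending parameters and condition."""

    def __init__(self, message: str, theta=None, condition=None):
        super().__init__(message)
        self.theta = theta
        self.condition = condition


@dataclass
class OdeModel:
    """ODE model ``dx/dt = f(x, u, p)`` with observation map ``g``.

    ``rhs(x, u, p)`` takes the state vector, the scalar input level of the
    active condition and the kinetic-parameter vector (ordered as
    ``parameter_names``) and returns dx/dt.  ``observables`` maps each
    measurable name to a function of the state-trajectory columns (a dict
    name -> 1-D array); the default identity readout is declared by
    listing state names.  ``conditions`` maps condition identifiers to
    constant input levels u.
    """

    name: str
    state_names: list[str]
    parameter_names: list[str]
    rhs: Callable[[np.ndarray, float, np.ndarray], np.ndarray]
    x0: np.ndarray
    conditions: dict[str, float] = field(default_factory=lambda: {"1": 1.0, "2": 2.0})
    observables: dict[str, Callable[[dict], np.ndarray]] | None = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (len(self.state_names),):
            raise ValueError("x0 length must match state_names")
        if self.observables is None:
            self.observables = {
                s: (lambda cols, _s=s: cols[_s]) for s in self.state_names
            }

    @property
    def observable_names(self) -> list[str]:
        return list(self.observables)

    def input_level(self, condition: str) -> float:
        try:
            return float(self.conditions[str(condition)])
        except KeyError:
            raise KeyError(
                f"model {self.name!r} has no condition {condition!r}; "
                f"known: {sorted(self.conditions)}"
            ) from None

    def kinetic_array(self, theta: ParameterVector | Mapping[str, float]) -> np.ndarray:
        if isinstance(theta, ParameterVector):
            return theta.as_array(self.parameter_names)
        return np.array([theta[n] for n in self.parameter_names], dtype=float)

    def observe(self, states: np.ndarray) -> dict[str, np.ndarray]:
        """Apply g to a trajectory (rows = times, columns = states)."""
        cols = {s: states[:, i] for i, s in enumerate(self.state_names)}
        return {name: np.asarray(fn(cols), dtype=float) for name, fn in self.observables.items()}


def _integrate(model, p, u, t_eval, atol, rtol, theta, condition):
    t = np.asarray(t_eval, dtype=float)
    with np.errstate(all="ignore"):
        states, info = odeint(
            lambda x, _t: model.rhs(x, u, p),
            model.x0,
            t,
            atol=atol,
            rtol=rtol,
            mxstep=10_000,
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.isfinite(states).all():
        raise SimulationError(
            f"integration failed for model {model.name!r}: {info['message']}",
            theta=theta,
            condition=condition,
        )
    return states


def simulate_ode(
    model: OdeModel,
    theta: ParameterVector | Mapping[str, float],
    condition: str,
    times: Sequence[float],
    atol: float = 1e-8,
    rtol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate the model under one condition and apply the observation map.

    Returns a DataFrame indexed by time with one column per observable.
    ``times`` must be sorted ascending and nonnegative.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    u = model.input_level(condition)
    p = model.kinetic_array(theta)
    # solve_ivp will not evaluate at t=0 unless requested explicitly; prepend it
    needs_zero = len(t) == 0 or t[0] > 0
    t_eval = np.concatenate([[0.0], t]) if needs_zero else t
    states = _integrate(model, p, u, t_eval, atol, rtol, theta, condition)
    if needs_zero:
        states = states[1:]
    obs = model.observe(states)
    return pd.DataFrame(obs, index=t)


def steady_state(
    model: OdeModel,
    theta: ParameterVector | Mapping[str, float],
    condition: str,
    t_horizon: float = 1000.0,
    atol: float = 1e-8,
    rtol: float = 1e-9,
    derivative_tol: float = 1e-8,
    max_doublings: int = 6,
) -> dict[str, float]:
    """Observables after relaxation: integrate to ``t_horizon`` and accept when
    ``max|dx/dt| < derivative_tol * max(|x|, 1)``, doubling the horizon until
    converged."""
    u = model.input_level(condition)
    p = model.kinetic_array(theta)
    horizon = float(t_horizon)
    for _ in range(max_doublings):
        states = _integrate(model, p, u, [0.0, horizon], atol, rtol, theta, condition)
        x = states[-1]
        rate = np.max(np.abs(model.rhs(x, u, p)))
        if rate < derivative_tol * max(np.max(np.abs(x)), 1.0):
            obs = model.observe(states[-1:][:])
            return {name: float(v[0]) for name, v in obs.items()}
        horizon *= 2.0
    raise SimulationError(
        f"model {model.name!r} did not reach steady state by t={horizon / 2:g}",
        theta=theta,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# likelihood and data generation
# ---------------------------------------------------------------------------


def log_likelihood(
    data: Dataset,
    predictions: Mapping[tuple, float] | np.ndarray,
    sigma: float | Mapping[str, float],
) -> float:
    """Gaussian log likelihood of the dataset given point predictions.

    The independence assumption makes the likelihood a product over time
    series and time points, so the log likelihood is a plain sum of
    per-point Gaussian log densities of the residuals.

    ``predictions`` is either an array aligned with the dataset rows or a
    mapping keyed by ``(observable, condition, time-or-sentinel)``.
    ``sigma`` may be a scalar or a per-observable mapping.
    """
    df = data.frame
    if isinstance(predictions, Mapping):
        pred = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            t = STEADY_STATE if row.steady else float(row.time)
            key = (row.observable, row.condition, t)
            if key not in predictions:
                raise KeyError(f"no prediction for data record {key}")
            pred[i] = predictions[key]
    else:
        pred = np.asarray(predictions, dtype=float)
        if pred.shape != (len(df),):
            raise ValueError("prediction array must align with dataset rows")
    if isinstance(sigma, Mapping):
        sig = df["observable"].map(sigma).to_numpy(dtype=float)
    else:
        sig = np.full(len(df), float(sigma))
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    resid = df["value"].to_numpy(dtype=float) - pred
    return float(np.sum(-0.5 * (resid / sig) ** 2 - np.log(sig) - 0.5 * math.log(2 * math.pi)))


def _predict_points(model, theta, points: Sequence[DesignPoint], atol=1e-8, rtol=1e-9):
    """Noise-free model predictions at arbitrary design points, grouped by
    condition to share integrations."""
    out: dict[tuple, float] = {}
    if isinstance(model, LinearBasisModel):
        times = [p.time for p in points]
        if any(p.is_steady for p in points):
            raise ValueError("linear basis models have no steady state")
        vals = simulate_linear(model, theta, times)
        for p, v in zip(points, vals):
            out[(p.observable, p.condition, p.time)] = float(v)
        return out
    by_cond: dict[str, list[DesignPoint]] = {}
    for p in points:
        by_cond.setdefault(p.condition, []).append(p)
    for cond, pts in by_cond.items():
        timed = sorted({p.time for p in pts if not p.is_steady})
        if timed:
            traj = simulate_ode(model, theta, cond, timed, atol=atol, rtol=rtol)
            for p in pts:
                if not p.is_steady:
                    out[(p.observable, cond, p.time)] = float(
                        traj.loc[p.time, p.observable]
                    )
        if any(p.is_steady for p in pts):
            ss = steady_state(model, theta, cond, atol=atol, rtol=rtol)
            for p in pts:
                if p.is_steady:
                    out[(p.observable, cond, STEADY_STATE)] = ss[p.observable]
    return out


def generate_data(
    model,
    theta_true: ParameterVector,
    design: Sequence[tuple[DesignPoint, int]],
    sigma: float,
    seed: int | np.random.Generator,
    atol: float = 1e-8,
    rtol: float = 1e-9,
) -> Dataset:
    """Simulate the model at the design points and add i.i.d. Gaussian noise.

    ``design`` is a sequence of (DesignPoint, replicate count).  Reproducible
    given the seed; ``sigma=0`` returns the noise-free simulation.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    points = [p for p, _ in design]
    preds = _predict_points(model, theta_true, points, atol=atol, rtol=rtol)
    records = []
    for point, n_rep in design:
        key = (point.observable, point.condition, point.time)
        mu = preds[key]
        noise = rng.normal(0.0, sigma, size=n_rep) if sigma > 0 else np.zeros(n_rep)
        for r in range(n_rep):
            records.append((point.observable, point.condition, point.time, r, mu + noise[r]))
    return Dataset.from_records(records)


def regular_design(
    observable: str,
    times: Sequence[float],
    n_replicates: int = 1,
    condition: str = "1",
) -> list[tuple[DesignPoint, int]]:
    """Convenience: the same replicate count at every time of one observable."""
    return [(DesignPoint(observable, t, condition), n_replicates) for t in times]
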