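"""Posterior predictive samples for candidate experiments.

A candidate experiment is an ordered list of d design points (observable,
condition, time or steady-state).  Its posterior predictive sample under a
model is the N x d matrix obtained by simulating the model at those points
for every posterior parameter draw and adding measurement noise drawn from
the error model -- future observations will be noisy too, so the noise
belongs in the predictive density used for design.  When the noise sd was
inferred, each row uses its own draw's sigma, propagating the full
uncertainty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .inference import GaussianPosterior, PosteriorSample
from .models import (
    DesignPoint,
    LinearBasisModel,
    _predict_points,
)

__all__ = [
    "CandidateExperiment",
    "PredictiveSample",
    "CandidateColumnSource",
    "sample_ppd",
    "enumerate_candidates",
    "build_column_source",
]


@dataclass(frozen=True)
class CandidateExperiment:
    """An ordered combination of d >= 1 design points.

    Duplicated points are legal and mean a replicate measurement of the
    same quantity (with independent noise).
    """

    points: tuple[DesignPoint, ...]
    label: str = ""

    def __post_init__(self):
        pts = tuple(self.points)
        if len(pts) < 1:
            raise ValueError("a candidate needs at least one design point")
        object.__setattr__(self, "points", pts)
        if not self.label:
            object.__setattr__(self, "label", " + ".join(p.label for p in pts))

    @property
    def d(self) -> int:
        return len(self.points)


@dataclass
class PredictiveSample:
    """N x d matrix of predicted observation values for one candidate."""

    model_name: str
    candidate: CandidateExperiment
    matrix: np.ndarray
    noise_included: bool
    seed: int | None = None
    n_dropped: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.candidate.d:
            raise ValueError("matrix must be N x d with d matching the candidate")
        if not np.isfinite(self.matrix).all():
            raise ValueError("predictive sample contains non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, columns=[p.label for p in self.candidate.points]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _noise_matrix(rng, sigmas, shape):
    """Independent Gaussian noise; ``sigmas`` is a scalar or per-row vector."""
    eps = rng.standard_normal(shape)
    sig = np.asarray(sigmas, dtype=float)
    if sig.ndim == 0:
        return eps * float(sig)
    return eps * sig[:, None]


def sample_ppd(
    posterior,
    model,
    candidate: CandidateExperiment,
    sigma: float | None = None,
    noise: bool = True,
    seed: int | np.random.Generator = 0,
    n: int | None = None,
    log_transform: bool = False,
    atol: float = 1e-8,
    rtol: float = 1e-9,
    max_drop_fraction: float = 0.01,
) -> PredictiveSample:
    """Draw a posterior predictive sample for one candidate experiment.

    ``posterior`` is either a :class:`GaussianPosterior` (linear model;
    ``n`` draws are taken from it, ``sigma`` must be given) or a
    :class:`PosteriorSample` (one row per retained draw; ``sigma`` falls
    back to each draw's inferred value when present).  With
    ``log_transform`` the strictly positive noiseless predictions are
    log-transformed before noise is added on that scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = list(candidate.points)

    if isinstance(posterior, GaussianPosterior):
        if not isinstance(model, LinearBasisModel):
            raise TypeError("GaussianPosterior goes with a LinearBasisModel")
        if sigma is None:
            raise ValueError("sigma is required for the analytic path")
        if n is None:
            raise ValueError("n (number of predictive draws) is required")
        times = np.array([p.time for p in pts], dtype=float)
        B_c = model.design_matrix(times)
        draws = posterior.sample(n, rng)
        preds = draws @ B_c.T
        sigmas: float | np.ndarray = float(sigma)
        n_dropped = 0
    elif isinstance(posterior, PosteriorSample):
        rows = []
        sig_rows = []
        n_dropped = 0
        has_sigma = "sigma" in posterior.param_names
        if sigma is None and not has_sigma:
            raise ValueError("sigma not inferred; pass it explicitly")
        for i in range(len(posterior)):
            theta = dict(zip(posterior.param_names, posterior.draws[i]))
            try:
                pred_map = _predict_points(model, theta, pts, atol=atol, rtol=rtol)
            except Exception:
                n_dropped += 1
                continue
            rows.append([pred_map[(p.observable, p.condition, p.time)] for p in pts])
            sig_rows.append(theta["sigma"] if has_sigma else float(sigma))
        if n_dropped > max_drop_fraction * len(posterior):
            raise RuntimeError(
                f"{n_dropped}/{len(posterior)} predictive draws failed to simulate"
            )
        preds = np.asarray(rows, dtype=float)
        sigmas = np.asarray(sig_rows, dtype=float)
    else:
        raise TypeError(f"unsupported posterior type {type(posterior).__name__}")

    if log_transform:
        if np.any(preds <= 0):
            raise ValueError("log transform requires strictly positive predictions")
        preds = np.log(preds)

    if noise:
        preds = preds + _noise_matrix(rng, sigmas, preds.shape)

    return PredictiveSample(
        model_name=getattr(model, "name", "model"),
        candidate=candidate,
        matrix=preds,
        noise_included=noise,
        n_dropped=n_dropped,
    )


def enumerate_candidates(
    observables,
    times,
    conditions=("1",),
    d: int = 1,
    cap: int = 50_000,
) -> list[CandidateExperiment]:
    """All unordered size-d combinations (with repetition) of the
    observable x time x condition grid.

    Repetition is allowed so that replicate measurements of the same point
    can be represented.  Designs beyond d=3 are rarely useful because the
    neighbor-distance density estimates degrade with dimension.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    grid = [
        DesignPoint(obs, t, cond)
        for obs in observables
        for cond in conditions
        for t in times
    ]
    m = len(grid)
    n_combos = comb(m + d - 1, d)
    if n_combos > cap:
        raise ValueError(
            f"{n_combos} candidates exceed the cap of {cap}; coarsen the grid "
            "or lower d"
        )
    return [
        CandidateExperiment(points=pts)
        for pts in itertools.combinations_with_replacement(grid, d)
    ]


# ---------------------------------------------------------------------------
# column source for design matrices
# ---------------------------------------------------------------------------


@dataclass
class CandidateColumnSource:
    """Noiseless predictions over a grid of single design points, from which
    noisy candidate columns are drawn on demand.

    Design matrices evaluate many candidates sharing the same grid points;
    simulating once and adding fresh noise per requested column keeps
    replicate measurements (the same grid point twice) independent, as they
    would be in the laboratory.
    """

    model_name: str
    grid: list[DesignPoint]
    noiseless: np.ndarray  # N x m
    sigmas: np.ndarray | float

    def __post_init__(self):
        self.noiseless = np.asarray(self.noiseless, dtype=float)
        if self.noiseless.shape[1] != len(self.grid):
            raise ValueError("noiseless matrix must have one column per grid point")

    @property
    def n(self) -> int:
        return self.noiseless.shape[0]

    def columns(self, indices, rng, noise: bool = True) -> np.ndarray:
        """N x len(indices) matrix; repeated indices get independent noise."""
        idx = list(indices)
        out = self.noiseless[:, idx].copy()
        if noise:
            out += _noise_matrix(rng, self.sigmas, out.shape)
        return out

    def candidate(self, indices) -> CandidateExperiment:
        return CandidateExperiment(points=tuple(self.grid[i] for i in indices))


def build_column_source(
    posterior,
    model,
    grid,
    sigma: float | None = None,
    seed: int | np.random.Generator = 0,
    n: int | None = None,
    atol: float = 1e-8,
    rtol: float = 1e-9,
) -> CandidateColumnSource:
    """Simulate the noiseless prediction matrix over a grid of single design
    points (one shared simulation pass per posterior draw)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = list(grid)
    cand = CandidateExperiment(points=tuple(grid))
    ps = sample_ppd(
        posterior,
        model,
        cand,
        sigma=sigma if sigma is not None else 1.0,
        noise=False,
        seed=rng,
        n=n,
        atol=atol,
        rtol=rtol,
    )
    if isinstance(posterior, PosteriorSample) and "sigma" in posterior.param_names:
        if ps.n_dropped:
            raise RuntimeError(
                "dropped draws would misalign per-draw sigmas with the "
                "prediction matrix; rerun with a more robust posterior sample"
            )
        sigmas: np.ndarray | float = posterior.column("sigma")
    else:
        if sigma is None:
            raise ValueError("sigma required when not inferred")
        sigmas = float(sigma)
    return CandidateColumnSource(
        model_name=getattr(model, "name", "model"),
        grid=grid,
        noiseless=ps.matrix,
        sigmas=sigmas,
    )
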