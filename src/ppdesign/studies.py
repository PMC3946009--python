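"""Benchmark model suites and end-to-end validation studies.

Two packaged studies validate the design criterion:

* the *linear study*: randomly generated pairs of linear basis-function
  models, where posteriors, predictive densities and marginal likelihoods
  are analytic, so the kNN-JSD of every candidate measurement can be
  compared against the Monte-Carlo expected change in log10 Bayes factor
  toward the true model (their Spearman rank correlation is the headline
  summary);
* the *motif study*: four ODE models of a phosphorylation cascade that
  differ only in the origin and point of action of a negative feedback
  loop, fit by population MCMC to a shared noisy dataset, with design
  matrices over combinations of two measurements and three named
  validation experiments.

The motif equations here are this package's own reconstruction of a
feedback-motif benchmark (mass action cascade with complex formation and
saturating inhibition); they are synthetic models built to exercise the
method, not measurements of any real pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .divergence import knn_jsd
from .evidence import analytic_log_evidence, bayes_factor, expected_bf_update
from .inference import analytic_posterior, population_mcmc, thin
from .models import (
    STEADY_STATE,
    Dataset,
    DesignPoint,
    GammaPrior,
    HalfNormalPrior,
    LinearBasisModel,
    OdeModel,
    ParameterVector,
    PriorSpec,
    generate_data,
    make_basis,
    regular_design,
)
from .ppd import (
    CandidateExperiment,
    build_column_source,
)
from .design import DesignMatrix, compute_design_matrix

__all__ = [
    "LinearModelPair",
    "LinearStudyResult",
    "MotifQuartet",
    "MotifStudyResult",
    "linear_quartet",
    "random_linear_model",
    "run_linear_study",
    "quartet_example",
    "motif_quartet",
    "motif_default_design",
    "run_motif_study",
    "diagonal_darkness",
]


# ---------------------------------------------------------------------------
# linear quartet and random model pairs
# ---------------------------------------------------------------------------


def linear_quartet() -> list[LinearBasisModel]:
    """The nested regression quartet used throughout the linear examples.

    M1: th1 t
    M2: th1 t + th2 t^2
    M3: th1 t + th2 t^2 + th3 sin(15 t)/3   (designated truth)
    M4: M3 + th4 sin(2 t) t
    """
    b_t = make_basis("poly", 1)
    b_t2 = make_basis("poly", 2)
    b_sin15 = make_basis("sin_scaled", 15, 3)
    b_sin2t = make_basis("sin_poly", 2, 1)
    return [
        LinearBasisModel([b_t], name="M1"),
        LinearBasisModel([b_t, b_t2], name="M2"),
        LinearBasisModel([b_t, b_t2, b_sin15], name="M3"),
        LinearBasisModel([b_t, b_t2, b_sin15, b_sin2t], name="M4"),
    ]


#: Basis-function families the random-model generator draws from: the
#: polynomial and modulated-sinusoid forms of the linear quartet.
_RANDOM_BASIS_POOL = [
    ("poly", (1,)),
    ("poly", (2,)),
    ("poly", (3,)),
    ("sin_scaled", (15, 3)),
    ("sin_poly", (1, 0)),
    ("sin_poly", (2, 1)),
    ("sin_poly", (5, 0)),
    ("sin_poly", (5, 1)),
]


@dataclass
class LinearModelPair:
    true_model: LinearBasisModel
    competitor: LinearBasisModel
    theta_true: np.ndarray


def random_linear_model(seed: int, max_terms: int = 3, xi: float = 1.0) -> LinearModelPair:
    """Draw a true/competitor pair of linear models with overlapping but
    non-identical basis sets.

    True coefficients are drawn from the N(0, xi^2) prior, keeping the
    generating process consistent with the inference model.  Degenerate
    draws (identical basis sets) are redrawn a bounded number of times.
    """
    if max_terms < 2:
        raise ValueError("max_terms must be >= 2")
    rng = np.random.default_rng(seed)
    n_pool = len(_RANDOM_BASIS_POOL)
    for _ in range(100):
        n_true = int(rng.integers(1, max_terms + 1))
        true_idx = sorted(rng.choice(n_pool, size=n_true, replace=False))
        comp_idx = set(true_idx)
        # mutate: drop and/or add a term so the sets overlap but differ
        if len(comp_idx) > 1 and rng.random() < 0.5:
            comp_idx.discard(int(rng.choice(sorted(comp_idx))))
        candidates = [i for i in range(n_pool) if i not in comp_idx]
        must_add = comp_idx == set(true_idx)
        if (must_add or rng.random() < 0.7) and candidates and len(comp_idx) < max_terms:
            comp_idx.add(int(rng.choice(candidates)))
        comp_idx = sorted(comp_idx)
        if comp_idx == list(true_idx) or not comp_idx:
            continue
        true_model = LinearBasisModel(
            [make_basis(k, *a) for k, a in (_RANDOM_BASIS_POOL[i] for i in true_idx)],
            name=f"true[{','.join(map(str, true_idx))}]",
        )
        competitor = LinearBasisModel(
            [make_basis(k, *a) for k, a in (_RANDOM_BASIS_POOL[i] for i in comp_idx)],
            name=f"comp[{','.join(map(str, comp_idx))}]",
        )
        theta_true = rng.normal(0.0, xi, size=true_model.n_params)
        return LinearModelPair(true_model, competitor, theta_true)
    raise RuntimeError("failed to draw a non-degenerate model pair")


# ---------------------------------------------------------------------------
# linear study
# ---------------------------------------------------------------------------


@dataclass
class LinearStudyResult:
    """Per-candidate JSD vs expected Bayes-factor-update records and their
    per-pair Spearman correlations."""

    records: pd.DataFrame
    spearman: list[float]
    mean_spearman: float
    n_skipped: int
    settings: dict = field(default_factory=dict)


def _linear_data_window(
    pair: LinearModelPair,
    rng: np.random.Generator,
    n_data: int,
    sigma: float,
    xi: float,
    max_tries: int = 25,
):
    """Simulate data from the true model in a window where the initial
    comparison is indecisive (|log10 B| < 1): the regime in which new
    experiments are actually needed."""
    for _ in range(max_tries):
        t0 = rng.uniform(0.0, 1.0)
        span = rng.uniform(0.5, 1.5)
        times = np.linspace(t0, t0 + span, n_data)
        design = regular_design("y", times, n_replicates=1)
        data = generate_data(pair.true_model, ParameterVector(
            dict(zip(pair.true_model.parameter_names, pair.theta_true))
        ), design, sigma, rng)
        b = bayes_factor(
            analytic_log_evidence(pair.true_model, data, sigma, xi),
            analytic_log_evidence(pair.competitor, data, sigma, xi),
        )
        if abs(b.log10_bf) < 1.0:
            return data, times, b
    return None


def run_linear_study(
    n_model_pairs: int = 30,
    n_rep: int = 100,
    candidate_grid=None,
    seed: int = 0,
    sigma: float = 0.2,
    xi: float = 1.0,
    n_data: int = 10,
    n_ppd: int = 5000,
    n_candidates: int = 20,
    k: int = 10,
    max_terms: int = 3,
) -> LinearStudyResult:
    """Monte-Carlo comparison of the JSD criterion against expected
    Bayes-factor updates over random linear-model pairs.

    For each pair, noisy data is simulated from the true model in a window
    where the models are initially indistinguishable; candidate single
    measurements on a grid extending well beyond that window are then
    scored both by the kNN-JSD between the two models' predictive samples
    and by the Monte-Carlo mean change in log10 Bayes factor toward the
    true model after actually (virtually) performing the measurement.  The
    per-pair Spearman rank correlation between the two scores, averaged
    over pairs, summarizes how well the divergence predicts experimental
    value.
    """
    if n_model_pairs < 1 or n_rep < 10:
        raise ValueError("need n_model_pairs >= 1 and n_rep >= 10")
    root = np.random.SeedSequence(seed)
    rows = []
    correlations: list[float] = []
    n_skipped = 0
    pair_seeds = root.spawn(n_model_pairs)
    for pid, ss in enumerate(pair_seeds):
        rng = np.random.default_rng(ss)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pair = random_linear_model(sub_seed, max_terms=max_terms, xi=xi)
        found = _linear_data_window(pair, rng, n_data, sigma, xi)
        if found is None:
            n_skipped += 1
            continue
        data, times, b0 = found
        t0, t1 = times[0], times[-1]
        span = t1 - t0
        if candidate_grid is None:
            grid_times = np.linspace(t0 - 1.5 * span, t1 + 1.5 * span, n_candidates)
        else:
            grid_times = np.asarray(candidate_grid, dtype=float)
        grid = [DesignPoint("y", t) for t in grid_times]

        post_t = analytic_posterior(pair.true_model, data, sigma, xi)
        post_c = analytic_posterior(pair.competitor, data, sigma, xi)
        src_t = build_column_source(
            post_t, pair.true_model, grid, sigma=sigma, seed=rng, n=n_ppd
        )
        src_c = build_column_source(
            post_c, pair.competitor, grid, sigma=sigma, seed=rng, n=n_ppd
        )

        jsds = np.empty(len(grid))
        dbs = np.empty(len(grid))
        for i in range(len(grid)):
            est = knn_jsd(
                src_t.columns([i], rng), src_c.columns([i], rng), k=k,
                labels=(pair.true_model.name, pair.competitor.name),
            )
            jsds[i] = est.jsd_bits
            upd = expected_bf_update(
                (pair.true_model, pair.competitor),
                data,
                CandidateExperiment(points=(grid[i],)),
                sigma,
                xi,
                n_rep=n_rep,
                seed=int(rng.integers(0, 2**31 - 1)),
                generating_model=pair.true_model,
            )
            dbs[i] = upd.mean
            rows.append(
                {
                    "pair_id": pid,
                    "true": pair.true_model.name,
                    "competitor": pair.competitor.name,
                    "time": grid_times[i],
                    "in_window": bool(t0 <= grid_times[i] <= t1),
                    "jsd": jsds[i],
                    "mean_delta_b": dbs[i],
                    "ci_lo": upd.ci[0],
                    "ci_hi": upd.ci[1],
                    "initial_log10_b": b0.log10_bf,
                }
            )
        if np.allclose(jsds, jsds[0]) or np.allclose(dbs, dbs[0]):
            n_skipped += 1
            continue
        rho = sps.spearmanr(jsds, dbs).statistic
        if np.isfinite(rho):
            correlations.append(float(rho))
        else:
            n_skipped += 1

    mean_rho = float(np.mean(correlations)) if correlations else float("nan")
    return LinearStudyResult(
        records=pd.DataFrame(rows),
        spearman=correlations,
        mean_spearman=mean_rho,
        n_skipped=n_skipped,
        settings={
            "n_model_pairs": n_model_pairs,
            "n_rep": n_rep,
            "sigma": sigma,
            "xi": xi,
            "n_data": n_data,
            "n_ppd": n_ppd,
            "n_candidates": n_candidates,
            "k": k,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# the quartet example (extrapolation-vs-interpolation pattern)
# ---------------------------------------------------------------------------


#: Angular frequency of the oscillatory basis term in the quartet.
_QUARTET_OMEGA = 15.0
#: Period of that term; also the default measurement spacing below.
_QUARTET_PERIOD = 2 * np.pi / _QUARTET_OMEGA


def quartet_example(
    seed: int = 0,
    sigma: float = 0.2,
    xi: float = 1.0,
    n_data: int = 10,
    n_rep: int = 50,
    n_ppd: int = 5000,
    k: int = 10,
    theta_true=(0.5, 0.3, 1.0),
    window_start: float = 2.0,
) -> dict:
    """Reproduce the regression-quartet design example.

    The measured window samples ``n_data`` equidistant points starting at
    ``window_start`` with spacing equal to the period of M3's oscillatory
    term.  At that spacing the oscillation is invisible in the data (every
    sample hits the same phase), so all four models describe the window
    equally well and the sine coefficient keeps its prior uncertainty,
    while the quadratic trend is decisively resolved: model selection is
    unsuccessful where it matters (M3 vs M2/M4) before any new experiment,
    which is the regime in which design is needed.

    Candidate single measurements on the window grid and on quarter-phase
    offset grids at negative times and beyond the window are scored by JSD
    and expected Bayes-factor update for M3 vs M1 (differences between
    those two models live mostly outside the measured region).
    Two-measurement candidates over the off-window blocks are scored by
    JSD for M3 vs M2: the unresolved oscillation is an odd function of
    time, anticorrelating M3's predictions at negative versus positive
    times while M2's stay positively correlated, so one negative-time plus
    one positive-time measurement discriminates best.
    """
    rng = np.random.default_rng(seed)
    m1, m2, m3, m4 = linear_quartet()
    theta = np.asarray(theta_true, dtype=float)
    sp = _QUARTET_PERIOD
    times = window_start + np.arange(n_data) * sp
    t0, t1 = times[0], times[-1]
    data = generate_data(
        m3,
        ParameterVector(dict(zip(m3.parameter_names, theta))),
        regular_design("y", times, 1),
        sigma,
        rng,
    )
    # candidate grid: in-window times plus quarter-phase blocks at negative
    # times and beyond the window (|sin| = 1 at every off-window candidate,
    # with opposite sign on the two sides)
    neg_times = (np.arange(-8, -3) + 0.25) * sp
    pos_times = t1 + (np.arange(1, 6) - 0.25) * sp
    grid_times = np.concatenate([neg_times, times, pos_times])
    in_window = (grid_times >= t0) & (grid_times <= t1)
    grid = [DesignPoint("y", t) for t in grid_times]

    posts = {m.name: analytic_posterior(m, data, sigma, xi) for m in (m1, m2, m3, m4)}
    sources = {
        m.name: build_column_source(posts[m.name], m, grid, sigma=sigma, seed=rng, n=n_ppd)
        for m in (m1, m2, m3, m4)
    }

    jsd_31 = np.empty(len(grid))
    db_31 = np.empty(len(grid))
    for i in range(len(grid)):
        jsd_31[i] = knn_jsd(
            sources["M3"].columns([i], rng), sources["M1"].columns([i], rng), k=k
        ).jsd_bits
        db_31[i] = expected_bf_update(
            (m3, m1), data, CandidateExperiment(points=(grid[i],)), sigma, xi,
            n_rep=n_rep, seed=int(rng.integers(0, 2**31 - 1)), generating_model=m3,
        ).mean

    # two-measurement candidates for M3 vs M2 over the off-window blocks
    neg_idx = [i for i, t in enumerate(grid_times) if t in neg_times]
    pos_idx = [i for i, t in enumerate(grid_times) if t in pos_times]
    pair_jsd = {}
    for ii in neg_idx + pos_idx:
        for jj in neg_idx + pos_idx:
            if jj < ii:
                continue
            est = knn_jsd(
                sources["M3"].columns([ii, jj], rng),
                sources["M2"].columns([ii, jj], rng),
                k=k,
            )
            kind = (
                "mixed"
                if (ii in neg_idx) != (jj in neg_idx)
                else ("neg" if ii in neg_idx else "pos")
            )
            pair_jsd[(ii, jj)] = (kind, est.jsd_bits)

    initial_bf = {
        m.name: bayes_factor(
            analytic_log_evidence(m3, data, sigma, xi),
            analytic_log_evidence(m, data, sigma, xi),
        ).log10_bf
        for m in (m1, m2, m4)
    }

    return {
        "grid_times": grid_times,
        "in_window": in_window,
        "jsd_31": jsd_31,
        "db_31": db_31,
        "pair_jsd_32": pair_jsd,
        "initial_bf": initial_bf,
        "data": data,
    }


# ---------------------------------------------------------------------------
# feedback-motif quartet (ODE reconstruction)
# ---------------------------------------------------------------------------

_MOTIF_STATES = ["Bp", "Cp", "BpCp", "Dp"]
_MOTIF_PARAMS = ["k1", "kd1", "k2", "kd2", "k3", "kd3", "k4", "kd4", "kfb"]

#: True parameters of the data-generating feedback variant, chosen once so
#: that Bp shows a clear overshoot above the 0.03 noise level on the
#: default measurement times.
MOTIF_TRUE_PARAMS = {
    "k1": 0.5,
    "kd1": 0.2,
    "k2": 1.0,
    "kd2": 0.2,
    "k3": 4.0,
    "kd3": 0.2,
    "k4": 0.5,
    "kd4": 0.05,
    "kfb": 20.0,
}

MOTIF_MEASURED_TIMES = [0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 100.0]
MOTIF_SIGMA = 0.03


def _motif_rhs(variant: int):
    """Mass-action cascade with one negative feedback loop.

    u -> B phosphorylation, Bp-catalyzed C phosphorylation, Bp + Cp
    binding to the BpCp complex, BpCp-driven D phosphorylation, first-order
    reverse steps.  Total B, C and D pools are conserved (normalized to 1),
    so the unphosphorylated species are eliminated: B = 1 - Bp - BpCp,
    C = 1 - Cp - BpCp, D = 1 - Dp.  The feedback acts as a saturating
    inhibition factor 1/(1 + kfb X) whose origin X and point of action
    differ per variant:

    1: Dp inhibits u -> B      2: Dp inhibits Bp + Cp binding
    3: BpCp inhibits u -> B    4: Cp inhibits u -> B
    """

    def rhs(x, u, p):
        Bp, Cp, BpCp, Dp = x
        k1, kd1, k2, kd2, k3, kd3, k4, kd4, kfb = p
        B = 1.0 - Bp - BpCp
        C = 1.0 - Cp - BpCp
        D = 1.0 - Dp
        inh1 = 1.0
        inh2 = 1.0
        if variant == 1:
            inh1 = 1.0 / (1.0 + kfb * Dp)
        elif variant == 2:
            inh2 = 1.0 / (1.0 + kfb * Dp)
        elif variant == 3:
            inh1 = 1.0 / (1.0 + kfb * BpCp)
        elif variant == 4:
            inh1 = 1.0 / (1.0 + kfb * Cp)
        v1 = k1 * u * B * inh1
        v2 = kd1 * Bp
        v3 = k2 * Bp * C
        v4 = kd2 * Cp
        v5 = k3 * Bp * Cp * inh2
        v6 = kd3 * BpCp
        v7 = k4 * BpCp * D
        v8 = kd4 * Dp
        return np.array(
            [
                v1 - v2 - v5 + v6,
                v3 - v4 - v5 + v6,
                v5 - v6,
                v7 - v8,
            ]
        )

    return rhs


_MOTIF_OBSERVABLES = {
    "Bp": lambda c: c["Bp"],
    "Cp": lambda c: c["Cp"],
    "BpCp": lambda c: c["BpCp"],
    "Dp": lambda c: c["Dp"],
    "Bptot": lambda c: c["Bp"] + c["BpCp"],
}


@dataclass
class MotifQuartet:
    """Four feedback variants of the cascade plus the shared study setup."""

    models: list[OdeModel]
    true_params: ParameterVector
    prior: PriorSpec
    sigma: float = MOTIF_SIGMA
    measured_times: Sequence[float] = tuple(MOTIF_MEASURED_TIMES)

    @property
    def true_model(self) -> OdeModel:
        return self.models[0]

    @property
    def observables(self) -> list[str]:
        return self.models[0].observable_names


def motif_quartet() -> MotifQuartet:
    """Build the four-variant feedback quartet (variant 1 generates data)."""
    x0 = np.zeros(4)
    models = [
        OdeModel(
            name=f"M{v}",
            state_names=list(_MOTIF_STATES),
            parameter_names=list(_MOTIF_PARAMS),
            rhs=_motif_rhs(v),
            x0=x0,
            conditions={"1": 1.0, "2": 2.0},
            observables=dict(_MOTIF_OBSERVABLES),
        )
        for v in (1, 2, 3, 4)
    ]
    prior = PriorSpec(
        {**{n: GammaPrior(1.0, 3.0) for n in _MOTIF_PARAMS}, "sigma": HalfNormalPrior(1.0)}
    )
    return MotifQuartet(
        models=models,
        true_params=ParameterVector(dict(MOTIF_TRUE_PARAMS)),
        prior=prior,
    )


def motif_default_design() -> list[tuple[DesignPoint, int]]:
    """Bp in triplicate and Dp in duplicate at the standard times, stimulus 1."""
    design = []
    for t in MOTIF_MEASURED_TIMES:
        design.append((DesignPoint("Bp", t, "1"), 3))
        design.append((DesignPoint("Dp", t, "1"), 2))
    return design


def motif_dataset(quartet: MotifQuartet, seed: int = 0) -> Dataset:
    return generate_data(
        quartet.true_model,
        quartet.true_params,
        motif_default_design(),
        quartet.sigma,
        seed,
    )


# ---------------------------------------------------------------------------
# motif study
# ---------------------------------------------------------------------------


@dataclass
class MotifStudyResult:
    matrices: dict[tuple[str, str], DesignMatrix]
    experiments: pd.DataFrame
    peak_time: float
    settings: dict = field(default_factory=dict)
    posteriors: dict = field(default_factory=dict)
    sources: dict = field(default_factory=dict)


def _motif_bf_validation(
    quartet, data, experiments, sources, experiments_df,
    n_temps, n_samples, seed, atol, rtol, n_rep: int = 3,
):
    """Validate the divergence predictions by realized Bayes-factor updates.

    For each named experiment, outcomes are drawn from the true model's
    predictive source, appended to the dataset, and every model is re-fit
    by population MCMC with thermodynamic-integration evidence.  Each
    replicate costs four full inference runs, which is why this path is
    gated behind an explicit flag and defaults to very few replicates.
    """
    from .evidence import thermodynamic_log_evidence

    def ti_logz(model, dataset, run_seed):
        chains = population_mcmc(
            model, dataset, quartet.prior, n_temps=n_temps,
            n_samples=n_samples, seed=run_seed, swaps_per_sweep=n_temps,
            atol=atol, rtol=rtol,
        )
        return thermodynamic_log_evidence(chains).logz

    base_logz = {
        m.name: ti_logz(m, data, seed + 101 + i)
        for i, m in enumerate(quartet.models)
    }
    true_src = sources[quartet.true_model.name]
    rng = np.random.default_rng(seed)
    deltas: dict[tuple[str, str], list[float]] = {}
    for label, idx in experiments.items():
        outcome_rows = true_src.columns(idx, rng)
        for rep in range(n_rep):
            y_new = outcome_rows[rng.integers(0, outcome_rows.shape[0])]
            records = []
            for col, point_i in enumerate(idx):
                p = true_src.grid[point_i]
                records.append((p.observable, p.condition, p.time, 900 + rep, float(y_new[col])))
            augmented = data.concat(Dataset.from_records(records))
            logz = {
                m.name: ti_logz(m, augmented, seed + 997 * (rep + 1) + i)
                for i, m in enumerate(quartet.models)
            }
            for a in logz:
                for b in logz:
                    if a < b:
                        delta = ((logz[a] - logz[b]) - (base_logz[a] - base_logz[b])) / np.log(10)
                        deltas.setdefault((label, a, b), []).append(delta)
    experiments_df = experiments_df.copy()
    experiments_df["delta_log10_bf"] = [
        float(np.mean(deltas.get((row.experiment, row.model_a, row.model_b), [np.nan])))
        for row in experiments_df.itertuples()
    ]
    return experiments_df


def diagonal_darkness(matrix: DesignMatrix, n_times: int) -> float:
    """Fraction of observable-pair tiles whose same-point diagonal is darker
    (lower JSD on average) than the rest of the tile.

    The grid must be ordered as consecutive blocks of ``n_times`` times per
    (observable, condition) section; only timed grid points participate.
    """
    m = len(matrix.grid)
    n_sections = m // n_times
    wins = 0
    total = 0
    v = matrix.values
    for s in range(n_sections):
        sl = slice(s * n_times, (s + 1) * n_times)
        tile = v[sl, sl]
        diag = np.diag(tile)
        off = tile[~np.eye(n_times, dtype=bool)]
        total += 1
        if diag.mean() < off.mean():
            wins += 1
    return wins / max(total, 1)


def run_motif_study(
    quartet: MotifQuartet,
    data: Dataset | None = None,
    n_temps: int = 40,
    n_samples: int = 10_000,
    n_ppd: int = 1000,
    time_grid: Sequence[float] = (2.0, 5.0, 10.0, 20.0, 60.0),
    k: int = 10,
    seed: int = 0,
    atol: float = 1e-8,
    rtol: float = 1e-9,
    burn_in: int | None = None,
    expensive_bf: bool = False,
) -> MotifStudyResult:
    """End-to-end design study on the feedback-motif quartet.

    Runs population MCMC for all four models on the shared dataset, builds
    predictive column sources over the observable x condition x time grid
    (plus steady-state points), computes all six pairwise d=2 design
    matrices, and scores the three named validation experiments:

    1. steady-state Cp and BpCp (joint),
    2. Bp and Dp at the Bp peak under the second stimulus,
    3. steady-state Cp alone.

    Bayes-factor validation of the predictions requires re-running MCMC
    plus thermodynamic integration per hypothetical dataset; it is gated
    behind ``expensive_bf`` and intentionally not part of the default
    pipeline.
    """
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(8)]
    if data is None:
        data = motif_dataset(quartet, seed=seeds[0])

    posteriors = {}
    for i, model in enumerate(quartet.models):
        chains = population_mcmc(
            model,
            data,
            quartet.prior,
            n_temps=n_temps,
            n_samples=n_samples,
            seed=seeds[1] + i,
            burn_in=burn_in,
            swaps_per_sweep=n_temps,
            atol=atol,
            rtol=rtol,
        )
        posteriors[model.name] = thin(chains, min(n_ppd, n_samples))

    # candidate grid: every observable under both stimuli, timed + steady
    grid: list[DesignPoint] = []
    for cond in ("1", "2"):
        for obs in quartet.observables:
            for t in time_grid:
                grid.append(DesignPoint(obs, t, cond))
    steady_grid = [
        DesignPoint(obs, STEADY_STATE, cond)
        for cond in ("1",)
        for obs in quartet.observables
    ]
    full_grid = grid + steady_grid

    sources = {
        m.name: build_column_source(
            posteriors[m.name], m, full_grid, seed=seeds[2] + j, atol=atol, rtol=rtol
        )
        for j, m in enumerate(quartet.models)
    }

    names = [m.name for m in quartet.models]
    pairs = [(a, b) for ai, a in enumerate(names) for b in names[ai + 1:]]
    matrices = {
        pair: compute_design_matrix(sources, pair, k=k, d=2, seed=seeds[3])
        for pair in pairs
    }

    # peak time of Bp under stimulus 2: posterior median over the true model
    true_src = sources[quartet.true_model.name]
    bp2_cols = [
        i
        for i, p in enumerate(full_grid)
        if p.observable == "Bp" and p.condition == "2" and not p.is_steady
    ]
    med = [np.median(true_src.noiseless[:, i]) for i in bp2_cols]
    peak_time = float(full_grid[bp2_cols[int(np.argmax(med))]].time)

    def gi(obs, time, cond):
        return full_grid.index(DesignPoint(obs, time, cond))

    experiments = {
        "exp1_ss_Cp_BpCp": [gi("Cp", STEADY_STATE, "1"), gi("BpCp", STEADY_STATE, "1")],
        "exp2_peak_Bp_Dp_u2": [gi("Bp", peak_time, "2"), gi("Dp", peak_time, "2")],
        "exp3_ss_Cp": [gi("Cp", STEADY_STATE, "1")],
    }
    rows = []
    for ei, (label, idx) in enumerate(experiments.items()):
        for pair in pairs:
            ss = np.random.SeedSequence(entropy=seeds[4], spawn_key=(ei,))
            rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(2)]
            est = knn_jsd(
                sources[pair[0]].columns(idx, rng_a),
                sources[pair[1]].columns(idx, rng_b),
                k=k,
                labels=pair,
            )
            rows.append(
                {
                    "experiment": label,
                    "pair": f"{pair[0]} vs {pair[1]}",
                    "model_a": pair[0],
                    "model_b": pair[1],
                    "jsd": est.jsd_bits,
                    "d": len(idx),
                }
            )
    experiments_df = pd.DataFrame(rows)

    if expensive_bf:
        experiments_df = _motif_bf_validation(
            quartet, data, experiments, sources, experiments_df,
            n_temps=n_temps, n_samples=n_samples, seed=seeds[5],
            atol=atol, rtol=rtol,
        )

    return MotifStudyResult(
        matrices=matrices,
        experiments=experiments_df,
        peak_time=peak_time,
        settings={
            "n_temps": n_temps,
            "n_samples": n_samples,
            "n_ppd": n_ppd,
            "time_grid": list(time_grid),
            "k": k,
            "seed": seed,
            "atol": atol,
            "rtol": rtol,
        },
        posteriors=posteriors,
        sources=sources,
    )
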