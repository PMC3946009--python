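"""Model simulation, likelihood, priors and synthetic-data generation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppdesign import (
    Dataset,
    DesignPoint,
    GammaPrior,
    GaussianPrior,
    HalfNormalPrior,
    LinearBasisModel,
    OdeModel,
    ParameterVector,
    PriorSpec,
    STEADY_STATE,
    generate_data,
    log_likelihood,
    log_prior,
    make_basis,
    simulate_linear,
    simulate_ode,
    steady_state,
)
from ppdesign.models import regular_design
from ppdesign import studies


# ---------------------------------------------------------------------------
# linear simulation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "basis, theta, times, expected",
    [
        ([("t", lambda t: t)], [2.0], [0, 1, 3], [0.0, 2.0, 6.0]),
        ([("t", lambda t: t), ("t2", lambda t: t**2)], [0.0, 0.0], [0.5, 2.0], [0.0, 0.0]),
    ],
)
def test_simulate_linear_direct_evaluation(basis, theta, times, expected):
    model = LinearBasisModel(list(basis))
    np.testing.assert_allclose(simulate_linear(model, theta, times), expected)


def test_quartet_m3_vanishes_at_origin():
    m3 = studies.linear_quartet()[2]
    # t + t^2 + sin(15 t)/3 all vanish at t = 0
    np.testing.assert_allclose(simulate_linear(m3, [1.0, 1.0, 1.0], [0.0]), [0.0])


def test_simulate_linear_rejects_nonfinite_basis():
    model = LinearBasisModel([make_basis("poly", -1)])  # 1/t blows up at 0
    with pytest.raises(FloatingPointError, match="basis 1"):
        simulate_linear(model, [1.0], [0.0])


def test_simulate_linear_rejects_wrong_coefficient_count():
    model = LinearBasisModel([make_basis("poly", 1)])
    with pytest.raises(ValueError, match="coefficients"):
        simulate_linear(model, [1.0, 2.0], [0.0])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _dataset(values, times=None):
    times = times if times is not None else list(range(len(values)))
    return Dataset.from_records(
        [("y", "1", t, 0, v) for t, v in zip(times, values)]
    )


def test_log_likelihood_gaussian_mode():
    data = _dataset([1.0])
    assert log_likelihood(data, np.array([1.0]), 1.0) == pytest.approx(
        math.log(1.0 / math.sqrt(2 * math.pi))
    )


def test_log_likelihood_factorizes_over_points():
    one = _dataset([0.7], times=[0])
    two = Dataset.from_records(
        [("y", "1", 0, 0, 0.7), ("y", "1", 1, 0, 0.7)]
    )
    single = log_likelihood(one, np.array([0.2]), 0.5)
    double = log_likelihood(two, np.array([0.2, 0.2]), 0.5)
    assert double == pytest.approx(2 * single, rel=1e-12)


def test_log_likelihood_matches_per_point_oracle():
    rng = np.random.default_rng(0)
    values = rng.normal(size=5)
    preds = rng.normal(size=5)
    sigma = 0.7
    data = _dataset(values)
    # independent brute-force summation of per-point Gaussian log densities
    oracle = sum(stats.norm(p, sigma).logpdf(v) for p, v in zip(preds, values))
    assert log_likelihood(data, preds, sigma) == pytest.approx(oracle, abs=1e-12)


def test_log_likelihood_of_concatenated_dataset_is_sum_of_parts():
    rng = np.random.default_rng(1)
    a = _dataset(rng.normal(size=4), times=[0, 1, 2, 3])
    b = Dataset.from_records([("z", "2", t, 0, v) for t, v in zip(range(4), rng.normal(size=4))])
    pa, pb = rng.normal(size=4), rng.normal(size=4)
    whole = a.concat(b)
    ll_whole = log_likelihood(whole, np.concatenate([pa, pb]), 0.3)
    ll_parts = log_likelihood(a, pa, 0.3) + log_likelihood(b, pb, 0.3)
    assert ll_whole == pytest.approx(ll_parts, abs=1e-12)


def test_log_likelihood_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        log_likelihood(_dataset([1.0]), np.array([1.0]), 0.0)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def test_log_prior_values_and_support():
    spec = PriorSpec({"k": GammaPrior(1.0, 3.0)})
    # exponential with mean 3: density 1/3 at the origin
    assert log_prior({"k": 1e-12}, spec) == pytest.approx(math.log(1 / 3), abs=1e-9)
    assert log_prior({"k": -0.5}, spec) == -math.inf
    gspec = PriorSpec({"c": GaussianPrior(1.0)})
    assert log_prior({"c": 0.0}, gspec) == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))


@pytest.mark.parametrize(
    "prior, ref",
    [
        (GammaPrior(2.5, 0.7), stats.gamma(2.5, scale=0.7)),
        (GammaPrior(1.0, 3.0, rate_convention=True), stats.gamma(1.0, scale=1 / 3)),
        (GaussianPrior(1.4), stats.norm(scale=1.4)),
        (HalfNormalPrior(1.2), stats.halfnorm(scale=1.2)),
    ],
)
def test_prior_logpdf_matches_scipy(prior, ref):
    x = np.array([0.05, 0.5, 1.1, 2.7])
    np.testing.assert_allclose(prior.logpdf(x), ref.logpdf(x), atol=1e-12)


# ---------------------------------------------------------------------------
# ODE simulation
# ---------------------------------------------------------------------------


def _decay_model():
    return OdeModel(
        name="decay",
        state_names=["x"],
        parameter_names=["p"],
        rhs=lambda x, u, p: np.array([-p[0] * x[0]]),
        x0=np.array([1.0]),
        conditions={"1": 1.0},
    )


def test_ode_fixed_point_stays_constant():
    model = OdeModel(
        name="flat",
        state_names=["a", "b"],
        parameter_names=["p"],
        rhs=lambda x, u, p: np.zeros(2),
        x0=np.array([0.3, 1.7]),
        conditions={"1": 1.0},
    )
    traj = simulate_ode(model, {"p": 1.0}, "1", [0.0, 1.0, 10.0])
    np.testing.assert_allclose(traj["a"], 0.3, atol=1e-10)
    np.testing.assert_allclose(traj["b"], 1.7, atol=1e-10)


def test_ode_linear_decay_matches_closed_form():
    model = _decay_model()
    times = np.linspace(0.0, 100.0, 25)
    traj = simulate_ode(model, {"p": 1.0}, "1", times)
    # within 10x the integrator tolerance across the whole range
    np.testing.assert_allclose(traj["x"].to_numpy(), np.exp(-times), atol=1e-7)


def test_ode_rejects_unsorted_or_negative_times():
    model = _decay_model()
    with pytest.raises(ValueError):
        simulate_ode(model, {"p": 1.0}, "1", [1.0, 0.5])
    with pytest.raises(ValueError):
        simulate_ode(model, {"p": 1.0}, "1", [-1.0, 0.5])


def test_ode_unknown_condition_is_reported():
    with pytest.raises(KeyError, match="condition"):
        simulate_ode(_decay_model(), {"p": 1.0}, "9", [0.0, 1.0])


def test_steady_state_of_decay_is_zero():
    ss = steady_state(_decay_model(), {"p": 1.0}, "1", t_horizon=100.0)
    assert abs(ss["x"]) < 1e-6


def test_motif_true_model_shows_overshoot():
    """Bp rises well above its eventual steady state before settling: the
    transient used to choose the generating parameters."""
    q = studies.motif_quartet()
    traj = simulate_ode(q.true_model, q.true_params, "1", studies.MOTIF_MEASURED_TIMES)
    bp = traj["Bp"]
    ss = steady_state(q.true_model, q.true_params, "1")
    assert bp.max() > ss["Bp"] + 3 * studies.MOTIF_SIGMA
    assert np.isfinite(traj.to_numpy()).all()


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------


def test_generate_data_zero_noise_equals_simulation(linear_benchmark):
    model = linear_benchmark["model"]
    theta = linear_benchmark["theta"]
    times = [0.5, 1.0, 1.5]
    data = generate_data(model, theta, regular_design("y", times, 1), 0.0, 0)
    np.testing.assert_allclose(data.values, simulate_linear(model, theta, times))


def test_generate_data_is_reproducible_given_seed(linear_benchmark):
    model = linear_benchmark["model"]
    theta = linear_benchmark["theta"]
    design = regular_design("y", [0.0, 1.0], 3)
    d1 = generate_data(model, theta, design, 0.1, 123)
    d2 = generate_data(model, theta, design, 0.1, 123)
    pd.testing.assert_frame_equal(d1.frame, d2.frame)


def test_generate_data_noise_is_gaussian_with_requested_scale():
    model = LinearBasisModel([make_basis("poly", 1)])
    theta = ParameterVector({"theta_1": 1.0})
    sigma = 0.25
    data = generate_data(
        model, theta, [(DesignPoint("y", 1.0), 10_000)], sigma, 7
    )
    resid = data.values - 1.0
    assert abs(resid.std() / sigma - 1.0) < 0.03
    # residuals should pass a normality check
    assert stats.normaltest(resid).pvalue > 1e-3


def test_motif_default_dataset_layout():
    q = studies.motif_quartet()
    data = studies.motif_dataset(q, seed=0)
    df = data.frame
    assert len(df) == len(studies.MOTIF_MEASURED_TIMES) * 5
    assert set(df["observable"]) == {"Bp", "Dp"}
    assert df.groupby("observable")["replicate"].max().to_dict() == {"Bp": 2, "Dp": 1}


# ---------------------------------------------------------------------------
# dataset container / IO
# ---------------------------------------------------------------------------


def test_dataset_rejects_duplicates_and_nonfinite():
    with pytest.raises(ValueError, match="duplicate"):
        Dataset.from_records([("y", "1", 0, 0, 1.0), ("y", "1", 0, 0, 2.0)])
    with pytest.raises(ValueError, match="finite"):
        Dataset.from_records([("y", "1", 0, 0, float("nan"))])


def test_dataset_csv_roundtrip_with_steady_state(tmp_path):
    data = Dataset.from_records(
        [
            ("Cp", "1", STEADY_STATE, 0, 0.21),
            ("Bp", "2", 5.0, 0, 0.13),
            ("Bp", "2", 5.0, 1, 0.16),
        ]
    )
    path = tmp_path / "data.csv"
    data.to_csv(path)
    text = path.read_text()
    assert "-1.0" in text  # steady state encoded as time = -1 plus flag
    back = Dataset.read_csv(path)
    pd.testing.assert_frame_equal(back.frame, data.frame)
    pts = back.design_points()
    assert pts[0].is_steady and pts[0].time == STEADY_STATE


def test_design_point_labels_and_validation():
    p = DesignPoint("Bp", STEADY_STATE, "2")
    assert p.is_steady and "ss" in p.label
    q = DesignPoint("y", -1.5)  # negative time is legal for regression models
    assert q.time == -1.5
    with pytest.raises(ValueError):
        DesignPoint("y", float("nan"))
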