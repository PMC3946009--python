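"""Posterior sampling: conjugate closed forms, the temperature ladder, the
population sampler and its diagnostics."""

import numpy as np
import pytest

from ppdesign import (
    Dataset,
    GaussianPrior,
    LinearBasisModel,
    PriorSpec,
    analytic_posterior,
    check_propriety,
    population_mcmc,
    temperature_schedule,
    thin,
)
from ppdesign.inference import FlatPrior, _Target, TemperedChains
from ppdesign.models import GammaPrior, make_basis
from ppdesign import studies


# ---------------------------------------------------------------------------
# analytic posterior
# ---------------------------------------------------------------------------


def test_analytic_posterior_with_no_data_is_the_prior():
    model = LinearBasisModel([make_basis("poly", 1), make_basis("poly", 2)])
    post = analytic_posterior(model, Dataset.from_records([]), sigma=0.5, xi=2.0)
    np.testing.assert_allclose(post.mean, 0.0)
    np.testing.assert_allclose(post.cov, 4.0 * np.eye(2))


def test_analytic_posterior_uninformative_data_limit(linear_benchmark):
    b = linear_benchmark
    post = analytic_posterior(b["model"], b["data"], sigma=1e12, xi=b["xi"])
    np.testing.assert_allclose(post.mean, 0.0, atol=1e-6)
    np.testing.assert_allclose(post.cov, b["xi"] ** 2 * np.eye(2), atol=1e-6)


def test_analytic_posterior_constant_basis_recovers_sample_mean():
    model = LinearBasisModel([make_basis("poly", 0)])
    data = Dataset.from_records([("y", "1", 0.0, 0, 1.0), ("y", "1", 1.0, 0, 3.0)])
    post = analytic_posterior(model, data, sigma=1.0, xi=1e6)
    assert post.mean[0] == pytest.approx(2.0, abs=1e-4)


# ---------------------------------------------------------------------------
# temperature ladder
# ---------------------------------------------------------------------------


def test_temperature_schedule_quartic_ladder():
    t = temperature_schedule(40)
    assert t[0] == 0.0
    assert t[-1] == 1.0
    assert t[20] == pytest.approx(0.0625)
    assert np.all(np.diff(t) > 0)
    with pytest.raises(ValueError):
        temperature_schedule(1)


def test_population_mcmc_defaults_match_reference_configuration():
    import inspect

    sig = inspect.signature(population_mcmc)
    assert sig.parameters["n_temps"].default == 40
    assert inspect.signature(thin).parameters["target"].default == 10_000


# ---------------------------------------------------------------------------
# sampler correctness against the conjugate oracle
# ---------------------------------------------------------------------------


def _mc_se(x):
    try:
        import arviz as az

        ess = float(az.ess(np.asarray(x)[None, :]))
    except Exception:
        ess = len(x)
    ess = max(min(ess, len(x)), 1.0)
    return np.std(x) / np.sqrt(ess)


def test_mcmc_recovers_conjugate_posterior(linear_benchmark, linear_chains):
    b = linear_benchmark
    draws = linear_chains.chain_at_one()
    for i in range(2):
        se = _mc_se(draws[:, i])
        assert abs(draws[:, i].mean() - b["posterior"].mean[i]) < 3 * se
    sample_cov = np.cov(draws.T)
    np.testing.assert_allclose(sample_cov, b["posterior"].cov, rtol=0.10, atol=2e-4)


def test_temperature_zero_chain_samples_the_prior(linear_chains, linear_benchmark):
    """At T=0 the power posterior is the prior itself."""
    draws = linear_chains.draws[0]  # first ladder rung, T = 0
    xi = linear_benchmark["xi"]
    for i in range(draws.shape[1]):
        x = draws[:, i]
        se = _mc_se(x)
        assert abs(x.mean()) < 4 * max(se, 1e-3)
        assert abs(x.std() - xi) < 0.15 * xi


def test_stored_loglik_traces_match_recomputation(linear_benchmark, linear_chains):
    b = linear_benchmark
    target = _Target(
        b["model"], b["data"], b["model"].default_prior(b["xi"]), sigma=b["sigma"]
    )
    rng = np.random.default_rng(0)
    for _ in range(5):
        c = int(rng.integers(0, linear_chains.draws.shape[0]))
        i = int(rng.integers(0, linear_chains.draws.shape[1]))
        assert target.loglik(linear_chains.draws[c, i]) == pytest.approx(
            linear_chains.logliks[c, i], abs=1e-9
        )


def test_disabling_swaps_does_not_shift_the_posterior(linear_benchmark):
    """Exchange moves must preserve the per-temperature marginals."""
    b = linear_benchmark
    prior = b["model"].default_prior(b["xi"])
    ch = population_mcmc(
        b["model"], b["data"], prior, n_temps=8, n_samples=3000, seed=9,
        sigma=b["sigma"], swaps_per_sweep=0,
    )
    draws = ch.chain_at_one()
    for i in range(2):
        se = _mc_se(draws[:, i])
        assert abs(draws[:, i].mean() - b["posterior"].mean[i]) < 3 * se


def test_longer_run_does_not_shift_quantiles(linear_benchmark, linear_chains):
    """With adaptation frozen after burn-in, doubling the run length leaves
    the posterior quantiles unchanged up to Monte-Carlo error."""
    b = linear_benchmark
    prior = b["model"].default_prior(b["xi"])
    longer = population_mcmc(
        b["model"], b["data"], prior, n_temps=12, n_samples=8000, seed=5,
        sigma=b["sigma"],
    )
    q_short = np.quantile(linear_chains.chain_at_one(), [0.25, 0.5, 0.75], axis=0)
    q_long = np.quantile(longer.chain_at_one(), [0.25, 0.5, 0.75], axis=0)
    sd = np.sqrt(np.diag(b["posterior"].cov))
    assert np.all(np.abs(q_short - q_long) < 0.15 * sd)


def test_motif_posterior_covers_true_parameters(motif_study_result):
    """Central 95% credible intervals from the fitted true-model posterior
    should cover most generating parameter values (reduced-scale check)."""
    ps = motif_study_result.posteriors["M1"]
    truth = dict(studies.MOTIF_TRUE_PARAMS, sigma=studies.MOTIF_SIGMA)
    hits = 0
    for name, value in truth.items():
        lo, hi = np.percentile(ps.column(name), [2.5, 97.5])
        hits += lo <= value <= hi
    assert hits >= 0.8 * len(truth)


# ---------------------------------------------------------------------------
# thinning / persistence
# ---------------------------------------------------------------------------


def test_thin_even_stride_and_identity(linear_chains):
    ps = thin(linear_chains, 2000)
    assert len(ps) == 2000
    full = linear_chains.chain_at_one()
    np.testing.assert_array_equal(ps.draws[0], full[0])
    np.testing.assert_array_equal(ps.draws[-1], full[-1])
    ident = thin(linear_chains, full.shape[0])
    np.testing.assert_array_equal(ident.draws, full)
    with pytest.raises(ValueError, match="at least"):
        thin(linear_chains, full.shape[0] + 1)


def test_chains_hdf5_roundtrip(tmp_path, linear_chains):
    path = tmp_path / "chains.h5"
    linear_chains.to_hdf5(path)
    back = TemperedChains.from_hdf5(path)
    np.testing.assert_array_equal(back.draws, linear_chains.draws)
    np.testing.assert_array_equal(back.temperatures, linear_chains.temperatures)
    assert back.param_names == linear_chains.param_names
    assert back.seed == linear_chains.seed


# ---------------------------------------------------------------------------
# propriety check
# ---------------------------------------------------------------------------


def test_propriety_informative_data_is_proper(linear_benchmark):
    b = linear_benchmark
    prior = b["model"].default_prior(b["xi"])
    rep = check_propriety(
        b["model"], b["data"], prior, "theta_1",
        np.linspace(-3, 3, 13), sigma=b["sigma"],
    )
    assert rep.proper
    # unimodal profile: maximum away from the ends
    assert 0 < int(np.nanargmax(rep.log_profile)) < len(rep.grid) - 1


def test_propriety_flat_prior_dummy_parameter_is_improper():
    """A parameter the likelihood ignores, under an improper flat prior,
    leaves likelihood x prior flat along its axis."""
    model = LinearBasisModel([make_basis("poly", 0), ("zero", lambda t: 0.0 * t)])
    data = Dataset.from_records([("y", "1", 0.0, 0, 1.0), ("y", "1", 1.0, 0, 1.2)])
    prior = PriorSpec({"theta_1": GaussianPrior(1.0), "theta_2": FlatPrior()})
    rep = check_propriety(model, data, prior, "theta_2", np.linspace(-5, 5, 11), sigma=0.3)
    assert not rep.proper


def test_propriety_profile_follows_prior_without_data():
    """With a constant (empty-data) likelihood the profile is the prior."""
    model = LinearBasisModel([make_basis("poly", 1)], name="m")
    prior = PriorSpec({"theta_1": GammaPrior(2.0, 1.0)})
    grid = np.linspace(0.05, 8.0, 15)
    rep = check_propriety(model, Dataset.from_records([]), prior, "theta_1", grid, sigma=1.0)
    expected = prior.priors["theta_1"].logpdf(grid)
    np.testing.assert_allclose(rep.log_profile, expected, atol=1e-8)
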