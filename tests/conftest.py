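"""Shared fixtures: a conjugate linear benchmark and a reduced-scale motif
study, both reused across unit and acceptance tests to keep the suite fast."""

import numpy as np
import pytest

from ppdesign import (
    ParameterVector,
    analytic_posterior,
    population_mcmc,
)
from ppdesign.models import generate_data, regular_design
from ppdesign import studies


@pytest.fixture(scope="session")
def linear_benchmark():
    """Two-parameter regression model with data from known coefficients."""
    model = studies.linear_quartet()[1]  # theta_1 t + theta_2 t^2
    sigma, xi = 0.2, 1.0
    theta = ParameterVector({"theta_1": 0.8, "theta_2": -0.4})
    times = np.linspace(0.0, 2.0, 12)
    data = generate_data(model, theta, regular_design("y", times, 1), sigma, 42)
    return {
        "model": model,
        "data": data,
        "sigma": sigma,
        "xi": xi,
        "theta": theta,
        "posterior": analytic_posterior(model, data, sigma, xi),
    }


@pytest.fixture(scope="session")
def linear_chains(linear_benchmark):
    """Population-MCMC chains on the linear benchmark (conjugate oracle
    available for every downstream quantity)."""
    b = linear_benchmark
    return population_mcmc(
        b["model"],
        b["data"],
        b["model"].default_prior(b["xi"]),
        n_temps=40,
        n_samples=4000,
        seed=5,
        sigma=b["sigma"],
    )


@pytest.fixture(scope="session")
def motif_study_result():
    """Reduced-scale end-to-end motif study (four ODE models, population
    MCMC, design matrices, named validation experiments).

    Problem sizes are chosen for a fast suite: a short temperature ladder,
    a few thousand sweeps per model and 800 predictive draws; the JSD
    values carry corresponding Monte-Carlo error.
    """
    quartet = studies.motif_quartet()
    return studies.run_motif_study(
        quartet,
        n_temps=5,
        n_samples=2500,
        burn_in=2000,
        n_ppd=800,
        time_grid=(2.0, 5.0, 10.0, 20.0, 60.0),
        k=10,
        seed=7,
        atol=1e-7,
        rtol=1e-6,
    )
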