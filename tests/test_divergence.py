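"""The kNN Jensen-Shannon divergence estimator and its brute-force oracle."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from ppdesign import jsd_oracle, knn_density, knn_jsd, unit_ball_volume
from ppdesign.divergence import k_sensitivity


# ---------------------------------------------------------------------------
# unit ball volumes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d, expected",
    [(1, 2.0), (2, math.pi), (3, 4 * math.pi / 3)],
)
def test_unit_ball_volumes(d, expected):
    assert unit_ball_volume(d) == pytest.approx(expected, rel=1e-12)


def test_unit_ball_volume_rejects_nonpositive_dimension():
    with pytest.raises(ValueError):
        unit_ball_volume(0)


# ---------------------------------------------------------------------------
# kNN density
# ---------------------------------------------------------------------------


def test_knn_density_two_point_hand_computation():
    # query 0 in {0, 1} with leave-one-out: rho_1 = 1, density = (1/1)/(1*2)
    assert knn_density(0.0, np.array([0.0, 1.0]), k=1, leave_one_out=True) == pytest.approx(0.5)


def test_knn_density_scaling_change_of_variables():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    c = 3.7
    d1 = knn_density(0.2, x, k=10)
    d2 = knn_density(0.2 * c, x * c, k=10)
    assert d2 == pytest.approx(d1 / c, rel=1e-9)


def test_knn_density_consistent_for_uniform_sample():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, 20_000)
    est = knn_density(0.5, x, k=50)
    assert est == pytest.approx(1.0, abs=0.15)


def test_knn_density_requires_enough_neighbors():
    with pytest.raises(ValueError):
        knn_density(0.0, np.array([0.0, 1.0]), k=2, leave_one_out=True)


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------


def test_oracle_identical_densities_give_zero():
    p = stats.norm(0, 1).pdf
    assert jsd_oracle(p, p) == pytest.approx(0.0, abs=1e-9)


def test_oracle_disjoint_supports_saturate_at_one_bit():
    p = stats.norm(0, 0.1).pdf
    q = stats.norm(50, 0.1).pdf
    assert jsd_oracle(p, q) == pytest.approx(1.0, abs=1e-9)


def test_oracle_reproducible_across_integration_ranges():
    p = stats.norm(0, 1).pdf
    q = stats.norm(0, 2).pdf
    v1 = jsd_oracle(p, q)
    v2 = jsd_oracle(p, q, support=(-40, 40))
    assert v1 == pytest.approx(v2, abs=1e-6)


def test_oracle_rejects_unnormalized_density():
    with pytest.raises(ValueError, match="normalized"):
        jsd_oracle(lambda x: 2 * stats.norm.pdf(x), stats.norm.pdf)


def test_oracle_equals_mixture_classifier_mutual_information():
    """With equal weights the JSD is the mutual information between a draw
    from the two-model mixture and the model label; compute I = H(C) -
    E_y[H(C|y)] by quadrature as an independent route."""
    pa = stats.norm(0, 1).pdf
    pb = stats.norm(1.5, 0.7).pdf

    def h_cond(y):
        m = 0.5 * pa(y) + 0.5 * pb(y)
        w = 0.5 * pa(y) / m
        out = 0.0
        for wi in (w, 1 - w):
            if wi > 0:
                out -= wi * math.log2(wi)
        return out * m

    e_h, _ = quad(h_cond, -12, 12, limit=400)
    mi = 1.0 - e_h  # H(C) = 1 bit for equal weights
    assert jsd_oracle(pa, pb) == pytest.approx(mi, abs=1e-6)


def test_oracle_monte_carlo_mode_matches_quadrature():
    pa_d, pb_d = stats.norm(0, 1), stats.norm(1, 1)
    v_quad = jsd_oracle(pa_d.pdf, pb_d.pdf)
    v_mc = jsd_oracle(
        pa_d.pdf,
        pb_d.pdf,
        mc_samplers=(
            lambda rng, n: pa_d.rvs(n, random_state=rng),
            lambda rng, n: pb_d.rvs(n, random_state=rng),
        ),
        n_mc=200_000,
        seed=0,
    )
    assert v_mc == pytest.approx(v_quad, abs=5e-3)


# ---------------------------------------------------------------------------
# kNN JSD estimator
# ---------------------------------------------------------------------------


def test_knn_jsd_symmetry_is_exact():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, (1500, 2))
    b = rng.normal(0.5, 1.2, (1500, 2))
    assert knn_jsd(a, b, k=10).jsd_bits == knn_jsd(b, a, k=10).jsd_bits


def test_knn_jsd_interleaved_halves_of_one_sample_are_indistinguishable():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 8000)
    est = knn_jsd(x[::2], x[1::2], k=10)
    assert abs(est.jsd_bits) < 0.02


def test_knn_jsd_disjoint_clouds_saturate():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 3000)
    b = rng.normal(200, 1, 3000)
    assert knn_jsd(a, b, k=10).jsd_bits == pytest.approx(1.0, abs=0.02)


def test_knn_jsd_bounds_across_random_problems():
    rng = np.random.default_rng(5)
    for d in (1, 2, 3):
        for _ in range(3):
            mu = rng.normal(0, 1, d)
            a = rng.normal(0, 1, (1200, d))
            b = mu + rng.normal(0, 1, (1200, d)) * rng.uniform(0.5, 2)
            v = knn_jsd(a, b, k=10).jsd_bits
            assert -0.05 <= v <= 1.05


def test_knn_jsd_rigid_motion_invariance():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, (2000, 2))
    b = rng.normal(0.7, 1.1, (2000, 2))
    th = 1.1
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shift = np.array([5.0, -3.0])
    v1 = knn_jsd(a, b, k=10).jsd_bits
    v2 = knn_jsd(a @ rot.T + shift, b @ rot.T + shift, k=10).jsd_bits
    assert v1 == pytest.approx(v2, abs=1e-10)


def test_knn_jsd_consistency_error_shrinks_with_sample_size():
    """Median absolute error against the quadrature oracle decreases over
    N in {500, 2000, 10000} for 1-D and 2-D Gaussian pairs (median over 40
    seeds; fewer make the median itself too noisy to order)."""
    oracle_1d = jsd_oracle(stats.norm(0, 1).pdf, stats.norm(1, 1).pdf)
    for dim in (1, 2):
        med = []
        for n in (500, 2000, 10_000):
            errs = []
            for s in range(40):
                rng = np.random.default_rng(1000 * dim + s)
                a = rng.normal(0, 1, (n, dim))
                b = rng.normal(0, 1, (n, dim))
                b[:, 0] += 1.0
                errs.append(abs(knn_jsd(a, b, k=10).jsd_bits - oracle_1d))
            med.append(np.median(errs))
        assert med[2] < med[1] < med[0], (dim, med)


def test_knn_jsd_counts_degenerate_duplicates():
    a = np.zeros((50, 1))
    b = np.linspace(0, 1, 50)[:, None]
    est = knn_jsd(a, b, k=5)
    assert est.degeneracies > 0
    assert np.isfinite(est.jsd_bits)


def test_knn_jsd_validates_k():
    rng = np.random.default_rng(7)
    a, b = rng.normal(size=30), rng.normal(size=30)
    with pytest.raises(ValueError):
        knn_jsd(a, b, k=29)
    with pytest.raises(ValueError):
        knn_jsd(a, b, k=0)


def test_standardize_makes_estimate_scale_invariant():
    """Robust per-column scaling removes unit dependence: rescaling one
    coordinate of both samples leaves the standardized estimate unchanged
    while the raw-distance default shifts."""
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, (1500, 2))
    b = rng.normal(0.8, 1, (1500, 2))
    a2, b2 = a.copy(), b.copy()
    a2[:, 1] *= 1000
    b2[:, 1] *= 1000
    v_std = knn_jsd(a, b, k=10, standardize=True).jsd_bits
    v_std_scaled = knn_jsd(a2, b2, k=10, standardize=True).jsd_bits
    assert v_std_scaled == pytest.approx(v_std, abs=1e-9)
    v_raw_scaled = knn_jsd(a2, b2, k=10).jsd_bits
    assert abs(v_raw_scaled - v_std) > 0.02


def test_k_sensitivity_sweep_is_stable_for_easy_problem():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, 4000)
    b = rng.normal(4, 1, 4000)
    sweep = k_sensitivity(a, b, ks=(1, 5, 10, 20, 50))
    vals = np.array(list(sweep.values()))
    assert set(sweep) == {1, 5, 10, 20, 50}
    assert vals.std() < 0.05  # well-separated clouds: estimate barely moves with k
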