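"""k-nearest-neighbor estimation of the Jensen-Shannon divergence.

The design criterion is the JSD between two models' multivariate posterior
predictive samples.  With equal model weights the JSD is bounded in [0, 1]
bit and equals the mutual information between a draw from the two-component
predictive mixture and a model-identity classifier, which is exactly the
information a new measurement carries about which model is true.

Only samples of the predictive densities are available, so the densities
entering the KL integrals are replaced by kNN density estimates: the local
density at a point is k/N divided by the volume of the smallest Euclidean
ball containing its k nearest neighbors.  Substituting these estimates into
the JSD gives a closed-form statistic of k-th neighbor distances within and
across the two samples, evaluated here with exact k-d tree searches.

A brute-force quadrature / Monte-Carlo oracle for the JSD of known
densities is provided for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.spatial import cKDTree
from scipy.special import gammaln, polygamma

__all__ = [
    "DivergenceEstimate",
    "unit_ball_volume",
    "knn_density",
    "knn_jsd",
    "jsd_oracle",
    "k_sensitivity",
]

#: Floor applied to k-th neighbor distances, as a fraction of the per-column
#: scale.  The Q ratio is undefined at zero distance (exactly replicated
#: prediction vectors); flooring keeps it in (0, 2] and the number of floored
#: distances is reported.
DEGENERACY_FLOOR = 1e-12


@dataclass
class DivergenceEstimate:
    """A kNN-JSD value in bits together with the settings that produced it."""

    jsd_bits: float
    k: int
    n_a: int
    n_b: int
    d: int
    labels: tuple[str, str] = ("M1", "M2")
    weights: tuple[float, float] = (0.5, 0.5)
    degeneracies: int = 0

    def __float__(self) -> float:
        return self.jsd_bits

    def to_dict(self) -> dict:
        return {
            "jsd_bits": self.jsd_bits,
            "k": self.k,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "d": self.d,
            "labels": list(self.labels),
            "degeneracies": self.degeneracies,
        }


def unit_ball_volume(d: int) -> float:
    """Volume pi^(d/2) / Gamma(d/2 + 1) of the unit ball in R^d."""
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    return math.exp(0.5 * d * math.log(math.pi) - gammaln(0.5 * d + 1.0))


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("sample must be an (N, d) matrix")
    if not np.isfinite(a).all():
        raise ValueError("sample contains non-finite entries")
    return a


def knn_density(
    point,
    sample,
    k: int = 10,
    leave_one_out: bool = False,
) -> float:
    """kNN density estimate (k/N) / (rho_k^d * v_d) at one query point.

    ``rho_k`` is the Euclidean distance from the query to its k-th nearest
    neighbor in ``sample``.  With ``leave_one_out`` the query is assumed to
    be a member of the sample: its zero self-distance is skipped and N is
    reduced by one.
    """
    s = _as_matrix(sample)
    q = np.atleast_1d(np.asarray(point, dtype=float))
    n, d = s.shape
    n_eff = n - 1 if leave_one_out else n
    if k >= n_eff + 1:
        raise ValueError(f"k={k} requires more than {k} sample points (have {n_eff})")
    tree = cKDTree(s)
    kth = k + 1 if leave_one_out else k
    dist, _ = tree.query(q, k=kth)
    rho = float(np.atleast_1d(dist)[-1])
    if rho <= 0:
        rho = DEGENERACY_FLOOR
    return (k / n_eff) / (rho**d * unit_ball_volume(d))


def _floored(dist: np.ndarray, scale: float, counter: list[int]) -> np.ndarray:
    floor = DEGENERACY_FLOOR * max(scale, 1.0)
    bad = dist <= 0
    if bad.any():
        counter[0] += int(bad.sum())
        dist = np.where(bad, floor, dist)
    return dist


def knn_jsd(
    sample_a,
    sample_b,
    k: int = 10,
    labels: tuple[str, str] = ("M1", "M2"),
    bias_correction: bool = True,
    standardize: bool = False,
) -> DivergenceEstimate:
    """kNN Jensen-Shannon divergence between two predictive samples.

    For each point of each sample the Euclidean distance to its k-th nearest
    neighbor is found both in the *other* sample and in its *own* sample
    with the point itself excluded (exact k-d tree searches).  These
    distances form, per point i of sample a,

        Q_ab(i) = 2 N_b r_cross^d / (N_b r_cross^d + (N_a - 1) r_own^d)

    which is the estimated ratio of that model's predictive density to the
    equal-weight two-model mixture.  The divergence is the average of
    log2 Q over both samples, halved:

        D_js = mean_a(log2 Q_ab) / 2 + mean_b(log2 Q_ba) / 2

    The estimator is symmetric in its arguments and consistent for the true
    JSD in bits; small overshoots outside [0, 1] are possible at finite N.

    Averaging log2 Q, a concave function of the log density ratio whose
    k-th-neighbor fluctuation has variance ~ 2 psi'(k), incurs a finite-k
    Jensen bias of about -psi'(k) sigma(u) sigma(-u) / ln 2 per point
    (u the log ratio, sigma the logistic function): roughly -0.04 bits at
    k=10 for heavily overlapping samples, vanishing for well-separated
    ones and as k grows.  ``bias_correction`` (default on) subtracts this
    second-order term point by point, leaving the k -> infinity behavior
    untouched.

    Distances are computed on raw Euclidean coordinates by default.  With
    ``standardize`` every column of BOTH samples is divided by a robust
    scale (1.4826 x the pooled median absolute deviation), which stops one
    coordinate from dominating when a candidate mixes observables with very
    different units; this changes the estimate and is off by default.

    Duplicated prediction vectors produce zero distances where the ratio is
    undefined; those distances are floored and counted in ``degeneracies``.
    """
    a = _as_matrix(sample_a)
    b = _as_matrix(sample_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share dimension d")
    if standardize:
        pooled = np.concatenate([a, b])
        med = np.median(pooled, axis=0)
        mad = 1.4826 * np.median(np.abs(pooled - med), axis=0)
        mad = np.where(mad > 0, mad, 1.0)
        a = a / mad
        b = b / mad
    n_a, d = a.shape
    n_b = b.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= min(n_a, n_b) - 1:
        raise ValueError(
            f"k={k} too large for sample sizes ({n_a}, {n_b}); need k < min(N)-1"
        )
    scale = float(np.median(np.abs(np.concatenate([a, b]))) + 1.0)
    degen = [0]

    tree_a = cKDTree(a)
    tree_b = cKDTree(b)

    # distances to the k-th neighbor: cross-sample, and own-sample with the
    # query point excluded (hence k+1 ranks, dropping the zero self-distance)
    d_ab = tree_b.query(a, k=k)[0]
    d_ab = d_ab[:, -1] if k > 1 else np.ravel(d_ab)
    d_aa = tree_a.query(a, k=k + 1)[0][:, -1]
    d_ba = tree_a.query(b, k=k)[0]
    d_ba = d_ba[:, -1] if k > 1 else np.ravel(d_ba)
    d_bb = tree_b.query(b, k=k + 1)[0][:, -1]

    d_ab = _floored(d_ab, scale, degen)
    d_aa = _floored(d_aa, scale, degen)
    d_ba = _floored(d_ba, scale, degen)
    d_bb = _floored(d_bb, scale, degen)

    trigamma_k = float(polygamma(1, k))

    def mean_log2_q(cross, own, n_other, n_own):
        # log Q on the log scale to avoid overflow of r^d for large d
        lc = d * np.log(cross) + math.log(n_other)
        lo = d * np.log(own) + math.log(n_own - 1)
        u = lc - lo
        # log2 Q = 1 - log2(1 + e^{-u}), evaluated stably
        log2_q = (math.log(2.0) + np.minimum(u, 0.0) - np.log1p(np.exp(-np.abs(u)))) / math.log(2.0)
        if bias_correction:
            # Jensen debias: Var(u) ~ 2 psi'(k), curvature -sig(u) sig(-u)/ln 2
            sig = 1.0 / (1.0 + np.exp(-np.abs(u)))
            log2_q = log2_q + trigamma_k * sig * (1.0 - sig) / math.log(2.0)
        return float(np.mean(log2_q))

    jsd = 0.5 * mean_log2_q(d_ab, d_aa, n_b, n_a) + 0.5 * mean_log2_q(
        d_ba, d_bb, n_a, n_b
    )
    return DivergenceEstimate(
        jsd_bits=jsd,
        k=k,
        n_a=n_a,
        n_b=n_b,
        d=d,
        labels=labels,
        degeneracies=degen[0],
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _finite_bounds(pdfs, lo, hi):
    """Bracket the union of the densities' effective supports and collect
    breakpoints at their peaks, so adaptive quadrature cannot overlook a
    narrow peak on a wide interval."""
    if np.isfinite(lo) and np.isfinite(hi):
        probe_lo, probe_hi = float(lo), float(hi)
        xs = np.linspace(probe_lo, probe_hi, 801)
    else:
        xs = np.concatenate(
            [-np.logspace(-3, 4, 400)[::-1], [0.0], np.logspace(-3, 4, 400)]
        )
    keep = np.zeros(xs.shape, dtype=bool)
    peaks = []
    for p in pdfs:
        v = np.array([float(p(x)) for x in xs])
        vmax = v.max()
        if vmax <= 0:
            raise ValueError("density evaluates to zero everywhere on the probe grid")
        keep |= v > vmax * 1e-14
        peaks.append(float(xs[int(np.argmax(v))]))
    sel = xs[keep]
    span = sel.max() - sel.min() + 1.0
    if np.isfinite(lo) and np.isfinite(hi):
        return float(lo), float(hi), sorted(peaks)
    return float(sel.min() - 0.2 * span), float(sel.max() + 0.2 * span), sorted(peaks)


def _check_normalized(pdf, lo, hi, points, tol=1e-4):
    total, _ = quad(pdf, lo, hi, limit=400, points=points)
    if abs(total - 1.0) > tol:
        raise ValueError(f"density is not normalized: integral={total:.6f}")


def jsd_oracle(
    density_a,
    density_b,
    weights: tuple[float, float] = (0.5, 0.5),
    support: tuple[float, float] = (-np.inf, np.inf),
    mc_samplers=None,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Jensen-Shannon divergence (bits) of two known densities.

    In one dimension the two KL integrals against the mixture are evaluated
    by adaptive quadrature over ``support`` after checking normalization.
    For higher dimensions, supply ``mc_samplers=(draw_a, draw_b)`` (each a
    callable ``rng, n -> (n, d) array``) and the divergence is estimated by
    Monte Carlo averaging of the log density ratios under each component.
    ``density_a``/``density_b`` are callables returning the pdf at a point
    (vectorized for the MC path).
    """
    w_a, w_b = weights
    if abs(w_a + w_b - 1.0) > 1e-12 or w_a < 0 or w_b < 0:
        raise ValueError("weights must be nonnegative and sum to 1")

    if mc_samplers is None:
        lo, hi, peaks = _finite_bounds((density_a, density_b), *support)
        _check_normalized(density_a, lo, hi, peaks)
        _check_normalized(density_b, lo, hi, peaks)

        def kl_to_mixture(p, q, w_p, w_q):
            def integrand(x):
                px = p(x)
                if px <= 0:
                    return 0.0
                mx = w_p * px + w_q * q(x)
                return px * math.log2(px / mx)

            val, _ = quad(integrand, lo, hi, limit=400, points=peaks)
            return val

        return w_a * kl_to_mixture(density_a, density_b, w_a, w_b) + w_b * kl_to_mixture(
            density_b, density_a, w_b, w_a
        )

    rng = np.random.default_rng(seed)
    draw_a, draw_b = mc_samplers
    out = 0.0
    for w, draw, p, q, w_p, w_q in (
        (w_a, draw_a, density_a, density_b, w_a, w_b),
        (w_b, draw_b, density_b, density_a, w_b, w_a),
    ):
        if w == 0:
            continue
        x = draw(rng, n_mc)
        px = np.asarray(p(x), dtype=float)
        mx = w_p * px + w_q * np.asarray(q(x), dtype=float)
        out += w * float(np.mean(np.log2(px / mx)))
    return out


def k_sensitivity(
    sample_a,
    sample_b,
    ks=(1, 5, 10, 20, 50),
) -> dict[int, float]:
    """JSD estimates across a sweep of k, for judging estimator stability.

    Accuracy of the neighbor-distance density estimates degrades as the
    candidate dimension grows, so a stable plateau across k is a useful
    sanity check before trusting a ranking.
    """
    return {k: knn_jsd(sample_a, sample_b, k=k).jsd_bits for k in ks}
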