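"""Kernel dependence statistics shared by feature selection and CI testing.

Implements the biased (V-statistic) Hilbert–Schmidt independence criterion
HSIC_b = trace(K H L H) / n² with Gaussian kernels and the median-distance
bandwidth heuristic, squared sample distance covariance via double-centered
Euclidean distance matrices, and the standard two-moment gamma approximation
to the permutation null of either statistic.

Distance covariance is the same V-statistic evaluated on the distance-induced
kernel: with A = H D_x H and B = H D_y H (double-centered distance matrices),
dCov²(x, y) = mean(A ∘ B) = HSIC_b with centered kernels −A/2, −B/2, up to the
factor 4.  The gamma machinery therefore operates on centered kernel matrices
and serves both statistics.
"""

from __future__ import annotations

import numpy as np
import scipy.spatial.distance
import scipy.stats

__all__ = [
    "median_bandwidth",
    "gaussian_kernel",
    "center_kernel",
    "hsic_statistic",
    "centered_distance",
    "dcov_statistic",
    "gamma_pvalue",
    "GammaFitError",
]

_MAX_HEURISTIC_PAIRS = 1000


class GammaFitError(RuntimeError):
    """The two-moment gamma fit to the null is degenerate."""


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("samples must be a vector or an n × d matrix")
    return x


def median_bandwidth(x: np.ndarray, seed: int = 0) -> float:
    """Median pairwise Euclidean distance of the rows of ``x``.

    For n(n−1)/2 > 1000 a seeded subsample of 1000 pairs is used, so the
    value is deterministic for a given input.  A zero median (heavily tied
    data) falls back to bandwidth 1.
    """
    x = _as_2d(x)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two samples for the median heuristic")
    if n * (n - 1) // 2 <= _MAX_HEURISTIC_PAIRS:
        d = scipy.spatial.distance.pdist(x)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=_MAX_HEURISTIC_PAIRS)
        j = rng.integers(0, n - 1, size=_MAX_HEURISTIC_PAIRS)
        j = np.where(j >= i, j + 1, j)  # j != i, uniform over off-diagonal pairs
        d = np.linalg.norm(x[i] - x[j], axis=1)
    med = float(np.median(d))
    return med if med > 0 else 1.0


def gaussian_kernel(x: np.ndarray, bandwidth: float | None = None, seed: int = 0) -> np.ndarray:
    """Gaussian kernel matrix exp(−‖xi−xj‖² / (2σ²)) with median-heuristic default σ."""
    x = _as_2d(x)
    if bandwidth is None:
        bandwidth = median_bandwidth(x, seed=seed)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sq = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x, "sqeuclidean"))
    return np.exp(-sq / (2.0 * bandwidth**2))


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a kernel matrix: H K H with H = I − 11ᵀ/n."""
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


def hsic_statistic(
    x: np.ndarray,
    y: np.ndarray,
    bandwidth_x: float | None = None,
    bandwidth_y: float | None = None,
) -> float:
    """Biased HSIC estimator trace(K H L H)/n² between samples ``x`` and ``y``."""
    x, y = _as_2d(x), _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    if x.shape[0] < 2:
        raise ValueError("HSIC requires at least two samples")
    Kc = center_kernel(gaussian_kernel(x, bandwidth_x))
    Lc = center_kernel(gaussian_kernel(y, bandwidth_y))
    return float((Kc * Lc).mean())


def centered_distance(x: np.ndarray) -> np.ndarray:
    """Double-centered Euclidean distance matrix H D H."""
    x = _as_2d(x)
    D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    return center_kernel(D)


def dcov_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Squared sample distance covariance mean(A ∘ B) (V-statistic)."""
    x, y = _as_2d(x), _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    if x.shape[0] < 2:
        raise ValueError("distance covariance requires at least two samples")
    return float((centered_distance(x) * centered_distance(y)).mean())


def gamma_pvalue(Kc: np.ndarray, Lc: np.ndarray, variance_floor: float = 1e-12) -> tuple[float, float]:
    """Two-moment gamma approximation to the permutation null of mean(Kc ∘ Lc).

    ``Kc`` and ``Lc`` are centered kernel matrices.  The null mean and
    variance of the scaled statistic T = n · mean(Kc ∘ Lc) under independence
    are estimated with the standard HSIC moment formulas

        E[T]   ≈ tr(Kc) tr(Lc) / (n−1)²
        Var[T] ≈ n² · 2(n−4)(n−5) / (n(n−1)(n−2)(n−3)) · mean_offdiag((Kc ∘ Lc)²)

    and T is referred to the matched Gamma(shape, scale).  Returns
    ``(statistic, p_value)`` where statistic is mean(Kc ∘ Lc) (unscaled).

    Raises
    ------
    GammaFitError
        If the fitted mean or variance is not positive (degenerate input);
        callers fall back to a permutation test.
    """
    n = Kc.shape[0]
    if n < 6:
        raise GammaFitError("gamma approximation needs at least 6 samples")
    stat = float((Kc * Lc).mean())
    test_stat = n * stat
    mean = float(np.trace(Kc) * np.trace(Lc)) / (n - 1) ** 2 / n  # E[mean(Kc∘Lc)]
    mean *= n  # scale to T
    prod_sq = (Kc * Lc) ** 2
    off_mean = (prod_sq.sum() - np.trace(prod_sq)) / (n * (n - 1))
    var = 2.0 * (n - 4) * (n - 5) / (n * (n - 1) * (n - 2) * (n - 3)) * off_mean * n**2
    var = max(var, variance_floor)
    if mean <= 0:
        raise GammaFitError("non-positive null mean in gamma fit")
    shape = mean**2 / var
    scale = var / mean
    p = float(scipy.stats.gamma.sf(test_stat, a=shape, scale=scale))
    return stat, min(max(p, 0.0), 1.0)


def permutation_pvalue(
    Kc: np.ndarray,
    Lc: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation p-value for mean(Kc ∘ Lc) with the add-one estimator.

    One argument's samples are permuted ``n_permutations`` times;
    p = (1 + #{perm ≥ observed}) / (1 + B), so p is never 0.
    """
    n = Kc.shape[0]
    observed = float((Kc * Lc).mean())
    exceed = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        if float((Kc[np.ix_(idx, idx)] * Lc).mean()) >= observed:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_permutations)
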