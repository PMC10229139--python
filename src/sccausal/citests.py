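"""Conditional-independence tests X ⫫ Y | S pluggable into the PC algorithm.

Seven tests are provided, selected by tag:

``gauss``
    Partial correlation with the Fisher z transform; assumes joint
    Gaussianity and linear relationships.
``hsic.gamma`` / ``hsic.perm``
    Gaussian-kernel HSIC with a two-moment gamma null or a permutation null.
    Conditioning residualizes each tested variable on the conditioning set by
    kernel ridge regression before the unconditional test.
``dcc.gamma`` / ``dcc.perm``
    Squared distance covariance with the same null handling and the same
    residualization scheme.
``rcit`` / ``rcot``
    Random-Fourier-feature approximations of the kernel conditional
    independence test; the null is a weighted chi-square handled with
    Hall–Buckley–Eagleson moment matching.  ``rcot`` residualizes the
    features of both X and Y on the features of S; ``rcit`` builds the Y
    features on (Y, S) jointly (its published asymmetric scheme).

All tests standardize each used column to zero mean and unit variance first
and return a :class:`CITestResult` with the statistic and a p-value in [0,1].
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Sequence

import numpy as np
import scipy.linalg
import scipy.stats

from . import kernels
from .kernels import GammaFitError

__all__ = ["CITester", "CITestResult", "gauss_ci_test", "hsic_test", "dcov_test", "rcot_test", "METHODS"]

METHODS = ("gauss", "hsic.gamma", "hsic.perm", "dcc.gamma", "dcc.perm", "rcit", "rcot")


class ValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test."""

    statistic: float
    p_value: float
    method: str
    cond_size: int
    n_used: int
    warning: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _check_args(data: np.ndarray, i: int, j: int, S: Sequence[int]) -> tuple[np.ndarray, tuple[int, ...]]:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be an n × p matrix (columns = variables)")
    S = tuple(sorted(int(s) for s in S))
    if i == j:
        raise ValidationError("i and j must differ")
    if i in S or j in S:
        raise ValidationError("tested variables cannot appear in the conditioning set")
    n = data.shape[0]
    if n <= len(S) + 3:
        raise ValidationError(f"need n > |S| + 3 samples (n={n}, |S|={len(S)})")
    return data, S


def gauss_ci_test(data: np.ndarray, i: int, j: int, S: Sequence[int] = ()) -> CITestResult:
    """Partial-correlation CI test with the Fisher z transform.

    The partial correlation r of columns i, j given S comes from inverting
    the correlation matrix of (i, j, S); z = √(n−|S|−3) · ½ ln((1+r)/(1−r))
    is referred to N(0,1) two-sided.  A singular correlation matrix is
    ridge-regularized and flagged in the result.
    """
    data, S = _check_args(data, i, j, S)
    n = data.shape[0]
    cols = [i, j, *S]
    sub = _standardize(data[:, cols])
    corr = (sub.T @ sub) / n
    warning = None
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        prec = np.linalg.inv(corr + 1e-8 * np.eye(corr.shape[0]))
        warning = "singular correlation matrix; ridge-regularized"
    if not np.isfinite(prec).all() or prec[0, 0] * prec[1, 1] <= 0:
        prec = np.linalg.inv(corr + 1e-8 * np.eye(corr.shape[0]))
        warning = "singular correlation matrix; ridge-regularized"
    r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.sqrt(n - len(S) - 3) * np.arctanh(r)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return CITestResult(float(z), min(p, 1.0), "gauss", len(S), n, warning)


def _kernel_ridge_residuals(y: np.ndarray, Ks: np.ndarray, cho_factor) -> np.ndarray:
    """Residual of y after Gaussian-kernel ridge regression on the conditioning set."""
    alpha = scipy.linalg.cho_solve(cho_factor, y)
    return y - Ks @ alpha


@dataclasses.dataclass
class CITester:
    """Named CI-test specification usable as the PC algorithm's decision rule.

    Parameters
    ----------
    method
        One of :data:`METHODS`.
    permutations
        Null permutations B for the ``.perm`` variants (≥ 19; add-one
        estimator keeps p ≥ 1/(B+1)).
    f_xy, f_z
        Random Fourier feature counts for rcit/rcot (defaults 5 and 25).
    ridge
        Ridge weight of the kernel regression used to residualize on S.
    seed
        Seeds permutations and Fourier features; fixed seed ⇒ identical
        p-values across runs.
    """

    method: str = "dcc.gamma"
    permutations: int = 100
    f_xy: int = 5
    f_z: int = 25
    bandwidth: float | None = None
    ridge: float = 1e-3
    seed: int = 0
    cache: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown CI test {self.method!r}; choose from {METHODS}")
        if self.method.endswith(".perm") and self.permutations < 19:
            raise ValidationError("permutation tests require B >= 19")
        if self.method in ("rcit", "rcot") and (self.f_xy < 1 or self.f_z < 1):
            raise ValidationError("rcit/rcot require f_xy >= 1 and f_z >= 1")
        self._residual_cache: dict[Hashable, np.ndarray] = {}
        self._chol_cache: dict[Hashable, tuple] = {}
        self._data_key: int | None = None

    # -- caching ---------------------------------------------------------
    def _sync_cache(self, data: np.ndarray) -> None:
        key = (id(data), data.shape)
        if key != self._data_key:
            self._data_key = key
            self._residual_cache.clear()
            self._chol_cache.clear()

    def _residualize(self, data: np.ndarray, col: int, S: tuple[int, ...]) -> np.ndarray:
        """Column ``col`` minus its kernel ridge fit on columns ``S`` (standardized)."""
        ckey = (col, S)
        if self.cache and ckey in self._residual_cache:
            return self._residual_cache[ckey]
        n = data.shape[0]
        y = _standardize(data[:, col])
        if self.cache and S in self._chol_cache:
            Ks, cho = self._chol_cache[S]
        else:
            Zs = _standardize(data[:, list(S)])
            Ks = kernels.gaussian_kernel(Zs, self.bandwidth, seed=self.seed)
            cho = scipy.linalg.cho_factor(Ks + n * self.ridge * np.eye(n))
            if self.cache:
                self._chol_cache[S] = (Ks, cho)
        res = _kernel_ridge_residuals(y, Ks, cho)
        if self.cache:
            self._residual_cache[ckey] = res
        return res

    # -- dispatch --------------------------------------------------------
    def test(self, data: np.ndarray, i: int, j: int, S: Sequence[int] = ()) -> CITestResult:
        if self.method == "gauss":
            return gauss_ci_test(data, i, j, S)
        if self.method.startswith("hsic."):
            return hsic_test(data, i, j, S, self.method.split(".")[1], self)
        if self.method.startswith("dcc."):
            return dcov_test(data, i, j, S, self.method.split(".")[1], self)
        return rcot_test(data, i, j, S, self.method, self)


def _perm_rng(params: CITester, i: int, j: int, S: tuple[int, ...]) -> np.random.Generator:
    # independent but reproducible stream per (seed, i, j, S)
    return np.random.default_rng([params.seed, i, j, *S, 0x5EED])


def _conditional_xy(
    data: np.ndarray, i: int, j: int, S: tuple[int, ...], params: CITester
) -> tuple[np.ndarray, np.ndarray]:
    if S:
        params._sync_cache(data)
        x = params._residualize(data, i, S)
        y = params._residualize(data, j, S)
    else:
        x = _standardize(data[:, i])
        y = _standardize(data[:, j])
    return x, y


def hsic_test(
    data: np.ndarray, i: int, j: int, S: Sequence[int] = (), variant: str = "gamma",
    params: CITester | None = None,
) -> CITestResult:
    """HSIC-based CI test (``gamma`` or ``perm`` null); see module docstring."""
    params = params or CITester(method=f"hsic.{variant}")
    data, S = _check_args(data, i, j, S)
    i, j = min(i, j), max(i, j)  # the test is symmetric; canonical order fixes the perm stream
    x, y = _conditional_xy(data, i, j, S, params)
    Kc = kernels.center_kernel(kernels.gaussian_kernel(x, params.bandwidth, seed=params.seed))
    Lc = kernels.center_kernel(kernels.gaussian_kernel(y, params.bandwidth, seed=params.seed))
    return _null_pvalue(Kc, Lc, f"hsic.{variant}", variant, data.shape[0], S, params, i, j)


def dcov_test(
    data: np.ndarray, i: int, j: int, S: Sequence[int] = (), variant: str = "gamma",
    params: CITester | None = None,
) -> CITestResult:
    """Distance-covariance CI test (``gamma`` or ``perm`` null)."""
    params = params or CITester(method=f"dcc.{variant}")
    data, S = _check_args(data, i, j, S)
    i, j = min(i, j), max(i, j)
    x, y = _conditional_xy(data, i, j, S, params)
    # dCov² = mean(A∘B) with A = H Dx H; −A/2 is the centered distance-induced kernel
    A = kernels.centered_distance(x)
    B = kernels.centered_distance(y)
    return _null_pvalue(-A / 2.0, -B / 2.0, f"dcc.{variant}", variant, data.shape[0], S, params, i, j)


def _null_pvalue(
    Kc: np.ndarray, Lc: np.ndarray, method: str, variant: str, n: int,
    S: tuple[int, ...], params: CITester, i: int, j: int,
) -> CITestResult:
    warning = None
    if variant == "gamma":
        try:
            stat, p = kernels.gamma_pvalue(Kc, Lc)
            return CITestResult(stat, p, method, len(S), n, None)
        except GammaFitError:
            warning = "degenerate gamma fit; fell back to permutation null"
    if params.permutations < 19:
        raise ValidationError("permutation tests require B >= 19")
    stat, p = kernels.permutation_pvalue(Kc, Lc, params.permutations, _perm_rng(params, i, j, S))
    return CITestResult(stat, p, method, len(S), n, warning)


# -- random Fourier features ---------------------------------------------

def _rff(x: np.ndarray, n_features: int, rng: np.random.Generator) -> np.ndarray:
    """Random Fourier features of a Gaussian kernel with median-heuristic bandwidth."""
    if x.ndim == 1:
        x = x[:, None]
    bw = kernels.median_bandwidth(x)
    w = rng.standard_normal((x.shape[1], n_features)) / bw
    b = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
    return np.sqrt(2.0 / n_features) * np.cos(x @ w + b)


def _hbe_pvalue(coeffs: np.ndarray, x: float) -> float:
    """Hall–Buckley–Eagleson p-value for P(Σ λ_k χ²₁ ≥ x)."""
    coeffs = coeffs[coeffs > 0]
    if coeffs.size == 0:
        return 1.0
    k1 = coeffs.sum()
    k2 = 2.0 * (coeffs**2).sum()
    k3 = 8.0 * (coeffs**3).sum()
    if k2 <= 0 or k3 <= 0:
        return 1.0
    nu = 8.0 * k2**3 / k3**2
    t = (x - k1) * np.sqrt(2.0 * nu / k2) + nu
    return float(scipy.stats.chi2.sf(t, df=nu))


def rcot_test(
    data: np.ndarray, i: int, j: int, S: Sequence[int] = (), variant: str = "rcot",
    params: CITester | None = None,
) -> CITestResult:
    """Fourier-feature approximation of the kernel CI test (``rcit``/``rcot``).

    With S = ∅ both variants coincide with the unconditional Fourier-feature
    independence test; the statistic is n ‖cov(f_x, f_y)‖²_F and the null a
    weighted chi-square evaluated by Hall–Buckley–Eagleson moment matching.
    """
    if variant not in ("rcit", "rcot"):
        raise ValidationError(f"unknown variant {variant!r}")
    params = params or CITester(method=variant)
    if params.f_xy < 1 or params.f_z < 1:
        raise ValidationError("rcit/rcot require f_xy >= 1 and f_z >= 1")
    data, S = _check_args(data, i, j, S)
    if variant == "rcot":
        i, j = min(i, j), max(i, j)  # rcot is symmetric; rcit's Y block is asymmetric by design
    n = data.shape[0]
    rng = np.random.default_rng([params.seed, 0xF0F0])
    x = _standardize(data[:, i])[:, None]
    y = _standardize(data[:, j])[:, None]
    fx = _rff(x, params.f_xy, rng)
    if S and variant == "rcit":
        z_cols = _standardize(data[:, list(S)])
        fy = _rff(np.hstack([y, z_cols]), params.f_xy, rng)
    else:
        fy = _rff(y, params.f_xy, rng)
    fx = fx - fx.mean(axis=0)
    fy = fy - fy.mean(axis=0)
    if S:
        fz = _rff(_standardize(data[:, list(S)]), params.f_z, rng)
        fz = fz - fz.mean(axis=0)
        # partial the S features out of both blocks by ridge-stabilized OLS
        gram = fz.T @ fz + 1e-10 * np.eye(fz.shape[1])
        beta_x = np.linalg.solve(gram, fz.T @ fx)
        beta_y = np.linalg.solve(gram, fz.T @ fy)
        fx = fx - fz @ beta_x
        fy = fy - fz @ beta_y
    Cxy = fx.T @ fy / n
    stat = float(n * (Cxy**2).sum())
    # null weights: eigenvalues of the covariance of the feature products
    prods = fx[:, :, None] * fy[:, None, :]
    prods = prods.reshape(n, -1)
    cov = np.cov(prods, rowvar=False)
    cov = np.atleast_2d(cov)
    eigs = np.linalg.eigvalsh(cov)
    p = _hbe_pvalue(eigs, stat)
    return CITestResult(stat, min(max(p, 0.0), 1.0), variant, len(S), n, None)
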