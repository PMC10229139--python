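"""Unit-level behavior of the seven conditional-independence tests."""

import math

import numpy as np
import pytest
import scipy.stats

import sccausal as sc
from sccausal.citests import CITester, ValidationError
from sccausal.kernels import dcov_statistic

KERNEL_METHODS = ("hsic.gamma", "hsic.perm", "dcc.gamma", "dcc.perm")


def _chain(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 2.0 * x + rng.standard_normal(n)
    z = -1.5 * y + rng.standard_normal(n)
    return np.column_stack([x, y, z])


class TestGauss:
    def test_matches_residual_regression_oracle(self):
        """Partial correlation + Fisher z agrees with an independent
        least-squares residualization implementation to 1e-10."""
        data = _chain(500, 42)
        res = sc.gauss_ci_test(data, 0, 2, [1])
        ones = np.column_stack([np.ones(500), data[:, 1]])
        ri = data[:, 0] - ones @ np.linalg.lstsq(ones, data[:, 0], rcond=None)[0]
        rj = data[:, 2] - ones @ np.linalg.lstsq(ones, data[:, 2], rcond=None)[0]
        r = np.corrcoef(ri, rj)[0, 1]
        z = math.sqrt(500 - 1 - 3) * np.arctanh(r)
        p = 2 * scipy.stats.norm.sf(abs(z))
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_correlation_gives_p_one(self):
        data = np.column_stack([[1.0, 1, -1, -1], [1.0, -1, 1, -1]])
        res = sc.gauss_ci_test(data, 0, 1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_unconditional_calibration(self):
        rej = 0
        for r in range(200):
            rng = np.random.default_rng(r)
            rej += sc.gauss_ci_test(rng.standard_normal((1000, 2)), 0, 1).p_value < 0.05
        assert 0.02 <= rej / 200 <= 0.09

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            sc.gauss_ci_test(np.zeros((4, 3)), 0, 1, [2])


class TestKernelTests:
    def test_perm_constant_input_gives_p_one(self):
        data = np.column_stack([np.ones(30), np.arange(30.0)])
        res = sc.hsic_test(data, 0, 1, variant="perm")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_add_one_permutation_estimator_floor(self):
        # strong dependence, B = 19: observed beats every permutation → p = 1/20
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        data = np.column_stack([x, x])
        res = sc.hsic_test(data, 0, 1, variant="perm", params=CITester("hsic.perm", permutations=19))
        assert res.p_value == pytest.approx(1 / 20)

    def test_b_below_19_rejected(self):
        with pytest.raises(ValidationError):
            CITester("hsic.perm", permutations=5)

    def test_dcov_self_dependence_is_distance_variance(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert dcov_statistic(x, x) == pytest.approx(0.8125, abs=1e-12)  # brute-force dVar
        dcor = dcov_statistic(x, x) / math.sqrt(dcov_statistic(x, x) * dcov_statistic(x, x))
        assert dcor == pytest.approx(1.0)

    def test_dcov_brute_force_fixture(self):
        # frozen by explicit 4×4 double-centered evaluation
        assert dcov_statistic(np.array([0.0, 1, 2, 3]), np.array([3.0, 1, 2, 0])) == pytest.approx(
            0.5625, abs=1e-12
        )

    @pytest.mark.parametrize("method", ["gauss", *KERNEL_METHODS])
    def test_symmetry_in_i_and_j(self, method):
        data = _chain(80, 5)
        tester = CITester(method, permutations=50, seed=3)
        a = tester.test(data, 0, 2, [1]).p_value
        b = tester.test(data, 2, 0, [1]).p_value
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("method", ["hsic.gamma", "hsic.perm", "dcc.gamma", "dcc.perm"])
    def test_quadratic_power(self, method):
        """y = x² + small noise is detected in ≥ 90 % of replicates at n=300."""
        rej = 0
        for r in range(40):
            rng = np.random.default_rng(1000 + r)
            x = rng.standard_normal(300)
            y = x**2 + 0.3 * rng.standard_normal(300)
            tester = CITester(method, seed=r)
            rej += tester.test(np.column_stack([x, y]), 0, 1).p_value < 0.05
        assert rej >= 36

    def test_gamma_and_perm_rank_pvalues_alike(self):
        """Across a 50-scenario dependence grid (within the permutation
        resolution), gamma and permutation p-values agree in rank order."""
        strengths = np.linspace(0.0, 0.3, 50)
        for base in ("hsic", "dcc"):
            pvals = {"gamma": [], "perm": []}
            for variant in pvals:
                for idx, s in enumerate(strengths):
                    rng = np.random.default_rng(9000 + idx)
                    x = rng.standard_normal(150)
                    y = s * x**2 + rng.standard_normal(150)
                    tester = CITester(f"{base}.{variant}", permutations=100, seed=idx)
                    pvals[variant].append(tester.test(np.column_stack([x, y]), 0, 1).p_value)
            rho = scipy.stats.spearmanr(pvals["gamma"], pvals["perm"]).statistic
            assert rho >= 0.9, f"{base}: spearman {rho:.3f}"


class TestFourierTests:
    def test_fixed_seed_reproducible(self):
        data = _chain(200, 11)
        for method in ("rcit", "rcot"):
            tester = CITester(method, seed=4)
            a = tester.test(data, 0, 2, [1]).p_value
            b = CITester(method, seed=4).test(data, 0, 2, [1]).p_value
            assert a == b

    def test_feature_count_validation(self):
        with pytest.raises(ValidationError):
            CITester("rcot", f_xy=0)

    def test_detects_quadratic_dependence(self):
        rej = 0
        for r in range(40):
            rng = np.random.default_rng(500 + r)
            x = rng.standard_normal(300)
            y = x**2 + 0.3 * rng.standard_normal(300)
            rej += CITester("rcot", seed=r).test(np.column_stack([x, y]), 0, 1).p_value < 0.05
        assert rej >= 34

    def test_conditioning_removes_chain_dependence(self):
        # X → Y → Z: marginal X,Z dependence must vanish given Y
        for method in ("rcit", "rcot"):
            p_cond, p_marg = [], []
            for seed in range(10):
                data = _chain(400, seed)
                tester = CITester(method, seed=seed)
                p_cond.append(tester.test(data, 0, 2, [1]).p_value)
                p_marg.append(tester.test(data, 0, 2, []).p_value)
            assert max(p_marg) < 0.01
            assert np.median(p_cond) > 0.1


class TestResultContract:
    @pytest.mark.parametrize("method", sc.METHODS)
    def test_pvalue_in_unit_interval_and_metadata(self, method):
        data = _chain(100, 31)
        res = CITester(method, permutations=30, seed=1).test(data, 0, 2, [1])
        assert 0.0 <= res.p_value <= 1.0
        assert res.cond_size == 1
        assert res.n_used == 100

    def test_i_equals_j_rejected(self):
        with pytest.raises(ValidationError):
            sc.gauss_ci_test(np.random.default_rng(0).standard_normal((50, 2)), 0, 0)

    def test_conditioning_on_tested_variable_rejected(self):
        with pytest.raises(ValidationError):
            sc.hsic_test(np.random.default_rng(0).standard_normal((50, 3)), 0, 1, [0])
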