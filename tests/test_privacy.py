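"""Privatization mechanisms, the Laplace mixture and the l1 projection."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from ldpcusum import (
    ChangeModel,
    IndicatorLaplaceMechanism,
    LaplaceMixture,
    TruncationLaplaceMechanism,
    mixture_log_ratio,
    np_region,
    project_l1_ball,
    region_probabilities,
    verify_ldp,
)
from ldpcusum.privacy import mixture_log_ratio_bounds


@pytest.fixture
def indicator_mech(gaussian_shift):
    return IndicatorLaplaceMechanism(1.0, np_region(gaussian_shift))


class TestIndicatorMechanism:
    def test_noise_free_output_is_indicator(self, indicator_mech):
        assert indicator_mech.privatize(1.3, noise=0.0) == 1.0
        assert indicator_mech.privatize(-0.2, noise=0.0) == 0.0

    def test_output_distribution_is_shifted_laplace(self, indicator_mech):
        # x in A: Z = 1 + Lap(1/alpha)
        rng = np.random.default_rng(0)
        z = indicator_mech.privatize(np.full(10**5, 2.0), rng)
        stat, pval = stats.kstest(z, stats.laplace(1.0, 1.0).cdf)
        assert pval > 0.01

    def test_invalid_alpha_rejected(self, gaussian_shift):
        with pytest.raises(ValueError):
            IndicatorLaplaceMechanism(0.0, np_region(gaussian_shift))

    def test_privatized_histogram_matches_mixture(self, gaussian_shift):
        """Under f_i, the privatized output follows the two-component
        Laplace mixture with weight p_i (chi-square GOF at level 0.01)."""
        alpha = 1.0
        region = np_region(gaussian_shift)
        mech = IndicatorLaplaceMechanism(alpha, region)
        p0, p1 = region_probabilities(gaussian_shift, region)
        rng = np.random.default_rng(123)
        for which, p in ((0, p0), (1, p1)):
            x = gaussian_shift.sample(which, 10**5, rng)
            z = mech.privatize(x, rng)
            mix = LaplaceMixture(alpha, p)
            edges = np.linspace(-4.0, 5.0, 30)
            # fold the tails into the end bins so every draw is counted
            z = np.clip(z, edges[0] + 1e-9, edges[-1] - 1e-9)
            obs, _ = np.histogram(z, bins=edges)
            probs = np.array(
                [integrate.quad(mix.pdf, a, b)[0] for a, b in
                 zip(edges[:-1], edges[1:])]
            )
            probs[0] += integrate.quad(mix.pdf, -np.inf, edges[0])[0]
            probs[-1] += integrate.quad(mix.pdf, edges[-1], np.inf)[0]
            exp = probs / probs.sum() * len(z)
            chi2 = np.sum((obs - exp) ** 2 / exp)
            assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)


class TestLaplaceMixture:
    def test_single_component_mode_height(self):
        assert LaplaceMixture(2.0, 0.0).pdf(0.0) == pytest.approx(1.0)

    def test_symmetry_at_half_weight(self):
        mix = LaplaceMixture(1.5, 0.5)
        z = np.linspace(-3, 4, 101)
        np.testing.assert_allclose(mix.pdf(z), mix.pdf(1.0 - z), atol=1e-14)

    @pytest.mark.parametrize("alpha,p", [(0.5, 0.2), (1.0, 0.69), (4.0, 0.5)])
    def test_density_normalizes(self, alpha, p):
        mix = LaplaceMixture(alpha, p)
        total = sum(
            integrate.quad(mix.pdf, a, b, limit=200)[0]
            for a, b in [(-np.inf, 0), (0, 1), (1, np.inf)]
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_logpdf_consistent_with_pdf(self):
        mix = LaplaceMixture(1.0, 0.3)
        z = np.linspace(-5, 6, 81)
        np.testing.assert_allclose(np.exp(mix.logpdf(z)), mix.pdf(z), rtol=1e-12)


class TestMixtureLogRatio:
    def test_zero_at_midpoint(self):
        for p0, p1, a in [(0.1, 0.9, 0.5), (0.3, 0.7, 2.0), (0.45, 0.5, 7.0)]:
            assert mixture_log_ratio(p0, p1, a, 0.5) == pytest.approx(0.0, abs=1e-14)

    def test_zero_when_weights_equal(self):
        z = np.linspace(-10, 10, 101)
        np.testing.assert_allclose(
            mixture_log_ratio(0.4, 0.4, 1.0, z), 0.0, atol=1e-14
        )

    def test_limit_at_large_z(self):
        p0, p1, a = 0.3085, 0.6915, 1.0
        lim = math.log((1 - p1 + p1 * math.e) / (1 - p0 + p0 * math.e))
        assert mixture_log_ratio(p0, p1, a, 50.0) == pytest.approx(lim, abs=1e-10)

    def test_monotone_and_flat_outside_unit_interval(self):
        z = np.linspace(-100, 100, 20001)
        vals = mixture_log_ratio(0.2, 0.7, 1.3, z)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.ptp(vals[z <= 0]) < 1e-12
        assert np.ptp(vals[z >= 1]) < 1e-12

    def test_bounded_by_limiting_values(self):
        p0, p1, a = 0.25, 0.6, 2.0
        lo, hi = mixture_log_ratio_bounds(p0, p1, a)
        z = np.linspace(-50, 50, 10001)
        vals = mixture_log_ratio(p0, p1, a, z)
        assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)

    def test_stable_for_extreme_arguments(self):
        vals = mixture_log_ratio(0.3, 0.7, 50.0, np.array([-1e6, 1e6]))
        assert np.all(np.isfinite(vals))

    def test_kl_positivity_under_both_marginals(self):
        """E_m0[increment] < 0 < E_m1[increment] whenever p0 != p1."""
        p0, p1, a = 0.31, 0.69, 1.0
        m0, m1 = LaplaceMixture(a, p0), LaplaceMixture(a, p1)
        for mix, sign in ((m0, -1.0), (m1, 1.0)):
            val = sum(
                integrate.quad(
                    lambda z: mix.pdf(z) * mixture_log_ratio(p0, p1, a, z),
                    lo, hi, limit=200,
                )[0]
                for lo, hi in [(-30, 0), (0, 1), (1, 30)]
            )
            assert sign * val > 0

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_degenerate_weights_rejected(self, bad):
        with pytest.raises(ValueError):
            mixture_log_ratio(bad, 0.5, 1.0, 0.3)


class TestTruncationMechanism:
    def test_clipping_without_noise(self):
        mech = TruncationLaplaceMechanism(1.0, K=2.0)
        assert mech.privatize(4.0, noise=0.0) == 2.0
        assert mech.privatize(1.5, noise=0.0) == 1.5
        assert mech.privatize(-7.0, noise=0.0) == -2.0

    def test_noise_scale_is_2K_over_alpha(self):
        mech = TruncationLaplaceMechanism(0.5, K=1.0)
        rng = np.random.default_rng(4)
        z = mech.privatize(np.zeros(10**5), rng)
        scale = 2 * 1.0 / 0.5
        assert abs(np.mean(z)) < 4 * math.sqrt(2) * scale / math.sqrt(10**5)
        assert np.var(z) == pytest.approx(2 * scale**2, rel=0.05)

    def test_multivariate_projection_then_noise(self):
        mech = TruncationLaplaceMechanism(1.0, K=1.0, k=2)
        out = mech.privatize(np.array([[3.0, 0.0]]), noise=0.0)
        np.testing.assert_allclose(out, [[1.0, 0.0]])

    def test_univariate_consistency_of_multivariate_path(self):
        m1 = TruncationLaplaceMechanism(1.0, K=1.5, k=1)
        x = np.array([2.0, -3.0, 0.7])
        np.testing.assert_allclose(
            m1.privatize(x, noise=0.0), np.clip(x, -1.5, 1.5)
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TruncationLaplaceMechanism(1.0, K=0.0)
        with pytest.raises(ValueError):
            TruncationLaplaceMechanism(-1.0, K=1.0)


class TestL1Projection:
    def test_interior_point_unchanged(self):
        x = np.array([0.2, -0.3, 0.1])
        np.testing.assert_array_equal(project_l1_ball(x, 1.0), x)

    def test_axis_point_soft_threshold(self):
        np.testing.assert_allclose(
            project_l1_ball(np.array([3.0, 0.0]), 1.0), [1.0, 0.0]
        )

    def test_scalar_case_reduces_to_clipping(self):
        x = np.array([2.5])
        np.testing.assert_allclose(project_l1_ball(x, 1.0), [1.0])

    def test_idempotent_and_feasible(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3, size=(200, 4))
        v = project_l1_ball(x, 1.5)
        assert np.all(np.abs(v).sum(axis=1) <= 1.5 + 1e-12)
        np.testing.assert_allclose(project_l1_ball(v, 1.5), v, atol=1e-12)

    def test_matches_kkt_enumeration_oracle(self):
        """Exact brute-force oracle: enumerate candidate active sets and
        keep the unique KKT-feasible soft-thresholding solution."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            k = int(rng.integers(1, 5))
            x = rng.normal(0, 3.0, k)
            K = float(rng.uniform(0.3, 3.0))
            expected = _l1_oracle(x, K)
            np.testing.assert_allclose(project_l1_ball(x, K), expected, atol=1e-8)


def _l1_oracle(x, K):
    if np.abs(x).sum() <= K:
        return x
    k = len(x)
    best, best_obj = None, np.inf
    for size in range(1, k + 1):
        for S in itertools.combinations(range(k), size):
            theta = (sum(abs(x[j]) for j in S) - K) / size
            if theta < 0:
                continue
            w = np.zeros(k)
            ok = True
            for j in range(k):
                if j in S:
                    wj = abs(x[j]) - theta
                    if wj <= 0:
                        ok = False
                        break
                    w[j] = math.copysign(wj, x[j])
                elif abs(x[j]) > theta:
                    ok = False
                    break
            if ok:
                obj = float(np.sum((w - x) ** 2))
                if obj < best_obj:
                    best, best_obj = w, obj
    return best


class TestVerifyLdp:
    @pytest.mark.parametrize("alpha", [0.25, 1.0, 3.0])
    def test_indicator_bound_is_exp_alpha(self, gaussian_shift, alpha):
        mech = IndicatorLaplaceMechanism(alpha, np_region(gaussian_shift))
        assert verify_ldp(mech) == pytest.approx(math.exp(alpha))

    def test_truncation_bound_is_exp_alpha(self):
        for K in (0.5, 1.0, 10.0):
            mech = TruncationLaplaceMechanism(2.0, K=K)
            assert verify_ldp(mech) == pytest.approx(math.exp(2.0))

    def test_unsupported_mechanism_rejected(self):
        with pytest.raises(TypeError):
            verify_ldp(object())
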