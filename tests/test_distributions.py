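"""Unit and property tests for the count families.

The independent oracle throughout is direct summation of the series /
support with scipy.special.gammaln, coded separately from the package's
windowed summation.
"""

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp
import scipy.stats as st

from gaslc.distributions import (
    CellParams,
    ComPoissonDivergenceError,
    ComPoissonParams,
    Family,
    FamilySpec,
    approx_mean_var,
    compoisson_logpmf,
    compoisson_rvs,
    exact_moment,
    log_normalizer,
    log_pmf,
    partial_information,
    partial_score,
    sample,
)


def brute_logz(lam, nu, s_max=None):
    """From-zero log-sum oracle for the normalizing constant."""
    if s_max is None:
        s_max = int(max(lam ** (1.0 / nu), 1.0) * 3 + 2000)
    s = np.arange(s_max + 1, dtype=float)
    return float(logsumexp(s * np.log(lam) - nu * gammaln(s + 1.0)))


class TestLogNormalizer:
    def test_poisson_case_is_exact(self):
        assert log_normalizer(1.0, 1.0) == 1.0
        assert log_normalizer(523.7, 1.0) == 523.7

    def test_geometric_case(self):
        assert log_normalizer(0.5, 0.0) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_bernoulli_limit(self):
        assert np.exp(log_normalizer(2.0, 50.0)) == pytest.approx(3.0, abs=1e-6)

    @pytest.mark.parametrize("lam,nu", [(4.0, 1.5), (0.5, 0.3), (30.0, 0.7), (200.0, 2.0)])
    def test_matches_bruteforce(self, lam, nu):
        assert log_normalizer(lam, nu) == pytest.approx(brute_logz(lam, nu), abs=1e-10)

    def test_divergent_series_raises(self):
        with pytest.raises(ComPoissonDivergenceError):
            log_normalizer(1.5, 0.0)
        with pytest.raises(ComPoissonDivergenceError):
            ComPoissonParams(1.0, 0.0)

    @pytest.mark.parametrize("lam,nu", [(np.nan, 1.0), (-1.0, 1.0), (1.0, -0.5)])
    def test_domain_errors(self, lam, nu):
        with pytest.raises(ValueError):
            log_normalizer(lam, nu)

    def test_large_lambda_no_overflow(self):
        val = log_normalizer(1e6, 1.0)
        assert np.isfinite(val) and val == 1e6


class TestLogPmf:
    def test_poisson_closed_form(self):
        spec = FamilySpec(Family.POISSON)
        got = log_pmf(spec, CellParams(lam=np.array([3.0])), np.array([2.0]))[0]
        assert got == pytest.approx(-3.0 + 2 * np.log(3.0) - np.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 5.0, 50.0])
    def test_compoisson_nu1_equals_poisson(self, lam):
        y = np.arange(0, 150)
        cp = compoisson_logpmf(y, lam, 1.0)
        pois = st.poisson.logpmf(y, lam)
        np.testing.assert_allclose(cp, pois, atol=1e-10)

    def test_compoisson_nu0_is_geometric(self):
        assert compoisson_logpmf(1, 0.5, 0.0)[0] == pytest.approx(np.log(0.25), abs=1e-10)

    def test_compoisson_bernoulli_limit(self):
        p1 = np.exp(compoisson_logpmf(1, 2.0, 50.0)[0])
        assert p1 == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_out_of_support_is_minus_inf(self):
        spec = FamilySpec(Family.BINOMIAL)
        cell = CellParams(l=np.array([10.0]), q=np.array([0.6]))
        assert log_pmf(spec, cell, np.array([11.0]))[0] == -np.inf
        assert compoisson_logpmf(-1, 2.0, 1.5)[0] == -np.inf
        assert compoisson_logpmf(2.5, 2.0, 1.5)[0] == -np.inf

    @pytest.mark.parametrize(
        "spec,cell,support",
        [
            (FamilySpec(Family.POISSON), CellParams(lam=np.array([7.0])), 200),
            (FamilySpec(Family.COM_POISSON, nu=1.4), CellParams(lam=np.array([7.0])), 200),
            (FamilySpec(Family.COM_POISSON, nu=0.6), CellParams(lam=np.array([4.0])), 600),
            (
                FamilySpec(Family.BINOMIAL),
                CellParams(l=np.array([60.0]), q=np.array([0.55])),
                60,
            ),
            (
                FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.array([6.0])),
                CellParams(r=np.array([6.0]), h=np.array([0.3])),
                800,
            ),
        ],
    )
    def test_normalization(self, spec, cell, support):
        y = np.arange(support + 1, dtype=float)
        if spec.family is Family.COM_POISSON:
            probs = np.exp(compoisson_logpmf(y, cell.lam[0], spec.nu))
        else:
            probs = np.exp(
                [log_pmf(spec, cell, np.array([yy]))[0] for yy in y]
            )
        assert probs.sum() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("lam,nu", [(3.0, 0.7), (8.0, 1.3), (2.0, 2.5)])
    def test_successive_ratio_law(self, lam, nu):
        # pmf(y-1)/pmf(y) must equal y**nu / lambda, as the series dictates
        y = np.arange(1, 51, dtype=float)
        lp = compoisson_logpmf(np.arange(0, 51), lam, nu)
        ratios = np.exp(lp[:-1] - lp[1:])
        np.testing.assert_allclose(ratios, y**nu / lam, rtol=1e-8)

    def test_sufficient_statistics_determine_likelihood(self, rng):
        # two samples with equal sum(y) and sum(log y!) have equal likelihood
        a = np.array([0, 1, 2, 2, 3, 4])
        b = np.array([2, 1, 0, 4, 3, 2])  # same multiset sums
        for lam, nu in [(2.0, 0.8), (5.0, 1.3)]:
            la = compoisson_logpmf(a, lam, nu).sum()
            lb = compoisson_logpmf(b, lam, nu).sum()
            assert la == pytest.approx(lb, abs=1e-10)


class TestMoments:
    def test_poisson_mean(self):
        assert exact_moment(3.0, 1.0, 1) == pytest.approx(3.0, abs=1e-8)

    def test_geometric_mean(self):
        assert exact_moment(0.5, 0.0, 1) == pytest.approx(1.0, abs=1e-8)

    def test_second_moment_cross_check(self):
        # at nu=1 the second moment is lambda + lambda**2
        assert exact_moment(4.0, 1.0, 2) == pytest.approx(20.0, rel=1e-8)

    def test_moment_oracle_vs_pmf_sum(self):
        lam, nu = 4.0, 1.5
        y = np.arange(0, 400)
        pmf = np.exp(compoisson_logpmf(y, lam, nu))
        assert exact_moment(lam, nu, 2) == pytest.approx(float((y**2 * pmf).sum()), rel=1e-9)

    def test_approx_mean_var_poisson_case(self):
        m = approx_mean_var(16.0, 1.0)
        assert (m.mean, m.variance) == (16.0, 16.0)
        assert m.within_region

    def test_approx_mean_var_example(self):
        m = approx_mean_var(4.0, 0.5)
        assert m.mean == pytest.approx(16.5)
        assert m.variance == pytest.approx(32.0)

    def test_approx_close_to_exact_inside_region(self):
        m = approx_mean_var(30.0, 1.1)
        assert m.mean == pytest.approx(exact_moment(30.0, 1.1, 1), rel=0.02)
        exact_var = exact_moment(30.0, 1.1, 2) - exact_moment(30.0, 1.1, 1) ** 2
        assert m.variance == pytest.approx(exact_var, rel=0.02)

    def test_outside_region_flagged(self):
        assert not approx_mean_var(2.0, 3.0).within_region
        with pytest.raises(ValueError):
            approx_mean_var(2.0, 0.0)


class TestSampling:
    def test_poisson_lln(self, rng):
        spec = FamilySpec(Family.POISSON)
        draws = sample(spec, CellParams(lam=np.array([5.0])), n=100_000, rng=rng)
        assert abs(draws.mean() - 5.0) < 3 * np.sqrt(5.0 / 1e5)

    def test_seed_determinism(self):
        a = compoisson_rvs(4.0, 0.7, size=50, rng=np.random.default_rng(7))
        b = compoisson_rvs(4.0, 0.7, size=50, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_nu1_matches_poisson_distribution(self):
        cp = compoisson_rvs(6.0, 1.0, size=20_000, rng=np.random.default_rng(1))
        pois = np.random.default_rng(2).poisson(6.0, 20_000)
        stat = st.ks_2samp(cp, pois)
        assert stat.pvalue > 0.01

    def test_mean_matches_exact_moment(self):
        lam, nu = 4.0, 0.7
        draws = compoisson_rvs(lam, nu, size=100_000, rng=np.random.default_rng(3))
        mu = exact_moment(lam, nu, 1)
        var = exact_moment(lam, nu, 2) - mu**2
        assert abs(draws.mean() - mu) < 3 * np.sqrt(var / 1e5)

    def test_inadmissible_parameters_raise(self):
        with pytest.raises(ValueError):
            compoisson_rvs(-1.0, 1.0, size=5, rng=np.random.default_rng(0))
        spec = FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.array([5.0]))
        with pytest.raises(ValueError):
            sample(spec, CellParams(r=np.array([5.0]), h=np.array([1.5])), n=5)


class TestScoreAndInformation:
    def test_printed_formulas(self):
        pois = FamilySpec(Family.POISSON)
        assert partial_score(pois, 0.1, 100, CellParams(lam=90.0)) == pytest.approx(1.0)
        assert partial_information(pois, 0.1, CellParams(lam=90.0)) == pytest.approx(0.9)
        binm = FamilySpec(Family.BINOMIAL)
        assert partial_score(binm, 0.2, 5, CellParams(l=100.0, q=0.04)) == pytest.approx(0.2)
        nb = FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.array([5.0]))
        cell = CellParams(r=5.0, h=0.1)
        assert partial_score(nb, 0.1, 50, cell) == pytest.approx(0.05)
        assert partial_information(nb, 0.1, cell) == pytest.approx(0.045)

    def test_compoisson_nu1_score_equals_poisson(self):
        cp = FamilySpec(Family.COM_POISSON, nu=1.0)
        pois = FamilySpec(Family.POISSON)
        for d, lam, b in [(10, 8.0, 0.3), (0, 2.0, 0.05)]:
            assert partial_score(cp, b, d, CellParams(lam=lam)) == pytest.approx(
                partial_score(pois, b, d, CellParams(lam=lam))
            )

    def test_score_form_switch(self):
        cp = FamilySpec(Family.COM_POISSON, nu=2.0)
        cell = CellParams(lam=5.0)
        offset = partial_score(cp, 1.0, 5, cell, score_form="offset")
        s54 = partial_score(cp, 1.0, 5, cell, score_form="plain")
        assert offset - s54 == pytest.approx((2.0 - 1.0) / 4.0)

    def test_nu_zero_score_undefined(self):
        cp = FamilySpec(Family.COM_POISSON, nu=0.0)
        with pytest.raises(ValueError):
            partial_score(cp, 0.1, 1, CellParams(lam=0.5))

    def test_information_nonnegative(self, rng):
        for _ in range(50):
            b = rng.normal()
            lam = rng.uniform(0.1, 100)
            assert partial_information(FamilySpec(Family.POISSON), b, CellParams(lam=lam)) >= 0

    def test_score_zero_mean_monte_carlo(self, rng):
        # E[partial score] = 0 at the true parameters (exact for these families)
        n = 50_000
        cases = [
            (FamilySpec(Family.POISSON), CellParams(lam=np.array([90.0]))),
            (FamilySpec(Family.BINOMIAL), CellParams(l=np.array([200.0]), q=np.array([0.6]))),
            (
                FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.array([5.0])),
                CellParams(r=np.array([5.0]), h=np.array([0.1])),
            ),
        ]
        for spec, cell in cases:
            draws = sample(spec, cell, n=n, rng=rng)
            scores = partial_score(spec, 0.1, draws, cell)
            se = scores.std() / np.sqrt(n)
            assert abs(scores.mean()) < 3 * se

    def test_compoisson_score_bias_bounded(self, rng):
        # the dispersion offset is an approximation to lambda - E[Y]
        lam, nu, b = 20.0, 0.8, 0.1
        draws = compoisson_rvs(lam, nu, size=50_000, rng=rng)
        spec = FamilySpec(Family.COM_POISSON, nu=nu)
        scores = partial_score(spec, b, draws, CellParams(lam=lam))
        bound = abs(b * ((nu - 1) / (2 * nu) - (lam - exact_moment(lam, nu, 1))))
        se = scores.std() / np.sqrt(draws.size)
        assert abs(scores.mean()) <= bound + 3 * se


class TestFamilySpecValidation:
    def test_dispersion_shape_rules(self):
        with pytest.raises(ValueError):
            FamilySpec(Family.POISSON, nu=1.0)
        with pytest.raises(ValueError):
            FamilySpec(Family.NEGATIVE_BINOMIAL)
        with pytest.raises(ValueError):
            FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.array([1.0, -2.0]))
        spec = FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.array([1.0, 2.0]))
        assert spec.n_dispersion == 2
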