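import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dmrscape import (CoveragePolicy, MethylomeMatrix, SampleMeta, bh_adjust,
                      call_dms, coverage_filter, site_logistic_test)
from dmrscape import test_sites as run_site_tests
from oracle_utils import bh_oracle


def _matrix(case_depths, ref_depths, case_meth=None, ref_meth=None):
    depths = np.array([list(case_depths) + list(ref_depths)])
    meth = np.array([list(case_meth or [0] * len(case_depths))
                     + list(ref_meth or [0] * len(ref_depths))])
    samples = ([SampleMeta(f"c{i}", "case") for i in range(len(case_depths))]
               + [SampleMeta(f"r{i}", "reference") for i in range(len(ref_depths))])
    return MethylomeMatrix(np.array(["chr1"]), np.array([100]), meth, depths, samples)


class TestCoverageFilter:
    @pytest.mark.parametrize("case,ref,expected", [
        ((6, 6, 0), (5, 5, 5, 5, 0, 0), True),   # 2 case and 4 refs at >= 5x
        ((6, 4, 4), (10, 10, 10, 10, 10, 10), False),  # only one case >= 5x
        ((0, 0, 0), (0, 0, 0, 0, 0, 0), False),
    ])
    def test_depth_rule(self, case, ref, expected):
        mask = coverage_filter(_matrix(case, ref), CoveragePolicy())
        assert mask[0] == expected


class TestSiteLogisticTest:
    def test_identical_groups_give_null_result(self):
        diff, p = site_logistic_test([(5, 10)] * 2, [(5, 10)] * 4)
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_meth_diff_is_pooled_fraction_difference(self):
        diff, _ = site_logistic_test([(10, 10), (9, 10)],
                                     [(1, 10), (0, 10), (1, 10), (0, 10)])
        assert diff == pytest.approx(19 / 20 - 2 / 40)

    def test_lrt_p_matches_closed_form_deviance(self):
        # oracle: deviance between the pooled-proportion and group-proportion
        # binomial models, computed from first principles
        case, ref = [(10, 10), (9, 10)], [(1, 10), (0, 10), (1, 10), (0, 10)]
        mc, tc = 19, 20
        mr, tr = 2, 40
        p1, p2, pp = mc / tc, mr / tr, (mc + mr) / (tc + tr)

        def ll(m, t, p):
            out = 0.0
            if m > 0:
                out += m * np.log(p)
            if t - m > 0:
                out += (t - m) * np.log(1 - p)
            return out

        G = 2 * (ll(mc, tc, p1) + ll(mr, tr, p2) - ll(mc, tc, pp) - ll(mr, tr, pp))
        expected = stats.chi2.sf(G, 1)
        _, p = site_logistic_test(case, ref, dispersion="none")
        assert p == pytest.approx(expected, rel=1e-12)

    def test_lrt_matches_statsmodels_glm(self):
        # independent oracle: iterative GLM fit of the same logistic model
        import statsmodels.api as sm
        case, ref = [(7, 12), (3, 9)], [(2, 11), (5, 10), (1, 8), (4, 12)]
        endog = np.array([[m, t - m] for m, t in case + ref], dtype=float)
        group = np.array([1] * len(case) + [0] * len(ref), dtype=float)
        X = sm.add_constant(group)
        full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones((len(endog), 1)),
                      family=sm.families.Binomial()).fit()
        G = 2 * (full.llf - null.llf)
        expected = stats.chi2.sf(G, 1)
        _, p = site_logistic_test(case, ref, dispersion="none")
        assert p == pytest.approx(expected, rel=1e-8)

    def test_complete_separation_gives_finite_p(self):
        diff, p = site_logistic_test([(10, 10)] * 2, [(0, 10)] * 4,
                                     dispersion="none")
        assert diff == 1.0
        assert 0 < p < 1e-10 or p > 0  # finite, not NaN
        assert np.isfinite(p)

    def test_swap_antisymmetry(self):
        case, ref = [(8, 10), (6, 9)], [(2, 10), (3, 11), (1, 9), (2, 10)]
        d1, p1 = site_logistic_test(case, ref, dispersion="none")
        d2, p2 = site_logistic_test(ref, case, dispersion="none")
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_zero_depth_group_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            site_logistic_test([(0, 0)], [(5, 10)] * 4)

    def test_binned_mode_needs_ensemble(self):
        with pytest.raises(ValueError, match="binned"):
            site_logistic_test([(5, 10)] * 2, [(5, 10)] * 4, dispersion="binned")


class TestBHAdjust:
    def test_spec_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_adjust([0.5])[0] == 0.5

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestCallDms:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_diff",
                                         "p_value", "q_value"])
        df["passes_coverage"] = True
        df["meth_frac_case"] = 0.5
        df["meth_frac_ref"] = 0.5
        return df

    def test_direction_from_sign_of_diff(self):
        res = self._results([("chr1", 10, -0.4, 0.001, 0.01)])
        dms = call_dms(res, 0.05)
        assert list(dms["direction"]) == ["hypo"]

    def test_above_threshold_excluded(self):
        res = self._results([("chr1", 10, -0.4, 0.1, 0.2)])
        assert call_dms(res, 0.05).empty

    def test_zero_diff_excluded(self):
        res = self._results([("chr1", 10, 0.0, 0.001, 0.01)])
        assert call_dms(res, 0.05).empty


def _beta_binomial_null(rng, n_sites, p0=0.85, rho=0.05, cov=20, nc=3, nr=6):
    t = rng.poisson(cov, size=(n_sites, nc + nr))
    a = p0 * (1 - rho) / rho
    b = (1 - p0) * (1 - rho) / rho
    m = rng.binomial(t, rng.beta(a, b, size=t.shape))
    samples = ([SampleMeta(f"c{i}", "case") for i in range(nc)]
               + [SampleMeta(f"r{i}", "reference") for i in range(nr)])
    return MethylomeMatrix(np.array(["chr1"] * n_sites),
                           np.arange(n_sites) * 50, m, t, samples)


def test_null_calibration_under_overdispersion():
    """Raw-p fractions match nominal alpha within 3 MC SE under a
    beta-binomial null with equal methylation in both groups."""
    rng = np.random.default_rng(123)
    matrix = _beta_binomial_null(rng, 25_000)
    res = run_site_tests(matrix)
    p = res["p_value"].to_numpy()
    n = np.isfinite(p).sum()
    for alpha in (0.05, 0.01):
        frac = np.nanmean(p < alpha)
        band = 3 * np.sqrt(alpha * (1 - alpha) / n)
        assert abs(frac - alpha) <= band, (alpha, frac, band)


def test_null_dms_fraction_controlled():
    """BH at q <= 0.05 on a null simulation yields (almost) no DMS."""
    rng = np.random.default_rng(7)
    matrix = _beta_binomial_null(rng, 20_000)
    dms = call_dms(run_site_tests(matrix), 0.05)
    assert len(dms) / matrix.n_sites <= 0.05
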