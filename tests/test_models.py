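"""Unit and property tests for the six-model likelihood framework."""

import numpy as np
import pytest
from scipy.special import xlogy

from migselect.datatypes import TriGroupCounts
from migselect.models import (
    MODEL_DF,
    MODEL_NAMES,
    fit_all_models,
    fit_model,
    general_vs_null,
    llr_pvalue,
    select_model,
)

from conftest import random_count_tables


def grid_mle_1d(loglik, lo=0.0, hi=1.0, points=2001, rounds=4):
    """Refined grid search maximizing a 1-D log-likelihood on (0, 1)."""
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = loglik(grid)
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, points - 1)]
    return grid[i]


class TestClosedFormFits:
    def test_toy_frequencies(self, toy_counts):
        fits = fit_all_models(toy_counts)
        assert fits["null"].freq_with == pytest.approx(0.425)
        assert fits["subset"].freq_with == pytest.approx(0.5)
        assert fits["subset"].freq_without == pytest.approx(0.4)
        assert fits["subset"].freq_ctrl == pytest.approx(0.4)
        assert (
            fits["general"].freq_with,
            fits["general"].freq_without,
            fits["general"].freq_ctrl,
        ) == pytest.approx((0.5, 0.4, 0.4))

    def test_toy_logliks(self, toy_counts):
        fits = fit_all_models(toy_counts)
        assert fits["null"].loglik == pytest.approx(-272.74, abs=0.01)
        assert fits["subset"].loglik == pytest.approx(-271.22, abs=0.01)
        # without-group and control sample frequencies coincide, so the
        # general fit collapses onto the subset fit
        assert fits["general"].loglik == pytest.approx(fits["subset"].loglik)

    def test_df_bookkeeping(self):
        assert MODEL_DF == {
            "null": 1,
            "basic": 2,
            "subset": 2,
            "inverse_subset": 2,
            "modifier": 2,
            "general": 3,
        }

    def test_information_criteria_formulas(self, toy_counts):
        for fit in fit_all_models(toy_counts).values():
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.df)
            assert fit.bic == pytest.approx(
                -2 * fit.loglik + fit.df * np.log(toy_counts.n_individuals)
            )

    def test_equal_frequencies_collapse(self):
        c = TriGroupCounts(30, 100, 60, 200, 90, 300)
        fits = fit_all_models(c)
        lls = {m: f.loglik for m, f in fits.items()}
        for m in MODEL_NAMES:
            assert lls[m] == pytest.approx(lls["null"], abs=1e-8)
        assert fits["modifier"].freq_with == pytest.approx(0.3, abs=1e-5)
        assert fits["modifier"].freq_without == pytest.approx(0.3, abs=1e-5)


class TestModifier:
    def test_constraint_holds_exactly(self, toy_counts):
        fit = fit_model(toy_counts, "modifier")
        w = toy_counts.n_with / (toy_counts.n_with + toy_counts.n_without)
        assert fit.freq_ctrl == pytest.approx(
            w * fit.freq_with + (1 - w) * fit.freq_without, abs=1e-12
        )

    def test_bracketed_by_null_and_general(self):
        rng = np.random.default_rng(7)
        for c in random_count_tables(rng, 50):
            fits = fit_all_models(c)
            assert fits["null"].loglik <= fits["modifier"].loglik + 1e-7
            assert fits["modifier"].loglik <= fits["general"].loglik + 1e-7

    def test_matches_2d_grid_search(self, toy_counts):
        k, n = toy_counts.as_arrays()
        w = n[0] / (n[0] + n[1])

        def ll(pw, po):
            pc = w * pw + (1 - w) * po
            return (
                xlogy(k[0], pw) + xlogy(n[0] - k[0], 1 - pw)
                + xlogy(k[1], po) + xlogy(n[1] - k[1], 1 - po)
                + xlogy(k[2], pc) + xlogy(n[2] - k[2], 1 - pc)
            )

        lo = np.array([0.0, 0.0])
        hi = np.array([1.0, 1.0])
        for _ in range(5):
            gw = np.linspace(lo[0], hi[0], 201)
            go = np.linspace(lo[1], hi[1], 201)
            vals = ll(gw[:, None], go[None, :])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            lo = np.array([gw[max(i - 1, 0)], go[max(j - 1, 0)]])
            hi = np.array([gw[min(i + 1, 200)], go[min(j + 1, 200)]])
        fit = fit_model(toy_counts, "modifier")
        assert fit.freq_with == pytest.approx(gw[i], abs=1e-5)
        assert fit.freq_without == pytest.approx(go[j], abs=1e-5)


class TestNesting:
    def test_loglik_ordering_random_tables(self):
        rng = np.random.default_rng(11)
        for c in random_count_tables(rng, 200):
            ll = {m: f.loglik for m, f in fit_all_models(c).items()}
            for m in MODEL_NAMES:
                assert ll["general"] >= ll[m] - 1e-7
                assert ll[m] >= ll["null"] - 1e-7


class TestGridOracle:
    def test_closed_form_mles_match_grid(self):
        """Every closed-form pooled frequency maximizes its own 1-D slice."""
        rng = np.random.default_rng(3)
        for c in random_count_tables(rng, 25):
            k, n = c.as_arrays()
            slices = {
                "null": (k.sum(), n.sum()),
                "basic_case": (k[0] + k[1], n[0] + n[1]),
                "subset_with": (k[0], n[0]),
                "subset_shared": (k[1] + k[2], n[1] + n[2]),
                "inverse_shared": (k[0] + k[2], n[0] + n[2]),
            }
            for kk, nn in slices.values():
                grid_opt = grid_mle_1d(
                    lambda p, kk=kk, nn=nn: xlogy(kk, p) + xlogy(nn - kk, 1 - p)
                )
                assert grid_opt == pytest.approx(kk / nn, abs=1e-6)


class TestSelection:
    def test_toy_bic_selects_null(self, toy_counts):
        assert select_model(toy_counts, "bic").selected == "null"

    def test_toy_aic_selects_subset(self, toy_counts):
        res = select_model(toy_counts, "aic")
        assert res.selected == "subset"
        assert res.llr_stat == pytest.approx(3.05, abs=0.01)
        assert res.llr_df == 1

    def test_selection_matches_explicit_enumeration(self, toy_counts):
        for criterion in ("bic", "aic"):
            fits = fit_all_models(toy_counts)
            crit = {
                m: (f.bic if criterion == "bic" else f.aic) for m, f in fits.items()
            }
            expected = min(
                MODEL_NAMES,
                key=lambda m: (crit[m], fits[m].df, MODEL_NAMES.index(m)),
            )
            assert select_model(toy_counts, criterion).selected == expected

    def test_equal_frequencies_select_null(self):
        c = TriGroupCounts(30, 100, 60, 200, 90, 300)
        for criterion in ("bic", "aic"):
            res = select_model(c, criterion)
            assert res.selected == "null"
            assert res.llr_stat == 0.0
            assert res.llr_p_analytic == 1.0

    def test_bic_nonnull_implies_aic_nonnull(self):
        """BIC's penalty exceeds AIC's once ln(n) > 2, i.e. n > 7."""
        rng = np.random.default_rng(19)
        for c in random_count_tables(rng, 200):
            if c.n_individuals <= 7:
                continue
            if select_model(c, "bic").selected != "null":
                assert select_model(c, "aic").selected != "null"


class TestLlrPvalue:
    @pytest.mark.parametrize(
        "stat,df,expected,tol",
        [
            (0.0, 1, 1.0, 0.0),
            (3.841, 1, 0.050, 1e-3),
            (4.0, 2, np.exp(-2.0), 1e-12),
        ],
    )
    def test_reference_values(self, stat, df, expected, tol):
        assert llr_pvalue(stat, df) == pytest.approx(expected, abs=max(tol, 1e-15))

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            llr_pvalue(1.0, 0)

    def test_negative_stat(self):
        with pytest.raises(ValueError):
            llr_pvalue(-0.5, 1)


class TestAnalyticCalibration:
    def test_forced_general_p_uniform_under_null(self):
        """Analytic 2-df LLR p of general-vs-null is ~uniform under the null."""
        from scipy.stats import kstest

        rng = np.random.default_rng(23)
        ps = []
        for _ in range(5000):
            n = np.array([1000, 1600, 2400])
            k = rng.binomial(n, 0.3)
            c = TriGroupCounts(
                int(k[0]), 1000, int(k[1]), 1600, int(k[2]), 2400
            )
            ps.append(general_vs_null(c).llr_p_analytic)
        assert kstest(ps, "uniform").pvalue > 0.01
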