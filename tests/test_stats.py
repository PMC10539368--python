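"""Mixed models, bootstrap test, pooled log-odds, Welch/Holm, signed-rank."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from barrelquant import stats as st
from barrelquant import synthdata as sd


class TestPooledLogOdds:
    def test_morphology_proportions_worked_example(self):
        # 89% vs 42% pyramidal -> log odds ratio 2.41 (2 d.p.)
        assert round(st.log_odds_ratio(0.89, 0.42), 2) == 2.41

    def test_overexpression_proportions(self):
        # 94% vs 42% -> ~3.07, close to the clustered-model estimate
        assert st.log_odds_ratio(0.94, 0.42) == pytest.approx(3.07, abs=0.005)

    def test_equal_proportions_zero(self):
        assert st.log_odds_ratio(0.3, 0.3) == 0.0

    def test_table_matches_closed_form(self, rng):
        y0 = (rng.random(200) < 0.42).astype(int)
        y1 = (rng.random(200) < 0.89).astype(int)
        tab = pd.DataFrame({
            "group": [0] * 200 + [1] * 200,
            "outcome": np.concatenate([y0, y1]),
        })
        expected = st.log_odds_ratio(y1.mean(), y0.mean())
        assert st.pooled_log_odds(tab) == pytest.approx(expected)

    def test_degenerate_continuity_correction(self):
        tab = pd.DataFrame({"group": [0] * 10 + [1] * 10,
                            "outcome": [0] * 5 + [1] * 5 + [1] * 10})
        with pytest.warns(UserWarning):
            val = st.pooled_log_odds(tab)
        assert np.isfinite(val)


class TestBinomialGlmm:
    def test_sigma_zero_collapses_to_logistic(self):
        # with no between-animal variance the GLMM is a plain logistic
        # regression; statsmodels Logit is the independent reference
        import statsmodels.api as sm

        tab, _ = sd.make_morphology_data((8, 8), 40, beta=1.5, sigma=0.0, seed=4)
        fit = st.BinomialMixedModel.from_dataframe(tab).fit()
        X = sm.add_constant(tab["group"].to_numpy(dtype=float))
        logit = sm.Logit(tab["outcome"].to_numpy(), X).fit(disp=0)
        assert fit.beta == pytest.approx(logit.params[1], abs=1e-3)
        assert fit.sigma_u < 0.05

    def test_matches_reference_glmm(self):
        # frozen reference values from lme4::glmer (nAGQ=25) on this table
        tab, _ = sd.make_morphology_data((10, 6), 12, beta=2.0, sigma=0.6,
                                         baseline_logit=-0.3, seed=5)
        fit = st.BinomialMixedModel.from_dataframe(tab).fit()
        assert fit.beta == pytest.approx(3.15537, abs=2e-4)
        assert fit.se_beta == pytest.approx(0.56408, abs=2e-3)
        assert fit.sigma_u == pytest.approx(0.19613, abs=2e-3)
        assert fit.llf == pytest.approx(-97.24296, abs=2e-4)

    def test_quadrature_stable_to_doubling(self):
        tab, _ = sd.make_morphology_data((10, 6), 12, beta=2.0, sigma=0.6, seed=5)
        f25 = st.BinomialMixedModel.from_dataframe(tab, n_quad=25).fit()
        f50 = st.BinomialMixedModel.from_dataframe(tab, n_quad=50).fit()
        assert abs(f25.beta - f50.beta) < 1e-4

    def test_label_swap_negates_beta(self):
        tab, _ = sd.make_morphology_data((6, 6), 20, beta=1.2, sigma=0.4, seed=6)
        fit = st.BinomialMixedModel.from_dataframe(tab).fit()
        swapped = tab.assign(group=1 - tab["group"])
        fit_sw = st.BinomialMixedModel.from_dataframe(swapped).fit()
        assert fit.beta == pytest.approx(-fit_sw.beta, abs=2e-3)

    def test_llf_at_optimum_beats_logistic(self):
        import statsmodels.api as sm

        tab, _ = sd.make_morphology_data((8, 6), 15, beta=2.0, sigma=0.8, seed=7)
        fit = st.BinomialMixedModel.from_dataframe(tab).fit()
        X = sm.add_constant(tab["group"].to_numpy(dtype=float))
        logit = sm.Logit(tab["outcome"].to_numpy(), X).fit(disp=0)
        assert fit.llf >= logit.llf - 1e-6

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            st.BinomialMixedModel([0, 1, 2], ["a", "a", "b"], [0, 0, 1])


class TestLinearMixed:
    @staticmethod
    def _sections_table(beta=21.0, sigma=4.0, tau=3.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in (0, 1):
            for a in range(3):
                u = rng.normal(0, sigma)
                for _ in range(6):
                    rows.append((f"g{g}a{a}", g, 3.0 + beta * g + u + rng.normal(0, tau)))
        return pd.DataFrame(rows, columns=["animal", "group", "outcome"])

    def test_no_cluster_variance_gives_mean_difference(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "animal": [f"a{i}" for i in range(40)],
            "group": [0] * 20 + [1] * 20,
            "outcome": rng.normal(0, 1, 40) + np.r_[np.zeros(20), np.full(20, 5.0)],
        })
        fit = st.LinearMixedModel.from_dataframe(tab).fit()
        diff = tab[tab.group == 1].outcome.mean() - tab[tab.group == 0].outcome.mean()
        assert fit.beta == pytest.approx(diff, abs=1e-6)

    def test_matches_statsmodels_ml(self):
        import statsmodels.formula.api as smf

        tab = self._sections_table(seed=3)
        fit = st.LinearMixedModel.from_dataframe(tab).fit()
        ref = smf.mixedlm("outcome ~ group", tab, groups=tab["animal"]).fit(reml=False)
        assert fit.beta == pytest.approx(ref.params["group"], abs=1e-5)
        assert fit.sigma_u == pytest.approx(np.sqrt(ref.cov_re.iloc[0, 0]), abs=1e-3)
        assert fit.sigma_resid == pytest.approx(np.sqrt(ref.scale), abs=1e-3)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-5)

    def test_parameter_recovery(self):
        betas = [st.LinearMixedModel.from_dataframe(
            self._sections_table(beta=21.0, sigma=4.0, tau=3.0, seed=s)).fit().beta
            for s in range(30)]
        assert np.mean(betas) == pytest.approx(21.0, abs=2.0)

    def test_label_swap_negates_beta(self):
        tab = self._sections_table(seed=9)
        fit = st.LinearMixedModel.from_dataframe(tab).fit()
        fit_sw = st.LinearMixedModel.from_dataframe(tab.assign(group=1 - tab.group)).fit()
        assert fit.beta == pytest.approx(-fit_sw.beta, abs=1e-8)


class TestBootstrap:
    def test_p_floor_when_statistic_exceeds_all(self):
        # a huge true effect: observed LR exceeds every null replicate,
        # so p hits the floor 1/(B+1)
        tab = TestLinearMixed._sections_table(beta=40.0, sigma=1.0, tau=1.0, seed=2)
        fit = st.LinearMixedModel.from_dataframe(tab).fit()
        bt = st.parametric_bootstrap_test(fit, B=199, seed=10)
        assert bt.p_value == pytest.approx(1 / 200)
        assert bt.n_exceed == 0

    def test_p_never_zero_and_granularity(self):
        tab = TestLinearMixed._sections_table(beta=0.0, seed=4)
        fit = st.LinearMixedModel.from_dataframe(tab).fit()
        bt = st.parametric_bootstrap_test(fit, B=19, seed=1)
        assert 0 < bt.p_value <= 1
        assert (bt.p_value * 20) == pytest.approx(round(bt.p_value * 20))

    def test_binomial_bootstrap_small(self):
        tab, _ = sd.make_morphology_data((8, 8), 12, beta=2.5, sigma=0.3, seed=8)
        fit = st.BinomialMixedModel.from_dataframe(tab, n_quad=9).fit()
        bt = st.parametric_bootstrap_test(fit, B=99, seed=3)
        assert bt.p_value == pytest.approx(1 / 100)

    def test_requires_group_effect(self):
        tab, _ = sd.make_morphology_data((4, 4), 10, beta=1.0, sigma=0.2, seed=1)
        null = st.BinomialMixedModel(tab["outcome"], tab["animal"], None).fit()
        with pytest.raises(ValueError):
            st.parametric_bootstrap_test(null, B=9, seed=0)


class TestWelchHolm:
    def test_identical_groups_p_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        out = st.welch_holm(g, [("a", "b")])
        assert out.p_adj.iloc[0] == pytest.approx(1.0)

    def test_textbook_case_matches_hand_formula(self):
        xa, xb = np.arange(1.0, 6.0), np.arange(6.0, 11.0)
        out = st.welch_holm({"a": xa, "b": xb}, [("a", "b")])
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        se = np.sqrt(va / 5 + vb / 5)
        t = (xa.mean() - xb.mean()) / se
        df = (va / 5 + vb / 5) ** 2 / ((va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4)
        p = 2 * sps.t.sf(abs(t), df)
        assert out.t.iloc[0] == pytest.approx(t)
        assert out.df.iloc[0] == pytest.approx(df)
        assert out.p_raw.iloc[0] == pytest.approx(p)

    def test_holm_first_step_multiplies_smallest_p(self, rng):
        groups = {"ref": rng.normal(0, 1, 10)}
        pairs = []
        for i, shift in enumerate([8.0, 0.1, 0.05]):
            groups[f"g{i}"] = rng.normal(shift, 1, 10)
            pairs.append(("ref", f"g{i}"))
        out = st.welch_holm(groups, pairs)
        smallest = out.p_raw.min()
        assert out.loc[out.p_raw.idxmin(), "p_adj"] == pytest.approx(
            min(1.0, 3 * smallest))

    def test_bh_correction_runs(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, 8) for i in range(4)}
        out = st.welch_holm(groups, [("g0", "g1"), ("g0", "g2"), ("g0", "g3")],
                            correction="bh")
        assert (out.p_adj >= out.p_raw - 1e-12).all()

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            out = st.welch_holm({"a": [1.0, 1.0], "b": [1.0, 1.0]}, [("a", "b")])
        assert np.isnan(out.p_adj.iloc[0])


def _enumerated_signed_rank_p(values, direction, shift):
    """Brute force: all 2^n sign assignments of the |d| midranks."""
    mu0 = -shift if direction == "down" else shift
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if direction == "down":
            count += w <= w_obs + 1e-9
        else:
            count += w >= w_obs - 1e-9
    return count / 2**n


class TestDirectionalShift:
    def test_all_strongly_down(self):
        # 9 values all far below the -0.1 null point: one-sided p = 1/2^9
        p = st.directional_shift_test([-1.0] * 9, "down")
        assert p == pytest.approx(1 / 512)

    def test_symmetric_values_near_half(self, rng):
        vals = -0.1 + np.concatenate([np.arange(1, 6), -np.arange(1, 6)]) * 0.01
        p = st.directional_shift_test(vals, "down")
        assert 0.4 < p < 0.7

    def test_matches_enumeration(self, rng):
        for n in (4, 7, 10, 12):
            for direction in ("down", "up"):
                vals = rng.normal(-0.2, 0.3, n)
                p = st.directional_shift_test(vals, direction)
                p_ref = _enumerated_signed_rank_p(vals, direction, 0.1)
                assert p == pytest.approx(p_ref), (n, direction)

    def test_matches_scipy_without_ties(self, rng):
        vals = rng.normal(0.0, 1.0, 15)
        p = st.directional_shift_test(vals, "up", shift=0.1)
        ref = sps.wilcoxon(vals - 0.1, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(ref)

    def test_all_at_null_point_returns_one(self):
        with pytest.warns(UserWarning):
            p = st.directional_shift_test([-0.1, -0.1, -0.1], "down")
        assert p == 1.0
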