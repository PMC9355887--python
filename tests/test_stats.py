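"""Statistical battery: frequentist tests vs sums-of-squares oracles,
Bayes factors vs independent quadrature/implementations, power, and the
outlier-pruned regression."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import sstlab as sl
from sstlab.errors import ZeroVarianceError
from sstlab.stats import PowerSpec, bonferroni

from oracles import mixed_anova_oracle, one_way_anova_oracle, rm_anova_oracle


def _mixed_frame(values_by_group):
    """values_by_group: {group: [(cond_a, cond_b), ...]} -> long frame."""
    rows = []
    sid = 0
    for group, pairs in values_by_group.items():
        for a, b in pairs:
            rows.append(dict(subject=f"s{sid}", group=group, condition="emotional", value=a))
            rows.append(dict(subject=f"s{sid}", group=group, condition="neutral", value=b))
            sid += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_conditions_give_zero_within_f(self):
        data = _mixed_frame({"a": [(1.0, 1.0), (2.0, 2.0)], "b": [(3.0, 3.0), (4.0, 4.0)]})
        res = sl.mixed_anova_2x3(data)
        assert res["within"].statistic == 0.0

    def test_toy_table_matches_cell_means_oracle(self):
        data = _mixed_frame({"a": [(3.0, 5.0), (4.0, 7.0)], "b": [(6.0, 6.0), (9.0, 8.0)]})
        res = sl.mixed_anova_2x3(data)
        oracle = mixed_anova_oracle(data)
        for key in ("between", "within", "interaction"):
            assert res[key].statistic == pytest.approx(oracle[key], rel=1e-9)
            assert res[key].eta_p2 == pytest.approx(oracle[f"{key}_np2"], rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_designs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = rng.integers(2, 4)
        n_per = rng.integers(3, 6)
        data = _mixed_frame(
            {
                f"g{g}": [tuple(rng.normal(size=2)) for _ in range(n_per)]
                for g in range(n_groups)
            }
        )
        res = sl.mixed_anova_2x3(data)
        oracle = mixed_anova_oracle(data)
        for key in ("between", "within", "interaction"):
            assert res[key].statistic == pytest.approx(oracle[key], rel=1e-8)

    def test_missing_condition_rejected(self):
        data = _mixed_frame({"a": [(1.0, 2.0), (2.0, 1.0)], "b": [(1.0, 3.0), (0.0, 2.0)]})
        with pytest.raises(ValueError):
            sl.mixed_anova_2x3(data.iloc[:-1])

    def test_detects_within_shift_with_adequate_power(self, rng):
        """At the realised effect size of a 90-subject two-condition
        design (dz ~ 0.41) the within effect is detected at alpha = .05
        in >= 90% of replicates."""
        hits = 0
        reps = 100
        for _ in range(reps):
            diff = rng.normal(-8.3, 20.4, 90)
            base = rng.normal(235.0, 40.0, 90)
            data = _mixed_frame(
                {
                    "g1": list(zip(base[:30] + diff[:30], base[:30])),
                    "g2": list(zip(base[30:60] + diff[30:60], base[30:60])),
                    "g3": list(zip(base[60:] + diff[60:], base[60:])),
                }
            )
            if sl.mixed_anova_2x3(data)["within"].p < 0.05:
                hits += 1
        assert hits >= 90

    def test_posthoc_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(0)
        data = _mixed_frame(
            {g: [tuple(rng.normal(size=2)) for _ in range(5)] for g in "abc"}
        )
        res = sl.mixed_anova_2x3(data, posthoc=True)
        ph = res["within"].posthoc
        assert (ph["p_corr"].dropna() >= ph.loc[ph["p_corr"].notna(), "p_unc"] - 1e-12).all()


class TestRmAnova:
    @staticmethod
    def _frame(cube):
        """cube[s][i][j] -> long frame with factors emotion (2) x stimulus (3)."""
        rows = []
        for s, plane in enumerate(cube):
            for i, row in enumerate(plane):
                for j, v in enumerate(row):
                    rows.append(
                        dict(subject=f"s{s}", emotion=f"e{i}", stimulus=f"k{j}", value=v)
                    )
        return pd.DataFrame(rows)

    def test_constant_ratings_give_zero_f(self):
        data = self._frame([[[5.0] * 3] * 2] * 4)
        res = sl.rm_anova_2x3_within(data, within=("emotion", "stimulus"))
        assert all(r.statistic == 0.0 for r in res.values())

    def test_toy_table_matches_within_ss_oracle(self):
        rng = np.random.default_rng(3)
        data = self._frame(rng.normal(size=(3, 2, 3)))
        res = sl.rm_anova_2x3_within(data, within=("emotion", "stimulus"))
        oracle = rm_anova_oracle(data, factors=("emotion", "stimulus"))
        for key in ("emotion", "stimulus", "interaction"):
            assert res[key].statistic == pytest.approx(oracle[key], rel=1e-8)

    def test_pure_emotion_shift_leaves_stimulus_null_calibrated(self, rng):
        """A generative emotion main effect must not inflate the
        stimulus or interaction tests beyond their nominal level."""
        rejections = np.zeros(2)
        reps = 100
        for _ in range(reps):
            base = rng.normal(0, 1, size=(8, 1, 1))
            shift = np.array([1.0, 0.0]).reshape(1, 2, 1)
            cube = base + shift + rng.normal(0, 1, size=(8, 2, 3))
            res = sl.rm_anova_2x3_within(self._frame(cube), within=("emotion", "stimulus"))
            rejections += [res["stimulus"].p < 0.05, res["interaction"].p < 0.05]
        assert (rejections / reps <= 0.12).all()

    def test_missing_cell_rejected(self):
        data = self._frame(np.zeros((3, 2, 3)))
        with pytest.raises(ValueError):
            sl.rm_anova_2x3_within(data.iloc[:-1], within=("emotion", "stimulus"))


class TestSimpleTests:
    def test_paired_t_closed_form_example(self):
        """Differences 10, 10, 13: mean 11, SE 1 -> t(2) = 11."""
        res = sl.paired_t([310, 315, 323], [300, 305, 310])
        assert res.statistic == pytest.approx(11.0)
        assert res.df == (2.0,)

    def test_paired_t_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            sl.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_chi2_demographic_gender_counts(self):
        res = sl.chi2_independence([[19, 16, 20], [11, 14, 10]])
        assert res.statistic == pytest.approx(1.216, abs=5e-4)
        assert res.df == (2.0,)

    def test_chi2_proportional_table_is_zero(self):
        assert sl.chi2_independence([[10, 20], [30, 60]]).statistic == pytest.approx(0.0)

    def test_chi2_diagonal_2x2_equals_n(self):
        assert sl.chi2_independence([[10, 0], [0, 10]]).statistic == pytest.approx(20.0)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sl.chi2_independence([[0, 0], [5, 5]])

    def test_one_way_identical_groups_give_zero_f(self):
        res = sl.one_way_anova([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert res.statistic == pytest.approx(0.0)

    def test_one_way_matches_ss_oracle(self, rng):
        y = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        res = sl.one_way_anova(y, g)
        assert res.statistic == pytest.approx(one_way_anova_oracle(y, g), rel=1e-9)

    def test_one_way_single_group_rejected(self):
        with pytest.raises(ValueError):
            sl.one_way_anova([1.0, 2.0], ["a", "a"])

    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.4, 3) == 1.0
        assert bonferroni(0.01, 3) == pytest.approx(0.03)


class TestJzsBayesFactor:
    def test_null_t_favors_null_and_reciprocity(self):
        res = sl.jzs_bf_ttest(0.0, 30)
        assert res.bf10 < 1.0
        assert res.bf10 * res.bf01 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_absolute_t(self):
        bfs = [sl.jzs_bf_ttest(t, 30).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t,n", [(2.41, 30), (2.11, 30), (-1.3, 12), (4.0, 50)])
    def test_matches_independent_implementation(self, t, n):
        ours = sl.jzs_bf_ttest(t, n).bf10
        theirs = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_sign_of_t_is_immaterial(self):
        assert sl.jzs_bf_ttest(2.41, 30).bf10 == pytest.approx(
            sl.jzs_bf_ttest(-2.41, 30).bf10, rel=1e-9
        )


class TestDefaultBfAnova:
    def test_strong_separation_favors_alternative(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20), rng.normal(6, 1, 20)])
        g = np.repeat(["a", "b", "c"], 20)
        assert sl.default_bf_anova(y, g, seed=5).bf10 > 100

    def test_null_simulations_favor_null_on_median(self, rng):
        bf01 = []
        for _ in range(60):
            y = rng.normal(size=45)
            g = np.repeat(["a", "b", "c"], 15)
            bf01.append(sl.default_bf_anova(y, g, n_mc=8000, seed=3).bf01)
        assert np.median(bf01) > 1.0

    def test_within_two_level_agrees_with_jzs_quadrature(self, rng):
        """scale_fixed 0.5 on a two-level within factor corresponds to a
        Cauchy width 0.707 paired-t prior; Monte Carlo must agree with
        the quadrature route within its own error."""
        x = rng.normal(0.4, 1.0, 25)
        data = np.column_stack([x, np.zeros(25)])
        mc = sl.default_bf_anova(None, within=data, scale_fixed=0.5, n_mc=100_000, seed=9)
        t = float(x.mean() / (x.std(ddof=1) / np.sqrt(25)))
        quad = sl.jzs_bf_ttest(t, 25, scale=0.5 * np.sqrt(2.0))
        assert mc.bf10 == pytest.approx(quad.bf10, abs=6 * mc.mc_error)

    def test_mc_error_reported(self, rng):
        res = sl.default_bf_anova(rng.normal(size=30), np.repeat(["a", "b"], 15), seed=0)
        assert res.mc_error is not None and res.mc_error > 0


class TestCorrelationBayesFactor:
    def test_null_correlation_large_n_favors_null(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert sl.bf_correlation(x, y).bf10 < 1.0

    def test_near_perfect_correlation_overwhelms_null(self, rng):
        x = np.linspace(0, 1, 20)
        y = x + rng.normal(0, 0.01, 20)
        assert sl.bf_correlation(x, y).bf10 > 1000

    def test_matches_riemann_grid_oracle(self):
        """n = 20, r = 0.5: agree with a fine-grid Riemann integration of
        the same exact likelihood to 3 significant digits."""
        from scipy import special

        n, r = 20, 0.5
        # construct data with an exact sample correlation of 0.5
        x = np.arange(n, dtype=float)
        x = (x - x.mean()) / x.std()
        e = np.zeros(n)
        e[: n // 2] = 1.0
        e = e - e.mean()
        e = e - (e @ x) / (x @ x) * x
        e /= np.linalg.norm(e)
        y = r * x / np.linalg.norm(x) + np.sqrt(1 - r**2) * e
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)

        rho = np.linspace(-0.9999, 0.9999, 200_001)
        kern = (
            (1 - rho**2) ** ((n - 1) / 2)
            * (1 - rho * r) ** (1.5 - n)
            * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
        )
        oracle = np.trapezoid(kern * 0.5, rho) / (
            special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
        )
        ours = sl.bf_correlation(x, y).bf10
        assert ours == pytest.approx(oracle, rel=1e-3)

    def test_matches_independent_implementation(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        r = float(np.corrcoef(x, y)[0, 1])
        ours = sl.bf_correlation(x, y).bf10
        theirs = float(pg.bayesfactor_pearson(r, 25))
        assert ours == pytest.approx(theirs, rel=5e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ZeroVarianceError):
            sl.bf_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestPower:
    def test_zero_effect_gives_alpha(self):
        assert sl.power_rm_within(PowerSpec(0.0, alpha=0.05, n=20)) == pytest.approx(0.05)

    def test_strictly_increasing_in_n(self):
        powers = [sl.power_rm_within(PowerSpec(0.25, n=n)) for n in (10, 20, 40, 80)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_classical_convention_is_more_conservative(self):
        spec = PowerSpec(0.4, alpha=0.01, n=30, m=2, rho=0.5)
        assert sl.power_rm_within(spec, "classical") < sl.power_rm_within(spec, "gpower")

    def test_solve_n_returns_smallest_sufficient_n(self):
        n = sl.solve_n_rm_within(0.95, 0.3, alpha=0.05)
        assert sl.power_rm_within(PowerSpec(0.3, 0.05, n)) >= 0.95
        assert sl.power_rm_within(PowerSpec(0.3, 0.05, n - 1)) < 0.95


class TestRegression:
    @staticmethod
    def _design(rng, n=60):
        return pd.DataFrame(
            {
                "STAI-Y2": rng.normal(46, 9, n),
                "BIS-motor": rng.normal(17, 3, n),
                "BIS-attentional": rng.normal(20, 4, n),
                "BIS-nonplanning": rng.normal(26, 4, n),
            }
        )

    def test_noise_free_data_recovered_exactly(self, rng):
        x = self._design(rng)
        y = 2.0 + 1.192 * x["BIS-nonplanning"] - 0.5 * x["STAI-Y2"]
        res = sl.regress_ssrt_index(y, x)
        assert res.final.r2 == pytest.approx(1.0)
        coef = res.final.coef.set_index("term")["b"]
        assert coef["BIS-nonplanning"] == pytest.approx(1.192, abs=1e-8)
        assert coef["STAI-Y2"] == pytest.approx(-0.5, abs=1e-8)

    def test_planted_outliers_removed_once(self, rng):
        x = self._design(rng)
        y = (1.0 * x["BIS-nonplanning"] + rng.normal(0, 1.0, len(x))).to_numpy()
        y[[5, 17, 40]] += [25.0, -30.0, 28.0]
        res = sl.regress_ssrt_index(y, x, sigma_threshold=2.0)
        assert len(res.removed) == 3
        assert set(res.removed) == {5, 17, 40}
        assert res.final.df[1] == res.initial.df[1] - 3

    def test_collinear_predictors_rejected(self, rng):
        x = self._design(rng)
        x["dup"] = x["STAI-Y2"] * 2.0
        with pytest.raises(ValueError):
            sl.regress_ssrt_index(rng.normal(size=len(x)), x)

    def test_stepwise_mode_selects_the_active_predictor(self, rng):
        x = self._design(rng, n=120)
        y = 1.5 * x["BIS-nonplanning"] + rng.normal(0, 2.0, len(x))
        res = sl.regress_ssrt_index(y, x, stepwise=True)
        assert "BIS-nonplanning" in list(res.final.coef["term"])

    def test_ci_covers_generative_slope(self, rng):
        x = self._design(rng, n=90)
        y = -8.3 + 1.192 * (x["BIS-nonplanning"] - 26) + rng.normal(0, 5.0, len(x))
        res = sl.regress_ssrt_index(y, x)
        row = res.final.coef.set_index("term").loc["BIS-nonplanning"]
        assert row["ci_low"] <= 1.192 <= row["ci_high"]
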