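"""Variance decomposition, multilevel reliability and agreement ICC.

Every estimator is checked against an independent oracle: hand ANOVA mean
squares for the balanced decompositions, direct formula substitution for
the reliability coefficients, pingouin's ICC implementation and an explicit
two-way ANOVA for the agreement coefficient, and cronbach's alpha from
pingouin for the per-person reliability.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from emaqc import (
    ThreeLevelComponents,
    decompose_three_level,
    decompose_two_level,
    icc_from_components,
    multilevel_reliability,
    person_alpha,
    person_alpha_table,
    reliability_band,
    simulate_two_level_scores,
    stability_icc,
)
from emaqc.reliability import ReliabilityError


class TestICCFromComponents:
    @pytest.mark.parametrize(
        "between,within,expected",
        [(0.94, 0.81, 0.54), (0.88, 0.80, 0.52), (0.42, 0.50, 0.46), (1.0, 1.0, 0.50)],
    )
    def test_reported_decompositions(self, between, within, expected):
        assert round(icc_from_components(between, within), 2) == expected

    def test_both_zero_undefined(self):
        assert icc_from_components(0.0, 0.0) is None

    def test_scale_and_shift_invariance(self):
        # multiplying all scores by c scales both components by c^2
        icc1 = icc_from_components(0.7, 0.3)
        icc2 = icc_from_components(0.7 * 4, 0.3 * 4)
        assert icc1 == pytest.approx(icc2)


class TestTwoLevel:
    @staticmethod
    def _balanced_oracle(df):
        """One-way ANOVA expected-mean-squares estimator, written out."""
        n = df.groupby("person_id").size().iloc[0]
        means = df.groupby("person_id")["score"].mean()
        grand = df["score"].mean()
        msb = n * ((means - grand) ** 2).sum() / (len(means) - 1)
        ssw = sum(
            ((g["score"] - g["score"].mean()) ** 2).sum()
            for _, g in df.groupby("person_id")
        )
        msw = ssw / (len(df) - len(means))
        return (msb - msw) / n, msw

    def test_balanced_toy_matches_ems_oracle(self):
        df = simulate_two_level_scores(6, 8, 1.2, 0.5, seed=4)
        s_b, s_w = self._balanced_oracle(df)
        comp = decompose_two_level(df)
        assert comp.sigma2_between == pytest.approx(s_b, abs=1e-6)
        assert comp.sigma2_within == pytest.approx(s_w, abs=1e-6)

    def test_balanced_reml_agrees_with_closed_form(self):
        df = simulate_two_level_scores(20, 10, 1.0, 0.7, seed=14)
        auto = decompose_two_level(df)
        reml = decompose_two_level(df, method="reml")
        assert reml.sigma2_between == pytest.approx(auto.sigma2_between, abs=1e-4)
        assert reml.sigma2_within == pytest.approx(auto.sigma2_within, abs=1e-4)

    def test_parameter_recovery_continuous(self):
        df = simulate_two_level_scores(600, 40, 0.94, 0.81, seed=5)
        comp = decompose_two_level(df)
        assert comp.sigma2_between == pytest.approx(0.94, abs=0.08)
        assert comp.sigma2_within == pytest.approx(0.81, abs=0.03)
        assert comp.icc == pytest.approx(0.54, abs=0.02)

    def test_constant_persons_at_distinct_levels(self):
        df = pd.DataFrame(
            {
                "person_id": np.repeat(["a", "b", "c"], 4),
                "score": np.repeat([1.0, 3.0, 6.0], 4),
            }
        )
        comp = decompose_two_level(df)
        assert comp.sigma2_within == pytest.approx(0.0, abs=1e-8)
        assert comp.icc == pytest.approx(1.0)

    def test_all_constant_returns_zero_components(self):
        df = pd.DataFrame({"person_id": ["a"] * 3 + ["b"] * 3, "score": 2.0})
        comp = decompose_two_level(df)
        assert (comp.sigma2_between, comp.sigma2_within) == (0.0, 0.0)
        assert comp.diagnostics


def _three_level_frame(a, n, k, s_p, s_t, s_i, s_pi, s_e, seed):
    rng = np.random.default_rng(seed)
    p_eff = rng.normal(0, np.sqrt(s_p), a)
    t_eff = rng.normal(0, np.sqrt(s_t), (a, n))
    i_eff = rng.normal(0, np.sqrt(s_i), k)
    pi_eff = rng.normal(0, np.sqrt(s_pi), (a, k))
    rows = []
    for p in range(a):
        for t in range(n):
            for i in range(k):
                rows.append(
                    (
                        f"p{p}",
                        t,
                        f"i{i}",
                        p_eff[p] + t_eff[p, t] + i_eff[i] + pi_eff[p, i]
                        + rng.normal(0, np.sqrt(s_e)),
                    )
                )
    return pd.DataFrame(rows, columns=["person_id", "occasion", "item", "value"])


def _brute_force_ems(df):
    """Independent mean-squares solution for the balanced p x i, t:p design."""
    a = df["person_id"].nunique()
    n = df["occasion"].nunique()
    k = df["item"].nunique()
    y = df.set_index(["person_id", "occasion", "item"])["value"]
    grand = y.mean()
    mp = y.groupby("person_id").mean()
    mpt = y.groupby(["person_id", "occasion"]).mean()
    mi = y.groupby("item").mean()
    mpi = y.groupby(["person_id", "item"]).mean()
    ms_p = n * k * ((mp - grand) ** 2).sum() / (a - 1)
    ms_t = k * sum(
        (mpt[p] - mp[p]) ** 2 for p in mp.index for _ in [0]
    ).sum() / (a * (n - 1))
    ms_i = a * n * ((mi - grand) ** 2).sum() / (k - 1)
    ss_pi = sum(
        (mpi[(p, i)] - mp[p] - mi[i] + grand) ** 2
        for p in mp.index
        for i in mi.index
    )
    ms_pi = n * ss_pi / ((a - 1) * (k - 1))
    ss_e = sum(
        (y[(p, t, i)] - mpt[(p, t)] - mpi[(p, i)] + mp[p]) ** 2
        for (p, t, i) in y.index
    )
    ms_e = ss_e / (a * (n - 1) * (k - 1))
    s_e = ms_e
    s_pi = (ms_pi - ms_e) / n
    s_t = (ms_t - ms_e) / k
    s_i = (ms_i - ms_pi) / (a * n)
    s_p = (ms_p - ms_t - ms_pi + ms_e) / (n * k)
    return s_p, s_t, s_i, s_pi, s_e


class TestThreeLevel:
    def test_balanced_fixture_matches_brute_force_ems(self):
        df = _three_level_frame(4, 3, 2, 1.0, 0.5, 0.2, 0.3, 0.4, seed=6)
        oracle = _brute_force_ems(df)
        comp = decompose_three_level(df, method="ems")
        got = (
            comp.sigma2_person,
            comp.sigma2_time_in_person,
            comp.sigma2_item,
            comp.sigma2_person_item,
            comp.sigma2_error,
        )
        for est, exp in zip(got, oracle):
            assert est == pytest.approx(max(exp, 0.0), abs=1e-10)

    def test_balanced_reml_agrees_with_ems(self):
        df = _three_level_frame(30, 10, 4, 1.0, 0.6, 0.1, 0.25, 0.8, seed=7)
        ems = decompose_three_level(df, method="ems")
        reml = decompose_three_level(df, method="reml")
        assert reml.sigma2_person == pytest.approx(ems.sigma2_person, abs=1e-4)
        assert reml.sigma2_time_in_person == pytest.approx(
            ems.sigma2_time_in_person, abs=1e-4
        )
        assert reml.sigma2_person_item == pytest.approx(
            ems.sigma2_person_item, abs=1e-4
        )
        assert reml.sigma2_error == pytest.approx(ems.sigma2_error, abs=1e-4)

    def test_null_item_components_recovered(self):
        df = _three_level_frame(40, 12, 3, 1.0, 0.5, 0.0, 0.0, 0.5, seed=8)
        comp = decompose_three_level(df, method="ems")
        assert comp.sigma2_item == pytest.approx(0.0, abs=0.05)
        assert comp.sigma2_person_item == pytest.approx(0.0, abs=0.05)
        # person variance carries the usual chi-square sampling noise at a=40
        assert comp.sigma2_person == pytest.approx(1.0, abs=0.6)

    def test_all_identical_responses(self):
        df = _three_level_frame(3, 2, 2, 0, 0, 0, 0, 0, seed=9)
        df["value"] = 5.0
        comp = decompose_three_level(df)
        assert comp.sigma2_person == comp.sigma2_error == 0.0


class TestMultilevelReliability:
    def test_noise_free_limit(self):
        comp = ThreeLevelComponents(1.0, 0.5, 0.1, 0.2, 0.0, k=5, n=40)
        assert multilevel_reliability(comp).r_cn == 1.0

    def test_no_within_person_signal(self):
        comp = ThreeLevelComponents(1.0, 0.0, 0.1, 0.2, 0.6, k=5, n=40)
        assert multilevel_reliability(comp).r_cn == 0.0

    def test_closed_form_substitution(self):
        comp = ThreeLevelComponents(1.0, 0.5, 0.1, 0.2, 0.6, k=5, n=40)
        rel = multilevel_reliability(comp)
        num = 1.0 + 0.2 / 5
        expected_krn = num / (num + 0.5 / 40 + 0.6 / 200)
        expected_cn = 0.5 / (0.5 + 0.6 / 5)
        assert rel.r_krn == pytest.approx(expected_krn, abs=1e-12)
        assert rel.r_cn == pytest.approx(expected_cn, abs=1e-12)

    def test_simulation_reproduces_closed_form(self):
        # simulate from the exact components and re-estimate
        comp_true = ThreeLevelComponents(1.0, 0.5, 0.1, 0.2, 0.6, k=5, n=40)
        df = _three_level_frame(500, 40, 5, 1.0, 0.5, 0.1, 0.2, 0.6, seed=10)
        est = decompose_three_level(df, method="ems")
        rel_true = multilevel_reliability(comp_true)
        rel_est = multilevel_reliability(est)
        assert rel_est.r_krn == pytest.approx(rel_true.r_krn, abs=0.03)
        assert rel_est.r_cn == pytest.approx(rel_true.r_cn, abs=0.03)

    def test_monotone_in_n_and_k(self):
        base = ThreeLevelComponents(1.0, 0.5, 0.1, 0.2, 0.6, k=4, n=10)
        more_n = ThreeLevelComponents(1.0, 0.5, 0.1, 0.2, 0.6, k=4, n=30)
        more_k = ThreeLevelComponents(1.0, 0.5, 0.1, 0.2, 0.6, k=8, n=10)
        assert multilevel_reliability(more_n).r_krn >= multilevel_reliability(base).r_krn
        assert multilevel_reliability(more_k).r_krn >= multilevel_reliability(base).r_krn
        assert multilevel_reliability(more_k).r_cn >= multilevel_reliability(base).r_cn

    @pytest.mark.parametrize(
        "value,band",
        [(0.05, "practically none"), (0.3, "slight"), (0.5, "fair"),
         (0.7, "moderate"), (0.95, "substantial")],
    )
    def test_interpretation_bands(self, value, band):
        assert reliability_band(value) == band


class TestPersonAlpha:
    def test_parallel_items_give_one(self):
        occ = np.array([1.0, 3.0, 5.0, 2.0, 4.0])
        mat = np.column_stack([occ, occ, occ])
        assert person_alpha(mat) == pytest.approx(1.0)

    def test_constant_responses_undefined(self):
        assert np.isnan(person_alpha(np.full((6, 4), 3.0)))

    def test_single_occasion_undefined(self):
        assert np.isnan(person_alpha(np.array([[1.0, 2.0, 3.0]])))

    def test_toy_matrix_matches_pingouin(self):
        rng = np.random.default_rng(11)
        mat = rng.integers(1, 8, size=(12, 4)).astype(float)
        expected = pg.cronbach_alpha(pd.DataFrame(mat))[0]
        assert person_alpha(mat) == pytest.approx(expected, abs=1e-10)

    def test_table_on_generated_cohort(self, enriched_default):
        _, enriched, _ = enriched_default
        table = person_alpha_table(enriched)
        done = enriched[enriched["completed"] == 1]
        assert len(table) == done["person_id"].nunique()
        defined = table["alpha_pa"].dropna()
        # under a homoscedastic within-person model the typical person alpha
        # sits near the within-person reliability (~0.5), well above zero
        assert 0.35 < defined.median() < 0.75


class TestStabilityICC:
    @staticmethod
    def _two_way_oracle(arr):
        """Brute-force two-way ANOVA ICC(A,1)."""
        n, k = arr.shape
        grand = arr.mean()
        msr = k * ((arr.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((arr.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            (arr - arr.mean(1)[:, None] - arr.mean(0)[None, :] + grand) ** 2
        ).sum() / ((n - 1) * (k - 1))
        return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))

    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 5.0, 3.5])
        assert stability_icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(12)
        arr = rng.normal(size=(4000, 2))
        assert stability_icc(arr) == pytest.approx(0.0, abs=0.05)

    def test_five_person_fixture_matches_anova_oracle(self):
        arr = np.array([[3.0, 4.0], [5.0, 5.5], [1.0, 2.0], [4.0, 3.0], [2.5, 2.0]])
        assert stability_icc(arr) == pytest.approx(self._two_way_oracle(arr), abs=1e-6)

    def test_matches_pingouin_icc2(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=40)
        arr = np.column_stack([base + rng.normal(0, 0.4, 40), base + 0.2])
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": np.tile(["a", "b"], 40),
                "scores": arr.ravel(),
            }
        )
        icc2 = pg.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type").loc["ICC(A,1)", "ICC"]
        assert stability_icc(arr) == pytest.approx(icc2, abs=1e-8)

    def test_too_few_persons_rejected(self):
        with pytest.raises(ReliabilityError):
            stability_icc(np.ones((2, 2)))
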