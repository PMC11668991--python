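"""Careless-response flagging, psychometric antonyms and responder rules."""

import numpy as np
import pandas as pd
import pytest

from emaqc import (
    CarelessRuleConfig,
    GeneratorConfig,
    antonym_threshold_curve,
    enrich_assessments,
    flag_careless_responders,
    flag_careless_responses,
    minimum_valid_assessments,
    person_alpha_table,
    select_antonyms,
    simulate_cohort,
)
from emaqc.careless import CarelessError, careless_response_summary


def _assessment_frame(rows):
    """Minimal enriched assessment table from (tpi, sd, pct, items...) rows."""
    df = pd.DataFrame(rows)
    df["completed"] = df.get("completed", 1)
    df["person_id"] = df.get("person_id", [f"p{i}" for i in range(len(df))])
    return df


class TestSelectAntonyms:
    def test_perfectly_anticorrelated_pair_found(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "completed": 1,
                "item_a": x,
                "item_b": -x,
                "item_c": rng.normal(size=200),
            }
        )
        pair, r, _ = select_antonyms(df, ["item_a", "item_b", "item_c"])
        assert pair == ("item_a", "item_b")
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_minimum_on_generated_data(self, enriched_default):
        _, enriched, _ = enriched_default
        pair, r, _ = select_antonyms(enriched)
        done = enriched[enriched["completed"] == 1]
        cols = [f"item_{i:02d}" for i in range(1, 13)]
        corr = done[cols].astype(float).corr()
        brute = min(
            (corr.loc[a, b], (a, b))
            for i, a in enumerate(cols)
            for b in cols[i + 1 :]
        )
        assert r == pytest.approx(brute[0], abs=1e-12)
        assert r < 0  # PA and NA latents are negatively coupled

    def test_independent_items_give_near_zero_minimum(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame(
            {
                "completed": 1,
                **{f"it{j}": rng.normal(size=5000) for j in range(4)},
            }
        )
        _, r, _ = select_antonyms(df, [f"it{j}" for j in range(4)])
        assert r == pytest.approx(0.0, abs=0.06)

    def test_all_positive_correlations_warn_no_antonyms(self):
        rng = np.random.default_rng(35)
        factor = rng.normal(size=500)
        df = pd.DataFrame(
            {
                "completed": 1,
                **{
                    f"it{j}": factor + rng.normal(0, 0.3, size=500)
                    for j in range(3)
                },
            }
        )
        _, r, diags = select_antonyms(df, [f"it{j}" for j in range(3)])
        assert r > 0
        assert any("no psychometric antonyms" in d for d in diags)

    def test_constant_item_excluded_with_diagnostic(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=50)
        df = pd.DataFrame({"completed": 1, "a": x, "b": -x, "c": 3.0})
        pair, _, diags = select_antonyms(df, ["a", "b", "c"])
        assert pair == ("a", "b")
        assert any("constant items excluded" in d for d in diags)


class TestThresholdCurve:
    def test_infinite_threshold_recovers_full_sample_correlation(self, enriched_default):
        _, enriched, _ = enriched_default
        pair, full_r, _ = select_antonyms(enriched)
        curve = antonym_threshold_curve(
            enriched, "time_per_item", [np.inf], pair
        )
        assert curve["r"].iloc[0] == pytest.approx(full_r, abs=1e-12)
        assert curve["share"].iloc[0] == 1.0

    def test_straightlined_subset_forces_r_of_one(self, enriched_default):
        # inside straight-lined assessments both antonym items take the same
        # value, so across assessments the two columns are identical
        _, enriched, _ = enriched_default
        pair, _, _ = select_antonyms(enriched)
        curve = antonym_threshold_curve(enriched, "sd_items", [0.0], pair)
        assert curve["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_mode_threshold_equivalent_to_zero_sd(self, enriched_default):
        _, enriched, _ = enriched_default
        pair, _, _ = select_antonyms(enriched)
        by_sd = antonym_threshold_curve(enriched, "sd_items", [0.0], pair)
        by_mode = antonym_threshold_curve(enriched, "pct_mode", [1.0], pair)
        assert by_sd["n"].iloc[0] == by_mode["n"].iloc[0]

    def test_random_fast_responses_flatten_the_correlation(self):
        cfg = GeneratorConfig(
            n_participants=300, careless_fraction_fast=0.03, seed=33
        )
        _, assessments, _ = simulate_cohort(cfg)
        enriched = enrich_assessments(assessments)
        pair, full_r, _ = select_antonyms(enriched)
        curve = antonym_threshold_curve(enriched, "time_per_item", [1.0], pair)
        assert full_r < -0.1
        assert abs(curve["r"].iloc[0]) < 0.15

    def test_empty_subset_missing_not_crash(self, enriched_default):
        _, enriched, _ = enriched_default
        pair, _, _ = select_antonyms(enriched)
        curve = antonym_threshold_curve(enriched, "time_per_item", [1e-9], pair)
        assert np.isnan(curve["r"].iloc[0])
        assert curve["note"].iloc[0]


class TestResponseFlags:
    @pytest.mark.parametrize(
        "tpi,sd,expected",
        [(0.9, 1.2, "fast"), (3.9, 0.0, "straightline"), (3.9, 1.2, "none"),
         (0.5, 0.0, "both"), (1.0, 1.2, "fast")],  # inclusive boundary
    )
    def test_flag_rules(self, tpi, sd, expected):
        df = _assessment_frame([{"time_per_item": tpi, "sd_items": sd}])
        out = flag_careless_responses(df)
        assert out["careless_flag"].iloc[0] == expected

    def test_missed_assessments_never_flagged(self):
        df = _assessment_frame(
            [{"time_per_item": np.nan, "sd_items": np.nan, "completed": 0}]
        )
        out = flag_careless_responses(df)
        assert out["careless_flag"].iloc[0] == "none"

    def test_monotone_in_tpi_threshold(self, enriched_default):
        _, enriched, _ = enriched_default
        counts = [
            flag_careless_responses(
                enriched, CarelessRuleConfig(tpi_threshold_seconds=thr)
            )["careless"].sum()
            for thr in (0.5, 1.0, 2.0, 5.0)
        ]
        assert counts == sorted(counts)

    def test_flagged_with_variance_implies_fast(self, enriched_default):
        _, enriched, _ = enriched_default
        out = flag_careless_responses(enriched)
        flagged_varied = out[(out["careless"] == 1) & (out["sd_items"] > 0)]
        assert (flagged_varied["time_per_item"] <= 1.0).all()

    def test_detection_recovers_injected_labels(self, enriched_default):
        _, enriched, truth = enriched_default
        out = flag_careless_responses(enriched).merge(
            truth, on=["person_id", "day", "window"]
        )
        injected = out[out["injected_careless"] != "none"]
        assert (injected["careless"] == 1).all()
        summary = careless_response_summary(out)
        assert summary["n_flagged"] >= len(injected)


class TestMinimumValidAssessments:
    @pytest.fixture(scope="class")
    @staticmethod
    def stability(enriched_default):
        _, enriched, _ = enriched_default
        config = CarelessRuleConfig(subset_max=40, n_replicates=3)
        return minimum_valid_assessments(enriched, config, seed=101), config

    def test_identity_at_gold_standard_size(self, stability):
        curve, config = stability
        last = curve.curves[curve.curves["subset_size"] == config.gold_standard_n]
        for col in ("mean_pa", "sd_pa", "mean_na", "sd_na"):
            assert last[col].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_mean_agreement_rises_with_subset_size(self, stability):
        curve, _ = stability
        first10 = curve.curves["mean_pa"].iloc[:10].mean()
        last10 = curve.curves["mean_pa"].iloc[-10:].mean()
        assert last10 > first10

    def test_sd_stabilizes_later_than_mean(self, stability):
        # variability needs more assessments than the mean: the SD curves
        # must cross the 0.90 target at a strictly larger subset size
        curve, config = stability
        c = curve.curves

        def crossing(col):
            ok = c[col] >= config.icc_stability_target
            for i in range(len(c)):
                if ok.iloc[i:].all():
                    return c["subset_size"].iloc[i]
            return np.inf

        mean_cross = max(crossing("mean_pa"), crossing("mean_na"))
        sd_cross = max(crossing("sd_pa"), crossing("sd_na"))
        assert sd_cross > mean_cross
        assert curve.minimum_valid_assessments == max(mean_cross, sd_cross)

    def test_too_few_eligible_persons_rejected(self):
        df = pd.DataFrame(
            {
                "person_id": ["a"] * 5,
                "completed": 1,
                "prompt_time": pd.date_range("2022-04-04", periods=5, freq="h"),
                "pa_score": 1.0,
                "na_score": 1.0,
            }
        )
        with pytest.raises(CarelessError):
            minimum_valid_assessments(df, CarelessRuleConfig())


class TestResponderFlags:
    def _tables(self):
        participants = pd.DataFrame(
            {
                "person_id": ["a", "b", "c"],
                "invited": 1,
                "participated": 1,
                "n_completed": [56, 40, 30],
            }
        )
        flagged = pd.DataFrame(
            {
                "person_id": ["a"] * 56 + ["b"] * 40 + ["c"] * 30,
                "completed": 1,
                "careless": [0] * 56 + [0] * 40 + [1] * 10 + [0] * 20,
            }
        )
        alphas = pd.DataFrame(
            {
                "person_id": ["a", "b", "c"],
                "alpha_pa": [0.9, 0.9, 0.5],
                "alpha_na": [0.9, -0.2, np.nan],
            }
        )
        return participants, flagged, alphas

    def test_clean_person_not_flagged(self):
        p, f, a = self._tables()
        out = flag_careless_responders(p, f, a, minimum=25)
        assert out.set_index("person_id").loc["a", "responder_flag"] == "none"

    def test_negative_alpha_below_floor(self):
        p, f, a = self._tables()
        out = flag_careless_responders(p, f, a, minimum=25)
        assert out.set_index("person_id").loc["b", "responder_flag"] == "low_alpha"

    def test_careless_excluded_from_valid_count(self):
        # person c completed 30 but 10 are careless: 20 valid < minimum 25
        p, f, a = self._tables()
        out = flag_careless_responders(p, f, a, minimum=25)
        row = out.set_index("person_id").loc["c"]
        assert row["n_valid"] == 20
        assert row["responder_flag"] == "low_valid"
        assert row["alpha_undefined"] == 1  # missing alpha reported, not flagged

    def test_flags_superset_under_stricter_config(self):
        p, f, a = self._tables()
        lax = flag_careless_responders(p, f, a, minimum=20)
        strict = flag_careless_responders(
            p, f, a, minimum=45, config=CarelessRuleConfig(alpha_floor=0.95)
        )
        lax_flagged = set(lax.loc[lax["responder_flag"] != "none", "person_id"])
        strict_flagged = set(strict.loc[strict["responder_flag"] != "none", "person_id"])
        assert lax_flagged <= strict_flagged

    def test_injected_cluster_enriched_among_flags(self):
        cfg = GeneratorConfig(
            n_participants=200,
            careless_fraction_straightline=0.05,
            careless_cluster_size=6,
            seed=34,
        )
        participants, assessments, truth = simulate_cohort(cfg)
        enriched = enrich_assessments(assessments)
        flagged = flag_careless_responses(enriched)
        alphas = person_alpha_table(enriched)
        out = flag_careless_responders(participants, flagged, alphas, minimum=25)
        truth_careless = truth[truth["injected_careless"] != "none"]
        cluster = (
            truth_careless.groupby("person_id").size().sort_values(ascending=False)
        )
        heavy = set(cluster[cluster >= 5].index)
        flagged_ids = set(out.loc[out["responder_flag"] != "none", "person_id"])
        sensitivity = len(heavy & flagged_ids) / len(heavy)
        base_rate = len(flagged_ids) / len(out)
        assert sensitivity > 0
        assert sensitivity > base_rate
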