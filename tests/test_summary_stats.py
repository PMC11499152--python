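"""Descriptives, mixed model contract, correlations, accuracy, power."""

import numpy as np
import pandas as pd
import pytest

from gaze_dpa import (
    LmmSpec,
    accuracy_summary,
    fit_fixation_lmm,
    fixation_totals,
    paired_sample_size,
    proficiency_correlation,
    window_descriptives,
)
from gaze_dpa.summary_stats import _paired_power


def _props(values, window="anticipation", condition="negative"):
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(len(values))],
            "trial_id": [f"T{i}" for i in range(len(values))],
            "window": window,
            "condition": condition,
            "prop_factual": values,
            "prop_illusory": [100.0 - v for v in values],
        }
    )


class TestWindowDescriptives:
    def test_single_trial_mean_is_value(self):
        out = window_descriptives(_props([70.0]), aggregation="trials")
        row = out[(out["role"] == "factual")].iloc[0]
        assert row["mean_pct"] == pytest.approx(70.0)

    def test_three_trial_hand_values(self):
        out = window_descriptives(_props([50.0, 60.0, 70.0]), aggregation="trials")
        row = out[out["role"] == "factual"].iloc[0]
        assert row["mean_pct"] == pytest.approx(60.0)
        assert row["sd_pct"] == pytest.approx(10.0)

    def test_trial_order_invariance(self, small_roles):
        from gaze_dpa import proportions_by_window

        props = proportions_by_window(small_roles)
        shuffled = props.sample(frac=1.0, random_state=1)
        a = window_descriptives(props).sort_values(
            ["aggregation", "window", "condition", "role"]
        ).reset_index(drop=True)
        b = window_descriptives(shuffled).sort_values(
            ["aggregation", "window", "condition", "role"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_both_aggregations_emitted_and_labelled(self):
        out = window_descriptives(_props([50.0, 60.0]))
        assert set(out["aggregation"]) == {"trials", "participants"}


def _simulated_totals(rng, beta_illusory=-300.0, n_participants=32, n_items=20,
                      sd_participant=150.0, sd_item=100.0, sd_noise=250.0):
    rows = []
    bp = rng.normal(0, sd_participant, n_participants)
    bi = rng.normal(0, sd_item, n_items)
    for p in range(n_participants):
        for i in range(n_items):
            base = 1500.0 + bp[p] + bi[i]
            for target, shift in (("factual", 0.0), ("illusory", beta_illusory)):
                rows.append(
                    {
                        "participant_id": f"P{p}",
                        "item_id": f"I{i}",
                        "condition": "negative",
                        "target": target,
                        "fixtotal_ms": base + shift + rng.normal(0, sd_noise),
                    }
                )
    return pd.DataFrame(rows)


class TestFixationLmm:
    def test_sign_convention_factual_preference_gives_negative_beta(self, small_roles, small_dataset):
        cfg = small_dataset[0]
        totals = fixation_totals(small_roles, cfg.sample_period_ms, window="integration")
        res = fit_fixation_lmm(totals)
        beta = res.coef("C(target, Treatment('factual'))[T.illusory]")
        assert beta["beta"] < 0
        assert beta["se"] > 0

    def test_recovers_simulated_target_effect(self):
        rng = np.random.default_rng(12)
        totals = _simulated_totals(rng, beta_illusory=-300.0)
        res = fit_fixation_lmm(totals)
        beta = res.coef("T.illusory]")
        assert beta["beta"] == pytest.approx(-300.0, rel=0.20)

    def test_null_effect_rarely_significant(self):
        """Under beta_target = 0, |t| < 2 in at least 90% of simulated fits."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 50
        spec = LmmSpec(structures=("crossed_intercepts", "participant_only"))
        for _ in range(n_sim):
            totals = _simulated_totals(
                rng, beta_illusory=0.0, n_participants=10, n_items=6
            )
            res = fit_fixation_lmm(totals, spec)
            if abs(res.coef("T.illusory]")["t"]) < 2.0:
                hits += 1
        assert hits >= 0.9 * n_sim

    def test_totals_are_counts_times_period(self, small_roles, small_dataset):
        cfg = small_dataset[0]
        totals = fixation_totals(small_roles, cfg.sample_period_ms)
        assert (totals["fixtotal_ms"] % cfg.sample_period_ms == 0).all()
        # both targets present for every trial
        per_trial = totals.groupby(["participant_id", "trial_id"])["target"].nunique()
        assert (per_trial == 2).all()

    def test_too_few_participants_rejected(self):
        df = _simulated_totals(np.random.default_rng(0), n_participants=1, n_items=5)
        with pytest.raises(ValueError):
            fit_fixation_lmm(df)


class TestProficiencyCorrelation:
    def _participants(self, scores):
        return pd.DataFrame(
            {"participant_id": [f"P{i}" for i in range(len(scores))], "proficiency": scores}
        )

    def test_perfect_correlation(self):
        props = _props([10.0, 20.0, 30.0, 40.0, 50.0])
        res = proficiency_correlation(self._participants([1, 2, 3, 4, 5]), props, "negative")
        assert res.r == pytest.approx(1.0)

    def test_hand_dataset_matches_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        props = _props(list(y))
        res = proficiency_correlation(self._participants(list(x)), props, "negative")
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.n == 5

    def test_random_datasets_match_textbook_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            props = _props(list(50 + 10 * y))
            res = proficiency_correlation(
                self._participants(list(43 + 2 * x)), props, "negative"
            )
            r_oracle = np.corrcoef(x, y)[0, 1]
            assert res.r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        props = _props([50.0, 50.0, 50.0])
        with pytest.raises(ValueError, match="variance"):
            proficiency_correlation(self._participants([40, 41, 42]), props, "negative")

    def test_per_condition_reporting(self, small_roles, small_dataset):
        from gaze_dpa import proportions_by_window

        _, _, _, participants = small_dataset
        props = proportions_by_window(small_roles)
        for cond in ("positive", "negative"):
            res = proficiency_correlation(participants, props, cond)
            assert res.condition == cond
            assert -1.0 <= res.r <= 1.0


class TestAccuracy:
    def test_all_correct_is_100(self):
        trials = pd.DataFrame({"condition": ["positive"] * 4, "response_correct": [True] * 4})
        out = accuracy_summary(trials)
        assert out.loc[0, "pct_correct"] == 100.0

    def test_639_of_640_rounds_to_99_84(self):
        trials = pd.DataFrame(
            {"condition": ["nobody"] * 640, "response_correct": [True] * 639 + [False]}
        )
        out = accuracy_summary(trials)
        assert out.loc[0, "pct_correct"] == 99.84

    def test_reported_per_condition(self, study_dataset):
        _, trials, _, _ = study_dataset
        out = accuracy_summary(trials)
        assert set(out["condition"]) == {"positive", "negative", "nobody"}
        assert (out["pct_correct"] > 98.0).all()

    def test_trial_order_invariance(self, study_dataset):
        _, trials, _, _ = study_dataset
        a = accuracy_summary(trials)
        b = accuracy_summary(trials.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(
            a.sort_values("condition").reset_index(drop=True),
            b.sort_values("condition").reset_index(drop=True),
        )


class TestPairedSampleSize:
    def test_medium_effect_gives_34(self):
        assert paired_sample_size(0.5, alpha=0.05, power=0.80, tails=2) == 34

    def test_huge_effect_gives_5(self):
        assert paired_sample_size(2.0, alpha=0.05, power=0.80, tails=2) == 5

    def test_minimality_contract(self):
        for d in (0.3, 0.5, 0.8, 2.0):
            n = paired_sample_size(d)
            assert _paired_power(n, d, 0.05, 2) >= 0.80
            assert _paired_power(n - 1, d, 0.05, 2) < 0.80

    def test_nonincreasing_in_effect_size(self):
        ns = [paired_sample_size(d) for d in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_nondecreasing_in_power(self):
        ns = [paired_sample_size(0.5, power=p) for p in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_matches_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestPower

        for d in (0.4, 0.5, 0.7):
            n_sm = int(np.ceil(TTestPower().solve_power(effect_size=d, alpha=0.05, power=0.8)))
            assert paired_sample_size(d) == n_sm

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_sample_size(-0.5)
        with pytest.raises(ValueError):
            paired_sample_size(0.5, alpha=1.5)
        with pytest.raises(ValueError):
            paired_sample_size(0.5, tails=3)
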