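"""Divergence-point analysis: per-bin WLS, onset detection, bootstrap, contrasts."""

import numpy as np
import pandas as pd
import pytest

from gaze_dpa import (
    DivergencePointAnalysis,
    DpaConfig,
    SimulationConfig,
    assign_roles,
    between_language_difference,
    bootstrap_dpa,
    detect_onset,
    difference_distribution,
    fit_bin_models,
    generate_dataset,
)
from gaze_dpa.dpa import BootstrapDistribution
from gaze_dpa.gaze_io import default_layout
from gaze_dpa.timecourse import empirical_logit

from conftest import make_trial_counts


def _binned_from_counts(counts):
    """Participant-level binned table from (participant, bin) -> (y_f, y_i)."""
    rows = []
    for (p, b), (yf, yi) in counts.items():
        rows.append(
            {
                "participant_id": p,
                "bin_start_ms": float(b),
                "y_factual": yf,
                "y_illusory": yi,
                "n_total": yf + yi,
            }
        )
    return pd.DataFrame(rows)


class TestFitBinModels:
    def test_matches_statsmodels_wls_oracle(self):
        """4 participants, counts (15,5),(16,4),(14,6),(17,3) out of N=20:
        estimate and t must equal a generic weighted-least-squares fit on the
        same 8 elog points."""
        import statsmodels.api as sm

        pairs = [(15, 5), (16, 4), (14, 6), (17, 3)]
        counts = {(f"P{i}", 4000.0): c for i, c in enumerate(pairs)}
        res = fit_bin_models(_binned_from_counts(counts)).iloc[0]

        y, w, x = [], [], []
        for yf, yi in pairs:
            n = yf + yi
            e_f, w_f = empirical_logit(yf, n)
            e_i, w_i = empirical_logit(yi, n)
            y += [e_i, e_f]
            w += [1.0 / w_i, 1.0 / w_f]
            x += [0.0, 1.0]
        X = sm.add_constant(np.array(x))
        fit = sm.WLS(np.array(y), X, weights=np.array(w)).fit()
        assert res["estimate"] == pytest.approx(fit.params[1], rel=1e-10)
        assert res["se"] == pytest.approx(fit.bse[1], rel=1e-10)
        assert res["t_value"] == pytest.approx(fit.tvalues[1], rel=1e-10)
        # one-sided p for factual > illusory
        assert res["p_value"] == pytest.approx(fit.pvalues[1] / 2.0, rel=1e-10)

    def test_identical_counts_give_zero_estimate_and_ns(self):
        counts = {(f"P{i}", 4000.0): (10, 10) for i in range(4)}
        res = fit_bin_models(_binned_from_counts(counts)).iloc[0]
        assert res["estimate"] == pytest.approx(0.0)
        assert res["p_value"] >= 0.5

    def test_single_participant_bin_flagged_untestable(self):
        counts = {("P0", 4000.0): (15, 5)}
        res = fit_bin_models(_binned_from_counts(counts)).iloc[0]
        assert not res["testable"]
        assert np.isnan(res["p_value"])

    def test_bins_on_200ms_grid(self, study_roles):
        from gaze_dpa.timecourse import add_elog, bin_counts

        binned = add_elog(
            bin_counts(
                study_roles[study_roles["condition"] == "nobody"],
                bin_width_ms=200.0,
                span=(4000.0, 8000.0),
            )
        )
        res = fit_bin_models(binned)
        assert len(res) == 20
        assert (np.diff(res["bin_start_ms"]) == 200.0).all()

    def test_two_sided_option_doubles_tail(self):
        counts = {(f"P{i}", 4000.0): c for i, c in enumerate([(15, 5), (16, 4), (14, 6), (17, 3)])}
        binned = _binned_from_counts(counts)
        one = fit_bin_models(binned, DpaConfig(one_sided=True)).iloc[0]
        two = fit_bin_models(binned, DpaConfig(one_sided=False)).iloc[0]
        assert two["p_value"] == pytest.approx(2.0 * one["p_value"], rel=1e-10)


def _results_from_pattern(pattern, start=4000.0, width=200.0):
    return pd.DataFrame(
        {
            "bin_start_ms": start + width * np.arange(len(pattern)),
            "p_value": [0.01 if s else 0.5 for s in pattern],
        }
    )


class TestDetectOnset:
    def test_all_significant_onset_at_span_start(self):
        res = _results_from_pattern([1] * 12)
        assert detect_onset(res).onset_ms == 4000.0

    def test_leading_nonsignificant_bins_skipped(self):
        res = _results_from_pattern([0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        est = detect_onset(res)
        assert est.onset_ms == 4400.0
        assert est.qualifying_run_start_bin == 2

    def test_isolated_significant_bin_does_not_qualify(self):
        res = _results_from_pattern([1, 0, 1, 1, 1])
        assert detect_onset(res).onset_ms == 4400.0

    def test_no_run_gives_missing(self):
        res = _results_from_pattern([1, 1, 0, 1, 1, 0, 1, 1, 0])
        est = detect_onset(res)
        assert est.missing and est.onset_ms is None

    def test_untestable_bins_break_runs(self):
        res = _results_from_pattern([1, 1, 1, 1])
        res.loc[1, "p_value"] = np.nan
        assert detect_onset(res, DpaConfig(k_consecutive=3)).missing

    def test_k_consecutive_configurable(self):
        res = _results_from_pattern([0, 1, 1, 0, 0])
        assert detect_onset(res, DpaConfig(k_consecutive=2)).onset_ms == 4200.0


def _single_condition_roles(tau, seed, n_participants=32, n_items=20, **kw):
    cfg = SimulationConfig(
        n_participants=n_participants,
        n_items_per_condition=n_items,
        conditions=("negative",),
        true_onset_ms={"negative": tau},
        seed=seed,
        **kw,
    )
    trials, samples, _ = generate_dataset(cfg)
    return assign_roles(samples, trials, default_layout())


class TestBootstrap:
    def test_fixed_seed_is_reproducible(self, small_roles):
        cfg = DpaConfig(n_boot=40, seed=9)
        a = bootstrap_dpa(small_roles, "negative", cfg)
        b = bootstrap_dpa(small_roles, "negative", cfg)
        np.testing.assert_array_equal(a.onsets, b.onsets)

    def test_zero_between_trial_variance_degenerates(self):
        """Identical trials everywhere: every resample gives the same onset,
        the CI has width zero and the mean equals the point estimate."""
        pattern = {4000.0 + 200 * k: (10, 10) for k in range(20)}
        for k in range(5, 20):
            pattern[4000.0 + 200 * k] = (18, 2)
        trial_counts = make_trial_counts(pattern)
        est = DivergencePointAnalysis(n_boot=50, random_state=0).fit(trial_counts)
        assert est.onset_ms_ == 5000.0
        assert est.bootstrap_.ci_low_ms == est.bootstrap_.ci_high_ms == 5000.0
        assert est.mean_onset_ms_ == est.onset_ms_

    def test_parameter_recovery_strong_ramp(self):
        """True onset 5000 ms on the bin grid: recovered mean within one bin,
        stable across two independent data seeds."""
        for seed in (21, 22):
            roles = _single_condition_roles(5000.0, seed)
            boot = bootstrap_dpa(roles, "negative", DpaConfig(n_boot=200, seed=3))
            assert boot.defined
            assert abs(boot.mean_ms - 5000.0) <= 200.0

    def test_seed_sensitivity_below_one_bin(self):
        roles = _single_condition_roles(5000.0, 23)
        m = [
            bootstrap_dpa(roles, "negative", DpaConfig(n_boot=200, seed=s)).mean_ms
            for s in (1, 2)
        ]
        assert abs(m[0] - m[1]) < 200.0

    def test_recovered_onset_nondecreasing_in_true_onset(self):
        """Shifting the true onset later never moves the recovered mean earlier."""
        means = []
        for tau in (5000.0, 5200.0, 5400.0):
            roles = _single_condition_roles(tau, seed=31, n_participants=16, n_items=10)
            boot = bootstrap_dpa(roles, "negative", DpaConfig(n_boot=60, seed=5))
            means.append(boot.mean_ms)
        assert means[0] <= means[1] <= means[2]

    def test_resample_units_all_run(self, small_roles):
        for unit in ("trials", "participants", "bin_samples"):
            boot = bootstrap_dpa(
                small_roles, "positive", DpaConfig(n_boot=20, seed=4, resample_unit=unit)
            )
            assert len(boot.onsets) == 20


class TestDifferences:
    def _boot(self, onsets, condition="a"):
        return BootstrapDistribution(
            onsets=np.asarray(onsets, dtype=float),
            n_boot=len(onsets),
            seed=0,
            condition=condition,
        )

    def test_self_difference_is_identically_zero(self):
        a = self._boot([4600, 4800, 5000, 4600])
        d = difference_distribution(a, a)
        assert d.mean_ms == 0.0
        assert not d.excludes_zero
        assert (d.diffs == 0).all()

    def test_constant_shift_gives_degenerate_ci(self):
        b = self._boot([5000.0] * 10 + [5200.0] * 10, "b")
        a = self._boot(np.asarray(b.onsets) + 400.0, "a")
        d = difference_distribution(a, b)
        assert d.mean_ms == pytest.approx(400.0)
        assert (d.ci_low_ms, d.ci_high_ms) == (400.0, 400.0)
        assert d.excludes_zero

    def test_unequal_n_boot_rejected(self):
        a = self._boot([4600, 4800])
        b = self._boot([4600, 4800, 5000])
        with pytest.raises(ValueError, match="equal n_boot"):
            difference_distribution(a, b)

    def test_missing_pairs_dropped_and_counted(self):
        a = self._boot([4600, np.nan, 5000, 4800])
        b = self._boot([4400, 4600, np.nan, 4600])
        d = difference_distribution(a, b)
        assert len(d.diffs) == 2
        assert d.n_dropped_pairs == 2

    def test_between_language_recovery_and_direction(self):
        """L1 onset 6300 vs L2 onset 5100: difference mean ~1200 ms, positive
        sign meaning the L1 group was slower."""
        roles_l1 = _single_condition_roles(6300.0, seed=41)
        roles_l2 = _single_condition_roles(5100.0, seed=42)
        cfg = DpaConfig(n_boot=200, seed=6)
        b1 = bootstrap_dpa(roles_l1, "negative", cfg)
        b2 = bootstrap_dpa(roles_l2, "negative", DpaConfig(n_boot=200, seed=7))
        d = between_language_difference(b1, b2, cfg)
        assert d.mean_ms == pytest.approx(1200.0, abs=200.0)
        assert d.mean_ms > 0  # positive <=> first (L1) group slower
        assert d.excludes_zero
        assert d.label == "L1 - L2"


class TestEstimatorProtocol:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        est = DivergencePointAnalysis(n_boot=10, alpha=0.01)
        params = est.get_params()
        assert params["n_boot"] == 10 and params["alpha"] == 0.01
        est2 = clone(est).set_params(n_boot=20)
        assert est2.get_params()["n_boot"] == 20

    def test_multi_condition_requires_selection(self, small_roles):
        with pytest.raises(ValueError, match="condition"):
            DivergencePointAnalysis(n_boot=5).fit(small_roles)

    def test_fitted_attributes_present(self, small_roles):
        est = DivergencePointAnalysis(n_boot=10, random_state=0)
        est.fit(small_roles, condition="positive")
        for attr in ("bin_results_", "onset_", "onset_ms_", "bootstrap_", "mean_onset_ms_"):
            assert hasattr(est, attr)
        assert est.bootstrap_.n_boot == 10

    def test_invalid_config_rejected(self, small_roles):
        with pytest.raises(ValueError):
            DivergencePointAnalysis(n_boot=0).fit(small_roles, condition="positive")
        with pytest.raises(ValueError):
            DivergencePointAnalysis(resample_unit="bogus").fit(
                small_roles, condition="positive"
            )
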