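"""Divergence-point analysis: per-bin weighted tests, onset detection, bootstrap.

The divergence point (DP) of a fixation timecourse is the earliest time at
which looks to the factual picture statistically and *sustainedly* exceed
looks to the illusory picture.  The procedure:

1. aggregate looks into fixed-width bins (default 200 ms, anchored at the
   audio onset) per participant and fixation target;
2. fit, per bin, a weighted linear model of empirical logits on the fixation
   target (factual vs illusory), one elog per participant x target,
   weighted by the inverse of the elog variance term;
3. declare the onset at the left edge of the first bin of the first run of
   ``k_consecutive`` bins (default 3, i.e. a preference sustained for
   600 ms) with a significant factual advantage (one-sided p < alpha);
4. resample the data (default: trials with replacement within
   participant x condition strata), repeat, and summarise the resulting
   onset distribution by its mean and percentile confidence interval
   (default 2,000 resamples, 2.5/97.5 percentiles).

Contrasts between conditions or language groups are difference distributions
of paired bootstrap onsets; an effect is declared when the percentile CI of
the differences excludes zero.

The per-bin model has a single binary predictor, so the weighted
least-squares fit is computed in closed form (identical to a generic WLS
routine, which the test suite uses as an independent check); this keeps the
2,000-fold bootstrap fast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from gaze_dpa.timecourse import add_elog, bin_counts, empirical_logit

__all__ = [
    "DpaConfig",
    "BinTestResult",
    "OnsetEstimate",
    "BootstrapDistribution",
    "DifferenceDistribution",
    "DivergencePointAnalysis",
    "fit_bin_models",
    "detect_onset",
    "bootstrap_dpa",
    "difference_distribution",
    "between_language_difference",
]


@dataclass
class DpaConfig:
    """Tuning parameters of the divergence-point analysis."""

    bin_width_ms: float = 200.0
    span: tuple[float, float] = (4000.0, 8000.0)
    k_consecutive: int = 3
    alpha: float = 0.05
    n_boot: int = 2000
    ci: tuple[float, float] = (2.5, 97.5)
    one_sided: bool = True
    resample_unit: str = "trials"
    denominator: str = "aoi_only"
    missing_onset_policy: str = "exclude"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        if self.k_consecutive < 1:
            raise ValueError("k_consecutive must be at least 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.resample_unit not in ("trials", "participants", "bin_samples"):
            raise ValueError("resample_unit must be 'trials', 'participants' or 'bin_samples'")
        if self.missing_onset_policy != "exclude":
            raise ValueError("only the 'exclude' missing-onset policy is implemented")
        if not self.ci[0] < self.ci[1]:
            raise ValueError("ci percentiles must be increasing")

    @property
    def sustained_span_ms(self) -> float:
        """Length of the required significant run (600 ms by default)."""
        return self.k_consecutive * self.bin_width_ms


@dataclass(frozen=True)
class BinTestResult:
    bin_start_ms: float
    estimate: float
    se: float
    t_value: float
    p_value: float
    df: float
    n_participants: int
    testable: bool


@dataclass(frozen=True)
class OnsetEstimate:
    """A divergence point: bin left edge of the first sustained run, if any."""

    onset_ms: float | None
    qualifying_run_start_bin: int | None

    @property
    def missing(self) -> bool:
        return self.onset_ms is None


@dataclass
class BootstrapDistribution:
    """Bootstrap distribution of divergence onsets for one condition.

    ``onsets`` holds one value per resample, NaN where a resample produced
    no qualifying run.  The mean and percentile CI are computed over the
    non-missing onsets; a distribution where every resample was missing is
    flagged undefined and carries no mean/CI.
    """

    onsets: np.ndarray
    n_boot: int
    seed: int | None
    condition: str | None = None
    point_estimate: OnsetEstimate | None = None
    ci_percentiles: tuple[float, float] = (2.5, 97.5)
    mean_ms: float | None = field(init=False, default=None)
    ci_low_ms: float | None = field(init=False, default=None)
    ci_high_ms: float | None = field(init=False, default=None)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        good = self.onsets[~np.isnan(self.onsets)]
        if good.size:
            self.mean_ms = float(np.mean(good))
            lo, hi = np.percentile(good, list(self.ci_percentiles))
            self.ci_low_ms = float(lo)
            self.ci_high_ms = float(hi)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.onsets).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / len(self.onsets)

    @property
    def defined(self) -> bool:
        return self.mean_ms is not None


@dataclass
class DifferenceDistribution:
    """Paired difference of two bootstrap onset distributions (a - b)."""

    diffs: np.ndarray
    label: str = ""
    ci_percentiles: tuple[float, float] = (2.5, 97.5)
    n_dropped_pairs: int = 0
    mean_ms: float | None = field(init=False, default=None)
    ci_low_ms: float | None = field(init=False, default=None)
    ci_high_ms: float | None = field(init=False, default=None)

    def __post_init__(self):
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.diffs.size:
            self.mean_ms = float(np.mean(self.diffs))
            lo, hi = np.percentile(self.diffs, list(self.ci_percentiles))
            self.ci_low_ms = float(lo)
            self.ci_high_ms = float(hi)

    @property
    def excludes_zero(self) -> bool:
        if self.mean_ms is None:
            return False
        return not (self.ci_low_ms <= 0.0 <= self.ci_high_ms)


# ---------------------------------------------------------------------------
# Closed-form per-bin weighted least squares
# ---------------------------------------------------------------------------

def _fit_bins_from_elogs(e, v, valid, one_sided=True):
    """Per-bin WLS of elog on the fixation-target indicator, vectorised.

    Parameters are (P, B) arrays: ``e`` the factual-target elogs (under the
    aoi-only denominator the illusory elog is exactly ``-e`` with the same
    weight), ``v`` the regression weights (inverse variance terms), and
    ``valid`` whether the participant contributed to the bin.  Returns
    per-bin estimate, SE, t, p, residual df and participant count.  Bins
    with fewer than two contributing participants are untestable (NaN p).
    """
    v = np.where(valid, v, 0.0)
    ve = np.where(valid, v * e, 0.0)
    sv = v.sum(axis=0)
    n_part = valid.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wm = ve.sum(axis=0) / sv
        estimate = 2.0 * wm
        resid = np.where(valid, e - wm, 0.0)
        rss = 2.0 * (v * resid**2).sum(axis=0)
        df = 2.0 * n_part - 2.0
        sigma2 = rss / df
        se = np.sqrt(2.0 * sigma2 / sv)
        t_val = estimate / se
    testable = n_part >= 2
    # Degenerate bins: zero residual variance gives se == 0.
    zero_se = testable & (se == 0.0)
    t_val = np.where(zero_se & (estimate > 0), np.inf, t_val)
    t_val = np.where(zero_se & (estimate < 0), -np.inf, t_val)
    t_val = np.where(zero_se & (estimate == 0), 0.0, t_val)
    with np.errstate(invalid="ignore"):
        if one_sided:
            p = stats.t.sf(t_val, np.maximum(df, 1.0))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_val), np.maximum(df, 1.0))
    p = np.where(testable, p, np.nan)
    estimate = np.where(testable, estimate, np.nan)
    return estimate, se, t_val, p, df, n_part, testable


def fit_bin_models(
    binned: pd.DataFrame,
    config: DpaConfig | None = None,
) -> pd.DataFrame:
    """Per-bin weighted empirical-logit tests of factual vs illusory looks.

    ``binned`` holds one row per participant x bin with ``y_factual``,
    ``y_illusory`` (and ``n_total``) counts; elog/weight columns are added
    if absent, using ``config.denominator``.  Each bin's model regresses the
    two per-participant target elogs on the target indicator with inverse
    variance-term weights; the returned table carries the target
    coefficient's estimate, SE, t and p (one-sided for factual > illusory
    by default) plus a ``testable`` flag for bins with at least two
    contributing participants.
    """
    config = config or DpaConfig()
    config.validate()
    if "elog" not in binned.columns:
        binned = add_elog(binned, denominator=config.denominator)
    bins = np.sort(binned["bin_start_ms"].unique())
    participants = binned["participant_id"].unique()
    wide_e = (
        binned.pivot_table(index="participant_id", columns="bin_start_ms", values="elog")
        .reindex(index=participants, columns=bins)
    )
    wide_w = (
        binned.pivot_table(index="participant_id", columns="bin_start_ms", values="weight")
        .reindex(index=participants, columns=bins)
    )
    e = wide_e.to_numpy(dtype=float)
    w = wide_w.to_numpy(dtype=float)
    valid = np.isfinite(e) & np.isfinite(w) & (w > 0)
    with np.errstate(divide="ignore"):
        v = np.where(valid, 1.0 / w, 0.0)
    est, se, t_val, p, df, n_part, testable = _fit_bins_from_elogs(
        e, v, valid, one_sided=config.one_sided
    )
    return pd.DataFrame(
        {
            "bin_start_ms": bins,
            "estimate": est,
            "se": se,
            "t_value": t_val,
            "p_value": p,
            "df": df,
            "n_participants": n_part,
            "testable": testable,
        }
    )


def _first_sustained_run(sig: np.ndarray, k: int) -> int | None:
    """Index of the first bin opening a run of >= k consecutive True values."""
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= k:
            return i - k + 1
    return None


def detect_onset(results, config: DpaConfig | None = None) -> OnsetEstimate:
    """Find the divergence onset from ordered per-bin test results.

    The onset is the left edge of the first bin of the first run of at least
    ``k_consecutive`` bins with p < alpha; untestable bins (NaN p) break
    runs.  A missing onset is a valid outcome, not an error.
    """
    config = config or DpaConfig()
    if isinstance(results, pd.DataFrame):
        df = results.sort_values("bin_start_ms")
        p = df["p_value"].to_numpy(dtype=float)
        starts = df["bin_start_ms"].to_numpy(dtype=float)
    else:
        res = sorted(results, key=lambda r: r.bin_start_ms)
        p = np.array([r.p_value for r in res], dtype=float)
        starts = np.array([r.bin_start_ms for r in res], dtype=float)
    with np.errstate(invalid="ignore"):
        sig = (p < config.alpha) & ~np.isnan(p)
    idx = _first_sustained_run(sig, config.k_consecutive)
    if idx is None:
        return OnsetEstimate(onset_ms=None, qualifying_run_start_bin=None)
    return OnsetEstimate(onset_ms=float(starts[idx]), qualifying_run_start_bin=int(idx))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _trial_count_arrays(trial_binned: pd.DataFrame):
    """Pack per-trial bin counts into padded (P, T_max, B) arrays."""
    bins = np.sort(trial_binned["bin_start_ms"].unique())
    b_index = {b: j for j, b in enumerate(bins)}
    participants = list(pd.unique(trial_binned["participant_id"]))
    p_index = {p: i for i, p in enumerate(participants)}
    trial_keys = trial_binned[["participant_id", "trial_id"]].drop_duplicates()
    t_counts = trial_keys.groupby("participant_id", sort=False).size()
    n_trials = np.array([t_counts[p] for p in participants], dtype=int)
    t_max = int(n_trials.max())
    t_index = {}
    cursor = {p: 0 for p in participants}
    for p, t in trial_keys.itertuples(index=False):
        t_index[(p, t)] = cursor[p]
        cursor[p] += 1
    yf = np.zeros((len(participants), t_max, len(bins)))
    n = np.zeros_like(yf)
    pi = trial_binned["participant_id"].map(p_index).to_numpy()
    ti = np.array(
        [t_index[k] for k in zip(trial_binned["participant_id"], trial_binned["trial_id"])]
    )
    bi = trial_binned["bin_start_ms"].map(b_index).to_numpy()
    yf[pi, ti, bi] = trial_binned["y_factual"].to_numpy(dtype=float)
    n[pi, ti, bi] = (
        trial_binned["y_factual"] + trial_binned["y_illusory"]
    ).to_numpy(dtype=float)
    return yf, n, n_trials, bins


def _onset_from_counts(yf_pb, n_pb, bins, config) -> float:
    """Onset (ms, NaN if missing) from participant x bin aggregated counts."""
    elog, weight = empirical_logit(yf_pb, n_pb)
    valid = np.isfinite(elog)
    with np.errstate(divide="ignore"):
        v = np.where(valid, 1.0 / weight, 0.0)
    e = np.where(valid, elog, 0.0)
    _, _, _, p, _, _, _ = _fit_bins_from_elogs(e, v, valid, one_sided=config.one_sided)
    with np.errstate(invalid="ignore"):
        sig = (p < config.alpha) & ~np.isnan(p)
    idx = _first_sustained_run(sig, config.k_consecutive)
    return np.nan if idx is None else float(bins[idx])


def _bootstrap_onsets(yf, n, n_trials, bins, config, rng) -> np.ndarray:
    n_p, t_max, _ = yf.shape
    onsets = np.empty(config.n_boot)
    agg_yf = yf.sum(axis=1)
    agg_n = n.sum(axis=1)
    slot = np.arange(t_max)[None, :]
    slot_valid = slot < n_trials[:, None]
    for r in range(config.n_boot):
        if config.resample_unit == "trials":
            # Trials with replacement within each participant stratum.
            idx = (rng.random((n_p, t_max)) * n_trials[:, None]).astype(int)
            take = np.take_along_axis(yf, idx[:, :, None], axis=1)
            yf_pb = np.where(slot_valid[:, :, None], take, 0.0).sum(axis=1)
            take_n = np.take_along_axis(n, idx[:, :, None], axis=1)
            n_pb = np.where(slot_valid[:, :, None], take_n, 0.0).sum(axis=1)
        elif config.resample_unit == "participants":
            pick = rng.integers(0, n_p, n_p)
            yf_pb = agg_yf[pick]
            n_pb = agg_n[pick]
        else:  # bin_samples: redraw the AOI looks within each cell
            with np.errstate(invalid="ignore", divide="ignore"):
                p_cell = np.where(agg_n > 0, agg_yf / np.maximum(agg_n, 1.0), 0.0)
            yf_pb = rng.binomial(agg_n.astype(int), p_cell).astype(float)
            n_pb = agg_n
        onsets[r] = _onset_from_counts(yf_pb, n_pb, bins, config)
    return onsets


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class DivergencePointAnalysis(BaseEstimator):
    """Bootstrap divergence-point estimator for one condition's timecourse.

    Follows the scikit-learn estimator protocol: parameters are set in
    ``__init__``, :meth:`fit` consumes a data table and exposes fitted
    attributes with trailing underscores.

    Parameters
    ----------
    bin_width_ms : float, default 200
        Width of the aggregation bins, anchored at ``span[0]``.
    span : (float, float), default (4000, 8000)
        Analysis span in ms (half-open), covering the anticipation and
        integration windows.
    k_consecutive : int, default 3
        Number of consecutive significant bins required (600 ms sustained
        preference at the defaults).
    alpha : float, default 0.05
        Per-bin significance level (one-sided factual > illusory unless
        ``one_sided=False``).
    n_boot : int, default 2000
        Bootstrap resamples.
    ci : (float, float), default (2.5, 97.5)
        Percentiles of the bootstrap confidence interval.
    resample_unit : {"trials", "participants", "bin_samples"}
        Bootstrap stratification; the default resamples trials with
        replacement within participant strata.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    bin_results_ : DataFrame
        Per-bin test results on the full data.
    onset_ : OnsetEstimate
        Point estimate of the divergence onset.
    onset_ms_ : float or None
    bootstrap_ : BootstrapDistribution
    mean_onset_ms_, ci_low_ms_, ci_high_ms_ : float or None
    """

    def __init__(
        self,
        bin_width_ms: float = 200.0,
        span: tuple[float, float] = (4000.0, 8000.0),
        k_consecutive: int = 3,
        alpha: float = 0.05,
        n_boot: int = 2000,
        ci: tuple[float, float] = (2.5, 97.5),
        one_sided: bool = True,
        resample_unit: str = "trials",
        denominator: str = "aoi_only",
        random_state=None,
    ):
        self.bin_width_ms = bin_width_ms
        self.span = span
        self.k_consecutive = k_consecutive
        self.alpha = alpha
        self.n_boot = n_boot
        self.ci = ci
        self.one_sided = one_sided
        self.resample_unit = resample_unit
        self.denominator = denominator
        self.random_state = random_state

    def _config(self) -> DpaConfig:
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        cfg = DpaConfig(
            bin_width_ms=self.bin_width_ms,
            span=tuple(self.span),
            k_consecutive=self.k_consecutive,
            alpha=self.alpha,
            n_boot=self.n_boot,
            ci=tuple(self.ci),
            one_sided=self.one_sided,
            resample_unit=self.resample_unit,
            denominator=self.denominator,
            seed=seed,
        )
        cfg.validate()
        return cfg

    def fit(self, X: pd.DataFrame, y=None, condition: str | None = None):
        """Estimate the divergence point from role-labelled samples.

        ``X`` is either a role-annotated long table (``participant_id``,
        ``trial_id``, ``t_ms``, ``role``) or a per-trial binned-count table
        (``participant_id``, ``trial_id``, ``bin_start_ms``, ``y_factual``,
        ``y_illusory``).  If a ``condition`` column with several levels is
        present, ``condition=`` must name the one to analyse.
        """
        cfg = self._config()
        if "condition" in X.columns:
            levels = X["condition"].unique()
            if condition is not None:
                X = X[X["condition"] == condition]
                if X.empty:
                    raise ValueError(f"no rows for condition {condition!r}")
            elif len(levels) > 1:
                raise ValueError(
                    "X holds several conditions; pass condition= to select one"
                )
            else:
                condition = levels[0]
        if "role" in X.columns:
            trial_binned = bin_counts(
                X,
                bin_width_ms=cfg.bin_width_ms,
                span=cfg.span,
                by=["participant_id", "trial_id"],
            )
        else:
            for col in ("participant_id", "trial_id", "bin_start_ms", "y_factual", "y_illusory"):
                if col not in X.columns:
                    raise ValueError(f"binned input is missing column {col!r}")
            trial_binned = X
        if trial_binned.empty:
            raise ValueError("no samples in the analysis span")
        yf, n, n_trials, bins = _trial_count_arrays(trial_binned)
        if (n_trials < 1).any():
            raise ValueError("every participant needs at least one trial")

        agg = (
            trial_binned.groupby(["participant_id", "bin_start_ms"], as_index=False)[
                ["y_factual", "y_illusory"]
            ].sum()
        )
        agg["n_total"] = agg["y_factual"] + agg["y_illusory"]
        self.bin_results_ = fit_bin_models(agg, cfg)
        self.onset_ = detect_onset(self.bin_results_, cfg)
        self.onset_ms_ = self.onset_.onset_ms

        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        onsets = _bootstrap_onsets(yf, n, n_trials, bins, cfg, rng)
        self.bootstrap_ = BootstrapDistribution(
            onsets=onsets,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            condition=condition,
            point_estimate=self.onset_,
            ci_percentiles=cfg.ci,
        )
        self.mean_onset_ms_ = self.bootstrap_.mean_ms
        self.ci_low_ms_ = self.bootstrap_.ci_low_ms
        self.ci_high_ms_ = self.bootstrap_.ci_high_ms
        return self


def bootstrap_dpa(
    role_df: pd.DataFrame,
    condition: str | None = None,
    config: DpaConfig | None = None,
) -> BootstrapDistribution:
    """Bootstrap the divergence point for one condition (functional wrapper).

    Equivalent to fitting :class:`DivergencePointAnalysis` with the given
    configuration and returning its ``bootstrap_`` attribute.
    """
    config = config or DpaConfig()
    config.validate()
    est = DivergencePointAnalysis(
        bin_width_ms=config.bin_width_ms,
        span=config.span,
        k_consecutive=config.k_consecutive,
        alpha=config.alpha,
        n_boot=config.n_boot,
        ci=config.ci,
        one_sided=config.one_sided,
        resample_unit=config.resample_unit,
        denominator=config.denominator,
        random_state=config.seed,
    )
    est.fit(role_df, condition=condition)
    return est.bootstrap_


def difference_distribution(
    a: BootstrapDistribution,
    b: BootstrapDistribution,
    config: DpaConfig | None = None,
    label: str | None = None,
) -> DifferenceDistribution:
    """Paired difference (a - b) of two bootstrap onset distributions.

    The two distributions must have the same number of resamples; onsets
    are paired by resample index and pairs where either member is missing
    are dropped (the count is recorded).  The effect is declared significant
    when the percentile CI of the differences excludes zero.
    """
    config = config or DpaConfig()
    if len(a.onsets) != len(b.onsets):
        raise ValueError(
            "difference distributions require equal n_boot in both conditions"
        )
    both = ~np.isnan(a.onsets) & ~np.isnan(b.onsets)
    diffs = a.onsets[both] - b.onsets[both]
    if label is None:
        label = f"{a.condition or 'a'} - {b.condition or 'b'}"
    return DifferenceDistribution(
        diffs=diffs,
        label=label,
        ci_percentiles=config.ci,
        n_dropped_pairs=int((~both).sum()),
    )


def between_language_difference(
    lang1: BootstrapDistribution,
    lang2: BootstrapDistribution,
    config: DpaConfig | None = None,
    labels: tuple[str, str] = ("L1", "L2"),
) -> DifferenceDistribution:
    """Between-language onset difference, computed as L1 - L2.

    A positive mean means the first (L1) group diverged *later*, i.e. was
    slower to launch preferential looks, than the second (L2) group.
    """
    return difference_distribution(
        lang1, lang2, config=config, label=f"{labels[0]} - {labels[1]}"
    )
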