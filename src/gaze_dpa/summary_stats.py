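"""Window descriptives, mixed-effects contract, correlations, accuracy, power.

These are the statistics that surround the divergence-point analysis in a
blank-screen visual-world study: average fixation proportions per window and
condition, a linear mixed model testing whether total fixation time differs
between the factual and illusory targets, Pearson correlations of L2
proficiency with anticipatory fixation proportions, button-press accuracy,
and the a-priori paired-means sample-size computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gaze_dpa.timecourse import WindowSpec, assign_window

logger = logging.getLogger(__name__)

__all__ = [
    "LmmSpec",
    "LmmResult",
    "CorrelationResult",
    "fixation_totals",
    "window_descriptives",
    "fit_fixation_lmm",
    "proficiency_correlation",
    "accuracy_summary",
    "paired_sample_size",
]


@dataclass
class LmmSpec:
    """Contract for the fixation-duration mixed model.

    Outcome: total fixation length (ms) per trial x fixation target.  Fixed
    effects: target (treatment-coded, reference ``factual``) crossed with
    condition (reference ``positive``).  Random effects: the requested
    structure starts from crossed by-participant and by-item effects with
    target slopes and is simplified step by step on non-convergence (each
    simplification is logged); correlations between random effects are not
    estimated (variance components are independent).
    """

    window: str = "anticipation"
    target_reference: str = "factual"
    condition_reference: str = "positive"
    structures: tuple[str, ...] = (
        "crossed_slopes",  # participant & item intercepts + target slopes + participant:condition
        "crossed_target",  # participant & item intercepts + target slopes
        "crossed_intercepts",  # participant & item intercepts
        "participant_only",  # by-participant random intercept
    )


@dataclass
class LmmResult:
    """Fixed-effect table (beta, SE, t, p) plus the structure that converged."""

    fixed_effects: pd.DataFrame
    structure: str
    converged: bool
    formula: str

    def coef(self, name_contains: str) -> pd.Series:
        exact = self.fixed_effects[self.fixed_effects["term"] == name_contains]
        if len(exact) == 1:
            return exact.iloc[0]
        hits = self.fixed_effects[
            self.fixed_effects["term"].str.contains(name_contains, regex=False)
        ]
        if hits.empty:
            raise KeyError(f"{name_contains!r} matches no fixed-effect term")
        # prefer the main effect over interactions containing the same label
        return hits.loc[hits["term"].str.count(":").idxmin()]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    condition: str | None = None


def fixation_totals(
    role_df: pd.DataFrame,
    sample_period_ms: float,
    spec: WindowSpec | None = None,
    window: str = "anticipation",
) -> pd.DataFrame:
    """Total fixation length (ms) per trial x fixation target in one window.

    Computed as (number of in-window samples with the role) x sample period;
    trials contribute a 0 ms total for a target they never fixated.
    """
    spec = spec or WindowSpec()
    if window not in spec.names:
        raise ValueError(f"unknown window {window!r}")
    lo, hi = spec.bounds(window)
    t = role_df["t_ms"].to_numpy(dtype=float)
    in_win = (t >= lo) & (t < hi) if window != "integration" else (t >= lo) & (t <= hi)
    df = role_df.loc[in_win]
    df = df[df["role"].isin(["factual", "illusory"])]
    keys = ["participant_id", "trial_id"]
    extra = [c for c in ("condition", "item_id", "language") if c in role_df.columns]
    counts = (
        df.pivot_table(index=keys + extra, columns="role", aggfunc="size", fill_value=0)
        .reindex(columns=["factual", "illusory"], fill_value=0)
        .reset_index()
    )
    long = counts.melt(
        id_vars=keys + extra,
        value_vars=["factual", "illusory"],
        var_name="target",
        value_name="n_samples",
    )
    long["fixtotal_ms"] = long["n_samples"] * sample_period_ms
    return long.drop(columns="n_samples")


def window_descriptives(
    per_trial_props: pd.DataFrame,
    aggregation: str = "both",
) -> pd.DataFrame:
    """Mean and SD of fixation percentages per window x condition x role.

    ``aggregation="trials"`` pools all trials in a cell; ``"participants"``
    first averages within participant, then takes mean/SD across participant
    means.  ``"both"`` (default) emits both, labelled in an ``aggregation``
    column, since reported descriptives in this paradigm can follow either
    convention.
    """
    if aggregation not in ("trials", "participants", "both"):
        raise ValueError("aggregation must be 'trials', 'participants' or 'both'")
    frames = []
    long = per_trial_props.melt(
        id_vars=[c for c in ("participant_id", "trial_id", "window", "condition") if c in per_trial_props.columns],
        value_vars=["prop_factual", "prop_illusory"],
        var_name="role",
        value_name="pct",
    )
    long["role"] = long["role"].str.replace("prop_", "", regex=False)
    keys = ["window", "condition", "role"]
    if aggregation in ("trials", "both"):
        g = long.groupby(keys)["pct"].agg(["mean", "std", "count"]).reset_index()
        g["aggregation"] = "trials"
        frames.append(g)
    if aggregation in ("participants", "both"):
        pm = (
            long.groupby(keys + ["participant_id"])["pct"].mean().reset_index()
        )
        g = pm.groupby(keys)["pct"].agg(["mean", "std", "count"]).reset_index()
        g["aggregation"] = "participants"
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    empty = out["count"] == 0
    if empty.any():
        logger.warning("omitting %d empty descriptive cells", int(empty.sum()))
        out = out.loc[~empty]
    return out.rename(columns={"mean": "mean_pct", "std": "sd_pct", "count": "n"})


def _mixedlm_design(totals: pd.DataFrame, spec: LmmSpec):
    df = totals.copy()
    df["target_illusory"] = (df["target"] != spec.target_reference).astype(float)
    fixed = (
        f"fixtotal_ms ~ C(target, Treatment('{spec.target_reference}'))"
        f" * C(condition, Treatment('{spec.condition_reference}'))"
    )
    vc_by_structure = {
        "crossed_slopes": {
            "participant": "0 + C(participant_id)",
            "participant_target": "0 + C(participant_id):target_illusory",
            "participant_condition": "0 + C(participant_id):C(condition)",
            "item": "0 + C(item_id)",
            "item_target": "0 + C(item_id):target_illusory",
        },
        "crossed_target": {
            "participant": "0 + C(participant_id)",
            "participant_target": "0 + C(participant_id):target_illusory",
            "item": "0 + C(item_id)",
            "item_target": "0 + C(item_id):target_illusory",
        },
        "crossed_intercepts": {
            "participant": "0 + C(participant_id)",
            "item": "0 + C(item_id)",
        },
    }
    return df, fixed, vc_by_structure


def fit_fixation_lmm(totals: pd.DataFrame, spec: LmmSpec | None = None) -> LmmResult:
    """Mixed model of per-trial fixation totals on target x condition.

    Delegates the REML fit to statsmodels' MixedLM.  Crossed participant and
    item effects are expressed as variance components within a single
    grouping constant; the structure ladder in ``spec.structures`` is tried
    in order and the first converging, non-singular fit is returned (the
    simplification, if any, is logged).  With treatment coding and data in
    which the factual target attracts more looks, the ``illusory``
    coefficient is negative.
    """
    import statsmodels.formula.api as smf

    spec = spec or LmmSpec()
    for col in ("fixtotal_ms", "target", "condition", "participant_id", "item_id"):
        if col not in totals.columns:
            raise ValueError(f"totals table is missing column {col!r}")
    if totals["participant_id"].nunique() < 2 or totals["item_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 items")
    df, fixed, vc_by_structure = _mixedlm_design(totals, spec)
    df["_group"] = 1
    single_condition = df["condition"].nunique() < 2
    if single_condition:
        fixed = f"fixtotal_ms ~ C(target, Treatment('{spec.target_reference}'))"

    last_exc: Exception | None = None
    for structure in spec.structures:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if structure == "participant_only":
                    model = smf.mixedlm(
                        fixed, df, groups=df["participant_id"], re_formula="1"
                    )
                else:
                    vc = dict(vc_by_structure[structure])
                    if single_condition:
                        vc.pop("participant_condition", None)
                    model = smf.mixedlm(
                        fixed, df, groups=df["_group"], vc_formula=vc
                    )
                res = model.fit(reml=True, method="lbfgs", maxiter=500)
            if not np.isfinite(res.bse_fe).all():
                raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
            fe = pd.DataFrame(
                {
                    "term": res.fe_params.index,
                    "beta": res.fe_params.to_numpy(),
                    "se": res.bse_fe.to_numpy(),
                    "t": (res.fe_params / res.bse_fe).to_numpy(),
                }
            )
            fe["p"] = 2.0 * stats.norm.sf(np.abs(fe["t"]))
            if structure != spec.structures[0]:
                logger.warning(
                    "mixed model simplified to %r after a failed fit", structure
                )
            # The optimizer's convergence flag is recorded but advisory:
            # lbfgs flags variance-component fits liberally even when the
            # fixed effects are stable across structures.
            return LmmResult(
                fixed_effects=fe,
                structure=structure,
                converged=bool(getattr(res, "converged", True)),
                formula=fixed,
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
    raise RuntimeError(f"no mixed-model structure converged: {last_exc}")


def proficiency_correlation(
    participants: pd.DataFrame,
    per_trial_props: pd.DataFrame,
    condition: str,
    window: str = "anticipation",
) -> CorrelationResult:
    """Pearson correlation of proficiency with anticipation-window looks.

    Each participant contributes one proficiency score and one mean factual
    fixation percentage in the given window and condition; the two-sided p
    comes from the exact t reference distribution at n - 2 df.
    """
    props = per_trial_props
    props = props[(props["window"] == window) & (props["condition"] == condition)]
    if props.empty:
        raise ValueError(f"no proportion rows for condition {condition!r} in {window!r}")
    by_p = props.groupby("participant_id")["prop_factual"].mean()
    merged = participants.set_index("participant_id").join(by_p, how="inner")
    merged = merged.dropna(subset=["proficiency", "prop_factual"])
    n = len(merged)
    if n < 3:
        raise ValueError("need at least 3 participants for a correlation")
    x = merged["proficiency"].to_numpy(dtype=float)
    y = merged["prop_factual"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in proficiency or fixation proportions")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n, condition=condition)


def accuracy_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Percentage of correct button responses per condition (2 decimals)."""
    if "response_correct" not in trials.columns:
        raise ValueError("trials table is missing column 'response_correct'")
    g = trials.groupby("condition")["response_correct"].agg(["mean", "count"]).reset_index()
    g["pct_correct"] = (100.0 * g["mean"]).round(2)
    return g.rename(columns={"count": "n_trials"})[["condition", "pct_correct", "n_trials"]]


def _paired_power(n: int, d: float, alpha: float, tails: int) -> float:
    """Power of a paired t-test at n pairs, effect size d (Cohen's dz)."""
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def paired_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n with a paired t-test achieving the requested power.

    Iterates the noncentral-t power function over n (df = n - 1,
    noncentrality d * sqrt(n)) and returns the first n reaching the target;
    d = 0.5, alpha = .05, power = .80, two-tailed gives n = 34.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        if _paired_power(n, d, alpha, tails) >= power:
            return n
    raise ValueError("requested power unreachable within n_max pairs")
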