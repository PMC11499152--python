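"""Window segmentation, 200 ms binning, and weighted empirical logits.

The trial timeline is split into three analysis windows: *preview*
(pictures visible, no audio), *anticipation* (blank screen, audio playing)
and *integration* (pictures restored).  Looks are aggregated into fixed-width
time bins anchored at the audio onset, and per-cell counts are transformed to
empirical logits ``ln((y + 0.5) / (N - y + 0.5))`` with the companion
variance term ``1/(y + 0.5) + 1/(N - y + 0.5)``; the 0.5 corrections keep
both finite at y = 0 and y = N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "assign_window",
    "bin_counts",
    "empirical_logit",
    "add_elog",
    "proportions_by_window",
]


@dataclass(frozen=True)
class WindowSpec:
    """Boundaries (ms) of the three analysis windows.

    Membership is half-open on the left boundary of each window
    (4,000 ms belongs to anticipation); the trial end itself belongs to
    integration.  Defaults: preview 0-4,000 ms, anticipation 4,000-7,000 ms,
    integration 7,000-8,000 ms.
    """

    preview_start_ms: float = 0.0
    anticipation_start_ms: float = 4000.0
    integration_start_ms: float = 7000.0
    trial_end_ms: float = 8000.0

    def __post_init__(self):
        b = (
            self.preview_start_ms,
            self.anticipation_start_ms,
            self.integration_start_ms,
            self.trial_end_ms,
        )
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError("window boundaries must be strictly increasing")

    @property
    def names(self) -> tuple[str, str, str]:
        return ("preview", "anticipation", "integration")

    def bounds(self, window: str) -> tuple[float, float]:
        starts = {
            "preview": (self.preview_start_ms, self.anticipation_start_ms),
            "anticipation": (self.anticipation_start_ms, self.integration_start_ms),
            "integration": (self.integration_start_ms, self.trial_end_ms),
        }
        return starts[window]


def assign_window(t_ms, spec: WindowSpec | None = None):
    """Label time points with their analysis window.

    Accepts a scalar or array; raises if any time falls outside
    ``[preview_start, trial_end]``.
    """
    spec = spec or WindowSpec()
    t = np.asarray(t_ms, dtype=float)
    if (t < spec.preview_start_ms).any() or (t > spec.trial_end_ms).any():
        raise ValueError("time outside the trial timeline")
    labels = np.where(
        t < spec.anticipation_start_ms,
        "preview",
        np.where(t < spec.integration_start_ms, "anticipation", "integration"),
    )
    if np.isscalar(t_ms):
        return str(labels.item() if labels.ndim == 0 else labels[()])
    return labels


def bin_counts(
    role_df: pd.DataFrame,
    bin_width_ms: float = 200.0,
    span: tuple[float, float] = (4000.0, 8000.0),
    by: Sequence[str] = ("participant_id", "condition"),
) -> pd.DataFrame:
    """Aggregate role-labelled samples into fixed-width time bins.

    Returns one row per ``by``-group x bin over the *complete* bin grid
    (groups observed anywhere in the span get explicit zero rows for empty
    bins), with ``y_factual``, ``y_illusory`` and ``n_total`` counts.
    Samples at or beyond ``span[1]`` are excluded (half-open span).
    """
    start, end = float(span[0]), float(span[1])
    if end <= start:
        raise ValueError("empty analysis span")
    n_bins_f = (end - start) / bin_width_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("bin width must divide the span length")
    by = list(by)
    t = role_df["t_ms"].to_numpy(dtype=float)
    in_span = (t >= start) & (t < end)
    df = role_df.loc[in_span, by + ["role"]].copy()
    df["bin_start_ms"] = start + bin_width_ms * np.floor(
        (t[in_span] - start) / bin_width_ms
    )
    counts = (
        df.pivot_table(
            index=by + ["bin_start_ms"],
            columns="role",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=["factual", "illusory", "elsewhere"], fill_value=0)
    )
    # Complete grid: every observed group x every bin in the span.
    groups = df[by].drop_duplicates()
    grid = groups.merge(
        pd.DataFrame({"bin_start_ms": start + bin_width_ms * np.arange(n_bins)}),
        how="cross",
    )
    out = grid.merge(
        counts.reset_index(), on=by + ["bin_start_ms"], how="left"
    ).fillna({"factual": 0, "illusory": 0, "elsewhere": 0})
    out["y_factual"] = out["factual"].astype(int)
    out["y_illusory"] = out["illusory"].astype(int)
    out["n_total"] = (out["factual"] + out["illusory"] + out["elsewhere"]).astype(int)
    out["bin_end_ms"] = out["bin_start_ms"] + bin_width_ms
    out = out.drop(columns=["factual", "illusory", "elsewhere"])
    return out.sort_values(by + ["bin_start_ms"]).reset_index(drop=True)


def empirical_logit(y, n):
    """Empirical logit and its approximate variance for binned counts.

    ``elog = ln((y + 0.5) / (n - y + 0.5))`` and
    ``weight = 1/(y + 0.5) + 1/(n - y + 0.5)`` (the variance term whose
    inverse serves as the regression weight).  Cells with ``n == 0`` are
    undefined and come back as NaN rather than raising, so batch pipelines
    can flag them as missing.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if (y < 0).any() or (y > n).any():
        raise ValueError("counts must satisfy 0 <= y <= n")
    with np.errstate(divide="ignore", invalid="ignore"):
        elog = np.log((y + 0.5) / (n - y + 0.5))
        weight = 1.0 / (y + 0.5) + 1.0 / (n - y + 0.5)
    empty = n < 1
    elog = np.where(empty, np.nan, elog)
    weight = np.where(empty, np.nan, weight)
    if np.isscalar(y) or (elog.ndim == 0):
        return float(elog), float(weight)
    return elog, weight


def add_elog(binned: pd.DataFrame, denominator: str = "aoi_only") -> pd.DataFrame:
    """Attach N, elog and weight columns to a binned-count table.

    ``denominator="aoi_only"`` uses N = factual + illusory looks (the
    contrast denominator: elog > 0 means more factual than illusory looks);
    ``"all_samples"`` uses every sample in the bin including elsewhere looks.
    """
    if denominator not in ("aoi_only", "all_samples"):
        raise ValueError("denominator must be 'aoi_only' or 'all_samples'")
    out = binned.copy()
    n = (
        out["y_factual"] + out["y_illusory"]
        if denominator == "aoi_only"
        else out["n_total"]
    )
    out["N"] = n
    elog, weight = empirical_logit(out["y_factual"].to_numpy(), n.to_numpy(dtype=float))
    out["elog"] = elog
    out["weight"] = weight
    return out


def proportions_by_window(
    role_df: pd.DataFrame,
    spec: WindowSpec | None = None,
    denominator: str = "aoi_only",
) -> pd.DataFrame:
    """Per-trial fixation percentages for each analysis window.

    Returns one row per trial x window with ``prop_factual`` and
    ``prop_illusory`` in percent.  Under ``aoi_only`` the two add to 100;
    under ``all_samples`` the remainder went elsewhere.  Trials contributing
    no denominator samples to a window are excluded (count logged).
    """
    if denominator not in ("aoi_only", "all_samples"):
        raise ValueError("denominator must be 'aoi_only' or 'all_samples'")
    spec = spec or WindowSpec()
    df = role_df.copy()
    df["window"] = assign_window(df["t_ms"].to_numpy(), spec)
    keys = ["participant_id", "trial_id", "window"]
    extra = [c for c in ("condition", "item_id", "language") if c in df.columns]
    counts = (
        df.pivot_table(index=keys + extra, columns="role", aggfunc="size", fill_value=0)
        .reindex(columns=["factual", "illusory", "elsewhere"], fill_value=0)
        .reset_index()
    )
    denom = counts["factual"] + counts["illusory"]
    if denominator == "all_samples":
        denom = denom + counts["elsewhere"]
    empty = denom == 0
    if empty.any():
        logger.info("excluding %d trial-window cells with no denominator samples", int(empty.sum()))
        counts = counts.loc[~empty]
        denom = denom.loc[~empty]
    counts = counts.copy()
    counts["prop_factual"] = 100.0 * counts["factual"] / denom
    counts["prop_illusory"] = 100.0 * counts["illusory"] / denom
    counts["n_samples"] = denom
    return counts.drop(columns=["factual", "illusory", "elsewhere"]).reset_index(drop=True)
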