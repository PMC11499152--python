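"""Reading, writing and AOI role assignment for gaze-sample datasets.

Coordinates follow the web convention: origin at the top-left of the screen,
y increasing downward, units in pixels.  Areas of interest (AOIs) are the two
picture rectangles; during the blank anticipation window they are the
*remembered* rectangles at identical coordinates, which is the defining
property of the blank-screen paradigm.  Rectangle membership is half-open,
``[x0, x0+w) x [y0, y0+h)``, so no point can belong to two touching
rectangles.

Samples are used directly as looks; no fixation-event parsing (dispersion or
velocity filtering) is applied.  This is a documented simplification: the
downstream statistics are proportions of looks, not fixation events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "AOILayout",
    "SchemaError",
    "default_layout",
    "assign_roles",
    "read_dataset",
    "write_dataset",
]

CONDITIONS = ("positive", "negative", "nobody", "filler")
SIDES = ("left", "right")

TRIAL_COLUMNS = ("participant_id", "trial_id", "item_id", "condition", "factual_side")
SAMPLE_COLUMNS = ("participant_id", "trial_id", "t_ms", "x", "y")


class SchemaError(ValueError):
    """A required column is missing or a value fails validation."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with half-open membership."""

    x0: float
    y0: float
    w: float
    h: float

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.w)
            & (y >= self.y0)
            & (y < self.y0 + self.h)
        )

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x0 + other.w
            and other.x0 < self.x0 + self.w
            and self.y0 < other.y0 + other.h
            and other.y0 < self.y0 + self.h
        )


@dataclass(frozen=True)
class AOILayout:
    """Screen geometry: two lateral picture rectangles on a known screen.

    Picture placement is experiment-specific, so the layout is a required
    input for real data; :func:`default_layout` provides the geometry used by
    the synthetic generator (300x300 px pictures on a 1280x720 screen).
    """

    screen_w: float
    screen_h: float
    left: Rect
    right: Rect

    def __post_init__(self):
        if self.left.overlaps(self.right):
            raise ValueError("AOI rectangles must not overlap")
        if self.left.x0 > self.right.x0:
            raise ValueError("left rectangle must sit left of the right rectangle")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AOILayout":
        return cls(
            screen_w=float(d["screen_w"]),
            screen_h=float(d["screen_h"]),
            left=Rect(*(float(v) for v in d["left_rect"])),
            right=Rect(*(float(v) for v in d["right_rect"])),
        )

    @classmethod
    def from_yaml(cls, path) -> "AOILayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "screen_w": self.screen_w,
            "screen_h": self.screen_h,
            "left_rect": [self.left.x0, self.left.y0, self.left.w, self.left.h],
            "right_rect": [self.right.x0, self.right.y0, self.right.w, self.right.h],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def padded(self, pad: float) -> "AOILayout":
        """Layout with both rectangles grown by ``pad`` px on every side."""

        def grow(r: Rect) -> Rect:
            return Rect(r.x0 - pad, r.y0 - pad, r.w + 2 * pad, r.h + 2 * pad)

        return AOILayout(self.screen_w, self.screen_h, grow(self.left), grow(self.right))


def default_layout() -> AOILayout:
    """300x300 px pictures placed symmetrically on a 1280x720 screen."""
    return AOILayout(
        screen_w=1280,
        screen_h=720,
        left=Rect(140, 210, 300, 300),
        right=Rect(840, 210, 300, 300),
    )


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def assign_roles(
    samples: pd.DataFrame,
    trials: pd.DataFrame,
    layout: AOILayout,
) -> pd.DataFrame:
    """Label each gaze sample factual / illusory / elsewhere.

    A sample inside the left rectangle is ``factual`` when the trial's
    factual picture was on the left, ``illusory`` otherwise; symmetrically
    for the right rectangle; everything else (including samples on a
    rectangle's right/bottom edge, by the half-open convention) is
    ``elsewhere``.  Trial metadata (condition, item, factual side) is carried
    along so downstream stages can group by them.
    """
    _require_columns(samples, SAMPLE_COLUMNS, "sample")
    _require_columns(trials, TRIAL_COLUMNS, "trial")
    keep = [c for c in trials.columns if c not in ("x", "y", "t_ms")]
    out = samples.merge(trials[keep], on=["participant_id", "trial_id"], how="inner", validate="many_to_one")
    if len(out) != len(samples):
        logger.warning(
            "%d samples had no matching trial and were dropped", len(samples) - len(out)
        )
    in_left = layout.left.contains(out["x"], out["y"])
    in_right = layout.right.contains(out["x"], out["y"])
    fact_left = (out["factual_side"] == "left").to_numpy()
    role = np.full(len(out), "elsewhere", dtype=object)
    role[in_left & fact_left] = "factual"
    role[in_left & ~fact_left] = "illusory"
    role[in_right & ~fact_left] = "factual"
    role[in_right & fact_left] = "illusory"
    out = out.copy()
    out["role"] = role
    return out


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    _require_columns(trials, TRIAL_COLUMNS, "trial")
    bad = ~trials["condition"].isin(CONDITIONS)
    if bad.any():
        first = trials.loc[bad, "condition"].iloc[0]
        raise SchemaError(f"unknown condition label {first!r}; expected one of {CONDITIONS}")
    nonfiller = trials["condition"] != "filler"
    bad_side = nonfiller & ~trials["factual_side"].isin(SIDES)
    if bad_side.any():
        raise SchemaError("factual_side must be 'left' or 'right' for non-filler trials")
    if "response_correct" in trials.columns:
        trials = trials.copy()
        trials["response_correct"] = trials["response_correct"].astype(bool)
    if "audio_duration_ms" in trials.columns:
        dur = pd.to_numeric(trials["audio_duration_ms"], errors="coerce")
        out_of_range = nonfiller & ~dur.between(2500, 3000)
        if out_of_range.any():
            logger.warning(
                "%d trials have audio_duration_ms outside [2500, 3000]",
                int(out_of_range.sum()),
            )
    return trials


def _validate_samples(samples: pd.DataFrame, source: str = "samples") -> pd.DataFrame:
    _require_columns(samples, SAMPLE_COLUMNS, "sample")
    samples = samples.copy()
    for col in ("t_ms", "x", "y"):
        parsed = pd.to_numeric(samples[col], errors="coerce")
        bad = parsed.isna() & samples[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"unparseable value in column {col!r} of {source}, row {row}: "
                f"{samples[col].iloc[row]!r}"
            )
        samples[col] = parsed
    if (samples["t_ms"] < 0).any():
        raise SchemaError(f"negative timestamps in {source}")
    if not np.isfinite(samples[["x", "y"]].to_numpy(dtype=float)).all():
        raise SchemaError(f"non-finite gaze coordinates in {source}")
    return samples


def read_dataset(
    trials_path,
    samples_path,
    participants_path=None,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
):
    """Read delimiter-separated trial and gaze-sample tables, with validation.

    ``column_map`` maps *external* column names to the canonical ones
    (e.g. ``{"subject": "participant_id", "time": "t_ms"}``) so logs from
    other experiment software can be ingested without editing files.
    """
    trials = pd.read_csv(trials_path, sep=sep)
    samples = pd.read_csv(samples_path, sep=sep)
    if column_map:
        trials = trials.rename(columns=column_map)
        samples = samples.rename(columns=column_map)
    trials = _validate_trials(trials)
    samples = _validate_samples(samples, source=str(samples_path))
    logger.info("read %d trials, %d gaze samples", len(trials), len(samples))
    out = (trials, samples)
    if participants_path is not None:
        participants = pd.read_csv(participants_path, sep=sep)
        _require_columns(participants, ("participant_id",), "participant")
        out = (trials, samples, participants)
    return out


def write_dataset(outdir, trials, samples, participants=None, sep: str = ",") -> dict:
    """Write the dataset tables as CSV; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("trials", trials), ("samples", samples), ("participants", participants)):
        if df is None:
            continue
        path = outdir / f"{name}.csv"
        df.to_csv(path, sep=sep, index=False)
        paths[name] = path
    return paths
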