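"""Generative model for blank-screen visual-world datasets with known onsets.

The generator emulates the design of a webcam visual-world study of negation:
each trial shows two lateral pictures (a *factual* picture matching the
sentence meaning and an *illusory* competitor) for a preview period, blanks
the screen while a spoken sentence plays (the anticipation window), then
restores the pictures until a button press (the integration window).
Gaze samples are emitted at webcam rate as screen coordinates; looks to the
remembered picture locations carry the experimental signal.

The key generative quantity is the per-condition *true divergence onset*
``tau``: before ``tau`` the probability of looking at either picture location
is at baseline (and exactly equal during preview); from ``tau`` the
probability of looking at the factual location rises along a logistic-shaped
ramp toward an asymptote while the illusory probability declines
complementarily.  ``tau`` is therefore, by construction, the earliest moment
at which looks to the factual exceed looks to the illusory -- the generative
analogue of the divergence point the bootstrap procedure estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "generate_dataset", "role_probabilities", "RAMP_SLOPE_600MS"]

#: Logistic rate (per ms) whose half-ramp rises from 10% to 90% in ~600 ms.
#: For r(t) = 2/(1+exp(-k*(t-tau))) - 1 the 10% and 90% crossings sit at
#: ln(11/9)/k and ln(19)/k after tau, a span of ~2.7438/k.
RAMP_SLOPE_600MS = float(np.log(19.0) - np.log(11.0 / 9.0)) / 600.0


def _default_onsets() -> dict[str, float]:
    return {"positive": 4600.0, "nobody": 5900.0, "negative": 6300.0}


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults mirror the study design: 32 participants, three sentence
    conditions (affirmative control ``positive``, sentential negation
    ``negative``, negative-concord ``nobody``), 20 items per condition, an
    8,000 ms trial with preview 0-4,000 ms, a 3,000 ms audio over a blank
    screen, pictures restored at 7,000 ms, and button-press accuracy near
    ceiling.  Proficiency scores are bounded-normal to match an
    upper-intermediate placement-test profile (mean 43 of 50, range 36-47).

    Parameters
    ----------
    true_onset_ms : mapping of condition -> ms
        Ground-truth divergence onset per condition.
    ramp_slope : float
        Logistic rate (per ms) of the fixation ramp.  The default gives a
        10-90% rise of ~600 ms.
    asymptote : float
        Probability of a factual look once the ramp has completed.
    baseline_p_factual, baseline_p_illusory : float
        Pre-onset look probabilities for the two picture locations; the
        remainder is "elsewhere" (the blank background).
    participant_onset_sd_ms, item_onset_sd_ms : float
        SDs of additive Gaussian onset heterogeneity, truncated to the trial.
    proficiency_coupling : float
        If nonzero, per-participant asymptotes deviate by
        ``coupling * z_p`` where ``z_p`` is the same standard-normal effect
        that drives the participant's proficiency score, so proficiency and
        anticipatory looking correlate.
    dropout_rate : float
        Optional uniform per-sample track-loss probability (no claim is made
        that any particular rate is faithful to webcam data; default 0).
    """

    n_participants: int = 32
    n_items_per_condition: int = 20
    conditions: Sequence[str] = ("positive", "nobody", "negative")
    true_onset_ms: Mapping[str, float] = field(default_factory=_default_onsets)
    ramp_slope: float = RAMP_SLOPE_600MS
    asymptote: float = 0.75
    baseline_p_factual: float = 0.40
    baseline_p_illusory: float = 0.40
    participant_onset_sd_ms: float = 40.0
    item_onset_sd_ms: float = 25.0
    sample_period_ms: float = 33.0
    trial_duration_ms: float = 8000.0
    preview_end_ms: float = 4000.0
    audio_duration_ms: float = 3000.0
    accuracy_p: float = 0.998
    proficiency_mean: float = 43.0
    proficiency_sd: float = 2.5
    proficiency_min: float = 36.0
    proficiency_max: float = 47.0
    proficiency_coupling: float = 0.0
    dropout_rate: float = 0.0
    language: str = "L1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_items_per_condition <= 0:
            raise ValueError("participant and item counts must be positive")
        if len(self.conditions) == 0:
            raise ValueError("at least one condition is required")
        for name, p in [
            ("asymptote", self.asymptote),
            ("baseline_p_factual", self.baseline_p_factual),
            ("baseline_p_illusory", self.baseline_p_illusory),
            ("accuracy_p", self.accuracy_p),
            ("dropout_rate", self.dropout_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.asymptote <= 0.0:
            raise ValueError("asymptote must lie in (0, 1]")
        if self.baseline_p_factual + self.baseline_p_illusory > 1.0:
            raise ValueError("baseline look probabilities must sum to at most 1")
        for cond in self.conditions:
            if cond not in self.true_onset_ms:
                raise ValueError(f"true_onset_ms missing condition {cond!r}")
            tau = self.true_onset_ms[cond]
            if not 0.0 <= tau <= self.trial_duration_ms:
                raise ValueError(f"onset for {cond!r} outside [0, trial_duration_ms]")
        if self.sample_period_ms <= 0 or self.trial_duration_ms <= 0:
            raise ValueError("sample period and trial duration must be positive")
        if self.ramp_slope < 0:
            raise ValueError("ramp_slope must be nonnegative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["true_onset_ms"] = dict(self.true_onset_ms)
        return d


def _ramp(t: np.ndarray, tau: np.ndarray, slope: float) -> np.ndarray:
    """Half-logistic ramp completion: 0 before ``tau``, -> 1 afterwards.

    The upper half of a logistic anchored at ``tau``; with the default slope
    the 10-90% rise spans ~600 ms.  Anchoring at zero (rather than centring
    the logistic on ``tau``) keeps the pre-onset period signal-free, so
    ``tau`` is exactly the first moment of factual preference.
    """
    dt = t - tau
    r = 2.0 / (1.0 + np.exp(-slope * np.clip(dt, 0.0, None))) - 1.0
    return np.where(dt < 0.0, 0.0, r)


def role_probabilities(
    config: SimulationConfig,
    tau_ms: float | np.ndarray,
    t_ms: np.ndarray,
    asymptote: float | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample probabilities of (factual, illusory, elsewhere) looks.

    During preview the two picture locations are equally likely; from the
    anticipation window on, P(factual) climbs from baseline toward the
    asymptote along the ramp while P(illusory) declines complementarily
    (proportionally to the realised fraction of the factual gain), and the
    remainder goes to the blank background.  A flat ramp
    (``asymptote == baseline_p_factual``) leaves every probability at
    baseline, i.e. carries no divergence signal.
    """
    a = config.asymptote if asymptote is None else asymptote
    b_f = config.baseline_p_factual
    b_i = config.baseline_p_illusory
    t = np.asarray(t_ms, dtype=float)
    tau = np.asarray(tau_ms, dtype=float)
    gain_span = np.asarray(a, dtype=float) - b_f
    r = _ramp(t, tau, config.ramp_slope)
    completion = np.where(gain_span > 0.0, r, 0.0)
    p_f = b_f + gain_span * completion
    p_i = b_i * (1.0 - completion)
    preview = t < config.preview_end_ms
    p_equal = 0.5 * (b_f + b_i)
    p_f = np.where(preview, p_equal, p_f)
    p_i = np.where(preview, p_equal, p_i)
    p_else = 1.0 - p_f - p_i
    return p_f, p_i, p_else


def generate_dataset(config: SimulationConfig, layout=None):
    """Simulate one language group's dataset.

    Returns
    -------
    trials : DataFrame
        One row per participant x condition x item with the factual side
        (counterbalanced left/right), the button response, and the trial's
        realised ground-truth onset (``true_onset_ms``).
    samples : DataFrame
        Gaze samples (participant_id, trial_id, t_ms, x, y) at
        ``sample_period_ms`` resolution over the whole trial.
    participants : DataFrame
        Proficiency scores and the latent per-participant effects.
    """
    from gaze_dpa.gaze_io import default_layout

    config.validate()
    if layout is None:
        layout = default_layout()
    rng = np.random.default_rng(config.seed)

    n_p = config.n_participants
    n_i = config.n_items_per_condition
    conditions = list(config.conditions)

    # Shared participant effect drives proficiency and (optionally) asymptote.
    z_p = rng.standard_normal(n_p)
    proficiency = np.clip(
        config.proficiency_mean + config.proficiency_sd * z_p,
        config.proficiency_min,
        config.proficiency_max,
    )
    asym_p = np.clip(config.asymptote + config.proficiency_coupling * z_p, 0.0, 0.98)
    offset_p = rng.normal(0.0, config.participant_onset_sd_ms, n_p)
    offset_i = rng.normal(0.0, config.item_onset_sd_ms, n_i)

    participant_ids = np.array([f"P{k + 1:02d}" for k in range(n_p)])
    participants = pd.DataFrame(
        {
            "participant_id": participant_ids,
            "language": config.language,
            "proficiency": np.round(proficiency).astype(int),
            "onset_offset_ms": offset_p,
            "asymptote": asym_p,
        }
    )

    # Trial grid: participant x condition x item.
    p_idx, c_idx, i_idx = np.meshgrid(
        np.arange(n_p), np.arange(len(conditions)), np.arange(n_i), indexing="ij"
    )
    p_idx, c_idx, i_idx = p_idx.ravel(), c_idx.ravel(), i_idx.ravel()
    n_trials = p_idx.size
    tau_cond = np.array([config.true_onset_ms[c] for c in conditions])
    tau_trial = np.clip(
        tau_cond[c_idx] + offset_p[p_idx] + offset_i[i_idx],
        0.0,
        config.trial_duration_ms,
    )
    factual_left = (p_idx + i_idx) % 2 == 0
    correct = rng.random(n_trials) < config.accuracy_p
    factual_side = np.where(factual_left, "left", "right")
    other_side = np.where(factual_left, "right", "left")
    response_side = np.where(correct, factual_side, other_side)
    rt = np.clip(rng.normal(900.0, 200.0, n_trials), 250.0, None)

    trials = pd.DataFrame(
        {
            "participant_id": participant_ids[p_idx],
            "trial_id": [f"T{k + 1:04d}" for k in range(n_trials)],
            "item_id": [f"I{j + 1:02d}" for j in i_idx],
            "condition": np.array(conditions)[c_idx],
            "language": config.language,
            "factual_side": factual_side,
            "audio_onset_ms": config.preview_end_ms,
            "audio_duration_ms": config.audio_duration_ms,
            "response_side": response_side,
            "response_correct": correct,
            "rt_ms": np.round(rt, 1),
            "true_onset_ms": tau_trial,
        }
    )

    # Gaze samples: draw a role per sample, then place coordinates inside the
    # matching AOI rectangle (or in the central background strip).
    t_grid = np.arange(0.0, config.trial_duration_ms, config.sample_period_ms)
    n_s = t_grid.size
    p_f, p_i, _ = role_probabilities(
        config, tau_trial[:, None], t_grid[None, :], asymptote=asym_p[p_idx, None]
    )
    u = rng.random((n_trials, n_s))
    role_code = np.where(u < p_f, 0, np.where(u < p_f + p_i, 1, 2))  # 0=factual 1=illusory 2=elsewhere

    left, right = layout.left, layout.right
    on_left = (role_code == 0) == factual_left[:, None]  # factual role on left side
    in_aoi = role_code < 2
    rect_x0 = np.where(on_left, left.x0, right.x0)
    rect_y0 = np.where(on_left, left.y0, right.y0)
    rect_w = np.where(on_left, left.w, right.w)
    rect_h = np.where(on_left, left.h, right.h)
    jx = rng.random((n_trials, n_s))
    jy = rng.random((n_trials, n_s))
    # Background strip between the two rectangles (outside both AOIs).
    strip_x0 = left.x0 + left.w
    strip_w = right.x0 - strip_x0
    x = np.where(in_aoi, rect_x0 + jx * rect_w, strip_x0 + jx * strip_w)
    y = np.where(in_aoi, rect_y0 + jy * rect_h, jy * layout.screen_h)

    samples = pd.DataFrame(
        {
            "participant_id": np.repeat(participant_ids[p_idx], n_s),
            "trial_id": np.repeat(trials["trial_id"].to_numpy(), n_s),
            "t_ms": np.tile(t_grid, n_trials),
            "x": np.round(x.ravel(), 2),
            "y": np.round(y.ravel(), 2),
        }
    )
    if config.dropout_rate > 0.0:
        keep = rng.random(len(samples)) >= config.dropout_rate
        samples = samples.loc[keep].reset_index(drop=True)

    return trials, samples, participants
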