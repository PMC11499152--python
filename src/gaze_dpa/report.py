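"""End-to-end orchestration: simulate/ingest -> bin -> DPA -> stats -> figures.

A single :class:`RunConfig` (usually loaded from YAML) describes either a
simulation block (one or two language groups) or paths to input tables, plus
the window and DPA settings.  :func:`run_pipeline` runs every stage, writes
tidy CSV tables, advisory figures, and a machine-readable JSON manifest, and
is deterministic under a fixed seed: per-condition bootstrap streams are
spawned from the run seed in a fixed order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from gaze_dpa import __version__ as _pkg_version
from gaze_dpa.dpa import (
    BootstrapDistribution,
    DifferenceDistribution,
    DpaConfig,
    DivergencePointAnalysis,
    between_language_difference,
    difference_distribution,
)
from gaze_dpa.gaze_io import AOILayout, assign_roles, default_layout, read_dataset, write_dataset
from gaze_dpa.summary_stats import (
    LmmSpec,
    accuracy_summary,
    fit_fixation_lmm,
    fixation_totals,
    proficiency_correlation,
    window_descriptives,
)
from gaze_dpa.synthetic_data import SimulationConfig, generate_dataset
from gaze_dpa.timecourse import WindowSpec, add_elog, bin_counts, proportions_by_window

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "plot_fixation_curves", "plot_difference_histograms"]

NEGATION_CONDITIONS = ("negative", "nobody")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``simulation`` (a dict of :class:`SimulationConfig`
    overrides, or ``{language_label: overrides}`` for a two-language run)
    and ``inputs`` (paths: ``trials``, ``samples``, optional
    ``participants``, optional ``layout`` YAML) must be given.
    """

    out_dir: str | Path = "gaze_dpa_run"
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None
    windows: WindowSpec = field(default_factory=WindowSpec)
    dpa: DpaConfig = field(default_factory=DpaConfig)
    fit_lmm: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' and 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "windows" in kwargs:
            kwargs["windows"] = WindowSpec(**kwargs["windows"])
        if "dpa" in kwargs:
            dpa_kwargs = dict(kwargs["dpa"])
            for key in ("span", "ci"):
                if key in dpa_kwargs:
                    dpa_kwargs[key] = tuple(dpa_kwargs[key])
            kwargs["dpa"] = DpaConfig(**dpa_kwargs)
        return cls(**kwargs)

    def echo(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "simulation": self.simulation,
            "inputs": {k: str(v) for k, v in self.inputs.items()} if self.inputs else None,
            "windows": dataclasses.asdict(self.windows),
            "dpa": dataclasses.asdict(self.dpa),
            "fit_lmm": self.fit_lmm,
        }
        return d


def _simulation_blocks(sim: dict) -> dict[str, dict]:
    """Normalise the simulation block to {language_label: overrides}."""
    if sim and all(isinstance(v, dict) for v in sim.values()) and all(
        k not in SimulationConfig.__dataclass_fields__ for k in sim
    ):
        return {str(k): dict(v) for k, v in sim.items()}
    return {str(sim.get("language", "L1")): dict(sim)}


def _datasets(config: RunConfig):
    """Yield (label, trials, samples, participants, layout) per language."""
    out = []
    if config.simulation is not None:
        blocks = _simulation_blocks(config.simulation)
        for i, (label, overrides) in enumerate(sorted(blocks.items())):
            overrides = dict(overrides)
            overrides.setdefault("language", label)
            overrides.setdefault("seed", config.seed + i)
            sim_cfg = SimulationConfig(**overrides)
            trials, samples, participants = generate_dataset(sim_cfg)
            out.append((label, trials, samples, participants, default_layout(), sim_cfg))
    else:
        paths = config.inputs
        layout = (
            AOILayout.from_yaml(paths["layout"]) if "layout" in paths else default_layout()
        )
        tables = read_dataset(
            paths["trials"], paths["samples"], paths.get("participants")
        )
        trials, samples = tables[0], tables[1]
        participants = tables[2] if len(tables) == 3 else None
        label = trials["language"].iloc[0] if "language" in trials.columns else "L1"
        out.append((str(label), trials, samples, participants, layout, None))
    return out


def _analysis_conditions(trials: pd.DataFrame) -> list[str]:
    return [c for c in trials["condition"].unique() if c != "filler"]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory results (per-language bootstrap
    distributions, difference distributions, descriptive tables) and the
    paths written.  Stage failures abort with a stage-named error; outputs
    written before the failure are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(config.seed)
    results: dict = {"languages": {}, "paths": {}, "between_language": {}}
    manifest: dict = {
        "package": "gaze-dpa",
        "version": _pkg_version,
        "seed": config.seed,
        "config": config.echo(),
        "outputs": [],
    }

    def _write(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)
        results["paths"][name] = path

    datasets = _datasets(config)
    boot_by_language: dict[str, dict[str, BootstrapDistribution]] = {}

    for label, trials, samples, participants, layout, sim_cfg in datasets:
        stage = f"{label}:ingest"
        try:
            exp_trials = trials[trials["condition"] != "filler"]
            role_df = assign_roles(samples, exp_trials, layout)
            if sim_cfg is not None:
                write_dataset(out_dir / f"dataset_{label}", trials, samples, participants)
                with open(out_dir / f"dataset_{label}" / "config.yaml", "w") as fh:
                    yaml.safe_dump(sim_cfg.to_dict(), fh)

            stage = f"{label}:timecourse"
            props = proportions_by_window(role_df, config.windows, config.dpa.denominator)
            _write(props, f"proportions_{label}.csv")
            desc = window_descriptives(props)
            _write(desc, f"descriptives_{label}.csv")
            binned = bin_counts(
                role_df,
                bin_width_ms=config.dpa.bin_width_ms,
                span=config.dpa.span,
                by=["participant_id", "condition"],
            )
            binned = add_elog(binned, config.dpa.denominator)
            _write(binned, f"binned_{label}.csv")

            stage = f"{label}:dpa"
            boots: dict[str, BootstrapDistribution] = {}
            conditions = sorted(_analysis_conditions(trials))
            for cond in conditions:
                child = np.random.default_rng(seed_root.spawn(1)[0])
                est = DivergencePointAnalysis(
                    bin_width_ms=config.dpa.bin_width_ms,
                    span=config.dpa.span,
                    k_consecutive=config.dpa.k_consecutive,
                    alpha=config.dpa.alpha,
                    n_boot=config.dpa.n_boot,
                    ci=config.dpa.ci,
                    one_sided=config.dpa.one_sided,
                    resample_unit=config.dpa.resample_unit,
                    denominator=config.dpa.denominator,
                    random_state=child,
                )
                est.fit(role_df, condition=cond)
                boots[cond] = est.bootstrap_
                est.bin_results_.assign(condition=cond).to_csv(
                    out_dir / f"bin_tests_{label}_{cond}.csv", index=False
                )
                manifest["outputs"].append(f"bin_tests_{label}_{cond}.csv")
            boot_by_language[label] = boots
            dpa_summary = pd.DataFrame(
                [
                    {
                        "language": label,
                        "condition": cond,
                        "point_onset_ms": b.point_estimate.onset_ms,
                        "mean_ms": b.mean_ms,
                        "ci_low_ms": b.ci_low_ms,
                        "ci_high_ms": b.ci_high_ms,
                        "n_boot": b.n_boot,
                        "n_missing": b.n_missing,
                    }
                    for cond, b in boots.items()
                ]
            )
            _write(dpa_summary, f"dpa_summary_{label}.csv")
            onsets_long = pd.DataFrame(
                {cond: b.onsets for cond, b in boots.items()}
            )
            _write(onsets_long, f"bootstrap_onsets_{label}.csv")

            diffs = {}
            for a, b in combinations(sorted(boots), 2):
                dd = difference_distribution(
                    boots[a], boots[b], config.dpa, label=f"{a} - {b}"
                )
                diffs[f"{a} - {b}"] = dd
            diff_table = pd.DataFrame(
                [
                    {
                        "language": label,
                        "contrast": name,
                        "mean_ms": d.mean_ms,
                        "ci_low_ms": d.ci_low_ms,
                        "ci_high_ms": d.ci_high_ms,
                        "excludes_zero": d.excludes_zero,
                        "n_pairs": len(d.diffs),
                        "n_dropped_pairs": d.n_dropped_pairs,
                    }
                    for name, d in diffs.items()
                ]
            )
            _write(diff_table, f"differences_{label}.csv")

            stage = f"{label}:summary"
            acc = accuracy_summary(exp_trials)
            _write(acc, f"accuracy_{label}.csv")
            lmm_rows = []
            if config.fit_lmm and sim_cfg is not None:
                for window in ("anticipation", "integration"):
                    totals = fixation_totals(
                        role_df, sim_cfg.sample_period_ms, config.windows, window
                    )
                    res = fit_fixation_lmm(totals, LmmSpec(window=window))
                    fe = res.fixed_effects.assign(
                        window=window, structure=res.structure, language=label
                    )
                    lmm_rows.append(fe)
                _write(pd.concat(lmm_rows, ignore_index=True), f"lmm_{label}.csv")
            if participants is not None and "proficiency" in participants.columns:
                corr_rows = []
                for cond in sorted(_analysis_conditions(trials)):
                    c = proficiency_correlation(participants, props, cond)
                    corr_rows.append(
                        {"language": label, "condition": cond, "r": c.r, "p": c.p, "n": c.n}
                    )
                _write(pd.DataFrame(corr_rows), f"correlations_{label}.csv")

            stage = f"{label}:figures"
            fig_path = out_dir / f"fixation_curves_{label}.png"
            plot_fixation_curves(role_df, config.windows, boots, fig_path)
            manifest["outputs"].append(fig_path.name)
            hist_path = out_dir / f"difference_histograms_{label}.png"
            plot_difference_histograms(diffs, hist_path)
            manifest["outputs"].append(hist_path.name)

            results["languages"][label] = {
                "bootstrap": boots,
                "differences": diffs,
                "descriptives": desc,
                "accuracy": acc,
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if len(boot_by_language) == 2:
        (l1, b1), (l2, b2) = sorted(boot_by_language.items())
        rows = []
        bl: dict[str, DifferenceDistribution] = {}
        for cond in NEGATION_CONDITIONS:
            if cond in b1 and cond in b2:
                dd = between_language_difference(
                    b1[cond], b2[cond], config.dpa, labels=(l1, l2)
                )
                bl[cond] = dd
                rows.append(
                    {
                        "condition": cond,
                        "contrast": f"{l1} - {l2}",
                        "mean_ms": dd.mean_ms,
                        "ci_low_ms": dd.ci_low_ms,
                        "ci_high_ms": dd.ci_high_ms,
                        "excludes_zero": dd.excludes_zero,
                        "n_pairs": len(dd.diffs),
                    }
                )
        if rows:
            _write(pd.DataFrame(rows), "between_language_differences.csv")
            results["between_language"] = bl

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def _curve_table(role_df: pd.DataFrame, bin_width: float = 200.0) -> pd.DataFrame:
    """Mean fixation proportion per condition x role x bin across participants."""
    df = role_df.copy()
    df["bin_start_ms"] = bin_width * np.floor(df["t_ms"] / bin_width)
    counts = (
        df.pivot_table(
            index=["condition", "participant_id", "bin_start_ms"],
            columns="role",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=["factual", "illusory", "elsewhere"], fill_value=0)
        .reset_index()
    )
    denom = counts["factual"] + counts["illusory"]
    counts = counts[denom > 0].copy()
    for role in ("factual", "illusory"):
        counts[f"p_{role}"] = counts[role] / (counts["factual"] + counts["illusory"])
    g = counts.groupby(["condition", "bin_start_ms"])[["p_factual", "p_illusory"]]
    mean = g.mean()
    sem = g.sem()
    out = mean.join(sem, rsuffix="_sem").reset_index()
    return out


def plot_fixation_curves(role_df, windows: WindowSpec, boots, path) -> None:
    """Fixation-proportion curves with 95% CI bands and DP whiskers."""
    table = _curve_table(role_df)
    conditions = sorted(table["condition"].unique())
    fig, axes = plt.subplots(1, len(conditions), figsize=(4.2 * len(conditions), 3.4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, cond in zip(axes, conditions):
        sub = table[table["condition"] == cond]
        t = sub["bin_start_ms"]
        for role, color in (("factual", "tab:blue"), ("illusory", "tab:orange")):
            m = sub[f"p_{role}"]
            s = 1.96 * sub[f"p_{role}_sem"]
            ax.plot(t, m, color=color, label=role)
            ax.fill_between(t, m - s, m + s, color=color, alpha=0.25, linewidth=0)
        for edge in (windows.anticipation_start_ms, windows.integration_start_ms):
            ax.axvline(edge, color="grey", linewidth=0.8, linestyle=":")
        boot = boots.get(cond) if boots else None
        if boot is not None and boot.defined:
            ax.errorbar(
                [boot.mean_ms],
                [0.9],
                xerr=[[boot.mean_ms - boot.ci_low_ms], [boot.ci_high_ms - boot.mean_ms]],
                fmt="o",
                color="black",
                capsize=3,
            )
        ax.set_title(cond)
        ax.set_xlabel("time (ms)")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("fixation proportion")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_difference_histograms(diffs, path) -> None:
    """Histograms of onset-difference distributions with mean, CI and zero line."""
    names = list(diffs)
    if not names:
        return
    fig, axes = plt.subplots(1, len(names), figsize=(4.0 * len(names), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        d = diffs[name]
        if d.diffs.size:
            ax.hist(d.diffs, bins=20, color="tab:grey", edgecolor="white")
            y = ax.get_ylim()[1] * 0.9
            ax.errorbar(
                [d.mean_ms],
                [y],
                xerr=[[d.mean_ms - d.ci_low_ms], [d.ci_high_ms - d.mean_ms]],
                fmt="o",
                color="black",
                capsize=3,
            )
        ax.axvline(0.0, color="black", linestyle=":")
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("onset difference (ms)")
    axes[0].set_ylabel("resamples")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
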