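"""End-to-end analysis: trials -> events -> parameters -> CRP -> SPM -> stats.

The pipeline runs every trial through event detection, parameter
extraction, and CRP normalization; averages CRP curves and parameters per
player; computes the sex-grouped descriptive/ANOVA/correlation block; and
runs the two-sample SPM on per-player mean CRP curves (SPM inference
assumes independent observations, so the player, not the trial, is the
unit). Trials that fail event detection are logged and excluded; the run
aborts if more than ``max_failure_fraction`` of trials fail.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, groupstats, io, kinematics, spm

logger = logging.getLogger("golfswing")


class PipelineAbort(RuntimeError):
    """Too many trials failed event detection; results would be unreliable."""


@dataclass
class PipelineConfig:
    """All knobs of one analysis run; serialized into every output artifact."""

    input_dir: str = "."
    metadata_path: str = "metadata.csv"
    output_dir: str = "results"
    alpha: float = 0.05
    filter_cutoff_hz: float | None = kinematics.DEFAULT_CUTOFF_HZ
    crp_align_strategy: str = "split"
    crp_align_fraction: float = 0.5
    crp_negate: bool = False
    crp_pad_fraction: float = 0.5
    spm_curve_unit: str = "player_mean"
    spm_balance_seed: int | None = None
    spm_two_sided: bool = True
    millimetres: bool = False
    max_failure_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    parameters: list[kinematics.SwingParameters]
    crp_curves: list[coupling.CRPCurve]
    player_means: pd.DataFrame
    stats: dict
    spm_result: spm.SPMResult | None
    failures: list[dict] = field(default_factory=list)
    n_trials: int = 0

    @property
    def parameters_frame(self) -> pd.DataFrame:
        return io._params_frame(self.parameters)


def _analyze_trial(trial: io.TrialRecording, config: PipelineConfig):
    events = kinematics.detect_events(trial, cutoff_hz=config.filter_cutoff_hz)
    angles = kinematics.segment_angles(trial, cutoff_hz=config.filter_cutoff_hz)
    speed, _, _ = kinematics.club_speed_accel(trial,
                                              cutoff_hz=config.filter_cutoff_hz)
    params = kinematics.extract_parameters(
        angles, events, speed,
        participant_id=trial.participant_id, trial_index=trial.trial_index,
    )
    curve = coupling.trial_crp_curve(
        angles, events,
        negate=config.crp_negate,
        pad_fraction=config.crp_pad_fraction,
        align_fraction=config.crp_align_fraction,
        strategy=config.crp_align_strategy,
        participant_id=trial.participant_id, trial_index=trial.trial_index,
    )
    return events, params, curve


def run_pipeline(
    config: PipelineConfig,
    cohort: io.Cohort | None = None,
    *,
    write: bool = True,
) -> PipelineResult:
    """Run the full analysis over a cohort; optionally write all artifacts."""
    if cohort is None:
        cohort = io.read_cohort(config.input_dir, config.metadata_path,
                                millimetres=config.millimetres)
    parameters: list[kinematics.SwingParameters] = []
    curves: list[coupling.CRPCurve] = []
    failures: list[dict] = []
    for trial in cohort.trials:
        try:
            events, params, curve = _analyze_trial(trial, config)
        except (ValueError, RuntimeError) as exc:
            logger.warning("trial %s_%s excluded: %s",
                           trial.participant_id, trial.trial_index, exc)
            failures.append({
                "participant_id": trial.participant_id,
                "trial_index": trial.trial_index,
                "error": str(exc),
            })
            continue
        logger.info(
            "trial %s_%s: start=%d top=%d impact=%d",
            trial.participant_id, trial.trial_index,
            events.start_frame, events.top_frame, events.impact_frame,
        )
        parameters.append(params)
        curves.append(curve)
    n_total = len(cohort.trials)
    if n_total and len(failures) / n_total > config.max_failure_fraction:
        raise PipelineAbort(
            f"{len(failures)}/{n_total} trials failed event detection "
            f"(limit {config.max_failure_fraction:.0%}); aborting"
        )
    if not parameters:
        raise PipelineAbort("no analyzable trials")

    params_df = io._params_frame(parameters)
    means = groupstats.player_means(params_df)
    sex_by_player = {p.participant_id: p.sex for p in cohort.participants}
    stats = groupstats.cohort_statistics(means, sex_by_player)
    stats["excluded_trials"] = failures
    stats["n_trials_analyzed"] = len(parameters)
    stats["config"] = config.to_dict()

    spm_result = None
    mean_curves: dict[str, np.ndarray] = {}
    for pid in means["participant_id"]:
        own = [c.values for c in curves if c.participant_id == pid]
        if own:
            mean_curves[pid] = np.mean(own, axis=0)
    group_f = [mean_curves[p] for p in mean_curves if sex_by_player[p] == "F"]
    group_m = [mean_curves[p] for p in mean_curves if sex_by_player[p] == "M"]
    if len(group_f) >= 2 and len(group_m) >= 2:
        spm_result = spm.spm_ttest2(
            group_f, group_m,
            alpha=config.alpha,
            balance_seed=config.spm_balance_seed,
            two_sided=config.spm_two_sided,
        )
        spm_result.metadata.update({
            "curve_unit": config.spm_curve_unit,
            "group_a": "F",
            "group_b": "M",
            "align_node": curves[0].align_node if curves else None,
            "config": config.to_dict(),
        })
    else:
        logger.warning("fewer than 2 players per sex: SPM not computed")

    result = PipelineResult(
        config=config,
        parameters=parameters,
        crp_curves=curves,
        player_means=means,
        stats=stats,
        spm_result=spm_result,
        failures=failures,
        n_trials=n_total,
    )
    if write:
        out_dir = Path(config.output_dir)
        io.write_results(
            parameters, curves,
            spm_result if spm_result is not None else {"not_computed": True},
            stats, out_dir,
        )
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return result


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def report(result: PipelineResult) -> str:
    """Human-readable markdown summary of one pipeline run."""
    lines = ["# Golf swing analysis report", ""]
    lines.append(f"Trials analyzed: {result.stats['n_trials_analyzed']} "
                 f"of {result.n_trials} "
                 f"({len(result.failures)} excluded).")
    lines += ["", "## Descriptive statistics (per-player means)", "",
              "| Parameter | Sex | n | Mean | SD |",
              "|---|---|---|---|---|"]
    for param, records in result.stats["descriptives"].items():
        for rec in records:
            lines.append(
                f"| {param} | {rec['group']} | {rec['n']} | "
                f"{_fmt(rec['mean'])} | {_fmt(rec['sd'])} |"
            )
    lines += ["", "## Sex effect (one-way ANOVA)", "",
              "| Parameter | F | p | eta_p^2 | df |",
              "|---|---|---|---|---|"]
    for param, a in result.stats["anova"].items():
        lines.append(
            f"| {param} | {_fmt(a['F'])} | {_fmt(a['p'], 4)} | "
            f"{_fmt(a['eta_p2'], 3)} | ({a['df1']}, {a['df2']}) |"
        )
    lines += ["", "## Correlation with club velocity (per sex)", "",
              "| Sex | Parameter | r | p | n |", "|---|---|---|---|---|"]
    for sex, block in result.stats.get("correlations", {}).items():
        for param, c in block.items():
            lines.append(f"| {sex} | {param} | {_fmt(c['r'], 3)} | "
                         f"{_fmt(c['p'], 3)} | {c['n']} |")
    lines += ["", "## Pelvis-thorax coupling (SPM)", ""]
    if result.spm_result is None:
        lines.append("SPM: not computed (needs >= 2 players per sex).")
    else:
        s = result.spm_result
        lines.append(
            f"Two-sample SPM on per-player mean CRP curves "
            f"(n = {s.n1} F vs {s.n2} M, df = {s.df}): "
            f"critical |t*| = {_fmt(s.threshold, 3)} at alpha = {s.alpha}, "
            f"residual FWHM = {_fmt(s.fwhm, 1)} nodes."
        )
        align = s.metadata.get("align_node")
        if s.clusters:
            lines.append("")
            lines.append("Suprathreshold clusters (node ranges; the align node "
                         f"{align} marks maximal pelvis rotation):")
            for a, b in s.clusters:
                side = "backswing" if align is not None and a < align else "downswing"
                lines.append(f"- nodes {a}-{b} ({side} side)")
        else:
            lines.append("No suprathreshold clusters.")
        lines += ["", "```", _ascii_spm(s), "```"]
    return "\n".join(lines) + "\n"


def _ascii_spm(s: spm.SPMResult, width: int = 80, height: int = 11) -> str:
    """Tiny ASCII rendering of the t trajectory against +-t*."""
    t = np.asarray(s.t_trajectory)
    idx = np.linspace(0, len(t) - 1, width).round().astype(int)
    tt = t[idx]
    lim = max(np.abs(tt).max(), s.threshold) * 1.1
    rows = []
    for r in range(height):
        level = lim - 2 * lim * r / (height - 1)
        row = []
        for v in tt:
            if abs(v - level) <= lim / (height - 1):
                row.append("*")
            elif abs(abs(level) - s.threshold) <= lim / (height - 1) / 2:
                row.append("-")
            elif abs(level) <= lim / (height - 1) / 2:
                row.append(".")
            else:
                row.append(" ")
        rows.append("".join(row))
    rows.append(f"t(t) trajectory; '-' = +/-t* = {s.threshold:.2f}")
    return "\n".join(rows)
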