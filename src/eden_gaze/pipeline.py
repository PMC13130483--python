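"""Seed-reproducible orchestration: simulate -> depth-rois -> fit-hmm ->
metrics -> compare -> report.

Every stage reads and writes plain-text artifacts inside one output
directory, so any intermediate can be deleted and regenerated identically
from its upstream files. A run manifest records the configuration
snapshot, package version, SHA-256 hashes of every stage output, and wall
timestamps; with a fixed seed, two runs produce identical output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .depth_rois import read_roi_sets, rois_for_stimuli, write_roi_sets
from .errors import EdenGazeError, PipelineDependencyError
from .group_stats import (
    assign_groups,
    cohort_assignments,
    group_timecourse_contrast,
    normalize_ratings,
    paired_summary_table,
)
from .hmm import fit_model, read_model, write_model
from .io import (
    filter_valid_trials,
    normalize_coordinates,
    read_gaze_csv,
    read_localization_csv,
    read_ratings_csv,
    read_stimulus_meta,
    write_gaze_csv,
    write_localization_csv,
    write_ratings_csv,
    write_stimulus_meta,
)
from .synthetic import (
    SynthConfig,
    ground_truth_to_json_dict,
    simulate_localization,
    simulate_ratings,
    simulate_trials,
)
from .window_metrics import metrics_table

ALL_STAGES = ("simulate", "depth-rois", "fit-hmm", "metrics", "compare", "report")

# files each stage needs (relative to out_dir) and which stage makes them
_STAGE_INPUTS: dict[str, dict[str, str]] = {
    "simulate": {},
    "depth-rois": {"localization.csv": "simulate", "stimuli.yaml": "simulate"},
    "fit-hmm": {"gaze.csv": "simulate", "stimuli.yaml": "simulate"},
    "metrics": {"gaze.csv": "simulate", "stimuli.yaml": "simulate",
                "depth_rois.json": "depth-rois", "models": "fit-hmm"},
    "compare": {"metrics.csv": "metrics", "ground_truth.json": "simulate"},
    "report": {"comparisons_windows.csv": "compare"},
}


@dataclass
class PipelineConfig:
    """Full run configuration; YAML-loadable via :meth:`from_yaml`."""

    out_dir: str = "eden_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synth: SynthConfig = field(default_factory=SynthConfig)
    max_gap_ms: float = 2000.0
    roi_threshold: int | None = None
    roi_connectivity: int = 8
    K: int = 14
    n_restarts: int = 10
    hmm_max_iter: int = 500
    hmm_tol: float = 1e-6
    bin_s: float = 3.0
    duration_s: float = 30.0
    grouping: str = "cohort"         # "cohort" (ground truth) or "ratings"
    design: str = "between_pooled"
    metric: str = "dwell_ratio"
    divergence_threshold: float = 0.2

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise EdenGazeError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        synth = data.pop("synth", {})
        cfg = cls(**data)
        if synth:
            cfg.synth = SynthConfig(**{**dataclasses.asdict(cfg.synth), **synth})
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["depth_state_ids"] = list(self.synth.depth_state_ids)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    hashes: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_outputs(out_dir: Path, rels: list[str], hashes: dict[str, str]) -> None:
    for rel in rels:
        p = out_dir / rel
        if p.is_dir():
            for f in sorted(p.iterdir()):
                hashes[f"{rel}/{f.name}"] = _sha256(f)
        elif p.exists():
            hashes[rel] = _sha256(p)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    A stage requested without its inputs (file missing and producing stage
    not enabled) raises :class:`PipelineDependencyError` naming the
    missing stage. On a stage failure, that stage's partial outputs are
    removed before the error propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__)

    # dependency check up front
    for stage in config.stages:
        for rel, producer in _STAGE_INPUTS[stage].items():
            if producer not in config.stages and not (out_dir / rel).exists():
                raise PipelineDependencyError(
                    f"stage '{stage}' needs '{rel}' but stage '{producer}' "
                    "is not enabled and the file is missing"
                )

    stage_outputs = {
        "simulate": ["gaze.csv", "localization.csv", "ratings.csv",
                     "stimuli.yaml", "ground_truth.json"],
        "depth-rois": ["depth_rois.json"],
        "fit-hmm": ["models"],
        "metrics": ["metrics.csv"],
        "compare": ["comparisons_windows.csv", "comparisons.csv"],
        "report": ["report.md", "report_summary.csv"],
    }
    runners = {
        "simulate": _stage_simulate,
        "depth-rois": _stage_depth_rois,
        "fit-hmm": _stage_fit_hmm,
        "metrics": _stage_metrics,
        "compare": _stage_compare,
        "report": _stage_report,
    }
    for stage in config.stages:
        try:
            warns = runners[stage](config, out_dir) or []
            manifest.warnings.extend(f"{stage}: {w}" for w in warns)
        except Exception as exc:
            for rel in stage_outputs[stage]:
                p = out_dir / rel
                if p.is_dir():
                    for f in p.iterdir():
                        f.unlink()
                    p.rmdir()
                elif p.exists():
                    p.unlink()
            raise EdenGazeError(f"stage '{stage}' failed: {exc}") from exc
        manifest.timestamps[stage] = datetime.now(timezone.utc).isoformat()
        _hash_outputs(out_dir, stage_outputs[stage], manifest.hashes)
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out_dir: Path) -> list[str]:
    synth = dataclasses.replace(config.synth, seed=config.seed)
    trials, gt = simulate_trials(synth)
    write_gaze_csv(trials, out_dir / "gaze.csv")
    write_localization_csv(
        simulate_localization(gt, seed=config.seed), out_dir / "localization.csv"
    )
    write_ratings_csv(simulate_ratings(gt, seed=config.seed), out_dir / "ratings.csv")
    write_stimulus_meta(gt.stimulus_meta(), out_dir / "stimuli.yaml")
    (out_dir / "ground_truth.json").write_text(
        json.dumps(ground_truth_to_json_dict(gt), indent=2, sort_keys=True) + "\n"
    )
    return []


def _load_trials(config: PipelineConfig, out_dir: Path):
    meta = read_stimulus_meta(out_dir / "stimuli.yaml")
    trials = read_gaze_csv(out_dir / "gaze.csv", config.synth.rate_hz)
    kept, excluded = filter_valid_trials(trials, config.max_gap_ms)
    kept = [
        normalize_coordinates(tr, meta[tr.stimulus_id]["width_px"],
                              meta[tr.stimulus_id]["height_px"])
        for tr in kept
    ]
    return kept, excluded, meta


def _stage_depth_rois(config: PipelineConfig, out_dir: Path) -> list[str]:
    meta = read_stimulus_meta(out_dir / "stimuli.yaml")
    responses = read_localization_csv(out_dir / "localization.csv")
    roi_sets = rois_for_stimuli(
        responses, meta, threshold=config.roi_threshold,
        connectivity=config.roi_connectivity,
    )
    write_roi_sets(roi_sets, out_dir / "depth_rois.json")
    return [f"{sid}: no depth consensus" for sid, rs in roi_sets.items()
            if rs.no_consensus]


def _stage_fit_hmm(config: PipelineConfig, out_dir: Path) -> list[str]:
    kept, excluded, _ = _load_trials(config, out_dir)
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    warns = [f"excluded trial {tr.participant_id}x{tr.stimulus_id}: {why}"
             for tr, why in excluded]
    by_stim: dict[str, list] = {}
    for tr in kept:
        by_stim.setdefault(tr.stimulus_id, []).append(tr)
    for sid in sorted(by_stim):
        model = fit_model(
            by_stim[sid], K=config.K, n_restarts=config.n_restarts,
            max_iter=config.hmm_max_iter, tol=config.hmm_tol, seed=config.seed,
        )
        write_model(model, models_dir / f"{sid}.json")
        if not model.converged:
            warns.append(f"{sid}: EM did not converge")
        if model.clamp_events:
            warns.append(f"{sid}: {model.clamp_events} covariance clamps fired")
    return warns


def _stage_metrics(config: PipelineConfig, out_dir: Path) -> list[str]:
    kept, _, _ = _load_trials(config, out_dir)
    roi_sets = read_roi_sets(out_dir / "depth_rois.json")
    models = {p.stem: read_model(p) for p in sorted((out_dir / "models").glob("*.json"))}
    table = metrics_table(
        kept, models=models, roi_sets=roi_sets,
        bin_s=config.bin_s, duration_s=config.duration_s,
    )
    table.to_csv(out_dir / "metrics.csv", index=False, float_format="%.10g")
    return []


def _load_assignments(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    gt = json.loads((out_dir / "ground_truth.json").read_text())
    stimuli = sorted(gt["state_means"])
    if config.grouping == "cohort":
        return cohort_assignments(gt["cohort"], stimuli)
    meta = read_stimulus_meta(out_dir / "stimuli.yaml")
    ratings = read_ratings_csv(out_dir / "ratings.csv")
    normalized = normalize_ratings(
        ratings, set_labels={sid: m["set_label"] for sid, m in meta.items()}
    )
    return assign_groups(normalized)


def _stage_compare(config: PipelineConfig, out_dir: Path) -> list[str]:
    metrics = pd.read_csv(out_dir / "metrics.csv",
                          dtype={"participant_id": str, "stimulus_id": str})
    assignments = _load_assignments(config, out_dir)
    windows = group_timecourse_contrast(
        metrics, assignments, metric=config.metric, design=config.design,
        cumulative=True,
    )
    windows.to_csv(out_dir / "comparisons_windows.csv", index=False,
                   float_format="%.10g")
    summary = paired_summary_table(metrics, assignments)
    summary.to_csv(out_dir / "comparisons.csv", index=False, float_format="%.10g")
    return []


def estimate_divergence_onset(
    windows: pd.DataFrame, threshold: float = 0.2
) -> float | None:
    """Earliest cumulative-window end whose effect size exceeds the
    threshold there *and in every later window* (sustained divergence);
    None when no window qualifies."""
    w = windows.dropna(subset=["effect_r"]).sort_values("window_end_s")
    ends = w["window_end_s"].to_numpy()
    r = w["effect_r"].to_numpy()
    for i in range(len(ends)):
        if np.all(r[i:] > threshold):
            return float(ends[i])
    return None


def _stage_report(config: PipelineConfig, out_dir: Path) -> list[str]:
    windows = pd.read_csv(out_dir / "comparisons_windows.csv")
    warns = []
    if windows.empty:
        warns.append("empty comparisons; report is empty")
        onset = None
    else:
        pooled = windows[windows["stimulus_id"].isin(["__pooled__", "__paired__"])]
        pooled = pooled if len(pooled) else windows
        onset = estimate_divergence_onset(pooled, config.divergence_threshold)
    summary_path = out_dir / "comparisons.csv"
    try:
        summary = pd.read_csv(summary_path) if summary_path.exists() else pd.DataFrame()
    except pd.errors.EmptyDataError:
        summary = pd.DataFrame()

    lines = ["# Gaze-dynamics run report", ""]
    lines.append(f"Metric contrasted per window: `{config.metric}` "
                 f"({config.design}, {config.grouping} grouping).")
    lines.append("")
    if onset is not None:
        lines.append(
            f"**Sustained divergence onset:** effect size first exceeds "
            f"{config.divergence_threshold:g} at the 0-{onset:g} s window "
            "and stays above it through the end of viewing."
        )
    else:
        lines.append("**Sustained divergence onset:** none detected "
                     f"(no window holds effect size > {config.divergence_threshold:g} "
                     "through the end of viewing).")
    lines.append("")
    lines.append("## Effect size by cumulative window")
    lines.append("")
    lines.append("| window (s) | n high | n low | effect r | p |")
    lines.append("|---|---|---|---|---|")
    if not windows.empty:
        pooled_sorted = pooled.sort_values("window_end_s")
        for _, row in pooled_sorted.iterrows():
            lines.append(
                f"| 0-{row['window_end_s']:g} | {row['n_high']} | {row['n_low']} "
                f"| {row['effect_r']:.3f} | {row['p']:.3g} |"
            )
    lines.append("")
    if len(summary):
        lines.append("## Paired state-metric summary (windows after 6 s)")
        lines.append("")
        lines.append("| metric | nPaired | median high | median low | diff | p | r_rb |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, row in summary.iterrows():
            lines.append(
                f"| {row['metric']} | {row['nPaired']} | {row['median_high']:.4g} "
                f"| {row['median_low']:.4g} | {row['medianDiff_HminusL']:.4g} "
                f"| {row['p_signrank']:.3g} | {row['r_rankBiserial']:.3f} |"
            )
        lines.append("")
    (out_dir / "report.md").write_text("\n".join(lines))
    if not windows.empty:
        pooled_sorted.loc[:, ["window_end_s", "n_high", "n_low", "effect_r", "p"]].to_csv(
            out_dir / "report_summary.csv", index=False, float_format="%.10g"
        )
    else:
        pd.DataFrame(columns=["window_end_s", "n_high", "n_low", "effect_r", "p"]).to_csv(
            out_dir / "report_summary.csv", index=False
        )
    return warns
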