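"""Config-driven end-to-end runs with manifests.

A run is described by a single declarative JSON/YAML config; unknown keys are
rejected, the resolved config is written beside the outputs, and a manifest
records the tool version, a config hash, input checksums, per-stage counts
and warnings, so a rerun with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .behavior import (ClassifierConfig, TrialRecord, classify_response,
                       escape_metrics, response_rate)
from .stats import CorrelationResult, FisherZResult
from .tracking import TrackingConfig, load_frames, track_video
from .trogo import TectumMeasurement, assay_correlations, assemble_assay, measure_stack

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_behavior_pipeline", "run_trogo_pipeline"]

_BEHAVIOR_KEYS = {"video", "events", "out_dir", "fps", "tracking", "classifier",
                  "smooth_window", "seed"}
_TROGO_KEYS = {"metadata", "stacks_dir", "out_dir", "k_sd", "min_size",
               "exclusion_rule_enabled", "compare_conditions", "seed"}


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_checksums: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


@dataclass
class RunConfig:
    """Validated stage parameters loaded from a JSON/YAML mapping."""

    raw: Dict

    @classmethod
    def load(cls, path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        return cls(raw=raw)

    def validate(self, allowed: set) -> None:
        unknown = set(self.raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _resolve_out(config: RunConfig) -> Path:
    out = Path(config.raw.get("out_dir", "run_out"))
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.json").write_text(
        json.dumps(config.raw, indent=2, sort_keys=True, default=str))
    return out


def run_behavior_pipeline(config: RunConfig) -> pd.DataFrame:
    """Track a video, score each loom trial, and summarize response rates.

    Config keys: ``video`` (file or frame directory), ``events`` (CSV with
    trial_id, onset_s, polarity), ``out_dir``, optional ``fps``,
    ``tracking`` and ``classifier`` parameter mappings, ``smooth_window``.
    Writes metrics.csv, report.json and manifest.json.
    """
    config.validate(_BEHAVIOR_KEYS)
    out = _resolve_out(config)
    manifest = RunManifest(tool_version=__version__, config_hash=config.hash())

    video = Path(config.raw["video"])
    events_path = Path(config.raw["events"])
    events = pd.read_csv(events_path)
    for col in ("trial_id", "onset_s", "polarity"):
        if col not in events.columns:
            raise ValueError(f"events CSV missing column {col!r}")
    manifest.input_checksums[str(events_path)] = _checksum(events_path)
    if video.is_file():
        manifest.input_checksums[str(video)] = _checksum(video)

    frames, fps = load_frames(video, config.raw.get("fps"))
    tcfg = TrackingConfig(**config.raw.get("tracking", {}))
    ccfg = ClassifierConfig(**config.raw.get("classifier", {}))
    smooth = int(config.raw.get("smooth_window", 3))
    traj = track_video(frames, fps, tcfg)
    traj.to_csv(out / "trajectory.csv")

    rows = []
    labels_by_polarity: Dict[str, list] = {}
    for ev in events.itertuples():
        trial = TrialRecord(trajectory=traj, onset_s=float(ev.onset_s),
                            polarity=str(ev.polarity), trial_id=str(ev.trial_id))
        label = classify_response(trial, ccfg, smooth)
        row = {"trial_id": trial.trial_id, "polarity": trial.polarity,
               "onset_s": trial.onset_s, "label": label.label,
               "rationale": label.rationale}
        try:
            m = escape_metrics(trial, smooth)
            row.update(pre_distance_mm=m.pre_distance_mm,
                       post_distance_mm=m.post_distance_mm,
                       escape_distance_mm=m.escape_distance_mm,
                       max_velocity_mms=m.max_velocity_mms,
                       escape_angle_deg=m.escape_angle_deg)
        except ValueError as exc:
            manifest.warnings.append(f"trial {trial.trial_id}: {exc}")
        rows.append(row)
        labels_by_polarity.setdefault(trial.polarity, []).append(label)

    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    report = {"n_trials": len(rows), "rates": {}}
    for pol, labels in labels_by_polarity.items():
        try:
            report["rates"][pol] = response_rate(labels)
        except ValueError as exc:
            manifest.warnings.append(f"{pol}: {exc}")
    (out / "report.json").write_text(json.dumps(report, indent=2))
    manifest.counts = {"frames": len(frames), "trials": len(rows),
                       "valid_frames": int(traj.frames["valid"].sum())}
    manifest.write(out / "manifest.json")
    return metrics


def _result_to_dict(res) -> Dict:
    if isinstance(res, (CorrelationResult, FisherZResult)):
        return asdict(res)
    return res


def run_trogo_pipeline(config: RunConfig,
                       measurements: Optional[List[TectumMeasurement]] = None
                       ) -> Dict:
    """Segment stacks, assemble the day-4/day-5 table, and correlate.

    Config keys: ``metadata`` (CSV: animal_id, day, axon_count, blebbing,
    condition, and in image mode red_tif/green_tif paths relative to
    ``stacks_dir``), ``out_dir``, ``k_sd``, ``min_size``,
    ``exclusion_rule_enabled``, ``compare_conditions`` (pair of condition
    names for the Fisher-z contrast).  ``measurements`` can be passed
    directly (table mode) to skip image processing.
    """
    config.validate(_TROGO_KEYS)
    out = _resolve_out(config)
    manifest = RunManifest(tool_version=__version__, config_hash=config.hash())
    k_sd = float(config.raw.get("k_sd", 2.0))
    min_size = int(config.raw.get("min_size", 1500))
    rule = bool(config.raw.get("exclusion_rule_enabled", True))

    if measurements is None:
        import tifffile

        meta_path = Path(config.raw["metadata"])
        manifest.input_checksums[str(meta_path)] = _checksum(meta_path)
        meta = pd.read_csv(meta_path)
        stacks_dir = Path(config.raw.get("stacks_dir", meta_path.parent))
        measurements = []
        missing = []
        for row in meta.itertuples():
            red_p = stacks_dir / str(row.red_tif)
            green_p = stacks_dir / str(row.green_tif)
            if not red_p.exists() or not green_p.exists():
                missing.append(str(row.animal_id))
                continue
            from .trogo import StackPair
            pair = StackPair(red=tifffile.imread(red_p),
                             green=tifffile.imread(green_p),
                             animal_id=str(row.animal_id), day=int(row.day))
            _, meas = measure_stack(pair, k_sd=k_sd, min_size=min_size,
                                    axon_count=int(row.axon_count),
                                    blebbing=bool(row.blebbing),
                                    condition=str(getattr(row, "condition", "control")))
            measurements.append(meas)
        if missing:
            raise FileNotFoundError(f"stacks missing for animals: {missing}")

    conditions = sorted({m.condition for m in measurements})
    tables = {c: assemble_assay([m for m in measurements if m.condition == c],
                                exclusion_rule_enabled=rule)
              for c in conditions}
    all_rows = pd.concat([t.data for t in tables.values()], ignore_index=True)
    if all_rows.empty or all_rows["excluded"].all():
        raise ValueError("no animals retained after exclusions")
    all_rows.to_csv(out / "assay_table.csv", index=False)
    for row in all_rows[all_rows["excluded"]].itertuples():
        log.info("excluded %s: %s", row.animal_id, row.exclusion_reason)

    report: Dict = {"conditions": {}}
    cmp_pair = config.raw.get("compare_conditions")
    for c, t in tables.items():
        other = None
        if cmp_pair and c == cmp_pair[0]:
            other = tables.get(cmp_pair[1])
        res = assay_correlations(t, other)
        report["conditions"][c] = {k: _result_to_dict(v) for k, v in res.items()}
    (out / "correlation_report.json").write_text(
        json.dumps(report, indent=2, default=float))
    manifest.counts = {
        "measurements": len(measurements),
        "animals": int(len(all_rows)),
        "excluded": int(all_rows["excluded"].sum()),
    }
    manifest.write(out / "manifest.json")
    return report
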