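"""End-to-end orchestration: detection -> quantification -> screening.

:func:`run_pipeline` consumes an on-disk plate dataset (the directory layout
written by :func:`fretscreen.simulate.simulate_plate_to_dir`), processes
wells in the scheduler's interleaved-control order, and emits per-stage CSV
artifacts plus a final screen report.  Every discarded worm is logged with a
reason; identical inputs, config and seed reproduce byte-identical outputs.

The run log uses a logical protocol clock (seconds of instrument time
accumulated from the per-worm phase durations), not wall time, so reruns
are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .detection import (
    DetectionConfig,
    NeuronTemplate,
    autofocus_z,
    classify_orientation,
    qc_brightness,
)
from .fret import QuantConfig, extract_trace, quantify_trace, track_neuron
from .scene import SceneParams
from .screening import PlateLayout, call_hits, compound_effect, schedule, summarize_well
from .simulate import ProtocolTiming

__all__ = ["RunConfig", "RunLog", "ScreenResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run; echoed into the output dir."""

    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    alpha: float = 0.05
    controls_every: int = 9
    multiple_testing: str = "none"
    wash_every_n_worms: int | None = None
    worms_per_well: int = 15
    age_day: int = 12
    seed: int = 0
    grace_s: float = 5.0
    responder_threshold_pct: float = 2.0
    smooth_samples: int = 11
    baseline_s: float = 10.0

    def quant_config(self) -> QuantConfig:
        t_on, t_off = self.timing.t_on, self.timing.t_off
        return QuantConfig(
            t_on=t_on,
            t_off=t_off,
            baseline_window=(max(0.0, t_on - self.baseline_s), t_on),
            bleach_window=(0.0, t_on),
            grace_s=self.grace_s,
            responder_threshold_pct=self.responder_threshold_pct,
            smooth_samples=self.smooth_samples,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "timing" in d:
            d["timing"] = ProtocolTiming(**d["timing"])
        if "detection" in d:
            det = d["detection"]
            for key in ("z_range_um", "brightness_bounds"):
                if key in det and det[key] is not None:
                    det[key] = tuple(det[key])
            d["detection"] = DetectionConfig(**det)
        return cls(**d)


class RunLog:
    """Append-only event log on the instrument's logical clock."""

    def __init__(self) -> None:
        self.events: list[dict] = []
        self.t_s: float = 0.0

    def add(self, event: str, detail: str = "") -> None:
        self.events.append({"t_s": round(self.t_s, 3), "event": event, "detail": detail})

    def advance(self, seconds: float) -> None:
        self.t_s += seconds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["t_s", "event", "detail"])


@dataclass
class ScreenResult:
    """Everything a plate run produces, in memory."""

    records: pd.DataFrame
    well_summaries: pd.DataFrame
    effects: pd.DataFrame
    hits: dict
    log: pd.DataFrame
    n_processed: int
    n_analyzed: int


def _worm_dirs(well_dir: Path) -> list[Path]:
    return sorted(p for p in well_dir.iterdir() if p.is_dir())


def _process_worm(
    worm_dir: Path, config: RunConfig, template: NeuronTemplate, log: RunLog
) -> dict:
    """Detection + quantification for one worm directory; returns a record row."""
    row: dict = {"worm_id": worm_dir.name, "qc": "analyzed", "x": np.nan, "y": np.nan,
                 "z_index": -1, "max_score": np.nan, "baseline_ratio": np.nan,
                 "peak_pct": np.nan, "slope_pct_s": np.nan, "responder": False}
    meta_path = worm_dir / "timeseries.json"
    viability = "alive"
    if meta_path.exists():
        with open(meta_path) as fh:
            viability = json.load(fh).get("viability", "alive")
    if viability == "dead":
        # recognized on-chip (no movement/pumping) and discarded before recording
        row["qc"] = "dead"
        return row

    zstack = fio.read_stack(worm_dir / "zstack.tif")
    _, h, w = zstack.shape
    geom = SceneParams(width=w, height=h)
    head, tail = geom.head_region(), geom.tail_region()

    orientation = classify_orientation(zstack, head, tail, config.detection, template)
    if orientation == "tail":
        row["qc"] = "tail_entry"
        return row
    if orientation == "none":
        row["qc"] = "neuron_not_found"
        return row

    det = autofocus_z(zstack, template, config.detection, head)
    if det.status != "head_loaded":
        row["qc"] = "neuron_not_found"
        return row
    row.update(x=det.x, y=det.y, z_index=det.z_index, max_score=float(np.max(det.scores)))

    bg = geom.background_region()
    plane = zstack.acceptor[det.z_index]
    r = config.detection.roi_radius_px
    yy, xx = np.ogrid[:h, :w]
    roi = (xx - det.x) ** 2 + (yy - det.y) ** 2 <= r * r
    roi_mean = float(plane[roi].mean() - np.median(bg.crop(plane)))
    bright = qc_brightness(roi_mean, config.detection.brightness_bounds)
    if bright != "pass":
        row["qc"] = bright
        return row

    series = fio.read_stack(worm_dir / "timeseries.tif")
    positions, lost = track_neuron(series, (det.x, det.y), config.detection)
    if lost.any():
        log.add("track_flagged", f"{worm_dir.name}: {int(lost.sum())} frames held")
    qc = config.quant_config()
    trace = extract_trace(series, positions, r, bg, qc.t_on, qc.t_off)
    metrics = quantify_trace(trace, qc)
    row.update(
        baseline_ratio=metrics.baseline_ratio,
        peak_pct=metrics.peak_pct,
        slope_pct_s=metrics.slope_pct_s,
        responder=metrics.responder,
    )
    return row


def run_pipeline(dataset_root: str | Path, config: RunConfig, out_dir: str | Path) -> ScreenResult:
    """Process a plate dataset end to end and write all artifacts to ``out_dir``."""
    root = Path(dataset_root)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    config.to_yaml(out / "config.yaml")

    layout = PlateLayout.from_yaml(root / "layout.yaml")
    template = NeuronTemplate(fio.read_template(root / "template.tif"), note="dataset template")
    present = {p.name for p in root.iterdir() if p.is_dir()}
    plan = schedule(
        layout, config.controls_every, config.wash_every_n_worms, config.worms_per_well
    )

    per_worm_s = config.timing.load_s + config.timing.duration_s + config.timing.unload_s
    rows: list[dict] = []
    control_records: dict[str, list[int]] = {}   # well -> row indices
    matched_control: dict[str, str] = {}         # compound well -> control well
    pending_block: list[str] = []

    for item in plan:
        if item.kind == "wash":
            log.add("wash")
            continue
        well = item.well
        if well not in present:
            log.add("well_skipped", f"{well}: no data on disk")
            if item.role == "compound":
                pending_block.append(well)
            continue
        log.add("well_started", well)
        for worm_dir in _worm_dirs(root / well):
            log.advance(per_worm_s)
            try:
                row = _process_worm(worm_dir, config, template, log)
            except (ValueError, KeyError, FileNotFoundError) as exc:
                row = {"worm_id": worm_dir.name, "qc": "malformed_input"}
                log.add("worm_discarded", f"{worm_dir.name}: {exc}")
            row.update(
                well=well,
                role=item.role,
                compound=layout.compound(well),
                concentration_uM=layout.concentration(well),
                age_day=config.age_day,
            )
            rows.append(row)
            if row["qc"] == "analyzed":
                log.add("worm_analyzed", row["worm_id"])
            else:
                log.add("worm_discarded", f"{row['worm_id']}: {row['qc']}")
        log.add("well_finished", well)
        if item.role == "compound":
            pending_block.append(well)
        else:
            control_records.setdefault(well, [])
            for cw in pending_block:
                matched_control[cw] = well
            pending_block = []

    columns = [
        "worm_id", "well", "role", "compound", "concentration_uM", "age_day", "qc",
        "x", "y", "z_index", "max_score", "baseline_ratio", "peak_pct", "slope_pct_s",
        "responder",
    ]
    records = pd.DataFrame(rows, columns=columns)
    fio.write_csv(records, out / "metrics.csv")

    summaries = []
    for well in sorted(records["well"].unique()) if len(records) else []:
        s = summarize_well(records[records["well"] == well], well)
        summaries.append(
            {
                "well": s.well, "n_analyzed": s.n_analyzed,
                "n_discarded": sum(s.n_discarded.values()),
                "mean_peak": s.mean_peak, "sem_peak": s.sem_peak,
                "mean_slope": s.mean_slope, "sem_slope": s.sem_slope,
            }
        )
    well_summaries = pd.DataFrame(
        summaries,
        columns=["well", "n_analyzed", "n_discarded", "mean_peak", "sem_peak",
                 "mean_slope", "sem_slope"],
    )
    fio.write_csv(well_summaries, out / "well_summaries.csv")

    effects = []
    effect_rows = []
    for well in sorted(matched_control):
        ctrl_well = matched_control[well]
        treated = records[(records["well"] == well) & (records["qc"] == "analyzed")]
        control = records[(records["well"] == ctrl_well) & (records["qc"] == "analyzed")]
        if len(treated) < 2 or len(control) < 2:
            log.add("effect_skipped", f"{well}: insufficient analyzed worms")
            continue
        eff = compound_effect(treated, control, config.alpha)
        effects.append(eff)
        effect_rows.append(
            {
                "well": well, "compound": eff.compound, "control_well": ctrl_well,
                "effect_pct": eff.effect_pct, "effect_slope_pct": eff.effect_slope_pct,
                "p_value": eff.p_value, "p_slope": eff.p_slope,
                "classification": eff.classification, "dual_action": eff.dual_action,
                "n_treated": eff.n_treated, "n_control": eff.n_control,
            }
        )

    hits_dict: dict = {"alpha": config.alpha, "multiple_testing": config.multiple_testing,
                       "counts": {}, "fractions": {}, "positive": [], "negative": []}
    if effects:
        summary = call_hits(effects, config.alpha, config.multiple_testing)
        for row, eff in zip(effect_rows, effects):
            row["classification"] = eff.classification   # may change under BH
        hits_dict.update(
            counts=summary.counts,
            fractions=summary.fractions,
            positive=[e.compound for e in summary.positives],
            negative=[e.compound for e in summary.negatives],
        )
    effects_df = pd.DataFrame(
        effect_rows,
        columns=["well", "compound", "control_well", "effect_pct", "effect_slope_pct",
                 "p_value", "p_slope", "classification", "dual_action", "n_treated",
                 "n_control"],
    )
    fio.write_csv(effects_df, out / "compound_effects.csv")
    with open(out / "classification.json", "w") as fh:
        json.dump(hits_dict, fh, indent=1, sort_keys=True)

    n_proc = len(records)
    n_ok = int((records["qc"] == "analyzed").sum()) if n_proc else 0
    log.add("run_finished", f"processed={n_proc} analyzed={n_ok}")
    log_df = log.to_frame()
    fio.write_csv(log_df, out / "run_log.csv")

    with open(out / "report.txt", "w") as fh:
        fh.write(_report_text(records, effects_df, hits_dict))

    return ScreenResult(records, well_summaries, effects_df, hits_dict, log_df, n_proc, n_ok)


def _report_text(records: pd.DataFrame, effects: pd.DataFrame, hits: dict) -> str:
    lines = ["Plate screen report", "==================="]
    n = len(records)
    if n == 0:
        lines.append("No worms processed.")
        return "\n".join(lines) + "\n"
    discard = records[records["qc"] != "analyzed"]["qc"].value_counts().to_dict()
    lines.append(f"Worms processed: {n}; analyzed: {n - sum(discard.values())}")
    for reason, count in sorted(discard.items()):
        lines.append(f"  discarded ({reason}): {count}")
    lines.append("")
    lines.append("Compound effects vs matched interleaved control (peak, % change):")
    for _, row in effects.iterrows():
        lines.append(
            f"  {row['compound']:<16s} {row['effect_pct']:+7.1f}%  p={row['p_value']:.4g}"
            f"  -> {row['classification']}"
        )
    c = hits.get("counts", {})
    if c:
        lines.append("")
        lines.append(
            f"Hit partition: {c.get('positive', 0)} positive, "
            f"{c.get('negative', 0)} negative, {c.get('none', 0)} no effect"
        )
    return "\n".join(lines) + "\n"
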