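"""End-to-end orchestration: read -> clean -> events -> QC -> spatiotemporal
+ kinematics + cyclograms -> report, plus a recovery mode that scores the
pipeline against synthetic ground truth."""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .cyclograms import build_cyclogram, cyclogram_metrics
from .events import (DetectionParams, QCConfig, detect_events, events_table,
                     qc_cycles, segment_cycles)
from .io import read_c3d, read_mocap_tsv, write_report
from .kinematics import (JointAngleSeries, SegmentModel, build_frames,
                         joint_angles, mean_curve, normalize_to_cycle,
                         summarize_events)
from .markers import LandmarkMap, Limb, MarkerTrajectorySet, fill_gaps, lowpass_filter
from .spatiotemporal import (aggregate, compute_lags, compute_record,
                             fit_line_of_progression, records_frame)
from .synthetic import SyntheticGaitConfig, synthesize_trial

log = logging.getLogger("ovigait")

_JOINT_PAIRS = (("knee", "ankle"), ("hip", "ankle"), ("hip", "knee"))


@dataclass
class PipelineConfig:
    """All tunables of one analysis run; round-trips through a flat INI file."""

    # cleaning
    max_gap_frames: int = 10
    lowpass_hz: float = 10.0
    filter_order: int = 4
    # event detection
    h_thresh: float = 0.015
    v_frac: float = 0.10
    min_run: int = 3
    # quality control
    speed_min: float = 0.5
    speed_max: float = 2.0
    heading_max_deg: float = 10.0
    duty_min: float = 0.5
    duty_max: float = 0.8
    # kinematics
    normalization_samples: int = 101
    cardan_sequence: str = "XYZ"
    reference: str = "anatomical"   # or "static-offset"
    # output
    output_dir: str = "ovigait_out"
    seed: int = 0

    def __post_init__(self):
        if self.cardan_sequence != "XYZ":
            raise ValueError("only the X-Y-Z Cardan sequence is supported")
        if self.reference not in ("anatomical", "static-offset"):
            raise ValueError("reference must be anatomical or static-offset")

    def detection(self) -> DetectionParams:
        return DetectionParams(h_thresh=self.h_thresh, v_frac=self.v_frac,
                               min_run=self.min_run)

    def qc(self) -> QCConfig:
        return QCConfig(speed_range=(self.speed_min, self.speed_max),
                        heading_max_deg=self.heading_max_deg,
                        duty_range=(self.duty_min, self.duty_max))

    _SECTIONS = {
        "cleaning": ("max_gap_frames", "lowpass_hz", "filter_order"),
        "events": ("h_thresh", "v_frac", "min_run"),
        "qc": ("speed_min", "speed_max", "heading_max_deg",
               "duty_min", "duty_max"),
        "kinematics": ("normalization_samples", "cardan_sequence", "reference"),
        "output": ("output_dir", "seed"),
    }

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: str(getattr(self, k)) for k in keys}
        with open(path, "w", encoding="utf-8") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        with open(path, "r", encoding="utf-8") as fh:
            cp.read_file(fh)
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for section, keys in cls._SECTIONS.items():
            for k in keys:
                raw = cp[section][k]
                t = types[k]
                kwargs[k] = int(raw) if t == "int" else (
                    float(raw) if t == "float" else raw)
        return cls(**kwargs)


def load_trial(path) -> MarkerTrajectorySet:
    """Dispatch on extension: .c3d or the tab-separated export dialect."""
    p = Path(path)
    if p.suffix.lower() == ".c3d":
        return read_c3d(p)
    return read_mocap_tsv(p)


@dataclass
class AnalysisResult:
    """In-memory results of one run, before/after writing the report."""

    tables: dict[str, pd.DataFrame]
    counts: dict[str, int]
    manifest: dict | None = None
    warnings: list[str] = field(default_factory=list)


def analyze_set(mset: MarkerTrajectorySet, lmap: LandmarkMap | None = None,
                config: PipelineConfig | None = None,
                static: MarkerTrajectorySet | None = None) -> AnalysisResult:
    """Run the full analysis on an in-memory marker set."""
    lmap = lmap or LandmarkMap.default()
    config = config or PipelineConfig()
    notes: list[str] = []

    work = fill_gaps(mset, config.max_gap_frames)
    filtered = lowpass_filter(work, config.lowpass_hz, config.filter_order)

    # events are detected on the unfiltered (gap-filled) trajectories: the
    # contact transient is exactly what a low-pass filter smears
    events = detect_events(work, lmap, config.detection())
    cycles = segment_cycles(events)
    progression = fit_line_of_progression(work, lmap, events=events)
    cycles = qc_cycles(cycles, work, lmap, config.qc(), progression[1])
    valid = [c for c in cycles if c.valid]
    counts = {
        "detected_cycles": len(cycles),
        "accepted_cycles": len(valid),
        "rejected_cycles": len(cycles) - len(valid),
    }
    for c in cycles:
        if not c.valid:
            log.info("rejected cycle %s @%d: %s", c.limb.label, c.ic_frame,
                     c.exclusion_reason)

    tables: dict[str, pd.DataFrame] = {"events": events_table(events)}
    tables["cycles"] = pd.DataFrame(
        [{"side": c.limb.side, "girdle": c.limb.girdle, "ic": c.ic_frame,
          "to": c.to_frame, "next_ic": c.next_ic_frame, "valid": c.valid,
          "reason": c.exclusion_reason} for c in cycles])

    # ---- spatiotemporal ---------------------------------------------------
    for girdle in ("hind", "fore"):
        recs = [compute_record(c, events, work, lmap, progression)
                for c in valid if c.limb.girdle == girdle]
        name = f"spatiotemporal_{girdle}"
        if recs:
            tables[name] = aggregate(recs)
            tables[name + "_cycles"] = records_frame(recs)
        else:
            notes.append(f"no valid {girdle} cycles; {name} table is empty")
            tables[name] = pd.DataFrame()
    try:
        lag = compute_lags(events)
        tables["lags"] = pd.DataFrame(
            [{"F lag (%)": lag.f_lag, "H lag (%)": lag.h_lag,
              "P lag (%)": lag.p_lag, "n": lag.n_cycles}])
    except ValueError as exc:
        notes.append(f"lags unavailable: {exc}")

    # ---- joint kinematics + cyclograms ------------------------------------
    static_frames_by_side: dict[str, dict] = {}
    for side in ("left", "right"):
        if not lmap.complete_hindlimb(side):
            notes.append(f"{side} hindlimb landmarks incomplete; "
                         "kinematics skipped")
            continue
        model = SegmentModel(side)
        side_cycles = [c for c in valid if c.limb == Limb(side, "hind")]
        if not side_cycles:
            notes.append(f"no valid {side} hind cycles; kinematics skipped")
            continue
        frames = build_frames(filtered, lmap, model)
        static_frames = None
        if static is not None and config.reference == "static-offset":
            if side not in static_frames_by_side:
                static_frames_by_side[side] = build_frames(
                    fill_gaps(static, config.max_gap_frames), lmap, model)
            static_frames = static_frames_by_side[side]
        angles = joint_angles(frames, model, static=static_frames)
        normalized: dict[str, list[JointAngleSeries]] = {}
        summary_rows = []
        for joint, series in angles.items():
            norm = [normalize_to_cycle(series, c, mset.rate,
                                       config.normalization_samples)
                    for c in side_cycles]
            normalized[joint] = norm
            summ = summarize_events(norm)
            summary_rows.append(summ.table())
            curve = mean_curve(norm)
            tables[f"joint_{side}_{joint}_curve"] = pd.DataFrame(
                curve.data, columns=list(JointAngleSeries.COMPONENTS))
        tables[f"joint_summary_{side}"] = pd.concat(
            summary_rows, ignore_index=True)
        for a_name, b_name in _JOINT_PAIRS:
            ca = mean_curve(normalized[a_name])
            cb = mean_curve(normalized[b_name])
            cyc = build_cyclogram(ca, cb)
            area, perim, orient = cyclogram_metrics(cyc)
            tables[f"cyclogram_{side}_{a_name}_{b_name}"] = pd.DataFrame({
                a_name: cyc.path[:, 0], b_name: cyc.path[:, 1]})
            tables.setdefault("cyclogram_metrics", pd.DataFrame(
                columns=["side", "pair", "area_deg2", "perimeter_deg",
                         "orientation", "to_index"]))
            tables["cyclogram_metrics"].loc[len(tables["cyclogram_metrics"])] = [
                side, f"{a_name}-{b_name}", area, perim, orient, cyc.to_index]

    for note in notes:
        log.warning(note)
    return AnalysisResult(tables=tables, counts=counts, warnings=notes)


def run_analysis(trial_path, config: PipelineConfig | None = None,
                 lmap: LandmarkMap | None = None,
                 static_path=None) -> dict:
    """File-to-files analysis; returns the written report manifest."""
    config = config or PipelineConfig()
    try:
        mset = load_trial(trial_path)
    except Exception as exc:
        raise RuntimeError(f"[read] failed on {trial_path}: {exc}") from exc
    static = load_trial(static_path) if static_path else None
    result = analyze_set(mset, lmap, config, static)
    manifest = write_report(result.tables, config.output_dir,
                            extra={"counts": result.counts,
                                   "warnings": result.warnings})
    result.manifest = manifest
    return manifest


# ---------------------------------------------------------------------------
# Recovery harness
# ---------------------------------------------------------------------------

#: absolute tolerances for parameter recovery, by quantity kind
RECOVERY_TOLERANCES = {"length": 0.01, "time": 0.01, "percent": 2.0,
                       "angle": 2.0, "speed": 0.03}


def run_recovery(gait_config: SyntheticGaitConfig | None = None,
                 pipeline_config: PipelineConfig | None = None,
                 side: str = "right") -> pd.DataFrame:
    """Synthesize a trial, analyze it, and score every recovered quantity
    against ground truth.  Columns: quantity, truth, estimate, abs_error,
    tolerance, passed."""
    gait_config = gait_config or SyntheticGaitConfig()
    pipeline_config = pipeline_config or PipelineConfig(seed=gait_config.seed)
    mset, truth = synthesize_trial(gait_config)
    result = analyze_set(mset, config=pipeline_config)
    rows: list[dict] = []

    def add(name: str, kind: str, true_val: float, est: float):
        tol = RECOVERY_TOLERANCES[kind]
        err = abs(est - true_val)
        rows.append({"quantity": name, "truth": true_val, "estimate": est,
                     "abs_error": err, "tolerance": tol,
                     "passed": bool(err <= tol)})

    per_cycle = result.tables["spatiotemporal_hind_cycles"]

    def est_mean(var, side_=None):
        g = per_cycle if side_ is None else per_cycle[per_cycle.side == side_]
        return float(g[var].mean())

    add("cycle_time", "time", truth.cycle_time, est_mean("cycle_time"))
    add("stance_time", "time", truth.stance_time, est_mean("stance_time"))
    add("swing_time", "time", truth.swing_time, est_mean("swing_time"))
    add("stance_pct", "percent", 100 * truth.duty_factor,
        est_mean("stance_pct"))
    add("duty_factor_pct", "percent", 100 * truth.duty_factor,
        100 * est_mean("duty_factor"))
    add("stride_length", "length", truth.stride_length,
        est_mean("stride_length"))
    add("stride_width", "length", truth.stride_width, est_mean("stride_width"))
    for s in ("left", "right"):
        add(f"step_length_{s}", "length", truth.step_length[s],
            est_mean("step_length", s))
        add(f"step_time_{s}", "time", truth.step_time[s],
            est_mean("step_time", s))
    add("double_support_time", "time", truth.double_support_time,
        est_mean("double_support_time"))
    add("no_support_time", "time", truth.no_support_time,
        est_mean("no_support_time"))
    add("speed", "speed", truth.speed, est_mean("speed"))
    lags = result.tables["lags"].iloc[0]
    add("f_lag", "percent", truth.f_lag, float(lags["F lag (%)"]))
    add("h_lag", "percent", truth.h_lag, float(lags["H lag (%)"]))
    add("p_lag", "percent", truth.p_lag, float(lags["P lag (%)"]))

    summary = result.tables[f"joint_summary_{side}"]
    for joint in ("hip", "knee", "ankle"):
        ts = truth.event_summary(joint)
        sub = summary[summary.joint == joint]
        for comp in ts:
            for event, true_val in ts[comp].items():
                est = float(sub[(sub.component == comp)
                                & (sub.event == event)]["mean"].iloc[0])
                add(f"{joint}.{comp}.{event}", "angle", true_val, est)
    return pd.DataFrame(rows)
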