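"""Hoof-contact event detection, cycle segmentation, and cycle quality control.

Initial contact (IC) and toe-off (TO) are detected kinematically from the
distal hoof marker: a frame belongs to stance when the marker sits within a
height band above the estimated floor AND its horizontal speed is a small
fraction of its peak speed in the trial.  The criterion uses the horizontal
speed magnitude, so detection is invariant to translating or yawing the lab
frame.  Short spurious runs are removed by morphological closing/opening,
which also merges events closer than the hysteresis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .markers import ALL_LIMBS, LandmarkMap, Limb, MarkerTrajectorySet


@dataclass(frozen=True)
class GaitEvent:
    limb: Limb
    kind: str       # "IC" | "TO"
    frame: int
    time: float     # frame / rate


@dataclass
class GaitCycle:
    """One IC -> IC interval of one limb with its TO split and QC status."""

    limb: Limb
    ic_frame: int
    to_frame: int
    next_ic_frame: int
    valid: bool = True
    exclusion_reason: str = ""

    def __post_init__(self):
        if not self.ic_frame < self.to_frame < self.next_ic_frame:
            raise ValueError("cycle frames must satisfy ic < to < next_ic")

    def cycle_time(self, rate: float) -> float:
        return (self.next_ic_frame - self.ic_frame) / rate

    def stance_time(self, rate: float) -> float:
        return (self.to_frame - self.ic_frame) / rate

    def swing_time(self, rate: float) -> float:
        return (self.next_ic_frame - self.to_frame) / rate

    @property
    def duty_factor(self) -> float:
        return (self.to_frame - self.ic_frame) / (self.next_ic_frame - self.ic_frame)


@dataclass
class DetectionParams:
    """Thresholds of the height + velocity contact detector."""

    h_thresh: float = 0.015        # m above the estimated floor
    v_frac: float = 0.10           # fraction of the hoof's peak forward speed
    min_run: int = 3               # frames; hysteresis for run cleaning
    floor_percentile: float = 2.0  # per-trial floor height estimate


class ConfigurationError(KeyError):
    """A required landmark is missing from the landmark map."""


def _runs(mask: np.ndarray):
    """(start, stop) pairs of consecutive True runs, stop exclusive."""
    idx = np.flatnonzero(
        np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def _contact_mask(pos: np.ndarray, rate: float, params: DetectionParams
                  ) -> np.ndarray:
    z = pos[:, 2]
    floor = np.percentile(z[np.isfinite(z)], params.floor_percentile)
    # forward-difference horizontal speed: a frame is static when the hoof
    # has not moved by the NEXT sample, which keeps contact edges sharp
    vel = np.diff(pos[:, :2], axis=0) * rate
    speed = np.linalg.norm(vel, axis=1)
    speed = np.append(speed, speed[-1])
    peak = np.nanmax(speed)
    slow = (speed < params.v_frac * peak) if peak > 1e-9 else np.ones_like(z, bool)
    contact = (z < floor + params.h_thresh) & slow
    if params.min_run > 1:
        # fill interior non-contact gaps shorter than the hysteresis window,
        # then drop contact runs shorter than it
        gaps = _runs(~contact)
        for start, stop in gaps:
            if start > 0 and stop < len(contact) and stop - start < params.min_run:
                contact[start:stop] = True
        for start, stop in _runs(contact):
            if stop - start < params.min_run:
                contact[start:stop] = False
    return contact


def detect_events(mset: MarkerTrajectorySet, lmap: LandmarkMap,
                  params: DetectionParams | None = None,
                  limbs: tuple[Limb, ...] | None = None) -> list[GaitEvent]:
    """Detect alternating IC/TO events for every analyzable limb.

    A contact run that starts at frame 0 or ends at the last frame is partial:
    its outer boundary is not emitted as an event (except for the degenerate
    whole-trial contact, which yields a single IC at the analysis start).
    """
    params = params or DetectionParams()
    if limbs is None:
        limbs = tuple(l for l in ALL_LIMBS if lmap.has(l.side, l.hoof_landmark))
        if not limbs:
            raise ConfigurationError("no limb has its hoof landmark mapped")
    events: list[GaitEvent] = []
    for limb in limbs:
        if not lmap.has(limb.side, limb.hoof_landmark):
            raise ConfigurationError(
                f"hoof landmark {limb.hoof_landmark!r} of {limb.label} "
                "missing from landmark map")
        label = lmap.label_for(limb.side, limb.hoof_landmark)
        pos = mset.get(label)
        gaps = mset.gaps(label)
        if gaps.any():
            # bridge gaps for detection only; QC invalidates affected cycles
            warnings.warn(f"hoof marker {label} has gaps; bridging for detection")
            t = mset.time
            valid = ~gaps
            pos = np.column_stack(
                [np.interp(t, t[valid], pos[valid, k]) for k in range(3)])
        contact = _contact_mask(pos, mset.rate, params)
        if contact.all():
            events.append(GaitEvent(limb, "IC", 0, 0.0))
            continue
        limb_events = []
        for start, stop in _runs(contact):
            if start > 0:  # a run touching frame 0 has an unseen IC
                limb_events.append(
                    GaitEvent(limb, "IC", int(start), start / mset.rate))
            if stop < len(contact):  # a run touching the end has an unseen TO
                limb_events.append(
                    GaitEvent(limb, "TO", int(stop), stop / mset.rate))
        if not limb_events:
            warnings.warn(f"no full gait cycle found for {limb.label}")
        events.extend(limb_events)
    events.sort(key=lambda e: (e.frame, e.limb.label))
    return events


def events_table(events: list[GaitEvent]):
    import pandas as pd
    return pd.DataFrame(
        [{"side": e.limb.side, "girdle": e.limb.girdle, "kind": e.kind,
          "frame": e.frame, "time": e.time} for e in events])


def segment_cycles(events: list[GaitEvent]) -> list[GaitCycle]:
    """One cycle per consecutive (IC, TO, next IC) triple of each limb."""
    cycles: list[GaitCycle] = []
    limbs = sorted({e.limb for e in events}, key=lambda l: l.label)
    for limb in limbs:
        seq = [e for e in events if e.limb == limb]
        seq.sort(key=lambda e: e.frame)
        i = 0
        while i + 2 < len(seq):
            e0, e1, e2 = seq[i], seq[i + 1], seq[i + 2]
            if e0.kind == "IC" and e1.kind == "TO" and e2.kind == "IC":
                cycles.append(GaitCycle(limb, e0.frame, e1.frame, e2.frame))
                i += 2
            else:
                i += 1
    cycles.sort(key=lambda c: (c.limb.label, c.ic_frame))
    return cycles


@dataclass
class QCConfig:
    """Cycle-rejection thresholds mirroring the study's qualitative exclusions
    (hesitation, limb dragging, running, curved walking)."""

    speed_range: tuple[float, float] = (0.5, 2.0)   # m/s, comfortable walk
    heading_max_deg: float = 10.0                   # deviation from progression line
    duty_range: tuple[float, float] = (0.5, 0.8)    # walking, not running
    check_gaps: bool = True


def qc_cycles(cycles: list[GaitCycle], mset: MarkerTrajectorySet,
              lmap: LandmarkMap, criteria: QCConfig | None = None,
              progression: np.ndarray | None = None) -> list[GaitCycle]:
    """Mark each cycle valid/invalid with one reason; valid cycles flow on.

    Reasons, checked in order: ``marker_gap`` (an unfilled gap in a required
    marker of the limb inside the cycle), ``speed_out_of_range`` (displacement
    speed of the reference marker), ``heading_deviation`` (cycle displacement
    direction vs. the line of progression), ``duty_factor_out_of_range``.
    """
    criteria = criteria or QCConfig()
    out: list[GaitCycle] = []
    for cyc in cycles:
        reason = ""
        sl = slice(cyc.ic_frame, cyc.next_ic_frame + 1)
        required = lmap.limb_labels(cyc.limb)
        if criteria.check_gaps:
            for label in required:
                if mset.gaps(label)[sl].any():
                    reason = "marker_gap"
                    break
        ref_label = (lmap.label_for(cyc.limb.side, "coxal_tuberosity")
                     if lmap.has(cyc.limb.side, "coxal_tuberosity")
                     else lmap.label_for(cyc.limb.side, cyc.limb.hoof_landmark))
        disp = (mset.get(ref_label)[cyc.next_ic_frame]
                - mset.get(ref_label)[cyc.ic_frame])
        if not reason and np.all(np.isfinite(disp)):
            speed = np.linalg.norm(disp[:2]) / cyc.cycle_time(mset.rate)
            lo, hi = criteria.speed_range
            if not lo <= speed <= hi:
                reason = "speed_out_of_range"
        if not reason and progression is not None and np.all(np.isfinite(disp)):
            u = np.asarray(progression, float)[:2]
            u = u / np.linalg.norm(u)
            d2 = disp[:2] / np.linalg.norm(disp[:2])
            ang = np.degrees(np.arccos(np.clip(abs(float(d2 @ u)), -1, 1)))
            if ang > criteria.heading_max_deg:
                reason = "heading_deviation"
        if not reason:
            lo, hi = criteria.duty_range
            if not lo < cyc.duty_factor < hi:
                reason = "duty_factor_out_of_range"
        out.append(GaitCycle(cyc.limb, cyc.ic_frame, cyc.to_frame,
                             cyc.next_ic_frame, valid=(reason == ""),
                             exclusion_reason=reason))
    return out
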