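"""Spatiotemporal gait parameters: per-cycle records, inter-limb lags, and
mean +/- SD aggregation.

Lengths are measured against the line of progression, a horizontal total
least-squares fit to the hind contact points, so nothing assumes the animal
walked parallel to a lab axis.  The "heel point" of a footfall is
operationalized as the distal hoof landmark position at the IC frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .events import GaitCycle, GaitEvent
from .markers import LandmarkMap, Limb, MarkerTrajectorySet


@dataclass
class SpatioTemporalRecord:
    """Per-cycle realization of every spatiotemporal variable.

    ``stance_pct + swing_pct == 100`` and ``cycle_time == stance_time +
    swing_time`` hold exactly by construction from the three event frames;
    ``speed * cycle_time == stride_length`` by definition of speed.
    Fields that need contralateral events are NaN when those are missing.
    """

    limb: Limb
    cycle_time: float
    stance_time: float
    swing_time: float
    stance_pct: float
    swing_pct: float
    step_length: float
    step_time: float
    stride_length: float
    stride_width: float
    double_support_time: float
    no_support_time: float
    speed: float
    duty_factor: float


@dataclass
class LagSummary:
    """Inter-limb contact delays as % of cycle duration (Abourachid lags).

    ``f_lag``: left-fore IC relative to right-fore IC; ``h_lag``: same for the
    hind pair; ``p_lag``: fore IC relative to the ipsilateral hind IC.  In a
    symmetric walk f_lag = h_lag = 50.  A pace (ipsilateral synchrony) has
    zero pair delay and is reported as 100 by convention.
    """

    f_lag: float
    h_lag: float
    p_lag: float
    n_cycles: int = 0


def fit_line_of_progression(mset: MarkerTrajectorySet, lmap: LandmarkMap,
                            span: tuple[int, int] | None = None,
                            events: list[GaitEvent] | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal principal-axis (total least squares) fit to the hind contact
    points; returns (point-on-line, unit direction with zero vertical part).

    Orientation is chosen so that the pelvis (or, failing that, hoof)
    displacement over the span projects positively.
    """
    if events is None:
        from .events import detect_events
        events = detect_events(mset, lmap)
    lo, hi = span if span is not None else (0, mset.n_frames)
    pts: dict[str, list[np.ndarray]] = {"left": [], "right": []}
    for e in events:
        if e.kind == "IC" and e.limb.girdle == "hind" and lo <= e.frame < hi:
            label = lmap.label_for(e.limb.side, "distal_phalanx")
            p = mset.get(label)[e.frame]
            if np.all(np.isfinite(p)):
                pts[e.limb.side].append(p[:2])
    n_total = sum(len(v) for v in pts.values())
    if n_total < 2:
        raise ValueError(
            f"need >= 2 hind contact points to fit the line of progression, "
            f"got {n_total}")
    # pooled within-side principal axis: centering each side's contacts
    # before the fit keeps an unbalanced left/right contact count from
    # tilting the line, and puts it midway between the two footfall tracks
    sides = [np.asarray(v) for v in pts.values() if len(v)]
    centroid = np.mean([s.mean(axis=0) for s in sides], axis=0)
    deviations = np.vstack([s - s.mean(axis=0) for s in sides])
    if len(deviations) < 2 or np.allclose(deviations, 0.0):
        raise ValueError("hind contact points do not define a direction")
    cov = deviations.T @ deviations
    _w, v = np.linalg.eigh(np.atleast_2d(cov))
    direction2 = v[:, -1]  # principal axis
    direction = np.array([direction2[0], direction2[1], 0.0])
    direction /= np.linalg.norm(direction)
    ref = None
    for side in ("right", "left"):
        if lmap.has(side, "coxal_tuberosity"):
            ref = mset.get(lmap.label_for(side, "coxal_tuberosity"))
            break
    if ref is None:
        ref = mset.get(lmap.label_for(events[0].limb.side,
                                      events[0].limb.hoof_landmark))
    disp = ref[min(hi, mset.n_frames) - 1] - ref[lo]
    if np.dot(disp[:2], direction[:2]) < 0:
        direction = -direction
    return np.array([centroid[0], centroid[1], 0.0]), direction


def _stance_intervals(events: list[GaitEvent], limb: Limb, rate: float
                      ) -> list[tuple[float, float]]:
    seq = sorted((e for e in events if e.limb == limb), key=lambda e: e.frame)
    out = []
    open_t = None
    for e in seq:
        if e.kind == "IC":
            open_t = e.time
        elif e.kind == "TO" and open_t is not None:
            out.append((open_t, e.time))
            open_t = None
    if open_t is not None:
        out.append((open_t, math.inf))
    # a leading TO means stance was already underway at the analysis start
    if seq and seq[0].kind == "TO":
        out.insert(0, (-math.inf, seq[0].time))
    return out


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def compute_record(cycle: GaitCycle, events: list[GaitEvent],
                   mset: MarkerTrajectorySet, lmap: LandmarkMap,
                   progression: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> SpatioTemporalRecord:
    """All spatiotemporal variables for one valid cycle.

    stride = same-hoof IC-to-IC displacement projected on the progression
    line; step = contralateral IC to this limb's closing IC; stride width =
    unsigned perpendicular distance between the two limbs' contact points;
    support times come from the stance overlap of the limb pair.
    """
    rate = mset.rate
    limb = cycle.limb
    if progression is None:
        progression = fit_line_of_progression(mset, lmap, events=events)
    _origin, u = progression
    n_perp = np.array([-u[1], u[0], 0.0])

    hoof = mset.get(lmap.label_for(limb.side, limb.hoof_landmark))
    p_ic = hoof[cycle.ic_frame]
    p_next = hoof[cycle.next_ic_frame]
    stride_length = abs(float((p_next - p_ic) @ u))
    cycle_time = cycle.cycle_time(rate)
    stance_time = cycle.stance_time(rate)
    swing_time = cycle.swing_time(rate)

    contra = limb.contralateral
    step_length = step_time = stride_width = np.nan
    double_support = no_support = np.nan
    contra_events = [e for e in events if e.limb == contra]
    if contra_events and lmap.has(contra.side, contra.hoof_landmark):
        contra_hoof = mset.get(lmap.label_for(contra.side, contra.hoof_landmark))
        contra_ics = [e for e in contra_events if e.kind == "IC"
                      and cycle.ic_frame < e.frame <= cycle.next_ic_frame]
        if contra_ics:
            ce = contra_ics[-1]
            step_time = (cycle.next_ic_frame - ce.frame) / rate
            step_length = abs(float(
                (hoof[cycle.next_ic_frame] - contra_hoof[ce.frame]) @ u))
            stride_width = abs(float((p_ic - contra_hoof[ce.frame]) @ n_perp))
        window = (cycle.ic_frame / rate, cycle.next_ic_frame / rate)
        own_stance = [(cycle.ic_frame / rate, cycle.to_frame / rate)]
        contra_stance = _stance_intervals(events, contra, rate)
        both = 0.0
        for a in contra_stance:
            clipped = (max(a[0], window[0]), min(a[1], window[1]))
            if clipped[1] > clipped[0]:
                both += _overlap(clipped, own_stance[0])
        double_support = both
        # span with neither limb of the pair in stance
        covered = sorted(
            [(max(s, window[0]), min(e, window[1]))
             for s, e in own_stance + contra_stance
             if min(e, window[1]) > max(s, window[0])])
        merged: list[list[float]] = []
        for s, e in covered:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        no_support = (window[1] - window[0]) - sum(e - s for s, e in merged)

    return SpatioTemporalRecord(
        limb=limb,
        cycle_time=cycle_time,
        stance_time=stance_time,
        swing_time=swing_time,
        stance_pct=100.0 * stance_time / cycle_time,
        swing_pct=100.0 * swing_time / cycle_time,
        step_length=step_length,
        step_time=step_time,
        stride_length=stride_length,
        stride_width=stride_width,
        double_support_time=double_support,
        no_support_time=no_support,
        speed=stride_length / cycle_time,
        duty_factor=stance_time / cycle_time,
    )


def compute_lags(events: list[GaitEvent], pace_tolerance: float = 1.0
                 ) -> LagSummary:
    """F/H/P lags as % of cycle duration, averaged over available cycles.

    Each lag is the delay from the reference limb's IC to the other limb's IC
    within the reference limb's concurrent cycle, modulo 100.  A pair delay
    within ``pace_tolerance`` of 0 (or 100) is reported as 100, the printed
    convention for a pace.
    """
    def ics(limb: Limb) -> list[float]:
        return sorted(e.time for e in events
                      if e.limb == limb and e.kind == "IC")

    def mean_lag(ref: Limb, other: Limb) -> tuple[float, int]:
        ref_ics, other_ics = ics(ref), ics(other)
        if len(ref_ics) < 2:
            raise ValueError(f"limb {ref.label} has fewer than 2 IC events")
        if not other_ics:
            raise ValueError(f"limb {other.label} has no IC events")
        vals = []
        for t1, t2 in zip(ref_ics[:-1], ref_ics[1:]):
            inside = [t for t in other_ics if t1 <= t < t2]
            if inside:
                vals.append(100.0 * (inside[0] - t1) / (t2 - t1))
        if not vals:
            raise ValueError(
                f"no IC of {other.label} inside any cycle of {ref.label}")
        return float(np.mean(vals)), len(vals)

    rf, lf = Limb("right", "fore"), Limb("left", "fore")
    rh, lh = Limb("right", "hind"), Limb("left", "hind")
    f_lag, nf = mean_lag(rf, lf)
    h_lag, nh = mean_lag(rh, lh)
    p_vals = []
    for hind, fore in ((rh, rf), (lh, lf)):
        p, _n = mean_lag(hind, fore)
        p_vals.append(p)
    p_lag = float(np.mean(p_vals))
    if p_lag <= pace_tolerance or p_lag >= 100.0 - pace_tolerance:
        p_lag = 100.0
    return LagSummary(f_lag=f_lag, h_lag=h_lag, p_lag=p_lag,
                      n_cycles=min(nf, nh))


#: Display names for the aggregate table, mirroring the reported layout.
VARIABLE_NAMES = {
    "cycle_time": "Cycle Time (s)",
    "stance_time": "Stance Time (s)",
    "swing_time": "Swing Time (s)",
    "stance_pct": "Stance (%)",
    "swing_pct": "Swing (%)",
    "step_length": "Step Length (m)",
    "step_time": "Step Time (s)",
    "stride_length": "Stride Length (m)",
    "stride_width": "Stride Width (m)",
    "double_support_time": "Double Limb Support Time (s)",
    "no_support_time": "No Support Time (s)",
    "speed": "Speed (m/s)",
    "duty_factor": "Duty Factor",
}

#: Variables pooled across left and right in the report layout.
POOLED_VARIABLES = ("stride_length", "stride_width", "double_support_time",
                    "no_support_time", "speed", "duty_factor")


def records_frame(records: list[SpatioTemporalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r) if f.name != "limb"}
        d["side"], d["girdle"] = r.limb.side, r.limb.girdle
        rows.append(d)
    return pd.DataFrame(rows)


def aggregate(records: list[SpatioTemporalRecord]) -> pd.DataFrame:
    """Mean and sample (n-1) SD of every variable, per limb side and pooled.

    Single-record groups report SD = 0 with n = 1 visible in the table.
    Rows: (Limb, Statistic); columns: the named gait variables.
    """
    if not records:
        raise ValueError("aggregate needs at least one record")
    df = records_frame(records)
    variables = list(VARIABLE_NAMES)
    rows = []
    groups = [("left", df[df.side == "left"]), ("right", df[df.side == "right"]),
              ("pooled", df)]
    for name, g in groups:
        if g.empty:
            continue
        mean_row = {"Limb": name, "Statistic": "mean", "n": len(g)}
        sd_row = {"Limb": name, "Statistic": "sd", "n": len(g)}
        for var in variables:
            vals = g[var].dropna().to_numpy()
            disp = VARIABLE_NAMES[var]
            mean_row[disp] = vals.mean() if len(vals) else np.nan
            sd_row[disp] = (vals.std(ddof=1) if len(vals) > 1
                            else (0.0 if len(vals) == 1 else np.nan))
        rows += [mean_row, sd_row]
    cols = ["Limb", "Statistic", "n"] + [VARIABLE_NAMES[v] for v in variables]
    return pd.DataFrame(rows)[cols]
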