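"""Segment coordinate frames and three-component joint angles.

Five segments (pelvis, thigh, shank, metatarsus, hoof) are built from the
landmark pairs that define each bone line plus one off-axis marker of the
same limb that resolves the segment plane; a two-marker segment leaves axial
rotation indeterminate, which is exactly what the shaft markers disambiguate.
Axis semantics: X = medio-lateral (flexion/extension axis), Y =
anterior-posterior (abduction/adduction axis), Z = longitudinal (axial
rotation axis).  Joint rotation = proximal-frame-transposed times distal
frame, decomposed in the intrinsic X-Y-Z Cardan sequence.

Component sign convention (as reported): flexion/dorsiflexion positive;
adduction positive, abduction negative; external rotation positive, internal
negative.  The left side mirrors the right through a sign flip of the second
and third components, so a symmetric gait yields identical reported curves
for both limbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import GaitCycle
from .markers import LandmarkMap, MarkerTrajectorySet

GIMBAL_GUARD_DEG = 85.0


# ---------------------------------------------------------------------------
# Cardan (intrinsic X-Y-Z) rotation algebra
# ---------------------------------------------------------------------------

def cardan_compose(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices from (alpha, beta, gamma) about body-fixed X, then
    rotated Y, then rotated Z.  Accepts shape (3,) or (n, 3)."""
    a = np.deg2rad(np.atleast_2d(angles_deg))
    ca, sa = np.cos(a[:, 0]), np.sin(a[:, 0])
    cb, sb = np.cos(a[:, 1]), np.sin(a[:, 1])
    cc, sc = np.cos(a[:, 2]), np.sin(a[:, 2])
    R = np.empty((len(a), 3, 3))
    R[:, 0, 0] = cb * cc
    R[:, 0, 1] = -cb * sc
    R[:, 0, 2] = sb
    R[:, 1, 0] = ca * sc + sa * sb * cc
    R[:, 1, 1] = ca * cc - sa * sb * sc
    R[:, 1, 2] = -sa * cb
    R[:, 2, 0] = sa * sc - ca * sb * cc
    R[:, 2, 1] = sa * cc + ca * sb * sc
    R[:, 2, 2] = ca * cb
    return R[0] if np.ndim(angles_deg) == 1 else R


def cardan_decompose(rotation: np.ndarray, warn_gimbal: bool = True
                     ) -> np.ndarray:
    """Cardan X-Y-Z angles (degrees) of one or many rotation matrices.

    The second angle is reported in (-90, 90); proximity to gimbal lock
    (|beta| > 85 deg) raises a warning, not an error.
    """
    R = np.atleast_3d(rotation) if rotation.ndim == 2 else rotation
    single = rotation.ndim == 2
    if single:
        R = rotation[None]
    beta = np.arcsin(np.clip(R[:, 0, 2], -1.0, 1.0))
    alpha = np.arctan2(-R[:, 1, 2], R[:, 2, 2])
    gamma = np.arctan2(-R[:, 0, 1], R[:, 0, 0])
    out = np.degrees(np.stack([alpha, beta, gamma], axis=1))
    if warn_gimbal and np.any(np.abs(out[:, 1]) > GIMBAL_GUARD_DEG):
        warnings.warn("Cardan decomposition close to gimbal lock "
                      f"(|second angle| > {GIMBAL_GUARD_DEG} deg)")
    return out[0] if single else out


def relative_rotation(prox_basis: np.ndarray, dist_basis: np.ndarray
                      ) -> np.ndarray:
    """Per-frame rotation of the distal frame expressed in the proximal one:
    ``R = prox^T . dist``."""
    if prox_basis.shape != dist_basis.shape:
        raise ValueError("proximal and distal series must have equal shapes")
    return np.einsum("...ji,...jk->...ik", prox_basis, dist_basis)


# ---------------------------------------------------------------------------
# Segment model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentRecipe:
    """Construction rule: bone line from ``proximal`` to ``distal``, segment
    plane resolved by the off-axis ``plane`` landmark."""

    proximal: str
    distal: str
    plane: str


@dataclass
class SegmentModel:
    """The five-segment chain pelvis-thigh-shank-metatarsus(-hoof) of one side."""

    side: str
    segments: dict[str, SegmentRecipe] = field(default_factory=dict)
    joints: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.segments:
            self.segments = {
                "pelvis": SegmentRecipe("ischial_tuberosity", "coxal_tuberosity",
                                        "greater_trochanter"),
                "thigh": SegmentRecipe("greater_trochanter", "knee",
                                       "femoral_shaft"),
                "shank": SegmentRecipe("knee", "calcaneus", "tibial_shaft"),
                "metatarsus": SegmentRecipe("calcaneus", "metatarsophalangeal",
                                            "metatarsal_shaft"),
                "hoof": SegmentRecipe("metatarsophalangeal", "distal_phalanx",
                                      "metatarsal_shaft"),
            }
        if not self.joints:
            self.joints = {"hip": ("pelvis", "thigh"),
                           "knee": ("thigh", "shank"),
                           "ankle": ("shank", "metatarsus")}
        if len(self.segments) != 5 or len(self.joints) != 3:
            raise ValueError("model must have exactly 5 segments and 3 joints")
        for joint, (p, d) in self.joints.items():
            if p not in self.segments or d not in self.segments:
                raise ValueError(f"joint {joint} references unknown segments")

    @property
    def plane_sign(self) -> float:
        # right side: the plane markers sit laterally (negative segment X)
        return -1.0 if self.side == "right" else 1.0

    @property
    def clinical_sign(self) -> float:
        # mirror abd/add and axial rotation on the left so both sides share
        # the reported sign convention
        return 1.0 if self.side == "right" else -1.0


@dataclass
class SegmentFrameSeries:
    """Per-frame origin and right-handed orthonormal basis of one segment.

    ``basis[n]`` columns are the X, Y, Z axes in lab coordinates.
    """

    segment: str
    origin: np.ndarray   # (n, 3)
    basis: np.ndarray    # (n, 3, 3)

    @property
    def n_frames(self) -> int:
        return self.basis.shape[0]


def segment_basis(prox: np.ndarray, dist: np.ndarray, plane: np.ndarray,
                  plane_sign: float = 1.0, min_angle_deg: float = 1.0,
                  segment: str = "?") -> np.ndarray:
    """Orthonormal bases from landmark trajectories.

    Z runs from the proximal to the distal landmark; Y = plane_sign *
    unit(Z x (plane - proximal)); X = Y x Z.  Raises on near-collinear
    construction markers, naming the first offending frame.
    """
    prox, dist, plane = (np.atleast_2d(np.asarray(p, float))
                         for p in (prox, dist, plane))
    z = dist - prox
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(zn < 1e-12):
        raise ValueError(f"{segment}: coincident line landmarks")
    z = z / zn
    v = plane - prox
    vn = np.linalg.norm(v, axis=1, keepdims=True)
    cosang = np.abs(np.sum(z * (v / np.maximum(vn, 1e-12)), axis=1))
    bad = np.flatnonzero(cosang > np.cos(np.deg2rad(min_angle_deg)))
    if bad.size:
        raise ValueError(
            f"{segment}: construction markers collinear (< {min_angle_deg} deg)"
            f" at frame {int(bad[0])}")
    y = plane_sign * np.cross(z, v)
    y = y / np.linalg.norm(y, axis=1, keepdims=True)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=2)


def build_frames(mset: MarkerTrajectorySet, lmap: LandmarkMap,
                 model: SegmentModel) -> dict[str, SegmentFrameSeries]:
    """The five segment frame series of one body side.

    Origins sit at the midpoint of the two line landmarks, a center-of-mass
    proxy.  All demanded landmarks must be present and gap-free.
    """
    side = model.side
    frames: dict[str, SegmentFrameSeries] = {}
    for name, recipe in model.segments.items():
        points = {}
        for role in ("proximal", "distal", "plane"):
            lm = getattr(recipe, role)
            if not lmap.has(side, lm):
                raise KeyError(f"missing landmark ({side}, {lm}) "
                               f"needed for segment {name}")
            label = lmap.label_for(side, lm)
            if mset.gaps(label).any():
                raise ValueError(
                    f"landmark ({side}, {lm}) has unfilled gaps; fill or "
                    "restrict the span before building frames")
            points[role] = mset.get(label)
        basis = segment_basis(points["proximal"], points["distal"],
                              points["plane"], model.plane_sign,
                              segment=f"{side} {name}")
        origin = 0.5 * (points["proximal"] + points["distal"])
        frames[name] = SegmentFrameSeries(name, origin, basis)
    return frames


# ---------------------------------------------------------------------------
# Joint angles
# ---------------------------------------------------------------------------

@dataclass
class JointAngleSeries:
    """Three-component angle trajectory of one joint, in degrees.

    Components: flexion/extension, abduction/adduction, internal/external
    rotation.  Normalized series have exactly 101 samples with samples 0 and
    100 at IC, and carry the cycle's stance fraction.
    """

    joint: str
    data: np.ndarray              # (n, 3) degrees
    rate: float | None = None     # None once normalized
    normalized: bool = False
    stance_fraction: float | None = None
    reference: str = "anatomical"

    COMPONENTS = ("flexion_extension", "abduction_adduction", "axial_rotation")

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n, 3)")
        if self.normalized and self.data.shape[0] != 101:
            raise ValueError("normalized series must have 101 samples")


def _unwrap_deg(data: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(data), axis=0))


def joint_angles(frames: dict[str, SegmentFrameSeries], model: SegmentModel,
                 static: dict[str, SegmentFrameSeries] | None = None,
                 clinical_signs: bool = True) -> dict[str, JointAngleSeries]:
    """Cardan joint angles for hip, knee and ankle.

    With a standing trial in ``static``, the standing posture's mean angles
    are subtracted (reference = "static-offset"); otherwise angles are
    reported against the anatomical segment frames directly.  Components are
    unwrapped so no inter-sample jump exceeds 180 degrees.
    """
    sign = model.clinical_sign if clinical_signs else 1.0
    comp_signs = np.array([1.0, sign, sign])
    out: dict[str, JointAngleSeries] = {}
    for joint, (prox, dist) in model.joints.items():
        rel = relative_rotation(frames[prox].basis, frames[dist].basis)
        ang = cardan_decompose(rel) * comp_signs
        ang = _unwrap_deg(ang)
        reference = "anatomical"
        if static is not None:
            for seg in (prox, dist):
                if seg not in static:
                    raise KeyError(
                        f"static trial lacks segment {seg} needed for {joint}")
            srel = relative_rotation(static[prox].basis, static[dist].basis)
            soff = (cardan_decompose(srel) * comp_signs).mean(axis=0)
            ang = ang - soff
            reference = "static-offset"
        out[joint] = JointAngleSeries(joint, ang, reference=reference)
    return out


def normalize_to_cycle(series: JointAngleSeries, cycle: GaitCycle,
                       rate: float, n: int = 101) -> JointAngleSeries:
    """Linear time-interpolation onto ``n`` equally spaced points over
    [IC, next IC]; TO maps to its fractional position (stance fraction)."""
    if series.normalized:
        raise ValueError("series is already normalized")
    n_frames = series.data.shape[0]
    if not (0 <= cycle.ic_frame and cycle.next_ic_frame < n_frames):
        raise ValueError("cycle lies outside the series span")
    frames = np.linspace(cycle.ic_frame, cycle.next_ic_frame, n)
    grid = np.arange(n_frames, dtype=float)
    data = np.column_stack(
        [np.interp(frames, grid, series.data[:, k]) for k in range(3)])
    return JointAngleSeries(series.joint, data, rate=None, normalized=True,
                            stance_fraction=cycle.duty_factor,
                            reference=series.reference)


@dataclass
class JointEventSummary:
    """Mean +/- SD (sample, across cycles) of each component at the gait
    events IC, STANCEmin, STANCEmax, TO, SWINGmin, SWINGmax."""

    joint: str
    mean: dict[str, dict[str, float]]   # component -> event -> value
    sd: dict[str, dict[str, float]]
    n: int

    EVENTS = ("IC", "STANCEmin", "STANCEmax", "TO", "SWINGmin", "SWINGmax")

    def table(self):
        import pandas as pd
        rows = []
        for comp in JointAngleSeries.COMPONENTS:
            for event in self.EVENTS:
                rows.append({"joint": self.joint, "component": comp,
                             "event": event, "mean": self.mean[comp][event],
                             "sd": self.sd[comp][event], "n": self.n})
        return pd.DataFrame(rows)


def _event_values(data: np.ndarray, stance_fraction: float) -> dict[str, np.ndarray]:
    to_idx = int(round(stance_fraction * 100))
    to_idx = min(max(to_idx, 1), 99)
    return {
        "IC": data[0],
        "STANCEmin": data[: to_idx + 1].min(axis=0),
        "STANCEmax": data[: to_idx + 1].max(axis=0),
        "TO": data[to_idx],
        "SWINGmin": data[to_idx + 1:].min(axis=0),
        "SWINGmax": data[to_idx + 1:].max(axis=0),
    }


def summarize_events(series: list[JointAngleSeries] | JointAngleSeries,
                     stance_fraction: float | None = None) -> JointEventSummary:
    """Event summary of one or many normalized cycles of the same joint.

    Stance extrema run over samples [0, TO] and swing extrema over (TO, 100];
    the TO sample itself sits on the stance/swing boundary.
    """
    if isinstance(series, JointAngleSeries):
        series = [series]
    if not series:
        raise ValueError("no series given")
    joint = series[0].joint
    per_cycle: dict[str, list[np.ndarray]] = {e: [] for e in JointEventSummary.EVENTS}
    for s in series:
        if not s.normalized:
            raise ValueError("summarize_events needs normalized series")
        sf = stance_fraction if stance_fraction is not None else s.stance_fraction
        if sf is None or not 0 < sf < 1:
            raise ValueError("stance fraction must lie in (0, 1)")
        vals = _event_values(s.data, sf)
        for e, v in vals.items():
            per_cycle[e].append(v)
    comps = JointAngleSeries.COMPONENTS
    mean = {c: {} for c in comps}
    sd = {c: {} for c in comps}
    n = len(series)
    for e, arrs in per_cycle.items():
        arr = np.stack(arrs)
        m = arr.mean(axis=0)
        s_ = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(3)
        for k, c in enumerate(comps):
            mean[c][e] = float(m[k])
            sd[c][e] = float(s_[k])
    return JointEventSummary(joint, mean, sd, n)


def mean_curve(series: list[JointAngleSeries]) -> JointAngleSeries:
    """Pointwise mean of normalized cycles (the ensemble-average curve)."""
    if not series:
        raise ValueError("no series given")
    data = np.mean([s.data for s in series], axis=0)
    sf = float(np.mean([s.stance_fraction for s in series]))
    return JointAngleSeries(series[0].joint, data, normalized=True,
                            stance_fraction=sf, reference=series[0].reference)
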