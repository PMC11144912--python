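"""Forward-kinematic generator of 22-marker sheep walking trials.

The generator emulates an overground lateral-sequence walk captured at
100 Hz: ten markers per hindlimb/pelvis side plus one distal forelimb marker
per side.  Each hindlimb is a rigid chain pelvis-thigh-shank-metatarsus-hoof
whose joint angles follow periodic profiles interpolated through per-phase
anchor values (means of the reported gait events).  The distal hoof marker is
anchored to an analytic contact schedule -- pinned to the floor for exactly
the duty-factor fraction of each cycle, swung forward by one stride length
otherwise -- and the chain is placed distally-to-proximally from it, so
contact timing, stride geometry, and joint angle curves are all known
exactly.  Every quantity the analysis pipeline estimates is available as
ground truth for parameter-recovery testing.

Timing and angle defaults are anchored on the reported means for healthy
adult Merino sheep walking at self-selected speed (cycle time 0.602 s, duty
factor 0.61, stride 0.695 m, stride width 0.191 m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .events import GaitEvent
from .kinematics import _event_values, cardan_compose
from .markers import ALL_LIMBS, LandmarkMap, Limb, MarkerTrajectorySet

# pelvis basis in the lab frame (columns X, Y, Z): X to the animal's left,
# Y up, Z along the direction of progression
_R_PELVIS = np.array([[0.0, 0.0, 1.0],
                      [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0]])
_MIRROR = np.diag([1.0, -1.0, 1.0])       # sagittal-plane reflection (y -> -y)
_HAND_FIX = np.diag([-1.0, 1.0, 1.0])     # restores right-handedness


#: Joint-angle anchors (phase in [0,1), degrees) at the gait events IC,
#: stance extrema, TO and swing extrema.  Hip carries all three components
#: and the ankle its frontal inversion/eversion from the reported event
#: table; remaining non-sagittal components default to small amplitudes.
DEFAULT_ANCHORS: dict[str, dict[str, list[tuple[float, float]]]] = {
    "hip": {
        "flexion_extension": [(0.00, 5.485), (0.50, 31.899),
                              (0.61, 31.231), (0.90, 4.135)],
        "abduction_adduction": [(0.00, -4.439), (0.15, -4.464), (0.50, 1.658),
                                (0.61, 1.336), (0.90, -5.438)],
        "axial_rotation": [(0.00, -7.765), (0.10, -8.423), (0.50, 2.129),
                           (0.61, 2.117), (0.90, -14.950)],
    },
    "knee": {
        "flexion_extension": [(0.00, 46.869), (0.61, 69.387),
                              (0.80, 80.622), (0.95, 46.384)],
        "abduction_adduction": [(0.00, 1.5), (0.30, -2.0), (0.61, 1.0),
                                (0.85, -2.5)],
        "axial_rotation": [(0.00, -2.0), (0.35, 2.0), (0.61, -1.5),
                           (0.85, 2.5)],
    },
    "ankle": {
        "flexion_extension": [(0.00, 45.448), (0.15, 38.030), (0.45, 56.225),
                              (0.61, 40.804), (0.80, 80.668)],
        "abduction_adduction": [(0.00, 13.682), (0.10, 15.184),
                                (0.40, -20.501), (0.61, -19.954),
                                (0.85, 15.207)],
        "axial_rotation": [(0.00, 3.0), (0.40, -3.5), (0.61, -2.5),
                           (0.85, 3.5)],
    },
}


class PeriodicProfile:
    """C1 periodic interpolant through (phase, value) anchors.

    Uses a monotone piecewise-cubic (PCHIP) fit on periodically extended
    anchors: the curve passes through every anchor exactly and never
    overshoots between them, so profile extrema sit at anchor values.
    """

    def __init__(self, anchors):
        pts = sorted((float(p), float(v)) for p, v in anchors)
        phases = np.array([p for p, _ in pts])
        values = np.array([v for _, v in pts])
        if np.any(phases < 0) or np.any(phases >= 1):
            raise ValueError("anchor phases must lie in [0, 1)")
        if np.any(np.diff(phases) <= 0):
            raise ValueError("duplicate anchor phases")
        self.phases, self.values = phases, values
        if len(pts) == 1:
            self._interp = None
        else:
            x = np.concatenate([phases - 1.0, phases, phases + 1.0])
            y = np.concatenate([values, values, values])
            self._interp = PchipInterpolator(x, y)

    def __call__(self, phase):
        phase = np.mod(np.asarray(phase, float), 1.0)
        if self._interp is None:
            return np.full_like(phase, self.values[0], dtype=float)
        return self._interp(phase)


def profiles_from_anchors(anchors, duty_factor: float | None = None):
    """Build periodic profiles from anchors; mirrors the input nesting.

    ``anchors`` is either a list of (phase, value) pairs or a (nested) dict
    whose leaves are such lists.  ``duty_factor`` is validated against (0,1)
    when given; anchor phases carry the event timing explicitly.
    """
    if duty_factor is not None and not 0 < duty_factor < 1:
        raise ValueError("duty_factor must lie in (0, 1)")
    if isinstance(anchors, dict):
        return {k: profiles_from_anchors(v) for k, v in anchors.items()}
    return PeriodicProfile(anchors)


@dataclass
class SyntheticGaitConfig:
    """Generator parameters; defaults are the study conditions."""

    cycle_time: float = 0.602          # s
    duty_factor: float = 0.61          # stance fraction
    stride_length: float = 0.695       # m
    stride_width: float = 0.191        # m, hind contact-point separation
    fore_stride_width: float = 0.162   # m
    step_split: float = 0.3745         # m, left-hind step; right = stride - split
    n_cycles: int = 20
    rate: float = 100.0                # Hz
    marker_noise_sd: float = 0.001     # m, i.i.d. Gaussian per coordinate
    seed: int = 42
    segment_lengths: dict[str, float] = field(default_factory=lambda: {
        "pelvis": 0.25, "thigh": 0.25, "shank": 0.30,
        "metatarsus": 0.20, "hoof": 0.06})
    joint_anchor_angles: dict = field(
        default_factory=lambda: {j: {c: list(a) for c, a in comps.items()}
                                 for j, comps in DEFAULT_ANCHORS.items()})
    limb_phase_offsets: dict[str, float] = field(default_factory=lambda: {
        "right hind": 0.0, "right fore": 0.25,
        "left hind": 0.5, "left fore": 0.75})
    swing_clearance: float = 0.08      # m, peak hoof lift
    hoof_stance_height: float = 0.02   # m, hoof marker height during stance
    plane_marker_offset: float = 0.05  # m, off-axis shaft-marker standoff
    hoof_pitch_deg: float = 30.0       # constant hoof-vs-metatarsus pitch
    fore_offset: float = 0.9           # m, fore hooves ahead of hind
    start_x: float = 0.3               # m, first right-hind contact position

    def __post_init__(self):
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must lie in (0, 1)")
        for name in ("cycle_time", "stride_length", "rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.marker_noise_sd < 0:
            raise ValueError("marker_noise_sd must be >= 0")

    @property
    def speed(self) -> float:
        """Mean progression speed implied by stride and cycle time."""
        return self.stride_length / self.cycle_time

    def profiles(self):
        return profiles_from_anchors(self.joint_anchor_angles, self.duty_factor)


def default_reference_config() -> SyntheticGaitConfig:
    """The reference condition: timing, stride geometry and joint-angle
    anchors set to the reported means, 100 Hz, 1 mm marker noise,
    lateral-sequence footfall order right hind - right fore - left hind -
    left fore."""
    return SyntheticGaitConfig()


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a synthetic trial."""

    config: SyntheticGaitConfig
    profiles: dict                      # joint -> component -> PeriodicProfile
    events: list[GaitEvent]             # exact scheduled contacts
    cycle_time: float
    duty_factor: float
    stance_time: float
    swing_time: float
    stride_length: float
    stride_width: float
    fore_stride_width: float
    step_length: dict[str, float]       # side -> m (hind pair)
    step_time: dict[str, float]
    double_support_time: float
    no_support_time: float
    speed: float
    f_lag: float
    h_lag: float
    p_lag: float
    clean_set: MarkerTrajectorySet | None = None
    rotations: dict = field(default_factory=dict)  # (side, segment) -> (n,3,3)

    def joint_curve(self, joint: str, phase) -> np.ndarray:
        """Prescribed (flex, abd, axial) profile of a joint at given phases."""
        comps = self.profiles[joint]
        return np.stack([comps["flexion_extension"](phase),
                         comps["abduction_adduction"](phase),
                         comps["axial_rotation"](phase)], axis=-1)

    def event_summary(self, joint: str) -> dict[str, dict[str, float]]:
        """True event values on the 101-sample normalized grid."""
        grid = np.linspace(0.0, 1.0, 101)
        data = self.joint_curve(joint, grid)
        vals = _event_values(data, self.duty_factor)
        comps = ("flexion_extension", "abduction_adduction", "axial_rotation")
        return {c: {e: float(v[k]) for e, v in vals.items()}
                for k, c in enumerate(comps)}


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------

_SWING_BLEND = 0.2  # linear share of the swing advance profile


def _swing_advance(s: np.ndarray) -> np.ndarray:
    """Normalized forward advance over the swing: a cubic smoothstep blended
    with a linear term, so the hoof leaves and lands with nonzero forward
    velocity (a crisp lift-off/touch-down, as in real hoof kinematics)."""
    smooth = s * s * (3.0 - 2.0 * s)
    return (1.0 - _SWING_BLEND) * smooth + _SWING_BLEND * s


def _hoof_anchor(t: np.ndarray, T: float, duty: float, phase_offset: float,
                 x0: float, stride: float, clearance: float, z0: float):
    """Analytic hoof trajectory: pinned during stance, smooth advance with
    squared-sine lift during swing."""
    u = t / T - phase_offset
    k = np.floor(u)
    psi = u - k
    stance = psi < duty
    s = np.clip((psi - duty) / (1.0 - duty), 0.0, 1.0)
    x = x0 + (k + np.where(stance, 0.0, _swing_advance(s))) * stride
    z = z0 + np.where(stance, 0.0, clearance * np.sin(np.pi * s) ** 2)
    return x, z


def _schedule_events(limb: Limb, T: float, duty: float, phase_offset: float,
                     t_end: float, rate: float) -> list[GaitEvent]:
    events = []
    k = int(np.ceil(-phase_offset)) - 1
    while True:
        t_ic = (k + phase_offset) * T
        t_to = t_ic + duty * T
        if t_ic > t_end:
            break
        if t_ic >= 0:
            events.append(GaitEvent(limb, "IC", int(round(t_ic * rate)), t_ic))
        if 0 <= t_to <= t_end:
            events.append(GaitEvent(limb, "TO", int(round(t_to * rate)), t_to))
        k += 1
    return sorted(events, key=lambda e: e.time)


def _chain_positions(config: SyntheticGaitConfig, psi: np.ndarray,
                     anchor_x: np.ndarray, anchor_y: float,
                     anchor_z: np.ndarray, profiles):
    """Canonical (right-geometry) marker positions and segment rotations for
    one hindlimb, chained proximally from the anchored hoof marker."""
    lengths = config.segment_lengths
    d_pl = config.plane_marker_offset

    def angles(joint):
        comps = profiles[joint]
        return np.stack([comps["flexion_extension"](psi),
                         comps["abduction_adduction"](psi),
                         comps["axial_rotation"](psi)], axis=1)

    E_hip = cardan_compose(angles("hip"))
    E_knee = cardan_compose(angles("knee"))
    E_ankle = cardan_compose(angles("ankle"))
    R_t = np.einsum("ij,njk->nik", _R_PELVIS, E_hip)
    R_s = np.einsum("nij,njk->nik", R_t, E_knee)
    R_m = np.einsum("nij,njk->nik", R_s, E_ankle)
    R_h = np.einsum("nij,jk->nik", R_m, cardan_compose(
        np.array([config.hoof_pitch_deg, 0.0, 0.0])))

    Xp, Yp, Zp = _R_PELVIS[:, 0], _R_PELVIS[:, 1], _R_PELVIS[:, 2]
    Zt, Xt = R_t[:, :, 2], R_t[:, :, 0]
    Zs, Xs = R_s[:, :, 2], R_s[:, :, 0]
    Zm, Xm = R_m[:, :, 2], R_m[:, :, 0]
    Zh = R_h[:, :, 2]

    p10 = np.column_stack([anchor_x, np.full_like(anchor_x, anchor_y), anchor_z])
    p9 = p10 - lengths["hoof"] * Zh
    p7 = p9 - lengths["metatarsus"] * Zm
    p8 = p7 + 0.04 * Zm - d_pl * Xm
    p5 = p7 - lengths["shank"] * Zs
    p6 = p7 - 0.5 * lengths["shank"] * Zs - d_pl * Xs
    p3 = p5 - lengths["thigh"] * Zt
    p4 = p5 - 0.5 * lengths["thigh"] * Zt - d_pl * Xt
    p2 = p3 - 0.12 * Zp + 0.08 * Xp
    p1 = p2 + lengths["pelvis"] * Zp

    n = len(psi)
    positions = {
        "coxal_tuberosity": p1, "ischial_tuberosity": p2,
        "greater_trochanter": p3, "femoral_shaft": p4, "knee": p5,
        "tibial_shaft": p6, "calcaneus": p7, "metatarsal_shaft": p8,
        "metatarsophalangeal": p9, "distal_phalanx": p10,
    }
    rotations = {
        "pelvis": np.broadcast_to(_R_PELVIS, (n, 3, 3)).copy(),
        "thigh": R_t, "shank": R_s, "metatarsus": R_m, "hoof": R_h,
    }
    return positions, rotations


def synthesize_trial(config: SyntheticGaitConfig
                     ) -> tuple[MarkerTrajectorySet, GroundTruth]:
    """Generate one noisy walking trial plus its exact ground truth.

    The trial spans ``n_cycles + 1.3`` cycles so that every limb contributes
    at least ``n_cycles`` complete IC-TO-IC triples after the leading partial
    stance is discarded.  Output is bit-reproducible for a fixed seed.
    """
    T, d, L, rate = (config.cycle_time, config.duty_factor,
                     config.stride_length, config.rate)
    n_frames = int(round((config.n_cycles + 1.3) * T * rate)) + 1
    t = np.arange(n_frames) / rate
    t_end = t[-1]
    profiles = config.profiles()
    phases = config.limb_phase_offsets

    x0 = {
        Limb("right", "hind"): config.start_x,
        Limb("left", "hind"): config.start_x + config.step_split,
        Limb("right", "fore"): config.start_x + config.fore_offset,
        Limb("left", "fore"): config.start_x + config.fore_offset + 0.5 * L,
    }
    y_half = {"hind": config.stride_width / 2.0,
              "fore": config.fore_stride_width / 2.0}

    lmap = LandmarkMap.default()
    labels = list(lmap.assignments)
    positions = np.zeros((n_frames, len(labels), 3))
    rotations: dict[tuple[str, str], np.ndarray] = {}
    events: list[GaitEvent] = []

    for limb in ALL_LIMBS:
        phi = phases[limb.label]
        xa, za = _hoof_anchor(t, T, d, phi, x0[limb], L,
                              config.swing_clearance, config.hoof_stance_height)
        events.extend(_schedule_events(limb, T, d, phi, t_end, rate))
        mirror = limb.side == "left"
        if limb.girdle == "fore":
            p11 = np.column_stack(
                [xa, np.full_like(xa, -y_half["fore"]), za])
            if mirror:
                p11 = p11 @ _MIRROR
            positions[:, labels.index(lmap.label_for(limb.side, "fore_hoof"))] = p11
            continue
        psi = np.mod(t / T - phi, 1.0)
        pos, rots = _chain_positions(config, psi, xa, -y_half["hind"], za,
                                     profiles)
        for lm, p in pos.items():
            if mirror:
                p = p @ _MIRROR
            positions[:, labels.index(lmap.label_for(limb.side, lm))] = p
        for seg, R in rots.items():
            if mirror:
                R = np.einsum("ij,njk,kl->nil", _MIRROR, R, _HAND_FIX)
            rotations[(limb.side, seg)] = R

    hoof_cols = [labels.index(lmap.label_for(s, lm))
                 for s in ("left", "right")
                 for lm in ("distal_phalanx", "fore_hoof")]
    other = [j for j in range(len(labels)) if j not in hoof_cols]
    min_z = positions[:, other, 2].min()
    if min_z < -0.005:
        warnings.warn(
            f"synthetic geometry dips {-min_z * 1e3:.1f} mm below the floor; "
            "check segment lengths / anchors")

    clean = MarkerTrajectorySet(
        labels=labels, positions=positions.copy(), rate=rate,
        meta={"format": "synthetic", "seed": config.seed})
    noisy_positions = positions
    if config.marker_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        noisy_positions = positions + rng.normal(
            0.0, config.marker_noise_sd, positions.shape)
    mset = MarkerTrajectorySet(
        labels=labels, positions=noisy_positions, rate=rate,
        meta={"format": "synthetic", "seed": config.seed,
              "noise_sd": config.marker_noise_sd})

    # pair-support truth for the hind pair (phase shift s, duty d)
    s_shift = (phases["left hind"] - phases["right hind"]) % 1.0

    def overlap(a0, a1, b0, b1):
        return max(0.0, min(a1, b1) - max(a0, b0))

    ds_frac = sum(overlap(0.0, d, b, b + d)
                  for b in (s_shift, s_shift - 1.0, s_shift + 1.0))
    grid = np.linspace(0.0, 1.0, 20001)[:-1]
    in_r = np.mod(grid, 1.0) < d
    in_l = np.mod(grid - s_shift, 1.0) < d
    no_support_frac = float(np.mean(~(in_r | in_l)))

    truth = GroundTruth(
        config=config, profiles=profiles, events=events,
        cycle_time=T, duty_factor=d, stance_time=d * T,
        swing_time=(1.0 - d) * T, stride_length=L,
        stride_width=config.stride_width,
        fore_stride_width=config.fore_stride_width,
        step_length={"left": config.step_split, "right": L - config.step_split},
        step_time={"left": s_shift * T, "right": (1.0 - s_shift) * T},
        double_support_time=ds_frac * T,
        no_support_time=no_support_frac * T,
        speed=L / T,
        f_lag=100.0 * ((phases["left fore"] - phases["right fore"]) % 1.0),
        h_lag=100.0 * s_shift,
        p_lag=100.0 * ((phases["right fore"] - phases["right hind"]) % 1.0),
        clean_set=clean, rotations=rotations,
    )
    return mset, truth


def synthesize_static(config: SyntheticGaitConfig, duration_s: float = 1.0,
                      ) -> tuple[MarkerTrajectorySet, dict]:
    """A standing trial: all four hooves grounded, joint angles frozen at
    their initial-contact values.  Returns the trial and the true standing
    angles per joint."""
    n_frames = max(2, int(round(duration_s * config.rate)))
    profiles = config.profiles()
    standing = {j: {c: [(0.0, float(profiles[j][c](0.0)))]
                    for c in profiles[j]} for j in profiles}
    static_cfg = replace(
        config, joint_anchor_angles=standing, n_cycles=1,
        marker_noise_sd=0.0)
    lmap = LandmarkMap.default()
    labels = list(lmap.assignments)
    positions = np.zeros((n_frames, len(labels), 3))
    psi = np.zeros(n_frames)
    static_profiles = static_cfg.profiles()
    for side in ("left", "right"):
        xa = np.full(n_frames, config.start_x)
        za = np.full(n_frames, config.hoof_stance_height)
        pos, _rots = _chain_positions(static_cfg, psi, xa,
                                      -config.stride_width / 2.0, za,
                                      static_profiles)
        for lm, p in pos.items():
            if side == "left":
                p = p @ _MIRROR
            positions[:, labels.index(lmap.label_for(side, lm))] = p
        p11 = np.column_stack([
            np.full(n_frames, config.start_x + config.fore_offset),
            np.full(n_frames, -config.fore_stride_width / 2.0), za])
        if side == "left":
            p11 = p11 @ _MIRROR
        positions[:, labels.index(lmap.label_for(side, "fore_hoof"))] = p11
    mset = MarkerTrajectorySet(labels=labels, positions=positions,
                               rate=config.rate,
                               meta={"format": "synthetic-static"})
    true_angles = {j: np.array([standing[j][c][0][1] for c in
                                ("flexion_extension", "abduction_adduction",
                                 "axial_rotation")]) for j in standing}
    return mset, true_angles
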