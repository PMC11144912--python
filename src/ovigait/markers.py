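"""Labeled 3D marker trajectories, the anatomical landmark map, and trajectory cleaning.

The container holds one optoelectronic capture: a set of labeled markers sampled
at a fixed rate, with per-sample gap flags for frames where a marker was not
reconstructed.  All coordinates are stored in meters in a lab frame with Z up;
unit conversion happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

#: The 11 anatomical landmarks of the marker set: ten on each hindlimb/pelvis
#: plus one distal forelimb marker per side used as a ground-contact indicator.
LANDMARKS = (
    "coxal_tuberosity",        # 1. coxal tuberosity of the iliac wing
    "ischial_tuberosity",      # 2. ischial tuberosity
    "greater_trochanter",      # 3. greater trochanter of the femur
    "femoral_shaft",           # 4. craniolateral aspect of the femoral shaft
    "knee",                    # 5. femorotibiopatellar joint
    "tibial_shaft",            # 6. caudoproximal aspect of the tibial shaft
    "calcaneus",               # 7. base of the calcaneus
    "metatarsal_shaft",        # 8. caudoproximal aspect of the IV metatarsal
    "metatarsophalangeal",     # 9. metatarsophalangeal joint
    "distal_phalanx",          # 10. lateral aspect of the distal phalanx
    "fore_hoof",               # 11. distal phalanx of the forelimb
)

HIND_LANDMARKS = LANDMARKS[:10]
SIDES = ("left", "right")


class FormatError(ValueError):
    """A mocap file violates the expected format; the message names the field."""


@dataclass(frozen=True)
class Limb:
    """One limb, identified by body side and girdle."""

    side: str   # "left" | "right"
    girdle: str  # "hind" | "fore"

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.girdle not in ("hind", "fore"):
            raise ValueError(f"unknown girdle {self.girdle!r}")

    @property
    def label(self) -> str:
        return f"{self.side} {self.girdle}"

    @property
    def contralateral(self) -> "Limb":
        return Limb("left" if self.side == "right" else "right", self.girdle)

    @property
    def hoof_landmark(self) -> str:
        return "distal_phalanx" if self.girdle == "hind" else "fore_hoof"


ALL_LIMBS = (
    Limb("right", "hind"), Limb("right", "fore"),
    Limb("left", "hind"), Limb("left", "fore"),
)


@dataclass
class MarkerTrajectorySet:
    """Labeled 3D point time series with rate, units (meters), and gap mask.

    Attributes
    ----------
    labels : list of str
        Unique marker names, one per column of ``positions``.
    positions : ndarray, shape (n_frames, n_markers, 3)
        Coordinates in meters; NaN is allowed only where ``gap_mask`` is True.
    rate : float
        Sampling frequency in Hz.
    gap_mask : ndarray of bool, shape (n_frames, n_markers)
        True where the marker is missing.
    meta : dict
        Free-form provenance (source file, original units, ...).
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    gap_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("marker labels must be unique")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("positions second axis must match number of labels")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.positions.shape[:2], dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.positions.shape[:2]:
            raise ValueError("gap_mask shape must be (n_frames, n_markers)")
        if not np.all(np.isfinite(self.positions[~self.gap_mask])):
            raise ValueError("positions must be finite wherever gap_mask is False")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in set") from None

    def get(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        return self.positions[:, self.index(label), :]

    def gaps(self, label: str) -> np.ndarray:
        return self.gap_mask[:, self.index(label)]

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            list(self.labels), self.positions.copy(), self.rate,
            self.gap_mask.copy(), dict(self.meta),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "MarkerTrajectorySet":
        """Rigidly transform every marker: ``p -> R p + t``."""
        out = self.copy()
        if rotation is not None:
            out.positions = out.positions @ np.asarray(rotation, float).T
        if translation is not None:
            out.positions = out.positions + np.asarray(translation, float)
        return out


@dataclass
class LandmarkMap:
    """Assignment of marker labels to (side, anatomical landmark) pairs."""

    assignments: dict[str, tuple[str, str]]

    def __post_init__(self):
        seen = {}
        for label, (side, landmark) in self.assignments.items():
            if side not in SIDES:
                raise ValueError(f"unknown side {side!r} for marker {label!r}")
            if landmark not in LANDMARKS:
                raise ValueError(f"unknown landmark {landmark!r} for marker {label!r}")
            key = (side, landmark)
            if key in seen:
                raise ValueError(
                    f"landmark {key} assigned to both {seen[key]!r} and {label!r}")
            seen[key] = label
        self._by_landmark = seen

    @classmethod
    def default(cls) -> "LandmarkMap":
        """The canonical 22-marker labeling: ``L_``/``R_`` prefix + landmark name."""
        assignments = {}
        for side in SIDES:
            prefix = side[0].upper()
            for lm in LANDMARKS:
                assignments[f"{prefix}_{lm}"] = (side, lm)
        return cls(assignments)

    def label_for(self, side: str, landmark: str) -> str:
        try:
            return self._by_landmark[(side, landmark)]
        except KeyError:
            raise KeyError(f"no marker assigned to ({side}, {landmark})") from None

    def has(self, side: str, landmark: str) -> bool:
        return (side, landmark) in self._by_landmark

    def complete_hindlimb(self, side: str) -> bool:
        return all(self.has(side, lm) for lm in HIND_LANDMARKS)

    def limb_labels(self, limb: Limb) -> list[str]:
        """Labels required to analyze one limb (full chain for hind, hoof for fore)."""
        if limb.girdle == "hind":
            lms = HIND_LANDMARKS
        else:
            lms = ("fore_hoof",)
        return [self.label_for(limb.side, lm) for lm in lms if self.has(limb.side, lm)]


def _gap_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of consecutive True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def fill_gaps(mset: MarkerTrajectorySet, max_gap_frames: int = 10) -> MarkerTrajectorySet:
    """Fill interior gap runs of length <= ``max_gap_frames`` by cubic-spline
    interpolation over time; longer runs and edge gaps remain flagged.

    Non-gap samples are never altered.  The default of 10 frames corresponds to
    0.1 s at the 100 Hz capture rate.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    out = mset.copy()
    t = out.time
    for j in range(out.n_markers):
        mask = out.gap_mask[:, j]
        if not mask.any():
            continue
        valid = ~mask
        if valid.sum() < 2:
            continue
        tv = t[valid]
        if valid.sum() >= 4:
            interp = CubicSpline(tv, out.positions[valid, j, :], axis=0)
        else:
            def interp(tq, _tv=tv, _pv=out.positions[valid, j, :]):
                return np.column_stack(
                    [np.interp(tq, _tv, _pv[:, k]) for k in range(3)])
        for start, stop in _gap_runs(mask):
            interior = start > 0 and stop < out.n_frames
            if interior and (stop - start) <= max_gap_frames:
                out.positions[start:stop, j, :] = interp(t[start:stop])
                out.gap_mask[start:stop, j] = False
    return out


def lowpass_filter(mset: MarkerTrajectorySet, cutoff_hz: float = 6.0,
                   order: int = 4) -> MarkerTrajectorySet:
    """Zero-phase forward-backward Butterworth low-pass of every coordinate.

    Markers with remaining gaps are linearly bridged before filtering and the
    gap flags are retained; flagged samples must not be consumed downstream.
    """
    nyquist = mset.rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={nyquist} Hz), got {cutoff_hz}")
    b, a = butter(order, cutoff_hz / nyquist)
    out = mset.copy()
    t = out.time
    for j in range(out.n_markers):
        pos = out.positions[:, j, :]
        mask = out.gap_mask[:, j]
        if mask.any():
            valid = ~mask
            if valid.sum() < 2:
                continue
            pos = np.column_stack(
                [np.interp(t, t[valid], pos[valid, k]) for k in range(3)])
        out.positions[:, j, :] = filtfilt(b, a, pos, axis=0)
        out.positions[mask, j, :] = np.nan
    return out


def mirror_sagittal(mset: MarkerTrajectorySet, swap_sides: bool = True
                    ) -> MarkerTrajectorySet:
    """Mirror a trial across the sagittal (XZ) plane: y -> -y.

    With ``swap_sides`` the ``L_``/``R_`` label prefixes are exchanged, so a
    right-limb recording becomes an anatomically consistent left-limb one.
    """
    out = mset.copy()
    out.positions[:, :, 1] *= -1.0
    if swap_sides:
        def swap(label: str) -> str:
            if label.startswith("L_"):
                return "R_" + label[2:]
            if label.startswith("R_"):
                return "L_" + label[2:]
            return label
        out.labels = [swap(l) for l in out.labels]
    return out
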