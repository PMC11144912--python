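"""Angle-angle coordination plots (cyclograms) over the normalized gait cycle.

A cyclogram pairs one component (sagittal flexion/extension by default) of
two joints sample-by-sample over the 101-point normalized cycle, yielding a
closed path whose shape expresses interjoint coordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import JointAngleSeries


@dataclass
class Cyclogram:
    """Closed angle-angle path of a joint pair over one normalized cycle."""

    pair: tuple[str, str]
    path: np.ndarray           # (101, 2) degrees; columns follow `pair`
    to_index: int              # sample index of toe-off
    component: int = 0         # which angle component is paired

    @property
    def ic_index(self) -> int:
        return 0


def build_cyclogram(a: JointAngleSeries, b: JointAngleSeries,
                    stance_fraction: float | None = None,
                    component: int = 0) -> Cyclogram:
    """Pair component ``component`` of two normalized series on the same grid."""
    if not (a.normalized and b.normalized):
        raise ValueError("both series must be normalized to the cycle")
    if a.data.shape[0] != b.data.shape[0]:
        raise ValueError(
            f"mismatched grids: {a.data.shape[0]} vs {b.data.shape[0]} samples")
    sf = stance_fraction
    if sf is None:
        cand = [s.stance_fraction for s in (a, b) if s.stance_fraction is not None]
        if not cand:
            raise ValueError("no stance fraction available")
        sf = float(np.mean(cand))
    if not 0 < sf < 1:
        raise ValueError("stance fraction must lie in (0, 1)")
    to_index = min(max(int(round(sf * 100)), 1), 99)
    path = np.column_stack([a.data[:, component], b.data[:, component]])
    return Cyclogram((a.joint, b.joint), path, to_index, component)


def cyclogram_metrics(c: Cyclogram) -> tuple[float, float, float]:
    """(area, perimeter, orientation) of the closed path.

    Area is the absolute shoelace area in deg^2; perimeter the closed
    polyline length in deg; orientation the sign of the signed area
    (+1 = counter-clockwise progression, 0 for a degenerate path).
    """
    closed = np.vstack([c.path, c.path[:1]])
    x, y = closed[:, 0], closed[:, 1]
    signed = 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    orientation = float(np.sign(signed))
    return abs(signed), perimeter, orientation


def plot_cyclogram(c: Cyclogram, path, title: str | None = None) -> None:
    """Render the cyclogram with IC and TO annotated, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(c.path[:, 0], c.path[:, 1], "-", lw=1.2, color="k")
    ax.annotate("IC", c.path[0], color="tab:blue", fontweight="bold")
    ax.annotate("TO", c.path[c.to_index], color="tab:red", fontweight="bold")
    # progression arrows along the path
    for i in range(10, 101, 20):
        ax.annotate("", xy=c.path[i], xytext=c.path[i - 1],
                    arrowprops=dict(arrowstyle="->", color="0.4"))
    ax.set_xlabel(f"{c.pair[0]} angle (deg)")
    ax.set_ylabel(f"{c.pair[1]} angle (deg)")
    ax.set_title(title or f"{c.pair[0]}-{c.pair[1]} cyclogram")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
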