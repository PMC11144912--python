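"""Tab-separated mocap export dialect.

Header lines carry ``FREQUENCY`` and ``MARKER_NAMES``; each subsequent row is
one frame with three columns (x, y, z, in millimeters) per marker.  A literal
``0 0 0`` triplet is the export convention for a missing marker and is treated
as a gap by default; NaN cells are gaps as well.
"""

from __future__ import annotations

import numpy as np

from ..markers import FormatError, MarkerTrajectorySet


def read_mocap_tsv(path, zero_as_gap: bool = True) -> MarkerTrajectorySet:
    """Read the TSV dialect into a marker set in meters."""
    rate = None
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            key = cells[0].strip().upper()
            if key == "FREQUENCY":
                try:
                    rate = float(cells[1])
                except (IndexError, ValueError):
                    raise FormatError("FREQUENCY header is not a number") from None
            elif key == "MARKER_NAMES":
                labels = [c.strip() for c in cells[1:] if c.strip()]
            else:
                def cell(c: str) -> float:
                    c = c.strip()
                    if not c or c.upper() in ("NAN", "NULL"):
                        return np.nan
                    return float(c)
                rows.append([cell(c) for c in cells])
    if rate is None:
        raise FormatError("missing FREQUENCY header line")
    if labels is None:
        raise FormatError("missing MARKER_NAMES header line")
    n = len(labels)
    data = np.full((len(rows), 3 * n), np.nan)
    for i, row in enumerate(rows):
        if len(row) != 3 * n:
            raise FormatError(
                f"frame {i + 1} has {len(row)} columns, expected "
                f"{3 * n} (3 x {n} markers)")
        data[i] = row
    positions = data.reshape(len(rows), n, 3) * 0.001  # mm -> m
    gap = np.isnan(positions).any(axis=2)
    if zero_as_gap:
        gap |= (data.reshape(len(rows), n, 3) == 0.0).all(axis=2)
    positions = positions.copy()
    positions[gap] = np.nan
    return MarkerTrajectorySet(
        labels=labels, positions=positions, rate=rate, gap_mask=gap,
        meta={"source": str(path), "format": "tsv", "original_units": "mm"},
    )


def write_mocap_tsv(path, mset: MarkerTrajectorySet) -> None:
    """Write a marker set in the TSV dialect (millimeters, gaps as ``0 0 0``)."""
    coords = mset.positions * 1000.0  # m -> mm
    with open(path, "w", encoding="utf-8") as fh:
        rate = mset.rate
        fh.write(f"FREQUENCY\t{int(rate) if float(rate).is_integer() else rate}\n")
        fh.write("MARKER_NAMES\t" + "\t".join(mset.labels) + "\n")
        for i in range(mset.n_frames):
            cells = []
            for j in range(mset.n_markers):
                if mset.gap_mask[i, j]:
                    cells += ["0", "0", "0"]
                else:
                    cells += [f"{c:.9f}" for c in coords[i, j]]
            fh.write("\t".join(cells) + "\n")
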