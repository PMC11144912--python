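"""Minimal C3D reader/writer for labeled 3D point data.

Covers the subset of the C3D standard needed for marker-only gait trials:
Intel (little-endian) processor type, float or scaled-integer point data, and
the POINT parameter group (USED, FRAMES, RATE, SCALE, DATA_START, UNITS,
LABELS).  Analog channels are ignored on read and never written.
"""

from __future__ import annotations

import struct

import numpy as np

from ..markers import FormatError, MarkerTrajectorySet

_BLOCK = 512
_PROC_INTEL = 84

_UNIT_SCALE = {"m": 1.0, "mm": 0.001, "cm": 0.01, "dm": 0.1}


def _read_params(buf: bytes):
    """Parse the parameter section into {group: {param: (type, dims, raw)}}."""
    if len(buf) < 4:
        raise FormatError("parameter section truncated")
    proc = buf[3]
    if proc != _PROC_INTEL:
        raise FormatError(f"unsupported processor type {proc} (PROCESSOR)")
    groups: dict[int, str] = {}
    params: dict[int, dict[str, tuple]] = {}
    pos = 4
    while pos + 2 <= len(buf):
        nchar = struct.unpack_from("b", buf, pos)[0]
        gid = struct.unpack_from("b", buf, pos + 1)[0]
        if nchar == 0:
            break
        name = buf[pos + 2: pos + 2 + abs(nchar)].decode("ascii", "replace")
        p = pos + 2 + abs(nchar)
        offset = struct.unpack_from("<h", buf, p)[0]
        next_pos = p + offset if offset > 0 else len(buf)
        p += 2
        if gid < 0:  # group record
            groups[-gid] = name.upper()
        else:  # parameter record
            dtype = struct.unpack_from("b", buf, p)[0]
            ndims = buf[p + 1]
            dims = list(buf[p + 2: p + 2 + ndims])
            p += 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            size = abs(dtype)
            raw = buf[p: p + count * size]
            params.setdefault(gid, {})[name.upper()] = (dtype, dims, raw)
        if offset <= 0:
            break
        pos = next_pos
    out: dict[str, dict[str, tuple]] = {}
    for gid, ps in params.items():
        out[groups.get(gid, str(gid))] = ps
    return out


def _param_float(entry) -> float:
    dtype, _dims, raw = entry
    if dtype == 4:
        return struct.unpack("<f", raw[:4])[0]
    if dtype == 2:
        return float(struct.unpack("<h", raw[:2])[0])
    raise FormatError(f"unexpected parameter type {dtype}")


def _param_int(entry) -> int:
    dtype, _dims, raw = entry
    if dtype == 2:
        return struct.unpack("<H", raw[:2])[0]
    if dtype == 4:
        return int(struct.unpack("<f", raw[:4])[0])
    raise FormatError(f"unexpected parameter type {dtype}")


def _param_strings(entry) -> list[str]:
    dtype, dims, raw = entry
    if dtype != -1 or len(dims) != 2:
        raise FormatError("expected a 2-D char parameter (LABELS)")
    width, n = dims
    return [raw[i * width:(i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n)]


def read_c3d(path) -> MarkerTrajectorySet:
    """Read labeled points from a C3D file into meters.

    Frames whose point residual is negative (invalid reconstruction) are
    flagged in the gap mask.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _BLOCK:
        raise FormatError("file shorter than one C3D block (header)")
    param_block, magic = data[0], data[1]
    if magic != 0x50:
        raise FormatError(f"bad C3D magic byte {magic:#x} (header word 1)")
    n_points = struct.unpack_from("<H", data, 2)[0]
    first_frame = struct.unpack_from("<H", data, 6)[0]
    last_frame = struct.unpack_from("<H", data, 8)[0]
    hdr_scale = struct.unpack_from("<f", data, 12)[0]
    data_block = struct.unpack_from("<H", data, 16)[0]
    rate = struct.unpack_from("<f", data, 20)[0]

    pstart = (param_block - 1) * _BLOCK
    if pstart >= len(data):
        raise FormatError("parameter block pointer beyond end of file")
    groups = _read_params(data[pstart:])
    point = groups.get("POINT", {})

    if "USED" in point:
        used = _param_int(point["USED"])
        if used != n_points:
            raise FormatError(
                f"POINT:USED={used} contradicts header point count {n_points}")
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        n_frames = _param_int(point["FRAMES"])
    if "RATE" in point:
        rate = _param_float(point["RATE"])
    if rate <= 0:
        raise FormatError(f"non-positive frame rate {rate} (POINT:RATE)")
    scale = _param_float(point["SCALE"]) if "SCALE" in point else hdr_scale
    if "DATA_START" in point:
        data_block = _param_int(point["DATA_START"])
    labels = (_param_strings(point["LABELS"]) if "LABELS" in point
              else [f"point_{i+1}" for i in range(n_points)])
    if len(labels) < n_points:
        raise FormatError(
            f"POINT:LABELS has {len(labels)} names for {n_points} points")
    labels = labels[:n_points]
    units = "mm"
    if "UNITS" in point:
        _t, _d, raw = point["UNITS"]
        units = raw.decode("ascii", "replace").strip()
    if units not in _UNIT_SCALE:
        raise FormatError(f"unknown POINT:UNITS {units!r}")

    start = (data_block - 1) * _BLOCK
    if scale < 0:  # float storage
        words = np.frombuffer(data, dtype="<f4", offset=start,
                              count=n_frames * n_points * 4)
        frame_data = words.reshape(n_frames, n_points, 4).astype(float)
        coords = frame_data[:, :, :3]
        residual = frame_data[:, :, 3]
    else:  # 16-bit integer storage scaled by |scale|
        words = np.frombuffer(data, dtype="<i2", offset=start,
                              count=n_frames * n_points * 4)
        frame_data = words.reshape(n_frames, n_points, 4).astype(float)
        coords = frame_data[:, :, :3] * scale
        residual = frame_data[:, :, 3]

    gap = residual < 0
    positions = coords * _UNIT_SCALE[units]
    positions = positions.copy()
    positions[gap] = np.nan
    return MarkerTrajectorySet(
        labels=list(labels), positions=positions, rate=float(rate),
        gap_mask=gap,
        meta={"source": str(path), "format": "c3d", "original_units": units,
              "first_frame": first_frame},
    )


def _pad_block(chunks: list[bytes]) -> bytes:
    raw = b"".join(chunks)
    pad = (-len(raw)) % _BLOCK
    return raw + b"\x00" * pad


def write_c3d(path, mset: MarkerTrajectorySet, units: str = "m") -> None:
    """Write a marker set as a float-data, Intel-format C3D file."""
    if units not in _UNIT_SCALE:
        raise ValueError(f"unsupported units {units!r}")
    n_frames, n_points = mset.n_frames, mset.n_markers
    coords = mset.positions / _UNIT_SCALE[units]
    residual = np.where(mset.gap_mask, -1.0, 0.0)

    # ---- parameter section -------------------------------------------------
    def group(name: bytes, gid: int) -> bytes:
        return struct.pack("bb", len(name), -gid) + name + struct.pack("<h", 3) + b"\x00"

    def param(name: bytes, gid: int, dtype: int, dims: list[int],
              payload: bytes) -> bytes:
        head = struct.pack("bb", len(name), gid) + name
        body = struct.pack("bb", dtype, len(dims)) + bytes(dims) + payload + b"\x00"
        return head + struct.pack("<h", 2 + len(body)) + body

    label_width = max(4, max((len(l) for l in mset.labels), default=4))
    labels_raw = b"".join(l.encode("ascii").ljust(label_width, b" ")
                          for l in mset.labels)
    units_raw = units.encode("ascii").ljust(4, b" ")

    entries = [
        group(b"POINT", 1),
        param(b"USED", 1, 2, [], struct.pack("<h", n_points)),
        param(b"FRAMES", 1, 2, [], struct.pack("<H", n_frames)),
        param(b"RATE", 1, 4, [], struct.pack("<f", mset.rate)),
        param(b"SCALE", 1, 4, [], struct.pack("<f", -1.0)),
        param(b"UNITS", 1, -1, [4], units_raw),
        param(b"LABELS", 1, -1, [label_width, n_points], labels_raw),
    ]

    data_start_placeholder = param(b"DATA_START", 1, 2, [], struct.pack("<h", 0))
    param_body = b"".join(entries) + data_start_placeholder + struct.pack("bb", 0, 0)
    n_param_blocks = (4 + len(param_body) + _BLOCK - 1) // _BLOCK
    data_block = 2 + n_param_blocks

    entries.append(param(b"DATA_START", 1, 2, [], struct.pack("<h", data_block)))
    param_section = _pad_block(
        [bytes([1, 0x50, n_param_blocks, _PROC_INTEL]),
         b"".join(entries), struct.pack("bb", 0, 0)])

    # ---- header ------------------------------------------------------------
    header = bytearray(_BLOCK)
    header[0] = 2            # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)          # analog per frame
    struct.pack_into("<H", header, 6, 1)          # first frame
    struct.pack_into("<H", header, 8, n_frames)   # last frame
    struct.pack_into("<H", header, 10, 0)         # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)      # scale < 0 -> float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 1)         # analog samples per frame
    struct.pack_into("<f", header, 20, mset.rate)

    frame_data = np.concatenate(
        [np.nan_to_num(coords), residual[:, :, None]], axis=2
    ).astype("<f4")
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(_pad_block([frame_data.tobytes()]))
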