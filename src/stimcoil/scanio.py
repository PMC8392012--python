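"""Delimited-text scan format shared by simulated and synthetic-measured data.

A scan file is a block of ``key: value`` header lines followed by one
whitespace-delimited row per sample with columns
``x_mm y_mm z_mm Bx_T By_T Bz_T Bmag_T``.  The same format carries planar
field maps (``kind: map``) and line scans (``kind: line``); metadata and
values round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .fieldmaps import FieldMap, LineScan, ScanRecord
from .geometry import MM, DriveCondition

_MANDATORY = ("kind", "step_mm", "current_A", "mode", "condition")
_COLUMNS = "x_mm y_mm z_mm Bx_T By_T Bz_T Bmag_T"


def write_scan(record: ScanRecord, path) -> None:
    """Serialize a ScanRecord (map or line payload) to a scan file."""
    payload = record.payload
    lines = ["# stimcoil scan v1"]

    def put(key, value):
        lines.append(f"{key}: {value}")

    if isinstance(payload, FieldMap):
        put("kind", "map")
        put("plane", payload.plane)
        put("origin_mm", " ".join(f"{v / MM:.12g}" for v in payload.origin))
        put("shape", f"{payload.shape[0]} {payload.shape[1]}")
        put("step_mm", f"{payload.step / MM:.12g}")
        pts = payload.points.reshape(-1, 3)
        vals = payload.values.reshape(-1, 3)
    elif isinstance(payload, LineScan):
        put("kind", "line")
        put("start_mm", " ".join(f"{v / MM:.12g}" for v in payload.start))
        put("direction", " ".join(f"{v:.17g}" for v in payload.direction))
        steps = np.diff(payload.positions)
        put("step_mm", f"{(steps[0] if len(steps) else 0.0) / MM:.12g}")
        pts = payload.start[None, :] + payload.positions[:, None] * payload.direction
        if payload.b_vectors is not None:
            vals = payload.b_vectors
        else:
            vals = np.zeros((len(payload.positions), 3))
            vals[:, 2] = payload.magnitude
        put("positions_mm", " ".join(f"{p / MM:.17g}" for p in payload.positions))
    else:
        raise TypeError(f"unsupported payload {type(payload).__name__}")

    put("current_A", f"{record.current:.17g}")
    put("mode", payload.excitation.mode)
    put("condition", record.condition)
    put("n_averages", record.n_averages)
    if record.seed is not None:
        put("seed", record.seed)
    if record.provenance:
        put("provenance", record.provenance)
    put("columns", _COLUMNS)

    mag = np.linalg.norm(vals, axis=1)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for p, v, m in zip(pts, vals, mag):
            fh.write(f"{p[0] / MM:.17g} {p[1] / MM:.17g} {p[2] / MM:.17g} "
                     f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g} {m:.17g}\n")


def read_scan(path) -> ScanRecord:
    """Parse a scan file back into a ScanRecord (exact round trip)."""
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if rows:
                rows.append(line)
                continue
            if ":" in line and not _looks_numeric(line.split()[0]):
                key, _, value = line.partition(":")
                header[key.strip()] = value.strip()
            else:
                rows.append(line)

    missing = [k for k in _MANDATORY if k not in header]
    if missing:
        raise FormatError(f"scan file {path} missing mandatory header keys: "
                          f"{missing}")

    try:
        data = np.array([[float(tok) for tok in r.split()] for r in rows])
    except ValueError as exc:
        raise FormatError(f"non-numeric data row in {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 7:
        raise FormatError(f"expected 7 data columns in {path}")

    current = float(header["current_A"])
    drive = DriveCondition(current=current, mode=header["mode"])
    condition = header["condition"]
    n_avg = int(header.get("n_averages", 1))
    seed = int(header["seed"]) if "seed" in header else None
    provenance = header.get("provenance", "")

    if header["kind"] == "map":
        shape = tuple(int(t) for t in header["shape"].split())
        if len(shape) != 2 or shape[0] * shape[1] != len(data):
            raise FormatError(f"shape header inconsistent with row count in {path}")
        points = data[:, :3].reshape(shape + (3,)) * MM
        values = data[:, 3:6].reshape(shape + (3,))
        payload: FieldMap | LineScan = FieldMap(
            plane=header.get("plane", "XZ"),
            origin=np.array([float(t) for t in header["origin_mm"].split()]) * MM,
            step=float(header["step_mm"]) * MM,
            points=points, values=values, excitation=drive)
    elif header["kind"] == "line":
        start = np.array([float(t) for t in header["start_mm"].split()]) * MM
        direction = np.array([float(t) for t in header["direction"].split()])
        positions = np.array([float(t) for t in header["positions_mm"].split()]) * MM
        if len(positions) != len(data):
            raise FormatError(f"positions header inconsistent with rows in {path}")
        if np.any(np.diff(positions) <= 0):
            raise FormatError(f"non-monotone scan positions in {path}")
        payload = LineScan(start=start, direction=direction,
                           positions=positions, magnitude=data[:, 6],
                           excitation=drive, b_vectors=data[:, 3:6])
    else:
        raise FormatError(f"unknown scan kind {header['kind']!r} in {path}")

    return ScanRecord(payload=payload, condition=condition, current=current,
                      n_averages=n_avg, provenance=provenance, seed=seed)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
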