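"""Readers and writers for the package's plain-text formats.

* Trace files: TSV/CSV with a ``#``-prefixed metadata header carrying
  ``sampling_hz`` and ``voltage_mV`` plus free-form keys, then columns
  ``time_s, current_pA, pressure_mmHg``.
* Geometry series: CSV with one row per pressure step (row with
  pressure 0 is the reference).
* Slab-area matrices: CSV of trajectories x slabs with the applied
  tension in a ``# tension_mN_per_m`` header line.
* Run reports: JSON with stable key order, floats at 6 significant
  digits and a provenance block (package version, seed, config hash).

The delimiter is auto-detected between tab and comma; parse errors carry
file and line context.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SerializationError, TraceParseError
from .gating import RecordingTrace
from .md_area import SlabAreaSeries
from .mechanics import PatchGeometry
from .synthetic import GEOMETRY_COLUMNS, Event

__all__ = [
    "read_trace", "write_trace", "read_geometry_series",
    "write_geometry_series", "geometry_frame_to_inputs", "read_slab_series",
    "write_slab_series", "write_events", "read_events", "run_report",
]

logger = logging.getLogger("mscmech")

_TRACE_COLUMNS = ["time_s", "current_pA", "pressure_mmHg"]


def _detect_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def write_trace(trace: RecordingTrace, path):
    """Write a trace; lossless round trip (%.17g floats)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("# mscmech trace v1\n")
        fh.write(f"# sampling_hz: {trace.sampling_rate:.17g}\n")
        fh.write(f"# voltage_mV: {trace.voltage:.17g}\n")
        for key, value in sorted(trace.metadata.items()):
            fh.write(f"# meta.{key}: {value}\n")
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        for t, c, p in zip(trace.time, trace.current, trace.pressure):
            fh.write(f"{t:.17g}\t{c:.17g}\t{p:.17g}\n")


def read_trace(path) -> RecordingTrace:
    path = Path(path)
    sampling = voltage = None
    metadata: dict = {}
    rows = []
    header_cols = None
    delim = "\t"
    with path.open("r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    continue
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "sampling_hz":
                    sampling = float(value)
                elif key == "voltage_mV":
                    voltage = float(value)
                elif key.startswith("meta."):
                    metadata[key[5:]] = value
                continue
            if header_cols is None:
                delim = _detect_delimiter(line)
                header_cols = [c.strip() for c in line.split(delim)]
                if header_cols != _TRACE_COLUMNS:
                    raise TraceParseError(
                        f"unexpected columns {header_cols!r}", path, lineno)
                continue
            parts = line.split(delim)
            if len(parts) != 3:
                raise TraceParseError(
                    f"expected 3 columns, got {len(parts)}", path, lineno)
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise TraceParseError(
                    f"non-numeric sample {line!r}", path, lineno) from None
    if header_cols is None:
        raise TraceParseError("no data header found", path)
    if sampling is None:
        raise TraceParseError("missing 'sampling_hz' metadata", path)
    if voltage is None:
        raise TraceParseError("missing 'voltage_mV' metadata", path)
    data = np.asarray(rows, dtype=float)
    if len(data) == 0:
        raise TraceParseError("trace has no samples", path)
    return RecordingTrace(time=data[:, 0], current=data[:, 1],
                          pressure=data[:, 2], sampling_rate=sampling,
                          voltage=voltage, metadata=metadata)


def write_geometry_series(frame: pd.DataFrame, path):
    frame.to_csv(path, index=False, lineterminator="\n")


def read_geometry_series(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise TraceParseError(f"cannot parse geometry CSV: {exc}", path) from exc
    missing = [c for c in GEOMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise TraceParseError(f"missing columns {missing}", path, 1)
    return frame[GEOMETRY_COLUMNS]


def geometry_frame_to_inputs(frame: pd.DataFrame):
    """Split a geometry series into (pressures, geometries, reference).

    The row with pressure 0 is the reference; if absent the
    lowest-|pressure| row is used and a warning is logged.
    """
    if len(frame) < 2:
        raise InvalidInputError("geometry series needs a reference and >= 1 step")

    def row_geometry(row) -> PatchGeometry:
        return PatchGeometry(
            tip_radius=row["tip_radius_um"], dome_radius=row["dome_radius_um"],
            protrusion_length=row["protrusion_um"],
            dome_height=row["dome_height_um"],
            curvature_radius=row["curvature_um"])

    zero = frame[frame["pressure_mmHg"] == 0]
    if len(zero):
        ref_idx = zero.index[0]
    else:
        ref_idx = frame["pressure_mmHg"].abs().idxmin()
        logger.warning(
            "no zero-pressure row; using the lowest-pressure row (%.3g mmHg) "
            "as reference", frame.loc[ref_idx, "pressure_mmHg"])
    reference = row_geometry(frame.loc[ref_idx])
    rest = frame.drop(index=ref_idx)
    pressures = rest["pressure_mmHg"].to_numpy(dtype=float)
    geometries = [row_geometry(row) for _, row in rest.iterrows()]
    return pressures, geometries, reference


def write_slab_series(series: SlabAreaSeries, path):
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# tension_mN_per_m: {series.applied_tension:.17g}\n")
        for row in series.areas:
            fh.write(",".join(f"{a:.17g}" for a in row) + "\n")


def read_slab_series(path, equilibration_exclusion: int = 0) -> SlabAreaSeries:
    path = Path(path)
    tension = None
    rows = []
    width = None
    with path.open("r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, value = body.partition(":")
                if key.strip() == "tension_mN_per_m":
                    tension = float(value)
                continue
            parts = line.split(_detect_delimiter(line))
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise TraceParseError(
                    f"ragged row: expected {width} columns, got {len(parts)}",
                    path, lineno)
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise TraceParseError(
                    f"non-numeric area {line!r}", path, lineno) from None
    if tension is None:
        raise TraceParseError("missing 'tension_mN_per_m' header", path)
    if not rows:
        raise TraceParseError("slab file has no area rows", path)
    return SlabAreaSeries(applied_tension=tension,
                          areas=np.asarray(rows, dtype=float),
                          equilibration_exclusion=equilibration_exclusion)


def write_events(events, path):
    payload = [
        {"time_s": e.time_s, "channel": e.channel,
         "from_level": e.from_level, "to_level": e.to_level}
        for e in events
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_events(path):
    payload = json.loads(Path(path).read_text())
    return [Event(**entry) for entry in payload]


def _round_floats(obj):
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if np.isnan(x):
            return None
        return float(f"{x:.6g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if obj is None or isinstance(obj, str):
        return obj
    raise SerializationError(f"cannot serialize {type(obj).__name__} in report")


def run_report(results: dict, path=None, seed=None, config=None,
               timestamp: bool = True) -> dict:
    """Assemble (and optionally write) a JSON result document.

    Keys are sorted, floats carry 6 significant digits, and a provenance
    block records the package version, seed and a config hash so that
    re-runs with the same inputs are byte-identical up to the timestamp.
    """
    from . import __version__

    body = _round_floats(dict(results))
    config_text = json.dumps(config, sort_keys=True, default=str) if config else ""
    provenance = {
        "package": "mscmech",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
    }
    if timestamp:
        provenance["created"] = _time.strftime("%Y-%m-%dT%H:%M:%S%z")
    document = {"provenance": provenance, "results": body}
    if path is not None:
        Path(path).write_text(
            json.dumps(document, indent=1, sort_keys=True) + "\n")
    return document
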