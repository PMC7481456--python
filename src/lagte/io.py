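"""Readers and writers for the plain-text formats of the pipeline.

Formats: bivariate series CSV (header ``x,y``), R-peak annotation text
(one event time in seconds per line), respiration CSV (``time,value`` or
value-only with an explicit rate), sleep-state interval CSV
(``start,end,state``), long-format result CSV and segment manifests
(JSON).  The CSV dialect is fixed (comma separator, dot decimal, header
row mandatory) to avoid locale drift; malformed rows are reported with
their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._design import BivariateSeries
from .preprocess import PhysioRecord, SegmentPair

__all__ = [
    "read_series", "write_series",
    "read_rpeaks", "write_rpeaks",
    "read_resp", "write_resp",
    "read_sleep_states", "write_sleep_states",
    "write_results", "read_results",
    "write_segments", "read_record",
]

FLOAT_FMT = "%.12g"


def _parse_float(tok: str, path, lineno: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: cannot parse {tok!r} as a number") from None


def read_series(path) -> BivariateSeries:
    """Bivariate series from a two-column CSV with header ``x,y``."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty input file")
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != ["x", "y"]:
        raise ValueError(f"{path}:1: expected header 'x,y', got {lines[0]!r}")
    xs, ys = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split(",")
        if len(toks) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        xs.append(_parse_float(toks[0], path, lineno))
        ys.append(_parse_float(toks[1], path, lineno))
    if not xs:
        raise ValueError(f"{path}: no data rows")
    return BivariateSeries(np.array(xs), np.array(ys))


def write_series(path, pair: BivariateSeries) -> None:
    df = pd.DataFrame({"x": pair.x, "y": pair.y})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rpeaks(path) -> np.ndarray:
    """R-peak annotation file: one event time (seconds) per line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    times = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        times.append(_parse_float(line.strip(), path, lineno))
    if len(times) < 2:
        raise ValueError(f"{path}: empty or single-event annotation file")
    t = np.array(times)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}:{int(bad[0]) + 2}: non-monotone R-peak time")
    return t


def write_rpeaks(path, times) -> None:
    Path(path).write_text(
        "\n".join(FLOAT_FMT % t for t in np.asarray(times)) + "\n")


def read_resp(path, rate: float | None = None):
    """Respiration waveform CSV.

    Either two columns ``time,value`` (rate inferred from the time grid)
    or a single ``value`` column with ``rate`` given explicitly.
    Returns (values, rate).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty input file")
    header = [h.strip() for h in lines[0].split(",")]
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        rows.append([_parse_float(t, path, lineno) for t in line.split(",")])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    if header[:2] == ["time", "value"]:
        dt = np.diff(arr[:, 0])
        if np.any(dt <= 0):
            raise ValueError(f"{path}: non-monotone time column")
        return arr[:, 1], float(1.0 / np.median(dt))
    if header[0] == "value":
        if rate is None:
            raise ValueError(
                f"{path}: value-only respiration file needs an explicit rate")
        return arr[:, 0], float(rate)
    raise ValueError(f"{path}:1: expected header 'time,value' or 'value'")


def write_resp(path, values, rate: float) -> None:
    t = np.arange(len(values)) / rate
    pd.DataFrame({"time": t, "value": values}).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_sleep_states(path) -> list:
    """Sleep-state intervals from a ``start,end,state`` CSV."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty input file")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = [t.strip() for t in line.split(",")]
        if len(toks) != 3:
            raise ValueError(f"{path}:{lineno}: expected start,end,state")
        start = _parse_float(toks[0], path, lineno)
        end = _parse_float(toks[1], path, lineno)
        if end <= start:
            raise ValueError(f"{path}:{lineno}: empty or inverted interval")
        out.append((start, end, toks[2]))
    return out


def write_sleep_states(path, states) -> None:
    pd.DataFrame(states, columns=["start", "end", "state"]).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def write_results(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_record(peaks_path, resp_path, states_path=None,
                rate: float | None = None, **meta) -> PhysioRecord:
    """Assemble a PhysioRecord from its on-disk parts."""
    resp, fs = read_resp(resp_path, rate)
    return PhysioRecord(
        rpeak_times=read_rpeaks(peaks_path),
        resp=resp, resp_fs=fs,
        sleep_states=read_sleep_states(states_path) if states_path else [],
        **meta)


def write_segments(out_dir, segments: list[SegmentPair]) -> Path:
    """Segment CSVs plus a JSON manifest with provenance; returns manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, seg in enumerate(segments):
        name = f"segment-{i:04d}.csv"
        pd.DataFrame({"rr": seg.rr, "resp": seg.resp}).to_csv(
            out_dir / name, index=False, float_format=FLOAT_FMT)
        manifest.append({
            "file": name, "record_id": seg.record_id,
            "sleep_state": seg.sleep_state, "start_index": seg.start_index,
            "n_rejected": seg.n_rejected, "ga_group": seg.ga_group,
            "covariates": seg.covariates,
        })
    mpath = out_dir / "segments.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
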