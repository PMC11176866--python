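"""Plain-text readers and writers for RR series, sessions and HRV tables.

RR files come in two dialects, never mixed in one file:

* interval dialect — one interval in ms per line;
* beat-time dialect — CSV with ``beat_time_s,rri_ms`` columns.

Either may carry ``# key=value`` header comments; ``start_clock`` (ISO 8601)
is required to place the recording on the wall clock.  Session tables are
CSV with one row per session and the intradialytic SBP readings
semicolon-separated in one field.
"""

from __future__ import annotations

import csv
from datetime import datetime
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .outcomes import DialysisSession
from .time_domain import HRVParams, RRISeries

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_header(lines: List[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_rr_file(path: PathLike, start_clock: Optional[datetime] = None) -> RRISeries:
    """Read an RR series from either dialect; ``start_clock`` overrides the
    header."""
    path = Path(path)
    raw = path.read_text().splitlines()
    header = [ln for ln in raw if ln.startswith("#")]
    meta = _parse_header(header)
    if start_clock is None:
        if "start_clock" not in meta:
            raise ParseError(f"{path}: no start_clock header and none given")
        start_clock = datetime.fromisoformat(meta["start_clock"])

    data = [(i + 1, ln.strip()) for i, ln in enumerate(raw)
            if ln.strip() and not ln.startswith("#")]
    if not data:
        raise ParseError(f"{path}: no data lines")

    first = data[0][1]
    is_csv = "," in first or first.replace(" ", "") == "beat_time_s,rri_ms"
    if is_csv:
        rows = []
        header_seen = False
        for lineno, ln in data:
            parts = [p.strip() for p in ln.split(",")]
            if not header_seen:
                if parts != ["beat_time_s", "rri_ms"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header 'beat_time_s,rri_ms'")
                header_seen = True
                continue
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two fields")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from None
            if v <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive interval {v}")
            rows.append((t, v))
        bt = np.array([r[0] for r in rows])
        iv = np.array([r[1] for r in rows])
        return RRISeries(start_clock=start_clock, beat_times=bt, intervals=iv)

    intervals = []
    for lineno, ln in data:
        if "," in ln:
            raise ParseError(
                f"{path}:{lineno}: mixed dialects (CSV row in interval file)")
        try:
            v = float(ln)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {ln!r}") from None
        if v <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive interval {v}")
        intervals.append(v)
    return RRISeries.from_intervals(intervals, start_clock)


def write_rr_file(series: RRISeries, path: PathLike) -> None:
    """Write the beat-time CSV dialect with a start_clock header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# start_clock={series.start_clock.isoformat()}\n")
        fh.write("beat_time_s,rri_ms\n")
        for t, v in zip(series.beat_times, series.intervals):
            fh.write(f"{t:.6f},{v:.6f}\n")


SESSION_COLUMNS = ["patient_id", "session_id", "pre_sbp", "pre_dbp",
                   "post_sbp", "post_dbp", "readings", "uf_kg"]


def read_sessions(path: PathLike) -> List[DialysisSession]:
    path = Path(path)
    sessions = []
    with path.open() as fh:
        reader = csv.DictReader(fh)
        missing = {"patient_id", "session_id", "pre_sbp", "readings"} - set(
            reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                readings = [float(x) for x in row["readings"].split(";") if x.strip()]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad readings field") from None
            if not readings:
                raise ParseError(
                    f"{path}:{lineno}: session {row['session_id']} has no readings")

            def _opt(key):
                v = row.get(key, "")
                return float(v) if v not in ("", None) else None

            sessions.append(DialysisSession(
                session_id=row["session_id"], patient_id=row["patient_id"],
                pre_sbp=float(row["pre_sbp"]), pre_dbp=_opt("pre_dbp"),
                post_sbp=_opt("post_sbp"), post_dbp=_opt("post_dbp"),
                uf_kg=_opt("uf_kg"), readings=readings))
    return sessions


def write_sessions(sessions: List[DialysisSession], path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SESSION_COLUMNS)
        for s in sessions:
            w.writerow([
                s.patient_id, s.session_id, f"{s.pre_sbp:.2f}",
                "" if s.pre_dbp is None else f"{s.pre_dbp:.2f}",
                "" if s.post_sbp is None else f"{s.post_sbp:.2f}",
                "" if s.post_dbp is None else f"{s.post_dbp:.2f}",
                ";".join(f"{r:.2f}" for r in s.readings),
                "" if s.uf_kg is None else f"{s.uf_kg:.2f}",
            ])


def hrv_params_frame(records: List[dict]) -> pd.DataFrame:
    """Normalise a list of {id fields + HRVParams} dicts into a table with
    the ten parameter columns in canonical order."""
    df = pd.DataFrame(records)
    id_cols = [c for c in df.columns if c not in HRVParams.FIELDS]
    return df[id_cols + [c for c in HRVParams.FIELDS if c in df.columns]]


def write_psd(psd, path: PathLike) -> None:
    """Two-column CSV with the Welch settings in a comment header."""
    with Path(path).open("w") as fh:
        fh.write(f"# taper={psd.taper} window_s={psd.window_s} "
                 f"overlap={psd.overlap} detrend={psd.detrend}\n")
        fh.write("frequency_hz,density_ms2_per_hz\n")
        for f, d in zip(psd.frequencies, psd.density):
            fh.write(f"{f:.6f},{d:.8e}\n")
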