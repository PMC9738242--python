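"""Plain-text interchange formats: session CSV and cohort manifest CSV.

A session file is a CSV with columns ``timestamp,x,y,z`` (timestamp in seconds
from recording start, accelerations in g) preceded by ``# key=value`` metadata
lines carrying subject id, group, sampling rate and seed.  Timestamps must
advance by exactly one sample period; gaps or disorder are parse errors naming
the offending line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .synth import RecordingSession


class SessionParseError(ValueError):
    """Malformed session file (bad row, gap, or missing metadata)."""


def write_session_csv(session: RecordingSession, path: str | Path) -> Path:
    """Write a session losslessly (float32 samples survive the round-trip)."""
    path = Path(path)
    n = session.samples.shape[0]
    ts = np.arange(n) / session.fs_hz
    with open(path, "w", newline="") as fh:
        fh.write(f"# subject_id={session.subject_id}\n")
        fh.write(f"# group={session.group}\n")
        fh.write(f"# fs_hz={session.fs_hz!r}\n")
        fh.write(f"# duration_s={session.duration_s!r}\n")
        fh.write(f"# seed={session.seed}\n")
        fh.write("timestamp,x,y,z\n")
        for i in range(n):
            x, y, z = session.samples[i]
            fh.write(f"{ts[i]:.6f},{x:.9g},{y:.9g},{z:.9g}\n")
    return path


def read_session_csv(path: str | Path) -> RecordingSession:
    """Parse a session file written by :func:`write_session_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float, float]] = []
    with open(path, newline="") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "timestamp,x,y,z":
                    raise SessionParseError(
                        f"{path}:{lineno}: expected header 'timestamp,x,y,z'"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise SessionParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                rows.append(tuple(float(p) for p in parts))  # type: ignore[arg-type]
            except ValueError as exc:
                raise SessionParseError(f"{path}:{lineno}: {exc}") from None

    for key in ("subject_id", "group", "fs_hz"):
        if key not in meta:
            raise SessionParseError(f"{path}: missing metadata '{key}'")
    fs_hz = float(meta["fs_hz"])
    if not rows:
        raise SessionParseError(f"{path}: no samples")

    data = np.asarray(rows, dtype=np.float64)
    ts = data[:, 0]
    period = 1.0 / fs_hz
    gaps = np.nonzero(np.abs(np.diff(ts) - period) > 0.01 * period)[0]
    if gaps.size:
        # +2 header-relative: first data line follows metadata + header
        bad = int(gaps[0]) + 1
        raise SessionParseError(
            f"{path}: non-uniform timestamp at sample {bad} "
            f"(dt={ts[bad] - ts[bad - 1]:.6f} s, expected {period:.6f} s)"
        )

    samples = data[:, 1:].astype(np.float32)
    duration_s = float(meta.get("duration_s", samples.shape[0] / fs_hz))
    return RecordingSession(
        subject_id=meta["subject_id"],
        group=meta["group"],
        fs_hz=fs_hz,
        duration_s=duration_s,
        samples=samples,
        seed=int(meta.get("seed", -1)),
    )


def write_manifest(sessions_with_paths: Iterable[tuple[RecordingSession, str]], path: str | Path) -> Path:
    """Cohort manifest: subject_id, group, path."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "path"])
        for session, spath in sessions_with_paths:
            writer.writerow([session.subject_id, session.group, spath])
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise SessionParseError(f"{path}: manifest needs columns {sorted(required)}")
    return df
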