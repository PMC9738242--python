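"""Sliding-window segmentation of tri-axial accelerometer sessions.

Each recording is cut into fixed-length windows of ``S`` seconds advancing by
``S/2`` (50 % overlap).  For a recording of duration ``t`` the number of full
windows is ``floor(2 t / S) - 1``; any trailing partial window is dropped, so
features are always computed on complete windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

#: The five window lengths (seconds) of the full-scale multi-scale strategy set,
#: spanning tremor-scale bursts (3 s) up to activity-of-daily-living scale (15 min).
FULL_SCALE_WINDOWS_S: tuple[float, ...] = (3.0, 10.0, 60.0, 300.0, 900.0)


class SegmentationError(ValueError):
    """Raised when a session is too short to yield a single full window."""


@dataclass(frozen=True)
class WindowSpec:
    """One windowing strategy: length in seconds at a given sampling rate.

    The hop is always half the window (50 % overlap).
    """

    window_s: float
    fs_hz: float

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.fs_hz <= 0:
            raise ValueError("window_s and fs_hz must be positive")

    @property
    def overlap_s(self) -> float:
        return self.window_s / 2.0

    @property
    def length(self) -> int:
        """Window length in samples."""
        return int(round(self.window_s * self.fs_hz))

    @property
    def hop(self) -> int:
        """Advance between consecutive windows in samples."""
        return self.length // 2


@dataclass(frozen=True)
class Segment:
    """One window of one subject's recording.

    ``block`` is a view of shape (length, 3); ``start_index`` is the 0-based
    sample index of the block's first sample, half-open ``[start, start+len)``.
    """

    subject_id: str
    window_s: float
    start_index: int
    block: np.ndarray


def segment_count(duration_s: float, window_s: float) -> int:
    """Number of 50 %-overlapping full windows: ``floor(2 t / S) - 1``.

    Returns 0 for recordings shorter than one window.
    """
    if duration_s < window_s:
        return 0
    return math.floor(2.0 * duration_s / window_s) - 1


def cohort_segment_count(durations_s: Sequence[float], window_s: float) -> int:
    """Total window count over a cohort: the per-subject counts summed."""
    if any(t <= 0 for t in durations_s):
        raise ValueError("durations must be positive")
    return sum(segment_count(t, window_s) for t in durations_s)


def segment_starts(n_samples: int, spec: WindowSpec) -> np.ndarray:
    """0-based start indices of the full windows inside ``n_samples`` samples."""
    length, hop = spec.length, spec.hop
    if n_samples < length:
        return np.empty(0, dtype=np.int64)
    n = (n_samples - length) // hop + 1
    return np.arange(n, dtype=np.int64) * hop


def segment_session(session, spec: WindowSpec) -> Iterator[Segment]:
    """Yield the windows of a session lazily (blocks are views, not copies).

    Raises :class:`SegmentationError` if the recording is shorter than one
    window, naming the subject and the window size.
    """
    samples = session.samples
    starts = segment_starts(samples.shape[0], spec)
    if starts.size == 0:
        raise SegmentationError(
            f"session {session.subject_id!r} ({session.duration_s:g} s) is shorter "
            f"than one {spec.window_s:g}-s window"
        )
    length = spec.length
    for s in starts:
        yield Segment(session.subject_id, spec.window_s, int(s), samples[s : s + length])


def export_segment_index(sessions, spec: WindowSpec, path) -> None:
    """Write a segment-index CSV (subject_id, window_s, start_index)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "window_s", "start_index"])
        for session in sessions:
            for start in segment_starts(session.samples.shape[0], spec):
                writer.writerow([session.subject_id, spec.window_s, int(start)])


def window_view(samples: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """All full windows of a (N, 3) array as a zero-copy (n_win, length, 3) view."""
    starts = segment_starts(samples.shape[0], spec)
    if starts.size == 0:
        return np.empty((0, spec.length, 3), dtype=samples.dtype)
    n = starts.size
    usable = samples[: starts[-1] + spec.length]
    return np.lib.stride_tricks.sliding_window_view(usable, spec.length, axis=0)[
        :: spec.hop
    ].transpose(0, 2, 1)[:n]
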