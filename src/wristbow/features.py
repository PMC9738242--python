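"""The ten-descriptor set (SDS) computed per window, and subject-level averages.

Per window the descriptors are:

* ``vm`` — mean per-sample signal vector magnitude sqrt(x^2+y^2+z^2) (g);
  orientation-independent movement-intensity proxy.
* ``rmsr_ap, rmsr_ml, rmsr_ver`` — per-axis RMS normalized by the Euclidean
  norm of the three axis RMS values, so the squared components sum to 1.
* ``disp_ap, disp_ml, disp_ver`` — movement dispersion: the mean absolute
  pairwise difference of within-window z-scores over the "valid" samples
  (those with |z| <= 2 on every axis).  Quantifies acceleration variability.
* ``ar_ap, ar_ml, ar_ver`` — per-axis acceleration range (max - min, g).

Device axes x, y, z are labelled AP, ML, Ver in fixed order; the descriptors
are either axis-symmetric or normalized, so the mapping is a labelling choice.

The dispersion sum over pairs is evaluated with the sorted prefix-sum identity
(for sorted values v_0 <= ... <= v_{m-1}, sum_{i<j} (v_j - v_i) =
sum_j (2j - m + 1) v_j), never by pair enumeration.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import WindowSpec, window_view

DESCRIPTOR_NAMES: tuple[str, ...] = (
    "vm",
    "rmsr_ap",
    "rmsr_ml",
    "rmsr_ver",
    "disp_ap",
    "disp_ml",
    "disp_ver",
    "ar_ap",
    "ar_ml",
    "ar_ver",
)

#: z-score magnitude beyond which a sample is an outlier (on any axis) and is
#: excluded from the dispersion valid set.
Z_OUTLIER = 2.0


def _as_block(segment) -> np.ndarray:
    block = np.asarray(getattr(segment, "block", segment), dtype=np.float64)
    if block.ndim != 2 or block.shape[1] != 3:
        raise ValueError("segment block must have shape (n, 3)")
    if block.shape[0] == 0:
        raise ValueError("empty segment")
    return block


def vector_magnitude(segment) -> float:
    """Mean over samples of the per-sample magnitude sqrt(x^2+y^2+z^2)."""
    block = _as_block(segment)
    return float(np.mean(np.sqrt(np.sum(block * block, axis=1))))


def rmsr(segment) -> tuple[float, float, float]:
    """Normalized per-axis RMS; components' squares sum to 1.

    An all-zero segment has no direction: returns (nan, nan, nan), the flagged
    null descriptor that is excluded from subject averages.
    """
    block = _as_block(segment)
    rms = np.sqrt(np.mean(block * block, axis=0))
    denom = float(np.sqrt(np.sum(rms * rms)))
    if denom == 0.0:
        return (float("nan"),) * 3  # type: ignore[return-value]
    out = rms / denom
    return float(out[0]), float(out[1]), float(out[2])


def dispersion(segment) -> tuple[float, float, float]:
    """Mean absolute pairwise z-score difference over valid samples, per axis.

    Samples are z-scored per axis within the window (population SD); any sample
    with |z| > 2 on any axis is dropped from the valid set for all axes.  A
    zero-variance axis contributes z = 0 everywhere (dispersion 0 on that
    axis); fewer than two valid samples gives dispersion 0.
    """
    block = _as_block(segment)
    if block.shape[0] < 2:
        raise ValueError("dispersion needs at least 2 samples")
    z = _zscores(block)
    valid = np.all(np.abs(z) <= Z_OUTLIER, axis=1)
    m = int(valid.sum())
    if m < 2:
        return (0.0, 0.0, 0.0)
    zv = z[valid]
    npairs = m * (m - 1) / 2.0
    out = []
    for i in range(3):
        v = np.sort(zv[:, i])
        coeff = 2.0 * np.arange(m) - (m - 1)
        out.append(float(np.dot(coeff, v) / npairs))
    return tuple(out)  # type: ignore[return-value]


def dispersion_bruteforce(segment) -> tuple[float, float, float]:
    """O(m^2) pair-enumeration reference for :func:`dispersion` (testing oracle)."""
    block = _as_block(segment)
    z = _zscores(block)
    valid = np.all(np.abs(z) <= Z_OUTLIER, axis=1)
    zv = z[valid]
    m = zv.shape[0]
    if m < 2:
        return (0.0, 0.0, 0.0)
    npairs = m * (m - 1) / 2.0
    out = []
    for i in range(3):
        total = 0.0
        v = zv[:, i]
        for a in range(m):
            for b in range(a + 1, m):
                total += abs(v[a] - v[b])
        out.append(total / npairs)
    return tuple(out)  # type: ignore[return-value]


def acceleration_range(segment) -> tuple[float, float, float]:
    """Per-axis max minus min (g)."""
    block = _as_block(segment)
    rng = block.max(axis=0) - block.min(axis=0)
    return float(rng[0]), float(rng[1]), float(rng[2])


def _zscores(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=0)
    sd = block.std(axis=0)  # population (n-denominator) SD
    z = np.zeros_like(block)
    nz = sd > 0
    z[:, nz] = (block[:, nz] - mu[nz]) / sd[nz]
    return z


def segment_descriptors(segment) -> np.ndarray:
    """The 10-value descriptor set of one segment, in DESCRIPTOR_NAMES order."""
    return np.array(
        [vector_magnitude(segment), *rmsr(segment), *dispersion(segment), *acceleration_range(segment)]
    )


# ---------------------------------------------------------------------------
# Vectorized batch path: all windows of a session at one window size at once.
# ---------------------------------------------------------------------------

def session_descriptors(samples: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Descriptors of every full window of ``samples`` at one window size.

    Returns an (n_windows, 10) float64 array; columns follow DESCRIPTOR_NAMES.
    Rows of all-zero windows carry NaN in the rmsr columns (flagged null).
    """
    win = window_view(np.asarray(samples), spec).astype(np.float64)  # (n, L, 3)
    n, L, _ = win.shape
    if n == 0:
        return np.empty((0, 10))

    vm = np.sqrt(np.sum(win * win, axis=2)).mean(axis=1)  # (n,)

    rms = np.sqrt(np.mean(win * win, axis=1))  # (n, 3)
    denom = np.sqrt(np.sum(rms * rms, axis=1))  # (n,)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmsr_ = np.where(denom[:, None] > 0, rms / denom[:, None], np.nan)

    ar = win.max(axis=1) - win.min(axis=1)  # (n, 3)

    disp = _dispersion_batch(win)

    return np.column_stack([vm, rmsr_, disp, ar])


def _dispersion_batch(win: np.ndarray) -> np.ndarray:
    """Vectorized dispersion for a (n, L, 3) window stack."""
    n, L, _ = win.shape
    mu = win.mean(axis=1, keepdims=True)
    sd = win.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (win - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    valid = np.all(np.abs(z) <= Z_OUTLIER, axis=2)  # (n, L)
    m = valid.sum(axis=1)  # (n,)

    # Invalid entries -> +inf so they sort to the end of each window.
    zmask = np.where(valid[:, :, None], z, np.inf)
    zs = np.sort(zmask, axis=1)  # (n, L, 3)
    # For window w with m_w valid values v_0<=...<=v_{m-1}:
    #   sum_{i<j}(v_j - v_i) = sum_j (2j - m + 1) v_j
    j = np.arange(L)[None, :, None]
    coeff = 2.0 * j - (m[:, None, None] - 1.0)
    contrib = np.where(np.isfinite(zs), coeff * zs, 0.0)
    total = contrib.sum(axis=1)  # (n, 3)
    npairs = m * (m - 1) / 2.0
    disp = np.zeros((n, 3))
    ok = m >= 2
    disp[ok] = total[ok] / npairs[ok, None]
    return disp


# ---------------------------------------------------------------------------
# Subject-level statistical features.
# ---------------------------------------------------------------------------

def _format_window(window_s: float) -> str:
    return f"{window_s:g}s"


def feature_columns(windows_s: Sequence[float]) -> list[str]:
    """Stable column order: windows ascending, descriptors in SDS order."""
    return [
        f"{d}_{_format_window(w)}" for w in sorted(windows_s) for d in DESCRIPTOR_NAMES
    ]


def subject_statistical_features(
    session, windows_s: Sequence[float]
) -> pd.Series:
    """Per-(window, descriptor) unweighted means over the subject's windows.

    Windows flagged null (all-zero signal, NaN rmsr) are excluded from the
    averages of the affected descriptors.  Raises if the session cannot be
    segmented at some requested window size.
    """
    from .segmentation import SegmentationError, segment_starts

    values: dict[str, float] = {}
    for w in sorted(windows_s):
        spec = WindowSpec(w, session.fs_hz)
        if segment_starts(session.samples.shape[0], spec).size == 0:
            raise SegmentationError(
                f"session {session.subject_id!r} shorter than {w:g}-s window"
            )
        desc = session_descriptors(session.samples, spec)
        means = np.nanmean(desc, axis=0)
        for name, val in zip(DESCRIPTOR_NAMES, means):
            values[f"{name}_{_format_window(w)}"] = float(val)
    return pd.Series(values, name=session.subject_id)


def cohort_feature_table(
    sessions: Iterable, windows_s: Sequence[float]
) -> pd.DataFrame:
    """One row per subject, columns ``<descriptor>_<window>s`` in stable order."""
    rows = [subject_statistical_features(s, windows_s) for s in sessions]
    table = pd.DataFrame(rows)
    return table[feature_columns(windows_s)]


def single_window_columns(columns: Sequence[str], window_s: float) -> list[str]:
    """The 10 columns of one windowing strategy, from a full feature table."""
    suffix = f"_{_format_window(window_s)}"
    return [c for c in columns if c.endswith(suffix)]
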