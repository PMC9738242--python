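"""Document-of-words representation of wrist recordings.

Per windowing strategy, the pooled segment descriptors of the training cohort
are clustered with K-medoids (PAM); the medoids form a vocabulary whose size k
is chosen by the elbow of the within-cluster sum of squares (WCSS) curve over
a candidate grid.  Each subject's segments are then mapped to their nearest
medoid ("word") and the subject becomes a document summarized by its term
frequencies — a probability vector over the vocabulary.  Concatenating the TF
vectors of all strategies gives the combined multi-scale document.

Descriptors are standardized (location/scale estimated on the vocabulary
building set) before any distance is computed: the 10 SDS components mix units
(g vs z-score units) and raw Euclidean distance would be dominated by a single
component.  The PAM objective, the exhaustive-search oracle used in tests, and
the reported WCSS are all the same quantity: the sum of squared standardized
Euclidean distances from each point to its assigned medoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Candidate vocabulary sizes scanned by the elbow method.
DEFAULT_K_CANDIDATES: tuple[int, ...] = (4, 8, 12, 16, 20, 24, 28, 32)


class VocabularyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PAM K-medoids
# ---------------------------------------------------------------------------

def _pairwise_sq(points: np.ndarray) -> np.ndarray:
    sq = np.sum(points * points, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * points @ points.T
    np.maximum(d, 0.0, out=d)
    np.fill_diagonal(d, 0.0)
    return d


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dmin = D[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of reductions in nearest-medoid distance
        gain = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        np.minimum(dmin, D[c], out=dmin)
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        med = np.asarray(medoids)
        dm = D[med]  # (k, n)
        order = np.argsort(dm, axis=0)
        nearest = order[0]          # index into med, per point
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if len(medoids) > 1 else np.full(n, np.inf)

        # T[h, i] = total cost change of swapping out medoid i for candidate h;
        # G[h, j] = min(d(j,h) - d1(j), 0) is j's change when its medoid survives
        G = np.minimum(D - d1[None, :], 0.0)  # rows: candidate h, cols: point j
        base = G.sum(axis=1)  # (n,) per candidate h
        # correction for points whose nearest medoid is the one removed
        repl = np.minimum(D, d2[None, :]) - d1[None, :] - G  # (h, j)
        onehot = np.zeros((len(medoids), n))
        onehot[nearest, np.arange(n)] = 1.0
        corr = repl @ onehot.T  # (h, k)
        T = base[:, None] + corr  # (h, i)
        T[med, :] = np.inf  # current medoids are not swap-in candidates
        h, i = np.unravel_index(np.argmin(T), T.shape)
        if T[h, i] >= -1e-12:
            break
        medoids[int(i)] = int(h)
    return medoids


def kmedoids(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM (build + swap) under squared Euclidean dissimilarity.

    Returns (medoid indices, point assignments as indices into the medoid
    list, WCSS).  Besides the deterministic greedy BUILD start, additional
    seeded random starts can be run; the solution with the lowest WCSS wins.

    Raises if ``k`` exceeds the number of distinct points.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be 2-D")
    n = points.shape[0]
    n_distinct = np.unique(points, axis=0).shape[0]
    if k < 1 or k > n:
        raise VocabularyError(f"k={k} out of range for n={n} points")
    if k > n_distinct:
        raise VocabularyError(f"k={k} exceeds {n_distinct} distinct points")

    D = _pairwise_sq(points)
    starts: list[list[int]] = [_pam_build(D, k)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(list(rng.choice(n, size=k, replace=False)))

    best: tuple[float, list[int]] | None = None
    for start in starts:
        med = _pam_swap(D, start)
        cost = float(D[med].min(axis=0).sum())
        if best is None or cost < best[0] - 1e-12:
            best = (cost, sorted(med))
    wcss, medoids = best  # type: ignore[misc]
    med = np.asarray(medoids)
    assignments = np.argmin(D[med], axis=0)
    return med, assignments, wcss


def kmedoids_exhaustive(points: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Global optimum by enumerating all medoid subsets (testing oracle; tiny n only)."""
    from itertools import combinations

    points = np.asarray(points, dtype=np.float64)
    D = _pairwise_sq(points)
    n = points.shape[0]
    best_cost = np.inf
    best_subset: tuple[int, ...] = ()
    for subset in combinations(range(n), k):
        cost = float(D[list(subset)].min(axis=0).sum())
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_subset = subset
    return np.asarray(best_subset), best_cost


# ---------------------------------------------------------------------------
# Elbow selection
# ---------------------------------------------------------------------------

def select_k_elbow(wcss_curve: Sequence[tuple[int, float]]) -> int:
    """The candidate k maximizing perpendicular distance to the chord joining
    the curve's endpoints; ties broken toward smaller k.

    The curve must be non-increasing (an increasing WCSS with k signals
    clustering instability) and contain at least 3 candidates.
    """
    curve = sorted((int(k), float(w)) for k, w in wcss_curve)
    if len(curve) < 3:
        raise VocabularyError("elbow selection needs at least 3 candidates")
    ks = np.array([c[0] for c in curve], dtype=np.float64)
    ws = np.array([c[1] for c in curve], dtype=np.float64)
    if np.any(np.diff(ws) > 1e-9 * max(1.0, ws[0])):
        raise VocabularyError("WCSS curve is not non-increasing")
    p0 = np.array([ks[0], ws[0]])
    p1 = np.array([ks[-1], ws[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return int(ks[1])
    pts = np.column_stack([ks, ws]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    # ties toward smaller k: argmax returns the first maximum on the sorted grid
    best = int(np.argmax(np.round(dist / max(dist.max(), 1e-300), 12)))
    if best in (0, len(curve) - 1) and len(curve) > 2:
        best = 1 if dist[1] >= dist[len(curve) - 2] else len(curve) - 2
    return int(ks[best])


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass
class VocabularyModel:
    """Per-window-size word vocabulary.

    ``medoids`` are stored in original descriptor units; ``loc``/``scale`` are
    the standardization parameters (estimated on the building set) applied
    before any distance computation, at build and at encode time alike.
    """

    window_s: float
    k: int
    medoids: np.ndarray          # (k, 10), original units
    loc: np.ndarray              # (10,)
    scale: np.ndarray            # (10,)
    wcss_curve: list[tuple[int, float]]
    k_candidates: tuple[int, ...]
    seed: int

    def standardize(self, descriptors: np.ndarray) -> np.ndarray:
        return (descriptors - self.loc) / self.scale

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "window_s": self.window_s,
            "k": self.k,
            "medoids": self.medoids.tolist(),
            "loc": self.loc.tolist(),
            "scale": self.scale.tolist(),
            "wcss_curve": [[int(k), float(w)] for k, w in self.wcss_curve],
            "k_candidates": list(self.k_candidates),
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "VocabularyModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            window_s=payload["window_s"],
            k=payload["k"],
            medoids=np.asarray(payload["medoids"]),
            loc=np.asarray(payload["loc"]),
            scale=np.asarray(payload["scale"]),
            wcss_curve=[(int(k), float(w)) for k, w in payload["wcss_curve"]],
            k_candidates=tuple(payload["k_candidates"]),
            seed=payload["seed"],
        )


def build_vocabulary(
    descriptors_by_subject: Mapping[str, np.ndarray],
    window_s: float,
    k_candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
    seed: int = 0,
    subsample_size: int = 2000,
    n_restarts: int = 2,
) -> VocabularyModel:
    """Learn a vocabulary from pooled cohort descriptors at one window size.

    CLARA-style: PAM runs on a seeded subsample (plus restarts; best WCSS
    kept), then every pooled descriptor is assigned to its nearest medoid to
    evaluate the WCSS reported for each candidate k.  k is chosen by
    :func:`select_k_elbow`; rows with non-finite descriptors (flagged null
    segments) are dropped before pooling.
    """
    if len(descriptors_by_subject) < 2:
        raise VocabularyError("vocabulary needs descriptors from >= 2 subjects")
    pooled = np.vstack([np.asarray(v, dtype=np.float64) for v in descriptors_by_subject.values()])
    pooled = pooled[np.all(np.isfinite(pooled), axis=1)]
    n = pooled.shape[0]
    k_candidates = tuple(sorted(int(k) for k in k_candidates))
    if subsample_size < max(k_candidates):
        raise VocabularyError("subsample smaller than the largest candidate k")

    loc = pooled.mean(axis=0)
    scale = pooled.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    std = (pooled - loc) / scale

    rng = np.random.default_rng(seed)
    if n > subsample_size:
        idx = rng.choice(n, size=subsample_size, replace=False)
        train = std[idx]
    else:
        train = std

    curve: list[tuple[int, float]] = []
    medoids_by_k: dict[int, np.ndarray] = {}
    for k in k_candidates:
        med_idx, _, _ = kmedoids(train, k, seed=seed + k, n_restarts=n_restarts)
        med = train[med_idx]
        # WCSS over the full pooled set, not just the subsample
        d = _cross_sq(std, med)
        curve.append((k, float(d.min(axis=1).sum())))
        medoids_by_k[k] = med

    chosen = select_k_elbow(curve)
    medoids_std = medoids_by_k[chosen]
    return VocabularyModel(
        window_s=window_s,
        k=chosen,
        medoids=medoids_std * scale + loc,
        loc=loc,
        scale=scale,
        wcss_curve=curve,
        k_candidates=k_candidates,
        seed=seed,
    )


def _cross_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    np.maximum(d, 0.0, out=d)
    return d


# ---------------------------------------------------------------------------
# Documents
# ---------------------------------------------------------------------------

@dataclass
class SubjectDocument:
    """One subject's word counts and term frequencies at one window size."""

    subject_id: str
    window_s: float
    counts: np.ndarray

    @property
    def tf(self) -> np.ndarray:
        return term_frequencies(self.counts)


def encode_document(
    subject_id: str, descriptors: np.ndarray, vocabulary: VocabularyModel
) -> SubjectDocument:
    """Map each segment descriptor to its nearest medoid word and count words."""
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if descriptors.size == 0:
        raise VocabularyError(f"subject {subject_id!r}: no segments to encode")
    bad = ~np.all(np.isfinite(descriptors), axis=1)
    if np.any(bad):
        raise VocabularyError(
            f"subject {subject_id!r}: non-finite descriptor in segment "
            f"{int(np.nonzero(bad)[0][0])}"
        )
    std = vocabulary.standardize(descriptors)
    med = vocabulary.standardize(vocabulary.medoids)
    words = np.argmin(_cross_sq(std, med), axis=1)
    counts = np.bincount(words, minlength=vocabulary.k)
    return SubjectDocument(subject_id, vocabulary.window_s, counts)


def term_frequencies(counts: np.ndarray) -> np.ndarray:
    """counts / total; a probability vector.  Errors on an empty document."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise VocabularyError("document has zero words")
    return counts / total


def concatenate_strategies(
    tf_by_window: Mapping[float, np.ndarray],
    strategy_order: Sequence[float],
) -> np.ndarray:
    """TF vectors concatenated in fixed ascending-window order."""
    missing = [w for w in strategy_order if w not in tf_by_window]
    if missing:
        raise VocabularyError(f"missing strategies: {missing}")
    return np.concatenate([np.asarray(tf_by_window[w]) for w in sorted(strategy_order)])


def word_feature_table(
    documents_by_window: Mapping[float, Sequence[SubjectDocument]],
) -> pd.DataFrame:
    """Subjects x concatenated-TF table; columns ``w<window>s_<i>``."""
    frames = []
    for w in sorted(documents_by_window):
        docs = documents_by_window[w]
        tf = np.vstack([d.tf for d in docs])
        cols = [f"w{w:g}s_{i}" for i in range(tf.shape[1])]
        frames.append(
            pd.DataFrame(tf, index=[d.subject_id for d in docs], columns=cols)
        )
    out = pd.concat(frames, axis=1)
    if out.isna().any().any():
        raise VocabularyError("subject sets differ across strategies")
    return out
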