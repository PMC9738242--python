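"""End-to-end feature pipelines over a cohort of recording sessions.

Bridges the signal modules into the two feature families compared by the
analysis: per-subject averaged statistical descriptors and per-subject
term-frequency documents, each at five windowing strategies and concatenated.

Two vocabulary scopes are first class:

* ``cohort`` (protocol-faithful) — vocabularies are built on descriptors pooled
  over the whole cohort; the test subjects of a later CV split contributed to
  the vocabulary (a known, deliberate leak in the original protocol);
* ``leak-free`` — vocabularies are rebuilt inside each training fold and the
  held-out subjects are encoded with medoids they never influenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bow, features, modeling
from .segmentation import FULL_SCALE_WINDOWS_S, WindowSpec
from .synth import CohortConfig, RecordingSession

#: Desk-scale windowing strategies (seconds): the five-scale ladder compressed
#: eightfold so the shortest window still spans ~2 cycles of a 5-Hz tremor at
#: 32 Hz while day-scale runs stay desk-sized.
DESK_WINDOWS_S: tuple[float, ...] = (0.375, 1.25, 7.5, 37.5, 112.5)


@dataclass
class Preset:
    """One coherent choice of cohort scale, window set and vocabulary knobs."""

    name: str
    windows_s: tuple[float, ...]
    fs_hz: float
    day_len_s: float
    days: int
    k_candidates: tuple[int, ...] = bow.DEFAULT_K_CANDIDATES
    subsample_size: int = 2000
    n_restarts: int = 2

    def cohort_config(self, master_seed: int = 0, **overrides) -> CohortConfig:
        kw = dict(
            days=self.days,
            day_len_s=self.day_len_s,
            fs_hz=self.fs_hz,
            master_seed=master_seed,
        )
        kw.update(overrides)
        return CohortConfig(**kw)


def desk_preset() -> Preset:
    """Compressed days (1800 s) at 32 Hz with eightfold-scaled windows."""
    return Preset(
        name="desk", windows_s=DESK_WINDOWS_S, fs_hz=32.0, day_len_s=1800.0, days=7
    )


def full_scale_preset() -> Preset:
    """Full scale: 100 Hz, 86 400-s days, the unscaled window set."""
    return Preset(
        name="full-scale",
        windows_s=FULL_SCALE_WINDOWS_S,
        fs_hz=100.0,
        day_len_s=86400.0,
        days=7,
        subsample_size=20000,
        n_restarts=5,
    )


def mini_preset(days: int = 2, day_len_s: float = 600.0) -> Preset:
    """A small desk variant for quick experiments and smoke runs."""
    return Preset(
        name="mini",
        windows_s=DESK_WINDOWS_S,
        fs_hz=32.0,
        day_len_s=day_len_s,
        days=days,
        k_candidates=(2, 4, 8, 12, 16),
        subsample_size=800,
        n_restarts=2,
    )


# ---------------------------------------------------------------------------
# Descriptor extraction
# ---------------------------------------------------------------------------

def cohort_descriptors(
    sessions: Iterable[RecordingSession], windows_s: Sequence[float]
) -> dict[float, dict[str, np.ndarray]]:
    """Per window size, per subject: the (n_segments, 10) descriptor arrays."""
    out: dict[float, dict[str, np.ndarray]] = {w: {} for w in windows_s}
    for session in sessions:
        for w in windows_s:
            spec = WindowSpec(w, session.fs_hz)
            out[w][session.subject_id] = features.session_descriptors(
                session.samples, spec
            )
    return out


def cohort_labels(sessions: Sequence[RecordingSession]) -> pd.Series:
    return pd.Series(
        {s.subject_id: s.group for s in sessions}, name="group"
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def statistical_feature_table(
    sessions: Sequence[RecordingSession], windows_s: Sequence[float]
) -> pd.DataFrame:
    """Subjects x (10 descriptors x windows) averaged-statistics table."""
    return features.cohort_feature_table(sessions, windows_s)


def statistical_table_from_descriptors(
    descriptors: Mapping[float, Mapping[str, np.ndarray]],
) -> pd.DataFrame:
    """Same table as :func:`statistical_feature_table`, reusing precomputed
    descriptor arrays (flagged-null segments excluded from the means)."""
    columns = {}
    for w in sorted(descriptors):
        by_subject = descriptors[w]
        for sid, arr in by_subject.items():
            means = np.nanmean(np.asarray(arr, dtype=np.float64), axis=0)
            for name, val in zip(features.DESCRIPTOR_NAMES, means):
                columns.setdefault(f"{name}_{w:g}s", {})[sid] = float(val)
    table = pd.DataFrame(columns)
    return table[features.feature_columns(list(descriptors))]


def build_vocabularies(
    descriptors: Mapping[float, Mapping[str, np.ndarray]],
    preset: Preset,
    seed: int = 0,
    subjects: Sequence[str] | None = None,
) -> dict[float, bow.VocabularyModel]:
    """One vocabulary per windowing strategy.

    With ``subjects`` given, only those subjects' descriptors enter the
    vocabulary (the leak-free training scope); encoding remains possible for
    any subject.
    """
    vocabularies = {}
    for i, w in enumerate(sorted(descriptors)):
        by_subject = descriptors[w]
        if subjects is not None:
            by_subject = {s: by_subject[s] for s in subjects}
        vocabularies[w] = bow.build_vocabulary(
            by_subject,
            window_s=w,
            k_candidates=preset.k_candidates,
            seed=seed + i,
            subsample_size=preset.subsample_size,
            n_restarts=preset.n_restarts,
        )
    return vocabularies


def word_feature_table(
    descriptors: Mapping[float, Mapping[str, np.ndarray]],
    vocabularies: Mapping[float, bow.VocabularyModel],
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Subjects x concatenated-TF table across all strategies."""
    docs_by_window = {}
    for w, vocab in vocabularies.items():
        by_subject = descriptors[w]
        ids = list(subjects) if subjects is not None else list(by_subject)
        docs_by_window[w] = [
            bow.encode_document(sid, by_subject[sid], vocab) for sid in ids
        ]
    return bow.word_feature_table(docs_by_window)


def single_strategy_tables(
    table: pd.DataFrame, windows_s: Sequence[float], kind: str
) -> dict[str, pd.DataFrame]:
    """Split a concatenated table into its per-window single-strategy tables."""
    out = {}
    for w in sorted(windows_s):
        if kind == "stat":
            cols = features.single_window_columns(table.columns, w)
        elif kind == "word":
            cols = [c for c in table.columns if c.startswith(f"w{w:g}s_")]
        else:
            raise ValueError(kind)
        out[f"{w:g}s"] = table[cols]
    return out


# ---------------------------------------------------------------------------
# Leak-free word-feature cross-validation
# ---------------------------------------------------------------------------

def leak_free_word_cv(
    descriptors: Mapping[float, Mapping[str, np.ndarray]],
    labels: pd.Series,
    preset: Preset,
    classifier_id: str = "SVM",
    settings: modeling.CVSettings | None = None,
    seed: int = 0,
    vocab_hash_log: list | None = None,
) -> modeling.ExperimentResult:
    """Repeated CV where vocabularies are rebuilt on each run's training folds.

    Slower than the cohort-scope path by a factor of ``folds``; intended for
    leakage-sensitivity analyses.  ``vocab_hash_log`` (if given) receives
    (train-subject tuple, vocabulary hash) pairs for leakage auditing.
    """
    from sklearn.model_selection import StratifiedKFold

    settings = settings or modeling.CVSettings(n_runs=5, folds=5, compute_auc=False)
    subjects = list(labels.index)
    y = (labels.to_numpy() == "PD").astype(int)
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(2 * settings.n_runs) % (2**31)

    accs = np.empty(settings.n_runs)
    for r in range(settings.n_runs):
        cv = StratifiedKFold(
            n_splits=settings.folds, shuffle=True, random_state=int(run_seeds[2 * r])
        )
        pred = np.empty_like(y)
        for train, test in cv.split(np.zeros((len(subjects), 1)), y):
            train_ids = [subjects[i] for i in train]
            vocabs = build_vocabularies(
                descriptors, preset, seed=int(run_seeds[2 * r + 1]), subjects=train_ids
            )
            if vocab_hash_log is not None:
                vocab_hash_log.append(
                    (tuple(sorted(train_ids)), _vocab_hash(vocabs))
                )
            table = word_feature_table(descriptors, vocabs, subjects=subjects)
            X = table.to_numpy()
            model = modeling.make_classifier(classifier_id, int(run_seeds[2 * r + 1]))
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        accs[r] = float(np.mean(pred == y))
    return modeling.ExperimentResult(
        feature_set="words-leakfree",
        classifier_id=classifier_id,
        accuracies=accs,
        aucs=None,
        n_runs=settings.n_runs,
        folds=settings.folds,
        seed=seed,
    )


def _vocab_hash(vocabs: Mapping[float, bow.VocabularyModel]) -> str:
    import hashlib

    h = hashlib.sha256()
    for w in sorted(vocabs):
        v = vocabs[w]
        h.update(np.ascontiguousarray(v.medoids).tobytes())
        h.update(str(v.k).encode())
    return h.hexdigest()
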