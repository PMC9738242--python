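"""Classifier evaluation harness and genetic-algorithm feature selection.

Evaluation follows the repeated cross-validation protocol: each of ``n_runs``
runs draws a fresh shuffled stratified 10-fold split, each classifier predicts
every subject exactly once per run, and the run's accuracy is the pooled
held-out accuracy.  AUC is computed per run from the pooled held-out decision
scores.  Six classifiers are evaluated: SVM (RBF kernel), naive Bayes,
decision tree, random forest, KNN and AdaBoost, each behind a
standardize-then-fit pipeline with pinned hyperparameters.

The GA evolves binary feature masks: population 40, 50 generations, 20 parents
per generation (the 10 fittest plus 10 random), 4 uniform crossovers of random
parent pairs, and a 14 % per-individual mutation chance.  Fitness combines the
mean cross-validated accuracy over the classifier set with a sparsity penalty
``lambda * n_selected / n_total``; the best individual ever seen is carried
forward (elitism), so the returned optimum's fitness trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.metrics import roc_auc_score

CLASSIFIER_IDS: tuple[str, ...] = ("SVM", "NB", "DT", "RF", "KNN", "AB")

#: Pinned hyperparameters (library defaults unless noted); recorded in results.
CLASSIFIER_PARAMS: dict[str, dict] = {
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "NB": {},
    "DT": {},
    "RF": {"n_estimators": 100},
    "KNN": {"n_neighbors": 5},
    "AB": {"n_estimators": 50},
}


def make_classifier(classifier_id: str, seed: int) -> BaseEstimator:
    """A fresh standardize-then-fit pipeline for one classifier id."""
    p = CLASSIFIER_PARAMS
    if classifier_id == "SVM":
        clf = SVC(random_state=seed, **p["SVM"])
    elif classifier_id == "NB":
        clf = GaussianNB(**p["NB"])
    elif classifier_id == "DT":
        clf = DecisionTreeClassifier(random_state=seed, **p["DT"])
    elif classifier_id == "RF":
        clf = RandomForestClassifier(random_state=seed, **p["RF"])
    elif classifier_id == "KNN":
        clf = KNeighborsClassifier(**p["KNN"])
    elif classifier_id == "AB":
        clf = AdaBoostClassifier(random_state=seed, **p["AB"])
    else:
        raise ValueError(f"unknown classifier id {classifier_id!r}")
    return make_pipeline(StandardScaler(), clf)


@dataclass
class CVSettings:
    """Repeated cross-validation protocol parameters."""

    n_runs: int = 100
    folds: int = 10
    stratified: bool = True
    compute_auc: bool = True


@dataclass
class ExperimentResult:
    """Per-run accuracy (and AUC) arrays for one (feature set, classifier)."""

    feature_set: str
    classifier_id: str
    accuracies: np.ndarray
    aucs: np.ndarray | None
    n_runs: int
    folds: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def run_cv(
    X,
    y,
    classifier_id: str,
    settings: CVSettings | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Repeated k-fold evaluation of one classifier.

    Per run: a fresh shuffled (stratified by default) fold split; accuracy is
    pooled over the folds' held-out predictions.  Deterministic given ``seed``.
    """
    settings = settings or CVSettings()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need two classes")
    if settings.folds > X.shape[0]:
        raise ValueError("more folds than subjects")
    y_bin = (y == classes[-1]).astype(int)

    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(2 * settings.n_runs) % (2**31)
    accs = np.empty(settings.n_runs)
    aucs = np.empty(settings.n_runs) if settings.compute_auc else None
    for r in range(settings.n_runs):
        split_seed = int(run_seeds[2 * r])
        fit_seed = int(run_seeds[2 * r + 1])
        cv_cls = StratifiedKFold if settings.stratified else KFold
        cv = cv_cls(n_splits=settings.folds, shuffle=True, random_state=split_seed)
        pred = np.empty_like(y_bin)
        score = np.empty(len(y_bin), dtype=np.float64)
        for train, test in cv.split(X, y_bin):
            model = make_classifier(classifier_id, fit_seed)
            model.fit(X[train], y_bin[train])
            pred[test] = model.predict(X[test])
            if settings.compute_auc:
                score[test] = _scores(model, X[test])
        accs[r] = float(np.mean(pred == y_bin))
        if settings.compute_auc:
            aucs[r] = float(roc_auc_score(y_bin, score))
    return ExperimentResult(
        feature_set="",
        classifier_id=classifier_id,
        accuracies=accs,
        aucs=aucs,
        n_runs=settings.n_runs,
        folds=settings.folds,
        seed=seed,
        params=dict(CLASSIFIER_PARAMS[classifier_id]),
    )


def evaluate_feature_sets(
    feature_sets: Mapping[str, pd.DataFrame],
    labels: pd.Series,
    classifier_ids: Sequence[str] = CLASSIFIER_IDS,
    settings: CVSettings | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], ExperimentResult]:
    """One :class:`ExperimentResult` per (feature set, classifier).

    All tables must index the same subjects; the per-(set, classifier) seed is
    derived from ``seed`` so identical plans reproduce identical results.
    """
    settings = settings or CVSettings()
    results: dict[tuple[str, str], ExperimentResult] = {}
    subjects = None
    for set_idx, (name, table) in enumerate(feature_sets.items()):
        if subjects is None:
            subjects = tuple(table.index)
        elif tuple(table.index) != subjects:
            raise ValueError(f"feature set {name!r}: subject ids differ across tables")
        y = labels.loc[list(table.index)].to_numpy()
        for clf_idx, cid in enumerate(classifier_ids):
            sub_seed = int(
                np.random.SeedSequence([seed, set_idx, clf_idx]).generate_state(1)[0]
                % (2**31)
            )
            res = run_cv(table.to_numpy(), y, cid, settings, seed=sub_seed)
            res.feature_set = name
            results[(name, cid)] = res
    return results


def summarize_results(
    results: Mapping[tuple[str, str], ExperimentResult],
    scale: float = 100.0,
) -> pd.DataFrame:
    """Mean +/- sd accuracy table: one row per feature set, one column per classifier."""
    rows: dict[str, dict[str, str]] = {}
    for (name, cid), res in results.items():
        rows.setdefault(name, {})[cid] = (
            f"{scale * res.mean_accuracy:.1f} ± {scale * res.sd_accuracy:.1f}"
        )
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """GA hyperparameters for binary feature-mask evolution."""

    population_size: int = 40
    generations: int = 50
    parents_selected: int = 20   # half fittest, half random
    crossovers_per_generation: int = 4
    mutation_prob: float = 0.14
    sparsity_weight: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parents_selected > self.population_size:
            raise ValueError("parents_selected must not exceed population_size")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be a probability")


@dataclass
class FeatureMask:
    """A selected feature subset with its fitness and provenance."""

    columns: tuple[str, ...]
    mask: np.ndarray
    fitness: float
    generation_found: int
    fitness_trace: list[float] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [c for c, m in zip(self.columns, self.mask) if m]


def ga_select(
    features: pd.DataFrame,
    labels: pd.Series,
    ga_config: GAConfig | None = None,
    cv_settings: CVSettings | None = None,
    classifier_ids: Sequence[str] = CLASSIFIER_IDS,
) -> FeatureMask:
    """Evolve a feature mask maximizing mean CV accuracy minus a sparsity penalty.

    Fitness(mask) = mean over ``classifier_ids`` of the mean repeated-CV
    accuracy on the masked table, minus ``sparsity_weight * n_sel / n_total``.
    The next generation is {best} | crossover offspring | mutated parents |
    fresh random individuals, up to the population size.  Fitness values are
    memoized per mask.  Deterministic given the config seed.
    """
    cfg = ga_config or GAConfig()
    cv = cv_settings or CVSettings(n_runs=2, folds=5, compute_auc=False)
    n_feat = features.shape[1]
    if n_feat < 1:
        raise ValueError("empty feature table")
    X_full = features.to_numpy(dtype=np.float64)
    y = labels.loc[list(features.index)].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cols = np.nonzero(mask)[0]
            accs = [
                run_cv(X_full[:, cols], y, cid, cv, seed=cfg.seed).mean_accuracy
                for cid in classifier_ids
            ]
            cache[key] = float(np.mean(accs)) - cfg.sparsity_weight * (
                cols.size / n_feat
            )
        return cache[key]

    def random_mask() -> np.ndarray:
        m = rng.random(n_feat) < 0.5
        if not m.any():
            m[rng.integers(n_feat)] = True
        return m

    def mutate(mask: np.ndarray) -> np.ndarray:
        out = mask.copy()
        flips = rng.random(n_feat) < max(1.0 / n_feat, 0.05)
        out ^= flips
        if not out.any():
            out[rng.integers(n_feat)] = True
        return out

    population = [random_mask() for _ in range(cfg.population_size)]
    best_mask: np.ndarray | None = None
    best_fit = -np.inf
    best_gen = 0
    trace: list[float] = []

    for gen in range(cfg.generations + 1):
        fits = np.array([fitness(m) for m in population])
        order = np.argsort(-fits, kind="stable")
        gen_best = int(order[0])
        # lexicographic tie-break toward fewer features
        if fits[gen_best] > best_fit or (
            best_mask is not None
            and np.isclose(fits[gen_best], best_fit)
            and population[gen_best].sum() < best_mask.sum()
        ):
            best_fit = float(fits[gen_best])
            best_mask = population[gen_best].copy()
            best_gen = gen
        trace.append(best_fit)
        if gen == cfg.generations:
            break

        half = cfg.parents_selected // 2
        fittest = [population[i] for i in order[:half]]
        rest = [population[i] for i in order[half:]]
        n_random = min(cfg.parents_selected - half, len(rest))
        random_parents = [rest[i] for i in rng.choice(len(rest), n_random, replace=False)] if rest else []
        parents = fittest + random_parents

        offspring = []
        for _ in range(cfg.crossovers_per_generation):
            i, j = rng.choice(len(parents), size=2, replace=False)
            take = rng.random(n_feat) < 0.5
            child = np.where(take, parents[i], parents[j])
            if not child.any():
                child[rng.integers(n_feat)] = True
            offspring.append(child)

        mutated = [
            mutate(p) if rng.random() < cfg.mutation_prob else p.copy()
            for p in parents
        ]
        nxt = [best_mask.copy()] + offspring + mutated
        while len(nxt) < cfg.population_size:
            nxt.append(random_mask())
        population = nxt[: cfg.population_size]

    assert best_mask is not None
    return FeatureMask(
        columns=tuple(features.columns),
        mask=best_mask,
        fitness=best_fit,
        generation_found=best_gen,
        fitness_trace=trace,
    )


def nested_ga_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    classifier_id: str = "SVM",
    ga_config: GAConfig | None = None,
    ga_cv: CVSettings | None = None,
    ga_classifiers: Sequence[str] = ("NB",),
    settings: CVSettings | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Leak-free variant: the GA reruns inside each training fold.

    The standard protocol selects features against the full cohort and then
    cross-validates on that same cohort, which leaks selection information.
    Here each fold's mask is evolved on the training subjects only and applied
    to the held-out subjects; accuracies are therefore unbiased (and slower by
    a factor of runs x folds).
    """
    settings = settings or CVSettings(n_runs=2, folds=5, compute_auc=False)
    ga_config = ga_config or GAConfig(
        population_size=10, generations=3, parents_selected=6
    )
    X = features.to_numpy(dtype=np.float64)
    y = labels.loc[list(features.index)].to_numpy()
    classes = np.unique(y)
    y_bin = (y == classes[-1]).astype(int)
    run_seeds = np.random.SeedSequence(seed).generate_state(2 * settings.n_runs) % (
        2**31
    )
    accs = np.empty(settings.n_runs)
    for r in range(settings.n_runs):
        cv = StratifiedKFold(
            n_splits=settings.folds, shuffle=True, random_state=int(run_seeds[2 * r])
        )
        pred = np.empty_like(y_bin)
        for f, (train, test) in enumerate(cv.split(X, y_bin)):
            mask = ga_select(
                features.iloc[train],
                labels.iloc[train],
                dataclasses_replace_seed(ga_config, int(run_seeds[2 * r + 1]) + f),
                ga_cv,
                classifier_ids=ga_classifiers,
            )
            cols = np.nonzero(mask.mask)[0]
            model = make_classifier(classifier_id, int(run_seeds[2 * r + 1]))
            model.fit(X[np.ix_(train, cols)], y_bin[train])
            pred[test] = model.predict(X[np.ix_(test, cols)])
        accs[r] = float(np.mean(pred == y_bin))
    return ExperimentResult(
        feature_set="nested-ga",
        classifier_id=classifier_id,
        accuracies=accs,
        aucs=None,
        n_runs=settings.n_runs,
        folds=settings.folds,
        seed=seed,
    )


def dataclasses_replace_seed(cfg: GAConfig, seed: int) -> GAConfig:
    import dataclasses

    return dataclasses.replace(cfg, seed=int(seed) % (2**31))
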