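"""The two experiment workflows, end to end.

* :func:`fig1_workflow` — find the best feature-engineering method and
  windowing strategy: build statistical and word features per strategy,
  combined, and GA-reduced; evaluate every (feature set x classifier) with
  repeated CV; compare windowing strategies (ANOVA + Tukey on the word sets)
  and the two feature families (one-sided paired t-test).
* :func:`fig2_workflow` — find the optimal amount of data: truncate the cohort
  to 1..D day units, recompute the word pipeline per day count, evaluate the
  chosen classifier, and compare the day-wise accuracy distributions
  (Kruskal–Wallis + Dunn–Bonferroni behind normality/homogeneity gates).

Every workflow writes a self-describing artifact directory (config, seeds,
tables, reports) and returns a content hash over the artifacts, so identical
(config, seed) runs can be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bow, evalstats, modeling, pipeline, synth
from .modeling import CVSettings, GAConfig
from .pipeline import Preset


@dataclass
class RunConfig:
    """Everything one workflow run needs, serializable to YAML."""

    preset: Preset = field(default_factory=pipeline.desk_preset)
    n_he: int = synth.DEFAULT_N_HE
    n_pd: int = synth.DEFAULT_N_PD
    null_effect: bool = False
    cv: CVSettings = field(default_factory=CVSettings)
    ga: GAConfig = field(default_factory=GAConfig)
    ga_cv: CVSettings = field(default_factory=lambda: CVSettings(n_runs=1, folds=5, compute_auc=False))
    ga_classifiers: tuple[str, ...] = ("NB", "DT", "KNN")
    classifiers: tuple[str, ...] = modeling.CLASSIFIER_IDS
    comparison_classifier: str = "SVM"
    master_seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["preset"] = Preset(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload["preset"].items()
        })
        payload["cv"] = CVSettings(**payload["cv"])
        payload["ga"] = GAConfig(**payload["ga"])
        payload["ga_cv"] = CVSettings(**payload["ga_cv"])
        for key in ("ga_classifiers", "classifiers"):
            payload[key] = tuple(payload[key])
        return cls(**payload)

    def cohort_config(self) -> synth.CohortConfig:
        if self.null_effect:
            cfg = synth.null_cohort_config(
                n_he=self.n_he,
                n_pd=self.n_pd,
                days=self.preset.days,
                day_len_s=self.preset.day_len_s,
                fs_hz=self.preset.fs_hz,
                master_seed=self.master_seed,
            )
        else:
            cfg = self.preset.cohort_config(
                master_seed=self.master_seed, n_he=self.n_he, n_pd=self.n_pd
            )
        return cfg


@dataclass
class Fig1Result:
    feature_tables: dict[str, pd.DataFrame]
    results: dict[tuple[str, str], modeling.ExperimentResult]
    summary: pd.DataFrame
    windowing_report: evalstats.ComparisonReport
    methods_report: evalstats.ComparisonReport
    stat_mask: modeling.FeatureMask
    word_mask: modeling.FeatureMask
    vocabularies: dict[float, bow.VocabularyModel]
    artifact_hash: str


def _seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def build_feature_sets(
    sessions, config: RunConfig
) -> tuple[dict[str, pd.DataFrame], pd.Series, dict, modeling.FeatureMask, modeling.FeatureMask]:
    """All Fig-1 feature tables: per-strategy, combined, and GA-reduced, for
    both feature families."""
    preset = config.preset
    labels = pipeline.cohort_labels(sessions)
    descriptors = pipeline.cohort_descriptors(sessions, preset.windows_s)

    stat_all = pipeline.statistical_table_from_descriptors(descriptors)
    stat_all = stat_all.loc[list(labels.index)]
    vocabs = pipeline.build_vocabularies(
        descriptors, preset, seed=_seed(config.master_seed, 1)
    )
    word_all = pipeline.word_feature_table(descriptors, vocabs)
    word_all = word_all.loc[stat_all.index]

    tables: dict[str, pd.DataFrame] = {}
    for name, tab in pipeline.single_strategy_tables(stat_all, preset.windows_s, "stat").items():
        tables[f"stat-{name}"] = tab
    tables["stat-all"] = stat_all
    for name, tab in pipeline.single_strategy_tables(word_all, preset.windows_s, "word").items():
        tables[f"word-{name}"] = tab
    tables["word-all"] = word_all

    stat_mask = modeling.ga_select(
        stat_all,
        labels,
        dataclasses.replace(config.ga, seed=_seed(config.master_seed, 2)),
        config.ga_cv,
        classifier_ids=config.ga_classifiers,
    )
    word_mask = modeling.ga_select(
        word_all,
        labels,
        dataclasses.replace(config.ga, seed=_seed(config.master_seed, 3)),
        config.ga_cv,
        classifier_ids=config.ga_classifiers,
    )
    tables["stat-reduced"] = stat_all[stat_mask.selected]
    tables["word-reduced"] = word_all[word_mask.selected]
    return tables, labels, vocabs, stat_mask, word_mask


def fig1_workflow(config: RunConfig, outdir: str | Path | None = None) -> Fig1Result:
    """Feature-engineering and windowing comparison, end to end."""
    sessions = synth.generate_cohort(config.cohort_config())
    tables, labels, vocabs, stat_mask, word_mask = build_feature_sets(sessions, config)

    results = modeling.evaluate_feature_sets(
        tables,
        labels,
        classifier_ids=config.classifiers,
        settings=config.cv,
        seed=_seed(config.master_seed, 4),
    )
    summary = modeling.summarize_results(results)

    cid = config.comparison_classifier
    word_groups = {
        name: results[(name, cid)].accuracies
        for name in tables
        if name.startswith("word-")
    }
    windowing_report = evalstats.compare_windowing(word_groups)

    stat_acc = np.concatenate(
        [results[("stat-reduced", c)].accuracies for c in config.classifiers]
    )
    word_acc = np.concatenate(
        [results[("word-reduced", c)].accuracies for c in config.classifiers]
    )
    methods_report = evalstats.compare_methods(stat_acc, word_acc)

    artifact_hash = ""
    if outdir is not None:
        artifact_hash = _write_fig1_artifacts(
            Path(outdir), config, tables, results, summary,
            windowing_report, methods_report, stat_mask, word_mask, vocabs,
        )
    return Fig1Result(
        feature_tables=tables,
        results=results,
        summary=summary,
        windowing_report=windowing_report,
        methods_report=methods_report,
        stat_mask=stat_mask,
        word_mask=word_mask,
        vocabularies=vocabs,
        artifact_hash=artifact_hash,
    )


@dataclass
class Fig2Result:
    accuracy_by_day: dict[str, np.ndarray]
    report: evalstats.ComparisonReport
    artifact_hash: str


def fig2_workflow(config: RunConfig, outdir: str | Path | None = None) -> Fig2Result:
    """Day-wise data-amount experiment.

    For each d in 1..days, every session is truncated to its first d day
    units, the word pipeline (vocabularies included) is recomputed on the
    truncated cohort, and the comparison classifier is evaluated with repeated
    CV.  The day-wise accuracy groups then go through the gated omnibus test.
    """
    preset = config.preset
    sessions = synth.generate_cohort(config.cohort_config())
    labels = pipeline.cohort_labels(sessions)
    groups: dict[str, np.ndarray] = {}
    for d in range(1, preset.days + 1):
        truncated = [s.truncated(d * preset.day_len_s) for s in sessions]
        descriptors = pipeline.cohort_descriptors(truncated, preset.windows_s)
        vocabs = pipeline.build_vocabularies(
            descriptors, preset, seed=_seed(config.master_seed, 10, d)
        )
        table = pipeline.word_feature_table(descriptors, vocabs)
        table = table.loc[list(labels.index)]
        res = modeling.run_cv(
            table.to_numpy(),
            labels.to_numpy(),
            config.comparison_classifier,
            config.cv,
            seed=_seed(config.master_seed, 11, d),
        )
        groups[f"day{d}"] = res.accuracies
    report = evalstats.days_comparison(groups)

    artifact_hash = ""
    if outdir is not None:
        artifact_hash = _write_fig2_artifacts(Path(outdir), config, groups, report)
    return Fig2Result(accuracy_by_day=groups, report=report, artifact_hash=artifact_hash)


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _report_payload(report: evalstats.ComparisonReport) -> dict:
    return {
        "test_name": report.test_name,
        "statistic": report.statistic,
        "df": list(report.df),
        "p_value": report.p_value,
        "gates": report.gates,
        "extra": report.extra,
        "pairwise": [
            {
                "group_a": e.group_a,
                "group_b": e.group_b,
                "statistic": e.statistic,
                "p_adjusted": e.p_adjusted,
                "significant": e.significant,
            }
            for e in report.pairwise
        ],
    }


def _hash_dir(outdir: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "HASH"):
        h.update(f.relative_to(outdir).as_posix().encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def _write_runs_csv(results: Mapping[tuple[str, str], modeling.ExperimentResult], path: Path) -> None:
    rows = []
    for (name, cid), res in results.items():
        for r, acc in enumerate(res.accuracies):
            row = {"feature_set": name, "classifier": cid, "run": r, "accuracy": acc}
            if res.aucs is not None:
                row["auc"] = res.aucs[r]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_fig1_artifacts(
    outdir, config, tables, results, summary, windowing_report,
    methods_report, stat_mask, word_mask, vocabs,
) -> str:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary.to_csv(outdir / "summary_accuracy.csv")
    _write_runs_csv(results, outdir / "runs.csv")
    for name, tab in tables.items():
        tab.to_csv(outdir / f"features_{name}.csv")
    for w, v in vocabs.items():
        v.to_json(outdir / f"vocabulary_{w:g}s.json")
    (outdir / "masks.json").write_text(json.dumps({
        "stat_reduced": stat_mask.selected,
        "word_reduced": word_mask.selected,
        "stat_fitness": stat_mask.fitness,
        "word_fitness": word_mask.fitness,
    }, indent=1))
    (outdir / "windowing_report.json").write_text(
        json.dumps(_report_payload(windowing_report), indent=1)
    )
    (outdir / "methods_report.json").write_text(
        json.dumps(_report_payload(methods_report), indent=1)
    )
    manifest = {
        "master_seed": config.master_seed,
        "classifiers": list(config.classifiers),
        "cv": dataclasses.asdict(config.cv),
        "feature_set_hashes": {
            name: hashlib.sha256(
                tab.round(12).to_csv().encode()
            ).hexdigest()[:16]
            for name, tab in tables.items()
        },
    }
    (outdir / "experiment_manifest.json").write_text(json.dumps(manifest, indent=1))
    digest = _hash_dir(outdir)
    (outdir / "HASH").write_text(digest + "\n")
    return digest


def _write_fig2_artifacts(outdir, config, groups, report) -> str:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    pd.DataFrame(groups).to_csv(outdir / "day_accuracies.csv", index=False)
    (outdir / "days_report.json").write_text(
        json.dumps(_report_payload(report), indent=1)
    )
    report.dunn_matrix().to_csv(outdir / "dunn_matrix.csv")
    digest = _hash_dir(outdir)
    (outdir / "HASH").write_text(digest + "\n")
    return digest
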