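"""Hypothesis tests over classifier accuracy distributions.

Three comparisons mirror the analysis workflows:

* windowing strategies — Shapiro–Wilk normality gate, one-way ANOVA, Tukey HSD
  pairwise comparisons at 95 % confidence;
* feature-engineering methods — one-sided paired t-test (word features better
  than statistical features), with a Welch two-sample variant reported as a
  sensitivity analysis since the pairing across classifiers and runs is a
  protocol choice;
* amount of data in days — accuracies for 1..7 simulated days; Shapiro–Wilk
  and Levene gates choose the parametric (ANOVA + Tukey) or non-parametric
  (Kruskal–Wallis + Dunn with Bonferroni) path; the minimal number of days not
  significantly different from the 7-day baseline is reported.

Dunn's post-hoc z statistics use the standard rank-based formula with tie
correction; Bonferroni multiplies each raw p by the number of pairs, capped
at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class PairwiseEntry:
    group_a: str
    group_b: str
    statistic: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass
class ComparisonReport:
    """Outcome of one omnibus test plus its post-hoc pairwise matrix."""

    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    pairwise: list[PairwiseEntry] = field(default_factory=list)
    gates: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @property
    def rejects(self) -> bool:
        return self.p_value < ALPHA

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": e.group_a,
                    "group_b": e.group_b,
                    "statistic": e.statistic,
                    "p_adjusted": e.p_adjusted,
                    "significant": e.significant,
                }
                for e in self.pairwise
            ]
        )

    def dunn_matrix(self) -> pd.DataFrame:
        """Lower-triangular rendering: 'z / adjusted p' per (row, column) pair."""
        names = sorted({e.group_a for e in self.pairwise} | {e.group_b for e in self.pairwise})
        mat = pd.DataFrame("", index=names, columns=names)
        for e in self.pairwise:
            a, b = sorted([e.group_a, e.group_b])
            star = " *" if e.significant else ""
            mat.loc[b, a] = f"{e.statistic:.2f} / {e.p_adjusted:.4g}{star}"
        return mat


def _check_groups(groups: Mapping[str, np.ndarray], min_groups: int = 3) -> None:
    if len(groups) < min_groups:
        raise ValueError(f"need >= {min_groups} groups")
    for name, vals in groups.items():
        vals = np.asarray(vals)
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if np.ptp(vals) == 0:
            raise ValueError(f"group {name!r} is constant")


def _shapiro_gate(groups: Mapping[str, np.ndarray]) -> dict[str, float]:
    return {
        name: float(stats.shapiro(np.asarray(vals)).pvalue)
        for name, vals in groups.items()
    }


def compare_windowing(groups: Mapping[str, np.ndarray]) -> ComparisonReport:
    """One-way ANOVA across feature-set accuracy groups, Tukey HSD post hoc."""
    _check_groups(groups)
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    gates = {"shapiro_p": _shapiro_gate(groups)}

    f_stat, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = [
        PairwiseEntry(
            names[i],
            names[j],
            float(tukey.statistic[i, j]),
            float(tukey.pvalue[i, j]),
        )
        for i, j in itertools.combinations(range(k), 2)
    ]
    return ComparisonReport(
        test_name="one-way ANOVA + Tukey HSD",
        statistic=float(f_stat),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        pairwise=pairwise,
        gates=gates,
    )


def compare_methods(
    statistical: np.ndarray, words: np.ndarray
) -> ComparisonReport:
    """One-sided test that word features outperform statistical features.

    Primary: paired t-test on (classifier, run)-aligned accuracies.  The Welch
    two-sample variant is reported under ``extra['welch']``.
    """
    a = np.asarray(statistical, dtype=np.float64)
    b = np.asarray(words, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("paired comparison needs equal-length arrays")
    if np.ptp(b - a) == 0 and (b - a)[0] == 0:
        # all differences exactly zero: no evidence either way
        t = type("T", (), {"statistic": 0.0, "pvalue": 0.5})
    else:
        t = stats.ttest_rel(b, a, alternative="greater")
    welch = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    return ComparisonReport(
        test_name="paired t-test (words > statistical)",
        statistic=float(t.statistic),
        df=(float(a.size - 1),),
        p_value=float(t.pvalue),
        gates={"shapiro_p": _shapiro_gate({"statistical": a, "words": b})},
        extra={
            "welch": {
                "statistic": float(welch.statistic),
                "df": float(welch.df),
                "p_value": float(welch.pvalue),
            },
            "mean_statistical": float(a.mean()),
            "mean_words": float(b.mean()),
        },
    )


def dunn_test(
    groups: Mapping[str, np.ndarray], adjust: str = "bonferroni"
) -> list[PairwiseEntry]:
    """Dunn's rank-based pairwise z tests after Kruskal–Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), where T
    is the tie correction sum(t^3 - t) / (12 (N - 1)).  Two-sided p-values,
    Bonferroni-multiplied by the number of pairs.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    entries = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * len(pairs))
        else:
            p_adj = p_raw
        entries.append(PairwiseEntry(names[i], names[j], float(z), float(p_adj)))
    return entries


def days_comparison(groups: Mapping[str, np.ndarray]) -> ComparisonReport:
    """Compare day-wise accuracy groups (keys 'day1'..'day7').

    Shapiro–Wilk (per group) and Levene gates decide the path: if every group
    looks normal and variances homogeneous at alpha=0.05, one-way ANOVA with
    Tukey HSD; otherwise Kruskal–Wallis with Dunn–Bonferroni.  The report's
    ``extra['min_days_equivalent']`` is the smallest d whose adjusted p against
    the largest-d baseline exceeds alpha.
    """
    _check_groups(groups)
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    shapiro_p = _shapiro_gate(groups)
    levene_p = float(stats.levene(*arrays).pvalue)
    normal = all(p > ALPHA for p in shapiro_p.values())
    homogeneous = levene_p > ALPHA
    gates = {"shapiro_p": shapiro_p, "levene_p": levene_p, "parametric": normal and homogeneous}

    if normal and homogeneous:
        report = compare_windowing(groups)
        report.test_name = "one-way ANOVA + Tukey HSD (day-wise)"
    else:
        h, p = stats.kruskal(*arrays)
        report = ComparisonReport(
            test_name="Kruskal-Wallis + Dunn (Bonferroni)",
            statistic=float(h),
            df=(float(len(arrays) - 1),),
            p_value=float(p),
            pairwise=dunn_test(dict(zip(names, arrays))),
        )
    report.gates.update(gates)

    baseline = names[-1]
    adj_p_vs_baseline = {
        (e.group_a if e.group_b == baseline else e.group_b): e.p_adjusted
        for e in report.pairwise
        if baseline in (e.group_a, e.group_b)
    }
    minimal = baseline
    for name in names[:-1]:
        if adj_p_vs_baseline.get(name, 0.0) > ALPHA:
            minimal = name
            break
    report.extra["baseline"] = baseline
    report.extra["min_days_equivalent"] = minimal
    report.extra["means"] = {n: float(a.mean()) for n, a in zip(names, arrays)}
    return report
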