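"""Scoring and statistical comparison of mapping methods.

Correctness is cumulative down the hierarchy: a sentence is counted at
Levels 1+2 only when both levels are right, and at all three levels only
when the whole triple is right — so acc_l123 <= acc_l12 <= acc_l1 by
construction.  The extrapolation report counts sentences whose gold
triple is a *novel combination* (every term known, the three-way
combination unlicensed) and how many of those were still mapped exactly.
Method comparison across datasets uses the Friedman rank test with
Nemenyi post-hoc pairwise tests, plus a one-sample t-test for comparing
test-set scores against a fixed validation value.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .ontology import MappingTriple, Ontology, is_novel_combination

__all__ = [
    "EvaluationReport",
    "ExtrapolationReport",
    "MethodComparison",
    "cumulative_accuracy",
    "extrapolation_report",
    "friedman_nemenyi",
    "one_sample_t",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Cumulative per-level percent correct, overall and per dataset."""

    n: int
    acc_l1: float
    acc_l12: float
    acc_l123: float
    per_dataset: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def to_json(self) -> dict:
        d = {
            "n": self.n,
            "acc_l1": self.acc_l1,
            "acc_l12": self.acc_l12,
            "acc_l123": self.acc_l123,
        }
        if self.per_dataset:
            d["per_dataset"] = {k: v.to_json() for k, v in self.per_dataset.items()}
        return d

    def to_tsv(self, path: str | Path) -> None:
        rows = ["dataset\tn\tacc_l1\tacc_l12\tacc_l123"]
        items = list(self.per_dataset.items()) + [("all", self)]
        for name, r in items:
            rows.append(
                f"{name}\t{r.n}\t{r.acc_l1:.4f}\t{r.acc_l12:.4f}\t{r.acc_l123:.4f}"
            )
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def _score(gold: Sequence[MappingTriple], pred: Sequence[MappingTriple]) -> tuple:
    n = len(gold)
    c1 = sum(g.l1 == p.l1 for g, p in zip(gold, pred))
    c12 = sum(g.l1 == p.l1 and g.l2 == p.l2 for g, p in zip(gold, pred))
    c123 = sum(g.as_tuple() == p.as_tuple() for g, p in zip(gold, pred))
    return n, 100.0 * c1 / n, 100.0 * c12 / n, 100.0 * c123 / n


def cumulative_accuracy(
    gold: Sequence[MappingTriple],
    pred: Sequence[MappingTriple],
    datasets: Sequence[str] | None = None,
) -> EvaluationReport:
    """Percent correct at Level 1, Levels 1+2, and all three levels.

    Labels are compared as normalized strings (MappingTriple normalizes on
    construction).  ``datasets`` optionally tags each sentence for a
    per-dataset breakdown.
    """
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} pred")
    if not gold:
        raise ValueError("cumulative_accuracy: empty input")
    per: dict[str, EvaluationReport] = {}
    if datasets is not None:
        if len(datasets) != len(gold):
            raise ValueError("datasets tag list length mismatch")
        for ds in sorted(set(datasets)):
            idx = [i for i, d in enumerate(datasets) if d == ds]
            per[ds] = EvaluationReport(
                *_score([gold[i] for i in idx], [pred[i] for i in idx])
            )
    return EvaluationReport(*_score(gold, pred), per_dataset=per)


@dataclass(frozen=True)
class ExtrapolationReport:
    """Novel-combination sentences and how many were mapped exactly."""

    novel_count: int
    novel_correct: int

    def to_json(self) -> dict:
        return {"novel_count": self.novel_count, "novel_correct": self.novel_correct}


def extrapolation_report(
    gold: Sequence[MappingTriple],
    pred: Sequence[MappingTriple],
    o: Ontology,
) -> ExtrapolationReport:
    """Count gold triples that are novel combinations w.r.t. ``o`` and, of
    those, the exactly-correct predictions.  ``o`` should carry the
    training-time triple set."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} pred")
    novel = [i for i, g in enumerate(gold) if is_novel_combination(o, g)]
    correct = sum(gold[i].as_tuple() == pred[i].as_tuple() for i in novel)
    return ExtrapolationReport(novel_count=len(novel), novel_correct=correct)


@dataclass(frozen=True)
class MethodComparison:
    """Friedman test over a complete datasets × methods score matrix."""

    methods: tuple[str, ...]
    datasets: tuple[str, ...]
    scores: np.ndarray
    mean_ranks: np.ndarray
    friedman_statistic: float
    friedman_p: float
    nemenyi_p: np.ndarray  # symmetric, unit diagonal

    def to_json(self) -> dict:
        return {
            "methods": list(self.methods),
            "datasets": list(self.datasets),
            "mean_ranks": self.mean_ranks.tolist(),
            "friedman_statistic": self.friedman_statistic,
            "friedman_p": self.friedman_p,
            "nemenyi_p": self.nemenyi_p.tolist(),
        }


def friedman_nemenyi(
    scores: np.ndarray | Sequence[Sequence[float]],
    methods: Sequence[str] | None = None,
    datasets: Sequence[str] | None = None,
) -> MethodComparison:
    """Friedman chi-square over within-dataset ranks, with Nemenyi post-hoc.

    Scores are ranked within each dataset row (mean ranks for ties); the
    statistic is ``12n / (k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2`` on a
    chi-square with k-1 df.  Nemenyi pairwise p-values come from the
    studentized-range approximation with infinite df.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2 or S.shape[1] < 2:
        raise ValueError("scores must be a (>=2 datasets) x (>=2 methods) matrix")
    if not np.isfinite(S).all():
        raise ValueError("score matrix must be complete (no missing cells)")
    n, k = S.shape
    methods = tuple(methods) if methods else tuple(f"m{j}" for j in range(k))
    datasets = tuple(datasets) if datasets else tuple(f"d{i}" for i in range(n))

    ranks = np.apply_along_axis(stats.rankdata, 1, S)  # mean ranks for ties
    mean_ranks = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * float(np.sum((mean_ranks - (k + 1) / 2) ** 2))
    p = float(stats.chi2.sf(stat, df=k - 1))

    # Nemenyi: q = |Ri - Rj| / sqrt(k(k+1)/(12n)); p from studentized range
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    P = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        pij = float(stats.studentized_range.sf(q, k, np.inf))
        P[i, j] = P[j, i] = min(1.0, pij)
    return MethodComparison(
        methods=methods,
        datasets=datasets,
        scores=S,
        mean_ranks=mean_ranks,
        friedman_statistic=stat,
        friedman_p=p,
        nemenyi_p=P,
    )


def one_sample_t(values: Sequence[float], mu: float) -> tuple[float, float]:
    """Two-sided one-sample t-test of ``values`` against ``mu``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one_sample_t needs at least 2 values")
    if np.ptp(v) == 0:
        if v[0] == mu:
            return 0.0, 1.0
        raise ValueError("one_sample_t: zero variance")
    res = stats.ttest_1samp(v, mu)
    return float(res.statistic), float(res.pvalue)


def write_report_json(
    path: str | Path,
    evaluation: EvaluationReport,
    extrapolation: ExtrapolationReport | None = None,
) -> None:
    d = {"evaluation": evaluation.to_json()}
    if extrapolation is not None:
        d["extrapolation"] = extrapolation.to_json()
    Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")
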