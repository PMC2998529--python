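"""Benchmark construction and performance evaluation of similarity scores.

ROC curves sweep every distinct score as a classification threshold
(predicted positive when score >= threshold, equal scores grouped at one
threshold) and the AUC is the trapezoidal integral over (FPR, TPR).  F1 is
compared between methods as the mean ratio of F1 values over a shared
semantic-similarity cutoff grid.  Expression agreement averages per-
experiment Pearson correlations through Fisher's z transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .clustering import cluster
from .scoring import gene_pair_similarity

#: default semantic-similarity cutoff grid for F1 comparisons
DEFAULT_F1_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledPairSet:
    """Unordered, unique gene pairs with positive/negative labels."""

    positives: tuple[tuple[str, str], ...]
    negatives: tuple[tuple[str, str], ...]
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self):
        seen = set()
        for a, b in (*self.positives, *self.negatives):
            if a == b:
                raise EvaluationError(f"self-pair ({a}, {b}) not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise EvaluationError(f"duplicate pair ({a}, {b})")
            seen.add(key)

    def items(self) -> list[tuple[str, str, int]]:
        return [(a, b, 1) for a, b in self.positives] + [
            (a, b, 0) for a, b in self.negatives
        ]


def build_negative_set(
    universe: Sequence[str],
    known_positives: Iterable[tuple[str, str]],
    n: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Sample n distinct unordered non-positive, non-self pairs uniformly."""
    genes = sorted(set(universe))
    known = {frozenset(p) for p in known_positives}
    total = len(genes) * (len(genes) - 1) // 2
    candidates_exist = total - sum(1 for k in known if len(k) == 2 and k <= set(genes))
    if n > candidates_exist:
        raise EvaluationError(
            f"requested {n} negative pairs but only {candidates_exist} "
            f"candidate pairs exist ({len(genes)} genes, {len(known)} known positives)"
        )
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    # rejection sampling; falls back to full enumeration if the space is tight
    max_tries = 50 * max(n, 1)
    tries = 0
    while len(chosen) < n and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        a, b = sorted((genes[i], genes[j]))
        key = frozenset((a, b))
        if key in known or key in seen:
            continue
        seen.add(key)
        chosen.append((a, b))
    if len(chosen) < n:
        pool = [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
            if frozenset((genes[i], genes[j])) not in known
            and frozenset((genes[i], genes[j])) not in seen
        ]
        extra = rng.choice(len(pool), size=n - len(chosen), replace=False)
        chosen.extend(pool[k] for k in extra)
    return chosen


@dataclass(frozen=True)
class EvalCurve:
    """ROC points, per-threshold confusion counts and trapezoidal AUC."""

    thresholds: np.ndarray  # descending distinct scores
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "precision": self.precision,
                "f1": self.f1,
            }
        )


def roc_and_auc(scores: Sequence[float], labels: Sequence[int]) -> EvalCurve:
    """ROC curve over all distinct score thresholds plus trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be matching 1-d sequences")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC undefined: need at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[True, np.diff(s) != 0]  # first index of each tied block
    cum_tp = np.cumsum(y)
    cum_fp = np.cumsum(1 - y)
    last = np.r_[distinct[1:], True]  # last index of each tied block
    tp = cum_tp[last]
    fp = cum_fp[last]
    thresholds = s[last]
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        f1 = np.where(precision + tpr > 0, 2 * precision * tpr / (precision + tpr), 0.0)
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    return EvalCurve(
        thresholds=thresholds,
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=tpr, fpr=fpr, precision=precision, f1=f1,
        auc=auc,
    )


def f1_by_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoffs: Sequence[float] = DEFAULT_F1_GRID,
) -> pd.DataFrame:
    """Precision, recall and F1 at each fixed score cutoff (score >= cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    rows = []
    for c in cutoffs:
        pred = scores >= c
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = n_pos - tp
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows.append({"cutoff": c, "precision": precision, "recall": recall, "f1": f1})
    return pd.DataFrame(rows)


def f1_improvement(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[float, int]:
    """Mean of F1_a / F1_b over the shared cutoff grid.

    Cutoffs where F1_b = 0 are excluded (their count is returned alongside
    the ratio); if none remain the ratio is undefined.
    """
    merged = table_a.merge(table_b, on="cutoff", suffixes=("_a", "_b"))
    if merged.empty:
        raise EvaluationError("no common cutoffs between the two F1 tables")
    valid = merged[merged["f1_b"] > 0]
    excluded = len(merged) - len(valid)
    if valid.empty:
        raise EvaluationError("baseline F1 is zero at every cutoff; ratio undefined")
    ratio = float((valid["f1_a"] / valid["f1_b"]).mean())
    return ratio, excluded


@dataclass(frozen=True)
class GridSearchResult:
    best_cutoff: float
    table: pd.DataFrame  # cutoff, auc, mean_f1, n_scored


def grid_search_cutoff(
    dag,
    ann: AnnotationSet,
    benchmark: LabeledPairSet,
    cutoffs: Sequence[float],
    mode: Literal["max", "bma"] = "max",
) -> GridSearchResult:
    """Evaluate TCSS over a grid of topology cutoffs on a labeled benchmark.

    AUC is the selection criterion (mean F1 over the default grid is
    reported alongside); ties break toward the smaller cutoff.
    """
    items = benchmark.items()
    if not items:
        raise EvaluationError("empty benchmark")
    rows = []
    for c in sorted(cutoffs):
        clustering = cluster(dag, ann, c)
        scores, labels = [], []
        for a, b, y in items:
            r = gene_pair_similarity(clustering, ann, a, b, mode)
            if r.score is not None:
                scores.append(r.score)
                labels.append(y)
        curve = roc_and_auc(scores, labels)
        mean_f1 = float(f1_by_cutoff(scores, labels)["f1"].mean())
        rows.append(
            {"cutoff": c, "auc": curve.auc, "mean_f1": mean_f1, "n_scored": len(scores)}
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["auc"].idxmax(), "cutoff"]  # idxmax -> first (smallest)
    return GridSearchResult(best_cutoff=float(best), table=table)


# -- expression correlation ----------------------------------------------

_CLAMP = 1.0 - 1e-9


def fisher_z(r: float) -> float:
    """z = arctanh(r), with |r| = 1 clamped just inside the open interval."""
    r = float(np.clip(r, -_CLAMP, _CLAMP))
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    """r = tanh(z) = (e^{2z} - 1) / (e^{2z} + 1)."""
    return float(np.tanh(z))


def average_correlation(
    r_values: Sequence[float], denominator: Literal["printed", "n"] = "printed"
) -> float:
    """Average Pearson correlations through Fisher's z transform.

    The "printed" variant divides the summed z values by N - 1 (kept as the
    reference formula, with max(N-1, 1) so a single experiment stays
    finite); the "n" variant is the ordinary mean of z values.
    """
    if len(r_values) == 0:
        raise EvaluationError("no correlations to average")
    z = [fisher_z(r) for r in r_values]
    if denominator == "printed":
        denom = max(len(z) - 1, 1)
    elif denominator == "n":
        denom = len(z)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return fisher_z_inverse(sum(z) / denom)


def expression_correlation(
    pairs: Iterable[tuple[str, str]],
    experiments: Mapping[str, pd.DataFrame],
    denominator: Literal["printed", "n"] = "printed",
) -> pd.DataFrame:
    """Fisher-z-averaged Pearson correlation per gene pair.

    ``experiments`` maps experiment id -> DataFrame indexed by gene id with
    one column per sample (profiles of length >= 3).  Pairs with a gene
    missing from every experiment are reported with NA; zero-variance
    profiles skip that experiment for that pair.
    """
    rows = []
    for a, b in pairs:
        rs = []
        used = 0
        for name, frame in experiments.items():
            if a not in frame.index or b not in frame.index:
                continue
            xa = frame.loc[a].to_numpy(dtype=float)
            xb = frame.loc[b].to_numpy(dtype=float)
            if len(xa) < 3 or np.std(xa) == 0 or np.std(xb) == 0:
                continue
            rs.append(float(np.corrcoef(xa, xb)[0, 1]))
            used += 1
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "n_experiments": used,
                "r_mean": average_correlation(rs, denominator) if rs else np.nan,
            }
        )
    return pd.DataFrame(rows)
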