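"""Gold-standard construction and threshold/ROC/AUC evaluation.

Positives are pairs sharing at least one level-3 pathway.  For per-pathway
(level-2 category) benchmarks the pair universe is the union of all selected
categories' positive pairs, so every category's positives + negatives sum to
the same total.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import PairScoreTable, PathwayAnnotation, pair_key

logger = logging.getLogger("linkmark")


@dataclass
class GoldStandard:
    """A fixed pair universe with a positive subset."""

    universe: frozenset[tuple[str, str]]
    positives: frozenset[tuple[str, str]]
    scope: str

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")

    @property
    def negatives(self) -> frozenset[tuple[str, str]]:
        return self.universe - self.positives


def _pathway_members(annotation: PathwayAnnotation) -> dict[tuple[str, str], list[str]]:
    members: dict[tuple[str, str], list[str]] = {}
    for protein in annotation.proteins():
        for entry in annotation.memberships[protein]:
            members.setdefault(entry, []).append(protein)
    return members


def _copathway_pairs(members: Mapping[tuple[str, str], list[str]],
                     entries: Sequence[tuple[str, str]]) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for entry in entries:
        for a, b in itertools.combinations(sorted(members[entry]), 2):
            pairs.add(pair_key(a, b))
    return pairs


def build_global_gold(annotation: PathwayAnnotation) -> GoldStandard:
    """Global gold standard over all annotated proteins.

    Universe: every unordered pair of annotated proteins.  Positives: pairs
    sharing at least one level-3 pathway.
    """
    proteins = annotation.proteins()
    if len(proteins) < 2:
        raise ValueError("need at least 2 annotated proteins")
    universe = frozenset(itertools.combinations(proteins, 2))
    members = _pathway_members(annotation)
    positives = frozenset(_copathway_pairs(members, list(members)))
    return GoldStandard(universe=universe, positives=positives, scope="global")


def build_pathway_gold(annotation: PathwayAnnotation, category: str,
                       selected_categories: Sequence[str]) -> GoldStandard:
    """Category-scoped gold standard.

    Universe: pairs sharing at least one level-3 pathway whose level-2
    category is among ``selected_categories``.  Positives: pairs sharing a
    level-3 pathway belonging to ``category``; negatives are all other
    universe pairs.  The universe is therefore identical for every category.
    """
    if category not in selected_categories:
        raise KeyError(f"category {category!r} not among selected categories")
    members = _pathway_members(annotation)
    selected = set(selected_categories)
    universe_entries = [e for e in members if e[0] in selected]
    positive_entries = [e for e in members if e[0] == category]
    universe = frozenset(_copathway_pairs(members, universe_entries))
    positives = frozenset(_copathway_pairs(members, positive_entries))
    return GoldStandard(universe=universe, positives=positives, scope=f"pathway:{category}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative confusion count")

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


def _score_label_arrays(scores: PairScoreTable, gold: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    missing = [p for p in gold.universe if p not in scores.scores]
    if missing:
        sample = sorted(missing)[:10]
        raise KeyError(f"{len(missing)} universe pairs missing from {scores.method} "
                       f"score table, e.g. {sample}")
    pairs = sorted(gold.universe)
    s = np.array([scores.scores[p] for p in pairs])
    y = np.array([p in gold.positives for p in pairs], dtype=bool)
    return s, y


def confusion_at_threshold(scores: PairScoreTable, gold: GoldStandard,
                           threshold: float) -> ConfusionCounts:
    """Counts with the 'predicted positive iff score >= threshold' rule."""
    s, y = _score_label_arrays(scores, gold)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()), tn=int((~pred & ~y).sum()),
        threshold=threshold,
    )


@dataclass
class RocResult:
    """ROC points from (0,0) to (1,1) with trapezoidal AUC."""

    points: list[tuple[float, float]]
    auc: float
    thresholds: list[float]

    def __post_init__(self) -> None:
        fprs = [p[0] for p in self.points]
        tprs = [p[1] for p in self.points]
        if fprs != sorted(fprs) or tprs != sorted(tprs):
            raise ValueError("ROC points must be monotone non-decreasing")


def roc_curve(scores: PairScoreTable, gold: GoldStandard) -> RocResult:
    """ROC by sweeping the distinct observed scores in descending order.

    Tied scores form a single threshold step (a diagonal segment), so the
    trapezoidal AUC equals the Mann–Whitney statistic with half weight for
    ties.  Requires at least one positive and one negative pair.
    """
    s, y = _score_label_arrays(scores, gold)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"degenerate gold standard ({n_pos} positives, {n_neg} negatives)")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(~y_sorted)
    # last index of each distinct-score block
    distinct_last = np.nonzero(np.diff(s_sorted))[0]
    block_ends = np.r_[distinct_last, len(s_sorted) - 1]
    tprs = np.r_[0.0, tp_cum[block_ends] / n_pos]
    fprs = np.r_[0.0, fp_cum[block_ends] / n_neg]
    thresholds = [float(s_sorted[i]) for i in block_ends]
    if fprs[-1] != 1.0 or tprs[-1] != 1.0:  # cannot happen: full sweep covers all
        raise AssertionError("ROC sweep did not end at (1,1)")
    auc = float(np.trapezoid(tprs, fprs))
    points = [(float(f), float(t)) for f, t in zip(fprs, tprs)]
    return RocResult(points=points, auc=auc, thresholds=thresholds)


def tp_fp_series(scores: PairScoreTable, gold: GoldStandard,
                 thresholds: Sequence[float]) -> pd.DataFrame:
    """(threshold, tp, fp) table over an ascending threshold grid."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    s, y = _score_label_arrays(scores, gold)
    rows = []
    for t in thresholds:
        pred = s >= t
        rows.append({"threshold": t, "tp": int((pred & y).sum()), "fp": int((pred & ~y).sum())})
    return pd.DataFrame(rows, columns=["threshold", "tp", "fp"])


def auc_summary(score_tables: Mapping[str, PairScoreTable],
                golds: Mapping[str, GoldStandard]) -> pd.DataFrame:
    """Category × method AUC matrix with arithmetic 'Average' row and column.

    Averages are computed from the unrounded AUCs.  Cells whose gold standard
    is degenerate for that category are NaN and excluded from means.
    """
    methods = list(score_tables)
    categories = list(golds)
    data = {}
    for method, table in score_tables.items():
        col = []
        for category in categories:
            try:
                col.append(roc_curve(table, golds[category]).auc)
            except ValueError:
                logger.warning("degenerate gold for (%s, %s); AUC set to NaN", category, method)
                col.append(np.nan)
        data[method] = col
    df = pd.DataFrame(data, index=categories)
    df["Average"] = df[methods].mean(axis=1)
    df.loc["Average"] = df.mean(axis=0)
    return df
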