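"""Link-prediction evaluation: AUROC, AUPR, F1/recall/precision over
repeated random splits, for the learned model and the preferential-
attachment baseline.

Protocol: hold out 20% of the observed interactions as test positives,
sample an equal number of unobserved pairs as test negatives, score both
sets with a model trained on the remaining 80%, and repeat the whole
procedure over several random splits (default five), reporting the mean and
standard deviation of each metric.  The propagation graph handed to the
model contains training edges only; a test edge found in it is treated as
leakage and raises a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import LeakageError, UndefinedMetricError
from .graph import (
    BipartiteDFIGraph,
    Edge,
    EdgeSplit,
    PreferentialAttachment,
    sample_negatives,
    split_edges,
)

# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The probability that a uniformly chosen positive outranks a uniformly
    chosen negative, with tied scores counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as half-credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, average-precision form.

    The mean of precision evaluated at the rank of each positive when items
    are sorted by descending score (stable sort: tied scores keep input
    order).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if int((y == 1).sum()) == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    cum_pos = np.cumsum(y_sorted)
    ranks = np.arange(1, len(y_sorted) + 1)
    precision_at = cum_pos / ranks
    return float(precision_at[y_sorted == 1].mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(F1, recall, precision) after binarizing ``sigmoid(score) >= threshold``.

    Precision and F1 fall back to 0 when nothing is predicted positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise UndefinedMetricError("threshold metrics need both classes present")
    pred = _sigmoid(s) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return f1, recall, precision


# ---------------------------------------------------------------------------
# the evaluation loop
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-repeat metric values plus mean +/- std aggregation."""

    per_repeat: pd.DataFrame  # columns: repeat, auroc, aupr, f1, recall, precision

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat.drop(columns="repeat").mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repeat.drop(columns="repeat").std(ddof=1)

    def summary(self) -> str:
        lines = ["metric\tmean\tstd"]
        std = self.std if len(self.per_repeat) > 1 else self.mean * 0.0
        for k in ("auroc", "aupr", "f1", "recall", "precision"):
            lines.append(f"{k}\t{self.mean[k]:.4f}\t{std[k]:.4f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.per_repeat.to_csv(path, sep="\t", index=False)


ScorerFactory = Callable[[BipartiteDFIGraph, int], Callable[[Sequence[Edge]], np.ndarray]]


def evaluate_split(
    scorer: Callable[[Sequence[Edge]], np.ndarray],
    split: EdgeSplit,
    threshold: float = 0.5,
    train_graph: BipartiteDFIGraph | None = None,
) -> dict[str, float]:
    """All five metrics on one populated split.

    If ``train_graph`` is given it is checked against the held-out edges:
    any test positive present in it is leakage and raises.
    """
    if not split.test_neg:
        raise ValueError("split.test_neg is empty; populate negatives first")
    if train_graph is not None:
        leaked = split.test_pos & train_graph.edges
        if leaked:
            raise LeakageError(
                f"{len(leaked)} test edges present in the propagation graph"
            )
    pairs = sorted(split.test_pos) + sorted(split.test_neg)
    labels = np.r_[
        np.ones(len(split.test_pos), dtype=int),
        np.zeros(len(split.test_neg), dtype=int),
    ]
    scores = np.asarray(scorer(pairs), dtype=float)
    f1, recall, precision = threshold_metrics(scores, labels, threshold)
    return {
        "auroc": auroc(scores, labels),
        "aupr": aupr(scores, labels),
        "f1": f1,
        "recall": recall,
        "precision": precision,
    }


def evaluate(
    scorer_factory: ScorerFactory,
    graph: BipartiteDFIGraph,
    test_fraction: float = 0.2,
    repeats: int = 5,
    seed: int = 0,
    negative_ratio: int = 1,
    negative_mode: str = "uniform",
    threshold: float = 0.5,
) -> MetricsReport:
    """Repeated-split evaluation.

    For each repeat ``r`` the graph is re-split with seed ``seed + r``, test
    negatives are sampled ``negative_ratio``:1 against the test positives
    (never overlapping observed edges), ``scorer_factory(train_graph, seed+r)``
    builds a scorer trained on the training edges only, and all five metrics
    are computed on the held-out pairs.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rows = []
    for r in range(repeats):
        s = seed + r
        split = split_edges(graph, test_fraction=test_fraction, seed=s)
        split.test_neg = sample_negatives(
            graph,
            count=negative_ratio * len(split.test_pos),
            mode=negative_mode,
            seed=s,
        )
        train_graph = graph.without_edges(split.test_pos)
        scorer = scorer_factory(train_graph, s)
        metrics = evaluate_split(scorer, split, threshold, train_graph=train_graph)
        rows.append({"repeat": r, **metrics})
    return MetricsReport(pd.DataFrame(rows))


# -- ready-made scorer factories ------------------------------------------


def pa_factory() -> ScorerFactory:
    """Preferential-attachment baseline factory for :func:`evaluate`."""

    def make(train_graph: BipartiteDFIGraph, seed: int):
        baseline = PreferentialAttachment().fit(train_graph)
        return baseline.predict_pairs

    return make


def dfinder_factory(ssp=None, config=None, **model_kwargs) -> ScorerFactory:
    """DFinder factory for :func:`evaluate`.

    ``ssp`` is an :class:`dfinder.ssp.SSPMatrix` (or None for topology-only);
    ``config`` a :class:`dfinder.training.TrainConfig`.  The per-repeat seed
    overrides the config seed so repeats differ.
    """
    from .model import DFinder
    from .training import TrainConfig

    base = config if config is not None else TrainConfig()

    def make(train_graph: BipartiteDFIGraph, seed: int):
        model = DFinder(train_graph, ssp=ssp, **model_kwargs)
        res = model.fit(base.replace(seed=seed))
        return res.predict_pairs

    return make
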