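"""Early-recognition metrics for ranked retrieval of actives.

Implements recall at percentage cutoffs, sensitivity/specificity, the ROC
curve with trapezoidal AUC, the enrichment factor, and the
exponentially-weighted BEDROC score, plus cross-measure summaries (class
means, overall mean/median, best-measure-per-class tallies).

Conventions: the top-k size at a p% cutoff is ``k = max(1, round(p*N/100))``
with Python's round-half-even; recall is reported in percent (0-100); ties
at the k-th position are resolved by the ranking's deterministic order, not
fractionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .screening import Ranking

__all__ = [
    "EvaluationReport",
    "top_k_size",
    "recall_at_cutoff",
    "sensitivity_specificity",
    "roc_auc",
    "enrichment_factor",
    "bedroc",
    "evaluate_rankings",
    "summarize",
]


def top_k_size(n: int, pct: float) -> int:
    """Selection size for a percentage cutoff: max(1, round(pct*n/100))."""
    if not (0 < pct <= 100):
        raise ValueError(f"cutoff percentage {pct} outside (0, 100]")
    return max(1, round(pct * n / 100.0))


def _active_mask(ranking: Ranking, actives: Iterable[str]) -> np.ndarray:
    actives = set(actives)
    unknown = actives - set(ranking.order)
    if unknown:
        raise ValueError(f"actives not present in ranking: {sorted(unknown)[:5]}")
    return np.array([mol_id in actives for mol_id in ranking.order], dtype=bool)


def recall_at_cutoff(ranking: Ranking, actives: Iterable[str], pct: float) -> float:
    """Percentage of the actives retrieved in the top ``pct`` % of the list."""
    mask = _active_mask(ranking, actives)
    n_act = int(mask.sum())
    if n_act == 0:
        raise ValueError("actives set is empty")
    k = top_k_size(len(ranking), pct)
    return 100.0 * int(mask[:k].sum()) / n_act


def sensitivity_specificity(
    ranking: Ranking, actives: Iterable[str], k: int
) -> tuple[float, float]:
    """(Se, Sp) treating the top-k as the selected set.

    Se = TP / (TP + FN); Sp = TN / (TN + FP).
    """
    mask = _active_mask(ranking, actives)
    n = len(mask)
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    n_act = int(mask.sum())
    n_inact = n - n_act
    if n_act == 0 or n_inact == 0:
        raise ValueError("need at least one active and one inactive")
    tp = int(mask[:k].sum())
    fp = k - tp
    fn = n_act - tp
    tn = n_inact - fp
    return tp / (tp + fn), tn / (tn + fp)


def roc_auc(
    ranking: Ranking,
    actives: Iterable[str],
    truncate_fraction: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC for a ranking.

    Molecules with equal scores are collapsed into a single threshold
    step, so the curve (and AUC) is invariant to the tie-breaking order.
    With ``truncate_fraction`` in (0, 1], only the top fraction of the
    list is traced and the partial area is normalised by the observed
    FPR extent (non-default; the full-ranking AUC is the standard
    report).

    Returns ``(points, auc)`` where ``points`` is an (n+1, 2) array of
    (FPR, TPR) pairs starting at (0, 0).
    """
    mask = _active_mask(ranking, actives)
    n = len(mask)
    n_act = int(mask.sum())
    n_inact = n - n_act
    if n_act == 0 or n_inact == 0:
        raise ValueError("need at least one active and one inactive")
    limit = n
    if truncate_fraction is not None:
        if not (0 < truncate_fraction <= 1):
            raise ValueError("truncate_fraction must be in (0, 1]")
        limit = max(1, round(truncate_fraction * n))
    scores = ranking.scores[:limit]
    mask = mask[:limit]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < limit:
        j = i
        while j < limit and scores[j] == scores[i]:
            j += 1
        tp += int(mask[i:j].sum())
        fp += (j - i) - int(mask[i:j].sum())
        points.append((fp / n_inact, tp / n_act))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    if truncate_fraction is not None:
        if pts[-1, 0] > 0:
            auc /= pts[-1, 0]
        else:
            # no false positive seen before the cutoff: perfect early curve
            auc = 1.0 if pts[-1, 1] > 0 else 0.5
    return pts, auc


def enrichment_factor(ranking: Ranking, actives: Iterable[str], pct: float) -> float:
    """EF = (a/k) / (A/N): active concentration in the top pct% vs overall."""
    mask = _active_mask(ranking, actives)
    n = len(mask)
    n_act = int(mask.sum())
    if n_act == 0:
        raise ValueError("actives set is empty")
    k = top_k_size(n, pct)
    a = int(mask[:k].sum())
    return (a / k) / (n_act / n)


def bedroc(ranking: Ranking, actives: Iterable[str], alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon-Bayly).

    Exponentially weights early active ranks with parameter ``alpha``;
    bounded in [0, 1]. Requires at least one active and one inactive.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mask = _active_mask(ranking, actives)
    n = len(mask)
    n_act = int(mask.sum())
    if n_act == 0:
        raise ValueError("actives set is empty")
    if n_act == n:
        raise ValueError("all molecules active: BEDROC undefined")
    ranks = np.flatnonzero(mask) + 1  # 1-based positions of the actives
    ra = n_act / n
    s = float(np.exp(-alpha * ranks / n).sum())
    rie = s / (ra * (1.0 - np.exp(-alpha)) / (np.exp(alpha / n) - 1.0))
    factor = rie * ra * np.sinh(alpha / 2.0) / (
        np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * ra)
    )
    return float(factor + 1.0 / (1.0 - np.exp(alpha * (1.0 - ra))))


# ---------------------------------------------------------------------------
# per-run evaluation and cross-measure summaries

@dataclass
class EvaluationReport:
    """Tidy per-query metrics plus class/overall aggregates.

    ``per_query`` has columns (measure, activity_class, query_id, metric,
    value); ``per_class`` averages over each class's queries;
    ``overall`` holds the mean and median over classes per measure and
    metric; ``best_per_class[metric][measure]`` counts the classes in
    which the measure attains the maximal class-mean value (joint maxima
    credit all tied measures).
    """

    per_query: pd.DataFrame
    per_class: pd.DataFrame
    overall: pd.DataFrame
    best_per_class: dict[str, dict[str, int]]


def evaluate_rankings(
    rankings: Sequence[Ranking],
    class_of_query: dict[str, str],
    actives_by_class: dict[str, Sequence[str]],
    cutoffs: Sequence[float] = (1.0, 5.0),
    alpha: float = 20.0,
    ef_pct: float = 1.0,
) -> pd.DataFrame:
    """Compute the per-query metric table for a batch of rankings.

    Each ranking's query must appear in ``class_of_query``; its class's
    members (from ``actives_by_class``) are the actives, everything else
    in the database counts as inactive.
    """
    rows = []
    for rk in rankings:
        cls = class_of_query.get(rk.query_id)
        if cls is None:
            raise ValueError(f"query {rk.query_id!r} has no activity class")
        actives = actives_by_class[cls]
        metrics: dict[str, float] = {}
        for pct in cutoffs:
            metrics[f"recall@{pct:g}"] = recall_at_cutoff(rk, actives, pct)
        _, auc = roc_auc(rk, actives)
        metrics["auc"] = auc
        metrics[f"ef@{ef_pct:g}"] = enrichment_factor(rk, actives, ef_pct)
        metrics[f"bedroc{alpha:g}"] = bedroc(rk, actives, alpha)
        for name, value in metrics.items():
            rows.append(
                {
                    "measure": rk.measure,
                    "activity_class": cls,
                    "query_id": rk.query_id,
                    "metric": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["measure", "activity_class", "query_id", "metric", "value"])


def summarize(per_query: pd.DataFrame) -> EvaluationReport:
    """Aggregate a per-query table into class and overall summaries.

    All measures must have been evaluated on identical (class, query)
    sets, mirroring the unified-reference protocol.
    """
    required = {"measure", "activity_class", "query_id", "metric", "value"}
    if not required.issubset(per_query.columns):
        raise ValueError(f"per_query must have columns {sorted(required)}")
    query_sets = {
        m: frozenset(zip(g["activity_class"], g["query_id"]))
        for m, g in per_query.groupby("measure")
    }
    if len(set(query_sets.values())) > 1:
        raise ValueError("measures were evaluated on different query sets")

    per_class = (
        per_query.groupby(["measure", "activity_class", "metric"], as_index=False)["value"]
        .mean()
    )
    overall = (
        per_class.groupby(["measure", "metric"])["value"]
        .agg(["mean", "median"])
        .reset_index()
    )
    best: dict[str, dict[str, int]] = {}
    measures = sorted(per_query["measure"].unique())
    for metric, grp in per_class.groupby("metric"):
        tally = {m: 0 for m in measures}
        wide = grp.pivot(index="activity_class", columns="measure", values="value")
        for _, row in wide.iterrows():
            top = row.max()
            for m in measures:
                if row[m] == top:
                    tally[m] += 1
        best[str(metric)] = tally
    return EvaluationReport(
        per_query=per_query, per_class=per_class, overall=overall, best_per_class=best
    )
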