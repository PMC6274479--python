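"""Simulated virtual-screening protocol.

For each activity class a fixed number of reference structures (default
ten) is drawn at random; each reference in turn is used as a query and the
whole database is ranked by decreasing similarity (increasing distance for
distance measures). Reference selection depends only on the dataset, the
class label and the seed — never on the measure — so the same references
are reused when several measures are compared. References stay in the
ranked database and count as retrievable actives; set
``exclude_query=True`` on the config for the exclusive convention.
"""

from __future__ import annotations

import csv
import json
import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fingerprints import CountFingerprint, FingerprintDataset
from .similarity import (
    FeatureScaling,
    SimilarityConfig,
    compute_feature_scaling,
    get_measure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Ranking",
    "ScreenConfig",
    "select_references",
    "rank_database",
    "screen",
    "write_rankings",
    "read_rankings",
    "rankings_to_csv",
]


@dataclass
class Ranking:
    """One query's ordering of the database.

    ``order`` is a permutation of the database identifiers sorted by
    decreasing score (increasing for distance measures), ties broken by
    ascending molecule_id. ``scores[i]`` is the score of ``order[i]``.
    """

    query_id: str
    measure: str
    order: list[str]
    scores: np.ndarray
    is_distance: bool = False

    def __len__(self) -> int:
        return len(self.order)

    def validate(self, database_ids: Optional[Sequence[str]] = None) -> None:
        """Check the permutation and monotonicity invariants."""
        if len(self.order) != len(self.scores):
            raise ValueError("order and scores length mismatch")
        if len(set(self.order)) != len(self.order):
            raise ValueError("order contains duplicate ids")
        if database_ids is not None and set(self.order) != set(database_ids):
            raise ValueError("order is not a permutation of the database ids")
        diffs = np.diff(self.scores)
        if self.is_distance:
            if np.any(diffs < 0):
                raise ValueError("distance scores must be non-decreasing")
        elif np.any(diffs > 0):
            raise ValueError("similarity scores must be non-increasing")


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of one screening run."""

    measure: str = "asmtp"
    n_references: int = 10
    seed: int = 0
    cutoffs: tuple[float, ...] = (1.0, 5.0)
    lam: float = 0.0001
    scaling_mode: str = "nonzero-mean"
    exclude_query: bool = False

    def __post_init__(self):
        if self.n_references < 1:
            raise ValueError("n_references must be >= 1")
        for c in self.cutoffs:
            if not (0 < c <= 100):
                raise ValueError(f"cutoff {c} outside (0, 100]")
        get_measure(self.measure)  # fail fast on unknown names

    def similarity_config(self) -> SimilarityConfig:
        return SimilarityConfig(lam=self.lam, scaling_mode=self.scaling_mode)


def _class_rng(seed: int, activity_class: str) -> np.random.Generator:
    # per-class stream independent of class iteration order and of the measure
    tag = zlib.crc32(activity_class.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def select_references(
    dataset: FingerprintDataset, activity_class: str, n: int, seed: int
) -> list[str]:
    """Draw ``n`` distinct actives of ``activity_class`` reproducibly.

    The draw depends only on (dataset membership, class, seed); the
    returned list is sorted so downstream iteration order is stable.
    """
    actives = dataset.actives_of(activity_class)
    if len(actives) < n:
        raise ValueError(
            f"class {activity_class!r} has {len(actives)} actives, need {n}"
        )
    rng = _class_rng(seed, activity_class)
    chosen = rng.choice(len(actives), size=n, replace=False)
    return sorted(actives[i] for i in chosen)


def rank_database(
    query: CountFingerprint,
    dataset: FingerprintDataset,
    measure: str,
    scaling: Optional[FeatureScaling] = None,
    config: Optional[ScreenConfig] = None,
) -> Ranking:
    """Score every database molecule against ``query`` and sort.

    Degenerate pairs (score undefined, e.g. an all-zero molecule under
    cosine) are logged and assigned the worst possible rank.
    """
    config = config or ScreenConfig(measure=measure)
    meas = get_measure(measure)
    if query.M != dataset.M:
        from .exceptions import DimensionError

        raise DimensionError(f"query M={query.M} vs dataset M={dataset.M}")
    if meas.needs_scaling and scaling is None:
        scaling = compute_feature_scaling(dataset, config.scaling_mode)
    X = dataset.dense_matrix()
    ids = dataset.ids
    if config.exclude_query and query.molecule_id in ids:
        keep = [i for i, mid in enumerate(ids) if mid != query.molecule_id]
        X = X[keep]
        ids = [ids[i] for i in keep]
    scores = meas.batch(query.to_dense(), X, scaling, config.lam)
    bad = np.isnan(scores)
    if bad.any():
        logger.warning(
            "%d molecules had undefined %s scores for query %s; ranked last",
            int(bad.sum()),
            measure,
            query.molecule_id,
        )
        worst = np.inf if meas.is_distance else -np.inf
        scores = np.where(bad, worst, scores)
    sign = 1.0 if meas.is_distance else -1.0
    order_idx = sorted(range(len(ids)), key=lambda i: (sign * scores[i], ids[i]))
    return Ranking(
        query_id=query.molecule_id,
        measure=measure,
        order=[ids[i] for i in order_idx],
        scores=scores[order_idx],
        is_distance=meas.is_distance,
    )


def screen(
    dataset: FingerprintDataset,
    config: ScreenConfig,
    scaling: Optional[FeatureScaling] = None,
    classes: Optional[Sequence[str]] = None,
) -> list[Ranking]:
    """Run the full protocol: one ranking per reference per class.

    Returns ``len(classes) * n_references`` rankings in (class, reference)
    order, deterministic for a fixed seed.
    """
    classes = list(classes) if classes is not None else dataset.activity_classes
    if not classes:
        raise ValueError("dataset has no activity classes to screen")
    meas = get_measure(config.measure)
    if meas.needs_scaling and scaling is None:
        scaling = compute_feature_scaling(dataset, config.scaling_mode)
    rankings: list[Ranking] = []
    for cls in classes:
        refs = select_references(dataset, cls, config.n_references, config.seed)
        for ref_id in refs:
            fp = dataset.get(ref_id).fingerprint
            rankings.append(rank_database(fp, dataset, config.measure, scaling, config))
    return rankings


# ---------------------------------------------------------------------------
# serialization

_HEADER = ["query_id", "measure", "rank", "molecule_id", "score"]


def rankings_to_csv(rankings: Sequence[Ranking]) -> str:
    lines = [",".join(_HEADER)]
    for rk in rankings:
        for pos, (mol_id, score) in enumerate(zip(rk.order, rk.scores), start=1):
            lines.append(f"{rk.query_id},{rk.measure},{pos},{mol_id},{score:.17g}")
    return "\n".join(lines) + "\n"


def write_rankings(rankings: Sequence[Ranking], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(rankings_to_csv(rankings))


def read_rankings(path) -> list[Ranking]:
    rankings: list[Ranking] = []
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _HEADER:
            raise ValueError(f"unexpected rankings header {header!r}")
        cur_key: Optional[tuple[str, str]] = None
        order: list[str] = []
        scores: list[float] = []

        def flush():
            if cur_key is not None:
                q, m = cur_key
                is_dist = get_measure(m).is_distance
                rankings.append(
                    Ranking(q, m, list(order), np.array(scores), is_distance=is_dist)
                )

        for row in reader:
            qid, measure, _rank, mol_id, score = row
            key = (qid, measure)
            if key != cur_key:
                flush()
                cur_key = key
                order, scores = [], []
            order.append(mol_id)
            scores.append(float(score))
        flush()
    return rankings


def write_manifest(path, **fields) -> None:
    """Write a JSON run manifest (sorted keys for reproducible bytes)."""
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")
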