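"""Similarity coefficients for count fingerprints.

The central measure is a text-retrieval-derived score for sparse count
vectors. Per feature j it awards a Gaussian term
``0.5 * (1 + exp(-((m1j - m2j) / mu_j)^2))`` when both molecules carry the
feature (lower bound 0.5 at maximal disagreement, 1 at equality), charges a
fixed penalty ``-lam`` when exactly one carries it, and ignores jointly
absent features. ``mu_j`` is the dataset-wide mean of the non-zero values
of feature j. The per-feature sums are normalised by the number of features
present in either molecule and the ratio F is rescaled to [0, 1] via
``S = (F + lam) / (1 + lam)``.

Implementation note: S is evaluated in the algebraically equivalent form
``S = (G + lam * c) / ((1 + lam) * u)`` where G is the Gaussian sum, c the
number of shared features and u the union size. This makes the identities
``S(m, m) == 1.0`` and ``S == 0.0`` for disjoint supports hold exactly in
floating point.

Classical baselines (Tanimoto in both continuous and binary form, Dice,
cosine, Euclidean distance, extended Jaccard) are provided behind the same
registry so the screening layer can treat all measures uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .exceptions import DegenerateInputError, DimensionError
from .fingerprints import CountFingerprint, FingerprintDataset

__all__ = [
    "FeatureScaling",
    "SimilarityConfig",
    "compute_feature_scaling",
    "asmtp",
    "asmtp_batch",
    "tanimoto_continuous",
    "tanimoto_binary",
    "dice",
    "cosine",
    "euclidean",
    "extended_jaccard",
    "baseline_measure",
    "Measure",
    "MEASURES",
    "get_measure",
]

SCALING_MODES = ("nonzero-mean", "nonzero-stddev")


@dataclass(frozen=True)
class FeatureScaling:
    """Per-feature scale statistics over a dataset.

    ``mu[j]`` is the mean (or, in the std-dev variant, the standard
    deviation) of the non-zero values of feature j, and ``n[j]`` is the
    number of molecules carrying the feature. Features never seen get the
    sentinel scale 1.0; that branch is provably never consumed because the
    Gaussian case requires both compared values to be non-zero, which
    implies ``n[j] >= 2``.
    """

    mu: np.ndarray
    n: np.ndarray
    source_size: int
    mode: str = "nonzero-mean"

    def __post_init__(self):
        if len(self.mu) != len(self.n):
            raise DimensionError("mu and n must have equal length")

    @property
    def M(self) -> int:
        return len(self.mu)


@dataclass(frozen=True)
class SimilarityConfig:
    """Tunable knobs: mismatch penalty ``lam`` and the scaling variant."""

    lam: float = 0.0001
    scaling_mode: str = "nonzero-mean"

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.lam > 0.01:
            warnings.warn(
                f"lam={self.lam} is outside the recommended (0, 0.01] range",
                stacklevel=3,
            )
        if self.scaling_mode not in SCALING_MODES:
            raise ValueError(
                f"scaling_mode must be one of {SCALING_MODES}, got {self.scaling_mode!r}"
            )


def compute_feature_scaling(
    dataset: FingerprintDataset, mode: str = "nonzero-mean"
) -> FeatureScaling:
    """Compute per-feature scale statistics over an entire dataset.

    The statistics are intentionally global (references included): the
    scale of feature j reflects the whole screened database, with no
    per-query restriction.
    """
    if mode not in SCALING_MODES:
        raise ValueError(f"mode must be one of {SCALING_MODES}, got {mode!r}")
    if len(dataset) == 0:
        raise ValueError("cannot compute feature scaling over an empty dataset")
    X = dataset.dense_matrix()
    nz = X > 0
    n = nz.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, X.sum(axis=0) / np.maximum(n, 1), 1.0)
        if mode == "nonzero-mean":
            mu = mean
        else:
            # population std of the non-zero values; degenerate spread -> sentinel
            sq = np.where(n > 0, (X * X).sum(axis=0) / np.maximum(n, 1), 0.0)
            var = np.maximum(sq - mean * mean, 0.0)
            sd = np.sqrt(var)
            mu = np.where((n > 0) & (sd > 0), sd, 1.0)
    return FeatureScaling(mu=mu, n=n.astype(np.int64), source_size=len(dataset), mode=mode)


def _check_pair(m1: CountFingerprint, m2: CountFingerprint) -> None:
    if m1.M != m2.M:
        raise DimensionError(f"dimension mismatch: {m1.M} vs {m2.M}")


def asmtp(
    m1: CountFingerprint,
    m2: CountFingerprint,
    scaling: FeatureScaling,
    config: Optional[SimilarityConfig] = None,
) -> float:
    """Adapted text-processing similarity of two count fingerprints.

    Returns a score in [0, 1]; exactly 1.0 for identical non-empty
    fingerprints and exactly 0.0 for disjoint supports. Raises
    :class:`DegenerateInputError` when both fingerprints are empty.
    """
    _check_pair(m1, m2)
    if scaling.M != m1.M:
        raise DimensionError(
            f"scaling dimension {scaling.M} does not match fingerprints M={m1.M}"
        )
    config = config or SimilarityConfig()
    lam = config.lam

    union = sorted(set(m1.counts) | set(m2.counts))  # fixed order => exact symmetry
    u = len(union)
    if u == 0:
        raise DegenerateInputError("both fingerprints are empty")
    gauss_sum = 0.0
    n_shared = 0
    for j in union:
        v1 = m1.counts.get(j, 0)
        v2 = m2.counts.get(j, 0)
        if v1 > 0 and v2 > 0:
            z = (v1 - v2) / scaling.mu[j]
            gauss_sum += 0.5 * (1.0 + np.exp(-(z * z)))
            n_shared += 1
    return float((gauss_sum + lam * n_shared) / ((1.0 + lam) * u))


def asmtp_batch(
    query: np.ndarray,
    X: np.ndarray,
    scaling: FeatureScaling,
    lam: float = 0.0001,
) -> np.ndarray:
    """Vectorised scores of ``query`` against every row of ``X``.

    ``query`` is a dense (M,) count vector, ``X`` a dense (N, M) count
    matrix. Rows whose union with the query is empty get NaN (only
    possible when both the query and the row are all-zero).
    """
    if X.shape[1] != query.shape[0] or scaling.M != query.shape[0]:
        raise DimensionError("query, matrix and scaling dimensions must agree")
    qpos = query > 0
    Xpos = X > 0
    shared = Xpos & qpos
    n_union = (Xpos | qpos).sum(axis=1)
    n_shared = shared.sum(axis=1)
    z = (X - query) / scaling.mu
    g = 0.5 * (1.0 + np.exp(-(z * z)))
    gauss_sum = np.where(shared, g, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (gauss_sum + lam * n_shared) / ((1.0 + lam) * n_union)
    return np.where(n_union > 0, scores, np.nan)


# ---------------------------------------------------------------------------
# classical coefficients

def tanimoto_continuous(m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Continuous (count) Tanimoto: dot / (|a|^2 + |b|^2 - dot)."""
    _check_pair(m1, m2)
    dot = sum(c * m2.counts.get(j, 0) for j, c in m1.counts.items())
    sq1 = sum(c * c for c in m1.counts.values())
    sq2 = sum(c * c for c in m2.counts.values())
    denom = sq1 + sq2 - dot
    if denom == 0:
        raise DegenerateInputError("both fingerprints are empty")
    return dot / denom


def tanimoto_binary(m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Binary Tanimoto c / (a + b - c) on the on-bit sets (count > 0)."""
    _check_pair(m1, m2)
    a = len(m1.counts)
    b = len(m2.counts)
    c = len(set(m1.counts) & set(m2.counts))
    denom = a + b - c
    if denom == 0:
        raise DegenerateInputError("both fingerprints are empty")
    return c / denom


def dice(m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Dice coefficient 2*dot / (|a|^2 + |b|^2) on the count vectors."""
    _check_pair(m1, m2)
    dot = sum(c * m2.counts.get(j, 0) for j, c in m1.counts.items())
    denom = sum(c * c for c in m1.counts.values()) + sum(
        c * c for c in m2.counts.values()
    )
    if denom == 0:
        raise DegenerateInputError("both fingerprints are empty")
    return 2.0 * dot / denom


def cosine(m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Cosine similarity of the count vectors."""
    _check_pair(m1, m2)
    n1 = sum(c * c for c in m1.counts.values())
    n2 = sum(c * c for c in m2.counts.values())
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("cosine undefined for a zero-norm fingerprint")
    dot = sum(c * m2.counts.get(j, 0) for j, c in m1.counts.items())
    return dot / float(np.sqrt(n1) * np.sqrt(n2))


def euclidean(m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Euclidean distance between the count vectors (smaller = more similar)."""
    _check_pair(m1, m2)
    keys = set(m1.counts) | set(m2.counts)
    sq = sum((m1.counts.get(j, 0) - m2.counts.get(j, 0)) ** 2 for j in keys)
    return float(np.sqrt(sq))


def extended_jaccard(m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Extended Jaccard coefficient (same form as continuous Tanimoto)."""
    return tanimoto_continuous(m1, m2)


_BASELINES: dict[str, Callable[[CountFingerprint, CountFingerprint], float]] = {
    "dice": dice,
    "cosine": cosine,
    "euclidean": euclidean,
    "extended_jaccard": extended_jaccard,
}


def baseline_measure(name: str, m1: CountFingerprint, m2: CountFingerprint) -> float:
    """Evaluate one of the classical text-retrieval coefficients by name."""
    try:
        fn = _BASELINES[name]
    except KeyError:
        raise ValueError(
            f"unknown baseline {name!r}; expected one of {sorted(_BASELINES)}"
        ) from None
    return fn(m1, m2)


# ---------------------------------------------------------------------------
# measure registry for the screening layer

def _batch_from_pairwise(fn):
    def batch(query, X, scaling, lam):
        M = query.shape[0]
        q = CountFingerprint("__q__", {j: int(v) for j, v in enumerate(query) if v > 0}, M=M)
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            row = CountFingerprint(
                f"__r{i}__", {j: int(v) for j, v in enumerate(X[i]) if v > 0}, M=M
            )
            try:
                out[i] = fn(q, row)
            except DegenerateInputError:
                out[i] = np.nan
        return out

    return batch


def _tanimoto_batch(query, X, scaling, lam):
    dot = X @ query
    sq = (X * X).sum(axis=1) + float(query @ query)
    denom = sq - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dot / denom
    return np.where(denom > 0, out, np.nan)


def _tanimoto_binary_batch(query, X, scaling, lam):
    qpos = (query > 0).astype(np.float64)
    Xpos = (X > 0).astype(np.float64)
    c = Xpos @ qpos
    denom = Xpos.sum(axis=1) + qpos.sum() - c
    with np.errstate(invalid="ignore", divide="ignore"):
        out = c / denom
    return np.where(denom > 0, out, np.nan)


def _dice_batch(query, X, scaling, lam):
    dot = X @ query
    denom = (X * X).sum(axis=1) + float(query @ query)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * dot / denom
    return np.where(denom > 0, out, np.nan)


def _cosine_batch(query, X, scaling, lam):
    qn = float(np.sqrt(query @ query))
    xn = np.sqrt((X * X).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (X @ query) / (xn * qn)
    return np.where((xn > 0) & (qn > 0), out, np.nan)


def _euclidean_batch(query, X, scaling, lam):
    diff = X - query
    return np.sqrt((diff * diff).sum(axis=1))


def _asmtp_measure_batch(query, X, scaling, lam):
    if scaling is None:
        raise ValueError("asmtp requires a FeatureScaling")
    return asmtp_batch(query, X, scaling, lam)


@dataclass(frozen=True)
class Measure:
    """Registry entry: batch scorer plus ranking direction."""

    name: str
    batch: Callable[[np.ndarray, np.ndarray, Optional[FeatureScaling], float], np.ndarray]
    is_distance: bool = False
    needs_scaling: bool = False


MEASURES: dict[str, Measure] = {
    "asmtp": Measure("asmtp", _asmtp_measure_batch, needs_scaling=True),
    "tanimoto": Measure("tanimoto", _tanimoto_batch),
    "tanimoto_binary": Measure("tanimoto_binary", _tanimoto_binary_batch),
    "dice": Measure("dice", _dice_batch),
    "cosine": Measure("cosine", _cosine_batch),
    "euclidean": Measure("euclidean", _euclidean_batch, is_distance=True),
    "extended_jaccard": Measure("extended_jaccard", _tanimoto_batch),
}


def get_measure(name: str) -> Measure:
    try:
        return MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown measure {name!r}; expected one of {sorted(MEASURES)}"
        ) from None
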