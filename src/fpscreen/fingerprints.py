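"""Data model and I/O for fixed-length molecular count fingerprints.

Fingerprints are sparse non-negative integer vectors over a fixed feature
dimension ``M`` (default 1024). Only strictly positive counts are stored;
zeros are implicit. Two plain-text formats are supported:

* ``dense-csv`` — header ``molecule_id,activity_class,f0,...,f{M-1}``,
  one integer column per feature;
* ``sparse-pairs`` — header ``molecule_id,activity_class,features`` with
  the feature field holding space-separated ``idx:count`` pairs in
  ascending index order. The dimension is recorded in a leading
  ``#M=<int>`` comment line.

Larger feature spaces are mapped to the working dimension by modulo
folding with count summation (:func:`fold`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .exceptions import DimensionError, ParseError

DEFAULT_DIM = 1024

__all__ = [
    "DEFAULT_DIM",
    "CountFingerprint",
    "MoleculeRecord",
    "FingerprintDataset",
    "read_fingerprints",
    "write_fingerprints",
    "fold",
    "read_smiles",
]


@dataclass(frozen=True)
class CountFingerprint:
    """A sparse count vector of dimension ``M`` for one molecule.

    ``counts`` maps feature index -> strictly positive integer count;
    indices absent from the mapping are zero.
    """

    molecule_id: str
    counts: Mapping[int, int]
    M: int = DEFAULT_DIM

    def __post_init__(self):
        if self.M < 1:
            raise ValueError(f"feature dimension must be >= 1, got {self.M}")
        for idx, cnt in self.counts.items():
            if not (0 <= idx < self.M):
                raise ValueError(
                    f"feature index {idx} outside [0, {self.M}) for {self.molecule_id!r}"
                )
            if int(cnt) != cnt or cnt <= 0:
                raise ValueError(
                    f"count at index {idx} must be a positive integer, got {cnt!r}"
                )

    @classmethod
    def from_dense(cls, molecule_id: str, values: Sequence[int]) -> "CountFingerprint":
        counts = {i: int(v) for i, v in enumerate(values) if v != 0}
        return cls(molecule_id, counts, M=len(values))

    def to_dense(self, dtype=np.float64) -> np.ndarray:
        out = np.zeros(self.M, dtype=dtype)
        for idx, cnt in self.counts.items():
            out[idx] = cnt
        return out

    @property
    def n_features(self) -> int:
        """Number of non-zero features."""
        return len(self.counts)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountFingerprint):
            return NotImplemented
        return (
            self.molecule_id == other.molecule_id
            and self.M == other.M
            and dict(self.counts) == dict(other.counts)
        )


@dataclass(frozen=True)
class MoleculeRecord:
    """A fingerprint plus optional activity annotations."""

    fingerprint: CountFingerprint
    activity_class: Optional[str] = None
    is_active: Optional[bool] = None

    @property
    def molecule_id(self) -> str:
        return self.fingerprint.molecule_id


@dataclass
class FingerprintDataset:
    """An ordered, stable collection of labelled fingerprints.

    All member fingerprints share the same feature dimension ``M`` and
    molecule identifiers are unique. Iteration order is the insertion
    order, identical across runs for identical inputs.
    """

    records: list[MoleculeRecord]
    M: int = DEFAULT_DIM
    _matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.fingerprint.M != self.M:
                raise DimensionError(
                    f"fingerprint {rec.molecule_id!r} has M={rec.fingerprint.M}, "
                    f"dataset M={self.M}"
                )
            if rec.molecule_id in seen:
                raise ValueError(f"duplicate molecule_id {rec.molecule_id!r}")
            seen.add(rec.molecule_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FingerprintDataset):
            return NotImplemented
        return self.M == other.M and self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [rec.molecule_id for rec in self.records]

    @property
    def activity_classes(self) -> list[str]:
        """Sorted distinct activity class labels present in the dataset."""
        return sorted({r.activity_class for r in self.records if r.activity_class})

    def get(self, molecule_id: str) -> MoleculeRecord:
        for rec in self.records:
            if rec.molecule_id == molecule_id:
                return rec
        raise KeyError(molecule_id)

    def class_of(self, molecule_id: str) -> Optional[str]:
        return self.get(molecule_id).activity_class

    def actives_of(self, activity_class: str) -> list[str]:
        """Identifiers of the members of ``activity_class``, in dataset order."""
        return [
            r.molecule_id for r in self.records if r.activity_class == activity_class
        ]

    def dense_matrix(self) -> np.ndarray:
        """Dense (N, M) float64 count matrix in dataset order (cached)."""
        if self._matrix is None:
            mat = np.zeros((len(self.records), self.M), dtype=np.float64)
            for i, rec in enumerate(self.records):
                for idx, cnt in rec.fingerprint.counts.items():
                    mat[i, idx] = cnt
            self._matrix = mat
        return self._matrix


def fold(fingerprint: CountFingerprint, M: int) -> CountFingerprint:
    """Fold a fingerprint onto a smaller dimension ``M``.

    Target index = source index mod ``M``; counts at colliding indices
    are summed, so the total count is conserved. ``M`` must satisfy
    ``1 <= M <= fingerprint.M``.
    """
    if M <= 0:
        raise ValueError(f"target dimension must be positive, got {M}")
    if M > fingerprint.M:
        raise ValueError(
            f"cannot fold up: target M={M} exceeds source M={fingerprint.M}"
        )
    folded: dict[int, int] = {}
    for idx, cnt in fingerprint.counts.items():
        j = idx % M
        folded[j] = folded.get(j, 0) + cnt
    return CountFingerprint(fingerprint.molecule_id, folded, M=M)


# ---------------------------------------------------------------------------
# text I/O

_FORMATS = ("dense-csv", "sparse-pairs")


def _parse_count(token: str, line: int, what: str) -> int:
    try:
        val = int(token)
    except ValueError:
        raise ParseError(f"{what} {token!r} is not an integer", line) from None
    if val < 0:
        raise ParseError(f"negative {what} {val}", line)
    return val


def _parse_sparse_field(text: str, line: int) -> dict[int, int]:
    counts: dict[int, int] = {}
    if not text.strip():
        return counts
    for pair in text.split():
        if ":" not in pair:
            raise ParseError(f"malformed idx:count pair {pair!r}", line)
        idx_s, cnt_s = pair.split(":", 1)
        idx = _parse_count(idx_s, line, "feature index")
        cnt = _parse_count(cnt_s, line, "count")
        if cnt == 0:
            continue
        if idx in counts:
            raise ParseError(f"duplicate feature index {idx}", line)
        counts[idx] = cnt
    return counts


def read_fingerprints(path, format: str = "dense-csv", M: Optional[int] = None) -> FingerprintDataset:
    """Read a :class:`FingerprintDataset` from a delimited text file.

    ``format`` is one of ``dense-csv`` or ``sparse-pairs``. For the sparse
    format the dimension is taken from the ``#M=`` header comment unless
    overridden by ``M``.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    with open(path, "rt", encoding="utf-8") as fh:
        return _read_stream(fh, format, M)


def _read_stream(fh, format: str, M: Optional[int]) -> FingerprintDataset:
    records: list[MoleculeRecord] = []
    header = None
    lineno = 0
    for raw in fh:
        lineno += 1
        stripped = raw.rstrip("\n")
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped.startswith("#M=") and M is None:
                M = _parse_count(stripped[3:], lineno, "dimension")
            continue
        if header is None:
            header = stripped.split(",")
            if format == "dense-csv":
                n_feat = len(header) - 2
                if n_feat < 1:
                    raise ParseError("dense header needs feature columns", lineno)
                if M is None:
                    M = n_feat
                elif M != n_feat:
                    raise DimensionError(
                        f"line {lineno}: header has {n_feat} feature columns, expected M={M}"
                    )
            continue
        if format == "dense-csv":
            fields = stripped.split(",")
            if len(fields) != M + 2:
                raise DimensionError(
                    f"line {lineno}: expected {M + 2} fields, got {len(fields)}"
                )
            mol_id, cls = fields[0], fields[1]
            values = [_parse_count(t, lineno, "count") for t in fields[2:]]
            counts = {i: v for i, v in enumerate(values) if v > 0}
        else:
            fields = stripped.split(",", 2)
            if len(fields) != 3:
                raise ParseError("expected molecule_id,activity_class,features", lineno)
            mol_id, cls = fields[0], fields[1]
            if M is None:
                raise ValueError("sparse-pairs file lacks '#M=' header and no M given")
            counts = _parse_sparse_field(fields[2], lineno)
            for idx in counts:
                if idx >= M:
                    raise DimensionError(
                        f"line {lineno}: feature index {idx} >= M={M}"
                    )
        if not mol_id:
            raise ParseError("empty molecule_id", lineno)
        fp = CountFingerprint(mol_id, counts, M=M)
        records.append(
            MoleculeRecord(fp, activity_class=cls or None, is_active=bool(cls) or None)
        )
    if header is None:
        raise ParseError("file has no header row", lineno or 1)
    if M is None:
        raise ValueError("could not determine feature dimension")
    return FingerprintDataset(records, M=M)


def write_fingerprints(dataset: FingerprintDataset, path, format: str = "dense-csv") -> None:
    """Write a dataset so that :func:`read_fingerprints` round-trips it."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    with open(path, "wt", encoding="utf-8") as fh:
        _write_stream(dataset, fh, format)


def _write_stream(dataset: FingerprintDataset, fh: io.TextIOBase, format: str) -> None:
    M = dataset.M
    if format == "dense-csv":
        fh.write("molecule_id,activity_class," + ",".join(f"f{j}" for j in range(M)) + "\n")
        for rec in dataset:
            dense = rec.fingerprint.to_dense(dtype=np.int64)
            row = ",".join(str(int(v)) for v in dense)
            fh.write(f"{rec.molecule_id},{rec.activity_class or ''},{row}\n")
    else:
        fh.write(f"#M={M}\n")
        fh.write("molecule_id,activity_class,features\n")
        for rec in dataset:
            pairs = " ".join(
                f"{idx}:{cnt}" for idx, cnt in sorted(rec.fingerprint.counts.items())
            )
            fh.write(f"{rec.molecule_id},{rec.activity_class or ''},{pairs}\n")


def dumps(dataset: FingerprintDataset, format: str = "sparse-pairs") -> str:
    """Serialize a dataset to a string (mainly for hashing/tests)."""
    buf = io.StringIO()
    _write_stream(dataset, buf, format)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# optional structure adapter

def read_smiles(path, M: int = DEFAULT_DIM, radius: int = 2) -> FingerprintDataset:
    """Convert a SMILES file to folded circular count fingerprints.

    Input format: one molecule per line, ``id<TAB>smiles``. Requires RDKit.
    This open-source Morgan count fingerprint is an approximation of
    commercial ECFC pipelines, not a bit-for-bit reproduction.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("read_smiles requires the optional rdkit dependency") from exc

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    records: list[MoleculeRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected 'id<TAB>smiles'", lineno)
            mol_id, smiles = parts
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ParseError(f"unparsable SMILES {smiles!r}", lineno)
            sparse = gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
            counts: dict[int, int] = {}
            for idx, cnt in sparse.items():
                j = idx % M
                counts[j] = counts.get(j, 0) + cnt
            records.append(MoleculeRecord(CountFingerprint(mol_id, counts, M=M)))
    return FingerprintDataset(records, M=M)
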