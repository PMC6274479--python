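import numpy as np
import pytest

from fpscreen.fingerprints import CountFingerprint, FingerprintDataset, MoleculeRecord


def make_fp(molecule_id, dense, M=None):
    """Build a CountFingerprint from a dense sequence."""
    M = M if M is not None else len(dense)
    return CountFingerprint(molecule_id, {i: int(v) for i, v in enumerate(dense) if v}, M=M)


def random_sparse_pair(rng, M=1024, density=0.1, max_count=6):
    """Two random sparse count vectors (dense numpy arrays)."""
    out = []
    for _ in range(2):
        v = np.zeros(M)
        nz = rng.random(M) < density
        v[nz] = rng.integers(1, max_count + 1, size=int(nz.sum()))
        out.append(v)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    """Five molecules over M=6 with two classes and one unlabelled decoy."""
    rows = [
        ("a1", "alpha", [2, 0, 1, 0, 0, 0]),
        ("a2", "alpha", [3, 0, 2, 0, 0, 0]),
        ("b1", "beta", [0, 1, 0, 4, 0, 0]),
        ("b2", "beta", [0, 2, 0, 5, 0, 0]),
        ("d1", None, [0, 0, 0, 0, 1, 1]),
    ]
    records = [
        MoleculeRecord(make_fp(mid, dense), activity_class=cls, is_active=bool(cls) or None)
        for mid, cls, dense in rows
    ]
    return FingerprintDataset(records, M=6)
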