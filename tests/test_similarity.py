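import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpscreen.exceptions import DegenerateInputError, DimensionError
from fpscreen.fingerprints import FingerprintDataset, MoleculeRecord
from fpscreen.similarity import (
    FeatureScaling,
    SimilarityConfig,
    asmtp,
    asmtp_batch,
    baseline_measure,
    compute_feature_scaling,
    cosine,
    dice,
    euclidean,
    extended_jaccard,
    get_measure,
    tanimoto_binary,
    tanimoto_continuous,
)

from .conftest import make_fp, random_sparse_pair
from .oracles import asmtp_scalar, mean_nonzero, tanimoto_continuous_scalar


def scaling_from(mu, n=None):
    mu = np.asarray(mu, dtype=float)
    n = np.asarray(n if n is not None else [2] * len(mu))
    return FeatureScaling(mu=mu, n=n, source_size=2)


class TestFeatureScaling:
    def test_mean_of_nonzero_column(self):
        # column values [2,0,4,0,6] -> mu=4, n=3
        records = [
            MoleculeRecord(make_fp(f"m{i}", [v]))
            for i, v in enumerate([2, 0, 4, 0, 6])
        ]
        ds = FingerprintDataset(records, M=1)
        sc = compute_feature_scaling(ds)
        assert sc.mu[0] == 4.0
        assert sc.n[0] == 3
        assert sc.source_size == 5

    def test_all_zero_column_gets_sentinel(self):
        ds = FingerprintDataset([MoleculeRecord(make_fp("m", [1, 0]))], M=2)
        sc = compute_feature_scaling(ds)
        assert sc.mu[1] == 1.0
        assert sc.n[1] == 0

    def test_single_molecule_column(self):
        ds = FingerprintDataset([MoleculeRecord(make_fp("m", [5]))], M=1)
        sc = compute_feature_scaling(ds)
        assert sc.mu[0] == 5.0
        assert sc.n[0] == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_feature_scaling(FingerprintDataset([], M=4))

    def test_matches_loop_oracle(self, rng):
        X = np.where(rng.random((20, 30)) < 0.3, rng.integers(1, 6, (20, 30)), 0)
        records = [MoleculeRecord(make_fp(f"m{i}", X[i])) for i in range(20)]
        sc = compute_feature_scaling(FingerprintDataset(records, M=30))
        for j in range(30):
            mu, n = mean_nonzero(X[:, j])
            assert sc.mu[j] == pytest.approx(mu, abs=1e-12)
            assert sc.n[j] == n

    def test_stddev_mode(self):
        # nonzero values of the column: [2, 4] -> population sd = 1
        records = [MoleculeRecord(make_fp(f"m{i}", [v])) for i, v in enumerate([2, 4, 0])]
        sc = compute_feature_scaling(FingerprintDataset(records, M=1), mode="nonzero-stddev")
        assert sc.mu[0] == pytest.approx(1.0)

    def test_stddev_degenerate_spread_sentinel(self):
        records = [MoleculeRecord(make_fp(f"m{i}", [3])) for i in range(3)]
        sc = compute_feature_scaling(FingerprintDataset(records, M=1), mode="nonzero-stddev")
        assert sc.mu[0] == 1.0


class TestSimilarityConfig:
    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            SimilarityConfig(lam=0.0)

    def test_large_lambda_warns_but_is_accepted(self):
        with pytest.warns(UserWarning):
            cfg = SimilarityConfig(lam=0.5)
        assert cfg.lam == 0.5


class TestAsmtpHandExamples:
    def test_worked_example_lambda_001(self):
        m1 = make_fp("m1", [2, 0, 1])
        m2 = make_fp("m2", [2, 3, 0])
        sc = scaling_from([2, 3, 1])
        s = asmtp(m1, m2, sc, SimilarityConfig(lam=0.01))
        # shared j0 contributes 1.0, two mismatches -0.01 each:
        # F = 0.98/3, S = (F + 0.01)/1.01 = 1/3
        assert s == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert s == pytest.approx(0.333334, abs=1e-6)

    def test_worked_example_lambda_00001(self):
        m1 = make_fp("m1", [1, 2])
        m2 = make_fp("m2", [3, 2])
        sc = scaling_from([2, 2])
        s = asmtp(m1, m2, sc, SimilarityConfig(lam=0.0001))
        assert s == pytest.approx(0.841986, abs=1e-6)

    def test_identical_is_exactly_one(self, rng):
        dense = np.where(rng.random(50) < 0.2, rng.integers(1, 5, 50), 0)
        if not dense.any():
            dense[0] = 3
        m = make_fp("m", dense)
        sc = scaling_from(rng.uniform(1, 4, 50))
        assert asmtp(m, m, sc, SimilarityConfig(lam=0.0001)) == 1.0

    def test_disjoint_is_exactly_zero(self):
        m1 = make_fp("m1", [1, 0, 2, 0])
        m2 = make_fp("m2", [0, 3, 0, 4])
        sc = scaling_from([1, 1, 1, 1])
        assert asmtp(m1, m2, sc, SimilarityConfig(lam=0.0001)) == 0.0

    def test_both_empty_is_error(self):
        m1 = make_fp("m1", [0, 0])
        m2 = make_fp("m2", [0, 0])
        with pytest.raises(DegenerateInputError):
            asmtp(m1, m2, scaling_from([1, 1]))

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            asmtp(make_fp("a", [1]), make_fp("b", [1, 1]), scaling_from([1]))
        with pytest.raises(DimensionError):
            asmtp(make_fp("a", [1, 1]), make_fp("b", [1, 1]), scaling_from([1]))


class TestAsmtpOracle:
    def test_matches_scalar_oracle_on_random_sparse_pairs(self, rng):
        M = 1024
        mu = rng.uniform(1.0, 5.0, M)
        sc = scaling_from(mu)
        cfg = SimilarityConfig(lam=0.0001)
        for i in range(200):
            v1, v2 = random_sparse_pair(rng, M=M, density=0.1)
            if not (v1.any() or v2.any()):
                v1[0] = 1
            got = asmtp(make_fp(f"x{i}", v1), make_fp(f"y{i}", v2), sc, cfg)
            want = asmtp_scalar(v1, v2, mu, 0.0001)
            assert abs(got - want) < 1e-12

    def test_batch_matches_pairwise(self, rng):
        M = 256
        mu = rng.uniform(1.0, 4.0, M)
        sc = scaling_from(mu)
        cfg = SimilarityConfig(lam=0.001)
        q, _ = random_sparse_pair(rng, M=M, density=0.1)
        q[0] = 1  # never empty
        X = np.stack([random_sparse_pair(rng, M=M, density=0.1)[0] for _ in range(50)])
        batch = asmtp_batch(q, X, sc, lam=0.001)
        for i in range(50):
            if X[i].any() or q.any():
                want = asmtp(make_fp("q", q), make_fp(f"r{i}", X[i]), sc, cfg)
                assert batch[i] == pytest.approx(want, abs=1e-12)

    def test_batch_nan_for_empty_union(self):
        sc = scaling_from([1.0, 1.0])
        out = asmtp_batch(np.zeros(2), np.zeros((3, 2)), sc, lam=0.01)
        assert np.isnan(out).all()


class TestAsmtpProperties:
    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        M = 64
        mu = rng.uniform(1.0, 5.0, M)
        sc = scaling_from(mu)
        cfg = SimilarityConfig(lam=0.0001)
        v1, v2 = random_sparse_pair(rng, M=M, density=0.15)
        if not (v1.any() or v2.any()):
            v1[0] = 2
        s12 = asmtp(make_fp("a", v1), make_fp("b", v2), sc, cfg)
        s21 = asmtp(make_fp("b", v2), make_fp("a", v1), sc, cfg)
        assert s12 == s21
        assert 0.0 <= s12 <= 1.0

    def test_monotone_in_shared_value_gap(self):
        # widening |m1j - m2j| on a shared feature never increases the score
        sc = scaling_from([2.0, 2.0, 2.0])
        cfg = SimilarityConfig(lam=0.0001)
        m2 = make_fp("b", [3, 1, 2])
        prev = None
        for v in range(3, 12):
            s = asmtp(make_fp("a", [v, 1, 2]), m2, sc, cfg)
            if prev is not None:
                assert s <= prev + 1e-15
            prev = s

    def test_presence_absence_penalty(self):
        # adding a feature present in exactly one molecule lowers the score
        sc = scaling_from([2.0, 2.0, 2.0])
        cfg = SimilarityConfig(lam=0.0001)
        base = asmtp(make_fp("a", [2, 2, 0]), make_fp("b", [2, 2, 0]), sc, cfg)
        widened = asmtp(make_fp("a", [2, 2, 3]), make_fp("b", [2, 2, 0]), sc, cfg)
        assert widened < base

    def test_lambda_continuity_toward_zero(self):
        m1 = make_fp("a", [1, 0])
        m2 = make_fp("b", [0, 1])
        sc = scaling_from([1.0, 1.0])
        prev = None
        for lam in [0.01, 0.001, 0.0001, 1e-6, 1e-9]:
            s = asmtp(m1, m2, sc, SimilarityConfig(lam=lam))
            assert s == 0.0  # exact for disjoint supports at any lambda
            prev = s
        # continuity on a mixed pair: small lambda changes move S slightly
        m3 = make_fp("c", [1, 1])
        vals = [
            asmtp(m1, m3, sc, SimilarityConfig(lam=lam))
            for lam in [0.01, 0.005, 0.001, 0.0001]
        ]
        diffs = np.abs(np.diff(vals))
        assert (diffs < 0.01).all()


class TestTanimoto:
    def test_continuous_hand_example(self):
        s = tanimoto_continuous(make_fp("a", [1, 2, 0]), make_fp("b", [0, 2, 1]))
        assert s == pytest.approx(4 / 6, abs=1e-12)

    def test_continuous_identity_and_disjoint(self):
        a = make_fp("a", [1, 2, 0])
        assert tanimoto_continuous(a, a) == pytest.approx(1.0)
        assert tanimoto_continuous(a, make_fp("b", [0, 0, 3])) == 0.0

    def test_continuous_matches_oracle(self, rng):
        for _ in range(50):
            v1, v2 = random_sparse_pair(rng, M=64, density=0.3)
            if not (v1.any() or v2.any()):
                continue
            got = tanimoto_continuous(make_fp("a", v1), make_fp("b", v2))
            assert got == pytest.approx(tanimoto_continuous_scalar(v1, v2), abs=1e-12)

    def test_binary_hand_example(self):
        # a=4 on-bits, b=5 on-bits, c=3 common -> 3/(4+5-3) = 0.5
        a = make_fp("a", [1, 1, 1, 1, 0, 0, 0])
        b = make_fp("b", [5, 2, 9, 0, 1, 1, 0])
        assert tanimoto_binary(a, b) == pytest.approx(0.5)

    def test_binary_identity_and_disjoint(self):
        a = make_fp("a", [2, 0, 7])
        assert tanimoto_binary(a, make_fp("b", [9, 0, 1])) == 1.0
        assert tanimoto_binary(a, make_fp("c", [0, 4, 0])) == 0.0

    def test_both_empty_errors(self):
        e1, e2 = make_fp("a", [0, 0]), make_fp("b", [0, 0])
        with pytest.raises(DegenerateInputError):
            tanimoto_continuous(e1, e2)
        with pytest.raises(DegenerateInputError):
            tanimoto_binary(e1, e2)


class TestBaselines:
    def test_dice_hand_example(self):
        assert dice(make_fp("a", [1, 1, 0]), make_fp("b", [1, 0, 0])) == pytest.approx(2 / 3)

    def test_cosine_identity(self):
        a = make_fp("a", [1, 2, 3])
        assert cosine(a, a) == pytest.approx(1.0)

    def test_cosine_zero_norm_errors(self):
        with pytest.raises(DegenerateInputError):
            cosine(make_fp("a", [1, 0]), make_fp("b", [0, 0]))

    def test_euclidean_identity_and_value(self):
        a = make_fp("a", [1, 2, 0])
        assert euclidean(a, a) == 0.0
        assert euclidean(a, make_fp("b", [1, 0, 0])) == pytest.approx(2.0)

    def test_extended_jaccard_equals_continuous_tanimoto(self, rng):
        v1, v2 = random_sparse_pair(rng, M=32, density=0.4)
        v1[0] = 1
        a, b = make_fp("a", v1), make_fp("b", v2)
        assert extended_jaccard(a, b) == tanimoto_continuous(a, b)

    def test_baseline_registry_dispatch(self):
        a, b = make_fp("a", [1, 1, 0]), make_fp("b", [1, 0, 0])
        assert baseline_measure("dice", a, b) == dice(a, b)
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_measure("nope", a, b)


class TestMeasureRegistry:
    @pytest.mark.parametrize(
        "name", ["asmtp", "tanimoto", "tanimoto_binary", "dice", "cosine", "euclidean", "extended_jaccard"]
    )
    def test_registry_has_all_measures(self, name):
        m = get_measure(name)
        assert m.name in (name, "tanimoto")  # extended_jaccard shares the batch fn

    def test_euclidean_is_distance(self):
        assert get_measure("euclidean").is_distance
        assert not get_measure("asmtp").is_distance

    def test_unknown_measure(self):
        with pytest.raises(ValueError, match="unknown measure"):
            get_measure("forbes")

    @pytest.mark.parametrize("name", ["tanimoto", "tanimoto_binary", "dice", "cosine", "euclidean"])
    def test_batch_agrees_with_pairwise(self, name, rng):
        from fpscreen.similarity import _BASELINES

        pair_fns = {
            "tanimoto": tanimoto_continuous,
            "tanimoto_binary": tanimoto_binary,
            **_BASELINES,
        }
        meas = get_measure(name)
        q, _ = random_sparse_pair(rng, M=64, density=0.3)
        q[0] = 1
        X = np.stack([random_sparse_pair(rng, M=64, density=0.3)[0] for _ in range(20)])
        batch = meas.batch(q, X, None, 0.0001)
        for i in range(20):
            try:
                want = pair_fns[name](make_fp("q", q), make_fp(f"r{i}", X[i]))
            except DegenerateInputError:
                assert np.isnan(batch[i])
                continue
            assert batch[i] == pytest.approx(want, abs=1e-12)
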