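"""Feature encoders: dimensions, values, and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kptmpred as kp
from kptmpred.aaf import AAF_MATRIX, N_FACTORS
from kptmpred.alphabet import ALPHABET, ALPHABET_SIZE
from kptmpred.encoders import (AAFEncoder, BinaryEncoder, CKSAAPEncoder,
                               CouplingModel, EnsembleEncoder,
                               SequenceCouplingEncoder, fit_coupling)
from kptmpred.errors import (EmptyInputError, ShapeError, WindowTooShortError)

from conftest import random_windows


def cksaap_oracle(window, k_values):
    """Brute-force pair enumeration over all (i, i+k+1) positions."""
    out = []
    for k in k_values:
        counts = {a + b: 0 for a in ALPHABET for b in ALPHABET}
        pairs = [(i, i + k + 1) for i in range(len(window) - k - 1)]
        for i, j in pairs:
            counts[window[i] + window[j]] += 1
        out.extend(counts[a + b] / len(pairs)
                   for a in ALPHABET for b in ALPHABET)
    return np.array(out)


class TestAAF:
    def test_dimension_245_at_default_window(self):
        w = random_windows(np.random.default_rng(0), 3, 24)
        assert AAFEncoder(24).fit(w).transform(w).shape == (3, 245)

    def test_dimension_15_at_zeta_1(self):
        assert kp.encode_aaf("AKC").shape == (15,)

    def test_wildcard_window_is_zero(self):
        win = "Z" * 24 + "K" + "Z" * 24
        vec = kp.encode_aaf(win)
        center = vec[24 * N_FACTORS:25 * N_FACTORS]
        assert np.allclose(np.delete(vec, range(24 * N_FACTORS, 25 * N_FACTORS)), 0)
        assert np.allclose(center, AAF_MATRIX[ALPHABET.index("K")])

    def test_position_major_layout(self):
        vec = kp.encode_aaf("AKC")
        assert np.allclose(vec[:5], AAF_MATRIX[ALPHABET.index("A")])
        assert np.allclose(vec[10:], AAF_MATRIX[ALPHABET.index("C")])


class TestBinaryEncoding:
    @pytest.mark.parametrize("residue,expected", [
        ("A", "100000000000000000000"),
        ("G", "000001000000000000000"),  # index 5 in ACDEFGHIKLMNPQRSTVWYZ
        ("Z", "000000000000000000001"),
    ])
    def test_one_hot_patterns(self, residue, expected):
        vec = kp.encode_binary(residue + "K" + residue)
        assert "".join(str(int(v)) for v in vec[:21]) == expected

    def test_one_hot_index_matches_alphabet_order(self):
        for i, aa in enumerate(ALPHABET):
            vec = kp.encode_binary(aa + "K" + aa)
            assert vec[:21].argmax() == i and vec[:21].sum() == 1

    def test_dimension_1029_at_default_window(self):
        w = random_windows(np.random.default_rng(0), 2, 24)
        out = BinaryEncoder(24).fit(w).transform(w)
        assert out.shape == (2, 1029)
        assert np.all(out.sum(axis=1) == 49)  # one bit per residue


class TestCKSAAP:
    def test_dimensions(self):
        w = random_windows(np.random.default_rng(0), 2, 24)
        assert CKSAAPEncoder(24).fit(w).transform(w).shape == (2, 2205)
        assert CKSAAPEncoder(24, [0]).fit(w).transform(w).shape == (2, 441)

    def test_each_block_sums_to_one(self, rng):
        w = random_windows(rng, 20, 24)
        out = CKSAAPEncoder(24).fit(w).transform(w)
        sums = out.reshape(20, 5, 441).sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        ks = (0, 1, 2, 3, 4)
        windows = random_windows(rng, 200, 24)
        enc = CKSAAPEncoder(24, ks).fit(windows).transform(windows)
        for i, w in enumerate(windows):
            assert np.max(np.abs(enc[i] - cksaap_oracle(w, ks))) <= 1e-12

    def test_k_too_large_rejected(self):
        with pytest.raises(WindowTooShortError):
            CKSAAPEncoder(1, [2]).fit(["AKC"])


class TestSequenceCoupling:
    def test_identical_classes_give_zero_vector(self, rng):
        w = random_windows(rng, 10, 4)
        enc = fit_coupling(w, list(w), zeta=4)
        assert np.allclose(enc.transform(w), 0.0)
        assert enc.transform(w).shape == (10, 8)

    def test_dimension_48_at_default_window(self, rng):
        pos = random_windows(rng, 5, 24)
        neg = random_windows(rng, 5, 24)
        enc = fit_coupling(pos, neg, zeta=24)
        assert kp.encode_coupling(pos[0], enc).shape == (48,)

    def test_values_bounded_by_unit_interval(self, rng):
        pos = random_windows(rng, 30, 6)
        neg = random_windows(rng, 30, 6)
        enc = fit_coupling(pos, neg, zeta=6)
        out = enc.transform(random_windows(rng, 50, 6))
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_conditional_rows_sum_to_one(self, rng):
        model = CouplingModel.fit(random_windows(rng, 25, 5), zeta=5)
        for j, table in model.tables.items():
            if table.ndim == 2:
                assert np.allclose(table.sum(axis=0), 1.0, atol=1e-9)
            else:
                assert abs(table.sum() - 1.0) < 1e-9
            assert np.all(table >= 0) and np.all(table <= 1)

    def test_unseen_pair_probability_is_smoothed(self):
        # three windows, zeta=2: offset -2 conditions on offset -1
        windows = ["AAKCC", "AAKCC", "CAKCC"]
        eps = 1e-4
        model = CouplingModel.fit(windows, zeta=2, pseudocount=eps)
        t = model.tables[-2]
        a_col = ALPHABET.index("A")
        # context b='A' at offset -1 seen n_b=3 times; 'G' at -2 never
        expected_unseen = eps / (ALPHABET_SIZE * eps + 3)
        assert t[ALPHABET.index("G"), a_col] == pytest.approx(expected_unseen)
        assert t[ALPHABET.index("A"), a_col] == pytest.approx(
            (2 + eps) / (ALPHABET_SIZE * eps + 3))

    def test_antisymmetry_under_class_swap(self, rng):
        pos = random_windows(rng, 15, 5)
        neg = random_windows(rng, 15, 5)
        probe = random_windows(rng, 10, 5)
        fwd = fit_coupling(pos, neg, zeta=5).transform(probe)
        rev = fit_coupling(neg, pos, zeta=5).transform(probe)
        assert np.array_equal(fwd, -rev)

    def test_empty_class_rejected(self, rng):
        enc = SequenceCouplingEncoder(zeta=3)
        w = random_windows(rng, 4, 3)
        with pytest.raises(EmptyInputError):
            enc.fit(w, [1, 1, 1, 1])

    def test_json_round_trip(self, rng):
        model = CouplingModel.fit(random_windows(rng, 12, 4), zeta=4)
        back = CouplingModel.from_json(model.to_json())
        assert back.zeta == model.zeta
        for j in model.tables:
            assert np.allclose(back.tables[j], model.tables[j], atol=0)


class TestEnsemble:
    def test_full_dimension_3527(self, rng):
        w = random_windows(rng, 8, 24)
        y = [1, 0] * 4
        enc = EnsembleEncoder(zeta=24).fit(w, y=y)
        X = enc.transform(w)
        assert X.shape == (8, 3527)
        assert len(enc.feature_names_out_) == 3527
        assert np.isfinite(X).all()

    @given(zeta=st.integers(min_value=2, max_value=10),
           n_k=st.integers(min_value=1, max_value=3))
    @settings(max_examples=10, deadline=None)
    def test_dimension_bookkeeping_for_any_zeta(self, zeta, n_k):
        rng = np.random.default_rng(zeta * 100 + n_k)
        w = random_windows(rng, 6, zeta)
        y = [1, 0, 1, 0, 1, 0]
        ks = tuple(range(n_k))
        enc = EnsembleEncoder(zeta=zeta, k_values=ks).fit(w, y=y)
        expected = (5 * (2 * zeta + 1) + 21 * (2 * zeta + 1)
                    + 441 * n_k + 2 * zeta)
        assert enc.transform(w).shape[1] == expected

    def test_standardized_training_columns(self, rng):
        w = random_windows(rng, 40, 4)
        y = [1, 0] * 20
        enc = EnsembleEncoder(zeta=4, k_values=(0, 1)).fit(w, y=y)
        X = enc.transform(w)
        nonconst = enc.scaler_.var_ > 0
        assert np.abs(X[:, nonconst].mean(axis=0)).max() < 1e-9
        assert np.abs(X[:, nonconst].std(axis=0) - 1).max() < 1e-9
        # constant columns: scale left at 1, transformed to exactly 0
        assert np.allclose(X[:, ~nonconst], 0.0)

    def test_coupling_only_subset(self, rng):
        w = random_windows(rng, 10, 24)
        y = [1, 0] * 5
        enc = EnsembleEncoder(zeta=24, encoders=("coupling",)).fit(w, y=y)
        assert enc.transform(w).shape[1] == 48
        assert all(n.startswith("coupling:") for n in enc.feature_names_out_)

    def test_deterministic_bit_identical(self, rng):
        w = random_windows(rng, 12, 5)
        y = [1, 0] * 6
        a = EnsembleEncoder(zeta=5).fit(w, y=y).transform(w)
        b = EnsembleEncoder(zeta=5).fit(list(w), y=list(y)).transform(w)
        assert np.array_equal(a, b)

    def test_scaler_learned_on_training_subset_only(self, rng):
        train = random_windows(rng, 30, 3)
        other = random_windows(rng, 30, 3)
        y = [1, 0] * 15
        enc = EnsembleEncoder(zeta=3, k_values=(0,)).fit(train, y=y)
        X_other = enc.transform(other)
        # other-subset columns are scaled by train parameters, not refit
        assert np.abs(X_other.mean(axis=0)).max() > 1e-6

    def test_feature_tsv_round_trip(self, rng, tmp_path):
        w = random_windows(rng, 6, 3)
        y = [1, 0] * 3
        enc = EnsembleEncoder(zeta=3, k_values=(0,)).fit(w, y=y)
        X = enc.transform(w)
        path = tmp_path / "features.tsv"
        kp.write_feature_tsv(X, enc.feature_names_out_, path)
        back, names = kp.read_feature_tsv(path)
        assert names == list(enc.feature_names_out_)
        assert np.allclose(back, X, atol=1e-10)

    def test_window_length_mismatch_rejected(self, rng):
        enc = EnsembleEncoder(zeta=4, encoders=("aaf",)).fit(
            random_windows(rng, 3, 4))
        with pytest.raises(ShapeError):
            enc.transform(random_windows(rng, 3, 5))
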