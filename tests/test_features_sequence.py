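import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protloc.data_model import STANDARD_AA
from protloc.features_sequence import (
    SCORE_FLOOR,
    SEQUENCE_BLOCK_WIDTH,
    AAIndexTable,
    compute_aac,
    compute_pseaac,
    compute_weighted_sign_aaindex,
    extract_regions,
    sequence_block_map,
    sequence_feature_block,
)

sequences = st.text(alphabet=STANDARD_AA, min_size=1, max_size=300)


def random_sequence(rng, n):
    return "".join(rng.choice(list(STANDARD_AA), size=n))


class TestRegions:
    def test_len_90_slices(self):
        seq = random_sequence(np.random.default_rng(0), 90)
        r = extract_regions(seq)
        assert r.n30 == seq[0:30]
        assert r.mid3 == seq[30:60]
        assert r.c50 == seq[40:90]

    def test_len_30_n30_is_full(self):
        seq = random_sequence(np.random.default_rng(1), 30)
        assert extract_regions(seq).n30 == seq

    def test_len_300_against_index_oracle(self):
        seq = random_sequence(np.random.default_rng(2), 300)
        r = extract_regions(seq)
        third = 300 // 3
        start = (300 - third) // 2
        assert r.full == seq
        assert r.n30 == seq[:30]
        assert r.mid3 == seq[start : start + third]
        assert r.c50 == seq[-50:]

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_regions_are_contiguous_subsequences(self, seq):
        r = extract_regions(seq)
        for region in (r.n30, r.mid3, r.c50):
            assert region in seq  # contiguity
        assert len(r.n30) == min(30, len(seq))
        assert len(r.c50) == min(50, len(seq))
        assert len(r.mid3) == len(seq) // 3

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            extract_regions("")


class TestAAC:
    def test_homopolymer(self):
        aac = compute_aac("AAAA")
        assert aac[0] == 1.0 and aac[1:].sum() == 0.0

    def test_uniform_20mer(self):
        np.testing.assert_allclose(compute_aac(STANDARD_AA), np.full(20, 0.05))

    def test_counting_oracle_on_random_200mer(self, rng):
        seq = random_sequence(rng, 200)
        aac = compute_aac(seq)
        for i, aa in enumerate(STANDARD_AA):
            assert aac[i] == seq.count(aa) / 200

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_and_permutation_invariant(self, seq):
        aac = compute_aac(seq)
        assert abs(aac.sum() - 1.0) < 1e-9
        shuffled = "".join(sorted(seq))
        np.testing.assert_allclose(compute_aac(shuffled), aac)

    def test_empty_region_yields_zero_vector(self):
        assert compute_aac("").sum() == 0.0


class TestAAIndexTable:
    def test_default_table_shape_and_finiteness(self, aaindex):
        assert aaindex.values.shape == (100, 20)
        assert np.isfinite(aaindex.values).all()
        assert len(set(aaindex.ids)) == 100

    def test_tsv_round_trip(self, aaindex, tmp_path):
        p = tmp_path / "table.tsv"
        aaindex.to_tsv(p)
        back = AAIndexTable.from_tsv(p)
        assert back.ids == aaindex.ids
        np.testing.assert_allclose(back.values, aaindex.values, rtol=1e-5)

    def test_non_finite_rejected(self):
        vals = np.ones((100, 20))
        vals[3, 7] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            AAIndexTable([f"i{k}" for k in range(100)], vals)


class TestWeightedSignAAIndex:
    def test_single_acid_mass(self):
        vals = np.zeros((100, 20))
        vals[:, 0] = 10.0  # h(A) = 10 for every scale
        table = AAIndexTable([f"i{k}" for k in range(100)], vals)
        aac = np.zeros(20)
        aac[0] = 1.0
        w = compute_weighted_sign_aaindex(aac, table)
        np.testing.assert_allclose(w.score, 10.0)
        np.testing.assert_allclose(w.sign, 0.0)
        np.testing.assert_allclose(w.C, 1.0)  # log10(10)

    def test_constant_negative_index(self, rng):
        vals = -np.ones((100, 20))
        table = AAIndexTable([f"i{k}" for k in range(100)], vals)
        aac = rng.dirichlet(np.ones(20))
        w = compute_weighted_sign_aaindex(aac, table)
        np.testing.assert_allclose(w.score, -1.0, atol=1e-12)
        np.testing.assert_allclose(w.sign, 1.0)
        np.testing.assert_allclose(w.C, 0.0, atol=1e-12)

    def test_dot_product_oracle(self, rng):
        vals = rng.normal(size=(100, 20))
        table = AAIndexTable([f"i{k}" for k in range(100)], vals)
        aac = rng.dirichlet(np.ones(20))
        w = compute_weighted_sign_aaindex(aac, table)
        for i in range(100):
            expected = sum(aac[j] * vals[i, j] for j in range(20))
            assert abs(w.score[i] - expected) < 1e-12
            assert w.sign[i] == (1.0 if expected < 0 else 0.0)
            assert abs(w.C[i] - np.log10(max(abs(expected), SCORE_FLOOR))) < 1e-12

    def test_sign_complements_nonneg_scores(self, aaindex, rng):
        for _ in range(20):
            aac = rng.dirichlet(np.ones(20))
            w = compute_weighted_sign_aaindex(aac, aaindex)
            np.testing.assert_array_equal(w.sign == 1.0, w.score < 0)

    def test_magnitude_monotonicity(self, rng):
        vals = np.tile(np.linspace(0.1, 2.0, 20), (100, 1))
        table = AAIndexTable([f"i{k}" for k in range(100)], vals)
        lo = np.zeros(20); lo[0] = 1.0   # score 0.1
        hi = np.zeros(20); hi[19] = 1.0  # score 2.0
        w_lo = compute_weighted_sign_aaindex(lo, table)
        w_hi = compute_weighted_sign_aaindex(hi, table)
        assert (w_hi.C >= w_lo.C).all()


# independent PC-PseAAC oracle: published property values, term-by-term
_ORACLE_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.9, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.4, "I": 1.38, "K": -1.5, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_ORACLE_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_ORACLE_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _oracle_pseaac(seq, lam, omega):
    props = []
    for scale in (_ORACLE_HYDROPHOBICITY, _ORACLE_HYDROPHILICITY, _ORACLE_MASS):
        vals = [scale[aa] for aa in STANDARD_AA]
        mean = sum(vals) / 20
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
        props.append({aa: (scale[aa] - mean) / sd for aa in STANDARD_AA})

    def theta_pair(a, b):
        return sum((p[b] - p[a]) ** 2 for p in props) / 3

    thetas = []
    for k in range(1, lam + 1):
        pairs = [theta_pair(seq[i], seq[i + k]) for i in range(len(seq) - k)]
        thetas.append(sum(pairs) / len(pairs))
    freqs = [seq.count(aa) / len(seq) for aa in STANDARD_AA]
    denom = sum(freqs) + omega * sum(thetas)
    return [f / denom for f in freqs] + [omega * t / denom for t in thetas]


class TestPseAAC:
    def test_lambda_zero_equals_aac(self):
        seq = "MKVLATMKVLAT"
        np.testing.assert_allclose(compute_pseaac(seq, lam=0), compute_aac(seq))

    def test_homopolymer_zero_correlation(self):
        seq = "A" * 50
        vec = compute_pseaac(seq, lam=8)
        np.testing.assert_allclose(vec[:20], compute_aac(seq))
        np.testing.assert_allclose(vec[20:], 0.0)

    def test_term_by_term_oracle(self):
        vec = compute_pseaac("MKVLAT", lam=2, omega=0.05)
        expected = _oracle_pseaac("MKVLAT", 2, 0.05)
        np.testing.assert_allclose(vec, expected, atol=1e-12)

    @given(st.text(alphabet=STANDARD_AA, min_size=10, max_size=120))
    @settings(max_examples=40, deadline=None)
    def test_nonnegative_and_sums_to_one(self, seq):
        vec = compute_pseaac(seq, lam=8)
        assert (vec >= 0).all()
        assert abs(vec.sum() - 1.0) < 1e-9

    def test_short_sequence_error(self):
        with pytest.raises(ValueError, match="lambda"):
            compute_pseaac("MKV", lam=8)


class TestSequenceBlock:
    def test_block_map_spans_cover_exactly(self):
        bm = sequence_block_map()
        spans = sorted(span for _, span in bm.items())
        assert spans[0][0] == 0
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            assert hi == lo
        assert spans[-1][1] == bm.total_width == SEQUENCE_BLOCK_WIDTH

    def test_deterministic(self, aaindex, rng):
        seq = random_sequence(rng, 120)
        b1 = sequence_feature_block(seq, aaindex)
        b2 = sequence_feature_block(seq, aaindex)
        np.testing.assert_array_equal(b1, b2)

    def test_permutation_changes_correlations_not_full_aac(self, aaindex, rng):
        seq = random_sequence(rng, 150)
        perm = "".join(rng.permutation(list(seq)))
        bm = sequence_block_map()
        b1 = sequence_feature_block(seq, aaindex)
        b2 = sequence_feature_block(perm, aaindex)
        np.testing.assert_allclose(bm.slice(b1, "aac_full"), bm.slice(b2, "aac_full"))
        assert not np.allclose(bm.slice(b1, "pseaac")[20:], bm.slice(b2, "pseaac")[20:])
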