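import itertools
import math

import numpy as np
import pytest

from protloc.data_model import Dataset, Location, ProteinRecord
from protloc.features_go import (
    GOAnnotationSource,
    GOFeatureSpec,
    binary_mutual_information,
    go_vector,
    read_go_annotations,
    regular_mrmr,
    select_k_by_cv,
)


def _naive_mi(x, y):
    """Enumeration oracle for binary MI in nats."""
    n = len(x)
    mi = 0.0
    for xv, yv in itertools.product([0, 1], repeat=2):
        nxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv)
        if nxy == 0:
            continue
        px = sum(1 for a in x if a == xv) / n
        py = sum(1 for b in y if b == yv) / n
        mi += (nxy / n) * math.log((nxy / n) / (px * py))
    return mi


def _oracle_greedy_mrmr(X, term_ids, Y, k):
    """Brute-force greedy selection recomputing every MI term naively."""
    usable = [j for j in range(X.shape[1]) if 0 < X[:, j].sum() < len(X)]
    rel = {
        j: sum(_naive_mi(X[:, j], Y[:, l]) for l in range(Y.shape[1])) / Y.shape[1]
        for j in usable
    }
    selected = []
    while len(selected) < k:
        best, best_obj = None, -np.inf
        for j in usable:
            if j in selected:
                continue
            red = (
                sum(_naive_mi(X[:, j], X[:, s]) for s in selected) / len(selected)
                if selected
                else 0.0
            )
            obj = rel[j] - red
            if obj > best_obj or (obj == best_obj and term_ids[j] < term_ids[best]):
                best, best_obj = j, obj
        selected.append(best)
    return [term_ids[j] for j in selected]


def _label_matrix(labels):
    Y = np.zeros((len(labels), 6), dtype=int)
    for i, locs in enumerate(labels):
        for l in locs:
            Y[i, int(l)] = 1
    return Y


class TestBinaryMI:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            x = rng.random(40) < rng.uniform(0.2, 0.8)
            y = rng.random(40) < rng.uniform(0.2, 0.8)
            assert binary_mutual_information(x, y) == pytest.approx(
                max(_naive_mi(x.astype(int), y.astype(int)), 0.0), abs=1e-12
            )

    def test_independent_variables_have_zero_mi(self):
        x = np.array([0, 0, 1, 1], dtype=bool)
        y = np.array([0, 1, 0, 1], dtype=bool)
        assert binary_mutual_information(x, y) == 0.0

    def test_identical_variables_have_entropy_mi(self):
        x = np.array([0, 1, 1, 0], dtype=bool)
        assert binary_mutual_information(x, x) == pytest.approx(math.log(2))


class TestGoVector:
    def test_single_matching_term(self):
        spec = GOFeatureSpec(terms=("GO:0000001", "GO:0000002", "GO:0000003"))
        rec = ProteinRecord("p", "M" * 80, go_terms=("GO:0000001",))
        vec, missing = go_vector(rec, spec)
        np.testing.assert_array_equal(vec, [1, 0, 0])
        assert not missing

    def test_no_terms_zero_vector_with_flag(self):
        spec = GOFeatureSpec(terms=("GO:0000001",))
        vec, missing = go_vector(ProteinRecord("p", "M" * 80), spec)
        assert vec.sum() == 0 and missing

    def test_membership_oracle_on_synthetic_records(self, small_proteome):
        dataset, truth = small_proteome
        spec = GOFeatureSpec(terms=truth.all_terms[:20])
        for rec in dataset.records[:20]:
            vec, _ = go_vector(rec, spec)
            expected = [1.0 if t in truth.planted_go[rec.id] else 0.0 for t in spec.terms]
            np.testing.assert_array_equal(vec, expected)

    def test_similarity_fallback_inherits_neighbor_terms(self, small_proteome):
        dataset, truth = small_proteome
        donor = dataset.records[0]
        source = GOAnnotationSource(
            annotations={donor.id: frozenset(donor.go_terms)},
            reference=Dataset([donor]),
        )
        orphan = ProteinRecord("orphan", donor.sequence)
        terms, via_sim = source.terms_for(orphan)
        assert via_sim and terms == frozenset(donor.go_terms)

    def test_malformed_go_id_rejected(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("p1\tGO:123\n")
        with pytest.raises(ValueError, match="malformed"):
            read_go_annotations(p)

    def test_read_go_groups_terms_by_protein(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("p1\tGO:0000001\np1\tGO:0000002\np2\tGO:0000003\n")
        ann = read_go_annotations(p)
        assert ann["p1"] == frozenset({"GO:0000001", "GO:0000002"})
        assert ann["p2"] == frozenset({"GO:0000003"})


class TestRegularMrmr:
    def _random_instance(self, rng, n=60, n_terms=8):
        labels = [
            frozenset({Location(int(rng.integers(0, 6)))}) for _ in range(n)
        ]
        Y = _label_matrix(labels)
        X = rng.random((n, n_terms)) < 0.5
        term_ids = [f"GO:{j + 1:07d}" for j in range(n_terms)]
        return X, term_ids, labels, Y

    def test_perfect_indicator_selected_first(self, rng):
        n = 80
        labels = [
            frozenset({Location.NUCLEUS if i % 2 else Location.CYTOPLASM})
            for i in range(n)
        ]
        X = rng.random((n, 6)) < 0.5
        X[:, 3] = [Location.NUCLEUS in s for s in labels]  # perfect indicator
        term_ids = [f"GO:{j + 1:07d}" for j in range(6)]
        spec = regular_mrmr(X, term_ids, labels, k=3)
        assert spec.terms[0] == "GO:0000004"

    def test_duplicate_column_deprioritized(self):
        # t0 strong, t1 == t0 (duplicate), t2 weak but independent
        n = 40
        labels = [
            frozenset({Location.NUCLEUS if i < 20 else Location.CYTOPLASM})
            for i in range(n)
        ]
        strong = np.array([i < 20 for i in range(n)])
        weak = np.array([(i % 4) == 0 if i < 20 else (i % 4) != 0 for i in range(n)])
        X = np.column_stack([strong, strong.copy(), weak])
        spec = regular_mrmr(X, ["GO:0000001", "GO:0000002", "GO:0000003"], labels, k=2)
        assert spec.terms[0] == "GO:0000001"  # tie with duplicate: lexicographic
        assert spec.terms[1] == "GO:0000003"  # duplicate penalized below weak term

    def test_matches_bruteforce_greedy_oracle(self, rng):
        for _ in range(20):
            X, term_ids, labels, Y = self._random_instance(rng)
            k = int(rng.integers(1, 5))
            spec = regular_mrmr(X, term_ids, labels, k=k)
            assert list(spec.terms) == _oracle_greedy_mrmr(X, term_ids, Y, k)

    def test_row_permutation_invariance(self, rng):
        X, term_ids, labels, _ = self._random_instance(rng)
        spec = regular_mrmr(X, term_ids, labels, k=4)
        perm = rng.permutation(len(X))
        spec_p = regular_mrmr(X[perm], term_ids, [labels[i] for i in perm], k=4)
        assert spec.terms == spec_p.terms

    def test_constant_columns_skipped(self, rng):
        X, term_ids, labels, _ = self._random_instance(rng)
        X[:, 0] = True
        spec = regular_mrmr(X, term_ids, labels, k=7)
        assert term_ids[0] not in spec.terms

    def test_k_too_large_rejected(self, rng):
        X, term_ids, labels, _ = self._random_instance(rng)
        with pytest.raises(ValueError, match="exceeds"):
            regular_mrmr(X, term_ids, labels, k=100)


class TestSelectK:
    def test_singleton_grid(self, rng):
        X, term_ids, labels, _ = TestRegularMrmr()._random_instance(rng)
        assert select_k_by_cv(X, term_ids, labels, [4]) == 4

    def test_recovers_informative_term_count(self):
        # signal concentrated in 5 terms: one near-perfect indicator for each
        # of 5 locations; remaining terms are noise
        rng = np.random.default_rng(7)
        n = 240
        labels = [frozenset({Location(int(rng.integers(0, 5)))}) for _ in range(n)]
        X = rng.random((n, 12)) < 0.3
        for l in range(5):
            member = np.array([Location(l) in s for s in labels])
            flip = rng.random(n) < 0.05
            X[:, l] = member ^ flip
        term_ids = [f"GO:{j + 1:07d}" for j in range(12)]
        best = select_k_by_cv(X, term_ids, labels, [3, 5, 10], seed=7)
        assert best == 5
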