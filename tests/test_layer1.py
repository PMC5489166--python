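import numpy as np
import pytest

from protloc.data_model import Dataset, Location, ProteinRecord
from protloc.layer1_svm import (
    DEFAULT_MODELS_PER_LOCATION,
    choose_ratio_and_m,
    plan_all_locations,
    plan_partitions,
    predict_layer1,
    train_layer1,
)


def _dataset(n, rng, n_locations=6):
    """Labeled dataset with separable one-hot-ish features per location."""
    records, features = [], {}
    for i in range(n):
        loc = Location(int(rng.integers(0, n_locations)))
        pid = f"p{i:03d}"
        records.append(ProteinRecord(pid, "M" * 80, frozenset({loc})))
        vec = rng.normal(scale=0.3, size=8)
        vec[int(loc)] += 4.0
        features[pid] = vec
    return Dataset(records), features


class TestPlanPartitions:
    def _balanced(self, n_pos, n_neg):
        records = [
            ProteinRecord(f"pos{i}", "M" * 80, frozenset({Location.NUCLEUS}))
            for i in range(n_pos)
        ] + [
            ProteinRecord(f"neg{i}", "K" * 80, frozenset({Location.CYTOPLASM}))
            for i in range(n_neg)
        ]
        return Dataset(records)

    def test_even_split_100_negatives(self):
        specs = plan_partitions(self._balanced(10, 100), Location.NUCLEUS, m=5)
        assert [len(s.negative_ids) for s in specs] == [20] * 5

    def test_remainder_rule_101_negatives(self):
        specs = plan_partitions(self._balanced(10, 101), Location.NUCLEUS, m=5)
        sizes = [len(s.negative_ids) for s in specs]
        assert sorted(sizes, reverse=True) == [21, 20, 20, 20, 20]
        union = set().union(*(s.negative_ids for s in specs))
        assert len(union) == 101

    def test_negative_union_equals_complement_oracle(self, rng):
        locs = list(Location)
        records = [
            ProteinRecord(
                f"p{i}", "M" * 80,
                frozenset(rng.choice(locs, size=int(rng.integers(1, 3)), replace=False).tolist()),
            )
            for i in range(60)
        ]
        ds = Dataset(records)
        for loc in (Location.NUCLEUS, Location.ER_GOLGI):
            specs = plan_partitions(ds, loc, m=3, seed=4)
            seen = [nid for s in specs for nid in s.negative_ids]
            oracle = {r.id for r in records if loc not in r.locations}
            assert len(seen) == len(set(seen))  # each negative exactly once
            assert set(seen) == oracle
            for s in specs:
                assert set(s.positive_ids) == {r.id for r in records if loc in r.locations}

    def test_even_m_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            plan_partitions(self._balanced(5, 50), Location.NUCLEUS, m=4)

    def test_too_few_negatives_rejected(self):
        with pytest.raises(ValueError, match="negatives"):
            plan_partitions(self._balanced(5, 2), Location.NUCLEUS, m=3)

    def test_default_plan_totals_32(self, rng):
        ds, _ = _dataset(120, rng)
        plan = plan_all_locations(ds)
        assert plan.total_models == 32
        for loc, m in DEFAULT_MODELS_PER_LOCATION.items():
            assert plan.m(loc) == m and m % 2 == 1 and 3 <= m <= 9


class TestTrainPredict:
    def test_separable_submodels_fit_training_data(self, rng):
        ds, feats = _dataset(150, rng)
        plan = plan_all_locations(ds, seed=1)
        ens = train_layer1(ds, feats, plan, seed=1)
        for spec, clf in zip(plan.specs, ens.classifiers):
            ids = list(spec.positive_ids) + list(spec.negative_ids)
            X = np.array([feats[i] for i in ids])
            y = np.array([1] * len(spec.positive_ids) + [-1] * len(spec.negative_ids))
            assert clf.score(X, y) >= 0.95

    def test_deterministic_given_seed(self, rng):
        ds, feats = _dataset(80, rng)
        plan = plan_all_locations(ds, seed=2)
        ids = [r.id for r in ds.records]
        out1 = predict_layer1(train_layer1(ds, feats, plan, seed=3), ids, feats)
        out2 = predict_layer1(train_layer1(ds, feats, plan, seed=3), ids, feats)
        np.testing.assert_array_equal(out1.decision_values, out2.decision_values)

    def test_own_location_submodels_vote_positive(self, rng):
        ds, feats = _dataset(150, rng)
        plan = plan_all_locations(ds, seed=1)
        ens = train_layer1(ds, feats, plan, seed=1)
        out = predict_layer1(ens, [r.id for r in ds.records], feats)
        correct = 0
        for i, rec in enumerate(ds.records):
            loc = next(iter(rec.locations))
            cols = plan.location_columns(loc)
            correct += out.votes[i, cols].mean() > 0.5
        assert correct / len(ds) >= 0.9

    def test_vote_is_sign_of_decision_value(self, rng):
        ds, feats = _dataset(60, rng)
        plan = plan_all_locations(ds, seed=0)
        out = predict_layer1(
            train_layer1(ds, feats, plan, seed=0), [r.id for r in ds.records], feats
        )
        np.testing.assert_array_equal(out.votes, (out.decision_values > 0).astype(float))

    def test_output_ordering_stable_across_save_load(self, rng, tmp_path):
        from protloc.data_model import load_model, save_model

        ds, feats = _dataset(60, rng)
        plan = plan_all_locations(ds, seed=0)
        ens = train_layer1(ds, feats, plan, seed=0)
        ids = [r.id for r in ds.records]
        before = predict_layer1(ens, ids, feats)
        save_model(ens, tmp_path / "l1.bundle")
        after = predict_layer1(load_model(tmp_path / "l1.bundle"), ids, feats)
        np.testing.assert_array_equal(before.decision_values, after.decision_values)

    def test_feature_dimension_mismatch_rejected(self, rng):
        ds, feats = _dataset(60, rng)
        plan = plan_all_locations(ds, seed=0)
        ens = train_layer1(ds, feats, plan, seed=0)
        bad = {pid: np.zeros(3) for pid in feats}
        with pytest.raises(ValueError, match="dimension"):
            predict_layer1(ens, [r.id for r in ds.records], bad)

    def test_empty_positive_set_rejected(self, rng):
        ds, feats = _dataset(60, rng)
        plan = plan_all_locations(ds, seed=0)
        plan.specs[0] = type(plan.specs[0])(
            location=plan.specs[0].location,
            model_index=1,
            positive_ids=(),
            negative_ids=plan.specs[0].negative_ids,
        )
        with pytest.raises(ValueError, match="positive"):
            train_layer1(ds, feats, plan, seed=0)


class TestChooseRatioAndM:
    def test_singleton_grids_returned_unchanged(self, rng):
        ds, feats = _dataset(60, rng)
        assert choose_ratio_and_m(ds, feats, Location.NUCLEUS, [2.0], [3]) == (2.0, 3)

    def test_tie_breaks_to_smallest_m_then_ratio(self, rng):
        # perfectly separable features: every grid point scores 1.0
        ds, feats = _dataset(120, rng)
        ratio, m = choose_ratio_and_m(
            ds, feats, Location.NUCLEUS, [1.0, 2.0], [3, 5], seed=5
        )
        assert (ratio, m) == (1.0, 3)

    def test_balanced_ratio_helps_on_imbalanced_data(self):
        # 1:10 imbalance with noisy features: some capped ratio should do at
        # least as well as training on the full imbalance
        rng = np.random.default_rng(11)
        records, feats = [], {}
        for i in range(220):
            is_pos = i < 20
            pid = f"p{i}"
            loc = Location.MITOCHONDRION if is_pos else Location.CYTOPLASM
            records.append(ProteinRecord(pid, "M" * 80, frozenset({loc})))
            vec = rng.normal(scale=1.0, size=6)
            if is_pos:
                vec[3] += 1.5
            feats[pid] = vec
        ds = Dataset(records)
        ratio, m = choose_ratio_and_m(
            ds, feats, Location.MITOCHONDRION, [1.0, 100.0], [3], seed=11
        )
        assert m == 3 and ratio == 1.0
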