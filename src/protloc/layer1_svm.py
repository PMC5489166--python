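"""First learning layer: per-location binary SVM sub-models.

Class imbalance between a location's members (positives) and everything
else (negatives) is handled by *full-negative-coverage partitioning*: each
location trains an odd number m of sub-models (3-9) that share all
positives while the negatives are shuffled and split into m disjoint,
near-equal chunks.  Every negative therefore informs exactly one sub-model
— no information is discarded — while each sub-model sees a much more
balanced class ratio.  The default per-location model counts sum to 32.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .data_model import Dataset, Location

__all__ = [
    "DEFAULT_MODELS_PER_LOCATION",
    "SubModelSpec",
    "PartitionPlan",
    "plan_partitions",
    "plan_all_locations",
    "choose_ratio_and_m",
    "Layer1Ensemble",
    "Layer1Output",
    "train_layer1",
    "predict_layer1",
]

logger = logging.getLogger(__name__)

#: Default odd sub-model counts per location, summing to 32.
DEFAULT_MODELS_PER_LOCATION: dict[Location, int] = {
    Location.CELL_MEMBRANE: 5,
    Location.CYTOPLASM: 5,
    Location.ER_GOLGI: 5,
    Location.MITOCHONDRION: 5,
    Location.NUCLEUS: 7,
    Location.EXTRACELLULAR: 5,
}


@dataclasses.dataclass
class SubModelSpec:
    """Bookkeeping for one binary sub-model of a location's group."""

    location: Location
    model_index: int  # 1-based within the location
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]

    @property
    def realized_ratio(self) -> float:
        """Negatives per positive actually seen by this sub-model."""
        return len(self.negative_ids) / max(len(self.positive_ids), 1)


@dataclasses.dataclass
class PartitionPlan:
    """All sub-model specs, grouped per location in fixed order."""

    specs: list[SubModelSpec]

    def for_location(self, location: Location) -> list[SubModelSpec]:
        return [s for s in self.specs if s.location == location]

    def m(self, location: Location) -> int:
        return len(self.for_location(location))

    @property
    def total_models(self) -> int:
        return len(self.specs)

    def column_index(self, location: Location, model_index: int) -> int:
        for i, s in enumerate(self.specs):
            if s.location == location and s.model_index == model_index:
                return i
        raise KeyError((location, model_index))

    def location_columns(self, location: Location) -> list[int]:
        return [i for i, s in enumerate(self.specs) if s.location == location]


def plan_partitions(
    dataset: Dataset,
    location: Location,
    ratio: float = 1.0,
    m: int = 5,
    seed: int = 0,
) -> list[SubModelSpec]:
    """Partition a location's negatives into m disjoint chunks.

    All m sub-models share the full positive set; negatives are shuffled by
    *seed* and split into near-equal chunks (remainder spread over the first
    chunks), so each negative is used exactly once.  *ratio* is the target
    negatives-per-positive ratio and is advisory: the chunk size determined
    by m wins, and the realized ratio is logged per sub-model.
    """
    if m % 2 == 0:
        raise ValueError(f"m must be odd; got {m}")
    if not 3 <= m <= 9:
        raise ValueError(f"m must lie in [3, 9]; got {m}")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos_ids = tuple(r.id for r in dataset.positives(location))
    neg_ids = [r.id for r in dataset.negatives(location)]
    if not pos_ids:
        raise ValueError(f"no positive proteins for {location.label}")
    if len(neg_ids) < m:
        raise ValueError(
            f"{location.label}: {len(neg_ids)} negatives cannot fill {m} sub-models"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(neg_ids))
    shuffled = [neg_ids[i] for i in order]
    chunks = [list(c) for c in np.array_split(shuffled, m)]
    specs = []
    for i, chunk in enumerate(chunks, start=1):
        spec = SubModelSpec(
            location=location,
            model_index=i,
            positive_ids=pos_ids,
            negative_ids=tuple(chunk),
        )
        logger.debug(
            "%s sub-model %d: %d pos, %d neg (target N/P ratio %.2f, realized %.2f)",
            location.label, i, len(pos_ids), len(chunk), ratio, spec.realized_ratio,
        )
        specs.append(spec)
    return specs


def plan_all_locations(
    dataset: Dataset,
    models_per_location: Mapping[Location, int] | None = None,
    ratios: Mapping[Location, float] | None = None,
    seed: int = 0,
) -> PartitionPlan:
    """Build the full plan over all six locations in fixed code order."""
    mpl = dict(models_per_location or DEFAULT_MODELS_PER_LOCATION)
    specs: list[SubModelSpec] = []
    for loc in Location:
        ratio = (ratios or {}).get(loc, 1.0)
        specs.extend(
            plan_partitions(dataset, loc, ratio=ratio, m=mpl[loc], seed=seed + int(loc))
        )
    return PartitionPlan(specs)


@dataclasses.dataclass
class Layer1Ensemble:
    """Trained binary classifiers + their partition specs + feature dimension."""

    plan: PartitionPlan
    classifiers: list[SVC]
    n_features: int
    svm_params: dict

    @property
    def total_models(self) -> int:
        return self.plan.total_models


@dataclasses.dataclass
class Layer1Output:
    """Per-protein sub-model outputs in fixed (location, model_index) order."""

    ids: list[str]
    decision_values: np.ndarray  # (n_proteins, total_models) signed margins
    votes: np.ndarray  # (n_proteins, total_models) in {0,1}


def train_layer1(
    dataset: Dataset,
    features: Mapping[str, np.ndarray],
    plan: PartitionPlan,
    svm_params: dict | None = None,
    seed: int = 0,
) -> Layer1Ensemble:
    """Fit one binary SVM per sub-model spec (positives labeled +1).

    *features* maps protein id -> feature vector; all vectors must share one
    dimension.  Training is deterministic given the plan, data and params.
    """
    params = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
    params.update(svm_params or {})
    dims = {len(v) for v in features.values()}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
    n_features = dims.pop()
    classifiers: list[SVC] = []
    for spec in plan.specs:
        if not spec.positive_ids:
            raise ValueError(
                f"sub-model {spec.location.label}#{spec.model_index}: empty positive set"
            )
        X = np.array(
            [features[i] for i in spec.positive_ids]
            + [features[i] for i in spec.negative_ids]
        )
        y = np.array([1] * len(spec.positive_ids) + [-1] * len(spec.negative_ids))
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"sub-model {spec.location.label}#{spec.model_index}: "
                "single-class training set"
            )
        clf = SVC(random_state=seed, **params)
        clf.fit(X, y)
        classifiers.append(clf)
    return Layer1Ensemble(
        plan=plan, classifiers=classifiers, n_features=n_features, svm_params=params
    )


def predict_layer1(
    ensemble: Layer1Ensemble, ids: Sequence[str], features: Mapping[str, np.ndarray]
) -> Layer1Output:
    """Run every sub-model on every protein; keep margins and hard votes."""
    X = np.array([features[i] for i in ids])
    if X.ndim != 2 or X.shape[1] != ensemble.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} != "
            f"ensemble dimension {ensemble.n_features}"
        )
    dec = np.column_stack([clf.decision_function(X) for clf in ensemble.classifiers])
    votes = (dec > 0).astype(float)
    return Layer1Output(ids=list(ids), decision_values=dec, votes=votes)


def choose_ratio_and_m(
    dataset: Dataset,
    features: Mapping[str, np.ndarray],
    location: Location,
    ratio_grid: Sequence[float],
    m_grid: Sequence[int],
    folds: int = 3,
    svm_params: dict | None = None,
    seed: int = 0,
) -> tuple[float, int]:
    """Grid-search the (N/P ratio, sub-model count) for one location.

    Scores each candidate by cross-validated *balanced* membership accuracy
    of the location's majority-voted sub-ensemble (mean of member recall and
    non-member recall, so the majority class cannot dominate the sweep).
    Ties break toward smaller m, then smaller ratio.  Here *ratio* caps how
    many negatives each chunk keeps (chunks larger than ratio * n_positives
    are subsampled for the sweep only — the final plan always keeps full
    negative coverage).
    """
    if not len(ratio_grid) or not len(m_grid):
        raise ValueError("ratio_grid and m_grid must be non-empty")
    if any(m % 2 == 0 for m in m_grid):
        raise ValueError("m_grid must contain odd values only")
    if len(ratio_grid) == 1 and len(m_grid) == 1:
        return float(ratio_grid[0]), int(m_grid[0])

    ids = [r.id for r in dataset.records]
    y = np.array([1 if location in r.locations else 0 for r in dataset.records])
    rng = np.random.default_rng(seed)
    results: dict[tuple[float, int], float] = {}
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for m in sorted(m_grid):
        for ratio in sorted(ratio_grid):
            y_true: list[bool] = []
            y_pred: list[bool] = []
            failed = False
            for train_idx, test_idx in kf.split(ids):
                train_ds = Dataset([dataset.records[i] for i in train_idx])
                try:
                    specs = plan_partitions(
                        train_ds, location, ratio=ratio, m=m, seed=seed
                    )
                except ValueError:
                    failed = True
                    break
                # subsample each chunk to the target ratio for the sweep
                capped = []
                for spec in specs:
                    cap = max(1, int(round(ratio * len(spec.positive_ids))))
                    negs = list(spec.negative_ids)
                    if len(negs) > cap:
                        keep = rng.choice(len(negs), size=cap, replace=False)
                        negs = [negs[i] for i in sorted(keep)]
                    capped.append(
                        dataclasses.replace(spec, negative_ids=tuple(negs))
                    )
                ens = train_layer1(
                    train_ds, features, PartitionPlan(capped),
                    svm_params=svm_params, seed=seed,
                )
                test_ids = [ids[i] for i in test_idx]
                out = predict_layer1(ens, test_ids, features)
                member = out.votes.sum(axis=1) > m / 2
                y_true.extend(y[test_idx].astype(bool))
                y_pred.extend(member)
            if failed:
                results[(ratio, m)] = -1.0
                continue
            yt = np.array(y_true)
            yp = np.array(y_pred)
            recalls = []
            for cls in (True, False):
                mask = yt == cls
                if mask.any():
                    recalls.append(np.mean(yp[mask] == cls))
            results[(ratio, m)] = float(np.mean(recalls))
    best = min(results, key=lambda rm: (-results[rm], rm[1], rm[0]))
    return float(best[0]), int(best[1])
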