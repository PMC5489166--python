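"""End-to-end pipeline: feature assembly, two-layer training, prediction.

Feature vectors concatenate, in fixed order: the sequence block (region
AAC + weighted sign aa index + PC-PseAAC, 908 values), optionally the
sequence-similarity-profile block (another 908), optionally the
surface-accessibility block (12), and optionally the selected GO-term
block (k values, default 35).  The block map records every span so any
slice can be traced back to its encoder.

Training: layer-1 sub-model SVMs are fit on the partition plan; the GANN
combiner is fit on *out-of-fold* layer-1 decision values produced by an
inner split of the training set (sub-models must never score a protein
they were trained on when building layer-2 training rows).  Layer 1 is
then refit on the full training set for deployment.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .data_model import Dataset, Location, ProteinRecord
from .evaluation import iterative_stratified_folds
from .features_go import (
    GOAnnotationSource,
    GOFeatureSpec,
    go_vector,
    regular_mrmr,
)
from .features_profile import (
    SA_BLOCK_WIDTH,
    AlignmentBackend,
    SimilarityBackend,
    aggregate_sa,
    compute_ssp,
)
from .features_sequence import (
    SEQUENCE_BLOCK_WIDTH,
    AAIndexTable,
    BlockMap,
    default_aaindex_table,
    sequence_feature_block,
)
from .layer1_svm import (
    DEFAULT_MODELS_PER_LOCATION,
    Layer1Ensemble,
    PartitionPlan,
    plan_all_locations,
    predict_layer1,
    train_layer1,
)
from .layer2_combiners import (
    GannConfig,
    GannModel,
    PredictionSet,
    gann_predict,
    gann_train,
    vote_predict,
)

__all__ = [
    "PipelineConfig",
    "FeatureExtractor",
    "TrainedModel",
    "train_model",
    "write_feature_matrix",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to train the predictor reproducibly."""

    use_ssp: bool = True
    use_sa: bool = True
    use_go: bool = True
    go_k: int = 35
    go_rank_depth: int = 50
    pseaac_lambda: int = 8
    pseaac_omega: float = 0.05
    ssp_min_score: float = 50.0
    models_per_location: dict[Location, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MODELS_PER_LOCATION)
    )
    ratios: dict[Location, float] = dataclasses.field(default_factory=dict)
    svm_params: dict = dataclasses.field(default_factory=dict)
    gann: GannConfig = dataclasses.field(default_factory=GannConfig)


class FeatureExtractor:
    """Learns (on training data) and applies the full feature layout."""

    def __init__(self, config: PipelineConfig, table: AAIndexTable | None = None):
        self.config = config
        self.table = table or default_aaindex_table()
        self.go_spec: GOFeatureSpec | None = None
        self.go_source: GOAnnotationSource | None = None
        self.reference: Dataset | None = None
        self.ssp_backend: SimilarityBackend | None = None
        # query blocks keyed by (id, sequence digest): distinct datasets may
        # reuse ids, so the id alone must never address a cached block
        self._block_cache: dict[tuple[str, str], np.ndarray] = {}
        # reference blocks keyed by plain id (the reference set is fixed)
        self._ref_block_cache: dict[str, np.ndarray] = {}
        self.block_map: BlockMap | None = None

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        dataset: Dataset,
        go_annotations: Mapping[str, frozenset[str]] | None = None,
    ) -> "FeatureExtractor":
        cfg = self.config
        self.reference = dataset
        if cfg.use_ssp:
            self.ssp_backend = AlignmentBackend(min_score=cfg.ssp_min_score)
        if cfg.use_go:
            annotations = dict(go_annotations or {})
            for r in dataset.records:
                if r.id not in annotations and r.go_terms:
                    annotations[r.id] = frozenset(r.go_terms)
            self.go_source = GOAnnotationSource(
                annotations=annotations,
                reference=dataset,
                backend=self.ssp_backend or AlignmentBackend(min_score=cfg.ssp_min_score),
            )
            self.go_spec = self._select_go_terms(dataset, annotations)
        self.block_map = self._build_block_map()
        return self

    def _select_go_terms(
        self, dataset: Dataset, annotations: Mapping[str, frozenset[str]]
    ) -> GOFeatureSpec:
        terms = sorted({t for ts in annotations.values() for t in ts})
        if not terms:
            raise ValueError("GO features enabled but no annotations available")
        X = np.zeros((len(dataset), len(terms)), dtype=bool)
        term_idx = {t: j for j, t in enumerate(terms)}
        for i, r in enumerate(dataset.records):
            for t in annotations.get(r.id, ()):  # direct annotations only
                X[i, term_idx[t]] = True
        labels = [r.locations for r in dataset.records]
        usable = int(np.sum((X.sum(axis=0) > 0) & (X.sum(axis=0) < len(dataset))))
        depth = min(self.config.go_rank_depth, usable)
        k = min(self.config.go_k, depth)
        if k < self.config.go_k:
            logger.info("GO selection: only %d usable terms; k reduced to %d", usable, k)
        ranked = regular_mrmr(X, terms, labels, k=depth)
        return GOFeatureSpec(terms=ranked.terms[:k], scores=ranked.scores[:k])

    def _build_block_map(self) -> BlockMap:
        bm = BlockMap()
        bm.add("sequence", SEQUENCE_BLOCK_WIDTH)
        if self.config.use_ssp:
            bm.add("ssp", SEQUENCE_BLOCK_WIDTH)
        if self.config.use_sa:
            bm.add("sa", SA_BLOCK_WIDTH)
        if self.config.use_go and self.go_spec is not None:
            bm.add("go", len(self.go_spec))
        return bm

    # -- applying ---------------------------------------------------------

    def sequence_block(self, record: ProteinRecord) -> np.ndarray:
        import hashlib

        key = (record.id, hashlib.md5(record.sequence.encode()).hexdigest())
        if key not in self._block_cache:
            self._block_cache[key] = sequence_feature_block(
                record.sequence,
                self.table,
                lam=self.config.pseaac_lambda,
                omega=self.config.pseaac_omega,
            )
        return self._block_cache[key]

    def transform(
        self, records: Sequence[ProteinRecord], training: bool = False
    ) -> dict[str, np.ndarray]:
        """Assemble the full feature vector for every record.

        ``training=True`` enforces leave-self-out in the SSP and GO
        similarity fallbacks, so no training protein matches its own entry.
        """
        if self.block_map is None:
            raise RuntimeError("FeatureExtractor.fit must run before transform")
        cfg = self.config
        out: dict[str, np.ndarray] = {}
        for record in records:
            parts = [self.sequence_block(record)]
            if cfg.use_ssp:
                ssp = compute_ssp(
                    record,
                    self.reference,
                    self.table,
                    backend=self.ssp_backend,
                    exclude_self=training,
                    block_cache=self._ref_block_cache,
                    query_block=parts[0],
                )
                parts.append(ssp.block)
            if cfg.use_sa:
                sa_vec, _missing = aggregate_sa(record)
                parts.append(sa_vec)
            if cfg.use_go and self.go_spec is not None:
                vec, _flag = go_vector(
                    record, self.go_spec, self.go_source, exclude_self=training
                )
                parts.append(vec)
            vec = np.concatenate(parts)
            assert len(vec) == self.block_map.total_width
            out[record.id] = vec
        return out

    def metadata(self) -> dict:
        """Bundle-level provenance: layout, GO terms, reference fingerprint."""
        import hashlib

        ref_ids = sorted(r.id for r in self.reference.records) if self.reference else []
        fingerprint = hashlib.sha256("\n".join(ref_ids).encode()).hexdigest()[:16]
        return {
            "block_map": self.block_map.to_dict() if self.block_map else None,
            "go_terms": list(self.go_spec.terms) if self.go_spec else None,
            "aaindex_ids": self.table.ids,
            "reference_fingerprint": fingerprint,
        }


@dataclasses.dataclass
class TrainedModel:
    """A trained two-layer predictor (the object save_model serializes)."""

    extractor: FeatureExtractor
    plan: PartitionPlan
    ensemble: Layer1Ensemble
    gann: GannModel | None
    config: PipelineConfig
    seed: int
    layer2_provenance: dict[str, frozenset[str]]

    def predict(
        self, records: Sequence[ProteinRecord]
    ) -> dict[str, list[PredictionSet]]:
        """Per-combiner predictions: keys ``vote``, ``gann`` (if trained), ``default``.

        The ``default`` rule follows the recommendation to trust the network
        for singleplex-looking queries and the vote for multiplex ones: it
        takes the GANN set when GANN predicts exactly one location, else the
        Vote set.
        """
        feats = self.extractor.transform(records, training=False)
        ids = [r.id for r in records]
        out1 = predict_layer1(self.ensemble, ids, feats)
        results: dict[str, list[PredictionSet]] = {"vote": [], "default": []}
        if self.gann is not None:
            results["gann"] = []
        for i, pid in enumerate(ids):
            vote_ps = vote_predict(out1.votes[i], self.plan, protein_id=pid)
            results["vote"].append(vote_ps)
            if self.gann is not None:
                gann_ps = gann_predict(self.gann, out1.decision_values[i], protein_id=pid)
                results["gann"].append(gann_ps)
                chosen = gann_ps if len(gann_ps.locations) == 1 else vote_ps
            else:
                chosen = vote_ps
            results["default"].append(
                PredictionSet(id=pid, locations=chosen.locations, scores=chosen.scores)
            )
        return results

    def metadata(self) -> dict:
        meta = self.extractor.metadata()
        meta.update(
            {
                "seed": self.seed,
                "total_sub_models": self.plan.total_models,
                "models_per_location": {
                    loc.label: self.plan.m(loc) for loc in Location
                },
            }
        )
        return meta


def train_model(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    inner_folds: int = 5,
    go_annotations: Mapping[str, frozenset[str]] | None = None,
    train_gann: bool = True,
    extractor: FeatureExtractor | None = None,
) -> TrainedModel:
    """Train the full two-layer predictor on a labeled dataset.

    The GANN combiner's training matrix is assembled from out-of-fold
    layer-1 decision values: the training set is split into *inner_folds*
    stratified folds, layer 1 is trained on each fold complement and scores
    the held-out fold.  ``layer2_provenance`` records, per protein, the ids
    the producing sub-models saw, which lets callers audit the no-leakage
    guarantee.  Layer 1 is finally refit on the complete training set.
    """
    config = config or PipelineConfig()
    unlabeled = [r.id for r in dataset.records if not r.locations]
    if unlabeled:
        raise ValueError(f"training records without locations: {unlabeled[:5]}")

    if extractor is None:
        extractor = FeatureExtractor(config).fit(dataset, go_annotations)
    feats = extractor.transform(dataset.records, training=True)
    plan = plan_all_locations(
        dataset, config.models_per_location, config.ratios, seed=seed
    )

    gann_model: GannModel | None = None
    provenance: dict[str, frozenset[str]] = {}
    if train_gann:
        n_cols = plan.total_models
        oof = np.zeros((len(dataset), n_cols))
        filled = np.zeros(len(dataset), dtype=bool)
        folds = iterative_stratified_folds(dataset, inner_folds, seed=seed + 1)
        for fold_idx in folds:
            hold = set(fold_idx)
            inner_train = Dataset(
                [r for i, r in enumerate(dataset.records) if i not in hold]
            )
            inner_plan = plan_all_locations(
                inner_train, config.models_per_location, config.ratios, seed=seed
            )
            inner_ens = train_layer1(
                inner_train, feats, inner_plan, svm_params=config.svm_params, seed=seed
            )
            hold_ids = [dataset.records[i].id for i in fold_idx]
            out = predict_layer1(inner_ens, hold_ids, feats)
            seen = frozenset(r.id for r in inner_train.records)
            for row, i in enumerate(fold_idx):
                oof[i] = out.decision_values[row]
                filled[i] = True
                provenance[dataset.records[i].id] = seen
        assert filled.all(), "inner folds did not cover every training protein"
        labels = [r.locations for r in dataset.records]
        gcfg = dataclasses.replace(config.gann, seed=seed)
        gann_model = gann_train(oof, labels, gcfg)
        logger.info(
            "GANN trained: best MSE %.4f after %d generations",
            gann_model.history[-1], len(gann_model.history) - 1,
        )

    ensemble = train_layer1(
        dataset, feats, plan, svm_params=config.svm_params, seed=seed
    )
    return TrainedModel(
        extractor=extractor,
        plan=plan,
        ensemble=ensemble,
        gann=gann_model,
        config=config,
        seed=seed,
        layer2_provenance=provenance,
    )


def write_feature_matrix(
    features: Mapping[str, np.ndarray],
    block_map: BlockMap,
    path,
) -> None:
    """Export an assembled feature matrix as TSV.

    The header comment records the block map (name and [start, end) span)
    so a consumer can recover which columns belong to which encoder.
    """
    spans = ";".join(f"{name}=[{lo},{hi})" for name, (lo, hi) in block_map.items())
    with open(path, "w") as fh:
        fh.write(f"# block_map: {spans}\n")
        fh.write("id\t" + "\t".join(f"f{j}" for j in range(block_map.total_width)) + "\n")
        for pid, vec in features.items():
            fh.write(pid + "\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")
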