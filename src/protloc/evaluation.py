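"""Evaluation: absolute true success rate and the nested CV protocol.

The headline metric is the *absolute true success rate* (ATSR): a protein
scores 1 only when its predicted location set equals its true set exactly
— any over- or under-prediction scores 0 — and the rate is the mean score.
Per-location rates restrict to proteins whose true set contains the
location; singleplex/multiplex rates split proteins by whether they have
one or several true locations.

Cross-validation of a two-layer model needs care: the second layer must
not be trained on first-layer outputs produced by sub-models that saw the
same protein.  ``nested_cv`` therefore builds the layer-2 training matrix
from out-of-fold layer-1 outputs via an inner split of the outer training
fold, and audits that constraint explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import Dataset, Location
from .layer2_combiners import PredictionSet

__all__ = [
    "EvalReport",
    "atsr",
    "per_location_atsr",
    "plex_breakdown",
    "iterative_stratified_folds",
    "nested_cv",
    "LeakageError",
]


def atsr(
    predictions: Sequence[PredictionSet],
    truths: Mapping[str, frozenset[Location]],
) -> float:
    """Exact-set-match success rate over the predictions."""
    if not predictions:
        raise ValueError("no predictions to evaluate")
    correct = 0
    for p in predictions:
        if p.id not in truths:
            raise KeyError(f"no truth for predicted protein {p.id!r}")
        correct += int(p.locations == truths[p.id])
    return correct / len(predictions)


def per_location_atsr(
    predictions: Sequence[PredictionSet],
    truths: Mapping[str, frozenset[Location]],
) -> dict[Location, tuple[float, int, int]]:
    """Location -> (rate, correct, total) over proteins whose true set contains it.

    A protein still needs its *entire* set right to count as correct, so a
    multiplex protein predicted half-right fails under every location row it
    belongs to.  Locations with no member proteins are absent from the map.
    """
    out: dict[Location, tuple[float, int, int]] = {}
    for loc in Location:
        members = [p for p in predictions if loc in truths[p.id]]
        if not members:
            continue
        correct = sum(int(p.locations == truths[p.id]) for p in members)
        out[loc] = (correct / len(members), correct, len(members))
    return out


def plex_breakdown(
    predictions: Sequence[PredictionSet],
    truths: Mapping[str, frozenset[Location]],
) -> tuple[tuple[float, int, int], tuple[float, int, int]]:
    """((singleplex rate, correct, total), (multiplex rate, correct, total)).

    Partition by true set size (1 vs >= 2); an empty partition reports
    (0.0, 0, 0).  Singleplex correct + multiplex correct = overall correct.
    """
    results = []
    for selector in (lambda s: len(s) == 1, lambda s: len(s) >= 2):
        part = [p for p in predictions if selector(truths[p.id])]
        correct = sum(int(p.locations == truths[p.id]) for p in part)
        rate = correct / len(part) if part else 0.0
        results.append((rate, correct, len(part)))
    return results[0], results[1]


@dataclasses.dataclass
class EvalReport:
    """Overall / per-location / plex-stratified exact-set-match rates."""

    overall: float
    correct: int
    total: int
    per_location: dict[Location, tuple[float, int, int]]
    singleplex: tuple[float, int, int]
    multiplex: tuple[float, int, int]

    @classmethod
    def from_predictions(
        cls,
        predictions: Sequence[PredictionSet],
        truths: Mapping[str, frozenset[Location]],
    ) -> "EvalReport":
        overall = atsr(predictions, truths)
        correct = round(overall * len(predictions))
        single, multi = plex_breakdown(predictions, truths)
        return cls(
            overall=overall,
            correct=correct,
            total=len(predictions),
            per_location=per_location_atsr(predictions, truths),
            singleplex=single,
            multiplex=multi,
        )

    def to_dict(self) -> dict:
        return {
            "overall": {"rate": self.overall, "correct": self.correct, "total": self.total},
            "per_location": {
                loc.label: {"rate": r, "correct": c, "total": t}
                for loc, (r, c, t) in self.per_location.items()
            },
            "singleplex": dict(zip(("rate", "correct", "total"), self.singleplex)),
            "multiplex": dict(zip(("rate", "correct", "total"), self.multiplex)),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        """Table-shaped TSV: one row per location plus overall/plex rows."""
        with open(path, "w") as fh:
            fh.write("row\trate_percent\tcorrect\ttotal\n")
            for loc, (r, c, t) in self.per_location.items():
                fh.write(f"{loc.label}\t{100 * r:.1f}\t{c}\t{t}\n")
            s, m = self.singleplex, self.multiplex
            fh.write(f"singleplex\t{100 * s[0]:.1f}\t{s[1]}\t{s[2]}\n")
            fh.write(f"multiplex\t{100 * m[0]:.1f}\t{m[1]}\t{m[2]}\n")
            fh.write(f"overall\t{100 * self.overall:.1f}\t{self.correct}\t{self.total}\n")


# ---------------------------------------------------------------------------
# Fold construction


def iterative_stratified_folds(
    dataset: Dataset, folds: int, seed: int = 0
) -> list[list[int]]:
    """Iterative stratification of a multi-label dataset into *folds* parts.

    Greedy algorithm: repeatedly take the label with the fewest remaining
    proteins and deal its proteins to the fold with the greatest remaining
    demand for that label (ties: greatest total remaining capacity, then
    seeded random).  Label-free proteins are dealt round-robin at the end.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    desired_total = np.full(folds, n / folds)
    label_counts = dataset.location_counts()
    desired_label = {
        loc: np.full(folds, label_counts[loc] / folds) for loc in Location
    }
    remaining = set(range(n))
    fold_of = np.full(n, -1)
    records = dataset.records
    while remaining:
        with_labels = [i for i in remaining if records[i].locations]
        if not with_labels:
            break
        # label with fewest remaining examples (ignore exhausted labels)
        counts = {
            loc: sum(1 for i in with_labels if loc in records[i].locations)
            for loc in Location
        }
        active = [loc for loc, c in counts.items() if c > 0]
        lab = min(active, key=lambda l: (counts[l], int(l)))
        for i in sorted(i for i in with_labels if lab in records[i].locations):
            demand = desired_label[lab]
            best = np.flatnonzero(demand == demand.max())
            if len(best) > 1:
                cap = desired_total[best]
                best = best[np.flatnonzero(cap == cap.max())]
            f = int(rng.choice(best))
            fold_of[i] = f
            remaining.discard(i)
            desired_total[f] -= 1
            for loc in records[i].locations:
                desired_label[loc][f] -= 1
    for j, i in enumerate(sorted(remaining)):
        fold_of[i] = j % folds
    return [list(np.flatnonzero(fold_of == f)) for f in range(folds)]


class LeakageError(AssertionError):
    """A layer-2 training row was produced by sub-models that saw its protein."""


def nested_cv(
    dataset: Dataset,
    config,
    folds: int = 5,
    seed: int = 0,
    combiners: Sequence[str] = ("vote", "gann"),
) -> dict[str, "EvalReport | list[EvalReport]"]:
    """Nested k-fold cross-validation of the full two-layer pipeline.

    Outer folds are stratified over the six labels.  Within each outer
    training fold, layer-1 sub-models are trained on inner folds so that
    every layer-2 training row is an *out-of-fold* layer-1 output; layer 1
    is then refit on the whole outer-train and the held-out outer fold is
    scored end-to-end.  An explicit audit raises :class:`LeakageError` if
    any layer-2 training row came from sub-models that saw its protein.

    *config* is a :class:`protloc.pipeline.PipelineConfig`.  Returns
    ``{"vote": EvalReport, "gann": EvalReport, "vote_folds": [...], ...}``.
    """
    from . import pipeline  # deferred: pipeline imports this module

    truths = {r.id: r.locations for r in dataset.records}
    fold_indices = iterative_stratified_folds(dataset, folds, seed=seed)
    all_preds: dict[str, list[PredictionSet]] = {c: [] for c in combiners}
    fold_reports: dict[str, list[EvalReport]] = {c: [] for c in combiners}

    for f, test_idx in enumerate(fold_indices):
        test_set = set(test_idx)
        train_records = [r for i, r in enumerate(dataset.records) if i not in test_set]
        test_records = [dataset.records[i] for i in test_idx]
        train_ds = Dataset(train_records)
        missing = [
            loc.label
            for loc, cnt in train_ds.location_counts().items()
            if cnt == 0
        ]
        if missing:
            warnings.warn(
                f"outer fold {f}: locations absent from training: {missing}"
            )
        model = pipeline.train_model(
            train_ds, config, seed=seed + f, inner_folds=folds
        )
        # leakage audit on the recorded layer-2 training provenance
        for pid, seen_ids in model.layer2_provenance.items():
            if pid in seen_ids:
                raise LeakageError(
                    f"layer-2 training row for {pid!r} produced by sub-models "
                    "trained on that protein"
                )
        preds = model.predict(test_records)
        for c in combiners:
            fold_pred = preds[c]
            all_preds[c].extend(fold_pred)
            fold_reports[c].append(EvalReport.from_predictions(fold_pred, truths))

    out: dict[str, EvalReport | list[EvalReport]] = {}
    for c in combiners:
        out[c] = EvalReport.from_predictions(all_preds[c], truths)
        out[f"{c}_folds"] = fold_reports[c]
    return out
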