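"""Gene Ontology term features and mutual-information feature selection.

GO annotations are converted into a binary presence vector over a fixed,
trained list of localization-relevant terms.  The list is chosen by a
greedy minimum-redundancy / maximum-relevance (mRMR) procedure adapted to
the multi-label setting: a term's relevance is the mean mutual information
with the six one-vs-rest location indicators, and its redundancy the mean
mutual information with already-selected terms (MID criterion, i.e.
relevance minus redundancy).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import Dataset, Location, ProteinRecord
from .features_profile import SimilarityBackend, similarity_search

__all__ = [
    "GOFeatureSpec",
    "GOAnnotationSource",
    "read_go_annotations",
    "go_vector",
    "binary_mutual_information",
    "regular_mrmr",
    "select_k_by_cv",
]

logger = logging.getLogger(__name__)

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclasses.dataclass(frozen=True)
class GOFeatureSpec:
    """Ordered list of selected GO term ids (most relevant first) + scores."""

    terms: tuple[str, ...]
    scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("selected GO terms must be unique")

    def __len__(self) -> int:
        return len(self.terms)


@dataclasses.dataclass
class GOAnnotationSource:
    """Protein id -> direct GO annotations, with a similarity fallback.

    Queries without direct annotations can inherit the terms of the most
    similar annotated protein in *reference* (when a similarity backend and
    reference set are supplied).
    """

    annotations: dict[str, frozenset[str]]
    reference: Dataset | None = None
    backend: SimilarityBackend | None = None

    def __post_init__(self) -> None:
        for pid, terms in self.annotations.items():
            for t in terms:
                if not _GO_ID_RE.match(t):
                    raise ValueError(f"protein {pid!r}: malformed GO id {t!r}")

    def terms_for(
        self, record: ProteinRecord, exclude_self: bool = False
    ) -> tuple[frozenset[str], bool]:
        """(terms, via_similarity_flag); empty set when nothing is found.

        The record's own terms take precedence over the stored mapping: a
        query may reuse a training protein's id while carrying different
        annotations.
        """
        if record.go_terms:
            return frozenset(record.go_terms), False
        direct = self.annotations.get(record.id)
        if direct:
            return direct, False
        if self.reference is not None and len(self.reference) > 0:
            annotated = self.reference.subset_ids(
                pid for pid in self.annotations if self.annotations[pid]
            )
            if len(annotated) > 0:
                hit = similarity_search(
                    record,
                    annotated,
                    backend=self.backend,
                    exclude_id=record.id if exclude_self else None,
                )
                if hit is not None:
                    return self.annotations[hit[0]], True
        return frozenset(), False


def read_go_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (protein_id TAB GO id), one pair per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected protein_id<TAB>GO id")
            pid, term = parts[0], parts[1]
            if not _GO_ID_RE.match(term):
                raise ValueError(f"{path}:{lineno}: malformed GO id {term!r}")
            out.setdefault(pid, set()).add(term)
    return {pid: frozenset(terms) for pid, terms in out.items()}


def go_vector(
    record: ProteinRecord,
    spec: GOFeatureSpec,
    source: GOAnnotationSource | None = None,
    exclude_self: bool = False,
) -> tuple[np.ndarray, bool]:
    """Binary presence vector over the selected terms: (vector, missing_flag).

    Entry j is 1 iff spec.terms[j] annotates the record (directly, or via the
    most similar annotated protein).  A record with no recoverable terms gets
    the zero vector and ``missing_flag=True`` — GO absence degrades the
    feature, never the pipeline.
    """
    if source is not None:
        terms, _ = source.terms_for(record, exclude_self=exclude_self)
    else:
        terms = frozenset(record.go_terms or ())
    vec = np.array([1.0 if t in terms else 0.0 for t in spec.terms])
    return vec, not terms


# ---------------------------------------------------------------------------
# Mutual information and mRMR


def binary_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI (nats) between two binary vectors from empirical 2x2 counts.

    Uses the 0*log(0)=0 convention and no pseudo-counts, so it agrees
    exactly with a naive enumeration oracle.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    n = len(x)
    if n == 0 or len(y) != n:
        raise ValueError("binary MI needs two equal-length non-empty vectors")
    mi = 0.0
    for xv in (False, True):
        for yv in (False, True):
            pxy = np.sum((x == xv) & (y == yv)) / n
            if pxy == 0:
                continue
            px = np.sum(x == xv) / n
            py = np.sum(y == yv) / n
            mi += pxy * np.log(pxy / (px * py))
    return float(max(mi, 0.0))


def _mi_matrix_vs_labels(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Mean MI of each binary column of X against the label columns of Y."""
    n_terms = X.shape[1]
    n_labels = Y.shape[1]
    rel = np.zeros(n_terms)
    for j in range(n_terms):
        rel[j] = np.mean(
            [binary_mutual_information(X[:, j], Y[:, l]) for l in range(n_labels)]
        )
    return rel


def _labels_matrix(labels: Sequence[frozenset[Location]]) -> np.ndarray:
    Y = np.zeros((len(labels), len(Location)), dtype=bool)
    for i, locs in enumerate(labels):
        for loc in locs:
            Y[i, int(loc)] = True
    return Y


def regular_mrmr(
    matrix: np.ndarray,
    term_ids: Sequence[str],
    labels: Sequence[frozenset[Location]],
    k: int,
) -> GOFeatureSpec:
    """Greedy multi-label mRMR selection of *k* GO terms.

    First pick maximizes relevance (mean MI against the six one-vs-rest
    location indicators); each later pick maximizes relevance minus the mean
    MI with already-selected terms.  Constant columns are skipped; ties break
    toward the lexicographically smallest GO id, making the selection fully
    deterministic.
    """
    X = np.asarray(matrix, dtype=bool)
    if X.ndim != 2 or X.shape[1] != len(term_ids):
        raise ValueError("matrix must be proteins x terms with matching term_ids")
    if not set(np.unique(np.asarray(matrix))) <= {0, 1, False, True}:
        raise ValueError("mRMR expects a binary matrix")
    Y = _labels_matrix(labels)
    if len(Y) != len(X):
        raise ValueError("labels and matrix row counts differ")

    usable = [j for j in range(X.shape[1]) if 0 < X[:, j].sum() < len(X)]
    skipped = X.shape[1] - len(usable)
    if skipped:
        logger.info("regular_mrmr: skipped %d constant candidate columns", skipped)
    if k > len(usable):
        raise ValueError(f"k={k} exceeds {len(usable)} usable candidate terms")

    relevance = _mi_matrix_vs_labels(X, Y)
    selected: list[int] = []
    scores: list[float] = []
    # cached MI of every usable candidate against each selected term
    redundancy_sum = np.zeros(X.shape[1])
    while len(selected) < k:
        best_j: int | None = None
        best_obj = -np.inf
        for j in usable:
            if j in selected:
                continue
            obj = relevance[j] - (
                redundancy_sum[j] / len(selected) if selected else 0.0
            )
            if obj > best_obj or (
                obj == best_obj and best_j is not None and term_ids[j] < term_ids[best_j]
            ):
                best_obj = obj
                best_j = j
        assert best_j is not None
        selected.append(best_j)
        scores.append(best_obj)
        for j in usable:
            if j not in selected:
                redundancy_sum[j] += binary_mutual_information(X[:, j], X[:, best_j])
    return GOFeatureSpec(
        terms=tuple(term_ids[j] for j in selected), scores=tuple(scores)
    )


def select_k_by_cv(
    matrix: np.ndarray,
    term_ids: Sequence[str],
    labels: Sequence[frozenset[Location]],
    k_grid: Sequence[int],
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the term count k whose GO-only classifier scores best under CV.

    For each k in *k_grid*, the top-k mRMR terms feed a one-vs-rest linear
    SVM; performance is cross-validated exact-set-match accuracy (each
    protein counts only if its full predicted location set is right).  Ties
    go to the smallest k.
    """
    from sklearn.model_selection import KFold
    from sklearn.svm import LinearSVC

    if not len(k_grid):
        raise ValueError("k_grid must be non-empty")
    k_grid = sorted(set(k_grid))
    if len(k_grid) == 1:
        return k_grid[0]

    X_full = np.asarray(matrix, dtype=float)
    Y = _labels_matrix(labels).astype(int)
    spec_all = regular_mrmr(matrix, term_ids, labels, k=max(k_grid))
    order = [list(term_ids).index(t) for t in spec_all.terms]

    results: dict[int, float] = {}
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for k in k_grid:
        cols = order[:k]
        X = X_full[:, cols]
        correct = 0
        for train_idx, test_idx in kf.split(X):
            pred = np.zeros((len(test_idx), Y.shape[1]), dtype=int)
            for l in range(Y.shape[1]):
                ytr = Y[train_idx, l]
                if len(np.unique(ytr)) < 2:
                    continue
                clf = LinearSVC(random_state=seed)
                clf.fit(X[train_idx], ytr)
                pred[:, l] = clf.predict(X[test_idx])
            # empty predicted sets fall back to the most confident label
            for r, ti in enumerate(test_idx):
                if pred[r].sum() == 0:
                    pred[r, int(np.argmax(Y[train_idx].sum(axis=0)))] = 1
                correct += int((pred[r] == Y[ti]).all())
        results[k] = correct / len(X)
    best = max(k_grid, key=lambda k: (results[k], -k))
    return best
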