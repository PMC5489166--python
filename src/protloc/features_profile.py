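"""Profile-based features: surface accessibility and the similarity profile.

Surface-accessibility (SA) features summarize externally supplied
per-residue accessibility predictions over the four sequence regions.  The
sequence similarity profile (SSP) substitutes the sequence-derived feature
block of the most similar reference protein for the query's own block,
giving near-duplicate sequences with different annotations an identical
learning signal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .data_model import Dataset, ProteinRecord
from .features_sequence import (
    AAIndexTable,
    REGION_NAMES,
    extract_regions,
    sequence_feature_block,
)

__all__ = [
    "SAProfile",
    "read_sa_profiles",
    "write_sa_profiles",
    "aggregate_sa",
    "SA_BLOCK_WIDTH",
    "SimilarityBackend",
    "AlignmentBackend",
    "TabularBackend",
    "similarity_search",
    "SSPBlock",
    "compute_ssp",
    "ASA_SCALE_CAP",
]

#: Min-max cap for absolute surface area (A^2); keeps ASA features in [0,~1].
ASA_SCALE_CAP = 250.0

#: SA sub-vector width: 4 regions x (mean RSA, scaled mean ASA, frac exposed).
SA_BLOCK_WIDTH = 12


@dataclasses.dataclass
class SAProfile:
    """Per-residue surface accessibility rows (one row per residue)."""

    rsa: np.ndarray  # relative surface accessibility, fraction (may exceed 1 slightly)
    asa: np.ndarray  # absolute surface accessibility, A^2
    exposed: np.ndarray  # boolean exposure class

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.asa = np.asarray(self.asa, dtype=float)
        self.exposed = np.asarray(self.exposed, dtype=bool)
        n = len(self.rsa)
        if len(self.asa) != n or len(self.exposed) != n:
            raise ValueError("SAProfile columns must have equal length")
        if (self.rsa < 0).any() or (self.rsa > 1.5).any():
            raise ValueError("RSA values must lie in [0, 1.5]")
        if (self.asa < 0).any():
            raise ValueError("ASA values must be non-negative")

    def __len__(self) -> int:
        return len(self.rsa)


def read_sa_profiles(path: str | Path) -> dict[str, SAProfile]:
    """Read per-residue SA rows from TSV.

    Columns: protein_id, residue_index (1-based), aa, class (B/E), RSA, ASA.
    This is the column subset emitted by common accessibility predictors.
    """
    per_protein: dict[str, list[tuple[int, bool, float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            pid, idx, _aa, cls, rsa, asa = parts
            per_protein.setdefault(pid, []).append(
                (int(idx), cls.upper().startswith("E"), float(rsa), float(asa))
            )
    out: dict[str, SAProfile] = {}
    for pid, rows in per_protein.items():
        rows.sort(key=lambda r: r[0])
        out[pid] = SAProfile(
            rsa=np.array([r[2] for r in rows]),
            asa=np.array([r[3] for r in rows]),
            exposed=np.array([r[1] for r in rows]),
        )
    return out


def write_sa_profiles(
    profiles: dict[str, SAProfile], sequences: dict[str, str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tresidue_index\taa\tclass\tRSA\tASA\n")
        for pid, prof in profiles.items():
            seq = sequences[pid]
            for i in range(len(prof)):
                cls = "E" if prof.exposed[i] else "B"
                fh.write(
                    f"{pid}\t{i + 1}\t{seq[i]}\t{cls}\t{prof.rsa[i]:.4f}\t{prof.asa[i]:.2f}\n"
                )


def aggregate_sa(record: ProteinRecord) -> tuple[np.ndarray, bool]:
    """Region-wise SA summary: (12-vector, missing_flag).

    Per region: mean RSA, mean ASA scaled by :data:`ASA_SCALE_CAP`, and the
    fraction of exposed residues.  A missing profile yields a zero block and
    ``missing_flag=True`` rather than an error, so prediction never aborts
    mid-batch; a present profile whose row count disagrees with the sequence
    length is an error.
    """
    if record.sa_profile is None:
        return np.zeros(SA_BLOCK_WIDTH), True
    prof: SAProfile = record.sa_profile
    n = len(record.sequence)
    if len(prof) != n:
        raise ValueError(
            f"protein {record.id!r}: SA profile has {len(prof)} rows "
            f"but sequence has {n} residues"
        )
    regions = extract_regions(record.sequence)
    # region boundaries mirror extract_regions' slicing
    third = n // 3
    mid_start = (n - third) // 2
    spans = {
        "full": (0, n),
        "n30": (0, min(30, n)),
        "mid3": (mid_start, mid_start + third),
        "c50": (max(0, n - 50), n),
    }
    out = np.zeros(SA_BLOCK_WIDTH)
    for r, name in enumerate(REGION_NAMES):
        lo, hi = spans[name]
        if hi <= lo:
            continue
        out[3 * r] = prof.rsa[lo:hi].mean()
        out[3 * r + 1] = min(prof.asa[lo:hi].mean() / ASA_SCALE_CAP, 1.0)
        out[3 * r + 2] = prof.exposed[lo:hi].mean()
    assert len(regions.full) == n
    return out, False


# ---------------------------------------------------------------------------
# Similarity search


class SimilarityBackend:
    """Contract: return (best reference id, score) for a query, or None."""

    def best_hit(
        self, query: ProteinRecord, reference: Dataset, exclude_id: str | None = None
    ) -> tuple[str, float] | None:
        raise NotImplementedError


class AlignmentBackend(SimilarityBackend):
    """Built-in Smith-Waterman local alignment with BLOSUM62.

    Gap penalties follow the common protein-search defaults (open 11,
    extend 1).  The best raw score wins; ties break toward the
    lexicographically smallest reference id; hits below *min_score* count
    as "no similar protein found".
    """

    def __init__(self, min_score: float = 50.0):
        self.min_score = min_score
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -11.0
        self._aligner.extend_gap_score = -1.0

    def score(self, seq_a: str, seq_b: str) -> float:
        return float(self._aligner.score(seq_a, seq_b))

    def best_hit(
        self, query: ProteinRecord, reference: Dataset, exclude_id: str | None = None
    ) -> tuple[str, float] | None:
        if len(reference) == 0:
            raise ValueError("similarity search against an empty reference set")
        best: tuple[str, float] | None = None
        for ref in reference:
            if exclude_id is not None and ref.id == exclude_id:
                continue
            s = self.score(query.sequence, ref.sequence)
            if best is None or s > best[1] or (s == best[1] and ref.id < best[0]):
                best = (ref.id, s)
        if best is None or best[1] < self.min_score:
            return None
        return best


class TabularBackend(SimilarityBackend):
    """External-tool adapter: consumes precomputed (query_id, subject_id, score) rows."""

    def __init__(self, hits: dict[str, list[tuple[str, float]]], min_score: float = 50.0):
        self.hits = hits
        self.min_score = min_score

    @classmethod
    def from_tsv(cls, path: str | Path, min_score: float = 50.0) -> "TabularBackend":
        hits: dict[str, list[tuple[str, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                qid, sid, score = line.split("\t")
                hits.setdefault(qid, []).append((sid, float(score)))
        return cls(hits, min_score=min_score)

    def best_hit(
        self, query: ProteinRecord, reference: Dataset, exclude_id: str | None = None
    ) -> tuple[str, float] | None:
        if len(reference) == 0:
            raise ValueError("similarity search against an empty reference set")
        ref_ids = {r.id for r in reference}
        cands = [
            (sid, s)
            for sid, s in self.hits.get(query.id, [])
            if sid in ref_ids and sid != exclude_id and s >= self.min_score
        ]
        if not cands:
            return None
        return min(cands, key=lambda c: (-c[1], c[0]))


def similarity_search(
    query: ProteinRecord,
    reference: Dataset,
    backend: SimilarityBackend | None = None,
    exclude_id: str | None = None,
) -> tuple[str, float] | None:
    """Most similar reference protein (id, score), or None below threshold."""
    if backend is None:
        backend = AlignmentBackend()
    return backend.best_hit(query, reference, exclude_id=exclude_id)


# ---------------------------------------------------------------------------
# Sequence similarity profile


@dataclasses.dataclass
class SSPBlock:
    """Sequence-feature block of the best reference hit (or the query itself).

    The layout is identical to the query's own sequence block; when no
    reference scores above threshold, the block falls back to the query's
    own features and ``matched_id`` equals the query id.
    """

    block: np.ndarray
    matched_id: str
    score: float | None


def compute_ssp(
    query: ProteinRecord,
    reference: Dataset,
    table: AAIndexTable,
    backend: SimilarityBackend | None = None,
    exclude_self: bool = False,
    block_cache: dict[str, np.ndarray] | None = None,
    query_block: np.ndarray | None = None,
) -> SSPBlock:
    """The SSP for *query* against *reference*.

    ``exclude_self=True`` enforces leave-self-out (training-time rule: a
    training protein must never match its own entry).  *block_cache* maps
    reference id -> precomputed sequence block to avoid recomputation.
    """
    hit = similarity_search(
        query, reference, backend=backend, exclude_id=query.id if exclude_self else None
    )
    if hit is None:
        block = (
            query_block
            if query_block is not None
            else sequence_feature_block(query.sequence, table)
        )
        return SSPBlock(block=np.asarray(block, dtype=float), matched_id=query.id, score=None)
    hit_id, score = hit
    if block_cache is not None and hit_id in block_cache:
        block = block_cache[hit_id]
    else:
        block = sequence_feature_block(reference.by_id(hit_id).sequence, table)
        if block_cache is not None:
            block_cache[hit_id] = block
    return SSPBlock(block=np.asarray(block, dtype=float), matched_id=hit_id, score=score)
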