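"""Core domain types and I/O for the localization predictor.

The predictor works over six human subcellular compartments.  A protein may
belong to one compartment (singleplex) or several (multiplex); labels are
therefore *sets* of locations.  This module holds the record/dataset types,
FASTA and annotation readers/writers, and model-bundle serialization.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import pickle
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Location",
    "ProteinRecord",
    "Dataset",
    "SanitizePolicy",
    "sanitize_sequence",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "filter_min_length",
    "save_model",
    "load_model",
    "ModelBundleError",
    "STANDARD_AA",
]

#: The 20 standard amino acids in alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class Location(enum.IntEnum):
    """The six subcellular compartments, with stable integer codes 0-5."""

    CELL_MEMBRANE = 0
    CYTOPLASM = 1
    ER_GOLGI = 2
    MITOCHONDRION = 3
    NUCLEUS = 4
    EXTRACELLULAR = 5

    @property
    def label(self) -> str:
        return _CANONICAL_LABELS[self]

    @classmethod
    def from_label(cls, text: str) -> "Location":
        """Resolve a (case-insensitive, synonym-tolerant) label to a Location."""
        key = text.strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return _LABEL_SYNONYMS[key]
        except KeyError:
            raise ValueError(f"unknown subcellular location label: {text!r}") from None


_CANONICAL_LABELS = {
    Location.CELL_MEMBRANE: "cell_membrane",
    Location.CYTOPLASM: "cytoplasm",
    Location.ER_GOLGI: "er_golgi",
    Location.MITOCHONDRION: "mitochondrion",
    Location.NUCLEUS: "nucleus",
    Location.EXTRACELLULAR: "extracellular",
}

_LABEL_SYNONYMS: dict[str, Location] = {}
for _loc, _lab in _CANONICAL_LABELS.items():
    _LABEL_SYNONYMS[_lab] = _loc
_LABEL_SYNONYMS.update(
    {
        "membrane": Location.CELL_MEMBRANE,
        "plasma_membrane": Location.CELL_MEMBRANE,
        "cell_membrane": Location.CELL_MEMBRANE,
        "cytosol": Location.CYTOPLASM,
        "er/golgi": Location.ER_GOLGI,
        "er_golgi": Location.ER_GOLGI,
        "endoplasmic_reticulum/golgi": Location.ER_GOLGI,
        "endoplasmic_reticulum_golgi": Location.ER_GOLGI,
        "golgi": Location.ER_GOLGI,
        "endoplasmic_reticulum": Location.ER_GOLGI,
        "mitochondria": Location.MITOCHONDRION,
        "mitochondrial": Location.MITOCHONDRION,
        "nuclear": Location.NUCLEUS,
        "secreted": Location.EXTRACELLULAR,
        "extracellular_space": Location.EXTRACELLULAR,
    }
)


class SanitizePolicy(str, enum.Enum):
    """How to treat non-standard residue letters (B, J, O, U, X, Z, ``*``).

    ``DROP``   remove the residue (default; keeps composition math over the
               20-letter alphabet exact).
    ``MAP``    map to the nearest standard residue (B->D, Z->E, U->C, J->L,
               O->K); X and ``*`` are dropped.
    ``REJECT`` raise on any non-standard letter.
    """

    DROP = "drop"
    MAP = "map"
    REJECT = "reject"


_AMBIGUOUS_MAP = {"B": "D", "Z": "E", "U": "C", "J": "L", "O": "K"}


def sanitize_sequence(seq: str, policy: SanitizePolicy = SanitizePolicy.DROP) -> str:
    """Uppercase *seq* and resolve non-standard letters per *policy*."""
    seq = seq.upper().replace(" ", "").replace("\n", "")
    out: list[str] = []
    for ch in seq:
        if ch in _STANDARD_SET:
            out.append(ch)
        elif policy is SanitizePolicy.REJECT:
            raise ValueError(f"non-standard residue {ch!r} in sequence")
        elif policy is SanitizePolicy.MAP and ch in _AMBIGUOUS_MAP:
            out.append(_AMBIGUOUS_MAP[ch])
        # DROP (or MAP on X/*): skip the character
    return "".join(out)


@dataclasses.dataclass
class ProteinRecord:
    """One protein: id, sanitized sequence, optional labels / GO terms / SA rows."""

    id: str
    sequence: str
    locations: frozenset[Location] = frozenset()
    go_terms: tuple[str, ...] | None = None
    sa_profile: "object | None" = None  # features_profile.SAProfile when present

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}; "
                "sanitize first (see sanitize_sequence)"
            )
        self.locations = frozenset(Location(l) for l in self.locations)
        if self.go_terms is not None:
            self.go_terms = tuple(self.go_terms)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_multiplex(self) -> bool:
        return len(self.locations) >= 2


@dataclasses.dataclass
class Dataset:
    """A list of protein records with per-location instance bookkeeping.

    A multiplex protein contributes one instance to every location it
    belongs to, so the instance total can exceed the number of proteins.
    """

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids in dataset: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, pid: str) -> ProteinRecord:
        for r in self.records:
            if r.id == pid:
                return r
        raise KeyError(pid)

    def location_counts(self) -> dict[Location, int]:
        counts = {loc: 0 for loc in Location}
        for r in self.records:
            for loc in r.locations:
                counts[loc] += 1
        return counts

    def instance_total(self) -> int:
        return sum(self.location_counts().values())

    def positives(self, location: Location) -> list[ProteinRecord]:
        return [r for r in self.records if location in r.locations]

    def negatives(self, location: Location) -> list[ProteinRecord]:
        return [r for r in self.records if location not in r.locations]

    def subset_ids(self, ids: Iterable[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset([r for r in self.records if r.id in wanted])


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(
    path: str | Path, policy: SanitizePolicy = SanitizePolicy.DROP
) -> list[ProteinRecord]:
    """Read a FASTA file into unlabeled :class:`ProteinRecord` objects.

    Sequences are uppercased and sanitized per *policy*.  Raises ``ValueError``
    on an empty or malformed file.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if first != ">":
            raise ValueError(f"{path}: line 1: expected '>' header, got {first!r}")
        fh.seek(0)
        for entry in SeqIO.parse(fh, "fasta"):
            seq = sanitize_sequence(str(entry.seq), policy)
            if not seq:
                raise ValueError(f"{path}: entry {entry.id!r} has no usable residues")
            records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation I/O (TSV: id TAB comma-separated labels)


def read_annotations(path: str | Path) -> dict[str, frozenset[Location]]:
    """Read per-protein location annotations from a two-column TSV."""
    path = Path(path)
    out: dict[str, frozenset[Location]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>labels'")
            pid, labels = parts
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            fields = [f for f in labels.split(",") if f.strip()]
            if not fields:
                raise ValueError(
                    f"{path}:{lineno}: protein {pid!r} has no locations "
                    "(labeled records need at least one)"
                )
            try:
                locs = frozenset(Location.from_label(f) for f in fields)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out[pid] = locs
    if not out:
        raise ValueError(f"{path}: no annotation lines found")
    return out


def write_annotations(
    annotations: Mapping[str, Iterable[Location]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pid, locs in annotations.items():
            labels = ",".join(l.label for l in sorted(locs))
            fh.write(f"{pid}\t{labels}\n")


def attach_annotations(
    records: Sequence[ProteinRecord], annotations: Mapping[str, frozenset[Location]]
) -> Dataset:
    """Join FASTA records with an annotation mapping into a labeled Dataset."""
    missing = [r.id for r in records if r.id not in annotations]
    if missing:
        raise ValueError(f"records without annotations: {missing[:5]}...")
    labeled = [
        dataclasses.replace(r, locations=annotations[r.id]) for r in records
    ]
    return Dataset(labeled)


def filter_min_length(dataset: Dataset, min_len: int = 80) -> Dataset:
    """Drop records shorter than *min_len* residues (training-set rule)."""
    return Dataset([r for r in dataset.records if len(r.sequence) >= min_len])


# ---------------------------------------------------------------------------
# Model bundle serialization

_BUNDLE_VERSION = 1


class ModelBundleError(RuntimeError):
    """Raised when a saved model bundle cannot be loaded."""


def save_model(bundle: object, path: str | Path) -> None:
    """Serialize a trained model bundle with an integrity checksum."""
    payload = pickle.dumps(bundle, protocol=pickle.HIGHEST_PROTOCOL)
    digest = hashlib.sha256(payload).hexdigest()
    header = f"PROTLOC{_BUNDLE_VERSION:04d}{digest}".encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload)


def load_model(path: str | Path) -> object:
    """Load a bundle written by :func:`save_model`, verifying version/checksum."""
    with open(path, "rb") as fh:
        raw = fh.read()
    magic, raw_version, digest, payload = raw[:7], raw[7:11], raw[11:75], raw[75:]
    if magic != b"PROTLOC":
        raise ModelBundleError(f"{path}: not a model bundle (bad magic)")
    version = int(raw_version)
    if version != _BUNDLE_VERSION:
        raise ModelBundleError(
            f"{path}: bundle version {version} != supported {_BUNDLE_VERSION}"
        )
    if hashlib.sha256(payload).hexdigest() != digest.decode("ascii"):
        raise ModelBundleError(f"{path}: checksum mismatch (corrupt bundle)")
    return pickle.loads(payload)
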