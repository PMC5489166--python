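"""Sequence-derived feature encoders.

Three encoders operate on four sequence regions (full length, first 30
N-terminal residues, middle third, last 50 C-terminal residues):

* **AAC** — amino acid composition, the 20-vector of residue fractions.
* **Weighted sign aa index** — for each of 100 amino-acid property scales,
  the composition-weighted property score is summarized as a (sign, log10
  magnitude) pair.  The sign separates e.g. net-hydrophobic from
  net-hydrophilic regions while the log compresses the magnitude.
* **PC-PseAAC** — pseudo amino acid composition: AAC augmented with lambda
  sequence-order correlation factors over three physicochemical properties
  (hydrophobicity, hydrophilicity, side-chain mass), mixed by weight omega.

All encoders are deterministic and purely compositional/sequential; they
need no external tools.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import STANDARD_AA

__all__ = [
    "RegionSet",
    "REGION_NAMES",
    "extract_regions",
    "compute_aac",
    "AAIndexTable",
    "default_aaindex_table",
    "WeightedSignAAIndex",
    "compute_weighted_sign_aaindex",
    "compute_pseaac",
    "sequence_feature_block",
    "BlockMap",
    "SCORE_FLOOR",
]

_AA_TO_IDX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: Region names in fixed feature-layout order.
REGION_NAMES = ("full", "n30", "mid3", "c50")

#: Zero-floor applied to |score| before the log10 so the feature stays finite.
SCORE_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class RegionSet:
    """The four analysis regions of a sequence (contiguous slices; may overlap)."""

    full: str
    n30: str
    mid3: str
    c50: str

    def as_dict(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in REGION_NAMES}


def extract_regions(sequence: str) -> RegionSet:
    """Slice *sequence* into the four fixed regions.

    ``n30`` is the prefix of length min(30, len), ``c50`` the suffix of length
    min(50, len), and ``mid3`` a centered slice of length ``len // 3``
    starting at ``(len - len // 3) // 2``.  Regions overlap for short
    sequences; ``mid3`` is empty for sequences shorter than 3 residues.
    """
    if not sequence:
        raise ValueError("cannot extract regions from an empty sequence")
    n = len(sequence)
    third = n // 3
    start = (n - third) // 2
    return RegionSet(
        full=sequence,
        n30=sequence[: min(30, n)],
        mid3=sequence[start : start + third],
        c50=sequence[max(0, n - 50) :],
    )


def compute_aac(region: str) -> np.ndarray:
    """Amino acid composition of *region*: count(aa)/N in alphabetical order.

    An empty region yields the zero vector (callers treat this as a flagged
    degenerate case; it cannot occur for length-filtered training data).
    """
    vec = np.zeros(20, dtype=float)
    if not region:
        return vec
    for ch in region:
        vec[_AA_TO_IDX[ch]] += 1.0
    return vec / len(region)


# ---------------------------------------------------------------------------
# Amino-acid index table and the weighted sign aa index


class AAIndexTable:
    """A bank of 100 amino-acid property scales (rows) over the 20 acids.

    The encoder is agnostic to which scales are used; only the count (100)
    and the column order (alphabetical one-letter) are fixed.
    """

    N_INDICES = 100

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (self.N_INDICES, 20):
            raise ValueError(
                f"AAIndexTable requires shape ({self.N_INDICES}, 20); got {values.shape}"
            )
        if not np.isfinite(values).all():
            bad = [ids[i] for i in np.unique(np.nonzero(~np.isfinite(values))[0])]
            raise ValueError(f"non-finite values in indices: {bad}")
        if len(ids) != self.N_INDICES or len(set(ids)) != self.N_INDICES:
            raise ValueError("need exactly 100 unique index ids")
        self.ids = list(ids)
        self.values = values

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAIndexTable":
        """Read a table from TSV: index_id + 20 columns in alphabetical order."""
        ids: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 21:
                    raise ValueError(f"{path}:{lineno}: expected 21 columns")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids, np.array(rows))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# aaindex table: index_id + 20 columns (" + STANDARD_AA + ")\n")
            for idx, row in zip(self.ids, self.values):
                fh.write(idx + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# Published property scales (values over ACDEFGHIKLMNPQRSTVWY).  These seed
# the default table; see default_aaindex_table.
_BASE_SCALES: dict[str, list[float]] = {
    # Kyte & Doolittle hydropathy
    "hydropathy_kd": [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
                      1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3],
    # Hopp & Woods hydrophilicity
    "hydrophilicity_hw": [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
                          -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3],
    # side-chain mass (Da)
    "side_chain_mass": [15.0, 47.0, 59.0, 73.0, 91.0, 1.0, 82.0, 57.0, 73.0, 57.0,
                        75.0, 58.0, 42.0, 72.0, 101.0, 31.0, 45.0, 43.0, 130.0, 107.0],
    # Grantham polarity
    "polarity_grantham": [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
                          5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2],
    # Zamyatnin residue volume (A^3)
    "volume_zamyatnin": [88.6, 108.5, 111.1, 138.4, 189.9, 60.1, 153.2, 166.7,
                         168.6, 166.7, 162.9, 114.1, 112.7, 143.8, 173.4, 89.0,
                         116.1, 140.0, 227.8, 193.6],
    # Zimmerman isoelectric point
    "isoelectric_zimmerman": [6.0, 5.05, 2.77, 3.22, 5.48, 5.97, 7.59, 6.02, 9.74,
                              5.98, 5.74, 5.41, 6.3, 5.65, 10.76, 5.68, 5.66, 5.96,
                              5.89, 5.66],
    # Bhaskaran & Ponnuswamy average flexibility
    "flexibility_bp": [0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462,
                       0.466, 0.365, 0.295, 0.463, 0.509, 0.493, 0.529, 0.507,
                       0.444, 0.386, 0.305, 0.42],
    # Chou & Fasman alpha-helix propensity
    "helix_cf": [1.42, 0.7, 1.01, 1.51, 1.13, 0.57, 1.0, 1.08, 1.16, 1.21,
                 1.45, 0.67, 0.57, 1.11, 0.98, 0.77, 0.83, 1.06, 1.08, 0.69],
    # Chou & Fasman beta-sheet propensity
    "sheet_cf": [0.83, 1.19, 0.54, 0.37, 1.38, 0.75, 0.87, 1.6, 0.74, 1.3,
                 1.05, 0.89, 0.55, 1.1, 0.93, 0.75, 1.19, 1.7, 1.37, 1.47],
    # Janin buried fraction
    "buried_janin": [0.28, 0.97, 0.19, 0.15, 0.5, 0.36, 0.19, 0.6, 0.03, 0.45,
                     0.4, 0.12, 0.18, 0.14, 0.01, 0.22, 0.23, 0.54, 0.27, 0.15],
}


def default_aaindex_table(seed: int = 20_170_628) -> AAIndexTable:
    """Build the packaged 100-scale table.

    The first rows are published physicochemical scales; the remainder is a
    synthetic bank of scales derived deterministically from seeded random
    mixtures of the published ones plus standardized noise.  This synthetic
    expansion stands in for a curated 100-entry catalogue of amino-acid
    indices: the downstream encoding depends only on there being 100 finite
    scales, not on their identity, and any 100-row table can be substituted
    via :meth:`AAIndexTable.from_tsv`.
    """
    rng = np.random.default_rng(seed)
    base_ids = list(_BASE_SCALES)
    base = np.array([_BASE_SCALES[k] for k in base_ids], dtype=float)
    # standardize the base scales so mixtures are balanced
    zbase = (base - base.mean(axis=1, keepdims=True)) / base.std(axis=1, keepdims=True)
    ids = list(base_ids)
    rows = [base[i] for i in range(len(base_ids))]
    while len(ids) < AAIndexTable.N_INDICES:
        w = rng.normal(size=len(base_ids))
        mix = w @ zbase / np.sqrt(len(base_ids))
        mix = mix + 0.35 * rng.normal(size=20)
        ids.append(f"syn_mix_{len(ids):03d}")
        rows.append(mix)
    return AAIndexTable(ids, np.array(rows))


@dataclasses.dataclass(frozen=True)
class WeightedSignAAIndex:
    """Per-region weighted sign aa index: 100 (sign, C) pairs.

    ``sign[i]`` is 1 when the composition-weighted property score is
    negative, 0 otherwise; ``C[i]`` is log10 of the score magnitude floored
    at :data:`SCORE_FLOOR`.
    """

    sign: np.ndarray  # (100,) in {0, 1}
    C: np.ndarray  # (100,) log10 magnitudes
    score: np.ndarray  # (100,) raw weighted scores

    def interleaved(self) -> np.ndarray:
        """(sign_1, C_1, sign_2, C_2, ...) as a flat 200-vector."""
        out = np.empty(200, dtype=float)
        out[0::2] = self.sign
        out[1::2] = self.C
        return out


def compute_weighted_sign_aaindex(
    aac: np.ndarray, table: AAIndexTable
) -> WeightedSignAAIndex:
    """Encode a region's AAC against each of the 100 property scales.

    score_i = sum_j AAC(a_j) * h_ij; C_i = log10(max(|score_i|, floor));
    sign_i = 1 iff score_i < 0.
    """
    aac = np.asarray(aac, dtype=float)
    if aac.shape != (20,):
        raise ValueError(f"AAC vector must have shape (20,); got {aac.shape}")
    score = table.values @ aac
    sign = (score < 0).astype(float)
    C = np.log10(np.maximum(np.abs(score), SCORE_FLOOR))
    return WeightedSignAAIndex(sign=sign, C=C, score=score)


# ---------------------------------------------------------------------------
# PC-PseAAC

# The three PC-PseAAC properties over ACDEFGHIKLMNPQRSTVWY (classic values:
# hydrophobicity, hydrophilicity, side-chain mass).
_PSE_PROPS = np.array(
    [
        [0.62, 0.29, -0.9, -0.74, 1.19, 0.48, -0.4, 1.38, -1.5, 1.06,
         0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26],
        _BASE_SCALES["hydrophilicity_hw"],
        _BASE_SCALES["side_chain_mass"],
    ],
    dtype=float,
)
# standardized over the 20 acids (population SD), per PseAAC convention
_PSE_Z = (_PSE_PROPS - _PSE_PROPS.mean(axis=1, keepdims=True)) / _PSE_PROPS.std(
    axis=1, keepdims=True
)


def _pse_theta(codes: np.ndarray, lam: int) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    Theta(R_i, R_j) is the mean squared difference of the three standardized
    property values; theta_k averages Theta over all residue pairs k apart.
    """
    props = _PSE_Z[:, codes]  # (3, L)
    L = props.shape[1]
    thetas = np.empty(lam, dtype=float)
    for k in range(1, lam + 1):
        diff = props[:, k:] - props[:, :-k] if k < L else np.zeros((3, 0))
        thetas[k - 1] = np.mean(diff**2) if diff.size else 0.0
    return thetas


def compute_pseaac(sequence: str, lam: int = 8, omega: float = 0.05) -> np.ndarray:
    """PC-PseAAC vector of length 20 + lam.

    First 20 entries derive from the AAC, the last *lam* from sequence-order
    correlation factors; both are normalized jointly so the vector sums to 1:

        x_u = f_u / (sum_f + omega * sum_theta)            for u <= 20
        x_u = omega * theta_{u-20} / (sum_f + omega * sum_theta)  otherwise

    With ``lam=0`` the vector equals the plain AAC.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if len(sequence) <= lam:
        raise ValueError(
            f"sequence length {len(sequence)} must exceed lambda={lam}; "
            "use a smaller lambda or a longer sequence"
        )
    freqs = compute_aac(sequence)  # fractions already sum to 1
    if lam == 0:
        return freqs.copy()
    codes = np.array([_AA_TO_IDX[ch] for ch in sequence], dtype=int)
    thetas = _pse_theta(codes, lam)
    denom = freqs.sum() + omega * thetas.sum()
    out = np.empty(20 + lam, dtype=float)
    out[:20] = freqs / denom
    out[20:] = omega * thetas / denom
    return out


# ---------------------------------------------------------------------------
# Block assembly


class BlockMap:
    """Named, disjoint index spans inside a flat feature vector."""

    def __init__(self) -> None:
        self._spans: dict[str, tuple[int, int]] = {}
        self._cursor = 0

    def add(self, name: str, width: int) -> tuple[int, int]:
        if name in self._spans:
            raise ValueError(f"duplicate block name {name!r}")
        span = (self._cursor, self._cursor + width)
        self._spans[name] = span
        self._cursor += width
        return span

    @property
    def total_width(self) -> int:
        return self._cursor

    def span(self, name: str) -> tuple[int, int]:
        return self._spans[name]

    def items(self):
        return self._spans.items()

    def slice(self, vector: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self._spans[name]
        return vector[lo:hi]

    def to_dict(self) -> dict[str, list[int]]:
        return {k: list(v) for k, v in self._spans.items()}


#: Layout of the per-protein sequence block: AAC x 4 regions (80) +
#: weighted sign aa index x 4 regions (800) + PC-PseAAC (28) = 908.
SEQUENCE_BLOCK_WIDTH = 4 * 20 + 4 * 200 + 28


def sequence_block_map() -> BlockMap:
    bm = BlockMap()
    for region in REGION_NAMES:
        bm.add(f"aac_{region}", 20)
    for region in REGION_NAMES:
        bm.add(f"wsaa_{region}", 200)
    bm.add("pseaac", 28)
    return bm


def sequence_feature_block(
    sequence: str,
    table: AAIndexTable,
    lam: int = 8,
    omega: float = 0.05,
) -> np.ndarray:
    """Concatenated sequence-derived features for one protein.

    Fixed order: AAC for the four regions, then the weighted sign aa index
    for the four regions (sign/C interleaved per scale), then PC-PseAAC.
    """
    regions = extract_regions(sequence)
    parts: list[np.ndarray] = []
    aacs = {name: compute_aac(reg) for name, reg in regions.as_dict().items()}
    for region in REGION_NAMES:
        parts.append(aacs[region])
    for region in REGION_NAMES:
        parts.append(compute_weighted_sign_aaindex(aacs[region], table).interleaved())
    parts.append(compute_pseaac(sequence, lam=lam, omega=omega))
    out = np.concatenate(parts)
    assert out.shape == (SEQUENCE_BLOCK_WIDTH,)
    return out
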