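"""Synthetic labeled proteomes with location-dependent structure.

The generator emulates the statistical assumptions the predictor relies
on, so every stage of the pipeline is testable without any download:

* each compartment has a characteristic amino-acid composition (a Dirichlet
  mean boosting a signature residue set over background frequencies);
* a configurable fraction of proteins is multiplex (two compartments, the
  dominant real-world case), drawing residues from the mixed profile;
* GO annotations are informative-by-construction: each location owns a few
  terms that fire with high probability for its members, on top of a bank
  of noise terms;
* surface-accessibility rows link burial to hydrophobicity.

The signal is compositional (i.i.d. residues given a per-protein
composition), which matches what the composition-dominated encoders can
learn; motifs and targeting peptides are deliberately not simulated.
"""

from __future__ import annotations

import dataclasses
import numpy as np

from .data_model import STANDARD_AA, Dataset, Location, ProteinRecord
from .features_profile import SAProfile
from .layer1_svm import (
    DEFAULT_MODELS_PER_LOCATION,
    PartitionPlan,
    SubModelSpec,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate",
    "generate_sa_profiles",
    "make_separable_layer1_fixture",
    "TRAINING_PREVALENCE",
]

_AA = np.array(list(STANDARD_AA))

#: Location prevalence proportional to a realistic human training corpus
#: (cell membrane, cytoplasm, ER/Golgi, mitochondrion, nucleus, extracellular).
TRAINING_PREVALENCE = np.array([1453, 1542, 562, 462, 2064, 795], dtype=float)

# Background amino-acid frequencies (approximate vertebrate averages).
_BACKGROUND = np.array(
    [0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
     0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

# Signature residues per compartment (loosely biology-motivated: membrane
# proteins hydrophobic, nuclear proteins basic, secreted proteins
# disulfide/glycosylation-rich, ...).
_SIGNATURES: dict[Location, str] = {
    Location.CELL_MEMBRANE: "LIVFA",
    Location.CYTOPLASM: "EKDQM",
    Location.ER_GOLGI: "STPGW",
    Location.MITOCHONDRION: "RLAGH",
    Location.NUCLEUS: "KRPSQ",
    Location.EXTRACELLULAR: "CGNTY",
}

# Kyte-Doolittle hydropathy, for linking RSA to hydrophobicity.
_KD = np.array(
    [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
     1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3]
)
# Theoretical maximum ASA per residue (A^2), for converting RSA to ASA.
_MAX_ASA = np.array(
    [129.0, 167.0, 193.0, 223.0, 240.0, 104.0, 224.0, 197.0, 236.0, 201.0,
     224.0, 195.0, 159.0, 225.0, 274.0, 155.0, 172.0, 174.0, 285.0, 263.0]
)


def location_profiles(signal_boost: float = 3.0) -> np.ndarray:
    """(6, 20) Dirichlet-mean composition profiles, one per location."""
    profiles = np.tile(_BACKGROUND, (len(Location), 1))
    for loc, sig in _SIGNATURES.items():
        for ch in sig:
            profiles[int(loc), STANDARD_AA.index(ch)] *= signal_boost
    return profiles / profiles.sum(axis=1, keepdims=True)


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for one synthetic proteome."""

    n_proteins: int = 500
    length_range: tuple[int, int] = (80, 600)
    multiplex_fraction: float = 0.15  # 0.44 emulates an independent test set
    prevalence: np.ndarray = dataclasses.field(
        default_factory=lambda: TRAINING_PREVALENCE / TRAINING_PREVALENCE.sum()
    )
    signal_boost: float = 3.0
    concentration: float = 200.0  # Dirichlet concentration around the profile
    n_go_terms: int = 60
    go_terms_per_location: int = 3
    go_signal_strength: float = 0.9
    go_noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if not np.isclose(self.prevalence.sum(), 1.0):
            self.prevalence = self.prevalence / self.prevalence.sum()
        if not 0 <= self.multiplex_fraction <= 1:
            raise ValueError("multiplex_fraction must lie in [0, 1]")
        if self.length_range[0] < 80:
            raise ValueError("minimum length must be >= 80 (training filter)")
        if self.go_terms_per_location * len(Location) > self.n_go_terms:
            raise ValueError("n_go_terms too small for the informative terms")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for auditing downstream rates."""

    location_sets: dict[str, frozenset[Location]]
    profiles: dict[str, np.ndarray]
    planted_go: dict[str, frozenset[str]]
    informative_terms: dict[Location, tuple[str, ...]]
    all_terms: tuple[str, ...]

    def multiplex_fraction(self) -> float:
        n = len(self.location_sets)
        return sum(len(s) >= 2 for s in self.location_sets.values()) / n


def _go_term_bank(config: GeneratorConfig) -> tuple[dict[Location, tuple[str, ...]], tuple[str, ...]]:
    informative = {}
    counter = 1
    for loc in Location:
        ids = tuple(
            f"GO:{counter + j:07d}" for j in range(config.go_terms_per_location)
        )
        informative[loc] = ids
        counter += config.go_terms_per_location
    n_noise = config.n_go_terms - counter + 1
    noise = tuple(f"GO:{counter + j:07d}" for j in range(n_noise))
    all_terms = tuple(t for ids in informative.values() for t in ids) + noise
    return informative, all_terms


def generate(config: GeneratorConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw a labeled synthetic proteome; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    profiles = location_profiles(config.signal_boost)
    informative, all_terms = _go_term_bank(config)
    noise_terms = [t for t in all_terms if not any(t in informative[l] for l in Location)]

    records: list[ProteinRecord] = []
    truth_sets: dict[str, frozenset[Location]] = {}
    truth_profiles: dict[str, np.ndarray] = {}
    truth_go: dict[str, frozenset[str]] = {}
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        pid = f"syn{i:0{width}d}"
        if rng.random() < config.multiplex_fraction:
            locs = rng.choice(len(Location), size=2, replace=False, p=config.prevalence)
            loc_set = frozenset(Location(int(l)) for l in locs)
        else:
            loc = int(rng.choice(len(Location), p=config.prevalence))
            loc_set = frozenset({Location(loc)})
        mean = np.mean([profiles[int(l)] for l in loc_set], axis=0)
        comp = rng.dirichlet(mean * config.concentration)
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(_AA, size=length, p=comp))
        go: set[str] = set()
        for loc in loc_set:
            for t in informative[loc]:
                if rng.random() < config.go_signal_strength:
                    go.add(t)
        for t in noise_terms:
            if rng.random() < config.go_noise_rate:
                go.add(t)
        records.append(
            ProteinRecord(
                id=pid, sequence=seq, locations=loc_set, go_terms=tuple(sorted(go))
            )
        )
        truth_sets[pid] = loc_set
        truth_profiles[pid] = comp
        truth_go[pid] = frozenset(go)

    return (
        Dataset(records),
        SyntheticTruth(
            location_sets=truth_sets,
            profiles=truth_profiles,
            planted_go=truth_go,
            informative_terms=informative,
            all_terms=all_terms,
        ),
    )


def generate_sa_profiles(dataset: Dataset, seed: int = 0) -> dict[str, SAProfile]:
    """Per-residue accessibility rows with burial linked to hydrophobicity.

    RSA is beta-distributed around a residue-specific mean that decreases
    with Kyte-Doolittle hydropathy; ASA is RSA times the residue's maximum
    accessible area; a residue is classed exposed when RSA >= 0.25.
    """
    rng = np.random.default_rng(seed)
    kd_z = (_KD - _KD.mean()) / _KD.std()
    mean_rsa = np.clip(0.42 - 0.12 * kd_z, 0.05, 0.85)
    nu = 25.0  # beta concentration: modest per-residue noise
    out: dict[str, SAProfile] = {}
    for record in dataset.records:
        codes = np.array([STANDARD_AA.index(ch) for ch in record.sequence])
        mu = mean_rsa[codes]
        rsa = rng.beta(mu * nu, (1 - mu) * nu)
        asa = rsa * _MAX_ASA[codes]
        out[record.id] = SAProfile(rsa=rsa, asa=asa, exposed=rsa >= 0.25)
    return out


def _dummy_plan(models_per_location: dict[Location, int]) -> PartitionPlan:
    specs = [
        SubModelSpec(
            location=loc, model_index=i + 1, positive_ids=("_fixture",), negative_ids=()
        )
        for loc in Location
        for i in range(models_per_location[loc])
    ]
    return PartitionPlan(specs)


def make_separable_layer1_fixture(
    n: int,
    seed: int = 0,
    mu: float = 3.0,
    noise: float = 1.0,
    multiplex_fraction: float = 0.15,
) -> tuple[np.ndarray, list[frozenset[Location]], PartitionPlan]:
    """A 32-column mock layer-1 output matrix with known labels.

    Each location's sub-model columns are centered at +mu for member
    proteins and -mu for non-members, plus Gaussian noise — the shape the
    second layer expects from a well-trained first layer.  Returns
    (matrix, labels, plan) where *plan* carries the column grouping.
    """
    if n < 50:
        raise ValueError("fixture needs n >= 50")
    rng = np.random.default_rng(seed)
    plan = _dummy_plan(dict(DEFAULT_MODELS_PER_LOCATION))
    prevalence = TRAINING_PREVALENCE / TRAINING_PREVALENCE.sum()
    labels: list[frozenset[Location]] = []
    X = np.empty((n, plan.total_models))
    for i in range(n):
        if rng.random() < multiplex_fraction:
            locs = rng.choice(len(Location), size=2, replace=False, p=prevalence)
            loc_set = frozenset(Location(int(l)) for l in locs)
        else:
            loc_set = frozenset({Location(int(rng.choice(len(Location), p=prevalence)))})
        labels.append(loc_set)
        for j, spec in enumerate(plan.specs):
            center = mu if spec.location in loc_set else -mu
            X[i, j] = center + noise * rng.normal()
    return X, labels, plan
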