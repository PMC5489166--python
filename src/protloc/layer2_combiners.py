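"""Second learning layer: GANN and majority Vote combiners.

The first layer emits one output per sub-model (32 under the default
plan).  Two many-to-many combiners map that vector to a predicted set of
locations:

* **GANN** — a single-hidden-layer feed-forward network (sigmoid
  activations, 6 outputs) whose weights are evolved by a genetic algorithm
  rather than gradient descent, avoiding poor local optima of
  backpropagation on this small, noisy input.  GA hyperparameters default
  to: population 500, per-gene mutation rate 0.3, crossover rate 0.7,
  weights bounded in [-25, 25], at most 1000 generations, stopping early
  once the best mean squared error reaches 0.05.
* **Vote** — per location, strict majority over that location's own
  sub-model votes; the odd sub-model count makes ties impossible.

Both combiners always emit a non-empty location set: an empty thresholded
set falls back to the single best-supported location (every labeled
protein has at least one location, so an empty prediction is always
wrong under exact-set-match scoring).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

from .data_model import Location
from .layer1_svm import PartitionPlan

__all__ = [
    "GannConfig",
    "GannModel",
    "gann_train",
    "gann_predict",
    "PredictionSet",
    "vote_predict",
]

logger = logging.getLogger(__name__)

N_LOCATIONS = len(Location)


@dataclasses.dataclass
class GannConfig:
    """Genetic-algorithm hyperparameters for the GANN combiner."""

    population: int = 500
    mutation_rate: float = 0.3
    crossover_rate: float = 0.7
    max_w: float = 25.0
    min_w: float = -25.0
    max_generations: int = 1000
    error_target: float = 0.05
    error_metric: str = "subset"  # "subset" (exact-set-match error) or "mse"
    hidden_size: int = 16
    mutation_sigma: float = 1.0
    tournament_size: int = 3
    seed: int = 0

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GannConfig":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))

    def __post_init__(self) -> None:
        if self.min_w >= self.max_w:
            raise ValueError("min_w must be < max_w")
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.error_metric not in ("subset", "mse"):
            raise ValueError("error_metric must be 'subset' or 'mse'")
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclasses.dataclass
class GannModel:
    """Evolved network weights plus the per-generation best-fitness trace."""

    w1: np.ndarray  # (n_inputs + 1, hidden) with bias row
    w2: np.ndarray  # (hidden + 1, 6) with bias row
    config: GannConfig
    history: np.ndarray  # best MSE per generation (non-increasing, elitism)

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0] - 1

    def history_to_tsv(self, path) -> None:
        """Best-MSE-per-generation trace, for convergence plots."""
        with open(path, "w") as fh:
            fh.write("generation\tbest_mse\n")
            for gen, mse in enumerate(self.history):
                fh.write(f"{gen}\t{mse:.8g}\n")

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"input width {X.shape[1]} != network input size {self.n_inputs}"
            )
        h = _sigmoid(np.hstack([X, np.ones((len(X), 1))]) @ self.w1)
        return _sigmoid(np.hstack([h, np.ones((len(X), 1))]) @ self.w2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip to avoid overflow in exp for large |w| (weights can reach +-25)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _genome_size(n_inputs: int, hidden: int) -> int:
    return (n_inputs + 1) * hidden + (hidden + 1) * N_LOCATIONS


def _unpack(genomes: np.ndarray, n_inputs: int, hidden: int):
    """Split a (pop, genome) array into per-layer weight tensors."""
    cut = (n_inputs + 1) * hidden
    w1 = genomes[:, :cut].reshape(-1, n_inputs + 1, hidden)
    w2 = genomes[:, cut:].reshape(-1, hidden + 1, N_LOCATIONS)
    return w1, w2


def _population_mse(
    genomes: np.ndarray, Xb: np.ndarray, Y: np.ndarray, n_inputs: int, hidden: int
) -> np.ndarray:
    """Vectorized MSE of every genome's network over the training set."""
    P = len(genomes)
    n = len(Xb)
    w1, w2 = _unpack(genomes, n_inputs, hidden)
    # (n, in+1) @ (in+1, P*h) -> (n, P, h): one big GEMM across the population
    h = _sigmoid((Xb @ w1.transpose(1, 0, 2).reshape(n_inputs + 1, -1)).reshape(n, P, hidden))
    hb = np.concatenate([h, np.ones((n, P, 1))], axis=2)
    out = _sigmoid(np.einsum("nph,pho->npo", hb, w2, optimize=True))
    err = out - Y[:, None, :]
    return np.mean(err * err, axis=(0, 2))


def gann_train(
    layer1_outputs: np.ndarray,
    labels: Sequence[frozenset[Location]] | np.ndarray,
    config: GannConfig | None = None,
) -> GannModel:
    """Evolve network weights against the layer-1 output matrix.

    Fitness is the negative mean squared error between the network's six
    sigmoid outputs and the binary label vectors.  Each generation applies
    tournament selection (size 3), uniform crossover at the crossover rate,
    per-gene Gaussian mutation at the mutation rate (clipped to the weight
    bounds), and single-individual elitism, so the best fitness never
    degrades.  Evolution stops at ``max_generations`` or once the incumbent
    best reaches ``error_target`` on the configured error metric — by
    default the training exact-set-match error (fraction of proteins whose
    thresholded output set is not exactly right); ``error_metric="mse"``
    stops on the fitness MSE instead.  Fully reproducible given the seed.
    """
    config = config or GannConfig()
    X = np.asarray(layer1_outputs, dtype=float)
    if X.ndim != 2:
        raise ValueError("layer1_outputs must be a 2-D matrix")
    Y = _as_label_matrix(labels)
    if len(Y) != len(X):
        raise ValueError("labels and layer1_outputs row counts differ")
    if len(np.unique(Y, axis=0)) == 1:
        warnings.warn("degenerate labels: all proteins share one location set")

    n, n_inputs = X.shape
    hidden = config.hidden_size
    G = _genome_size(n_inputs, hidden)
    rng = np.random.default_rng(config.seed)
    Xb = np.hstack([X, np.ones((n, 1))])

    def _stop_error(genome: np.ndarray, genome_mse: float) -> float:
        if config.error_metric == "mse":
            return genome_mse
        w1, w2 = _unpack(genome[None, :], n_inputs, hidden)
        model = GannModel(w1=w1[0], w2=w2[0], config=config, history=np.empty(0))
        act = model.forward(X)
        pred = act >= 0.5
        # empty rows fall back to the argmax, matching gann_predict
        empty = ~pred.any(axis=1)
        pred[empty, np.argmax(act[empty], axis=1)] = True
        return float(np.mean((pred != (Y > 0.5)).any(axis=1)))

    pop = rng.uniform(config.min_w, config.max_w, size=(config.population, G))
    mse = _population_mse(pop, Xb, Y, n_inputs, hidden)
    best_idx = int(np.argmin(mse))
    best_genome = pop[best_idx].copy()
    best_mse = float(mse[best_idx])
    history = [best_mse]
    best_err = _stop_error(best_genome, best_mse)

    for _gen in range(config.max_generations):
        if best_err <= config.error_target:
            break
        P = config.population
        # tournament selection of parents
        tours = rng.integers(0, P, size=(2 * P, config.tournament_size))
        winners = tours[np.arange(2 * P), np.argmin(mse[tours], axis=1)]
        parents = pop[winners].reshape(2, P, G)
        # uniform crossover per pair
        do_cross = rng.random(P) < config.crossover_rate
        mask = rng.random((P, G)) < 0.5
        children = np.where(mask, parents[0], parents[1])
        children[~do_cross] = parents[0][~do_cross]
        # per-gene Gaussian mutation, clipped to the weight box
        mut_mask = rng.random((P, G)) < config.mutation_rate
        noise = rng.normal(scale=config.mutation_sigma, size=(P, G))
        children = np.clip(
            children + mut_mask * noise, config.min_w, config.max_w
        )
        # elitism: the incumbent best survives unchanged
        children[0] = best_genome
        pop = children
        mse = _population_mse(pop, Xb, Y, n_inputs, hidden)
        gen_best = int(np.argmin(mse))
        if mse[gen_best] < best_mse:
            best_mse = float(mse[gen_best])
            best_genome = pop[gen_best].copy()
            best_err = _stop_error(best_genome, best_mse)
        history.append(best_mse)

    w1, w2 = _unpack(best_genome[None, :], n_inputs, hidden)
    return GannModel(
        w1=w1[0], w2=w2[0], config=config, history=np.array(history)
    )


def _as_label_matrix(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim == 2:
        return arr.astype(float)
    Y = np.zeros((len(labels), N_LOCATIONS), dtype=float)
    for i, locs in enumerate(labels):
        for loc in locs:
            Y[i, int(loc)] = 1.0
    return Y


@dataclasses.dataclass
class PredictionSet:
    """Predicted location set (never empty) plus per-location evidence."""

    id: str
    locations: frozenset[Location]
    scores: np.ndarray  # (6,) activations or positive-vote fractions

    def __post_init__(self) -> None:
        if not self.locations:
            raise ValueError("PredictionSet must contain at least one location")


def gann_predict(
    model: GannModel, layer1_output: np.ndarray, protein_id: str = ""
) -> PredictionSet:
    """Threshold the network's activations at 0.5.

    An all-below-threshold output falls back to the argmax activation
    (ties toward the lowest location code).
    """
    act = model.forward(np.atleast_2d(layer1_output))[0]
    locs = frozenset(Location(i) for i in range(N_LOCATIONS) if act[i] >= 0.5)
    if not locs:
        locs = frozenset({Location(int(np.argmax(act)))})
    return PredictionSet(id=protein_id, locations=locs, scores=act)


def vote_predict(
    layer1_votes: np.ndarray, plan: PartitionPlan, protein_id: str = ""
) -> PredictionSet:
    """Strict per-location majority over the location's own sub-model votes.

    A location is predicted when more of its sub-models vote for it than
    against (odd m forbids ties).  Scores are positive-vote fractions; an
    empty majority set falls back to the best-supported location.
    """
    votes = np.asarray(layer1_votes, dtype=float).ravel()
    if len(votes) != plan.total_models:
        raise ValueError(
            f"vote vector length {len(votes)} != plan total {plan.total_models}"
        )
    fractions = np.zeros(N_LOCATIONS)
    included = set()
    for loc in Location:
        cols = plan.location_columns(loc)
        m = len(cols)
        if m % 2 == 0:
            raise ValueError(f"{loc.label}: even sub-model count {m} permits ties")
        positive = votes[cols].sum()
        fractions[int(loc)] = positive / m
        if positive > m / 2:
            included.add(loc)
    if not included:
        included = {Location(int(np.argmax(fractions)))}
    return PredictionSet(id=protein_id, locations=frozenset(included), scores=fractions)
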