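# Methods

## The prediction problem

A human protein may reside in one or several of six subcellular
compartments: cell membrane, cytoplasm, ER/Golgi, mitochondrion, nucleus,
extracellular.  Prediction is therefore multi-label: the output is a
*set* of locations per protein, and the headline metric — the absolute
true success rate (ATSR) — credits a protein only when the predicted set
equals the true set exactly,

    ATSR = (1/N) Σ_i Δ(i),   Δ(i) = 1 iff predicted set_i = true set_i,

penalizing over- and under-prediction alike.  Per-location rates restrict
the denominator to proteins whose true set contains the location (a
multiplex protein predicted half-right fails in every row it belongs to);
singleplex/multiplex rates split proteins by true set size 1 vs ≥ 2.

## Feature encodings

All features live in a fixed-layout vector with a named block map.

**Regions.** Four regions of each sequence: full length, first 30
N-terminal residues, middle third (centered slice of length ⌊L/3⌋
starting at ⌊(L−⌊L/3⌋)/2⌋ — "middle third" admits several placements; we
fix the centered one), last 50 C-terminal residues.  Regions overlap for
short sequences; region extraction clamps rather than fails so prediction
never aborts on short queries.

**AAC** (20 per region): residue fractions in alphabetical one-letter
order; exact count/N.

**Weighted sign aa index** (2 × 100 per region): for each of 100
amino-acid property scales h (a bank of published physicochemical scales
plus seeded synthetic mixtures standing in for a curated 100-entry
catalogue — the encoding depends only on there being 100 finite scales,
and any table can be substituted via TSV), the region's
composition-weighted score s = Σ_j AAC(a_j)·h_j is stored as the pair
(sign, log10|s|) with sign = 1 iff s < 0.  |s| is floored at 1e-6 before
the log so a vanishing score yields a finite feature; log base 10 is a
pure rescaling and does not affect the downstream SVMs.

**PC-PseAAC** (20 + λ, λ = 8, ω = 0.05): classic pseudo amino acid
composition over hydrophobicity, hydrophilicity and side-chain mass, each
standardized over the 20 acids by population mean/SD.  θ_k is the mean
squared property difference of residue pairs k apart; the joint
normalization makes the vector sum to 1 and collapse to plain AAC at
λ = 0.

**Surface accessibility** (12, optional): per region, mean relative
accessibility, mean absolute accessibility scaled by a 250 Å² cap, and
the exposed fraction, from externally supplied per-residue rows (one row
per residue, enforced).  A missing profile contributes a zero block and a
flag, never an exception.

**Sequence similarity profile** (908, optional): the sequence block of
the most similar reference protein, found by Smith–Waterman local
alignment (BLOSUM62, gap open 11 / extend 1, best raw score, ties to the
lexicographically smallest id).  Below a minimum score (default 50) the
query's own block is used.  During training the search excludes the query
itself (leave-self-out) to avoid label leakage through duplicated
feature rows.  An external-tool adapter accepts precomputed
(query, subject, score) tables.

**GO block** (k = 35, optional): binary presence of k selected GO terms.
Terms are selected by a greedy multi-label mRMR: relevance = mean mutual
information with the six one-vs-rest membership indicators, redundancy =
mean MI with already-selected terms, objective = relevance − redundancy
(MID).  MI is computed from empirical 2×2 counts with 0·log 0 = 0 and no
pseudo-counts, so the selection is exactly reproducible by enumeration;
ties break to the smallest GO id.  The ranking depth (default 50) and k
are both configurable.  Queries without direct annotations inherit terms
from the most similar annotated protein; with nothing recoverable the
block is zero plus a flag.

## The two layers

**Layer 1 — one-to-one.** Each location trains an odd number m ∈ [3, 9]
of binary RBF-SVM sub-models (defaults 5,5,5,5,7,5 → 32 models).  All m
share the location's full positive set; the negatives are shuffled and
split into m disjoint near-equal chunks, so every negative is used
exactly once — no information is discarded — while each sub-model sees a
more balanced class ratio.  An optional sweep picks (ratio, m) per
location by cross-validated *balanced* membership accuracy of the
majority-voted sub-ensemble (plain accuracy would let the majority class
dominate and always prefer the full imbalance); during the sweep only,
chunks are capped at ratio × positives.  SVM kernel and C/gamma are
configurable; defaults are RBF, C = 1, gamma = "scale".

**Layer 2 — many-to-many.**  Two combiners map the 32 sub-model outputs
to a location set:

* *GANN*: a feed-forward network (32 → 16 hidden → 6, sigmoid) whose
  weights are evolved by a genetic algorithm — population 500, per-gene
  Gaussian mutation at rate 0.3 (σ = 1), uniform crossover at rate 0.7,
  tournament selection (size 3), single elitism, weights clipped to
  [−25, 25], at most 1000 generations.  Fitness is −MSE between the six
  outputs and the binary label vector.  The stop target "error ≤ 0.05" is
  applied by default to the training exact-set-match error (MSE-based
  stopping is available but halts while the thresholded predictions are
  still far from correct, which defeats the point of the target); GANN
  consumes the sub-models' signed decision values, the richer signal.
* *Vote*: per location, strict majority over that location's own
  sub-model hard votes; odd m makes ties impossible.

Both combiners always emit ≥ 1 location: an empty thresholded/majority
set falls back to the best-supported location (every labeled protein has
a location, so an empty set is always wrong under ATSR).  The deployment
default trusts GANN when it predicts exactly one location and Vote
otherwise, an operational rendering of "network for singleplex, vote for
multiplex" when the query's plexity is unknown a priori.

## Training protocol and anti-leakage

The GANN must not be trained on layer-1 outputs produced by sub-models
that saw the same protein (resubstituted outputs are optimistically
clean and would inflate every rate).  Training therefore splits the data
into inner stratified folds, fits layer 1 on each fold complement, and
scores the held-out fold; the out-of-fold decision values form the GANN
training matrix.  Per-protein provenance (which ids the producing
sub-models saw) is recorded and audited.  Layer 1 is refit on the full
training set for deployment.  `nested_cv` wraps this in outer stratified
folds (iterative multi-label stratification: labels dealt rarest-first to
the fold with the greatest remaining demand) and scores each outer test
fold end-to-end; it raises on any provenance violation.

## Synthetic proteomes

The generator emulates the structure the method assumes: each location
has a Dirichlet-mean composition profile (background vertebrate residue
frequencies with a signature residue set boosted ×3 by default, e.g.
hydrophobic residues for the membrane, basic for the nucleus); a protein
draws its composition from the Dirichlet (concentration 200) centered on
the mean of its locations' profiles and emits i.i.d. residues (length
uniform in 80–600, matching the ≥ 80 training filter); location sets are
singletons except for a configurable multiplex fraction (default 0.15
for training-like data, 0.44 for test-like data) of two-location sets
drawn by prevalence (proportional to a realistic human corpus:
1453/1542/562/462/2064/795).  Three GO terms per location fire with
probability 0.9 for members over a bank of noise terms firing at 0.05.
Accessibility rows tie burial to Kyte–Doolittle hydropathy.

Because residues are i.i.d. given the composition, the planted signal is
purely compositional: passing end-to-end tests shows the pipeline
recovers compositional and annotation signal, not that it would resolve
motif- or targeting-peptide-driven localization in real proteomes, and
synthetic rates are not comparable to rates on curated protein data.

## Problem sizes and numerical choices

End-to-end checks run at desk scale as the package's own choice: nested
five-fold CV on 600 proteins, holdout evaluation 600-train/300-test,
GANN capped at 150 generations inside CV (the full 1000-generation budget
is exercised separately on a mock separable layer-1 fixture).  In those
configurations the similarity-profile and accessibility blocks are
disabled — SSP needs ~n² alignments and adds little on compositional
data where every protein's own block already carries the signal.  The
"strong-signal" end-to-end fixtures use signature boost 5 and
concentration 300.  Degenerate inputs are handled as: empty regions →
zero AAC + flag; score 0 → log floor; constant GO columns skipped with a
log note; single-class SVM training sets and even vote counts are
errors.  All stochastic components take explicit seeds; identical seeds
give bit-identical models and byte-identical prediction files.

## Known limitations

* Compositional synthetic data cannot certify performance on real
  proteomes (no homology structure, no motifs, no annotation bias).
* GO terms are matched verbatim; no ontology ancestor propagation.
* The per-location sub-model counts and ratios are config defaults, not
  values fitted to any real corpus.
* The GA is a global optimizer run at fixed budgets; on hard layer-2
  problems it may stop at the generation cap rather than at the error
  target.
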