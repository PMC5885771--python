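# Methods

## Problem and model

The package classifies small molecules as bitterants (activating at least
one Tas2R bitter-taste receptor) or non-bitterants, from 2D structure alone.
The model family is classical fingerprint QSAR: a binary circular
fingerprint per molecule, a supervised classifier per hyperparameter grid
point, and an ensemble layer that averages probabilities over models trained
on repeated random splits.

## Fingerprint engine

Fingerprints are generated natively rather than delegated to an external
toolkit so that every bit remains traceable to its substructure.

- **Initial invariants.** Per heavy atom: atomic number, heavy-atom degree,
  attached-hydrogen count, formal charge, ring membership, and the Sybyl
  atom type string. Explicit hydrogens are always folded into the
  attached-H count; only heavy atoms carry identifiers.
- **Hash.** A fixed, seedless 32-bit BLAKE2b digest of the canonicalized
  tuple. This makes fingerprints bit-exact across runs and platforms. Bit
  *positions* are internal to this engine; correctness is established at the
  level of retained environments (below), not bit equality with other ECFP
  implementations, whose invariant sets and hashes differ anyway.
- **Iteration.** Round r rehashes (r, own identifier, sorted list of
  (bond-order code, neighbor identifier) pairs). Sorting by bond order then
  identifier is the standard tie-break.
- **Environments and duplicate removal.** The radius-r environment of an
  atom comprises all atoms within graph distance r and every bond whose
  nearer endpoint lies at distance ≤ r−1 (this includes perimeter-closing
  ring bonds). A candidate feature is discarded when its bond set equals
  that of an already-retained feature — earlier radius wins; within a
  radius, the smaller identifier wins. Radius-0 features have empty bond
  sets and instead deduplicate by identical identifier.
- **Folding.** bit = identifier mod k, k ∈ {1024, 2048}. A collision flag
  records when two distinct retained identifiers share a bit; nullification
  (below) therefore acts on all of them together, and the attribution
  report surfaces the collision.

Correctness is checked two ways: an independent brute-force BFS enumerator
(no hashing) must produce identical (radius, atom set, bond set) retained
environments on all fixture molecules up to 8 heavy atoms, and RDKit's
Morgan enumeration must yield the same radius ≥ 1 bond sets on probe
molecules. Ethanol at diameter 4 retains exactly six features (three at
radius 0, three at radius 1; every radius-2 environment duplicates the
whole-molecule bond set).

## Data handling

MOL2 is the native format (Sybyl types are an initial invariant, so the
parser is in-house; RDKit's MOL2 path discards them). The writer re-expands
attached hydrogens and stores the taste label as a `# label:` comment, so
read∘write is the identity on heavy-atom graph, Sybyl types and labels.
Formal charges are read from the ATOM charge column when near-integral;
partial charges are not modeled.

Curation applies four rules: reject multi-component structures (salts);
reject molecules with elements outside {C, H, O, N, S, P, Si, F, Cl, Br, I};
drop *all* copies of a structure appearing under both labels; keep the first
occurrence of within-label duplicates. Duplicate detection uses a
Weisfeiler–Lehman graph hash over (element, charge, attached-H) node labels
and bond-order edge labels — permutation-invariant, and for graphs of this
size collision-free in practice.

Molecular weight and Lipinski H-bond donor/acceptor counts use simple
counting rules (donors: O/N with ≥ 1 H; acceptors: all O and N). logP is
deliberately out of scope.

## Splitting protocol

One *scheme* = a stratified 20% test draw (per class,
floor(0.2 × class size), so 707/592 compounds give a 141/118 test set and a
566/474 CV pool) plus a stratified 5-fold partition of the CV pool.
Per-class fold remainders are assigned to the folds with the smallest
running totals, so overall fold sizes also differ by at most one (the
1,040-compound pool gives five folds of exactly 208). Scheme i uses seed
base_seed + i; defaults are 19 schemes for KNN/SVM/RF/GBM and 3 for the
neural networks.

## Learners and selection

Grids (defaults): KNN K ∈ {1,3,…,15} × {uniform, distance}; RBF-SVM
C ∈ {1e3…1e5} × γ ∈ {1e-4…0.1}; RF and GBM trees ∈ {10, 50, 100…1000},
GBM learning rate ∈ {0.1…0.9}; neural networks epochs {100…600} ×
batch {60…160} × regularization (5 values). For each grid point the mean F1
over the five internal-validation folds is computed (single-class folds are
excluded with a warning); the argmax wins, ties resolving to the first
point in enumeration order, and the final model is refit on the whole CV
pool at those hyperparameters. Mean-over-folds (rather than max) and the
refit are the package's choices where the protocol is ambiguous; the refit
makes ΔF1 well-defined for a single final model.

The deep learners are scikit-learn `MLPClassifier` networks: 2 or 3 hidden
layers of width equal to the input width, ReLU, adam. Their regularization
axis is an L2 penalty (alpha ∈ {1e-5…1e-1}) because dropout is not exposed
by MLPClassifier; depth, width, activation, optimizer and the 6×6×5 grid
shape are preserved. SVM probabilities come from Platt-style calibration
fit within the training data (`SVC(probability=True)`); KNN, RF, GBM and
the MLPs are natively probabilistic.

Feature selection takes the top 512/256/128 bits by normalized RF
importance, where the RF was trained on the *same scheme's* CV data with
full features — the held-out test set never influences selection. Ties in
importance resolve to the smaller bit index.

## Ensembles

Average models (AM) group same-configuration models across schemes and
report per-metric mean (std). Consensus models: CM01 takes the best
individual model of each scheme by test F1; CM02 the best AM of each method
family (the two network depths pooled into one family to give five
constituents); CM03 the top-5 AMs overall; CM04–CM09 the top-5 AMs within
KNN, SVM, GBM, RF and each network depth. Prediction averages constituent
probabilities (descending into AM members) and thresholds at 0.5, bitter
winning the exact tie; hard-label majority voting is intentionally not the
default because probability averaging is what the consensus metric
semantics (mean over constituents) correspond to.

Model comparisons use the two-sample Student (equal-variance) t-test on
per-scheme F1 samples with significance at p < 1e-4. Two zero-variance
samples with equal means report p = 1.

## Validation apparatus

- **Y-randomization.** CV labels are permuted uniformly (class totals
  preserved — the expected fraction of accidentally-correct labels is
  (n₁² + n₀²)/n², ≈ 0.504 at 566/474), the grid is retrained, and the
  models are evaluated on the untouched test set. Reliable originals
  collapse to MCC ≈ 0.
- **Applicability domain.** Mean Tanimoto similarity to the five nearest CV
  compounds, on the 2048-bit diameter-6 fingerprint by default (most
  features, fewest collisions); n = 5 mirrors the optimal K of the best
  full-feature KNN model. Strictly above 0.1 is in-domain. Self-queries
  exclude the query from its own neighbor list. Ties at the n-th rank
  resolve to the lower compound index.
- **Attribution.** w_i = P(bitter|x) − P(bitter|x, bit i := 0), defined
  only for set bits, bounded in [−1, 1]. Finite differences are not
  additive, so no conservation property is asserted.

## Metric display

NA (zero-denominator) metrics print as "–". Display rounding is three
decimals, half-even: the reference benchmark tables print 18/32 = 0.5625 as
0.562 (excluding half-up) and 30/52 = 0.57692 as 0.577 (excluding
truncation), so half-even is the only convention consistent with them.

## Synthetic fixture generator

The generator emulates the *shape* of a taste-labeled corpus: random
connected heavy-atom graphs of 3–12 atoms over {C, N, O} (random spanning
tree, occasional single-bond ring closure and C=C upgrade, valences
respected), with the bitter class carrying a thioamide-like N–C=S motif
attached at its carbon. Sulfur appears only in the motif, so the motif's
terminal =S atom environment — constant degree, H-count, type — gives a
single known fingerprint bit separating the classes perfectly before noise.
Labels are then flipped independently with probability 0.05 by default,
emulating panel noise; 200 molecules per class is the default library size.
Structure keys are unique across a library (collisions re-rolled), so
curation passes losslessly.

What this does *not* emulate: realistic drug-like property distributions,
scaffold redundancy between classes, multi-feature structure–activity
relationships, or class overlap beyond label noise. Passing tests therefore
demonstrate the correctness of the machinery (splitting, selection,
ensembling, attribution, collapse under label permutation), not the
attainable accuracy on real taste data — the published headline accuracies
depend on the original compound collection, which is not redistributable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the campaign at desk scale:
one fingerprint setting (diameter 4, 1024 bits), KNN/RF/GBM with reduced
grids, three splitting schemes, full features, a 400-molecule library and
ten label shuffles. The full-campaign bookkeeping (328 + 984 = 1,312
models, 96 AMs, 76 RF importance runs) is verified analytically by the
dry-run planner, which is exact by construction. All stochastic components
(splits, shuffles, forest seeds, network initialization) derive from a
single base seed; scheme i uses base_seed + i and shuffle s uses
base_seed + 1000 + s.

Known limitations: no stereochemistry, no counted-feature (ECFC) or
functional-class fingerprint variants, no tautomer/protonation handling,
no logP, and aromatic perception is taken from the input file (MOL2 bond
type `ar`) rather than recomputed.
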