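# Methods

## Problem setting

Disease-gene identification from confirmed disease genes is a
positive-unlabeled (PU) learning problem: a set *P* of confirmed disease
genes exists, but there is no confirmed non-disease gene set — the
remaining genome is an unlabeled set *U* that itself contains unknown
disease genes.  Training a binary classifier with *U* as the negative
class therefore learns from mislabeled examples.  This package instead
grades *U* by how likely each gene is to be a hidden positive, and feeds
those grades into a classifier that penalises errors according to label
confidence.

## Gene representation

Each gene *g* is a concatenated vector **V**_g = (D, MF, BP, CC, PPI):

* **D** — binary membership over a fixed ordered list of protein-domain
  accessions (Pfam-A-style identifiers).
* **MF / BP / CC** — one entry per ontology feature term *t*:
  max over the gene's annotated terms *f* of sim(*f*, *t*), the DAG
  semantic similarity below.  Genes with no annotations in a namespace
  get zeros there rather than being dropped.
* **PPI** — degree, the fraction of direct neighbours that are known
  positives (1N), the same fraction over the radius-1-or-2 neighbourhood
  excluding the gene itself (2N), and the clustering coefficient.  The
  block is min-max scaled to [0, 1] with ranges fitted on training genes
  only (and clipped for out-of-range test genes), so that Euclidean
  distances weigh all blocks commensurately — the other blocks are
  already in [0, 1].

### Ontology term similarity

For a term *A* in one namespace DAG, every ancestor *t* receives an
S-value: S_A(A) = 1 and
S_A(t) = max over children t′ of t inside the ancestor closure of
w_e(t→t′) · S_A(t′), with edge factors w_is_a = 0.8 and
w_part_of = 0.6.  Where a term has several children inside the closure,
the maximum over all of them is taken (equivalently, the best decayed
path from *A*).  The similarity of two terms is
Σ_{t ∈ T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)) with
SV(X) = Σ S_X(t): symmetric, in [0, 1], exactly 1 for identical terms.
S-values are computed by dynamic programming in topological order and
verified in the tests against exhaustive path enumeration; ancestries and
pair similarities are memoised per DAG.

## Feature selection

Each D/MF/BP/CC feature *f* receives affinity frequencies af(*f*, P) and
af(*f*, U): the mean association score over the set's genes, where the
association is binary membership for domains and the maximal term
similarity for ontology features.  Division by the set size (default on)
keeps the two frequencies comparable when |P| ≠ |U|.  The discrimination
ability score is

    da(f) = max(af_P, af_U) · |af_P − af_U| / (af_P + af_U),

zero when both frequencies vanish.  This form realises the qualitative
contract a discrimination score must satisfy — large when a feature is
frequent in exactly one of the two sets, small when it is frequent in
both or rare in both — and is isolated behind a single function so an
alternative (e.g. |af_P − af_U|² / (af_P + af_U)) can be substituted.
The top N features per category (default N = 1000; clamped when a
category is smaller) are kept, ties broken lexicographically so selection
is deterministic and order-invariant; the four PPI features are always
retained.

## Partitioning the unlabeled set

1. **Reliable negatives.**  The positive representative vector **pr** is
   the normalised component-wise sum of the positive vectors.  Two
   normalisations are implemented: division by |P| (the class centroid,
   default) and scaling to unit Euclidean norm.  The centroid is the
   default because distance to a unit-norm representative is dominated by
   each gene's own vector norm when annotation counts vary —
   dist(pr, v)² = ‖v‖² − 2 pr·v + 1 with ‖v‖ ≫ 1 — which empirically
   makes the filter uninformative (on synthetic studies it selects hidden
   positives into RN at above-chance rates), whereas distance to the
   centroid measures genuine dissimilarity from a typical positive.
   Unlabeled genes strictly farther from **pr** than the mean unlabeled
   distance form RN.
2. **Similarity network.**  Over P ∪ U,
   W_ij = exp(−‖V_i − V_j‖² / 2σ²) with σ defaulting to the median
   nonzero pairwise distance (configurable); each node keeps its Q = 10
   largest-weight neighbours, and the kept edges are union-symmetrised.
   Since the kernel is a monotone function of distance, Q-neighbour
   selection is equivalent to Q-nearest-neighbour selection; the kernel
   shape only sets the retained edge weights.
3. **Label propagation.**  Priors: +1 on each positive, −|P|/|RN| on
   each reliable negative (total mass +|P| and −|P|), 0 elsewhere.  With
   S = D^(−1/2) W D^(−1/2) (isolated nodes get zero rows), iterate
   G_r = α S G_{r−1} + (1−α) G_0 with α = 0.8 until the L1 change drops
   below ε = 1e−6 (cap 1000 iterations; non-convergence returns the last
   iterate with a warning).  The iteration is a contraction for α < 1 and
   converges to (1−α)(I − αS)^(−1) G_0, which the tests verify by direct
   linear solve.  Symmetric normalisation is used rather than the row
   normalisation D^(−1)W, and α weights the graph term — the standard
   formulation of this label-propagation family.
4. **Split.**  Remaining genes with positive steady-state score are
   likely positives (LP); among non-positive scores, those at or below
   their mean are likely negatives (LN) and the rest weak negatives
   (WN).  RN ∪ LP ∪ LN ∪ WN = U, pairwise disjoint, on every run.

## Multi-level weighted SVM

Training labels are +1 for P ∪ LP and −1 for RN ∪ LN ∪ WN.  The
soft-margin objective ½‖w‖² + Σ_i C_set(i) ξ_i applies a per-example
penalty equal to its set's factor, implemented as per-sample weights on a
unit base C (linear kernel by default; RBF available).  Default factors
C_P = 1.0, C_LP = 0.5, C_RN = 1.0, C_LN = 0.5, C_WN = 0.25 respect the
confidence orderings C_P ≥ C_LP and C_RN ≥ C_LN ≥ C_WN.  The orderings
are enforced non-strictly so that a collapsed profile (all factors equal)
reduces exactly to a plain two-class soft-margin SVM, which the tests
check against an independent fit.  An optional grid search selects the
factors by k-fold cross-validation on P (held-out positives) versus RN
(held-out negatives), maximising mean F-measure with ties broken toward
smaller penalties; the search is seeded and LP/LN/WN always remain on the
training side.

Decision scores map to probabilities through a Platt sigmoid fitted on
out-of-fold decision scores (3-fold, P positive vs RN negative) with the
slope constrained positive, so probability ranking always equals score
ranking.  A decision score of exactly zero is labeled non-disease.

## Evaluation protocol

k-fold cross-validation (default k = 10; k = 3 suits small positive
sets) draws folds separately over P and U.  Every training-side quantity
— the feature space, discrimination scores, the PPI min-max ranges, the
1N/2N known-positive set, the network bandwidth σ, and any penalty
search — is recomputed inside the training fold, so held-out positives
cannot leak into training features (asserted by a dedicated test).  Test
folds are scored with P-membership as ground truth; precision, recall and
F = 2pr/(p+r) are averaged over folds and a ROC curve is pooled from the
calibrated probabilities.  The `balance` option subsamples U to
|P| = |U| once per run, seeded.

## Synthetic studies

The generator emulates the five study inputs with a planted signal:

* per namespace, a rooted tree-like DAG of 60 terms (each non-root term
  has one uniformly chosen earlier parent, a second with probability 0.2;
  edges are `part_of` with probability 0.3, else `is_a`), with a hidden
  disease subset of 8 non-root terms;
* 600 genes, each with 1 + Poisson(4) annotations per namespace and
  1 + Poisson(1) domains from a pool of 50 (10 disease domains); planted
  disease genes sample disease terms/domains with weight ratio
  (enrichment odds) 6 : 1, background genes uniformly;
* an Erdős–Rényi PPI layer with mean degree 6 plus extra edges between
  pairs of planted disease genes with probability 0.05 (disease proteins
  cluster);
* 100 visible positives and round(ρ/(1−ρ)·100) = 43 hidden positives
  relabeled into U at contamination ρ = 0.3, recorded in a truth list.

These defaults are chosen to mimic a moderately informative study: the
planted annotation signal is strong enough that features separate classes
well, while ~9 % of U being hidden positives materially corrupts a naive
P-vs-U classifier.  Regeneration with the same parameters and seed is
byte-identical.  What the generator does **not** emulate: realistic
ontology depth and fan-out, annotation incompleteness bias (shallow or
missing annotation for poorly studied genes), scale (tens of thousands of
genes and terms), PPI degree heavy tails and study bias, or correlated
annotations across namespaces.  Passing the recovery benchmark therefore
demonstrates the machinery behaves as designed under a known generative
model, not performance on real curated resources.

### Benchmarks

*Hidden-positive recovery* (default study, 10 seeds): the pipeline runs
on P and U, and the SVM decision scores over U are assessed against the
truth list — (i) ranking AUC of hidden positives versus true negatives,
expected ≥ 0.8; (ii) F-measure at the score-zero threshold on a balanced
held-out test set (all hidden positives against an equal-size seeded
sample of U's true negatives), compared with a naive P-vs-U SVM control
evaluated identically.  The balanced composition mirrors the standard
|P| = |U| evaluation protocol for this task; on the raw ~10:1 imbalanced
U both methods' precisions are dominated by the negative majority and
the comparison degenerates.  *Null control* (10 seeds): with enrichment
odds 1 and PPI bias 0 the same AUC sits at 0.5 ± 0.1.

Problem sizes (600 genes, 60-term namespaces, 10 seeds per benchmark,
10-fold CV on one balanced study) were chosen so a full benchmark run
completes in well under a minute on a laptop while keeping fold sizes
statistically meaningful.

## Numerical choices and degenerate inputs

* Similarity identity sim(A, A) returns exactly 1.0 (bypassing float
  summation order effects); memoised and fresh computations agree
  exactly.
* An all-zero positive matrix has no representative (error); a single
  unlabeled gene can never exceed the mean distance (RN = ∅), and an
  empty RN is fatal with guidance, since propagation priors require both
  mass sources.
* σ falls back to 1.0 when all pairwise distances are zero; Q ≥ n−1
  yields a complete graph with a warning.
* Prior mass conservation (Σ G_0 = 0) holds by construction; in floating
  point the residual is at rounding level (≲ 1e−12·|P|), which is what
  the tests assert.
* Tie at the top-N selection cutoff: lexicographically smaller feature id
  wins.  Tie at the SVM decision threshold: score 0 → non-disease.
* Calibration falls back to the identity sigmoid when folds are
  infeasible or the fitted slope is non-positive.

## Known limitations

* The discrimination-score surrogate and the LP/LN/WN thresholds are
  reasonable members of their design families, not uniquely determined;
  both are isolated behind single functions and configurable.
* 2N uses the radius-2 neighbourhood excluding the gene itself; including
  the gene would shift the proportion slightly for positives.
* The pipeline is transductive over the supplied U for partitioning;
  scoring genes outside P ∪ U uses a model trained on the supplied sets.
* Feature matrices are dense; studies beyond ~10⁴ genes × 10⁴ features
  would need a sparse or blocked representation.
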