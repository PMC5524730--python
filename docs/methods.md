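# Methods

## Model overview

`sweetgate` treats sweetness prediction as a routed two-tier decision.
Structurally homogeneous sweetener families are handled by an unsupervised
similarity rule; the heterogeneous remainder is handled by a supervised
consensus with a rejection option. The two tiers fail differently — the
gate can only produce false sweets when a non-sweet analog of a sweetener
scaffold appears, while the consensus trades coverage for precision — and
the applicability domain is assessed per tier.

### Fingerprints

Circular (Morgan-style) substructure features up to radius `max_order = 2`
are hashed into a 2048-bit presence/absence vector, with each feature
setting `bits_per_pattern = 2` positions via salted 64-bit BLAKE2b double
hashing. Two hash positions per feature halve the effective collision rate
at a given density, at the cost of doubling it per feature; the choice is
conventional for dense similarity screening. Disconnected structures
(salts) contribute the union of their fragments' features, which is the
natural presence/absence semantics and is what the sparse feature
enumeration produces automatically. Whether "maximum pattern length"
denotes radius or diameter differs between toolkits; here it is the radius
and is configurable.

### Similarity gate

A cluster reference is a set of member fingerprints plus a distance cutoff.
The gate computes the average Jaccard–Tanimoto distance of the query to
each reference and classifies the query sweet when a cutoff is satisfied
with **strict** inequality (a distance exactly at the cutoff passes to the
consensus). Two combination rules are provided because the natural-language
description of the rule is genuinely ambiguous between AND and OR; the
default is `any` (OR), which matches the rationale that similarity to
*either* homogeneous sweet family is sufficient evidence. Shipped default
cutoffs are 0.6 (S1) and 0.8 (S2); a histogram-gap derivation
(`derive_threshold`: midpoint of the widest empty gap separating member
distances from the rest, with a configurable fallback) is available when
references are built from new data.

Reference clusters can be supplied explicitly, taken from generator ground
truth, or discovered: classical MDS of the Tanimoto distance matrix,
k-medoids with k chosen by silhouette, then clusters with ≥ 90% sweet
purity and ≥ 10 members (largest two) become S1/S2. Discovery replaces a
visual identification step and is deliberately conservative; with no
qualifying cluster the system degrades to pure consensus.

### Classical MDS

Torgerson double-centering with eigendecomposition. Tanimoto distance
matrices are generally non-Euclidean, so negative eigenvalues occur; they
are clipped to zero for the explained-variance fractions (reported as a
share of the positive spectrum) and the embedding uses only positive
eigenvalues. Requesting more dimensions than the positive rank truncates
with a warning.

### N3

Similarity is s = 1 − d with d the average Euclidean distance on
range-scaled descriptors, so both are bounded in [0, 1]; this is the
minimal conversion consistent with the named scaling and metric. Ranks are
assigned by decreasing similarity with tied blocks receiving the average
rank, which makes the classifier independent of training-row order.
Queries outside the training range are clipped to [0, 1] per column. A
query with zero total contribution receives uniform scores with a warning.
Exact class-score ties are rejections. Alternative neighbor-weighting
normalizations exist in the literature; the scoring function is isolated in
one method so a variant is a one-function change.

### PLSDA

NIPALS PLS2 on autoscaled descriptors (sample, n−1, standard deviation —
configurable) against a two-column {1,0}/{0,1} class dummy, assignment by
the larger predicted response, exact ties rejected. For one latent variable
the first weight vector has the closed form w ∝ Xᵀy (centered class
indicator), which the tests use as an oracle; training scores are mutually
orthogonal by construction and this is asserted to 1e-8. The score matrix
is retained for leverage computations.

### Cross-validation and hyperparameters

Venetian-blinds CV assigns sample i to cancelation group i mod G (G = 5 by
default); a training fold losing a class is an error with advice to
interleave classes rather than silently re-splitting. The N3 exponent α
(grid 0.5…3.0 by 0.5) and the PLSDA latent-variable count (grid 1…10) are
chosen by the lowest CV error rate 1 − NER, with ties broken toward the
simpler model — fewer latent variables, larger α (fewer effective
neighbors). Shipped defaults are α = 1.5 and 1 LV.

### V-WSP reduction

Distance 1 − |r| on the correlation matrix. The first seed is the
descriptor with the highest mean absolute correlation to all others
(removing the densest redundancy first; the reference algorithm leaves
seed choice open, and the alternative `first` rule is provided). The seed
is retained, every descriptor with |r| ≥ threshold to it is removed (with
1e-12 slack so exact duplicates fall at threshold 1.0), and the nearest
survivor becomes the next seed. All argmax ties break lexicographically by
descriptor name, which makes the output invariant to column order. The
post-conditions — retained pairs all below the threshold, every removed
descriptor represented by a retained one at or above it — are asserted in
tests over random correlated matrices.

### GA-VSS

Chromosomes are descriptor subsets capped at 15 variables; fitness is the
venetian-blinds CV NER of the coupled classifier (PLSDA by default, N3
plugs in unchanged). Defaults: population 30, 100 generations, uniform
crossover with probability 0.5, per-gene mutation 0.01, binary tournament
selection, elitism of 1 (making the best-so-far trace monotone
non-decreasing), all config-exposed; these are conservative small-model
QSAR conventions. Fitness evaluations are cached by subset; a chromosome
whose evaluation fails is discarded with a log entry.

Because the fold assignment is fixed, CV NER is a deterministic, discrete
criterion that wrapper search can overfit: the winning chromosome tends to
carry nuisance variables that happen to raise the CV score. The final
refinement therefore applies a **one-standard-error backward elimination**:
variables are removed greedily (best removal first) while the pruned
model's CV NER stays within one binomial standard error of the best
(SE = ½·sqrt(Sn(1−Sn)/n₁ + Sp(1−Sp)/n₂)). This is the classical
parsimony rule; it is configurable (`prune`, `prune_se_factor`) and on by
default. Two-stage (blockwise) selection runs the GA inside each descriptor
block, merges the survivors and reruns the GA on the union; a single-block
table degenerates to the plain run. Among candidate final models,
`rank_selection_results` prefers NER first and then the smallest |Sn − Sp|,
reflecting the balance criterion between sweet-class sensitivity and
specificity.

### Metrics and validation

Sensitivity and specificity of the sweet class are computed over assigned
molecules only; not-assigned molecules are excluded from both numerator and
denominator and reported as a separate percentage. This exclusion is the
only convention under which a high NER and a ~20% rejection rate are
simultaneously coherent, and the identity NER = (Sn + Sp)/2 is asserted at
report construction. Stratified splitting allocates per-class test counts
by largest-remainder rounding, which reproduces exactly the (108, 53)
allocation of 161 test molecules over classes of 435/214. Monte Carlo
validation draws stratified 80/20 splits, refits per iteration and pools
predictions across iterations before computing metrics once; per-iteration
seeds derive from a master seed, failed iterations are skipped with a
warning, and more than 5% failures aborts. By default the cluster
references and gate thresholds stay fixed from the initial fit while the
consensus classifiers are refit per iteration (the gate is calibrated once,
before validation); a full-refit mode rediscovers clusters each time.

### Applicability domain

Gate-path molecules are in-domain by definition. Consensus-path molecules
are checked on two branches: leverage h = tᵀ(TᵀT)⁻¹t in PLSDA score space
against the common cutoff h* = 3·LV/n_train (the mean training leverage is
LV/n_train, verified numerically), and average similarity to the N3
training set against the 5th percentile of the training self-similarities
(percentile configurable). Both sub-verdicts are reported; the default
requires both branches (`ad_rule="both"`), with `either` available, because
the two branches guard different failure modes (extrapolation in the linear
model's score space vs. local isolation for the neighbor model).

## Synthetic benchmark

The generator emulates exactly the features the method exploits: planted
sweet clusters whose members share a 200-bit scaffold block of the 2048-bit
vector plus 50 private bits each (within-cluster Tanimoto ≈ 0.67, distance
≈ 0.33, comfortably inside the 0.6 gate), a background of independent
250-bit molecules (distance ≈ 0.93 to any cluster, outside both gates), and
descriptors in which 6 of 100 carry a 1.5-SD class mean shift while the 94
nuisance descriptors are block-correlated at 0.7 through shared latent
factors. Molecules are shuffled so interleaved CV folds keep both classes.
Defaults: clusters of 40 + 40 over a 150/150 background (380 molecules);
the descriptor-only variant used for selection experiments drops the
clusters (n = 300).

What it does **not** emulate: realistic bit densities and collision
structure of hashed chemical fingerprints, descriptor distributions that
are skewed, discrete or bounded rather than Gaussian, label noise
(multisapophoric molecules whose taste depends on concentration), and any
structural correlation between fingerprint space and descriptor space.
Passing tests therefore demonstrate algorithmic correctness and the
method's behavior under its own assumptions, not field performance on real
taste panels — the synthetic class signal is deliberately clean, so
absolute NER values on the benchmark run higher than one should expect on
experimental data.

## Numerical choices and degenerate inputs

Strict inequality at gate thresholds; exact classifier ties are rejections,
not coin flips. Two empty fingerprints have similarity 1 (identical
objects, warned). Constant descriptor columns are errors at scaling time
and must be removed by the cleaning step (most frequent value occupying
> 95% of rows, cutoff configurable). Range-scaled test values are clipped
to [0, 1]. NIPALS uses a 1e-12 convergence tolerance and refuses more
latent variables than the scaled matrix rank. Distance matrices are
symmetrized and clipped to [0, 1] against floating-point drift.

## Known limitations

* Gate quality is entirely determined by the reference clusters; automated
  discovery is conservative and can return fewer than two clusters, which
  silently reduces coverage of the gate tier.
* The strict consensus trades ~20% coverage for precision; callers needing
  full coverage must fall back on the component predictions themselves.
* Fingerprint hashing here is a self-contained scheme; bit-level identity
  with any specific commercial fingerprint implementation is not a goal,
  only the preservation of similarity structure.
* Descriptor tables are consumed as input; the package does not compute
  molecular descriptors beyond fingerprints.
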