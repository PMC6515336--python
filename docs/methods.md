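# Methods

This note documents the modeling pipeline implemented by `diliqsar`, the
assumptions behind each stage, the defaults and why they are what they are,
and what the synthetic test data can and cannot demonstrate.

## The problem

Drug-induced liver injury (DILI) is a leading cause of attrition in drug
development and of post-market withdrawals. The package implements a binary
QSAR (quantitative structure–activity relationship) classifier: given a
compound structure, predict whether it is hepatotoxic (positive) or not
(negative). Because DILI labels come from heterogeneous sources — drug
labels, clinical case reports, animal and cell assays, literature curation —
the pipeline spends most of its machinery on data curation: harmonizing
structures, resolving label conflicts between sources, rebalancing the
classes, and filtering probable label errors before any model is fit.

## Structure standardization

Input structures (SMILES or SDF) are normalized before anything else:

1. counterions, water and solvents are stripped; the largest
   carbon-containing fragment becomes the parent, which converts salt forms
   to the corresponding free acid/base;
2. the parent must contain only elements from the organic whitelist
   {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; anything with a metal or
   rare element is rejected, as are carbon-free (inorganic) inputs and true
   mixtures (two or more components each with ≥ 4 carbons — a deliberate
   distinction from salt forms, which are converted rather than rejected);
3. aromatic systems are kekulized, formal charges neutralized where the fix
   is a pure (de)protonation (no bond edits), and all stereochemistry is
   cleared — the model deliberately treats enantiomers as one compound,
   since the label sources do not distinguish them reliably;
4. parents with fewer than 4 carbons or molecular weight above 900 are
   rejected. Both boundaries are strict (exactly 4 carbons and exactly
   MW 900 are kept); MW is the average molecular weight from standard
   atomic masses.

Structural identity is a short hash of the canonical, stereo-free SMILES of
the standardized parent, so salt forms and stereoisomers of one drug
deduplicate to a single key. The whole pass is idempotent.

## Descriptors and diversity

The feature block is a named, versioned set of 85 RDKit-computed descriptors
(`rdkit-85-v1`): 30 physicochemical (mass, lipophilicity, polarizability,
refractivity, H-bond counts, polar surface area, composition, charge) and 55
topological (ring-system counts, connectivity chi indices, kappa shape,
Balaban J, Bertz complexity, VSA partitions). Molecular polarizability has no
RDKit implementation, so it is an element-additive sum of tabulated atomic
polarizabilities (Å³) — a coarse but monotone surrogate adequate for a
feature, not a physical prediction. Descriptor values must all be finite;
a compound whose row fails is flagged and excluded from modeling, never
imputed. The set covers the same property families as the proprietary
descriptor packages commonly used in this area, but individual values are
not expected to match any other toolkit bit for bit.

Dataset diversity is summarized by pairwise Tanimoto similarity
|A∩B|/|A∪B| on hashed linear-path fingerprints (all paths of 1–7 bonds,
folded to 1024 bits — the FP2 convention), plus the molecular-weight and
ClogP ranges that define the usual chemical-space plot. Two all-zero
fingerprints (e.g. methane twice, which has no bond paths) are defined to
have similarity 1.0.

## Feature filtering

Two unsupervised filters, in order, both idempotent:

* **near-constant**: drop a feature whose modal value occurs in strictly
  more than 95% of compounds;
* **correlation**: for each surviving pair with |Pearson r| strictly above
  0.95, drop the later feature in the canonical column order (a greedy
  forward scan keeps the earliest member of a correlated clique). The
  absolute value is used: anti-correlated features are equally redundant.

Determinism comes from the fixed canonical column order. After filtering, no
retained pair exceeds the cutoff (re-verified from the full correlation
matrix in the tests). With this package's descriptor set the retained count
on any given dataset is whatever the filters produce — the count is
data- and descriptor-set-dependent and is not a contract.

## Curation: merge, balance, vote filter

**Source precedence.** Sources are split into two tiers; tier 1
(authoritative curated databases) wins all conflicts. Label conflicts within
tier 1 are treated as fatal curation errors rather than silently resolved.
Tier-2 structures already present in tier 1 are discarded; tier-2 structures
whose own sources disagree are removed entirely.

**Kennard–Stone balancing.** When negatives outnumber positives, the
negative class is reduced to the target count with the Kennard–Stone max-min
algorithm: seed with the two most distant negatives, then repeatedly add the
candidate whose minimum Euclidean distance to the selected set is largest.
Distances are computed on internally z-scored descriptors so heavy-tailed
features (molecular weight) do not dominate; ties resolve to the lowest row
index, making the selection deterministic. Unlike random undersampling this
keeps the retained negatives spread across chemical space. The excluded
negatives are kept as a reverse-validation pool (a negatives-only check of
specificity).

**Voting mislabel filter.** Each of the eight base classifiers is evaluated
by stratified k-fold cross-validation (default k = 10, one shared fold
partition so classifier votes are comparable); a compound earns one vote per
classifier whose out-of-fold prediction matches its recorded label, giving a
score in 0..8. Compounds scoring below 2 — compounds that essentially no
model family can reconcile with their label — are removed as probable label
errors or extreme outliers. Votes use out-of-fold predictions, not
resubstitution, so the filter does not simply reward memorization. Removal
is monotone in the threshold, and on synthetic data with planted label
flips, flipped rows score systematically lower than clean rows (this is the
property the filter exists for, and it is asserted in the acceptance tests).

## The ensemble

Eight base classifiers of deliberately different families: Gaussian naive
Bayes, 1-nearest-neighbor, a distance-weighted 5-NN (standing in for the
entropic instance-based KStar family), AdaBoost (10 stumps), bagged trees
(10), a single unpruned CART tree, a 100-tree random forest, and a small
fully-connected network (one hidden layer of 64 units) standing in for a
deep-learning component. Hyperparameters mirror the WEKA 3.8 defaults where
a scikit-learn counterpart exists; every learner sits behind a z-scoring
front end (the instance-based and network learners are scale-sensitive;
trees are scale-invariant, so the uniform pipeline is free).

The ensemble prediction is **soft voting**: the positive-class probability
is the unweighted arithmetic mean of the eight per-classifier probabilities.
The decision threshold is 0.5 with ties called positive — when the evidence
is exactly balanced the model flags the compound, consistent with the
screening use case where missing a hepatotoxin is the costlier error.

Evaluation is by stratified 10-fold cross-validation with pooled out-of-fold
predictions (each compound scored exactly once, by models that never saw
it). All stochastic learners derive their seeds from one master seed via
`numpy.random.SeedSequence`, so a run is exactly reproducible.

A second learner profile, `small` (20-tree half-sampled forest, 0.3-sampled
bagging, 16-unit network with 50 iterations), exists for procedures that
refit the stack hundreds of times — chiefly Y-randomization, where the
labels are permuted and model capacity has nothing to find. The default
profile is used everywhere a single model's quality matters.

## Evaluation and validation

Metrics are the standard confusion-matrix rates: ACC, SE (sensitivity), SP
(specificity), BACC = (SE+SP)/2, and AUC. AUC is computed two independent
ways — the Mann–Whitney rank statistic (ties at half credit) and the
trapezoidal area under the threshold-sweep ROC curve — and the
implementation asserts agreement to 1e-9 on every call; the identity is
exact for the average-rank tie convention, so any disagreement is a bug.

`reconstruct_confusion` inverts published comparison tables: given class
sizes and printed SE/SP, rounding SE·n_pos and SP·n_neg recovers the integer
confusion counts, from which ACC/BACC follow exactly. This is how the
package reproduces literature comparison rows without access to the
underlying predictions. (One caveat: a printed rate can be slightly
inconsistent with every integer count at the stated class size; the function
warns in that case, and balanced accuracy can equally be taken directly as
the mean of the printed rates.)

**Y-randomization.** The labels are permuted over the whole dataset (class
counts preserved by construction), the complete cross-validated ensemble is
refit, and the metrics recorded; 100 runs by default give a mean ± SD
reference distribution. A sound pipeline scores at chance — on balanced
data, ACC ≈ 0.5 with run-to-run SD on the binomial scale √(0.25/n) ≈ 0.014
at n = 1254 — and any real model must clear this band decisively. The
permutation is applied once per run over the whole set, not per fold.

## Synthetic data: what it shows and what it does not

The Gaussian generator produces two-class descriptor tables where each of
`n_informative` features (default 5) is shifted between classes by `signal`
within-class standard deviations, plus optional injected redundant columns
(r ≈ 0.999), near-constant columns, and recorded label flips. The Gaussian
class-conditional model was chosen for analyzability: the Bayes error is
known in closed form, so empirical accuracies have an analytic anchor
(signal 3 on 5 independent features gives Bayes accuracy ≈ 0.9996; signal 0
gives exactly 0.5).

The SMILES generator assembles a few hundred distinct valid structures from
aromatic/aliphatic scaffolds and substituent chains, with labels tied to a
noisy molecular-weight rule — a weak but real structure–label signal that
lets the chemistry stages run end to end.

What passing tests on this data shows: the algorithms do what their
definitions say (selection optimality, filter guarantees, chance-level
nulls, determinism, monotonicity). What it does not show: performance on
real hepatotoxicity data. Real descriptor marginals are skewed and
heavy-tailed, real label noise is not uniformly random (it correlates with
compound class and source), and real chemical redundancy is structured
rather than pairwise. Published accuracy figures for pipelines of this kind
depend on their specific descriptor toolkits, learner internals and curated
compound lists, none of which are reproduced here; the package reproduces
the *arithmetic* of published comparison tables exactly, and the
*behavioral* properties of the method, not any dataset-specific number.

## Problem sizes used in the shipped checks

The acceptance script evaluates the published-table arithmetic at the
printed class sizes (instantaneous), the Y-randomization null at the
reference dimensions n = 1254 × 55 features × 100 runs × 10-fold CV with the
`small` learner profile (about six minutes on one CPU), and the
label-independent AUC null at n = 2000. Unit and property tests use n in the
100–600 range, 5-fold or 10-fold CV, and the `small` profile so the whole
suite stays fast.

## Known limitations

* The 85-descriptor set is this package's own; counts surviving feature
  selection (and therefore any downstream numerology) will differ from
  pipelines built on other descriptor toolkits.
* The polarizability descriptor is element-additive and ignores
  hybridization and conjugation.
* No tautomer canonicalization; tautomers of one compound can receive
  different structure keys.
* The KStar and deep-learning components are family-level stand-ins, not
  reimplementations of the original algorithms.
* No hyperparameter search anywhere, by design: the pipeline runs on
  library defaults, and tuned learners would change what the vote filter
  removes.
* `reconstruct_confusion` assumes the printed rates were computed from the
  stated class sizes; tables with post-hoc exclusions will not invert
  cleanly.
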