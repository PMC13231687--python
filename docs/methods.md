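# Methods

## Series extraction and activity cliffs

Molecules (≤ 60 heavy atoms) are fragmented by cutting single acyclic bonds
between heavy atoms; each cut yields a core (the larger fragment, carrying
an attachment dummy) and a substituent. A cut is eligible when
`(n_sub − n_att) / n_mol ≤ 0.2` (inclusive), where `n_mol` is the parent's
heavy-atom count, `n_sub` the substituent's heavy-atom count (attachment
dummies not counted) and `n_att` the number of attachment points. Cores and
substituents are serialized as canonical SMILES with unlabeled attachment
dummies, so identical cores from different parents compare byte-identical
and symmetric cores need no extra attachment-numbering step.

The default is single cuts — the established matching-molecular-series
convention and the only variant for which core + substituent reassembly is
round-trip tested. `max_cuts=2` additionally enumerates bond pairs (the
two-attachment middle fragment is the core, the flanking fragments jointly
the substituent, `n_att = 2`); it is an indexing option, and the
substituent-to-site assignment of a double cut is not reconstructed.

A matching molecular series is every canonical core shared by ≥ 2
compounds; a compound may sit in several series. In a given assay, every
(active, inactive) pair within a series is one activity cliff, so a series
with `a` actives and `i` inactives contributes exactly `a·i` cliffs and all
of its members count as AC compounds.

## Matrix, similarity, leakage control

The profiling matrix is complete and binary; rows with no active cell are
removed before analysis (idempotent). Assay similarity is the Tanimoto
coefficient of active-compound sets, optionally restricted to a compound
subset; in every experiment that restriction is the training partition of
the current test assay, so similarity rankings, profile reductions and the
1-NN transfer never observe test compounds' relationship to the test assay.
If two active sets are both empty the similarity is defined as 0 (no shared
evidence), which keeps rankings total; ranking ties break by ascending
assay id. All cell reads go through a single accessor, which the test suite
overrides with an access-logging subclass to audit the leakage guarantees
directly rather than by argument inspection.

Series containing a compound whose profile (over the profile assays) is all
zero are excluded before modeling — such a compound has an empty feature
vector. The default removes the whole series; a flag removes only the
silent members, since the prose rule ("series containing consistently
inactive compounds are excluded") admits both readings.

## Splits

*Intra-series*: per series an orientation (actives→train or actives→test)
is drawn with probability ½ under the experiment seed. *Series-unit*: whole
series are allocated targeting an 80:20 train:test compound ratio; the
achievable train size closest to the target is found exactly by a boolean
subset-sum pass and realized by a seeded random backtrack, so which series
land in train varies with the seed while the ratio deviation is always
minimal. Compounds belonging to several series keep their first (seeded
processing order) assignment; a later series that cannot honor a pinned
compound without violating its scheme's invariant is dropped and counted.
Class weights are `n_total / (2 · n_class)`.

## Models

Random forest and XGBoost score by predicted probability of the active
class (threshold 0.5), the RBF-SVM by its signed decision value (threshold
0); ROC-AUC needs only the ranking, so SVM scores are not calibrated.
Hyperparameters are grid-searched under stratified 5-fold cross-validation
with balanced accuracy as the selection metric (folds shrink to the
minority-class count when classes are tiny); defaults are RF/XGB trees
{100, 500}, depth {None/6, 10}, XGB learning rate {0.1, 0.3}, SVM C
{0.1, 1, 10}, gamma {scale, 0.01}. The benchmark sweep uses
single-candidate grids (RF 200 trees) because the planted-signal
conclusions do not depend on tuning and a 60-cell sweep with full grids
costs ~20× the time.

MDI feature importance follows the weighted impurity-decrease definition:
for feature m, `Imp(m) = (1/N_T) Σ_T Σ_{t: v(t)=m} p(t) Δi(t)` with
`p(t) = N_t/N` and `Δi(t) = i(t) − p_L i(t_L) − p_R i(t_R)`, normalized to
sum 1 after averaging over trees. Note sklearn's `feature_importances_`
normalizes each tree *before* averaging; `per_tree_normalize=True`
reproduces that exactly (verified to 1e-9), while the default keeps the
formula above. With weighted training the node counts are weighted counts.

Metrics: BA = ½(TPR + TNR) (undefined and an error when a class is
absent); MCC per its product formula with the 0-denominator → 0
convention; ROC-AUC with midrank tie handling. Per-assay results are
grouped by MCC quartiles (linear interpolation; strictly above Q3 =
"positive", strictly below Q1 = "negative") — group counts can shift by ±1
under other quartile conventions. Representation pairs are compared by
two-sided Wilcoxon signed-rank tests (exact null for ≤ 25 untied non-zero
differences, normal approximation otherwise; all-zero differences are
flagged and reported non-significant) with Holm step-down adjustment at
α = 0.05 within one comparison family.

## Synthetic data: what it emulates and what it does not

The generator builds analog series from a pool of 15 distinct ring-system
scaffolds × 15 decorations (the pair unique per series) carrying 5–9
distinct small substituents (1–3 heavy atoms) at one site. Scaffolds are
mutually non-derivable and ≤ 6 ring atoms, and decorations have ≥ 4 heavy
atoms, so the substituent cut is the only one that can pass the 0.2 ratio
filter across series — ground-truth series come back from fragmentation as
single series essentially always, and a structure-collision guard raises if
a duplicate molecule is ever produced.

The matrix is complete and binary. Background cells are i.i.d. Bernoulli:
1% for ordinary compounds (the sparsity regime of real primary-screening
panels) and 5% for AC-series compounds — screening actives are frequent
hitters, and without this second tier ~30% of compounds would have all-zero
121-assay profiles and the silent-series exclusion would remove most of the
experiment, an artifact of independence that correlated real data does not
show. Each test assay receives a disjoint block of series with mixed labels
(actives drawn uniformly in [1, size−1]), making test assays statistically
independent — matching the near-zero pairwise similarity of real assay
panels. A planted nearest-neighbor profile assay is a copy of its test
assay's column with each cell flipped independently with probability ε;
similarity is controlled via ε (the induced Tanimoto is measured, not
asserted). Defaults: 180 series, 12 test + 121 profile assays, ε = 0.1 for
8 of 12 test assays, none for the rest.

Not emulated: assay biology and target families, potency values,
stereochemistry, correlated activity beyond the two-tier rate, and any
relationship between structure and activity labels — labels are planted,
so passing tests demonstrate the pipeline's statistical behavior
(leakage control, nearest-neighbor recovery, representation effects), not
chemical generalization.

## Benchmark design and problem sizes

The planted-neighbor benchmark runs, per test assay: 1-NN transfer under
the intra-series split, one classifier per representation (full profile,
top-10, random-10, ECFP4) on the same split, and a series-unit run on the
full profile. Per-assay split seeds are shared across representations so
paired differences reflect features alone; representation comparisons use
the median of per-assay paired BA differences, mirroring the paired
signed-rank methodology. Expected behavior, verified by the acceptance
tests: pooled 1-NN accuracy on planted assays ≈ 1 − ε within its binomial
interval; top-10 ≈ full profile (the full profile is mildly diluted by the
~111 uninformative assays); random-10 at chance; ECFP4 under the
intra-series split well below chance (training analogs carry the opposite
label of their test analogs); assays without a planted neighbor never reach
the positive MCC-quartile group. Problem sizes (~1250 compounds, 12 test
assays, ~40–50 test compounds per assay) were chosen so these bands have
adequate binomial precision while a full run stays at a few minutes on one
CPU.

## Known limitations

* Binary-label cliffs only; no potency-difference definition, no pair-level
  (AC vs non-AC) task.
* Single- and double-cut fragmentation only; no ring cuts or
  stereochemistry-aware series merging.
* The subset-sum allocation in the series-unit split stores an
  (n_series × total_compounds) boolean table; for very large per-assay
  series collections this is memory-heavier than a greedy pass.
* The all-pairs assay-similarity summary is computed over all retained
  compounds by default; whether a restriction should apply is
  context-dependent and left to the caller.
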