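# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Synthetic data model

`gen_descriptor_dataset` draws base descriptors i.i.d. standard normal and
labels from a logistic model: with a planted informative subset S of size
m and effect size β (log-odds units, default 2.0),

    logit P(y = +) = b + β · Σ_{j∈S} x_j / √m.

The score β·Σx_j/√m is N(0, β²), so β is directly the standard deviation
of the latent log-odds. The intercept b is solved numerically so the
expected positive fraction equals `class_balance` (default 0.5). Labels
are then *sampled* Bernoulli, which makes the Bayes accuracy of the
model computable by Monte Carlo as E[max(p, 1−p)]: about 0.70 at β = 2,
0.895 at β = 5, 0.94 at β = 10. No classifier can beat this ceiling, and
test expectations are set against it rather than against nominal
"perfect separation". Optional `correlated_frac` / `constant_frac`
fractions of columns are near-duplicates of earlier columns or constants;
they exist to exercise the pruning rules and are never informative.

What the generator does **not** emulate: real descriptor blocks are
heavy-tailed, integer-valued, and correlated in structured groups;
synthetic noise columns are exchangeable. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not predictive performance on real chemistry.

The PPI generator produces Erdős–Rényi or preferential-attachment
(Barabási–Albert) graphs with Uniform(0.4, 1.0] combined-score weights —
the medium-to-high confidence band of STRING-style scores. Weights decorate
edges only; all topology metrics are unweighted, as in Cytoscape's
NetworkAnalyzer. Fit-score tables plant true compound–target pairs at
Uniform(4, 8) and noise pairs at Uniform(0, 3.4), so the ≥ 4.0 retention
rule with 3.5 fallback has both branches exercised and recovers the truth
exactly. Annotation sets plant exactly one term with a fixed hit-list
overlap; all other terms are uniform draws from the background.

## Descriptor pretreatment

Variance threshold 1e-8 (a "numerically constant" cut) and absolute
Pearson correlation cap 0.95 are the conventional QSAR pretreatment
settings; both are required configuration keys. The correlation pass is a
greedy scan in column order — when a pair exceeds the cap the later
column is removed — which is deterministic and order-stable, and makes
pruning idempotent. Columns with more than 20 % non-finite cells are
dropped; sporadic non-finite cells are imputed with the column median and
logged (descriptor-calculation output commonly contains a few such
cells).

"PCA-80" is read as: z-score the pruned matrix, then keep the smallest
number of principal components whose cumulative explained variance is at
least 0.80. Center, scale and loadings are stored so held-out compounds
are projected through the training transform. In the pipeline, pruning
and PCA are fitted on the training partition only and applied to the
test/validation partitions; the stratified split is a pure function of
the labels and the seed, so the prep and evaluation stages re-derive the
identical partition.

## Classifiers

All five algorithms sit behind one train/predict contract with "+" the
positive class. Defaults (all configurable): KNN k = 5 on z-scored
features; SVM radial kernel, cost 1, kernel width γ = 1/p; random forest
500 trees with √p features per split; PLS-DA 2 components with the 0.5
decision threshold; network classifier one hidden layer of 10 logistic
units, SGD back-propagation, learning rate 0.01, 500 epochs, seeded
initialisation. KNN/SVM/RF and the network are backed by scikit-learn.

PLS-DA is implemented here from the NIPALS recursion (sequential
component extraction with deflation; coefficients B = W(PᵀW)⁻¹q) so its
decision rule is fully specified: predict "+" when the predicted dummy
response exceeds 0.5, ties to "−"; zero components give the
majority-class model. The low-level `plsda_fit` raises on rank
deficiency; the classifier wrapper instead caps the component count at
the matrix rank and backs off when the response is orthogonal to the
remaining X directions, so degenerate GA-selected subspaces still yield a
usable (majority-like) model instead of a failed factorial row.

Models serialise to a single-file joblib archive carrying a format
version; the tested contract is bit-identical predictions after a
save/load round trip.

## GA descriptor selection

Fitness of a chromosome c: mean stratified k-fold CV accuracy of the
classifier on the selected columns minus λ·|c|/p, with λ = 0.01 and
5-fold CV by default. The inner folds are re-seeded identically on every
call, so fitness is a pure function of the chromosome within a run and
results are reproducible from the configuration seed. An all-zero
chromosome scores 0 and is flagged invalid. Search: tournament size 3,
uniform crossover 0.8, per-bit mutation 0.01, elitism 1, initial
inclusion probability 0.1, population 50 × 100 generations at full
scale. With elitism ≥ 1 the best-fitness trace is non-decreasing. An
exhaustive enumerator over all 2^p − 1 subsets (p ≤ 20) serves as the
reference optimiser in tests. The GA operates on pruned descriptors by
default; running it over PCA scores instead is a caller choice, since
both composition orders are defensible.

## Evaluation

Splits are stratified per class with largest-remainder rounding into
TRS/TES/VAS at 0.6/0.2/0.2 — the conventional three-way QSAR split —
so class proportions are preserved within one compound. LOO is
deterministic; k-fold CV uses seeded stratified folds, and k = n
reproduces the LOO fold structure exactly, making the two schemes
coincide there. A training fold degenerating to fewer than two compounds
of a class falls back to predicting the training majority, with a
warning. Model selection is by VAS accuracy, ties broken by fewer
features, then the documented algorithm order, then the GA-free variant;
VAS is primary because it is the partition never touched by training or
selection.

The applicability domain is leverage-only: classification has no
continuous residual, so there is no Williams-plot residual axis; a
misclassification flag can be joined externally. Leverage uses the
intercept-augmented hat matrix, so training leverages sum to p + 1 and
are invariant to affine rescaling of descriptors. A condition number
above 1e12 on XᵀX raises, with the advice to prune or use PCA scores.

## Network topology and screening

Conventions follow Cytoscape NetworkAnalyzer, which is the reference
implementation for this kind of screen: betweenness normalized by
(N−1)(N−2)/2; closeness per connected component as (component size −
1)/Σ distances; centralization (N/(N−2))·(max DV/(N−1) − density);
heterogeneity = √(population variance of degree)/mean degree.
Centralization is undefined (NaN) below 3 nodes. The key-node screen
keeps nodes strictly above the network averages of DV, NBC and NCC
simultaneously; on a vertex-transitive graph every metric equals its
average and the screen is empty by design. The degree distribution (NDD)
is computed and reported but is not part of the screen, which uses the
three per-node indices. Identifiers are normalized to trimmed upper-case
throughout.

## Enrichment

Fisher is the one-tailed hypergeometric upper tail P(X ≥ k); EASE
replaces the overlap cell with max(k − 1, 0) while keeping all margins —
the documented DAVID "improved Fisher" convention — and is therefore
never anti-conservative relative to Fisher. The default background is
the union of all term members, overridable, since a web service's
internal background is not reproducible. FDR control is
Benjamini–Hochberg step-up (the procedure is not otherwise specified by
the workflow being reproduced); both the raw p < 0.05 and the q < 0.05
lists are available from the result table.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full method stack at
demonstration scale, chosen so every claim is exercised in minutes on a
single core: factorial datasets of 60 compounds × 20 descriptors with
forests of 40 trees and 60-epoch networks under a GA budget of population
20 × 20 generations; GA recovery at n = 200, p = 30 with 3 planted
descriptors; exhaustive GA validation at p = 12 (4 095 subsets) with the
1-component PLS-DA fitness, which is the cheapest exactly-specified
classifier in the package; null calibration at 100 compounds per seed.
These sizes are demonstration choices, not statistical necessities; all
scale up by configuration.

## Known limitations

- Synthetic chemistry only: no real descriptor computation from
  structures, no 3D descriptors.
- Label-flip symmetry holds exactly for the deterministic
  distance/margin classifiers (KNN, SVM, PLS-DA); seeded ensemble and
  gradient methods may break exact symmetry at vote ties.
- Edge weights are carried but never enter centralities (matching the
  reference conventions); weight-aware centralities are out of scope.
- Enrichment treats terms as flat sets; no ontology-graph propagation.
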