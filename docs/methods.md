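# Methods

`sstrans` implements a transductive, semi-supervised framework for
translating genomic responses from a mouse disease model to a human
cohort, together with the evaluation machinery needed to benchmark it and
a synthetic-cohort generator with planted ground truth.

## The translation problem

A mouse experiment provides an expression matrix with known phenotypes
(control vs. disease). A human cohort for the same disease provides an
expression matrix whose phenotypes we pretend not to know (in prospective
use they genuinely are unknown). The aim is not merely to classify the
human samples but to infer *human disease biology*: the differentially
expressed genes (DEGs) and enriched pathways that an analysis of the
human data with true phenotypes would reveal. Direct interpretation of
the mouse experiment often misses much of this biology because mouse
models recapitulate only part of the human disease program.

## Preprocessing

Both cohorts are harmonized into a shared feature space before modeling:

1. **Duplicate collapse.** When a gene symbol appears on several rows,
   the row with maximal mean expression across all samples is retained
   (first occurrence wins on exact ties).
2. **Homolog restriction.** Mouse symbols are mapped to human symbols
   through a user-supplied two-column homology table, restricted to 1:1
   pairs measured in both datasets (among many-to-one conflicts the
   first-listed pair is kept, with a warning), and both matrices take an
   identical row order.
3. **Per-gene z-scoring**, each cohort on its own samples (sample SD,
   n−1 denominator). Z-scoring the cohorts independently prevents any
   leakage of test-cohort statistics into training. Zero-variance genes
   are set to zero with a warning rather than aborting a run, since
   constant genes carry no class signal.

The order — collapse, then homolog restriction, then z-scoring — is fixed;
because z-scoring is per-gene and affine, restricting before or after
scaling changes nothing downstream of the rank-based statistics, but the
fixed order makes runs exactly reproducible.

## Feature selection

Genes are selected by an elastic-net-penalized logistic regression of
phenotype on z-scored expression. The mixing parameter α ∈ (0, 1]
interpolates between ridge-like (α → 0) and the Lasso (α = 1); the
benchmark grid is α ∈ {1.0, 0.9, 0.7, 0.5, 0.3, 0.1}. The penalty weight
is chosen to minimize mean cross-validated deviance over a geometric path
of 8 inverse-penalty values spanning 1e−2 to 1e2 (minimum-CV rather than
the 1-SE rule — the more permissive convention, consistent with the large
feature sets this style of analysis reports). The path search runs at a
loose solver tolerance; the final model is refit tightly at the chosen
penalty so the nonzero support is clean.

Cross-validation is 10-fold, stratified by class, falling back to
leave-one-out whenever the smaller class has fewer samples than the fold
count — the regime of the smallest mouse cohorts (4–5 animals per class).
Fold assignment is seeded and applied in sorted-sample-ID order, and the
design matrix is put in sorted-gene order before fitting, so the selected
set is invariant to row and column permutations of the input. If the
CV-optimal model is empty, the 10 genes with the largest absolute
class-mean difference are used instead, with a loud warning, so that
downstream training always has features.

## Classifiers

Four families, each with fixed hyperparameters and a common contract:
hard labels from the two training classes plus a per-sample confidence in
[0, 1] used *only for ranking* within a prediction batch.

| family | model | confidence |
|---|---|---|
| KNN | 3 nearest neighbors, Euclidean | fraction of the 3 votes for the predicted label (2/3 or 1) |
| SVM | linear kernel, C = 1 | within-batch rank of the absolute decision value, scaled to [0, 1] |
| RF | 50 bagged trees, √p features/split, full depth | fraction of trees voting the (majority) label, in [0.5, 1] |
| NN | 3-layer feed-forward | larger of the two softmax outputs |

The linear SVM kernel is the standard choice for few-samples,
many-genes expression data; rank-based SVM confidence avoids fitting a
probability calibration on cohorts of 8–40 samples. The network has one
input node per selected gene, two softmax output nodes (one per class,
normalized to sum to 1), and a hidden layer of ceil((n_in + 2)/2) tanh
units. It is trained by full-batch quasi-Newton minimization (L-BFGS) of
the cross-entropy, with a small L2 term (1e−4) for numerical
conditioning, to tolerance 1e−6 or 500 iterations; non-convergence
returns the best-so-far weights with a warning.

## The semi-supervised loop

Supervised translation selects features on the mouse cohort, trains one
classifier, and labels every human sample once. Semi-supervised
translation folds the human test set itself into training:

1. Iteration 1 is exactly the supervised step; all human samples are
   predicted with confidences.
2. The human samples in the top 10·i% of confidence at iteration *i* are
   merged — with their *predicted* phenotypes — into an augmented
   training set. Membership and pseudo-labels are refreshed from the
   newest predictions every iteration; mouse samples are never dropped,
   so the training set always retains both classes even if the human
   predictions are single-class.
3. Features are re-selected on the augmented set (same α and CV policy),
   the model retrained, and *all* human samples re-predicted.
4. The loop ends at the iteration whose threshold admits every human
   sample — at most 10 iterations — and that final prediction is the
   output.

The admission rule is rank-based: at iteration *i* the top
max(ceil(i·n/10), previous count) samples by confidence are admitted,
extended to include boundary ties (stable sample order breaks ranking
ties). A naive percentile cutoff cannot guarantee a non-shrinking merged
set when confidences are tie-heavy (KNN confidences take only two
values); the rank-based rule preserves the descending-threshold
semantics while making merged-set monotonicity hold by construction.

Because network training is stochastic, the semi-supervised NN proceeds
past iteration 1 only once more than one human sample is classified into
each class, retraining with fresh initial weights up to 50 times, after
which it proceeds with the last model regardless.

## Differential expression and pathways

Differential expression uses the two-sided Wilcoxon–Mann–Whitney test per
gene (exact null when the pooled size is ≤ 12 and tie-free, otherwise the
normal approximation with tie and continuity corrections), with
Benjamini–Hochberg adjustment across genes. A gene is a DEG when
p < 0.05 and q < 0.25 — permissive thresholds suited to small cohorts.
Pathway over-representation is the one-sided hypergeometric tail with the
measured genes as the universe, all DEGs pooled regardless of direction,
BH across sets, enrichment called at q < 0.05, and sets with fewer than 3
measured genes skipped.

## Evaluation

Predicted DEG/pathway sets are scored against the sets derived from the
true human phenotypes: TP = predicted ∩ truth, FP = predicted \ truth,
FN = truth \ predicted; precision, recall and the equal-weight F-score
(F1) summarize each modality, with the conventions P = R = F = 0 on empty
denominators. The mouse-direct baseline scores the mouse cohort's own
DEGs/pathways the same way. Phenotype discrimination is the rank-based
AUC (U/(n₁n₀) with midranks). A run whose predicted phenotypes are
single-class is scored with empty predicted sets. Note that DEG calling
is invariant to a global label flip (the two-sided rank test is
symmetric), so a model that separates the classes but swaps their names
still recovers the right biology.

The grid registry enumerates family × mode × α × case-study cells with
stable per-cell seeds (CRC32 of the cell coordinates). With the full
catalog — 4 families, 2 modes, 6 α values, 36 case studies — the grid has
1,728 cells. The meta-analysis stage fits an OLS linear model of a
performance response on dummy-coded family, numeric α, and optional
design covariates, with two-sided t-tests per coefficient; family-level
comparisons use a paired Wilcoxon signed-rank across case studies
(averaged over α), a documented package choice. Score summaries use
percentile-bootstrap 95% confidence intervals (10,000 seeded resamples).

## Synthetic cohorts

The generator plants three disjoint gene classes — shared DEGs
(shifted in both species), mouse-only, and human-only — on top of
i.i.d. Gaussian noise, with additive class-mean shifts in noise-SD
units, then z-scores each cohort as the real pipeline would. The
homology map is the identity (homology handling is tested separately).
Pathway collections contain "true" sets drawing a configurable fraction
(default 0.8) of members from the human truth DEGs — each verified
hypergeometrically enriched under the truth at generation time, with
redraws and purity escalation if a small universe defeats the first
draw — and decoy sets drawn from non-DEG genes.

Scenario library (defaults chosen once as the study conditions; all use
200 genes, human cohorts of 20+20, noise SD 1):

- **easy_transfer** — 20 shared DEGs at effect 2.5 in both species,
  mouse 20+20. Supervised and semi-supervised translation should agree.
- **divergent** — 10 shared + 25 mouse-only + 25 human-only DEGs; mouse
  effect 1.0 with only 5+5 animals, human effect 2.5. By construction
  the mouse cohort calls essentially no DEGs at p < 0.05 & q < 0.25
  (with 10 animals the smallest exact WMW p is 0.0079, which cannot
  survive BH across 200 genes unless many genes separate perfectly),
  mirroring the small endotoxemia/CLP-style model cohorts, while
  penalized selection — which needs no per-gene significance — can still
  find the shared foothold that bootstraps self-training.
- **imbalanced_mouse** — shared signal with a 4-vs-16 mouse cohort.
- **heterogeneous_mouse** — two mouse sub-cohorts (IDs `mA`/`mB`) whose
  effect vectors share the common DEGs but split the mouse-only ones.

What the simulations do *not* emulate: microarray platform and batch
effects, probe-level noise, correlated gene modules, non-Gaussian
expression distributions, and imperfect many-to-many homology. Passing
tests on these cohorts demonstrate the machinery's correctness and the
self-training mechanism under controlled truth, not performance on any
real mouse-human pairing.

## Numerical and design choices

- Elastic-net family is binomial (the phenotype is binary); penalty
  chosen at minimum CV deviance; saga solver, seeded.
- Percentile/threshold ties in the loop are admitted inclusively;
  ranking ties break by sample order.
- RF label ties (25/25 tree votes) resolve to the disease class,
  deterministically.
- Degenerate inputs: single-class training sets raise; zero-variance
  genes zero out with a warning; empty DEG sets yield empty (not
  erroneous) enrichment tables; single-class predictions score as empty
  predicted sets.
- All stochastic stages (fold assignment, saga, RF bagging, NN
  initialization, bootstrap) are seeded; grid cells and loop iterations
  derive their seeds from the master seed via CRC32 of the coordinates.

## Problem sizes in the checks

The packaged end-to-end checks run the mechanism study (divergent
scenario, ssNN, 20 seeds), the no-harm study (easy transfer, RF family,
20 seeds — supervised predictions are read from iteration 1 of the
semi-supervised trace, which is identical to the supervised model for
deterministic families), planted-truth recovery (10 seeds at effect 3.0,
40+40 per class), loop contracts on 100 randomized small cohorts, and
statistical-primitive oracles (exhaustive WMW enumeration to pooled
n = 10; 1,000-instance BH/AUC/F-score cross-checks). These sizes are the
package's chosen desk-scale study conditions.

## Known limitations

- SVM and KNN confidence definitions are package conventions (the
  contract requires only within-batch ranking); other monotone choices
  would change which human samples merge first.
- The NN is trained by L-BFGS rather than scaled conjugate gradient;
  both are batch gradient methods trained to the same tolerance, but
  individual fits are not numerically interchangeable.
- Real cross-species analyses hinge on homology quality and platform
  normalization, which are inputs here, not modeled steps.
- The divergent-scenario result shows the mechanism can recover planted
  human-only biology; effect sizes, cohort sizes and noise are idealized.
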