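# Methods

This note documents the models and procedures implemented in `subnet-attn`,
the defaults and why they were chosen, what the synthetic-study generator
does and does not emulate, and the numerical decisions that matter when
reproducing results.

## Inputs and identifier policy

Four files describe a study: a TPM expression matrix (TSV, genes in rows by
default), two-column sample labels, gene sets in MSigDB GMT dialect, and a
two-column PPI edge list. Gene identifiers are plain symbols compared
case-sensitively; no identifier mapping is attempted. Symbols that fail to
match across files are dropped and reported at the stage that notices them
(gene-set induction, expression lookup), never silently reconciled. The PPI
edge list is taken as already confidence-filtered; a `min-evidence` hook is
reserved but unimplemented.

## Subnetwork extraction

Each gene set's induced PPI subgraph is embedded independently (per-gene-set
embedding; a single global embedding is possible by passing the whole graph
but is not the default workflow, since the per-set subgraphs are what the
clusters are defined on).

**Random walks.** `walks_per_node` γ = 10 truncated uniform random walks of
length L = 40 start at every node; isolated nodes yield single-node walks.
These follow common DeepWalk practice scaled to gene-set graphs of tens to
a few hundred nodes: with γ·L = 400 visits per start node, empirical
transition frequencies are already indistinguishable from uniform over
neighbours (χ² test in the suite).

**Skip-gram with negative sampling.** Walks are sentences; all (center,
context) pairs within a symmetric window of 5 are trained with 5 negatives
drawn from the unigram^0.75 noise distribution, embedding dimension
d = 16, 5 epochs. The trainer is a deterministic single-threaded numpy
implementation. One implementation detail is load-bearing: pairs are
processed in mini-batches of 2048, and each embedding row receives the
*average* of its pair gradients in the batch (learning rate 0.3 decaying
linearly to 0.01). On vocabularies this small a node recurs hundreds of
times per batch, and summing per-pair updates at a word2vec-style step size
diverges. The averaged scheme recovers planted PPI blocks with adjusted
Rand index 1.0 across seeds on stochastic block models with p_in = 0.5,
p_out = 0.02. Graphs with ≤ d nodes reduce d to max(2, nodes − 1) to avoid
degenerate embeddings.

**GMM + BIC model selection.** Embedding rows are L2-normalised, then
Gaussian mixtures (diagonal covariance, best of 5 seeded EM restarts) are
fitted for k in 1..min(10, ⌊nodes/3⌋), and k* minimises

    BIC(k) = ln(n)·(k·d) − 2·loglik(k),

ties toward smaller k. The parameter count is k·d — component means only —
which is deliberately lighter than the textbook means+covariances+weights
count; `bic_mode="full-params"` provides the standard count. Two numerical
guards matter here. First, the normalisation puts all features on unit
scale, making one covariance floor meaningful across gene sets. Second,
`reg_covar = 1e-2` floors the EM variances: without it, components collapse
onto near-duplicate embedding vectors, the likelihood grows without bound,
and the BIC scan selects the largest k offered regardless of structure.
With both guards the selected k matches the planted block count in ≥ 80%
of seeded replicates (tested at 20/20 in the suite). Genes are
hard-assigned by maximum responsibility (ties to the lowest component
index); clusters with fewer than `min_size = 3` genes are dropped with a
log message (pair features need ≥ 2 genes; 3 keeps at least 3 pairs).
Subnetworks are named `GENESET_i` with `_1` the largest cluster.

## Subnetwork-level representation

**SAS (unsupervised).** For one sample with TPM values r over a subnetwork
graph with closeness centralities c (Wasserman–Faust component scaling;
isolated nodes 0):

    ACT_ij = N_ij · (c_i r_i + c_j r_j)² / (2 (r_i + r_j)),
    N_ij = a_ij / Σ_st a_st,   SAS = Σ_ij ACT_ij

over *ordered* pairs, so the normaliser is 2|E|. Pairs with r_i + r_j = 0
contribute 0 (the limit value). SAS is degree-1 homogeneous in the
expression vector and invariant to gene relabeling; both are property
tests.

**sSAS (supervised).** Each gene pair contributes the three terms
r_i²/(r_i+r_j), r_j²/(r_i+r_j), r_i·r_j/(r_i+r_j); 0/0 resolves to 0. Pair
order is lexicographic and identical across samples. The pair universe
defaults to all pairs within the subnetwork — the supervised fit is free to
rewire the subnetwork — with `pair_mode="ppi_edges"` restricting to
observed edges. A one-vs-rest logistic model per class is fitted on
training samples only, maximising the binomial log-likelihood minus an L2
penalty (strength 1.0, configurable). The penalty is a necessary deviation
from the pure maximum-likelihood objective: with 3·C(p,2) features and tens
of samples the separable-data MLE diverges. The intercept is included in
θ_k. Expression enters as raw TPM by default; ln(TPM+1) is available via
`log_expression`. A feature-selection hook exists but is a no-op.

Applying the frozen models gives q_mtk, normalised to
p_mtk = q_mtk / Σ_r q_mtr (the normaliser is strictly positive). The
per-sample representation is the T×k tensor of these distributions.

## Attention integration

Certainty per subnetwork is the negative Shannon entropy
c_t = Σ_k p_tk ln p_tk (0·ln 0 := 0), so c_t ∈ [ln(1/k), 0]. Attention is
H = softmax(W Cᵀ) per sample, computed with max-subtraction; the layer is
bias-free. The decision is d_k = Σ_t h_t p_tk with f = softmax(d).

Training minimises, over W only, one of: categorical cross-entropy
(default), squared hinge (targets ±1), or mean-absolute-percentage error
against one-hot targets with an ε = 1e-7 denominator floor — the latter two
because ensemble configurations using them performed best in the motivating
application. Optimiser: full-batch AdaGrad, learning rate 0.1, ≤ 500
epochs. Inverted dropout (rate 0.5) is applied to the certainty vector
during training only; placement on C is a design choice (the input to the
attention map is the natural site for regularising which subnetworks are
consulted). A stratified 10% validation split drives early stopping
(patience 20); the best-validation W is returned. W is initialised
Glorot-uniform from the seeded generator. Gradients are analytic and are
verified against central finite differences to 1e-5 in the suite (for MAPE
the comparison is relative: the ε-floored zero targets scale gradients far
above unit magnitude).

Because softmax-of-weighted-averages keeps d inside the simplex, f is
flatter than typical logit-based classifiers; argmax decisions and AUCs are
unaffected.

## Biomarker ranking and permutation test

FI_t is the column mean of the attention maps over a configurable sample
scope (train, test, or all samples — default all, matching how attention
tables are usually reported). FIR ranks FI ascending, rank 1 = smallest,
ties broken by subnetwork order. For a reference gene panel, RANK_g is the
mean FIR over subnetworks containing g (genes in no subnetwork are excluded
and reported), and SCORE is the mean RANK_g. The permutation test shuffles
FIR across subnetworks; p = #{permuted SCORE > SCORE}/iterations with
*strict* inequality and no +1 smoothing (an `add_one` flag gives
(x+1)/(n+1)). Since SCORE is linear in the rank vector, it collapses to a
fixed weight vector dotted with the permuted ranks; the implementation
exploits this for vectorised iteration and the tests verify it against
direct enumeration of all T! permutations on small instances. Default
iterations: 10⁶. Note that with few subnetworks the permutation null is
coarse (T! distinct values); p = 0 on a 4-subnetwork study means "no
permutation strictly exceeds", not "infinitely significant".

## Evaluation

Binary reports include the nine confusion-matrix rates (sensitivity,
specificity, precision, NPV, FPR, FDR, FNR, accuracy, F1); zero-denominator
metrics are flagged undefined (`None`), never NaN. mAUC is the unweighted
mean of one-vs-rest ROC AUCs (trapezoidal, midranked ties via
scikit-learn); classes absent from the labels are skipped with a warning.
For k > 2, F1 is macro-averaged, and both plain accuracy and balanced
accuracy (macro recall) are reported, since "mean accuracy" is ambiguous in
common usage. Rounding to 4 decimals happens only at report time.

Train/test splitting is stratified: per class, ⌊fraction·size⌋ samples go
to test. The floor (rather than round-half-away) matches the published
per-class test counts that motivated the convention. Explicit pre-split id
lists are supported for cross-cohort designs (train on one cohort, test on
another).

## Synthetic studies

The generator emulates the statistical structure the method assumes:

- **PPI**: planted-partition graph; blocks of `genes_per_block = 15` genes,
  within-block edge probability `p_in = 0.5`, between-block `p_out = 0.02`.
- **Gene sets**: unions of whole blocks (`blocks_per_geneset = 2`,
  `n_genesets = 2` by default), so discovered subnetworks have a ground
  truth to align with.
- **Expression**: TPM = exp(N(μ, σ)) with baseline log-mean 3.0 (≈ 20 TPM)
  and σ = 0.5. Driver blocks shift their log-mean by `effect_size = 2.0`
  for non-reference classes (class c ≥ 1 shifts driver block (c−1 mod
  #drivers) — a one-vs-rest pattern that generalises to k classes).
- **Labels**: balanced by default; `class_proportions` supports imbalanced
  designs (e.g. 22/11 for metric testing).

These defaults describe the study conditions used throughout the tests and
the acceptance script: 200 samples, 60 genes, one 15-gene driver block,
log-normal noise. What the generator does *not* emulate: count-based noise
(negative binomial dispersion, library-size variation), batch or cohort
effects, correlated expression beyond the block mean shift, and realistic
PPI degree heterogeneity. Passing recovery tests therefore demonstrates
that the pipeline identifies smooth monotone class signal routed through
planted network modules — not that it is robust to technical artefacts of
real RNA-seq.

## Problem sizes in the test suite and acceptance script

Unit tests use toy graphs and closed-form instances. Recovery tests run the
full pipeline at the default study conditions (200 samples, 4 blocks)
across 10 seeds per regime, and the block-count-selection check uses 20
replicates of a 45-node, 3-block SBM. The acceptance script runs one full
synthetic study plus five strong-signal and five null replicates, and a
10⁶-iteration permutation test. These sizes keep a complete run in minutes
on one CPU while leaving every statistical check adequately powered.

## Known limitations

- The BIC with the means-only parameter count under-penalises complex
  models by design fidelity; the covariance floor is what keeps the scan
  well-behaved. Use `bic_mode="full-params"` for the textbook criterion.
- The all-pairs sSAS feature space grows as O(genes²); subnetworks of
  hundreds of genes produce tens of thousands of features and will be slow
  and heavily regularised. `pair_mode="ppi_edges"` is the practical choice
  there.
- The attention trainer is full-batch; it targets studies of 10²–10³
  samples and a few hundred subnetworks, not larger.
- Multi-worker embedding training is not implemented; determinism is
  prioritised.
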