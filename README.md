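# subnet-attn

Subnetwork representation learning for discovering network biomarkers in
cancer transcriptomes.

Bulk RNA-seq classification problems in oncology — molecular subtyping,
predicting lymph-node metastasis from a primary-tumour profile — face three
obstacles at once: far more genes than samples, strong dependence between
genes acting through protein complexes and pathways, and cohort
heterogeneity. `subnet-attn` addresses them by reducing the ~20k-gene space
to a few hundred *subnetworks* — densely interacting gene groups inside
curated gene sets — and classifying samples from per-subnetwork probability
votes combined by an interpretable attention layer. The attention weights
double as a biomarker ranking: the subnetworks the classifier relies on are
the candidate network biomarkers.

## Method

The pipeline has four stages.

**1. Subnetwork extraction.** For each gene set (e.g. the 50 MSigDB hallmark
sets), the induced protein–protein interaction (PPI) subgraph is embedded by
truncated random walks fed to a skip-gram model (DeepWalk), and the node
vectors are clustered with a Gaussian mixture. The number of clusters k
minimises

    BIC(k) = ln(n) · (k·d) − 2 ln p(x | θ̂, M)

with n embedded genes, embedding dimension d, and the maximised mixture
likelihood p(x|θ̂,M). Each cluster of ≥ `min_size` genes becomes a
subnetwork `GENESET_i`.

**2. Supervised subnetwork activation (sSAS).** The unsupervised activation
score of a subnetwork sums, over PPI edges,
`ACT_ij = N_ij (c_i r_i + c_j r_j)² / (2(r_i + r_j))` with TPM values `r`,
closeness centralities `c` and edge normaliser `N_ij = a_ij / Σ a_st`. The
supervised variant decomposes each gene pair into the three terms
`r_i²/(r_i+r_j)`, `r_j²/(r_i+r_j)`, `r_i r_j/(r_i+r_j)`, treats their
coefficients as latent weights, and fits a one-vs-rest logistic model
per class and subnetwork: `q_k(x) = 1/(1+e^{−θ_kᵀx})`. Normalising
`p_k = q_k / Σ_r q_r` turns every subnetwork into a per-sample probability
distribution over classes; a sample's representation is the length-`T·k`
concatenation over `T` subnetworks.

**3. Attention-based master decision.** Each subnetwork's certainty is its
negative Shannon entropy `c_t = Σ_k p_tk ln p_tk`; the certainty vector `C`
is mapped through a trainable matrix to instance-wise attention
`H = softmax(W Cᵀ)`, and the decision is the attention-weighted vote
`d_k = Σ_t h_t p_tk`, `f = softmax(d)`. `W` is trained by AdaGrad with
dropout on `C` and early stopping (cross-entropy, squared hinge, or MAPE
loss).

**4. Biomarker ranking.** Feature importance `FI_t` is the mean attention on
subnetwork `t`; subnetworks are ranked ascending (`FIR`). A reference gene
panel is scored by the membership-weighted mean rank of its genes, and an
empirical p-value is obtained by shuffling the ranking
(`p = #{permuted score > observed} / iterations`).

Because the real cohorts behind such studies are access-restricted, the
package ships a synthetic-study generator: a planted-partition PPI graph,
gene sets that are unions of blocks, and log-normal TPM expression whose
designated "driver" blocks carry a class-dependent log-scale mean shift.
Every stage is tested against this ground truth.

## Worked example

```python
from subnet_attn import PipelineConfig, SyntheticConfig, make_dataset, run_on_dataset

dataset = make_dataset(SyntheticConfig(effect_size=2.0, n_samples=200, seed=1))
result = run_on_dataset(dataset, PipelineConfig(seed=1))
```

Running `python examples/03_attention_classifier.py` (the script around the
snippet above) prints:

```
train/test: 140/60 samples
held-out metrics:
  accuracy: 0.9500
  mauc: 0.9833
  f1: 0.9492
  sensitivity: 0.9333
  specificity: 0.9667
mean attention per subnetwork (the feature importance FI):
  GS0_1: 70.3%  (15 driver genes)
  GS0_2: 10.1%  (0 driver genes)
  GS1_1: 9.8%  (0 driver genes)
  GS1_2: 9.8%  (0 driver genes)
```

The study planted one 15-gene driver block whose expression shifts with the
class label. The pipeline classifies held-out samples at 95% accuracy
(mAUC 0.98), and the attention layer places 70% of its weight on `GS0_1` —
exactly the subnetwork containing the driver genes — while the three
uninformative subnetworks share the rest. `examples/04` then shows the
permutation test confirming the driver panel is top-ranked (p ≈ 0 at 10⁵
shuffles).

The other example scripts cover subnetwork discovery against planted blocks
(`examples/01`) and the SAS / sSAS representations (`examples/02`).

## Command-line interface

The same stages are available as a thin CLI over one YAML configuration:

```bash
subnet-attn simulate  --config run.yaml --out data/
subnet-attn run-all   --config run.yaml --out results/ --seed 7
subnet-attn permute   --config run.yaml --out results/ --iterations 1000000
```

`run-all` writes the partition, representations, fitted models, metrics,
attention table, biomarker ranking and a run log with the configuration
hash. See `subnet-attn --help` for the per-stage verbs
(`load-check`, `embed`, `discover`, `represent`, `train`, `evaluate`,
`rank`, `permute`).

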