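"""Subnetwork-level representations of transcriptome samples.

Two representations are provided.

**SAS** (subnetwork activation score) is unsupervised: for a subnetwork graph
with adjacency a_ij, closeness centralities c_i and one sample's TPM values
r_i, every connected ordered pair contributes

    ACT_ij = N_ij * (c_i r_i + c_j r_j)^2 / (2 (r_i + r_j)),
    N_ij = a_ij / sum_st a_st,

and SAS is the sum of ACT_ij over all ordered pairs.

**sSAS** (supervised SAS) replaces the topology-defined coefficients with
latent weights fitted to sample labels: the activation of each gene pair is
decomposed into the three terms r_i^2/(r_i+r_j), r_j^2/(r_i+r_j) and
r_i r_j/(r_i+r_j), the per-sample concatenation of those terms over all
pairs is the feature vector x, and a one-vs-rest logistic model per class
estimates q_k(x) = 1/(1+exp(-theta_k' x)). Normalising the per-class
probabilities, p_k = q_k / sum_r q_r, gives the subnetwork-level
representation of a sample: one probability distribution over classes per
subnetwork.

The pair universe defaults to all gene pairs within the subnetwork
(virtually rewiring its edges); ``pair_mode="ppi_edges"`` restricts to
observed PPI edges. The logistic fits carry an L2 penalty: the raw
maximum-likelihood problem diverges on separable data, which is the typical
regime at tens of samples and hundreds of pair features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from sklearn.linear_model import LogisticRegression

from .data_io import ExpressionMatrix, SampleLabels
from .discovery import SubnetworkPartition


def closeness(graph: nx.Graph) -> dict[str, float]:
    """Closeness centrality with Wasserman–Faust component scaling.

    For node i reaching R other nodes at total distance D in a graph of n
    nodes: c_i = (R / D) * (R / (n - 1)). Isolated nodes (and the singleton
    graph) get 0.
    """
    if len(graph) <= 1:
        return {n: 0.0 for n in graph.nodes()}
    return nx.closeness_centrality(graph, wf_improved=True)


def sas(graph: nx.Graph, centrality: dict[str, float], expr: dict[str, float]) -> float:
    """Subnetwork activation score of one sample (see module docstring).

    Ordered connected pairs share the normaliser sum_st a_st = 2|E|. Pairs
    with r_i + r_j = 0 contribute 0 (the zero-expression limit).
    """
    missing = [n for n in graph.nodes() if n not in expr]
    if missing:
        raise KeyError(f"expression missing for genes: {sorted(missing)}")
    edges = list(graph.edges())
    if not edges:
        return 0.0
    denom = 2.0 * len(edges)
    total = 0.0
    for u, v in edges:
        ru, rv = expr[u], expr[v]
        s = ru + rv
        if s <= 0:
            continue
        act = (centrality[u] * ru + centrality[v] * rv) ** 2 / (2.0 * s)
        total += 2.0 * act / denom  # (u,v) and (v,u) contribute identically
    return total


@dataclass
class PairFeatureVector:
    """Per-sample pair-decomposition features of one subnetwork."""

    sample_ids: list[str]
    pairs: list[tuple[str, str]]  # canonical (i < j lexicographic), stable
    features: np.ndarray  # (n_samples, 3 * n_pairs)


def pair_features(
    expr: ExpressionMatrix,
    genes: list[str],
    pair_mode: str = "all_pairs",
    graph: nx.Graph | None = None,
) -> PairFeatureVector:
    """The three division terms per canonical gene pair per sample.

    Pair order is lexicographic by gene id and identical across samples;
    feature layout is [t1, t2, t3] per pair, pairs concatenated. Pairs with
    r_i + r_j = 0 yield (0, 0, 0).
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("pair features require at least 2 genes")
    if pair_mode == "all_pairs":
        pairs = list(combinations(genes, 2))
    elif pair_mode == "ppi_edges":
        if graph is None:
            raise ValueError("pair_mode='ppi_edges' requires the subnetwork graph")
        gene_set = set(genes)
        pairs = sorted(
            tuple(sorted((u, v)))
            for u, v in graph.edges()
            if u in gene_set and v in gene_set
        )
        if not pairs:
            raise ValueError("no PPI edges among the given genes")
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    cols = expr.gene_columns(genes)
    idx = {g: i for i, g in enumerate(genes)}
    ri = cols[:, [idx[i] for i, _ in pairs]]  # (n_samples, n_pairs)
    rj = cols[:, [idx[j] for _, j in pairs]]
    s = ri + rj
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(s > 0, ri**2 / s, 0.0)
        t2 = np.where(s > 0, rj**2 / s, 0.0)
        t3 = np.where(s > 0, ri * rj / s, 0.0)
    feats = np.empty((cols.shape[0], 3 * len(pairs)))
    feats[:, 0::3] = t1
    feats[:, 1::3] = t2
    feats[:, 2::3] = t3
    return PairFeatureVector(list(expr.sample_ids), pairs, feats)


@dataclass
class SubnetworkModel:
    """One-vs-rest logistic models of a single subnetwork."""

    subnetwork_id: str
    class_set: list[str]
    theta: np.ndarray  # (n_classes, n_features + 1); last column = intercept
    reg_strength: float

    def q(self, features: np.ndarray) -> np.ndarray:
        """Raw one-vs-rest probabilities q_mtk, shape (n_samples, n_classes)."""
        z = features @ self.theta[:, :-1].T + self.theta[:, -1]
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def fit_subnetwork_model(
    features: PairFeatureVector,
    labels: SampleLabels,
    reg_strength: float = 1.0,
    seed: int = 0,
    subnetwork_id: str = "",
) -> SubnetworkModel:
    """Fit one L2-regularised logistic model per class, one-vs-rest.

    Maximises the binomial log-likelihood of y_mk = 1{label(m)=k} minus an L2
    penalty of strength ``reg_strength``; fits are deterministic (lbfgs on a
    convex objective).
    """
    if features.features.shape[0] != len(labels.sample_ids):
        raise ValueError("feature/label sample count mismatch")
    present = set(labels.labels)
    if len(present) < 2:
        raise ValueError("supervised fitting requires >= 2 classes present")
    X = features.features
    thetas = []
    for cls in labels.class_set:
        y = labels.indicator(cls)
        clf = LogisticRegression(
            C=1.0 / reg_strength,
            solver="lbfgs",
            max_iter=2000,
            random_state=seed,
        )
        clf.fit(X, y)
        if clf.classes_[1] != 1.0:  # orient toward the positive class
            coef, intercept = -clf.coef_[0], -clf.intercept_[0]
        else:
            coef, intercept = clf.coef_[0], clf.intercept_[0]
        thetas.append(np.concatenate([coef, [intercept]]))
    return SubnetworkModel(
        subnetwork_id, list(labels.class_set), np.array(thetas), reg_strength
    )


@dataclass
class RepresentationTensor:
    """Per-sample, per-subnetwork class-probability distributions.

    probs[m, t] is the normalised distribution p_mt over classes; raw holds
    the unnormalised one-vs-rest probabilities q_mt.
    """

    sample_ids: list[str]
    subnetwork_ids: list[str]
    class_set: list[str]
    probs: np.ndarray  # (n_samples, n_subnetworks, n_classes)
    raw: np.ndarray

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("representation rows must sum to 1")

    @property
    def n_subnetworks(self) -> int:
        return len(self.subnetwork_ids)

    def flatten(self) -> np.ndarray:
        """Per-sample vectors of length T * k."""
        return self.probs.reshape(self.probs.shape[0], -1)

    def subset_samples(self, sample_ids: list[str]) -> "RepresentationTensor":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return RepresentationTensor(
            list(sample_ids),
            list(self.subnetwork_ids),
            list(self.class_set),
            self.probs[idx],
            self.raw[idx],
        )


def represent(
    models: list[SubnetworkModel],
    features: list[PairFeatureVector],
) -> RepresentationTensor:
    """Apply frozen per-subnetwork models and normalise across classes.

    q_mtk comes from each subnetwork's logistic models; p_mtk = q_mtk /
    sum_r q_mtr. Logistic outputs are strictly positive so the normaliser
    never vanishes.
    """
    if len(models) != len(features):
        raise ValueError("one feature block per subnetwork model required")
    if not models:
        raise ValueError("no subnetwork models")
    class_set = models[0].class_set
    sample_ids = features[0].sample_ids
    qs = []
    for model, feat in zip(models, features):
        if model.class_set != class_set:
            raise ValueError("inconsistent class sets across subnetwork models")
        if feat.sample_ids != sample_ids:
            raise ValueError("inconsistent sample order across subnetworks")
        if model.theta.shape[1] != feat.features.shape[1] + 1:
            raise ValueError("feature dimension does not match fitted model")
        qs.append(model.q(feat.features))
    raw = np.stack(qs, axis=1)  # (n_samples, T, k)
    probs = raw / raw.sum(axis=2, keepdims=True)
    return RepresentationTensor(
        list(sample_ids),
        [m.subnetwork_id for m in models],
        list(class_set),
        probs,
        raw,
    )


def build_representation(
    expr: ExpressionMatrix,
    labels_train: SampleLabels,
    partition: SubnetworkPartition,
    pair_mode: str = "all_pairs",
    reg_strength: float = 1.0,
    seed: int = 0,
    graph: nx.Graph | None = None,
) -> tuple[list[SubnetworkModel], RepresentationTensor]:
    """Fit per-subnetwork models on training samples, represent all samples.

    ``labels_train`` lists the training samples only; model parameters never
    see the remaining samples' labels.
    """
    expr_train = expr.subset_samples(labels_train.sample_ids)
    models: list[SubnetworkModel] = []
    feats_all: list[PairFeatureVector] = []
    for sub in partition.subnetworks:
        feat_train = pair_features(expr_train, sub.genes, pair_mode, graph)
        models.append(
            fit_subnetwork_model(
                feat_train, labels_train, reg_strength, seed, sub.subnetwork_id
            )
        )
        feats_all.append(pair_features(expr, sub.genes, pair_mode, graph))
    return models, represent(models, feats_all)
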