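"""Subnetwork extraction: Gaussian-mixture clustering of node embeddings.

Each gene set's PPI subgraph is embedded (see :mod:`subnet_attn.deepwalk`)
and the embedded nodes are clustered with a Gaussian mixture model. The
number of components is selected by the Bayesian information criterion in
the form

    BIC(k) = ln(n) * (k * d) - 2 * loglik

where n is the number of embedded nodes, d the embedding dimension and
loglik the maximised mixture log-likelihood. Note the parameter count is
k*d — the component means only — rather than the usual means+covariances+
weights count; ``bic_mode="full-params"`` switches to the standard count.
The model with the lowest BIC wins; ties go to the smaller k. Every cluster
of at least ``min_size`` genes becomes a subnetwork named GENESET_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.mixture import GaussianMixture

from .data_io import GeneSetCollection
from .data_io import induce_geneset_graph
from .deepwalk import EmbeddingParams, NodeEmbedding, embed_graph

logger = logging.getLogger(__name__)


def bic_score(loglik: float, n: float, k: int, d: int, mode: str = "means") -> float:
    """BIC of a fitted k-component mixture over n points in d dimensions.

    ``mode="means"`` uses the k*d parameter count; ``mode="full-params"``
    uses k*d means + k*d diagonal variances + (k-1) weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "means":
        n_params = k * d
    elif mode == "full-params":
        n_params = 2 * k * d + (k - 1)
    else:
        raise ValueError(f"unknown bic mode {mode!r}")
    return float(np.log(n) * n_params - 2.0 * loglik)


@dataclass
class BicScan:
    """BIC model-selection scan over candidate cluster counts."""

    candidate_k: list[int]
    loglik: list[float]
    bic: list[float]
    n: int
    d: int
    assignments: dict[int, np.ndarray]  # k -> hard labels per node
    seed: int = 0


@dataclass
class GmmParams:
    k_min: int = 1
    k_max: int | None = None  # default min(10, n_nodes // 3)
    restarts: int = 5
    covariance_type: str = "diag"
    bic_mode: str = "means"
    reg_covar: float = 1e-2  # variance floor; data is unit-normalized at discovery
    normalize: bool = True  # L2-normalize embedding rows before clustering
    seed: int = 0


def fit_candidates(
    embedding: NodeEmbedding,
    k_range: list[int] | range,
    restarts: int = 5,
    seed: int = 0,
    covariance_type: str = "diag",
    bic_mode: str = "means",
    reg_covar: float = 1e-2,
) -> BicScan:
    """Fit a GMM for each candidate k and record loglik + BIC.

    Each fit takes the best of ``restarts`` seeded EM initialisations.
    Hard assignments (max responsibility, ties to the lowest component)
    are stored per k so the winning partition can be extracted later.
    ``reg_covar`` floors the component variances: without it EM collapses
    components onto near-duplicate points, and the runaway likelihood makes
    the BIC scan favour ever-larger k regardless of structure.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    X = embedding.vectors
    n, d = X.shape
    if ks[0] < 1:
        raise ValueError("k must be >= 1")
    if ks[-1] > n:
        raise ValueError(f"k_range max {ks[-1]} exceeds number of nodes {n}")
    logliks: list[float] = []
    bics: list[float] = []
    assignments: dict[int, np.ndarray] = {}
    if n == 1:  # degenerate scan: one point, one component at the point itself
        ll = float(-0.5 * d * np.log(2 * np.pi * reg_covar))
        return BicScan(
            [1], [ll], [bic_score(ll, n=1, k=1, d=d, mode=bic_mode)],
            n=1, d=d, assignments={1: np.zeros(1, dtype=int)}, seed=seed,
        )
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            n_init=restarts,
            random_state=seed,
            reg_covar=reg_covar,
        )
        gm.fit(X)
        ll = float(gm.score(X) * n)  # total log-likelihood
        logliks.append(ll)
        bics.append(bic_score(ll, n=n, k=k, d=d, mode=bic_mode))
        resp = gm.predict_proba(X)
        assignments[k] = np.argmax(resp, axis=1)  # argmax takes lowest index on ties
    return BicScan(ks, logliks, bics, n=n, d=d, assignments=assignments, seed=seed)


def select_partition(scan: BicScan) -> tuple[int, np.ndarray]:
    """Argmin-BIC k (ties toward smaller k) and its hard assignment."""
    if not scan.candidate_k:
        raise ValueError("empty BIC scan")
    best = min(zip(scan.bic, scan.candidate_k))[1]
    return best, scan.assignments[best]


@dataclass
class Subnetwork:
    subnetwork_id: str
    geneset: str
    genes: list[str]


@dataclass
class SubnetworkPartition:
    """Disjoint subnetworks per gene set, named GENESET_i."""

    subnetworks: list[Subnetwork]

    @property
    def subnetwork_ids(self) -> list[str]:
        return [s.subnetwork_id for s in self.subnetworks]

    def genes_of(self, subnetwork_id: str) -> list[str]:
        for s in self.subnetworks:
            if s.subnetwork_id == subnetwork_id:
                return s.genes
        raise KeyError(subnetwork_id)

    def membership(self, genes: list[str]) -> np.ndarray:
        """Indicator matrix SUB (len(genes) x n_subnetworks)."""
        sets = [set(s.genes) for s in self.subnetworks]
        return np.array(
            [[1.0 if g in members else 0.0 for members in sets] for g in genes]
        )


def discover_subnetworks(
    ppi: nx.Graph,
    genesets: GeneSetCollection,
    embed_params: EmbeddingParams | None = None,
    gmm_params: GmmParams | None = None,
    min_size: int = 3,
) -> SubnetworkPartition:
    """Per gene set: induce PPI subgraph, embed, scan k by BIC, emit clusters.

    Gene sets with fewer than ``min_size`` genes present in the PPI are
    skipped; clusters below ``min_size`` are dropped. Both events are logged.
    Subnetwork indices are assigned in decreasing cluster-size order (ties by
    smallest member gene) so that _1 is always the largest subnetwork.
    """
    if embed_params is None:
        embed_params = EmbeddingParams()
    if gmm_params is None:
        gmm_params = GmmParams()
    subnetworks: list[Subnetwork] = []
    for name in genesets.set_names:
        graph = induce_geneset_graph(ppi, genesets[name])
        n = len(graph)
        if n < min_size:
            logger.info("gene set %s skipped: %d genes in PPI < min_size %d", name, n, min_size)
            continue
        emb = embed_graph(graph, embed_params)
        if gmm_params.normalize:
            norms = np.linalg.norm(emb.vectors, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            emb = NodeEmbedding(emb.node_ids, emb.vectors / norms)
        k_max = gmm_params.k_max if gmm_params.k_max is not None else min(10, n // 3)
        k_max = max(gmm_params.k_min, min(k_max, n))
        scan = fit_candidates(
            emb,
            range(gmm_params.k_min, k_max + 1),
            restarts=gmm_params.restarts,
            seed=gmm_params.seed,
            covariance_type=gmm_params.covariance_type,
            bic_mode=gmm_params.bic_mode,
            reg_covar=gmm_params.reg_covar,
        )
        k_star, labels = select_partition(scan)
        clusters: list[list[str]] = []
        for comp in range(k_star):
            genes = [emb.node_ids[i] for i in np.flatnonzero(labels == comp)]
            if len(genes) >= min_size:
                clusters.append(sorted(genes))
            elif genes:
                logger.info(
                    "gene set %s: cluster of size %d below min_size %d dropped",
                    name, len(genes), min_size,
                )
        clusters.sort(key=lambda g: (-len(g), g[0]))
        for i, genes in enumerate(clusters, start=1):
            subnetworks.append(Subnetwork(f"{name}_{i}", name, genes))
    return SubnetworkPartition(subnetworks)


def write_partition(partition: SubnetworkPartition, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("subnetwork_id\tgeneset\tgene\n")
        for s in partition.subnetworks:
            for g in s.genes:
                fh.write(f"{s.subnetwork_id}\t{s.geneset}\t{g}\n")


def load_partition(path: str) -> SubnetworkPartition:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    subs: list[Subnetwork] = []
    for sid, grp in df.groupby("subnetwork_id", sort=False):
        subs.append(Subnetwork(str(sid), str(grp["geneset"].iloc[0]), [str(g) for g in grp["gene"]]))
    return SubnetworkPartition(subs)
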