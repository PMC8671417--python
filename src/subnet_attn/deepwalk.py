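"""Dense node embeddings of PPI graphs via truncated random walks.

The adjacency representation of a PPI network is extremely sparse (a typical
gene touches ~10 of >20,000 genes), which hampers statistical learning on raw
adjacency vectors. Following the DeepWalk recipe, we sample truncated uniform
random walks from every node and feed them, as sentences, to a skip-gram
model with negative sampling. Nodes that co-occur on short walks — i.e. that
are topologically close, directly or through shared neighbourhoods — end up
with nearby vectors, which turns subnetwork extraction into ordinary
clustering in the embedding space.

The skip-gram trainer is a deterministic, single-threaded numpy
implementation: pairs are processed in seeded mini-batches with AdaGrad-free
linearly decaying SGD, and negatives are drawn from the unigram^0.75 noise
distribution, matching word2vec conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


@dataclass
class WalkParams:
    walks_per_node: int = 10
    walk_length: int = 40
    seed: int = 0


@dataclass
class WalkCorpus:
    """Random walks over a graph, each rooted at its starting node."""

    walks: list[list[str]]
    params: WalkParams


@dataclass
class EmbeddingParams:
    dim: int = 16
    window: int = 5
    epochs: int = 5
    negative: int = 5
    walks_per_node: int = 10
    walk_length: int = 40
    learning_rate: float = 0.3
    min_learning_rate: float = 0.01
    batch_size: int = 2048
    seed: int = 0


@dataclass
class NodeEmbedding:
    node_ids: list[str]
    vectors: np.ndarray  # shape (n_nodes, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("one vector per node required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding values")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]


def sample_walks(
    graph: nx.Graph, walks_per_node: int, walk_length: int, seed: int
) -> WalkCorpus:
    """Sample ``walks_per_node`` truncated random walks rooted at every node.

    At each step the next node is uniform over the current node's neighbours.
    Isolated nodes yield the single-node walk. Node iteration order is sorted,
    so the corpus is fully determined by the seed.
    """
    if len(graph) == 0:
        raise ValueError("cannot sample walks from an empty graph")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    if walks_per_node < 1:
        raise ValueError("walks_per_node must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())
    neighbors = {n: sorted(graph.neighbors(n)) for n in nodes}
    walks: list[list[str]] = []
    for _ in range(walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < walk_length:
                nbrs = neighbors[walk[-1]]
                if not nbrs:
                    break
                walk.append(nbrs[rng.integers(len(nbrs))])
            walks.append(walk)
    return WalkCorpus(walks, WalkParams(walks_per_node, walk_length, seed))


def _skipgram_pairs(
    walks_idx: list[np.ndarray], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within a fixed window."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for walk in walks_idx:
        L = len(walk)
        for offset in range(1, window + 1):
            if offset >= L:
                break
            # pairs (i, i+offset) in both directions
            centers.append(walk[:-offset])
            contexts.append(walk[offset:])
            centers.append(walk[offset:])
            contexts.append(walk[:-offset])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_embedding(
    corpus: WalkCorpus,
    dim: int = 16,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.3,
    min_learning_rate: float = 0.01,
    batch_size: int = 2048,
) -> NodeEmbedding:
    """Skip-gram with negative sampling over walks treated as sentences.

    Deterministic given the seed: vocabulary order is sorted and pair order
    is shuffled by a seeded generator. Each mini-batch applies, per embedding
    row, the *average* of that row's pair gradients (duplicate indices are
    accumulated with ``np.add.at`` and divided by their counts): on the small
    dense vocabularies of gene-set graphs a node recurs hundreds of times per
    batch, and summed stale-gradient updates diverge. The learning rate
    decays linearly across batches.
    """
    if dim < 1:
        raise ValueError("embedding dimension must be >= 1")
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({n for walk in corpus.walks for n in walk})
    index = {n: i for i, n in enumerate(vocab)}
    n_vocab = len(vocab)
    walks_idx = [np.array([index[n] for n in w], dtype=np.int64) for w in corpus.walks]

    centers, contexts = _skipgram_pairs(walks_idx, window)
    rng = np.random.default_rng(seed)
    # word2vec-style init: uniform input vectors, zero output vectors
    w_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    w_out = np.zeros((n_vocab, dim))

    if centers.size == 0:
        # corpus of isolated nodes only: no co-occurrence signal
        return NodeEmbedding(vocab, w_in)

    counts = np.bincount(np.concatenate(walks_idx), minlength=n_vocab).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    n_pairs = centers.size
    total_batches = epochs * int(np.ceil(n_pairs / batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = order[lo : lo + batch_size]
            c = centers[sel]
            pos = contexts[sel]
            neg = rng.choice(n_vocab, size=(sel.size, negative), p=noise)
            lr = learning_rate + (min_learning_rate - learning_rate) * (
                batch_no / max(1, total_batches - 1)
            )
            batch_no += 1

            v_c = w_in[c]  # (B, d)
            targets = np.concatenate([pos[:, None], neg], axis=1)  # (B, 1+neg)
            v_t = w_out[targets]  # (B, 1+neg, d)
            score = np.einsum("bd,bkd->bk", v_c, v_t)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = label - sig  # (B, 1+neg)

            grad_c = np.einsum("bk,bkd->bd", err, v_t)
            grad_t = (err[:, :, None] * v_c[:, None, :]).reshape(-1, dim)
            flat_t = targets.ravel()

            acc_in = np.zeros_like(w_in)
            np.add.at(acc_in, c, grad_c)
            cnt_in = np.bincount(c, minlength=n_vocab).astype(float)
            rows = cnt_in > 0
            w_in[rows] += lr * acc_in[rows] / cnt_in[rows, None]

            acc_out = np.zeros_like(w_out)
            np.add.at(acc_out, flat_t, grad_t)
            cnt_out = np.bincount(flat_t, minlength=n_vocab).astype(float)
            rows = cnt_out > 0
            w_out[rows] += lr * acc_out[rows] / cnt_out[rows, None]

    return NodeEmbedding(vocab, w_in)


def embed_graph(graph: nx.Graph, params: EmbeddingParams | None = None) -> NodeEmbedding:
    """Walk sampling + skip-gram training for one graph.

    If the graph has no more nodes than the requested dimension, the
    dimension is reduced to max(2, n_nodes - 1) to avoid degenerate
    embeddings of tiny gene-set graphs.
    """
    if params is None:
        params = EmbeddingParams()
    if len(graph) == 0:
        raise ValueError("cannot embed an empty graph")
    dim = params.dim
    if len(graph) <= dim:
        dim = max(2, len(graph) - 1)
    corpus = sample_walks(graph, params.walks_per_node, params.walk_length, params.seed)
    return train_embedding(
        corpus,
        dim=dim,
        window=params.window,
        epochs=params.epochs,
        seed=params.seed,
        negative=params.negative,
        learning_rate=params.learning_rate,
        min_learning_rate=params.min_learning_rate,
        batch_size=params.batch_size,
    )
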