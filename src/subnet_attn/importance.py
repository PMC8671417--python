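"""Biomarker ranking from attention maps and a permutation enrichment test.

Feature importance of subnetwork t is the mean attention weight over
samples, FI_t = (1/N) sum_n h_nt; since each sample's attention weights lie
on the simplex, so does FI. Subnetworks are then ranked ascending: FIR_t = 1
for the smallest FI, T for the largest, ties broken by subnetwork order.

A reference gene set (e.g. the PAM50 genes) is scored against the ranking:
each reference gene found in at least one subnetwork gets RANK_g, the mean
FIR over the subnetworks containing it, and SCORE is the mean RANK_g over
those genes. The permutation test shuffles the FIR values across
subnetworks, recomputes the score, and reports the empirical p-value
p = #(permuted score > observed score) / iterations — strict inequality, no
+1 smoothing by default (``add_one=True`` gives the conservative
(x+1)/(n+1) variant). A high observed score (reference genes concentrated in
high-attention subnetworks) therefore yields a small p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discovery import SubnetworkPartition


@dataclass
class FeatureImportanceRanking:
    subnetwork_ids: list[str]
    fi: np.ndarray  # mean attention per subnetwork; sums to 1
    fir: np.ndarray  # ascending integer ranks, 1..T


def feature_importance(H: np.ndarray, subnetwork_ids: list[str]) -> FeatureImportanceRanking:
    """Mean attention per subnetwork and its ascending rank.

    ``H`` stacks per-sample attention maps, shape (n_samples, T).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("need at least one attention map")
    if H.shape[1] != len(subnetwork_ids):
        raise ValueError("attention width does not match subnetwork count")
    fi = H.mean(axis=0)
    order = np.argsort(fi, kind="stable")  # ties broken by subnetwork order
    fir = np.empty(len(fi), dtype=int)
    fir[order] = np.arange(1, len(fi) + 1)
    return FeatureImportanceRanking(list(subnetwork_ids), fi, fir)


def _reference_weights(
    reference_genes: list[str], partition: SubnetworkPartition
) -> tuple[np.ndarray, list[str]]:
    """Per-subnetwork weights w with SCORE = w . FIR, plus excluded genes.

    RANK_g averages FIR over the subnetworks containing g, and SCORE
    averages RANK_g over covered genes; both averages are linear in FIR, so
    SCORE collapses to a fixed weight vector dotted with (possibly permuted)
    FIR. Genes in no subnetwork are excluded from the average.
    """
    genes = list(dict.fromkeys(reference_genes))
    sub = partition.membership(genes)  # (G, T)
    per_gene = sub.sum(axis=1)
    covered = per_gene > 0
    excluded = [g for g, c in zip(genes, covered) if not c]
    if not covered.any():
        raise ValueError("no reference gene belongs to any subnetwork")
    w = (sub[covered] / per_gene[covered, None]).mean(axis=0)
    return w, excluded


def geneset_score(
    reference_genes: list[str],
    partition: SubnetworkPartition,
    fir: FeatureImportanceRanking,
) -> tuple[float, list[str]]:
    """Observed enrichment score of a reference gene set; excluded genes reported."""
    w, excluded = _reference_weights(reference_genes, partition)
    return float(w @ fir.fir), excluded


@dataclass
class PermutationResult:
    score: float
    iterations: int
    exceed_count: int
    p_value: float
    excluded_genes: list[str]
    seed: int


def permutation_test(
    reference_genes: list[str],
    partition: SubnetworkPartition,
    fir: FeatureImportanceRanking,
    iterations: int = 1_000_000,
    seed: int = 0,
    add_one: bool = False,
    chunk: int = 20_000,
) -> PermutationResult:
    """Empirical p-value of the reference score under shuffled rankings."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    w, excluded = _reference_weights(reference_genes, partition)
    base = float(w @ fir.fir)
    rng = np.random.default_rng(seed)
    ranks = fir.fir.astype(float)
    exceed = 0
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        perms = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
        scores = perms @ w
        exceed += int((scores > base + 1e-12).sum())
        done += m
    if add_one:
        p = (exceed + 1) / (iterations + 1)
    else:
        p = exceed / iterations
    return PermutationResult(base, iterations, exceed, float(p), excluded, seed)


def write_ranking(fir: FeatureImportanceRanking, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("subnetwork_id\tFI\tFIR\n")
        for sid, fi, r in zip(fir.subnetwork_ids, fir.fi, fir.fir):
            fh.write(f"{sid}\t{fi:.10g}\t{r}\n")
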