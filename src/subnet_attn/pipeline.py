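"""End-to-end orchestration: discover -> represent -> train -> evaluate -> rank.

The pipeline chains the stages behind one configuration with named seeds:

1. stratified train/test split (or explicit pre-split id lists, mirroring
   the cross-cohort design where train and test are different cohorts);
2. subnetwork discovery on the PPI graph restricted to each gene set;
3. per-subnetwork supervised representations, fitted on training samples
   only and applied to all samples;
4. attention training on the training representations;
5. prediction and metric reports on train and test sets;
6. feature-importance ranking of subnetworks (attention averaged over a
   configurable sample scope: train, test or all);
7. optionally, the permutation enrichment test of a reference gene list.

Every stage derives its seed from the master seed, so a rerun with the same
configuration reproduces all numeric artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import attention as attn
from .data_io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleLabels,
    load_expression,
    load_gmt,
    load_labels,
    load_ppi_edges,
)
from .deepwalk import EmbeddingParams
from .discovery import GmmParams, SubnetworkPartition, discover_subnetworks
from .evaluation import summarize
from .importance import (
    FeatureImportanceRanking,
    PermutationResult,
    feature_importance,
    permutation_test,
)
from .representation import RepresentationTensor, SubnetworkModel, build_representation
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)


def split_samples(
    labels: SampleLabels, test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Class-balanced random split: per class, floor(fraction * size) to test.

    Deterministic given the seed. Classes with fewer than 2 samples are
    rejected (they cannot appear on both sides).
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.array(labels.sample_ids)
    labs = np.array(labels.labels)
    train: list[str] = []
    test: list[str] = []
    for cls in labels.class_set:
        members = ids[labs == cls]
        if members.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        members = rng.permutation(members)
        n_test = int(np.floor(test_fraction * members.size))
        test.extend(members[:n_test])
        train.extend(members[n_test:])
    order = {s: i for i, s in enumerate(labels.sample_ids)}
    return sorted(train, key=order.get), sorted(test, key=order.get)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; seeds derive from ``seed``."""

    test_fraction: float = 0.3
    train_ids: list[str] | None = None  # explicit pre-split overrides fraction
    test_ids: list[str] | None = None
    embed: EmbeddingParams = field(default_factory=EmbeddingParams)
    gmm: GmmParams = field(default_factory=GmmParams)
    min_size: int = 3
    pair_mode: str = "all_pairs"
    reg_strength: float = 1.0
    log_expression: bool = False
    attention: attn.TrainConfig = field(default_factory=attn.TrainConfig)
    attention_avg_over: str = "all"  # {train, test, all}
    reference_genes: list[str] | None = None
    permutation_iterations: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.train_ids is None) != (self.test_ids is None):
            raise ValueError("train_ids and test_ids must be given together")
        if self.train_ids is not None and set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sample sets overlap")
        if self.attention_avg_over not in ("train", "test", "all"):
            raise ValueError("attention_avg_over must be train, test or all")

    def resolve_seeds(self) -> dict[str, int]:
        base = int(self.seed) % (2**31 - 10)
        return {
            "split": base,
            "embed": base + 1,
            "gmm": base + 2,
            "represent": base + 3,
            "attention": base + 4,
            "permutation": base + 5,
        }


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a plain (YAML-loaded) mapping."""
    kwargs = dict(raw)
    if "embed" in kwargs:
        kwargs["embed"] = EmbeddingParams(**kwargs["embed"])
    if "gmm" in kwargs:
        kwargs["gmm"] = GmmParams(**kwargs["gmm"])
    if "attention" in kwargs:
        kwargs["attention"] = attn.TrainConfig(**kwargs["attention"])
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    partition: SubnetworkPartition
    models: list[SubnetworkModel]
    representation: RepresentationTensor
    attention_model: attn.AttentionModel
    train_ids: list[str]
    test_ids: list[str]
    metrics_train: dict[str, float | None]
    metrics_test: dict[str, float | None]
    prediction_test: attn.PredictionResult
    attention_all: np.ndarray  # (n_samples, T), sample order of the expression matrix
    ranking: FeatureImportanceRanking
    permutation: PermutationResult | None


def run_pipeline(
    expression: ExpressionMatrix,
    labels: SampleLabels,
    ppi,
    genesets: GeneSetCollection,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full workflow on in-memory inputs (see module docstring)."""
    if config is None:
        config = PipelineConfig()
    seeds = config.resolve_seeds()

    if config.log_expression:
        expression = ExpressionMatrix(
            expression.sample_ids, expression.gene_ids, np.log1p(expression.values)
        )

    if config.train_ids is not None:
        train_ids, test_ids = list(config.train_ids), list(config.test_ids)
    else:
        train_ids, test_ids = split_samples(labels, config.test_fraction, seeds["split"])
    logger.info("split: %d train / %d test samples", len(train_ids), len(test_ids))

    embed_params = EmbeddingParams(**{**vars(config.embed), "seed": seeds["embed"]})
    gmm_params = GmmParams(**{**vars(config.gmm), "seed": seeds["gmm"]})
    partition = discover_subnetworks(
        ppi, genesets, embed_params, gmm_params, config.min_size
    )
    if not partition.subnetworks:
        raise RuntimeError("discovery stage produced no subnetworks")
    logger.info("discovered %d subnetworks", len(partition.subnetworks))

    labels_train = labels.subset(train_ids)
    labels_test = labels.subset(test_ids)
    models, rep_all = build_representation(
        expression,
        labels_train,
        partition,
        pair_mode=config.pair_mode,
        reg_strength=config.reg_strength,
        seed=seeds["represent"],
        graph=ppi,
    )
    rep_train = rep_all.subset_samples(train_ids)
    rep_test = rep_all.subset_samples(test_ids)

    train_cfg = attn.TrainConfig(**{**vars(config.attention), "seed": seeds["attention"]})
    model = attn.train(rep_train, labels_train, train_cfg)

    pred_train, H_train = attn.predict(model, rep_train)
    pred_test, H_test = attn.predict(model, rep_test)
    metrics_train = summarize(pred_train.predicted, pred_train.f, labels_train)
    metrics_test = summarize(pred_test.predicted, pred_test.f, labels_test)

    _, H_all = attn.predict(model, rep_all)
    scope = {"train": H_train, "test": H_test, "all": H_all}[config.attention_avg_over]
    ranking = feature_importance(scope, rep_all.subnetwork_ids)

    permutation = None
    if config.reference_genes:
        permutation = permutation_test(
            config.reference_genes,
            partition,
            ranking,
            iterations=config.permutation_iterations,
            seed=seeds["permutation"],
        )

    return PipelineResult(
        partition=partition,
        models=models,
        representation=rep_all,
        attention_model=model,
        train_ids=train_ids,
        test_ids=test_ids,
        metrics_train=metrics_train,
        metrics_test=metrics_test,
        prediction_test=pred_test,
        attention_all=H_all,
        ranking=ranking,
        permutation=permutation,
    )


def run_on_dataset(dataset: SyntheticDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Convenience wrapper for synthetic datasets."""
    return run_pipeline(
        dataset.expression, dataset.labels, dataset.ppi, dataset.genesets, config
    )


def load_inputs(
    expression_path: str,
    labels_path: str,
    ppi_path: str,
    gmt_path: str,
    genes_in_rows: bool = True,
) -> tuple[ExpressionMatrix, SampleLabels, Any, GeneSetCollection]:
    """Load and cross-check the four standard input files.

    Samples present in expression but unlabeled (or vice versa) are an
    error; gene-set genes absent from expression or PPI are reported by the
    downstream stages, not here.
    """
    expr = load_expression(expression_path, genes_in_rows=genes_in_rows)
    labels = load_labels(labels_path)
    ppi = load_ppi_edges(ppi_path)
    genesets = load_gmt(gmt_path)
    missing = set(expr.sample_ids) ^ set(labels.sample_ids)
    if missing:
        raise ValueError(f"samples not shared by expression and labels: {sorted(missing)[:10]}")
    labels = labels.subset(expr.sample_ids)  # align order
    return expr, labels, ppi, genesets
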