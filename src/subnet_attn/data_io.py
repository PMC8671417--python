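"""Readers, writers and containers for the pipeline's standard inputs.

Four files describe a study: a TPM expression matrix (TSV, genes in rows by
default, firebrowse-style), per-sample class labels (2-column TSV), gene sets
(MSigDB GMT dialect) and a protein-protein interaction (PPI) edge list
(2-column TSV of gene symbols). Gene identifiers are plain symbols, treated
case-sensitively, with no mapping layer: symbols that do not match across
files are reported and dropped, never silently fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of non-negative TPM values."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")
        if (self.values < 0).any():
            raise ValueError("negative expression values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_columns(self, genes: list[str]) -> np.ndarray:
        """Sub-matrix (samples x len(genes)) in the given gene order."""
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        idx = [self._gene_index[g] for g in genes]
        return self.values[:, idx]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(sample_ids), list(self.gene_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class SampleLabels:
    """One class label per sample; class_set is the ordered set of classes."""

    sample_ids: list[str]
    labels: list[str]
    class_set: list[str] = field(default=None)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in labels")
        if self.class_set is None:
            self.class_set = sorted(set(self.labels))
        unknown = set(self.labels) - set(self.class_set)
        if unknown:
            raise ValueError(f"labels outside class_set: {sorted(unknown)}")

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def subset(self, sample_ids: list[str]) -> "SampleLabels":
        d = self.as_dict()
        return SampleLabels(list(sample_ids), [d[s] for s in sample_ids], list(self.class_set))

    def indicator(self, cls: str) -> np.ndarray:
        """Binary one-vs-rest target y_mk for class ``cls``."""
        return np.array([1.0 if l == cls else 0.0 for l in self.labels])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50 MSigDB hallmark sets)."""

    set_names: list[str]
    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(set(self.set_names)) != len(self.set_names):
            raise ValueError("duplicate gene-set names")
        for name in self.set_names:
            if not self.members.get(name):
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.set_names)

    def __getitem__(self, name: str) -> list[str]:
        return self.members[name]


def load_expression(
    path: str,
    log_transform: bool = False,
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Load a TPM matrix from TSV.

    Default orientation follows the firebrowse convention: rows are genes,
    columns are samples; set ``genes_in_rows=False`` for the transpose.
    With ``log_transform``, values become ln(TPM + 1).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing or ragged entries")
    if genes_in_rows:
        df = df.T
    mat = ExpressionMatrix(
        [str(s) for s in df.index], [str(g) for g in df.columns], df.to_numpy(dtype=float)
    )
    if log_transform:
        mat = ExpressionMatrix(mat.sample_ids, mat.gene_ids, np.log1p(mat.values))
    return mat


def write_expression(mat: ExpressionMatrix, path: str, genes_in_rows: bool = True) -> None:
    df = mat.to_frame()
    if genes_in_rows:
        df = df.T
    df.to_csv(path, sep="\t")


def load_labels(path: str) -> SampleLabels:
    """Two-column TSV (sample_id, label); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, label)")
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    return SampleLabels(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: SampleLabels, path: str) -> None:
    with open(path, "w") as fh:
        for s, l in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}\t{l}\n")


def load_gmt(path: str) -> GeneSetCollection:
    """Parse the MSigDB GMT dialect: name TAB description TAB gene1 TAB ...

    Duplicate genes within one line are deduplicated (first occurrence kept).
    """
    names: list[str] = []
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            names.append(name)
            members[name] = genes
    return GeneSetCollection(names, members)


def write_gmt(sets: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in sets.set_names:
            fh.write("\t".join([name, "na"] + sets.members[name]) + "\n")


def load_ppi_edges(path: str) -> nx.Graph:
    """Load a gene-symbol edge list into an undirected simple graph.

    Reversed duplicates collapse; self-loops are dropped (count logged);
    columns beyond the first two are ignored.
    """
    graph = nx.Graph()
    self_loops = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: edge line has fewer than 2 columns")
            u, v = fields[0], fields[1]
            n_rows += 1
            if u == v:
                self_loops += 1
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    if n_rows == 0:
        raise ValueError(f"{path}: empty edge list")
    if self_loops:
        logger.info("dropped %d self-loop edges from %s", self_loops, path)
    return graph


def write_ppi_edges(graph: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def induce_geneset_graph(ppi: nx.Graph, genes: list[str]) -> nx.Graph:
    """Subgraph of the PPI network on the genes of one gene set.

    Genes absent from the PPI node set are dropped (logged). An empty
    intersection yields an empty graph; downstream stages decide what to do.
    """
    present = [g for g in genes if ppi.has_node(g)]
    missing = len(genes) - len(present)
    if missing:
        logger.info("induce_geneset_graph: %d of %d genes absent from PPI", missing, len(genes))
    return nx.Graph(ppi.subgraph(present))
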