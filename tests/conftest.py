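import networkx as nx
import pytest


@pytest.fixture
def tiny_expression_tsv(tmp_path):
    """2-sample x 3-gene TSV, genes in rows (firebrowse orientation)."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\n"
        "GA\t1\t4\n"
        "GB\t2\t5\n"
        "GC\t3\t6\n"
    )
    return str(path)


@pytest.fixture
def two_clique_graph():
    """Two K5 cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(f"n{base + i}", f"n{base + j}")
    g.add_edge("n0", "n5")
    return g
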