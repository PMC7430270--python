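import numpy as np
import pytest

from spfa.data import ExpressionDataset
from spfa.pathways import PathwayGraph


def make_graph(edges, nodes=(), pathway_id="P1", name="toy"):
    """Build a PathwayGraph from an edge list plus optional isolated nodes."""
    node_set = set(nodes)
    for s, t in edges:
        node_set.update((s, t))
    return PathwayGraph(pathway_id, name, frozenset(node_set), frozenset(edges))


def make_dataset(gene_values, n_normal=None, n_disease=None):
    """Build an ExpressionDataset from {gene: (normal values, disease values)}.

    ``gene_values`` maps gene ID to a pair of equal-length-per-condition
    sequences.
    """
    genes = list(gene_values)
    normal = np.array([gene_values[g][0] for g in genes], dtype=float)
    disease = np.array([gene_values[g][1] for g in genes], dtype=float)
    ns, nd = normal.shape[1], disease.shape[1]
    samples = [f"n{i}" for i in range(ns)] + [f"d{i}" for i in range(nd)]
    condition = {s: ("normal" if s.startswith("n") else "disease") for s in samples}
    return ExpressionDataset(
        genes=genes,
        samples=samples,
        values=np.hstack([normal, disease]),
        condition=condition,
    )


def pearson(x, y):
    """Textbook Pearson correlation, independent of the package's route."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    return float((xm * ym).sum() / denom)


@pytest.fixture
def chain_graph():
    """A -> B -> C: C is the only effector."""
    return make_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
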