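import networkx as nx
import numpy as np
import pandas as pd
import pytest

import reversig as rv
from reversig.formats import OntologyDAG
from reversig.synthetic import nb_counts


def make_two_group_counts(
    seed: int,
    G: int = 500,
    n: int = 10,
    dispersion: float = 0.2,
    mean: float | None = None,
    lfc_idx: np.ndarray | None = None,
    lfc: float = 0.0,
    group_names: tuple[str, str] = ("disease", "control"),
) -> rv.CountsMatrix:
    """Two-group NB count matrix with an optional planted log2FC subset."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(4.0, 1.0, G) if mean is None else np.full(G, float(mean))
    m_test = base.copy()
    if lfc_idx is not None:
        m_test[lfc_idx] = base[lfc_idx] * 2.0**lfc
    cols, groups = {}, {}
    test, ref = group_names
    for i in range(n):
        cols[f"{ref}_{i}"] = nb_counts(rng, base, dispersion)
        groups[f"{ref}_{i}"] = ref
        cols[f"{test}_{i}"] = nb_counts(rng, m_test, dispersion)
        groups[f"{test}_{i}"] = test
    frame = pd.DataFrame(cols, index=[f"g{i:04d}" for i in range(G)])
    return rv.CountsMatrix(frame, groups)


@pytest.fixture(scope="session")
def toy_dag() -> OntologyDAG:
    """Six-term tree: A root; B, C below A; D, E below B; F below C.

    Four annotated genes: x1→D, x2→E, x3→F, x4→C.
    """
    g = nx.DiGraph()
    g.add_edges_from([("B", "A"), ("C", "A"), ("D", "B"), ("E", "B"), ("F", "C")])
    ann = {
        "x1": frozenset({"D"}),
        "x2": frozenset({"E"}),
        "x3": frozenset({"F"}),
        "x4": frozenset({"C"}),
    }
    return OntologyDAG(g, "A", ann)


@pytest.fixture(scope="session")
def small_de_tables() -> dict[str, pd.DataFrame]:
    """Hand-built DE tables for three contrasts over a 4-gene panel universe."""

    def table(rows):
        df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"]).set_index("gene")
        df["pvalue"] = df["padj"]
        return df

    return {
        "disease_vs_control": table(
            [("p1", 2.0, 0.001), ("p2", 1.5, 0.01), ("p3", 0.0, 0.9), ("p4", -2.0, 0.001)]
        ),
        "treated_vs_disease": table(
            [("p1", -1.8, 0.002), ("p2", -1.2, 0.03), ("p3", 0.0, 0.8), ("p4", 1.9, 0.004)]
        ),
        "treated_vs_control": table(
            [("p1", 0.2, 0.7), ("p2", 0.3, 0.6), ("p3", 0.0, 0.95), ("p4", -0.1, 0.8)]
        ),
    }
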