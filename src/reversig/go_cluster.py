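"""Semantic-similarity clustering of enriched ontology terms.

When enrichment returns hundreds of significant processes, related terms are
grouped so the result reads as a handful of themes.  Information content of
a term is IC(t) = −ln p(t), where p(t) is the fraction of annotated genes
hitting t or any of its descendants (annotations propagate to ancestors).
Pairwise distance follows Jiang–Conrath,

    d(t1, t2) = IC(t1) + IC(t2) − 2·IC(MICA),

with MICA the common ancestor of maximal IC, converted to a similarity by
sim = 1 − min(1, d).  Terms are then agglomeratively clustered (average
linkage on 1 − sim) and the tree cut at a height; each cluster is summarised
by the median NES of its members and the union of their leading-edge genes.

An alternative similarity backend measures the Jaccard overlap of the
members' leading-edge gene lists instead of ontology structure; it is
offered because theme grouping by shared leading genes is sometimes the more
interpretable choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .formats import OntologyDAG

__all__ = [
    "compute_ic",
    "jiang_similarity",
    "similarity_matrix",
    "leading_gene_similarity",
    "cluster_terms",
    "summarize_clusters",
    "compare_direction",
]


def compute_ic(dag: OntologyDAG) -> pd.Series:
    """Information content per term: IC(t) = −ln p(t), natural log.

    p(t) is the annotation probability — the fraction of all annotated genes
    carrying t directly or through any descendant.  The root always has
    p = 1, hence IC 0.  Terms no annotated gene reaches (p = 0) are excluded.
    """
    if not dag.annotations:
        raise ValueError("ontology has no gene annotations")
    per_term = dag.term_genes()
    n_genes = len(dag.annotations)
    ic = {
        t: -np.log(len(genes) / n_genes)
        for t, genes in per_term.items()
        if genes
    }
    return pd.Series(ic, name="ic").sort_index()


def jiang_similarity(t1: str, t2: str, ic: pd.Series, dag: OntologyDAG) -> float:
    """Jiang–Conrath similarity in [0, 1]: 1 − min(1, d_JC)."""
    for t in (t1, t2):
        if t not in ic.index:
            raise KeyError(f"term {t!r} has no information content")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common &= set(ic.index)
    if not common:
        raise ValueError(f"terms {t1!r} and {t2!r} share no ancestor")
    mica_ic = max(ic.loc[t] for t in common)
    d = float(ic.loc[t1] + ic.loc[t2] - 2.0 * mica_ic)
    return 1.0 - min(1.0, d)


def similarity_matrix(terms: list[str], ic: pd.Series, dag: OntologyDAG) -> pd.DataFrame:
    """Symmetric Jiang similarity matrix over the given terms."""
    n = len(terms)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jiang_similarity(terms[i], terms[j], ic, dag)
    return pd.DataFrame(mat, index=terms, columns=terms)


def leading_gene_similarity(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Jaccard similarity of leading-edge gene lists (alternative backend)."""
    terms = list(enrichment.index)
    sets = [set(filter(None, str(enrichment.loc[t, "leading_edge"]).split(","))) for t in terms]
    n = len(terms)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            mat[i, j] = mat[j, i] = (len(sets[i] & sets[j]) / len(union)) if union else 0.0
    return pd.DataFrame(mat, index=terms, columns=terms)


def cluster_terms(
    sim: pd.DataFrame,
    cut_height: float = 0.7,
    method: str = "average",
) -> dict[str, int]:
    """Agglomerative clustering on distance = 1 − similarity, cut at a height.

    Returns term → cluster id (1-based).  Singleton clusters are allowed; a
    single term trivially forms cluster 1.
    """
    mat = sim.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("similarity matrix must be square and symmetric")
    terms = list(sim.index)
    if len(terms) == 1:
        return {terms[0]: 1}
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method=method)
    labels = fcluster(z, t=cut_height, criterion="distance")
    return {t: int(c) for t, c in zip(terms, labels)}


def summarize_clusters(partition: dict[str, int], enrichment: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster summary: median NES, merged leading genes, auto label.

    The label is the member term of largest |NES| (ties by term id) — a
    deterministic stand-in for the manual naming a human would do.  Median
    uses the midpoint convention for even cluster sizes.
    """
    missing = [t for t in partition if t not in enrichment.index]
    if missing:
        raise KeyError(f"terms without enrichment rows: {missing[:5]}")
    rows = []
    for cid in sorted(set(partition.values())):
        members = sorted(t for t, c in partition.items() if c == cid)
        nes = enrichment.loc[members, "nes"].to_numpy(dtype=float)
        leading: set[str] = set()
        for t in members:
            leading |= set(filter(None, str(enrichment.loc[t, "leading_edge"]).split(",")))
        label = max(members, key=lambda t: (abs(enrichment.loc[t, "nes"]), t))
        rows.append(
            {
                "cluster": cid,
                "label": label,
                "size": len(members),
                "median_nes": float(np.median(nes)),
                "members": ",".join(members),
                "merged_leading_genes": ",".join(sorted(leading)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def compare_direction(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    min_jaccard: float = 0.5,
) -> pd.DataFrame:
    """Match clusters across two conditions and flag NES sign flips.

    Clusters are matched by Jaccard overlap of member terms (best match per
    cluster of A, kept when ≥ ``min_jaccard``).  A matched pair is
    ``reversed`` when the sign of the median NES differs — e.g. a process
    theme up in disease and down under treatment.
    """
    members_a = {c: set(str(r["members"]).split(",")) for c, r in summaries_a.iterrows()}
    members_b = {c: set(str(r["members"]).split(",")) for c, r in summaries_b.iterrows()}
    rows = []
    for ca, ma in members_a.items():
        best, best_j = None, 0.0
        for cb, mb in members_b.items():
            j = len(ma & mb) / len(ma | mb)
            if j > best_j:
                best, best_j = cb, j
        if best is None or best_j < min_jaccard:
            continue
        nes_a = float(summaries_a.loc[ca, "median_nes"])
        nes_b = float(summaries_b.loc[best, "median_nes"])
        rows.append(
            {
                "cluster_a": ca,
                "cluster_b": best,
                "jaccard": best_j,
                "median_nes_a": nes_a,
                "median_nes_b": nes_b,
                "sign_a": int(np.sign(nes_a)),
                "sign_b": int(np.sign(nes_b)),
                "reversed": bool(np.sign(nes_a) * np.sign(nes_b) < 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_a", "cluster_b", "jaccard",
            "median_nes_a", "median_nes_b", "sign_a", "sign_b", "reversed",
        ],
    )
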