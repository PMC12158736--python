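"""Readers, writers and validated containers for every on-disk format the
pipeline touches.

Canonical dialect: UTF-8 TSV with ``\\t`` separators, ``\\n`` line endings and
no quoting.  Gene identifiers are opaque, case-sensitive strings — no symbol
normalisation happens here; cross-namespace mapping is the ortholog map's job.
Every reader composed with its writer is the identity on canonical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountsMatrix",
    "GeneSetCollection",
    "OntologyDAG",
    "OrthologMap",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_dag",
    "read_ortholog_map",
    "write_ortholog_map",
    "write_table",
]


class FormatError(ValueError):
    """A malformed or inconsistent input file."""


_INT_RE = re.compile(r"^\d+$")


@dataclass
class CountsMatrix:
    """Non-negative integer gene × sample count table with per-sample labels.

    ``groups`` maps each sample id to a label.  For bulk data the labels are
    study arms (e.g. ``control`` / ``disease`` / ``treated``); for a
    single-cell matrix they are cell types.  Downstream stages validate the
    labels they need.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))[0]
                raise FormatError(
                    f"non-integer count at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group label: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def subset_genes(self, genes) -> "CountsMatrix":
        return CountsMatrix(self.counts.loc[list(genes)], dict(self.groups))


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (the GMT exchange model)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                raise FormatError(f"gene set {name!r} contains duplicate genes")
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def filter_by_size(self, min_size: int, max_size: int) -> "GeneSetCollection":
        kept = {n: g for n, g in self.sets.items() if min_size <= len(g) <= max_size}
        return GeneSetCollection(kept, {n: self.descriptions[n] for n in kept})


@dataclass
class OntologyDAG:
    """A rooted acyclic is_a hierarchy with direct gene annotations.

    Edges run child → parent, so ancestors of a term are its descendants in
    the underlying digraph.
    """

    graph: nx.DiGraph
    root: str
    annotations: dict[str, frozenset[str]]

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus every term reachable via is_a edges."""
        return frozenset(nx.descendants(self.graph, term)) | {term}

    def term_genes(self) -> dict[str, set[str]]:
        """Genes annotated to each term directly or through any descendant."""
        per_term: dict[str, set[str]] = {t: set() for t in self.graph.nodes}
        for gene, terms in self.annotations.items():
            for t in terms:
                for anc in self.ancestors(t):
                    per_term[anc].add(gene)
        return per_term


@dataclass
class OrthologMap:
    """Injective source → target gene-id map (e.g. human symbol → rat symbol)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        targets: dict[str, str] = {}
        for src, tgt in self.pairs.items():
            if tgt in targets:
                raise FormatError(
                    f"ortholog map is not one-to-one: {targets[tgt]!r} and {src!r} "
                    f"both map to {tgt!r}"
                )
            targets[tgt] = src

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, gene: str) -> str | None:
        return self.pairs.get(gene)


# ---------------------------------------------------------------------------
# counts TSV


def read_counts(path: str | Path, groups: Mapping[str, str]) -> CountsMatrix:
    """Read a gene × sample TSV (header = sample ids, first column = gene ids).

    Cells must be non-negative integers; violations raise :class:`FormatError`
    naming the offending gene and sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    raw = df.to_numpy()
    ok = np.vectorize(lambda s: bool(_INT_RE.match(s)))(raw) if raw.size else np.ones((0, 0), bool)
    if raw.size and not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{path}: cell value {raw[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} is not a non-negative integer"
        )
    counts = df.astype(np.int64)
    return CountsMatrix(counts, dict(groups))


def write_counts(cm: CountsMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(cm.sample_ids) + "\n")
        arr = cm.counts.to_numpy()
        for gene, row in zip(cm.gene_ids, arr):
            fh.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# ontology DAG


def read_dag(
    edges_path: str | Path,
    annotations_path: str | Path,
    virtual_root: str | None = None,
) -> OntologyDAG:
    """Read a child→parent edge list and a gene→term annotation list.

    The hierarchy must be acyclic with a unique root (a term with no parent).
    Multiple parentless terms are an error unless ``virtual_root`` names a
    synthetic root to attach them to — information content needs a unique
    root whose annotation probability is 1.
    """
    g = nx.DiGraph()
    for lineno, fields in _read_two_columns(edges_path):
        child, parent = fields
        g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise FormatError(f"{edges_path}: ontology contains a cycle: {cycle}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        if virtual_root is None:
            raise FormatError(
                f"{edges_path}: expected a single root, found {sorted(roots)}; "
                "configure a virtual root to join them"
            )
        for r in roots:
            g.add_edge(r, virtual_root)
        root = virtual_root
    else:
        root = roots[0]

    annotations: dict[str, set[str]] = {}
    for lineno, fields in _read_two_columns(annotations_path):
        gene, term = fields
        if term not in g.nodes:
            raise FormatError(
                f"{annotations_path}:{lineno}: annotation to unknown term {term!r}"
            )
        annotations.setdefault(gene, set()).add(term)
    frozen = {g_: frozenset(t) for g_, t in annotations.items()}
    return OntologyDAG(g, root, frozen)


def _read_two_columns(path: str | Path):
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            yield lineno, fields


# ---------------------------------------------------------------------------
# ortholog map


def read_ortholog_map(path: str | Path) -> OrthologMap:
    pairs: dict[str, str] = {}
    for lineno, (src, tgt) in _read_two_columns(path):
        if src in pairs and pairs[src] != tgt:
            raise FormatError(
                f"{path}:{lineno}: source {src!r} maps to both {pairs[src]!r} and {tgt!r}"
            )
        pairs[src] = tgt
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for src, tgt in omap.pairs.items():
            fh.write(f"{src}\t{tgt}\n")


# ---------------------------------------------------------------------------
# generic result tables


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as canonical TSV, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")
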