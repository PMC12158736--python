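"""Synthetic study generator.

Emulates the data the analysis assumes, with ground truth attached so every
downstream stage can be tested by parameter recovery:

* a labelled single-cell count matrix with known per-cell-type expression
  profiles (the stand-in for a public liver atlas used as deconvolution
  reference);
* bulk samples mixed from those profiles with planted group-wise cell-type
  proportions;
* a three-group (control / disease / treated) bulk count matrix with planted
  differential expression and a planted reversal fraction ρ — the fraction of
  disease-regulated genes whose mean the treatment returns to the control
  level;
* a random ontology with depth-dependent annotation frequencies plus the
  matching gene-set collection;
* an injective ortholog map covering a chosen fraction of a gene panel.

Counts are negative binomial with variance μ + α·μ² (α = dispersion), the
same parameterisation the differential-expression stage fits.  All generators
are pure functions of (parameters, seed); a single study-level seed expands
into per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import CountsMatrix, GeneSetCollection, OntologyDAG, OrthologMap

import networkx as nx

__all__ = [
    "SyntheticTruth",
    "CellProfileSet",
    "simulate_reference",
    "simulate_bulk",
    "simulate_three_group_counts",
    "simulate_annotation",
    "simulate_ortholog_map",
    "nb_counts",
    "STAGE_SEED_OFFSETS",
]

# fixed per-stage offsets from the study-level seed, so each stage is
# independently reproducible
STAGE_SEED_OFFSETS = {
    "reference": 11,
    "bulk": 23,
    "three_group": 37,
    "annotation": 53,
    "ortholog": 71,
}

GROUPS = ("control", "disease", "treated")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests; round-trips through JSON."""

    seed: int
    dispersion: float
    true_proportions: dict[str, list[float]] = field(default_factory=dict)
    cell_types: list[str] = field(default_factory=list)
    true_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    de_up: dict[str, list[str]] = field(default_factory=dict)
    de_down: dict[str, list[str]] = field(default_factory=dict)
    reversal_fraction: float | None = None
    reversed_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group, p in self.true_proportions.items():
            arr = np.asarray(p, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-8:
                raise ValueError(f"proportions for {group!r} must be >=0 and sum to 1")
        if self.reversal_fraction is not None and not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal fraction must lie in [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        return cls(**json.loads(text))


@dataclass
class CellProfileSet:
    """Per-cell-type mean expression over a shared gene universe."""

    profiles: pd.DataFrame  # genes × cell types, non-negative reals

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("profiles must be non-negative")
        if (self.profiles.to_numpy().sum(axis=0) == 0).any():
            raise ValueError("all-zero cell-type profile")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)


def nb_counts(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial draws with variance μ + α·μ² (Poisson when α≈0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _gene_ids(G: int) -> list[str]:
    width = len(str(G - 1))
    return [f"g{i:0{width}d}" for i in range(G)]


def simulate_reference(
    K: int,
    G: int,
    cells_per_type: int,
    seed: int,
    log_mean: float = 1.0,
    log_sd: float = 1.0,
    lib_size: int = 5_000,
    dispersion: float = 0.1,
) -> tuple[CountsMatrix, CellProfileSet]:
    """Simulate a labelled single-cell count matrix plus its generating truth.

    Per-type mean profiles are log-normal; each cell's counts are NB around
    the type mean scaled to ``lib_size`` expected counts per cell.
    """
    if K < 2:
        raise ValueError("need at least 2 cell types")
    if G < 10:
        raise ValueError("need at least 10 genes")
    if cells_per_type < 2:
        raise ValueError("need at least 2 cells per type")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(G)
    types = [f"type{k}" for k in range(K)]
    raw = rng.lognormal(mean=log_mean, sigma=log_sd, size=(G, K))
    profiles = pd.DataFrame(raw, index=genes, columns=types)

    blocks, labels, cell_ids = [], {}, []
    for k, t in enumerate(types):
        mean = raw[:, k] / raw[:, k].sum() * lib_size
        cells = nb_counts(rng, np.tile(mean, (cells_per_type, 1)), dispersion).T
        blocks.append(cells)
        for c in range(cells_per_type):
            cid = f"{t}_c{c}"
            cell_ids.append(cid)
            labels[cid] = t
    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cell_ids)
    return CountsMatrix(counts, labels), CellProfileSet(profiles)


def simulate_bulk(
    profiles: CellProfileSet,
    group_props: dict[str, list[float]],
    n_per_group: int,
    lib_size: int,
    dispersion: float,
    seed: int,
) -> tuple[CountsMatrix, SyntheticTruth]:
    """Mix bulk samples from cell-type profiles with planted proportions.

    Per-sample expected expression is
    ``lib_size × Σ_k p_k · profile_k / Σ_g profile_k`` and observed counts are
    NB(mean, α).
    """
    K = len(profiles.cell_types)
    norm = profiles.profiles.to_numpy() / profiles.profiles.to_numpy().sum(axis=0)
    for group, p in group_props.items():
        arr = np.asarray(p, dtype=float)
        if arr.shape != (K,):
            raise ValueError(f"proportion vector for {group!r} must have length {K}")
        if abs(arr.sum() - 1.0) > 1e-8:
            raise ValueError(f"proportions for {group!r} do not sum to 1")
    rng = np.random.default_rng(seed)
    cols, labels = {}, {}
    for group, p in group_props.items():
        mean = lib_size * norm @ np.asarray(p, dtype=float)
        for i in range(n_per_group):
            sid = f"{group}_s{i}"
            cols[sid] = nb_counts(rng, mean, dispersion)
            labels[sid] = group
    counts = pd.DataFrame(cols, index=profiles.gene_ids)
    truth = SyntheticTruth(
        seed=seed,
        dispersion=dispersion,
        true_proportions={g: list(map(float, p)) for g, p in group_props.items()},
        cell_types=profiles.cell_types,
    )
    return CountsMatrix(counts, labels), truth


def simulate_three_group_counts(
    G: int,
    n_per_group: int,
    frac_de: float,
    lfc_sd: float,
    reversal_fraction: float,
    dispersion: float,
    seed: int,
    base_log_mean: float = 4.0,
    base_log_sd: float = 1.0,
    reversal_multiplier: float = 1.0,
) -> tuple[CountsMatrix, SyntheticTruth]:
    """Simulate the three-arm study design with a planted reversal fraction.

    A ``frac_de`` subset of genes is differentially expressed between disease
    and control with |log2FC| ~ |Normal(0, lfc_sd)|, half up and half down.
    A ``reversal_fraction`` ρ of the disease-up genes (and symmetrically of
    the disease-down genes) gets a treatment effect returning the mean toward
    the control level; ``reversal_multiplier`` = 1 restores it fully, which
    makes ρ identifiable.  Remaining genes keep the disease mean under
    treatment.
    """
    if not 0 <= frac_de <= 1 or not 0 <= reversal_fraction <= 1:
        raise ValueError("frac_de and reversal_fraction must lie in [0, 1]")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(G)
    base = rng.lognormal(mean=base_log_mean, sigma=base_log_sd, size=G)

    n_de = int(round(frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    magnitudes = np.abs(rng.normal(0.0, lfc_sd, size=n_de))
    signs = np.ones(n_de)
    signs[rng.permutation(n_de)[: n_de // 2]] = -1.0
    disease_lfc = np.zeros(G)
    disease_lfc[de_idx] = signs * magnitudes

    up_idx = de_idx[signs > 0]
    down_idx = de_idx[signs < 0]
    n_rev_up = int(round(reversal_fraction * len(up_idx)))
    n_rev_down = int(round(reversal_fraction * len(down_idx)))
    rev_idx = np.concatenate(
        [
            rng.choice(up_idx, size=n_rev_up, replace=False) if n_rev_up else np.empty(0, int),
            rng.choice(down_idx, size=n_rev_down, replace=False) if n_rev_down else np.empty(0, int),
        ]
    ).astype(int)

    # treated-vs-disease effect: reversed genes move back toward control
    treated_lfc = np.zeros(G)
    treated_lfc[rev_idx] = -reversal_multiplier * disease_lfc[rev_idx]

    mean_control = base
    mean_disease = base * 2.0 ** disease_lfc
    mean_treated = mean_disease * 2.0 ** treated_lfc

    cols, labels = {}, {}
    for group, mean in (
        ("control", mean_control),
        ("disease", mean_disease),
        ("treated", mean_treated),
    ):
        for i in range(n_per_group):
            sid = f"{group}_s{i}"
            cols[sid] = nb_counts(rng, mean, dispersion)
            labels[sid] = group
    counts = pd.DataFrame(cols, index=genes)

    gname = np.asarray(genes)
    truth = SyntheticTruth(
        seed=seed,
        dispersion=dispersion,
        true_log2fc={
            "disease_vs_control": {g: float(v) for g, v in zip(genes, disease_lfc) if v != 0},
            "treated_vs_disease": {g: float(v) for g, v in zip(genes, treated_lfc) if v != 0},
        },
        de_up={
            "disease_vs_control": sorted(gname[up_idx]),
            "treated_vs_disease": sorted(gname[rev_idx[disease_lfc[rev_idx] < 0]]),
        },
        de_down={
            "disease_vs_control": sorted(gname[down_idx]),
            "treated_vs_disease": sorted(gname[rev_idx[disease_lfc[rev_idx] > 0]]),
        },
        reversal_fraction=reversal_fraction,
        reversed_genes=sorted(gname[rev_idx]),
    )
    return CountsMatrix(counts, labels), truth


def simulate_annotation(
    n_terms: int,
    genes: list[str],
    depth: int,
    seed: int,
    branching: int = 2,
    annotations_per_gene: int = 3,
    block_assign: bool = False,
) -> tuple[OntologyDAG, GeneSetCollection]:
    """Random rooted ontology tree plus the matching GMT collection.

    Terms are laid out level by level to the stated depth; each gene draws
    ``annotations_per_gene`` direct annotations with deeper terms less
    likely, so term annotation frequency decreases with depth (as in real
    ontologies).  The gene set of a term is every gene annotated at or below
    it.

    ``block_assign`` additionally annotates consecutive genes (in the order
    given) to the same non-root term, emulating the coherent functional
    modules of a real ontology; callers who order genes by regulation class
    obtain terms that genuinely concentrate a signal.
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    terms = [f"T{i:03d}" for i in range(n_terms)]
    g.add_node(terms[0])
    levels: dict[str, int] = {terms[0]: 0}
    for i, t in enumerate(terms[1:], start=1):
        # parent chosen among existing terms above the max depth
        candidates = [u for u in levels if levels[u] < depth]
        parent = candidates[rng.integers(len(candidates))]
        if branching > 1 and rng.random() < 0.5:
            # bias toward recent terms to get a bushy tree
            recent = [u for u in terms[max(0, i - branching): i] if levels[u] < depth]
            if recent:
                parent = recent[rng.integers(len(recent))]
        g.add_edge(t, parent)
        levels[t] = levels[parent] + 1

    weights = np.array([2.0 ** -levels[t] for t in terms])
    # the root annotates trivially; skip it for direct annotation draws
    weights[0] = 0.0
    weights /= weights.sum()
    annotations: dict[str, frozenset[str]] = {}
    block = max(1, len(genes) // (n_terms - 1)) if block_assign else 0
    for i, gene in enumerate(genes):
        k = min(annotations_per_gene, n_terms - 1)
        chosen = set(rng.choice(terms, size=k, replace=False, p=weights))
        if block_assign:
            chosen.add(terms[1 + min(i // block, n_terms - 2)])
        annotations[gene] = frozenset(chosen)

    dag = OntologyDAG(g, terms[0], annotations)
    per_term = dag.term_genes()
    sets = {t: sorted(gs) for t, gs in per_term.items() if gs}
    collection = GeneSetCollection(sets, {t: f"synthetic term level {levels[t]}" for t in sets})
    return dag, collection


def simulate_ortholog_map(
    source_genes: list[str],
    mapped_fraction: float,
    seed: int,
    target_genes: list[str] | None = None,
    prefix: str = "orth_",
) -> OrthologMap:
    """Map exactly round(mapped_fraction × n) source genes injectively.

    Targets come from ``target_genes`` when given (sampled without
    replacement), otherwise are freshly named with ``prefix``.
    """
    if not 0 <= mapped_fraction <= 1:
        raise ValueError("mapped_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mapped = int(round(mapped_fraction * len(source_genes)))
    chosen = sorted(rng.choice(len(source_genes), size=n_mapped, replace=False))
    pairs: dict[str, str] = {}
    if target_genes is not None:
        if len(target_genes) < n_mapped:
            raise ValueError("not enough target genes for the requested fraction")
        targets = rng.choice(target_genes, size=n_mapped, replace=False)
        for i, tgt in zip(chosen, targets):
            pairs[source_genes[i]] = str(tgt)
    else:
        for i in chosen:
            pairs[source_genes[i]] = f"{prefix}{source_genes[i]}"
    return OrthologMap(pairs)
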