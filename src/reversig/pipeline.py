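"""End-to-end orchestration: one YAML config in, a directory of stage TSVs
plus a JSON run manifest out.

Stage order: gene filtering → size factors → NB Wald differential expression
for the three contrasts (disease vs control, treated vs disease, treated vs
control) → DEG calling → reversal statistic and biomarker panel → preranked
GSEA per contrast → semantic clustering of enriched terms with cross-
condition direction comparison → ridge deconvolution.  Every unstated
default is materialised into the manifest so a run is self-describing, and
all randomness derives from the single config seed; two runs of the same
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffexpr, go_cluster, gsea, reversal, synthetic
from .deconvolution import build_reference, deconvolve_cohort
from .formats import (
    CountsMatrix,
    read_counts,
    read_dag,
    read_gmt,
    read_ortholog_map,
    write_counts,
    write_gmt,
    write_table,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "synth_preset_config"]

logger = logging.getLogger(__name__)

CONTRASTS = [
    ("disease_vs_control", ("disease", "control")),
    ("treated_vs_disease", ("treated", "disease")),
    ("treated_vs_control", ("treated", "control")),
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``counts``/``groups`` paths or a ``synthetic`` generation block
    must be present.  Unset options take the documented defaults below,
    which are all written into the run manifest.
    """

    output_dir: str
    counts: str | None = None
    groups: dict[str, str] | None = None
    synthetic: dict | None = None
    gene_sets: str | None = None
    dag_edges: str | None = None
    dag_annotations: str | None = None
    ortholog_map: str | None = None
    sc_counts: str | None = None
    sc_labels: str | None = None
    panel: list[str] = field(default_factory=list)
    seed: int = 0
    lfc_min: float = 1.0
    alpha: float = 0.05
    gsea_n_perm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_exponent: float = 1.0
    gsea_sig_alpha: float = 0.05
    cluster_cut_height: float = 0.7
    cluster_linkage: str = "average"
    cluster_backend: str = "jiang"  # or "leading_genes"
    cluster_min_jaccard: float = 0.5
    deconv_lambda: float | str = "cv"
    deconv_mode: str = "per-group"

    def __post_init__(self) -> None:
        if self.synthetic is None and (self.counts is None or self.groups is None):
            raise ValueError("config needs either counts+groups paths or a synthetic block")
        if self.cluster_backend not in ("jiang", "leading_genes"):
            raise ValueError(f"unknown cluster backend {self.cluster_backend!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def synth_preset_config(output_dir: str, seed: int = 7) -> RunConfig:
    """The default synthetic three-arm study emulating the pipeline's design.

    2000 genes, 6 samples per arm, 30% of genes differentially expressed with
    |log2FC| ~ |N(0, 2)|, full reversal (ρ = 1), NB dispersion 0.2; a 25-gene
    biomarker panel of which 20 have orthologs; a 60-term ontology; a 5-type
    single-cell reference of 80 cells per type mixed into the deconvolution
    arm with distinct per-group compositions.
    """
    return RunConfig(
        output_dir=output_dir,
        seed=seed,
        gsea_n_perm=5000,
        synthetic={
            "G": 2000,
            "n_per_group": 6,
            "frac_de": 0.3,
            "lfc_sd": 2.0,
            "reversal_fraction": 1.0,
            "dispersion": 0.2,
            "n_terms": 60,
            "depth": 4,
            "panel_size": 25,
            "panel_mapped_fraction": 0.8,
            "K": 5,
            "cells_per_type": 80,
            "bulk_lib_size": 300_000,
            "group_proportions": {
                "control": [0.55, 0.15, 0.12, 0.10, 0.08],
                "disease": [0.35, 0.15, 0.12, 0.08, 0.30],
                "treated": [0.50, 0.15, 0.12, 0.09, 0.14],
            },
        },
    )


def _config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _generate_synthetic(config: RunConfig, out: Path) -> dict:
    """Materialise the synthetic study into the output directory."""
    s = dict(config.synthetic)
    seed = config.seed
    off = synthetic.STAGE_SEED_OFFSETS

    counts, truth = synthetic.simulate_three_group_counts(
        G=s.get("G", 2000),
        n_per_group=s.get("n_per_group", 6),
        frac_de=s.get("frac_de", 0.3),
        lfc_sd=s.get("lfc_sd", 2.0),
        reversal_fraction=s.get("reversal_fraction", 1.0),
        dispersion=s.get("dispersion", 0.2),
        seed=seed + off["three_group"],
    )
    write_counts(counts, out / "synthetic_counts.tsv")
    truth.to_json(out / "synthetic_truth.json")

    # genes ordered by regulation class so block-assigned terms form coherent
    # up/down modules, the structure real disease ontologies show
    up_set = set(truth.de_up["disease_vs_control"])
    down_set = set(truth.de_down["disease_vs_control"])
    ordered = (
        sorted(up_set)
        + sorted(down_set)
        + [g for g in counts.gene_ids if g not in up_set and g not in down_set]
    )
    dag, collection = synthetic.simulate_annotation(
        n_terms=s.get("n_terms", 60),
        genes=ordered,
        depth=s.get("depth", 4),
        seed=seed + off["annotation"],
        block_assign=True,
    )
    write_gmt(collection, out / "synthetic_sets.gmt")

    # biomarker panel: "human" ids whose orthologs are planted disease-up,
    # fully reversed genes — the strongest candidates a marker panel would hold
    panel_size = s.get("panel_size", 25)
    up = [g for g in truth.de_up["disease_vs_control"] if g in set(truth.reversed_genes)]
    panel_sources = [f"HUM{i:03d}" for i in range(panel_size)]
    omap = synthetic.simulate_ortholog_map(
        panel_sources,
        mapped_fraction=s.get("panel_mapped_fraction", 0.8),
        seed=seed + off["ortholog"],
        target_genes=up,
    )

    sc_counts, profiles = synthetic.simulate_reference(
        K=s.get("K", 5),
        G=s.get("G", 2000),
        cells_per_type=s.get("cells_per_type", 80),
        seed=seed + off["reference"],
    )
    write_counts(sc_counts, out / "synthetic_single_cell.tsv")
    bulk_mix, mix_truth = synthetic.simulate_bulk(
        profiles,
        group_props=s.get(
            "group_proportions",
            synth_preset_config(str(out)).synthetic["group_proportions"],
        ),
        n_per_group=s.get("n_per_group", 6),
        lib_size=s.get("bulk_lib_size", 300_000),
        dispersion=s.get("dispersion", 0.2),
        seed=seed + off["bulk"],
    )
    write_counts(bulk_mix, out / "synthetic_bulk_mixture.tsv")
    mix_truth.to_json(out / "synthetic_mixture_truth.json")

    return {
        "counts": counts,
        "dag": dag,
        "collection": collection,
        "omap": omap,
        "panel": panel_sources,
        "sc_counts": sc_counts,
        "deconv_bulk": bulk_mix,
        "truth": truth,
        "mix_truth": mix_truth,
    }


def _load_inputs(config: RunConfig, out: Path) -> dict:
    if config.synthetic is not None:
        return _generate_synthetic(config, out)
    inputs: dict = {
        "counts": read_counts(config.counts, config.groups),
        "dag": None,
        "collection": None,
        "omap": None,
        "panel": list(config.panel),
        "sc_counts": None,
        "deconv_bulk": None,
        "truth": None,
    }
    if config.gene_sets:
        inputs["collection"] = read_gmt(config.gene_sets)
    if config.dag_edges and config.dag_annotations:
        inputs["dag"] = read_dag(config.dag_edges, config.dag_annotations)
    if config.ortholog_map:
        inputs["omap"] = read_ortholog_map(config.ortholog_map)
    if config.sc_counts and config.sc_labels:
        labels = dict(
            pd.read_csv(config.sc_labels, sep="\t", header=None, dtype=str).itertuples(
                index=False, name=None
            )
        )
        inputs["sc_counts"] = read_counts(config.sc_counts, labels)
    return inputs


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are renamed with a ``.partial`` suffix so a
    truncated run is never mistaken for a complete one.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        write_table(df, path, index=index)
        written.append(path)

    stage = "inputs"
    try:
        inputs = _load_inputs(config, out)
        counts: CountsMatrix = inputs["counts"]

        stage = "filter"
        counts = diffexpr.filter_unexpressed(counts)

        stage = "size_factors"
        size_factors = diffexpr.estimate_size_factors(counts)
        emit(size_factors.rename_axis("sample").reset_index(), "size_factors.tsv")

        stage = "differential_expression"
        tables: dict[str, pd.DataFrame] = {}
        for name, (test, ref) in CONTRASTS:
            disp = diffexpr.estimate_dispersions(counts, size_factors, groups=[test, ref])
            table = diffexpr.fit_nb_wald(counts, size_factors, disp, (test, ref))
            tables[name] = table
            emit(table.rename_axis("gene").reset_index(), f"de_{name}.tsv")

        stage = "deg_calling"
        degs = {
            name: diffexpr.call_degs(
                tables[name], contrast=name, lfc_min=config.lfc_min, alpha=config.alpha
            )
            for name, _ in CONTRASTS
        }
        deg_rows = [
            {"contrast": name, "n_up": d.n_up, "n_down": d.n_down, "n_total": d.n_total}
            for name, d in degs.items()
        ]
        emit(pd.DataFrame(deg_rows), "deg_counts.tsv")

        stage = "reversal"
        rev = reversal.reversal_statistic(
            degs["disease_vs_control"], degs["treated_vs_disease"]
        )
        emit(rev.summary_frame(), "reversal_summary.tsv")
        if inputs["panel"]:
            mapped, unmapped = (
                reversal.map_panel(inputs["panel"], inputs["omap"])
                if inputs["omap"]
                else (inputs["panel"], [])
            )
            status = reversal.panel_status(
                mapped,
                tables["disease_vs_control"],
                tables["treated_vs_disease"],
                tables["treated_vs_control"],
                lfc_min=config.lfc_min,
                alpha=config.alpha,
            )
            emit(status.reset_index(), "panel_status.tsv")
            emit(
                pd.DataFrame(
                    {"unmapped_source_gene": unmapped}
                    if unmapped
                    else {"unmapped_source_gene": []}
                ),
                "panel_unmapped.tsv",
            )

        stage = "gsea"
        enrich: dict[str, pd.DataFrame] = {}
        if inputs["collection"] is not None:
            for i, (name, _) in enumerate(CONTRASTS[:2]):
                ranked = gsea.make_ranked_list(tables[name])
                res = gsea.gsea_run(
                    ranked,
                    inputs["collection"],
                    n_perm=config.gsea_n_perm,
                    seed=config.seed + 1000 + i,
                    min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                    exponent=config.gsea_exponent,
                )
                enrich[name] = res
                emit(res.reset_index(), f"gsea_{name}.tsv")

        stage = "clustering"
        summaries: dict[str, pd.DataFrame] = {}
        if enrich and (inputs["dag"] is not None or config.cluster_backend == "leading_genes"):
            ic = go_cluster.compute_ic(inputs["dag"]) if inputs["dag"] is not None else None
            for name, res in enrich.items():
                sig = res[res["padj"] < config.gsea_sig_alpha]
                if len(sig) == 0:
                    continue
                if config.cluster_backend == "jiang":
                    terms = [t for t in sig.index if t in ic.index]
                    if not terms:
                        continue
                    sim = go_cluster.similarity_matrix(terms, ic, inputs["dag"])
                else:
                    sim = go_cluster.leading_gene_similarity(sig)
                part = go_cluster.cluster_terms(
                    sim,
                    cut_height=config.cluster_cut_height,
                    method=config.cluster_linkage,
                )
                summary = go_cluster.summarize_clusters(part, res)
                summaries[name] = summary
                emit(summary.reset_index(), f"clusters_{name}.tsv")
            if len(summaries) == 2:
                comparison = go_cluster.compare_direction(
                    summaries["disease_vs_control"],
                    summaries["treated_vs_disease"],
                    min_jaccard=config.cluster_min_jaccard,
                )
                emit(comparison, "cluster_direction.tsv")

        stage = "deconvolution"
        if inputs["sc_counts"] is not None:
            reference = build_reference(inputs["sc_counts"])
            target_bulk = inputs["deconv_bulk"] if inputs["deconv_bulk"] is not None else counts
            deconv = deconvolve_cohort(
                target_bulk,
                reference,
                omap=None,
                lam=config.deconv_lambda,
                mode=config.deconv_mode,
                seed=config.seed,
            )
            emit(deconv, "deconvolution.tsv")

        stage = "manifest"
        manifest = {
            "package": "reversig",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "outputs": [p.name for p in written],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    except Exception as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return out
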