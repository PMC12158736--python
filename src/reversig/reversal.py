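"""Direction-reversal statistics and biomarker-panel assessment.

The headline question of the three-group design: of the genes a treatment
down-regulates (relative to disease), what fraction had been up-regulated by
the disease (relative to control)?  A high fraction means the treatment
reverses the disease expression signature rather than perturbing unrelated
genes.  The statistic is computed on thresholded DEG sets, not raw signs.

The panel utilities track a marker gene list (e.g. human disease biomarkers)
through an ortholog map and across the three contrasts, reporting per-gene
direction and whether the treatment mitigated the disease effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .diffexpr import DEGSets
from .formats import OrthologMap

__all__ = ["ReversalResult", "reversal_statistic", "map_panel", "panel_status"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ReversalResult:
    """Overlap of treatment-down DEGs with disease-up DEGs (and the mirror)."""

    n_down_treated: int
    n_overlap_down_treated_up_disease: int
    n_up_treated: int
    n_overlap_up_treated_down_disease: int

    @property
    def fraction(self) -> float | None:
        """Share of treatment-down genes that were disease-up; None if undefined."""
        if self.n_down_treated == 0:
            return None
        return self.n_overlap_down_treated_up_disease / self.n_down_treated

    @property
    def fraction_mirror(self) -> float | None:
        if self.n_up_treated == 0:
            return None
        return self.n_overlap_up_treated_down_disease / self.n_up_treated

    @property
    def percent(self) -> int | None:
        """Fraction × 100 rounded half away from zero, as conventionally printed."""
        return None if self.fraction is None else _round_half_away(100.0 * self.fraction)

    @property
    def percent_mirror(self) -> int | None:
        f = self.fraction_mirror
        return None if f is None else _round_half_away(100.0 * f)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direction": ["treated_down_in_disease_up", "treated_up_in_disease_down"],
                "n_treated": [self.n_down_treated, self.n_up_treated],
                "n_overlap": [
                    self.n_overlap_down_treated_up_disease,
                    self.n_overlap_up_treated_down_disease,
                ],
                "fraction": [self.fraction, self.fraction_mirror],
                "percent": [self.percent, self.percent_mirror],
            }
        )


def reversal_statistic(degs_disease: DEGSets, degs_treated: DEGSets) -> ReversalResult:
    """Fraction of treatment DEGs that reverse disease DEGs, both directions.

    ``degs_disease`` is the disease-vs-control contrast, ``degs_treated`` the
    treated-vs-disease contrast, both over the same gene universe.  An empty
    treated set leaves the corresponding fraction undefined (None), never 0.
    """
    down_rev = degs_treated.down & degs_disease.up
    up_rev = degs_treated.up & degs_disease.down
    return ReversalResult(
        n_down_treated=len(degs_treated.down),
        n_overlap_down_treated_up_disease=len(down_rev),
        n_up_treated=len(degs_treated.up),
        n_overlap_up_treated_down_disease=len(up_rev),
    )


def map_panel(panel: list[str], omap: OrthologMap) -> tuple[list[str], list[str]]:
    """Map a gene panel through an ortholog map, order-preserving.

    Returns (mapped target ids, unmapped source ids); together they partition
    the panel.  The unmapped remainder is itself a result and is never
    silently dropped.
    """
    mapped = [omap.pairs[g] for g in panel if g in omap.pairs]
    unmapped = [g for g in panel if g not in omap.pairs]
    return mapped, unmapped


def _direction(gene: str, table: pd.DataFrame, lfc_min: float, alpha: float) -> str:
    if gene not in table.index:
        return "absent"
    row = table.loc[gene]
    if row["padj"] < alpha and row["log2fc"] > lfc_min:
        return "up"
    if row["padj"] < alpha and row["log2fc"] < -lfc_min:
        return "down"
    return "ns"


def panel_status(
    panel: list[str],
    de_disease_vs_ctrl: pd.DataFrame,
    de_treated_vs_disease: pd.DataFrame,
    de_treated_vs_ctrl: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-panel-gene direction in each contrast plus a mitigation flag.

    ``mitigated`` is True when |log2fc(treated vs control)| <
    |log2fc(disease vs control)| — the treatment pulled the gene back toward
    the control level — and is only defined when both contrasts estimated the
    gene; otherwise it is reported False with ``mitigated_defined`` False.
    """
    rows = []
    for gene in panel:
        d_dis = _direction(gene, de_disease_vs_ctrl, lfc_min, alpha)
        d_trt = _direction(gene, de_treated_vs_disease, lfc_min, alpha)
        d_tvc = _direction(gene, de_treated_vs_ctrl, lfc_min, alpha)
        have_both = gene in de_disease_vs_ctrl.index and gene in de_treated_vs_ctrl.index
        mitigated = bool(
            have_both
            and abs(de_treated_vs_ctrl.loc[gene, "log2fc"])
            < abs(de_disease_vs_ctrl.loc[gene, "log2fc"])
        )
        rows.append(
            {
                "gene": gene,
                "disease_vs_control": d_dis,
                "treated_vs_disease": d_trt,
                "treated_vs_control": d_tvc,
                "mitigated": mitigated,
                "mitigated_defined": have_both,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def panel_summary(status: pd.DataFrame) -> dict[str, int]:
    """Counts of panel genes up in disease, down under treatment, mitigated."""
    return {
        "n_panel": int(len(status)),
        "n_up_in_disease": int((status["disease_vs_control"] == "up").sum()),
        "n_down_under_treatment": int((status["treated_vs_disease"] == "down").sum()),
        "n_mitigated": int((status["mitigated"] & status["mitigated_defined"]).sum()),
        "n_absent": int((status["disease_vs_control"] == "absent").sum()),
    }
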