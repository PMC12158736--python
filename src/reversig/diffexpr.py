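"""Negative-binomial differential expression for a labelled count matrix.

The stage mirrors the standard bulk RNA-seq workflow: drop genes with no
reads, normalise libraries with median-of-ratios size factors, estimate a
per-gene NB dispersion, fit a two-group NB GLM (log link, size factors as
offsets) per gene, test the group coefficient with a two-sided Wald test,
adjust p-values by Benjamini–Hochberg, and call DEGs at |log2FC| > 1 and
adjusted p < 0.05 (strict inequalities).

Design notes
------------
Dispersions are per-gene method-of-moments estimates pooled across the
contrast groups, moderated toward their across-gene mean (a constant common
dispersion, not a fitted mean-dispersion trend) and floored at 1e-8.  Log2
fold changes are the raw GLM
estimates; no shrinkage is applied.  Wald p-values use the normal
approximation.  The shifted-log "VST" here is a display scaling only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import CountsMatrix

__all__ = [
    "DEGSets",
    "filter_unexpressed",
    "estimate_size_factors",
    "estimate_dispersions",
    "fit_nb_wald",
    "adjust_bh",
    "call_degs",
    "vst_scale",
    "ddct_fold_change",
]

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

#: columns of a DE result table
DE_COLUMNS = ["base_mean", "log2fc", "se", "wald", "pvalue", "padj", "dispersion"]


@dataclass
class DEGSets:
    """Thresholded up/down gene sets for one contrast."""

    contrast: str
    up: frozenset[str]
    down: frozenset[str]
    lfc_min: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DEG sets overlap")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down)


def filter_unexpressed(counts: CountsMatrix) -> CountsMatrix:
    """Drop genes with no reads in any sample, preserving gene order."""
    keep = counts.counts.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("no expressed genes left after filtering")
    return CountsMatrix(counts.counts.loc[keep], dict(counts.groups))


def estimate_size_factors(counts: CountsMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene expressed in every sample, compute the ratio of its count
    to its across-sample geometric mean; a sample's factor is the median of
    those ratios.  ``pseudo_reference=True`` relaxes the all-samples
    requirement by building the geometric mean over positive counts only.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene is expressed in every sample; re-run with "
                "pseudo_reference=True to build the reference over positive counts"
            )
        use = (mat > 0).any(axis=1)
        logmat = np.where(mat > 0, np.log(np.where(mat > 0, mat, 1.0)), np.nan)
        geo = np.exp(np.nanmean(logmat[use], axis=1))
        ratios = np.where(mat[use] > 0, mat[use] / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        sub = mat[all_positive]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    if (factors <= 0).any() or not np.all(np.isfinite(factors)):
        raise ValueError("non-positive size factor estimated")
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def estimate_dispersions(
    counts: CountsMatrix,
    size_factors: pd.Series,
    groups: list[str] | None = None,
    prior_df: float = 20.0,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalised counts.

    Within each group the sample variance in excess of the Poisson part is
    converted to α via var = μ + α·μ², with two small-sample bias
    corrections: the Poisson part of a normalised count scales as μ/s, so
    the subtracted term is m·mean(1/s), and the squared group mean
    overestimates μ² by var/n, so the denominator is m² − v/n.  Group
    estimates are pooled by their degrees of freedom.

    Raw per-gene estimates are then moderated toward the across-gene mean
    with ``prior_df`` pseudo-degrees of freedom (0 disables), because at
    typical group sizes the per-gene estimator is noisy enough to make the
    downstream Wald test anticonservative.  The result is floored at 1e-8.
    """
    if groups is None:
        groups = sorted(set(counts.groups.values()))
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    norm = counts.counts.to_numpy(dtype=float) / sf
    num = np.zeros(counts.n_genes)
    den = np.zeros(counts.n_genes)
    labels = np.asarray([counts.groups[s] for s in counts.sample_ids])
    for group in groups:
        sel = labels == group
        n = int(sel.sum())
        if n < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        sub = norm[:, sel]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / sf[sel]))
        # cap the μ² de-noising correction at 4x and the per-gene estimate at
        # ±10: at small n the raw ratio is heavy-tailed and a single
        # degenerate gene must not dominate the moderation target
        denom = np.maximum(m**2 - v / n, 0.25 * m**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = (v - m * inv_s) / denom
        alpha_g = np.clip(np.where(np.isfinite(alpha_g), alpha_g, 0.0), -10.0, 10.0)
        num += (n - 1) * alpha_g
        den += n - 1
    raw = num / den
    if prior_df > 0:
        # the raw MoM estimates are unbiased but right-skewed; their mean is
        # the unbiased common-dispersion target (the median would under-centre)
        center = float(np.mean(raw))
        raw = (den * raw + prior_df * center) / (den + prior_df)
    alpha = np.maximum(raw, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def fit_nb_wald(
    counts: CountsMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test for ``contrast = (test_group, reference_group)``.

    The model is log μ = offset + β₀ + β₁·1[test group] with the log size
    factor as offset; log2fc = β₁/ln 2 and the Wald statistic is β₁/se(β₁)
    tested against a standard normal, two-sided.  Genes whose fit fails get
    no p-value and are dropped from the returned table, as are their rows in
    every downstream stage.
    """
    test_group, ref_group = contrast
    samples = [s for s in counts.sample_ids if counts.groups[s] in (test_group, ref_group)]
    for g in contrast:
        if sum(counts.groups[s] == g for s in samples) < 2:
            raise ValueError(f"contrast group {g!r} has fewer than 2 samples")
    y_all = counts.counts[samples].to_numpy(dtype=float)
    sf = size_factors.loc[samples].to_numpy(dtype=float)
    offset = np.log(sf)
    indicator = np.asarray([1.0 if counts.groups[s] == test_group else 0.0 for s in samples])
    design = sm.add_constant(indicator)
    base_mean = (y_all / sf).mean(axis=1)

    records = []
    dropped = 0
    for i, gene in enumerate(counts.gene_ids):
        alpha = max(float(dispersions.loc[gene]), DISPERSION_FLOOR)
        try:
            model = sm.GLM(
                y_all[i],
                design,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            )
            res = model.fit()
            beta, se = res.params[1], res.bse[1]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                raise ValueError("non-finite estimate")
        except Exception:  # noqa: BLE001 - any failed fit means no p-value
            dropped += 1
            continue
        wald = beta / se
        pvalue = 2.0 * stats.norm.sf(abs(wald))
        records.append(
            (gene, base_mean[i], beta / LN2, se / LN2, wald, pvalue, alpha)
        )
    if dropped:
        logger.info("fit_nb_wald: %d gene(s) failed to converge and were dropped", dropped)
    table = pd.DataFrame.from_records(
        records,
        columns=["gene", "base_mean", "log2fc", "se", "wald", "pvalue", "dispersion"],
    ).set_index("gene")
    table["padj"] = adjust_bh(table["pvalue"].to_numpy()) if len(table) else []
    return table[DE_COLUMNS]


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    contrast: str = "",
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> DEGSets:
    """Call DEGs at |log2fc| > lfc_min and padj < alpha (strict)."""
    sig = table["padj"] < alpha
    up = frozenset(table.index[sig & (table["log2fc"] > lfc_min)])
    down = frozenset(table.index[sig & (table["log2fc"] < -lfc_min)])
    return DEGSets(contrast=contrast, up=up, down=down, lfc_min=lfc_min, alpha=alpha)


def vst_scale(counts: CountsMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Shifted-log of normalised counts, then per-gene z-scaling.

    t(x) = log2(x / factor + 1) per sample, each gene row standardised to
    mean 0 and sd 1 across samples.  Constant genes scale to all zeros.
    Intended for heatmap display, not inference.
    """
    norm = counts.counts.to_numpy(dtype=float) / size_factors.loc[counts.sample_ids].to_numpy()
    t = np.log2(norm + 1.0)
    mean = t.mean(axis=1, keepdims=True)
    sd = t.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.info("vst_scale: %d constant gene(s) scaled to zeros", int(constant.sum()))
    sd[sd == 0] = 1.0
    scaled = (t - mean) / sd
    return pd.DataFrame(scaled, index=counts.gene_ids, columns=counts.sample_ids)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^−ΔΔCT method.

    ΔΔCT = (CT_target − CT_reference)_sample − (CT_target − CT_reference)_calibrator.
    """
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0**-ddct)
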