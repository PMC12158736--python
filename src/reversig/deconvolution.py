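"""Reference-based cell-type deconvolution of bulk expression by ridge
regression.

A labelled single-cell matrix is aggregated into a signature matrix: the
per-cell-type mean of per-cell CPM-normalised counts, each column rescaled
to counts-per-million.  A bulk profile (CPM) is then modelled as a
non-negative mixture of the signatures.  Coefficients come from L2-penalised
least squares solved in closed form,

    β = (XᵀX + λI)⁻¹ Xᵀ y,

on an internally standardised problem (columns of X scaled, y centred) and
back-transformed.  Negative coefficients are zeroed and the remainder is
renormalised to proportions summing to 1 — the convention that keeps the
estimate interpretable as a composition.  λ can be fixed or chosen by k-fold
cross-validation over genes.

Mixing is linear in transcript abundance, which is why both reference and
bulk live in linear CPM space here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CountsMatrix, OrthologMap

__all__ = [
    "ReferenceMatrix",
    "build_reference",
    "match_genes",
    "ridge_fit",
    "select_lambda",
    "to_proportions",
    "deconvolve_cohort",
]

CPM_SCALE = 1e6
MIN_SHARED_GENES = 50
DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-3, 4, dtype=float))


@dataclass
class ReferenceMatrix:
    """Genes × cell-types signature matrix in CPM units."""

    signatures: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.signatures.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signatures must be non-negative")
        if (arr.sum(axis=0) == 0).any():
            raise ValueError("all-zero cell-type signature column")

    @property
    def cell_types(self) -> list[str]:
        return list(self.signatures.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signatures.index)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column; columns with zero total stay zero."""
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    totals[totals == 0] = 1.0
    return counts / totals * CPM_SCALE


def build_reference(sc_counts: CountsMatrix) -> ReferenceMatrix:
    """Aggregate a labelled single-cell matrix into per-type CPM signatures.

    Each cell is CPM-normalised (so sequencing depth per cell cancels), cells
    of a type are averaged, and every signature column is rescaled back to
    CPM so the types share a common scale.
    """
    labels = pd.Series({s: sc_counts.groups[s] for s in sc_counts.sample_ids})
    type_counts = labels.value_counts()
    if len(type_counts) < 2:
        raise ValueError("need at least 2 cell types")
    small = type_counts[type_counts < 2]
    if len(small):
        raise ValueError(f"cell type(s) with fewer than 2 cells: {list(small.index)}")
    norm = cpm(sc_counts.counts.astype(float))
    sig = {}
    for cell_type in sorted(type_counts.index):
        cells = labels.index[labels == cell_type]
        profile = norm[cells].mean(axis=1)
        total = profile.sum()
        sig[cell_type] = profile / total * CPM_SCALE if total > 0 else profile
    return ReferenceMatrix(pd.DataFrame(sig, index=sc_counts.gene_ids))


def match_genes(
    reference: ReferenceMatrix,
    bulk: CountsMatrix,
    omap: OrthologMap | None = None,
    min_shared: int = MIN_SHARED_GENES,
) -> tuple[ReferenceMatrix, CountsMatrix]:
    """Align reference and bulk to a shared, ordered gene universe.

    ``omap`` translates reference gene ids into the bulk namespace (identity
    when None).  Only genes present on both sides after mapping are kept;
    fewer than ``min_shared`` shared genes aborts, because the fit would be
    unstable.
    """
    if omap is None:
        mapped = {g: g for g in reference.gene_ids}
    else:
        mapped = {g: omap.pairs[g] for g in reference.gene_ids if g in omap.pairs}
    bulk_genes = set(bulk.gene_ids)
    keep_ref = [g for g in reference.gene_ids if mapped.get(g) in bulk_genes]
    if len(keep_ref) < min_shared:
        raise ValueError(
            f"only {len(keep_ref)} genes shared between reference and bulk "
            f"(need ≥ {min_shared})"
        )
    sig = reference.signatures.loc[keep_ref].copy()
    sig.index = [mapped[g] for g in keep_ref]
    aligned_bulk = bulk.subset_genes(list(sig.index))
    return ReferenceMatrix(sig), aligned_bulk


def ridge_fit(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    standardize: bool = True,
) -> np.ndarray:
    """Closed-form ridge solution β = argmin ‖y − Xβ‖² + λ‖β‖².

    With ``standardize`` the columns of X are scaled to unit standard
    deviation and both X and y are centred before solving; coefficients are
    rescaled back to the original units (the centring absorbs the
    intercept).  λ = 0 requires full column rank.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if standardize:
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0, ddof=0)
        x_sd[x_sd == 0] = 1.0
        Xs = (X - x_mean) / x_sd
        ys = y - y.mean()
    else:
        x_sd = np.ones(X.shape[1])
        Xs = X
        ys = y
    gram = Xs.T @ Xs + lam * np.eye(X.shape[1])
    if lam == 0 and np.linalg.matrix_rank(gram) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "singular system at lambda=0 (collinear signatures); use lambda > 0"
        )
    beta_s = np.linalg.solve(gram, Xs.T @ ys)
    return beta_s / x_sd


def select_lambda(
    y: np.ndarray,
    X: np.ndarray,
    grid=DEFAULT_LAMBDA_GRID,
    k_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[float, pd.DataFrame]:
    """k-fold cross-validation over genes for the ridge penalty.

    Genes (rows) are shuffled deterministically under ``seed`` and split into
    folds; for each λ the out-of-fold mean squared prediction error is
    averaged.  Returns (λ*, per-λ CV table).  Ties prefer the smaller λ.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty lambda grid")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    k_folds = min(k_folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    errors = np.zeros(len(grid))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        for i, lam in enumerate(grid):
            try:
                beta = ridge_fit(y[mask], X[mask], lam, standardize=standardize)
            except np.linalg.LinAlgError:
                errors[i] += np.inf
                continue
            if standardize:
                resid = (y[fold] - y[mask].mean()) - (X[fold] - X[mask].mean(axis=0)) @ beta
            else:
                resid = y[fold] - X[fold] @ beta
            errors[i] += float(np.mean(resid**2))
    errors /= k_folds
    table = pd.DataFrame({"lambda": grid, "cv_mse": errors})
    best = int(np.lexsort((grid, errors))[0])
    return grid[best], table


def to_proportions(beta: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero negative coefficients and renormalise the rest to sum to 1.

    Returns (proportions, defined).  When every coefficient is ≤ 0 the
    proportions are undefined: the vector is all-NaN and ``defined`` is
    False — never silently uniform.
    """
    beta = np.asarray(beta, dtype=float)
    clipped = np.clip(beta, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.full_like(beta, np.nan), False
    return clipped / total, True


def deconvolve_cohort(
    bulk: CountsMatrix,
    reference: ReferenceMatrix,
    omap: OrthologMap | None = None,
    lam: float | str = "cv",
    mode: str = "per-group",
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Estimate cell-type composition per study group (or per sample).

    ``per-group`` (default) fits the group's mean CPM profile — one
    composition per arm, mirroring a cohort-level readout; ``per-sample``
    fits every sample and averages the proportions within each group,
    which exposes between-sample variability to the caller.  ``lam`` is a
    fixed penalty or ``"cv"`` for cross-validated selection on each fitted
    profile.
    """
    if mode not in ("per-group", "per-sample"):
        raise ValueError(f"unknown mode {mode!r}")
    ref, aligned = match_genes(reference, bulk, omap)
    X = ref.signatures.to_numpy(dtype=float)
    bulk_cpm = cpm(aligned.counts.astype(float))
    groups = sorted(set(aligned.groups.values()))

    def _fit(y: np.ndarray) -> tuple[np.ndarray, float, float]:
        if lam == "cv":
            lam_used, _ = select_lambda(y, X, seed=seed, standardize=standardize)
        else:
            lam_used = float(lam)
        beta = ridge_fit(y, X, lam_used, standardize=standardize)
        if standardize:
            resid = float(np.linalg.norm((y - y.mean()) - (X - X.mean(axis=0)) @ beta))
        else:
            resid = float(np.linalg.norm(y - X @ beta))
        return beta, lam_used, resid

    rows = []
    for group in groups:
        samples = aligned.samples_in_group(group)
        if not samples:
            raise ValueError(f"no samples in group {group!r}")
        if mode == "per-group":
            y = bulk_cpm[samples].mean(axis=1).to_numpy(dtype=float)
            beta, lam_used, resid = _fit(y)
            props, defined = to_proportions(beta)
            for k, ct in enumerate(ref.cell_types):
                rows.append(
                    {
                        "group": group,
                        "sample": "",
                        "cell_type": ct,
                        "beta": beta[k],
                        "proportion": props[k],
                        "defined": defined,
                        "lambda": lam_used,
                        "n_genes": X.shape[0],
                        "residual_norm": resid,
                    }
                )
        else:
            per_sample = []
            for s in samples:
                y = bulk_cpm[s].to_numpy(dtype=float)
                beta, lam_used, resid = _fit(y)
                props, defined = to_proportions(beta)
                per_sample.append(props)
                for k, ct in enumerate(ref.cell_types):
                    rows.append(
                        {
                            "group": group,
                            "sample": s,
                            "cell_type": ct,
                            "beta": beta[k],
                            "proportion": props[k],
                            "defined": defined,
                            "lambda": lam_used,
                            "n_genes": X.shape[0],
                            "residual_norm": resid,
                        }
                    )
            mean_props = np.nanmean(np.vstack(per_sample), axis=0)
            for k, ct in enumerate(ref.cell_types):
                rows.append(
                    {
                        "group": group,
                        "sample": "<group mean>",
                        "cell_type": ct,
                        "beta": np.nan,
                        "proportion": mean_props[k],
                        "defined": True,
                        "lambda": np.nan,
                        "n_genes": X.shape[0],
                        "residual_norm": np.nan,
                    }
                )
    return pd.DataFrame(rows)
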