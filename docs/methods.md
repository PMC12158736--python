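# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Study design and data model

The pipeline consumes a gene × sample matrix of non-negative integer counts
with each sample labelled `control`, `disease` or `treated`
(disease + treatment).  Counts for gene *g* in sample *j* are modelled as
negative binomial with mean μ_gj and dispersion α_g, parameterised so that
Var = μ + α·μ².  Library depth enters through per-sample size factors s_j.

## Differential expression

**Filtering.** Genes with zero reads across all samples are removed before
any estimation; genes whose GLM fit fails are dropped from the result table
(they have no p-value) and therefore from every downstream stage.

**Normalisation.** Size factors are the median-of-ratios: for genes positive
in every sample, s_j = median_g ( c_gj / geomean_g ).  Factors are defined
up to a common rescaling; no rescaling is applied.  If no gene is positive
everywhere, a pseudo-reference over positive counts is available behind an
explicit flag rather than silently.

**Dispersion.** Per gene, a method-of-moments estimate on normalised counts
is formed within each contrast group and pooled by degrees of freedom:
α̂ = (v − m·mean(1/s)) / (m² − v/n), where m and v are the within-group mean
and unbiased variance.  Two small-sample corrections are built in: the
Poisson part of a normalised count scales as μ/s (hence the mean(1/s)
factor), and m² overestimates μ² by v/n (hence the denominator).  The
denominator correction is capped at 4× and the raw per-gene value clipped to
[−10, 10], because at n ≈ 6 the raw ratio is heavy-tailed and a single
degenerate gene must not dominate what follows.  Raw estimates are then
moderated toward their across-gene **mean** with `prior_df = 20`
pseudo-degrees of freedom (weight ≈ ½ at 10 samples/group) and floored at
1e-8.  Rationale: with a plug-in dispersion the Wald test is
anticonservative in proportion to the estimator's noise; moderation toward a
constant common-dispersion target (deliberately *not* a fitted
mean–dispersion trend, to keep the estimator transparent) brings the null
type-I error at nominal 0.05 to ≈ 0.055 across simulation replicates at
G = 2000, n = 10/group, α = 0.2.  The mean, not the median, is the centre
because the raw estimates are right-skewed and the median under-centres
them.  `prior_df = 0` disables moderation.

**Testing.** For contrast (test, reference) each gene gets a two-column GLM
log μ = log s_j + β₀ + β₁·1[test], fit by IRLS (statsmodels, NB family with
the moderated α̂ fixed).  log2FC = β₁/ln 2, Wald z = β₁/se(β₁), two-sided
normal p-value, Benjamini–Hochberg adjustment across genes.  Log2FC is the
raw maximum-likelihood estimate; no shrinkage is applied, and the DEG
thresholds — |log2FC| > 1 and p-adj < 0.05, both strict — are applied to the
unshrunk estimate.

**Display scaling.** The "scaled VST" used for heatmaps is
log2(count/s + 1) followed by per-gene standardisation to mean 0, sd 1.
It is a display transform only; nothing is tested on it.  A gene constant
across samples scales to a row of zeros (logged).

**qPCR.** Relative expression by 2^−ΔΔCT, with
ΔΔCT = (CT_target − CT_ref)_sample − (CT_target − CT_ref)_calibrator.

## Reversal statistic and biomarker panel

The reversal statistic is computed on DEG *sets*, not raw signs: of the
genes called down in treated-vs-disease, the fraction also called up in
disease-vs-control (and the mirror).  Percentages round half away from zero.
An empty treated set leaves the fraction undefined (None), never 0.

Two properties of this statistic matter for interpreting recovery tests.
First, it estimates P(disease-up | treatment-down), which is near 1 whenever
the planted reversal is faithful, regardless of what fraction ρ of disease
genes was reverted — ρ controls the *size* of the treated DEG set, not the
overlap fraction.  Second, even with every planted gene fully reverted the
observed fraction sits below 1: the treated-down set contains
FDR-controlled false discoveries, and genes with true |log2FC| near the
threshold are called in one contrast but missed in the other (independent
estimation noise on two contrasts sharing the disease arm).  At G = 2000,
n = 6/group and |log2FC| ~ |N(0, 2)| this dilution leaves the observed
fraction around 0.85–0.95.  The end-to-end check therefore asks whether the
overlap is *statistically incompatible with chance* (exact binomial test
against the disease-up rate of the universe), not whether it reaches 1
exactly.

Biomarker panels are mapped through a validated injective ortholog map;
unmapped panel genes are reported, never dropped — the reduction (e.g.
25 → 20) is itself a result.  Per panel gene the pipeline reports the DEG
direction in each of the three contrasts and a `mitigated` flag:
|log2FC(treated vs control)| < |log2FC(disease vs control)|, defined only
when both contrasts estimated the gene.

## Preranked GSEA

Genes are ranked by log2FC descending, ties broken by gene id (so ranking is
total and deterministic).  For set S in a universe of N genes the running
sum steps up by |score|^p / Σ_hits |score|^p at members and down by
1/(N − |S|) otherwise; ES is the value of largest magnitude over all N
positions (earliest position wins exact ties), and the leading edge is the
members at/before the extremum for ES > 0, strictly after it for ES < 0.
If every member carries score 0, hit steps fall back to equal weights.

The null permutes gene labels: random subsets of the universe of the same
effective size are re-scored; sets of equal size share one null sample,
which changes nothing in distribution but keeps large collections cheap.
NES divides ES by the mean |null ES| of the same sign (sign-stratified
normalisation); p = (1 + #{same-sign nulls with |ES_null| ≥ |ES|}) /
(1 + #same-sign nulls), so p is never 0; family-wise adjustment is
Bonferroni over the tested sets.

Defaults: exponent p = 1, min_size = 10, max_size = 500, n_perm = 1000.
Note an interaction users should know: with Bonferroni over m sets, the
smallest achievable adjusted p is roughly m / (1 + n_perm/2); testing many
sets at few permutations makes significance unreachable.  The bundled
synthetic preset uses n_perm = 5000 for this reason.  Multilevel p-value
refinement and FDR q-values are deliberately out of scope.

## Semantic clustering of enriched terms

Annotations propagate from a term to all ancestors in the is_a DAG (unique
root required; multiple roots are an error unless a virtual root is
configured).  p(t) is the fraction of annotated genes reaching t;
IC(t) = −ln p(t) (natural log — any other base is a monotone rescaling), so
IC(root) = 0 and IC is monotone non-decreasing along child → parent edges
reversed.  Jiang–Conrath distance d = IC(t₁) + IC(t₂) − 2·IC(MICA) is turned
into sim = 1 − min(1, d), the convention that keeps similarity in [0, 1]
with sim(t, t) = 1.

Enriched terms (Bonferroni p-adj below the configured level) are clustered
agglomeratively on distance 1 − sim with average linkage and a flat cut at
height 0.7 (both configurable; the cut and linkage are reported in the run
manifest since no single convention exists).  Each cluster is summarised by
the median NES of its members (midpoint convention for even sizes), the
exact union of their leading edges, and an automatic label — the member of
largest |NES| — standing in for the manual naming a curator would do.
An alternative similarity backend uses the Jaccard overlap of leading-edge
gene lists instead of ontology structure; it is provided because grouping
"processes that share their driving genes" is sometimes the more
interpretable notion, without claiming either backend reproduces any
particular published clustering.

Cross-condition comparison matches clusters between the disease and the
treatment contrast by member-set Jaccard (best match per cluster, kept at
≥ 0.5) and flags a reversal when the median-NES signs differ.

## Deconvolution

A labelled single-cell matrix is aggregated per cell type: each cell is CPM-
normalised (depth cancels), cells of a type are averaged, and each signature
column rescaled to CPM so types share a scale.  Bulk samples are CPM-
normalised likewise; both sides live in *linear* CPM space because mixing is
linear in transcript abundance.  Reference and bulk are aligned on the
intersection of (optionally ortholog-mapped) gene ids; fewer than 50 shared
genes aborts.

Coefficients solve min ‖y − Xβ‖² + λ‖β‖² in closed form on a standardised
problem (columns scaled to unit sd, X and y centred — the centring absorbs
the intercept), then back-transformed; λ = 0 requires full column rank.
Standardisation matters because ridge penalties are scale-sensitive; it is a
flag, and the identity-design closed form (β = y/2 at λ = 1) holds with it
off.  λ is either fixed or chosen by 5-fold cross-validation over genes on a
log grid 1e-3…1e3 (deterministic under seed; ties prefer smaller λ; the CV
bias of the chosen λ on a noiseless mixture is ≈ λ/n_genes).  Negative
coefficients are zeroed and the remainder renormalised to proportions; if
every coefficient is ≤ 0 the proportions are flagged undefined rather than
returned uniform.  Default mode fits each group's mean CPM profile (one
composition per study arm); per-sample mode fits every sample and averages
within group, exposing between-sample spread.

## Synthetic-data generator

The generator exists so that every stage has a recovery test with known
truth; its defaults are the bundled study conditions.

- **Three-arm counts** (`simulate_three_group_counts`): baseline means
  log-normal (log-mean 4, log-sd 1 — library-scale counts in the tens to
  thousands); a fraction `frac_de = 0.3` of genes gets disease-vs-control
  effects with magnitudes |N(0, lfc_sd = 2)|, half up and half down; a
  fraction ρ of the disease-up genes (and symmetrically of the down genes)
  has its treated mean returned fully to the control level
  (`reversal_multiplier = 1`, configurable) — full return is what makes ρ
  identifiable.  NB dispersion 0.2 throughout, n = 6/group in the preset.
- **Single-cell reference** (`simulate_reference`): per-type mean profiles
  log-normal; cell counts NB around the type mean at ~5000 counts/cell.
- **Bulk mixtures** (`simulate_bulk`): expected expression is
  lib_size × Σ_k p_k · (profile_k / Σ_g profile_k); counts NB.  The preset
  plants distinct compositions per arm, with the disease arm shifted toward
  one type and the treated arm partway back — the qualitative pattern a
  restorative treatment produces.
- **Ontology** (`simulate_annotation`): a random rooted tree of the stated
  depth; each gene draws direct annotations with deeper terms less likely
  (term frequency decreases with depth, as in real ontologies).  With
  `block_assign`, consecutive genes in the given order also share one term,
  emulating coherent functional modules; the pipeline orders genes by
  planted regulation class so some terms genuinely concentrate signal —
  without this, gene sets are independent of the DE structure and there is
  nothing to enrich.
- **Ortholog map** (`simulate_ortholog_map`): exactly
  round(fraction × n) sources mapped injectively.

All generators are pure functions of (parameters, seed); one study seed
expands to stage seeds by fixed offsets.  Truth objects serialise to JSON
losslessly.  Not emulated: scRNA-seq dropout and ambient RNA, batch
effects, gene–gene correlation beyond the planted modules, and length/GC
biases — so passing recovery tests demonstrates correctness of the
estimators under the stated model, not robustness to those real-data
artefacts.

## Numerical conventions

All result tables are UTF-8 TSV with floats at 6 significant digits; two
runs of one config are byte-identical.  The run manifest records the seed,
the full config (including every default), a SHA-256 of the canonical config
serialisation, library versions and the output list.  Randomness flows only
through numpy Generators seeded from the config.  Tie-breaks are
deterministic everywhere (ranking by (−score, id); ES extremum earliest
position; cluster labels by (|NES|, id); CV λ ties to the smaller value).

## Sizes used in the test suite

Simulation-based checks run at G = 500–2000 genes and 5–10 samples per
group, 200–5000 permutations, and 20 replicate seeds where spread matters —
large enough for the statistical bands asserted, small enough that the whole
suite and the acceptance script each finish in a few minutes on one CPU.

## Known limitations

Two-group contrasts only; no covariates, interaction terms, outlier
replacement or independent filtering.  Unshrunk log2FC can be large for
low-count genes (the moderated dispersion, not LFC shrinkage, is the only
stabiliser).  The Wald normal approximation is slightly anticonservative at
very small n even with moderation.  GMT/edge-list/annotation TSV are the
only ontology inputs (no OBO).  The deconvolution assumes the reference
spans the cell types actually present; a missing type redistributes its
share over correlated signatures.
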