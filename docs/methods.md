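# Methods

This note documents the models and procedures implemented in `panepiclock`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Gene-level features

A profile is one library: donor x tissue x epigenetic layer. Features are
per-gene signal summaries:

* **ChIP-seq** — the arithmetic mean of the narrowPeak *score* column
  (column 5) over all peaks with >= 1 bp overlap of the gene body; genes
  without an overlapping peak get 0. We deliberately aggregate column 5
  rather than column 7 (signalValue) because "score" is the canonical name
  of column 5 in the narrowPeak standard; `use_signal_value=True` switches
  to column 7. Peaks are not length-weighted, a peak overlapping two genes
  contributes to both means, strand is ignored, and "gene body" means the
  annotated start-end span with no promoter extension.
* **WGBS** — the mean methylation fraction of CpGs strictly inside the
  gene body (0-based half-open everywhere; a CpG at the gene's end
  coordinate is outside); genes without CpGs get 0.

Coordinates are 0-based half-open internally; GTF/GFF3 input (1-based
inclusive) is converted on read, and only numerically named (autosomal)
chromosomes are kept. Mouse gene ids are renamed through a strict
one-to-one ortholog map; unmapped genes are dropped. When assembling the
cohort matrix, a gene that is zero or absent in *every* sample of a
{dataset x layer} stratum is recorded as missing for that stratum (no peak
was ever called there), and genes missing everywhere are dropped.

## Normalization and batch correction

Three steps, in order, each with strict fit/apply semantics:

1. **Stratum min-max** — each {dataset x layer} stratum is scaled to
   [0, 1] by its *global* min and max (not per gene). Per-gene scaling
   would be redundant with the per-gene INT that follows, and DNAm is
   already naturally in [0, 1]. Applied values are clipped to [0, 1]; a
   constant stratum maps to 0. A useful side effect: any additive
   batch offset that is constant within the stratum is removed here.
2. **Mean imputation (DNAm only)** — missing methylation values are
   replaced by the per-gene mean of the *training* rows; missingness in a
   histone layer is treated as an error (peak absence is a 0, not a
   missing value).
3. **Rank inverse normal transform (INT)** — per dataset and per gene,
   values are ranked across samples (average ranks for ties, matching the
   Spearman convention used downstream), converted to percentiles
   `r/(n+1)` — a convention that avoids infinite normal quantiles — and
   mapped through Φ⁻¹. Held-out rows are mapped through the *training*
   empirical CDF by linear interpolation between the unique training
   values' average-rank percentiles, clipped to `[1/(n+1), n/(n+1)]`; an
   exact training value therefore reproduces its fit-time percentile.

During clock training, min-max is applied once globally (its parameters
are stratum-level scale constants), while imputation and INT are refitted
inside each cross-validation fold on the training rows only. The leakage
contract is testable: permuting or transforming held-out rows never
changes any fitted parameter.

## Age representation

Donor age is expressed relative to the species' maximum lifespan (120 y
human, 4 y mouse; the registry is overridable) and transformed by
`scaled = −ln(−ln(age/lifespan))`, the natural-log variant (the transform
is only affine-equivalent across log bases, so the base is fixed and
documented). The transform is strictly increasing on (0, lifespan),
stretches development and compresses late life symmetrically in both
species, and inverts exactly via `age = lifespan·exp(−exp(−scaled))`.
Boundary ages (newborns at 0; ages at the lifespan cap) are clamped inward
by one day and logged; ages outside [0, lifespan] are errors. Clocks are
trained on scaled age and report years through the inverse transform, so
predicted ages always lie inside (0, lifespan).

## Cross-layer statistics

* **Age association** — per {species x layer} stratum, Spearman's ρ of
  each gene against chronological age (rank-based, so the age scale is
  irrelevant), two-sided p from the Student-t model
  `t = ρ√((n−2)/(1−ρ²))` on n−2 df, BH q-values within the stratum.
  Constant gene columns are flagged and recorded as ρ = 0, p = 1;
  p-values are floored at the smallest positive double so they stay in
  (0, 1]. At least 4 samples are required.
* **Top-k overlap enrichment** — the k (default 1000) genes with the
  strongest *unsigned* association per table, ties broken by ascending
  gene id for reproducibility; expected overlap `k²/G` over the shared
  universe of G genes; fold = observed/expected; significance by a
  two-sided exact binomial with success probability k/G over k trials.
  The binomial follows the expected-overlap formula's independence model;
  the exact hypergeometric null is available behind `null="hypergeom"`.
  Bonferroni across however many pairs are tested together.
* **Crosstalk** — for an ordered layer pair A→B, the median difference of
  B's associations between A's k most positive and k most negative genes,
  two-sided Mann-Whitney U, Bonferroni over the C(7,2) = 21 unordered
  layer pairs. Signed ρ ranks are used here (direction matters), unsigned
  for the overlap enrichments.
* **Direction gene sets** — "epigenetically repressed with age" is the
  intersection, over every available (species, mark) table, of the top-k
  most positively age-associated genes for repressive marks (H3K27me3,
  H3K9me3, DNAm) and the top-k most negatively associated for activating
  marks (H3K27ac, H3K36me3, H3K4me1, H3K4me3); "activated" is the
  converse.
* **Gene-set enrichment** — a local one-sided hypergeometric test of a
  query set against a user-supplied GMT library and explicit universe,
  with BH correction; terms overlapping the query in fewer than two genes
  or with q >= 0.05 are excluded. "Significant" in summary fractions means
  BH q < 0.05 per stratum (configurable).

## Clocks

* **Dataset filters** — excluded tissue labels (defaults: prostate,
  breast, ovary, testis, uterus, placenta, cell_line), tissues under 50
  libraries (configurable), and the two sparse layers H3K36me3/H3K9me3.
  CR samples are withheld from fitting and predicted by averaging all
  fold models (in scaled-age space, then inverted to years).
* **Folds** — donors are binned into quintiles of donor scaled age;
  within each quintile donors are assigned, largest profile count first
  (ties shuffled by the seed), to the fold currently holding the fewest
  profiles. This greedy scheme is our construction for the stated balance
  and grouping constraints; with single-profile donors it achieves
  per-quintile fold counts within 1.
* **Feature selection** — genes with |ρ| > 0.2 against age in both
  species separately, with matching sign, computed on the fold's training
  rows. For the pan clock the per-species ρ pools all training profiles
  regardless of layer (default); `feature_selection="union"` instead
  selects within each layer and takes the union, which matters when
  layers trend in opposite directions and pooling cancels. For
  single-layer clocks, only the trained layer's profiles enter the
  computation. A single-species fold applies the threshold to that
  species with a warning; an empty selection is an error advising a lower
  threshold.
* **Regressor** — XGBoost with its default hyper-parameters frozen as an
  explicit contract (100 rounds, max depth 6, learning rate 0.3,
  squared-error loss, single thread, seeded), so any engine reproducing
  that contract is conformant.
* **Evaluation** — predictions are averaged over tissues within donor x
  layer before correlating with age (per layer, per species, per tissue,
  or pooled "overall"). Constant predictions give ρ = 0 with a warning;
  groups with fewer than 4 donors are excluded with a warning.
* **Leave-one-layer-out** — 5-fold CV without one layer's profiles; the
  left-out layer is predicted by every fold's model and averaged (it
  never entered training), the remaining layers by their held-out fold
  models; percent change is measured against the full pan clock under the
  *same* folds.
* **Scaling rate** — for increasing training-cohort sizes, donors are
  sampled without replacement, a single-layer clock is cross-validated on
  the sample, and the held-out pooled ρ recorded; the rate is the
  zero-intercept OLS slope of ρ on log10(donors), `b = Σxy/Σx²`. The
  experiment assumes the sampled cohort keeps every dataset large enough
  to fit INT (>= 2 training samples per fold); run it on cohorts with few,
  large datasets — tiny subsamples of many small datasets cannot be
  normalized per dataset.

## Residual analyses

Residual = tissue-averaged (predicted − actual) age in years per donor x
layer; positive means epigenetically older. The age-adjusted variant
regresses residuals on the rank of chronological age within each
(species, layer) group and keeps the fit residual, so cross-layer
correlations of adjusted residuals are partial correlations controlling
for age — age is the only plausible conditioning variable and is logged
as such. Synchronization is pairwise Spearman over donors sharing both
layers (>= 10 required), p from the t model. The binned residual curve
groups donors around integer-year centers with a +/- 1 year window
(overlapping bins, per the rounding-with-halfwidth reading) and drops
bins with fewer than two donors. The CR comparison reports mouse
residuals in months (x12) and contrasts diet groups by two-sided
Mann-Whitney U, per layer or pooled over histone layers.

## The synthetic-data generator

The generator emulates the statistical skeleton of a two-species,
multi-study epigenetic aging cohort. The latent signal for donor d, gene
g, layer l is

    z = sign(l) · loading(g) · (scaled_age_eff(d) + rate(d))
        + baseline(g, l) + batch(dataset, l) + noise

* **Shared loadings, layer-specific signs** — informative genes draw a
  positive half-normal loading shared across layers; the sign map carries
  each layer's direction of age trend. The default signs follow the
  *empirically observed* pattern in multi-layer aging cohorts — the
  repressive marks (DNAm, H3K27me3, H3K9me3) plus H3K27ac and H3K4me3
  gain signal with age, while H3K4me1 and H3K36me3 oppose them — rather
  than the textbook activating/repressive split. Positive loadings make
  the planted trend direction exactly equal to the sign map, which is
  what the noise-free invariants assert.
* **Gene-by-layer baselines** (`gene_baseline_sd`, default 1.0) — each
  mark gets its own age-constant gene-wise occupancy pattern, as real
  marks do (promoter marks sit at promoters, heterochromatin marks at
  repeats). This is also what makes a profile's layer identifiable from
  data alone: with perfectly mirrored loadings and no baselines, an old
  donor's profile in a sign-inverted layer is mathematically
  indistinguishable from a young donor's profile in a majority-direction
  layer, and no layer-blind model can resolve the ambiguity.
* **Donor rate factors** (`donor_rate_sd`, scaled-age units, default
  0.1) — one additive offset per donor, common to all of the donor's
  profiles; the planted ground truth for aging-rate synchronization.
* **Batch shifts** (`batch_shift_sd`, default 0.5) — additive per
  {dataset x layer}; largely removed by stratum min-max, with the
  remainder handled by INT.
* **Caloric restriction** — `cr_fraction` (default 0.2) of mouse donors
  have `cr_offset_frac` (default 0.1) subtracted from their *effective*
  relative age (clamped above 0), i.e., a constant shift of 0.1 x 4 y ~
  4.8 months at the mouse lifespan — the order of the months-scale
  reductions reported for CR in the literature. Chronological ages are
  unchanged; only the epigenetic signal looks younger.
* **Realization** — histone layers are written as one gene-spanning
  narrowPeak with score `z + 8` (absent when non-positive, so the reader
  recovers 0); methylation as `cpgs_per_gene` CpGs inside the gene body
  sharing the fraction `sigmoid(0.4 z)`, coverage 30. Both mappings are
  strictly monotone, so the readers' aggregation recovers the latent
  ordering exactly and, at zero noise, the latent value itself (up to
  text formatting; the file round trip agrees with the in-memory matrix
  to < 1e-6).
* **Determinism** — one generator seeded per cohort for cohort-level
  draws; per-sample noise streams are derived from a stable hash (CRC32)
  of the sample id, so regenerating with more samples never reshuffles
  existing ones, and identical configs produce byte-identical files.
* **Defaults as study conditions** — 200 donors per species, the five
  clock layers, one tissue per donor, two datasets per species, ages
  uniform on 5-90% of relative lifespan (drawn uniformly in relative age
  and converted to years, matching the cross-species alignment),
  `noise_sd = 1.0` against loading sd 1.0 — per-gene noise of the same
  order as the per-gene signal.

What the generator does **not** emulate: read-level noise, peak calling,
chromatin-domain spatial structure, tissue-specific aging trajectories,
layer-specific gene universes, or non-monotone age trajectories. Passing
tests therefore demonstrate that the *pipeline* recovers planted structure
under realistic noise, batch and rate heterogeneity — not that real data
contain such structure.

## Problem sizes used by the test suite

The reference cohort for clock-recovery and leave-one-layer-out checks is
the generator default (400 donors over two species x 5 layers, 2000 genes
/ 300 informative, seed 0) with 10-fold CV for the clocks and 5-fold for
leave-one-layer-out. The residual-synchronization scenario uses 109
human donors x 5 layers with `donor_rate_sd = noise_sd = 1` and the CR
scenario 200 mouse donors (160 control / 40 CR); both use 300 genes / 100
informative and 5-fold CV — the donor counts and effect sizes are the
study conditions, while gene counts and fold counts at these two
scenarios are the package's own scaling choice. Null calibrations run 500
independent simulations at G = 2000, k = 200.

## Known limitations

* The binomial overlap test treats the two top-k sets as independent
  draws (the expected-overlap model); the hypergeometric option is exact
  but both k and G must come from the same shared universe.
* The pan clock carries no explicit layer covariate; on data where layers
  are exact mirrors of one another and carry no layer-identifying
  baseline pattern, predictions for minority-direction layers degrade
  (see the generator's baseline note).
* Scaling-rate estimates at small cohort sizes are noisy and the
  per-dataset INT bounds how small a subsample can get.
* `significant_fraction` depends on the chosen FDR threshold; no attempt
  is made to match any particular published percentage.
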