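# Methods

This note documents the models and procedures implemented in `neutromap`,
the parameters that matter, the numerical choices made where the published
descriptions leave room, and what the synthetic-data generators do and do
not emulate.

## Expression normalization (uniform genes)

Cross-dataset comparison of FPKM matrices uses the uniform-genes scheme:

1. **Uniform genes.** A gene is *uniform* if its expression lies between
   the 50th and 90th percentile of the sample's expression distribution in
   *every* sample. Percentiles are computed over all genes (zeros included)
   with linear interpolation between order statistics, and band membership
   is inclusive at both bounds; both conventions are configurable because
   the originating description does not pin them down. If a sample's 50th
   percentile is 0, membership additionally requires a strictly positive
   value so geometric means stay defined.
2. **Scaling factors.** Each sample's factor is the geometric mean
   (`exp(mean(log v))`) of its uniform-gene values. The reference mean is
   the arithmetic mean of the factors over the reference-group samples
   (flagged in the sample metadata, typically the human datasets); a
   geometric option exists since "mean scaling factor" is ambiguous.
3. **Normalization.** Each value is divided by its sample's factor and
   multiplied by the reference mean, so after normalization the
   uniform-gene geometric mean equals the reference mean in every sample.

Scale invariance: multiplying a sample by a positive constant before
normalization leaves its normalized values unchanged **provided the sample
is not in the reference group** — scaling a reference sample shifts the
reference mean and hence all outputs by a common constant. Tests check the
invariant in the form in which it actually holds.

**log transform.** log10 of FPKM with zeros assigned −4; positive values
below 10⁻⁴ are also floored to −4 so the codomain is bounded below
consistently (the published rule only covers exact zeros).

**Replicate averaging.** On the log scale (so arithmetic means are
geometric means of raw values), samples are averaged first within each lab
and then across labs with equal weight, preventing labs with more
replicates from dominating pooled profiles.

**Homolog and gene-type restriction.** Cross-species comparisons are
limited to homolog pairs from a user-supplied two-column table; one-to-many
mappings are dropped by default (a first-listed policy is available)
because multi-mapped genes would otherwise be double counted. Gene-type
filtering keeps e.g. protein-coding genes from a user-supplied annotation;
unannotated genes are dropped with a logged count.

## Similarity

Spearman correlations use average-rank ties; a constant column has
undefined rank correlation and is reported as missing with a warning.
Clustering uses distance 1 − ρ (hence heights in [0, 2]) and unweighted
average linkage (UPGMA), computed with scipy; sample labels are sorted
before linkage so distance ties resolve toward lexicographically smaller
labels, making dendrograms reproducible. Note a subtlety of UPGMA: a
duplicated sample merges with its twin at height 0 but, because unweighted
averages count leaves, it can shift *later* merge heights; this is a
property of the linkage, not an artifact.

PCA floors log expression at −2 before decomposition so noise in lowly
expressed genes cannot dominate the components; genes are mean-centered
(making the embedding translation-invariant in gene space) and components
are ordered by explained variance.

Fold-change reproducibility compares per-gene log10 fold changes
(treated − control, on the floored log scale) between two replicate pairs,
after excluding genes whose mean log10 expression over the four samples is
below −1; both Pearson and Spearman coefficients are reported. The
upregulated-gene filter keeps genes with mean log10 expression ≥ −1 across
the differentiation samples *and* fold change ≥ 3 (inclusive, with a
10⁻¹² epsilon so the bound stays inclusive under float rounding) in every
matched pair — a conjunction, so one failing pair excludes the gene.

## Cytometry

Gates are a quantile of a negative control's intensity distribution
(default 0.995, configurable; the exact quantile used in the source
experiments is unpublished, so gating is validated by synthetic parameter
recovery instead of by reproducing published percentages from raw data).
Percent positive restricts to the live (viability-stain-negative)
population first when a live gate is supplied. MFI is the arithmetic mean
over the live population (optionally gate-positive only) and is reported
relative to a reference sample scaled to exactly 100. Autofluorescence
correction subtracts the unstained control's mean from one channel;
negative corrected intensities are retained so means stay unbiased. Growth
curves are divided by their initial count.

## Chemotaxis

The angular-bias statistic is not published as a formula; the
implementation uses the simplest definition satisfying both printed
anchors: per-step score 90° − θ (θ = absolute angle between the step
displacement and the direction from the step's start to the source),
averaged per cell and then over cells. Perfect motion toward the source
scores 90°; uniformly random directions give θ uniform on [0°, 180°] and
expectation 0°; motion straight away scores −90°. A per-step-weighted
variant is available (`per_cell=False`) since the original weighting is
unstated.

Windows are half-open on the right and a step belongs to a window by its
start time, so "before" = [start, stimulus) and "after" = [stimulus, end];
the uncaging frame starts the "after" window. The source direction is
recomputed at each step's start position. Zero-displacement steps are
excluded from angle statistics (the angle is undefined) but contribute zero
length to path-length speeds, where elapsed time still passes. Speeds are
total in-window path length over elapsed time, in μm/min, averaged over
cells.

The mixed-population simulation draws each cell as a responder with
probability *f*; responder step angles are resampled with replacement from
an empirical responder sample (e.g. steps of cells with uniform receptor
expression) and non-responder angles are uniform on [0°, 180°]. Its
expected histogram is the closed-form mixture
`n · (f · p_responder + (1 − f)/n_bins)`, which tests verify against the
simulation. Combined with gating, this closes the loop of explaining a
partially-responding population's directionality histogram by its
receptor-positive fraction.

## Genotype concordance

Loci are kept when read depth is ≥ 10 in **all** samples and site quality
is **strictly** greater than 100 (both thresholds configurable). Identity
compares unphased allele multisets (0/1 ≡ 1/0 ≡ 0|1), since RNA-seq calls
carry no meaningful phase; multi-allelic genotypes are compared on the full
multiset without decomposition. "Quality" is the per-locus site quality;
per-genotype quality is not consulted. The concordance matrix is symmetric
with unit diagonal, and is invariant to locus and sample order.

## Morphometry

Segmentation takes pixels strictly above an explicit intensity threshold
(an Otsu convenience helper exists but the threshold is a required input of
the core procedure), labels 8-connected components, and discards components
below 100 pixels (inclusive bound: exactly 100 px is retained) as debris.
Dead cells are objects whose mean intensity in the co-registered viability
channel exceeds a threshold. Areas convert to μm² with a 0.4389 μm pixel
(100 px ≈ 19.26 μm²; an oft-quoted "~44" annotation for 100 px is
dimensionally inconsistent with this pixel size, so the explicit numbers
are implemented).

## Catalog

Averaged per-state log10 expression tables are outer-joined on gene id;
values missing in a state remain missing (an explicit `NA` token in CSV,
never the log floor, so absence is distinguishable from low expression).
Domain labels are a user-supplied two-column mapping — the catalog never
fetches external annotation. Queries are exact-match by gene, symbol or
domain, with stable sorting (ties keep catalog order, missing values last)
and optional top-k truncation; querying never mutates the catalog.

## Synthetic-data generators

All generators take an explicit seed, are bit-reproducible for a fixed
seed, and return hidden ground truth for parameter-recovery testing.

- **Expression**: log10 values are gene baseline `N(0.5, 1.0)` + lab offset
  `N(0, 0.05)` + condition shift on a random 10% signature-gene subset +
  replicate noise `N(0, 0.1)`, exponentiated to FPKM scale. Zeros are
  injected by masking the lowest-expressed fraction per sample (default
  5%), mimicking dropout of lowly expressed genes and matching the heavy
  left tail the −4 floor handles. Not emulated: length/GC biases, batch
  effects beyond a lab offset, count noise, isoform structure.
- **Cytometry**: marker intensity is `10^N(1.0, 0.3)` for negatives and
  `10^N(3.0, 0.3)` for positives (well-separated components, as FLPEP
  staining shows), plus an additive autofluorescence offset; the viability
  channel is an independent alive/dead mixture (`10^N(1.0, 0.25)` vs
  `10^N(3.0, 0.25)`), and the unstained control draws only from the
  negative/alive components. Not emulated: spillover between channels,
  debris/doublets, instrument saturation.
- **Tracks**: cells start uniformly in a 100–400 μm annulus around the
  source; step lengths are `N(5, 1.5)` μm per 30 s frame (≈ 10 μm/min,
  typical of differentiated PLB-985 cells), truncated at zero. Before the
  stimulus all headings are uniform; after it, responder cells draw
  headings from a von Mises centered on the instantaneous source direction
  with concentration κ (default 2), per step by default or once per cell
  (`angle_mode="per_cell"`) since the original simulation's sampling unit
  is unstated. Non-responders stay uniform. Not emulated: persistence of
  real cell motion, cell–cell collisions, gradient decay.
- **Genotypes**: same-group samples are exact copies; other groups deviate
  from the base group per locus with the discordance probability, so
  between-group identity is 1 − discordance in expectation and within-group
  identity is exactly 1. Depths are Poisson (mean 30), site qualities
  uniform in [50, 500]. Not emulated: allele-specific expression,
  missing genotypes, linkage.
- **Nuclei images**: elliptical nuclei with pixel areas `10^N(2.5, 0.12)`
  (≈ 315 px ≈ 61 μm², comfortably above the 100 px debris bound at > 3σ),
  axis ratio uniform in [0.6, 0.95], random orientation, placed by
  rejection sampling with a 2-px exclusion margin so 8-connected components
  never merge (a generation error is raised if placement fails within the
  retry budget). Foreground/background are 3000/200 (nuclear) and 2000/100
  (viability) on a 16-bit range with σ = 10 Gaussian noise. Not emulated:
  touching/lobed nuclei, uneven illumination, out-of-focus light.

Because the generators are idealized, passing parameter-recovery tests
shows the estimators are correct under their stated assumptions — it does
not certify performance on real data with overlapping stain distributions,
touching nuclei or confounded batch structure.

## Problem sizes and tolerances

Test and acceptance runs use sizes at which sampling error is predictable:
10⁴ cytometry events over 20 seeds (gating recovery within ±3 percentage
points), 10⁵ steps for the Monte-Carlo check of the 0° random-motion
anchor (±1°), 5 000-gene matrices for normalization properties (equalities
to 1e-9 relative), 10³ loci for concordance (±4 binomial SD), and ≤ 20-row
toys wherever a brute-force oracle recomputes the result exactly. Exact
contracts (zeros → −4, PCA floor −2, reference MFI = 100, depth/quality
boundaries) are asserted without tolerance; geometric anchors (90°) allow
only float round-off (1e-6).

## Known limitations

- Gating assumes well-separated negative/positive components; with heavy
  overlap a quantile gate is biased and mixture modeling (out of scope
  here) would be needed.
- UPGMA leaf order and tie-breaks are documented conventions, not inferred
  from the original figures.
- The catalog is a static exporter; no web service or database backend.
- VCF/FCS binary ingestion is out of scope; the package consumes the
  plain-text schemas in `neutromap.io`.
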