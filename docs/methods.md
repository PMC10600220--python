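# Methods

## Background and scope

Mouse rod photoreceptors are unusual in carrying an *inverted* nuclear
architecture: heterochromatin condenses into central chromocenters while
euchromatin lines the periphery, the reverse of the conventional
arrangement in which heterochromatin is tethered at the nuclear lamina
(by the lamin B receptor, Lbr, or by lamin A). `tetherscope` implements
the quantitative analyses used to study this system: image-based
morphometry of heterochromatin tethering, discovery of
accessibility peaks specific to tethered rods from multi-sample ATAC-seq
style inputs, promoter-proximal annotation, A/B compartment overlap, and
the supporting expression utilities (count QC, pseudo-bulk differential
expression, lamin A vs lamin C splice-junction discrimination). Read
alignment, peak calling, footprinting, GO enrichment, and cell-type
annotation are upstream/downstream tools whose outputs this package
consumes or emits; they are out of scope.

Every stage is exercised end to end on synthetic data with known ground
truth, generated by `tetherscope.simulate`.

## Synthetic nuclei

A nucleus is a disk (optionally an ellipse, `ellipticity` ≤ 1) of radius
`radius_px` on a dark background (background 10, euchromatin 60 on the
0–255 8-bit scale). The heterochromatin intensity excess
`(het_eu_contrast − 1) × 60` is split by the tethering parameter
θ = `tether_strength` ∈ [0, 1]:

- a peripheral shell of width `shell_width_frac · R` receives weight θ;
- `n_chromocenters` interior disks of radius `chromocenter_radius_px`
  receive weight 1 − θ.

Chromocenter centers are rejection-sampled (≥ 2 radii apart, error after
1000 attempts) within a radial band `(0.4 + 0.6 θ) · r_max`, so fully
inverted nuclei keep chromocenters within 0.4 R of the center and
tethering pushes them outward. Gaussian noise (`noise_sd`, default 4) is
added and the image clipped to [0, 255]. Ground truth records the
noiseless margin-intensity ratio (3-px band), chromocenter centroids, and
an organization label (inverted / intermediate / conventional at θ < 1/3,
1/3–2/3, > 2/3).

The generator reproduces the *geometry* of tethering, not microscopy:
no PSF, no shot-noise statistics, no 3D structure, no staining
heterogeneity. Passing tests demonstrate that the operators measure the
intended geometric quantities, not that segmentation is robust to real
imaging artifacts.

Defaults for cohort simulations follow the study design: 3 biological
replicates × 30 cells per group.

## Morphometry

- **Segmentation** — Gaussian smoothing (σ = 2 px), Otsu threshold,
  largest connected component, hole filling. Constant or empty images
  raise "no nucleus found".
- **Margin-intensity ratio** — mean intensity over the pixels within
  `band_width_px` (default 3; the manual tracing linewidth is not
  standardized, so this is exposed) of the mask boundary, divided by the
  mean over the whole mask. Exactly 1 on uniform nuclei by construction.
- **Chromocenters** — threshold at mask mean + `sd_multiplier` (default
  2.0) × mask SD, components ≥ `min_area_px` (default 4), touching blobs
  split by distance-transform watershed, intensity-weighted centroids.
  The detection criterion is a package choice; manual counting has no
  published threshold.
- **Margin distances** — per-chromocenter minimum Euclidean distance from
  centroid to the sub-pixel contour polygon (marching squares at the 0.5
  level), × `pixel_size_um`. The polygon, not the pixelated mask edge, is
  used for sub-pixel accuracy; the vectorized point-to-segment kernel is
  cross-checked in tests against shapely and a brute-force scan (< 1e−9).
- **Profiles** — perimeter profile by bilinear interpolation at equal
  arc-length positions along the contour (plus cumulative sum); transect
  profile along the major axis through the centroid, endpoints pulled
  1 px inside the mask so boundary samples do not blend with background.
- **Group comparison** — cells are collapsed to biological-replicate
  means (the primary analysis; a cell-level flag exists), then one-way
  ANOVA across groups, Tukey HSD pairwise adjusted p-values, Shapiro-Wilk
  on residuals and Brown-Forsythe (median-centered Levene) on variances.
  With 3 replicates × 3 groups the replicate-mean ANOVA holds the type-I
  error near nominal (tested over 200 null simulations, ≤ 0.10 observed
  bound at α = 0.05).

## Toy genome and accessibility analysis

The toy genome (default: one 2 Mb chromosome) carries non-overlapping
genes (uniform strands), `n_shared_peaks` accessible in every sample and
`n_tether_specific_peaks` called and elevated only in "tethered" samples.
Coverage inside a peak is baseline 1 plus a tent profile rising from half
`signal_amplitude` at the edges to the full amplitude at the summit
(strict maximum at the summit; in-peak mean ≥ amplitude/2 above
baseline). A/B compartments alternate in `compartment_block_bp` blocks.
`frac_proximal_planted` (default 0.10) of the tether-specific peaks are
placed inside a promoter window; the remainder avoid all windows, and
their summits favor A blocks with probability `frac_a_planted` (default
0.9), emulating the observed concentration of tethering-specific peaks in
the euchromatic A compartment. Gene promoter windows are kept mutually
disjoint and peaks ≥ 2.2 kb apart so planted labels are unambiguous and
summit-matrix flanks do not overlap neighboring peaks.

- **Intersection logic** — peaks from all samples are merged
  single-linkage (overlapping or book-ended intervals chain together,
  which makes the merged regions exactly the covered-basepair runs of the
  union, as with `bedtools merge`); each region records the contributing
  samples, and upset counts tally exclusive membership combinations
  (region-level counting; counts sum to the number of regions).
- **Summit matrices** — mean coverage per `bin_bp` (default 50) bin over
  [summit − flank, summit + flank) (flank default 1000), zero-filled past
  chromosome ends, scaled to counts-per-million of the track total by
  default (the normalization tag is recorded in outputs).
- **Clustering** — features are the per-sample row blocks after
  log2(x+1), concatenated; K-means (k default 3 — the real analysis shows
  a handful of patterns but states no k, so it is exposed) with seeded
  k-means++ and rows internally re-sorted by peak key, making labels
  invariant to input order. The *tethering cluster* is the cluster
  maximizing mean(tethered blocks) − mean(control blocks);
  `tethering_cluster_ids` additionally collects every cluster with at
  least half the maximal gap, so that an over-partitioned planted pattern
  (k larger than the number of real patterns) is still captured as one
  peak set. A near-zero maximal gap triggers a warning rather than an
  error.
- **Proximal annotation** — strand-aware TSS window, 5 kb upstream to
  1 kb downstream, half-open: [tss − 5000, tss + 1000) on +, mirrored on
  −. TSS anchoring is chosen over whole-gene-body anchoring as the
  promoter-proximal reading of "of a given gene"; a `body` anchor mode is
  available. A peak is proximal on ≥ 1 bp overlap with any window;
  nearest gene by |summit − tss|, ties broken by lexicographic gene id;
  the unique proximal gene set is exported for downstream GO tools.
- **Compartment overlap** — each summit is assigned to the containing
  A/B interval (binary search); summits in gaps count as unassigned;
  fractions sum to 1.

## Expression utilities

- **QC** (`qc_filter`) — thresholds 200 / 2500 detected genes per cell,
  18% mitochondrial fraction (prefix `mt-`, configurable), gene detected
  in ≥ 3 cells. Order fixed for determinism: genes first, then cells,
  with the mito fraction computed on pre-filter totals (total counts as
  denominator). Boundary semantics are inclusive where the rules say
  "less/more than": exactly 200 genes and exactly 3 cells survive. The
  genes-then-cells order is not mathematically idempotent in adversarial
  corner cases (a gene can fall below the 3-cell floor after cell
  removal); on realistic matrices re-filtering removes nothing, which the
  suite checks at fixed seeds.
- **Pseudo-bulk DE** (`pseudobulk_lfc`) — CPM normalization; LFC =
  log2((mean CPM case + pc) / (mean CPM control + pc)), pseudocount
  0.5 CPM; Wald z on the log2 ratio with a delta-method SE under the NB
  mean-variance law, per-gene method-of-moments dispersion floored at
  0.01; BH adjustment. This is a deliberately simple estimator — no
  shrinkage, no GLM — adequate for planted-effect recovery at large
  fold-changes; it is *not* a reimplementation of a full NB GLM framework
  and should not be used as one. All-zero genes report LFC 0, p 1.
  Antisymmetric under group swap by construction.
- **Junction classification** (`classify_junctions`) — the lamin A
  fraction α = LA-diagnostic reads / (LA + LC diagnostic reads), shared
  junctions excluded, with an exact Clopper-Pearson 95% CI (coverage
  ≥ 93/100 at n = 10,000 in the suite). The packaged Lmna model is a
  schematic with synthetic coordinates (lamin A and C share exons 1–10
  and diverge afterwards); supply a model JSON derived from a real
  annotation for real data.
- **Gene-set summary** — per-group gene-level mean CPM plus a Wilcoxon
  signed-rank test on paired gene means for a systematic shift.

## Pipeline and reproducibility

Pipelines are YAML configs validated by typed pydantic models; every
stage draws its seed from a spawned hierarchy under the global seed, so
identical config + seed yields byte-identical outputs (manifest records
the config hash and SHA-256 of every output; timestamps are excluded from
the determinism contract). Referenced input files are checked before the
first stage runs; a failing stage aborts the run, names itself, and
leaves a `<stage>.failed` marker.

`demo_paper_shape` runs both arms on defaults and asserts the qualitative
outcomes the method is designed to detect: margin ratio increasing with
tethering (Tukey p < 0.01 tethered vs inverted; a degenerate equal-θ
design is flagged instead), tethering-cluster recovery ≥ 90% with ≤ 5%
contamination, and a recovered proximal fraction within ±0.02 of the
planted 0.10.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the imaging arm at the
study design (3 groups × 3 replicates × 30 cells, radius 40 px), the toy
genome at its defaults (150 peaks, 60 genes, 2 Mb), DE at 2000 genes ×
5 + 5 samples, and the junction classifier at 100 replicates × 10,000
reads — sizes chosen so every stage's statistical behavior is visible
while the whole suite stays lightweight. Float comparisons use exact
identities where they hold (uniform-nucleus ratio = 1) and otherwise
oracle agreement (brute-force pixel partitions, per-basepair scans,
exhaustive overlap checks, pure-Python distance scans).

## Known limitations

- 2D single-plane geometry only; no Z-stacks, no PSF, no colocalization.
- The DE estimator's normal-quantile Wald test is mildly anticonservative
  at n = 5; BH across many genes keeps null rejections low, but single
  raw p-values near 0.05 should not be over-read.
- The intersection and track containers are dense per-basepair arrays —
  appropriate for toy genomes and small regions, not whole mammalian
  genomes.
- The packaged isoform model is synthetic; junction classification on
  real data requires a user-supplied model.
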