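# Methods

## Scope and design

The package is organised as an analysis project: every computation lives
in `src/grainaging` (so tests and the acceptance script can import it),
and the numbered scripts under `analysis/` are thin narrative drivers
over the same stages, which are also exposed as the `grainaging` CLI.
The chain is simulate → extract → analyze → cluster, with each stage
reading and writing plain CSV/PNG/Newick/JSON artifacts so stages can be
re-run individually and verified by checksum (the run manifest).

## Synthetic study generator

The generator emulates a multi-season genebank study: by default 44
near-homozygous genotypes (recombinant inbred lines), one scatter image
per genotype × harvest year (2003, 2004, 2009, 2014), 17–20 non-touching
grains per image on a near-white background with a 24-patch color chart
at a fixed position.

**Grain geometry.** Grains are ellipses (genotype-specific length ≈
6.5 ± 0.3 mm within archetype, width/length ≈ 0.45) with low-frequency
sinusoidal boundary perturbation (harmonics 2–4, relative amplitude
0.03) and ~5% within-image size jitter. Placement is rejection sampling
on circumscribed circles with a 4 px gap, so masks are disjoint from
each other and from the chart by construction.

**Coat color.** Color is modelled in CIELAB. Each genotype has a
baseline (L* ≈ 55, a* ≈ 9, b* ≈ 22); baselines scatter around three
archetypes (offsets on length, L*, b* with roughly twice the
within-archetype SD), giving the genotype clustering recoverable but
overlapping groups. Redness (a*) carries no archetype offset. Within a
grain, L* falls quadratically toward the boundary (shading depth 0.12,
emulating the 3D shading that motivates separating brightness from
chroma), with small per-pixel Lab noise; pixels are converted to sRGB
and quantized to 8-bit.

**Storage trend.** Per genotype × year cell, redness gains
`β·(rank − mean rank) + ε_cell` (σ_cell = 0.8) and each grain adds
ε_grain (σ = 1.2). β is derived in closed form from the configured
target population correlation r = −0.6 between year rank and
genotype-centered per-grain redness; because genotype centering removes
1/n_years of the cell-level noise variance, the residual entering the
formula is `(1 − 1/n_years)·σ_cell² + σ_grain²`. Across 30 simulated
full-size studies the realised centered correlation was −0.605 ± 0.023
(mean ± SD). Lightness falls by 0.15 L* per rank (a weak trend, ≈ −0.3
in correlation units, deliberately much smaller than the redness trend);
hue rises automatically as a* falls against a constant b*.

**Chart and cast.** The chart uses the familiar 24-patch layout with
published 8-bit targets scaled by 0.9: the headroom keeps every patch
below saturation under global gain casts up to ~1.15 — a clipped channel
carries no recoverable information, and no affine fit can undo it. Each
image receives a random diagonal cast (gains uniform in [0.94, 1.06])
applied to the whole scene before quantization. The chart sits at a
fixed, known position with a black corner fiducial; general chart
*detection* is deliberately out of scope (for real photographs the
location is supplied externally).

**Germination.** One value per genotype × year × replicate (4
replicates): `clip(90 + year_offset + slope·(cell mean redness − 9) +
noise, 0, 100)` with slope −1.5 %/a*-unit and offsets chosen so year
means land near 90 / 98 / 65 / 90% — the 2009 season depressed. 2009
additionally carries a genotype × year disturbance (SD 10), so a few
cells fall outside the ±15 outlier band and exercise the exclusion rule.
The link reads redness from the generator's own ground-truth table, not
from extracted traits, keeping ground truth independent of the pipeline
under test.

**Reproducibility.** One master seed; per-image streams are seeded by
(master, crc32(genotype), year), so partial regeneration is stable. All
per-grain scalar ground truth is drawn *before* any placement or pixel
work, so `generate_study(render=False)` emits byte-identical scalar
tables at a fraction of the cost — used by the population-level
invariant tests.

**What the generator does not emulate** — and hence what passing tests
do not show about real photographs: awns, crease and embryo spot;
touching or overlapping grains; shadows and specular highlights;
non-affine (spatially varying or strongly nonlinear) illumination;
camera noise models beyond i.i.d. Gaussian; real ColorChecker spectral
behaviour. Recovery results bound the pipeline's self-consistency, not
its accuracy on field images.

## Imaging stage

Chart patches are measured over the central 50% of each patch; the scale
is patch pitch (mm) / pitch (px), 0.1 mm/px by default. Color correction
is a least-squares 3×4 affine map from measured to reference patch
colors (≥ 4 patches, rank-checked; residual RMS and clipped-pixel
fraction are recorded). Segmentation is Otsu's threshold on BT.601
luminance computed outside the chart region, inverted (grains darker
than background), followed by disk-radius-2 morphological opening and
hole filling; the chart box is forced to background. Components touching
the border, outside a 4–80 mm² area band, or more elongated than 4:1 are
rejected with a logged reason.

Contours are marching-squares sub-pixel boundaries smoothed by a
circular moving average (window 5, 2 iterations). Raw marching-squares
contours overestimate a disk's perimeter by ~5%, which would bias
circularity to ~0.90; after smoothing a rasterized R = 100 disk measures
sCi ≈ 0.998. All four shape indices are computed from that one polygon
(shoelace area, perimeter, convex hull), which makes `sSo ≤ 1` and
`sRu ≥ 1` exact geometric identities; `sA` alone uses the mask pixel
count. The major axis is the maximum Feret diameter (so `sRo ≤ 1` by the
isodiametric inequality); `sL/sW` are the minimum-area rotated-rectangle
sides. Contours are stored counter-clockwise in pixel coordinates
(x right, y down).

## Color conventions

All descriptors live on 8-bit scales: HSV with H = degrees/2 ∈ [0, 180],
S, V ∈ [0, 255]; CIELAB via sRGB → D65 with L = 255·L*/100, a = a* + 128,
b = b* + 128 (clipped); YCrCb as full-range BT.601 (gray (g,g,g) →
(g, 128, 128)). The 3σ trim is per component and per space, a single
iteration, strict `>` comparison, population SD (a zero SD discards
nothing) — the {100×10, 250×1} worked example trims the 250 and returns
exactly 100. Dominant colors use k-means (k = 3, k-means++ with 10
restarts) per color space on that space's components, seeded per grain
from crc32(grain id); clusters are ranked by descending pixel fraction
with ties broken by the brightness component (V/L/Y; R+G+B for RGB).
If a grain has fewer than k distinct colors, the distinct colors fill
the leading ranks and rank 3 duplicates rank 1 with fraction 0, keeping
the 48-column schema fixed.

## Statistics

Trend correlations operate on per-seed rows with traits centered by
genotype (per-cell aggregation is available via `unit="cell"`). Year
encodings: `Year01` (early half 0 / late half 1), `YearRank` (1..n
ascending), `Year` (calendar year). Pearson r is reported for all three;
the envelope test runs on `YearRank`. The test draws 2000 permutation
replicates (trait shuffled against year) and 2000 bootstrap replicates;
the bootstrap resamples x and y *independently* with replacement, which
— like the permutation — estimates the null spread of r. (Resampling
(x, y) pairs would center the bootstrap envelope on the observed r and
the both-envelopes rule could never fire; the envelopes reported by this
rule in practice sit near ±2.5/√n.) Significance requires the observed r
strictly outside the min–max range of both replicate sets; measured over
5000 null studies at n = 176 this rule's type-I error is ≤ 2·10⁻³.

One-way ANOVA is run separately per factor (genotype, year) with
p-values from the F distribution and no multiple-testing correction
(the envelope rule is reported per trait). The germination analysis
centers germination by year, excludes genotype × year cells whose
centered mean lies outside [−15, 15] (closed interval retained; the
whole cell is dropped), joins the year-centered cell germination onto
every seed of the retained cells, and envelope-tests germination against
every trait. Traits are deliberately left uncentered here: the injected
viability link operates on absolute redness, and genotype centering
would remove the genotype-level part of that signal.

UPGMA uses average linkage on Euclidean distances between standardized
rows (scipy's hierarchy behind the module surface); tree heights are
half the cophenetic distance, Newick branch lengths are height
differences. Trait clustering treats the 55 traits as items (distance
between standardized trait columns across seeds); genotype clustering
uses per-genotype trait means over all 55 standardized traits, cut at
k = 3 to mirror the three-family structure. LDA/canonical variates is a
generalized symmetric eigenproblem on the between/within scatter
matrices of standardized traits, ridge-regularized when within-class
scatter is singular (logged; inevitable for 48 color traits over ~15
genotype means) and scaled so canonical scores have unit within-class
variance; singleton clusters are excluded from the LDA classes.

## Numerical choices and degenerate inputs

Tolerances asserted in tests: shape indices within ±0.01 of closed forms
on analytic polygons and ±0.02 on rasterized masks at radius ≥ 100 px;
chart round-trips within ±2 of the 8-bit references for in-gamut casts.
Constant inputs: Pearson r raises (and trend rows for constant traits
are flagged degenerate, never significant); zero-variance columns are
dropped with a warning before standardization; an all-background image
yields an empty mask, not an error; undefined F (zero between- and
within-variance) is flagged rather than fabricated. Bootstrap resamples
that are constant are ignored when taking envelopes. Grain placement
failure raises an error reporting the achieved count.

## Problem sizes

The bundled demo analyses use 16 genotypes × 4 years (~1200 grains,
about four minutes end to end); the same code runs the 44-genotype
design via `--full`. The type-I calibration uses 5000 null studies at
n = 176 with the full 2000 + 2000 replicates. These sizes give the trend
estimate a sampling SD of ~0.03–0.05, comfortably inside the ±0.1
recovery tolerance; the package's own choice, balancing statistical
resolution against a test suite that stays pleasant to run.

## Known limitations

* The chart locator verifies a fiducial at a configured position; it is
  not a detector. Real photographs need an externally supplied chart
  location.
* Touching grains are not separated (no watershed); they are rejected by
  the area/aspect filters instead.
* The germination link and the color-cast model are linear by design —
  adequate for validating the inference machinery, not a biophysical
  model of seed deterioration.
* Within the redness family (Lab a* vs YCrCb Cr descriptors) the ranking
  of germination correlations is not stable across realisations at demo
  scale; only the family-level statement is.
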