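# Methods

`lulcpipe` reconstructs an annual land-use/land-cover (LULC) mapping and
change-accounting workflow for a cloud-heavy tropical forest region, and
pairs it with a synthetic-landscape generator so every stage can be scored
against known truth. This note records the models, the defaults and why
they hold, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## The mapping problem

Persistent cloud cover makes single-date optical classification unreliable
in wet tropical regions, so the workflow classifies *annual statistics* of
16-day vegetation-index composites instead: five spectral variables (red,
NIR, MIR reflectance; NDVI and EVI) observed 23 times per year per 231.3 m
pixel. A 15-year record (2001–2015) therefore carries 345 composites per
variable and pixel. Cloud-polluted composites survive even in
maximum-value-composite products, so each pixel-year series is cleaned by a
Gaussian-weighted temporal filter before the annual mean is taken. The
seven classifier predictors are the five annual means plus elevation and
terrain slope.

Eight classes are mapped spectrally: woody vegetation, wetland, grassland,
crop, palm plantation, settlement, continental water, and bare ground.
Mature forest and shrubby secondary regrowth are spectrally inseparable at
this resolution and are merged as "woody"; they are separated afterwards by
temporal logic alone (see the split rule below).

## Temporal filter

Each 23-composite year-cycle is treated independently — no information
crosses a year boundary, matching the year-cycle design of the original
filtering. Smoothing uses a discrete Gaussian kernel, window 5, sigma 1
composite, renormalized to sum to one, with reflected edges.

Outlier logic (the composite-level cloud residue detector):

* residual = raw − smoothed; a composite is flagged when |residual|
  exceeds `outlier_k` (default 2.5) robust standard deviations, where the
  robust scale is the median absolute deviation of the cycle's residuals
  times 1.4826;
* an absolute floor `min_resid` (default 0.03, variable units) prevents
  flags on low-noise series: the smoother attenuates a seasonal curve by a
  few percent of its amplitude, producing purely systematic residuals up to
  ~0.02 for the strongest seasonal class, while every simulated cloud bias
  is ≥ 0.08 — noise-free data must pass through bit-identical, and does;
* flagged composites are replaced by a Gaussian estimate computed over the
  *unflagged* neighbours only (kernel renormalized over the clean support),
  so a spike never contaminates its own replacement;
* the smooth/flag/replace cycle runs for `passes` (default 2) iterations
  with flags re-derived against the raw series each time. This matters:
  after the first pass removes a spike from the smoothing reference, a
  neighbour whose residual was inflated only by that spike is released, so
  the final flag set converges to the true outliers instead of bleeding one
  or two composites in each direction.
* unflagged composites are returned bit-identical; an all-identical cycle
  has zero MAD and is never modified.

Detection is symmetric in sign (indices and NIR are depressed by cloud,
red is raised, so a one-sided rule would be wrong for at least one band).
For contamination *verdicts* (scoring against a known mask) the
per-variable flags are combined by consensus: a composite counts as
contaminated when at least 3 of the 5 variables flag it, since cloud hits
all bands of a composite at once. At the default contamination rate (10%
of composites) the consensus detector recovers ~85% of truly contaminated
composites with under 1% false flags, and cleaning widens the
woody/grassland annual-mean EVI separation.

Known limitation: runs of 3+ adjacent contaminated composites drag the
smoothing reference down with them and largely escape detection. At the
default 10% independent contamination such runs are rare; at 15%+ they are
common enough that cleaning can *worsen* between-class separation. Real
composites with correlated multi-week cloudiness would stress the filter
the same way; a QA-band prefilter, out of scope here, is the usual remedy.

## Synthetic landscape generator

The generator produces the statistical structure the pipeline assumes,
with truth retained for scoring:

* **Spatial structure.** A patch mosaic on a fine sub-pixel grid
  (subgrid factor 3): seed cells are drawn with class proportions, and
  every fine cell joins its nearest seed (simultaneous multi-source
  growth; seeded jitter breaks ties deterministically). Default patch
  density 0.004 seeds per fine cell gives mean patches of ~250 fine cells
  (~13 km²).
* **Class proportions.** Woody 0.60, grassland 0.12, wetland 0.06, crop
  0.06, palm 0.05, water 0.05, settlement 0.03, bare 0.03 — a woody-
  dominated mosaic matching the ~64% woody cover regime of the mapped
  region.
* **Transitions.** Annual per-fine-cell conversion probabilities, default
  woody→{grassland 0.010, crop 0.003, palm 0.002, settlement 0.001} and
  {grassland 0.020, crop 0.010, palm 0.005}→woody: slow deforestation
  dominated by pasture conversion, faster farm abandonment — the two
  processes the change analysis must recover. Cells convert independently,
  which keeps the change bookkeeping exactly binomial
  (deforested fraction after k years = 1−(1−r)^k); an optional
  minimum-patch smoothing pass (`min_transition_patch`, default off) can
  consolidate conversions into clearings at the cost of that exactness.
* **Spectra.** Per class and variable, value(t) = mean + amplitude·sin
  seasonal curve + stationary AR(1) noise (sd 0.03, lag-1 correlation 0.3).
  Signatures are validated at construction to differ by more than
  2·noise_sd in at least one variable's mean for every class pair —
  the separability the classifier-regime checks assume. Cloud
  contamination hits a composite (all variables) with probability 0.10 and
  adds fixed biases (NDVI −0.40, EVI −0.35, NIR −0.15, MIR −0.08,
  red +0.25). Indices are clipped to [−1, 1], reflectances to [0, 1].
* **Terrain.** Elevation is a smoothed random field plus class-correlated
  offsets (wetland/water near sea level, woody cover ~250 m); slope is the
  central-difference gradient magnitude converted to degrees.
* **Interpretation.** The simulated photo-interpreter returns the
  pixel-level true class, flipped to a uniformly random other class with
  probability 0.05 — chosen to land in the published interpreter-agreement
  regime (kappa ≈ 0.93, accuracy ≈ 0.95) without imposing any particular
  confusion structure, since only the overall agreement is documented.

What the generator does **not** emulate: mixed-pixel spectra (a pixel's
spectrum follows its majority class, not a sub-pixel mixture), spatially or
temporally correlated cloud fields, sensor drift, georegistration error,
and terrain-dependent illumination. Passing synthetic checks therefore
demonstrates the pipeline's logic and statistical machinery, not
performance on real imagery.

## Training design

Training sites are *pure pixels*: every fine sub-cell of the pixel holds
one class in the interpretation year. A 1-km grid admits at most one site
per square kilometre, and a greedy seeded thinning pass then enforces a
minimum pairwise separation of 3 pixel widths (693.9 m) — one-per-cell
selection alone cannot guarantee that, since picks in edge-adjacent cells
can sit a single pixel apart. Candidates are pooled over three
interpretation years spread across the record (defaults: second year,
middle year, penultimate year), emulating multi-date high-resolution
acquisitions; pooling before thinning also guarantees a pixel is used at
most once. The imbalance utility can reduce the woody majority to the
second-most-prevalent class size, mirroring the published sensitivity
check at its 14,228 → 1,144 scale.

## Classifier

A single 500-tree random forest (scikit-learn `RandomForestClassifier`,
bootstrap bagging, floor(√7) = 2 candidate predictors per split, modal
vote) is trained on the labeled site rows and applied to every year's
features. One model serves all years because the training labels are
interpreted once, not annually re-interpreted; per-year retraining is not
offered as a default. Accuracy is reported from a stratified held-out 20%
of sites rather than out-of-bag, the more conservative of the two.
Classes with a single row cannot be stratified and stay in training with a
warning. On the default 200 × 200 scene (~1,500–1,600 sites) the held-out
kappa lands near 0.91 — bounded above by the 5% interpreter label error in
the reference labels themselves — and the paired imbalance comparison
(both models scored on the same held-out set, so test-set resampling noise
cancels) moves kappa by well under 0.02.

## Forest/secondary split

A woody pixel in year t is **forest** iff it was woody in *every* year
from the sequence start through t (running-prefix rule), otherwise
**secondary**. The first input year only seeds the history, so a 15-year
input yields 14 refined maps (2002–2015). Consequences, enforced as
invariants: forest(t+1) ⊆ forest(t) (a pixel can lose forest status but
never regain it), and forest + secondary partition the woody pixels of
each year exactly. No debounce is applied to single-year non-woody blips —
the filter and classifier are the noise control — so per-year
classification errors convert permanent forest to apparent secondary at a
rate of roughly 1−(1−ε)^y for per-year woody misclassification ε. At the
default scene's ε (map kappa ≈ 0.999) the secondary-validation agreement
against the truth's woody-continuity record averages ~83%, matching the
published ~84% regime; with noisier maps this number degrades quickly,
which is the split rule's intrinsic sensitivity, not an implementation
artifact.

## Change accounting

Areas are pixel counts × 0.0535 km² (0.2313², 4 significant figures).
Trends are Pearson correlations of class area against calendar year within
an epoch; significance comes from a seeded permutation test (10,000
shuffles of the area values; two-sided on |R|, with the +1 correction so
p ∈ (0, 1]) with the classical t-based p reported alongside — permutation
inference keeps the test distribution-free while preserving the familiar
R statistic. Zero-variance series are reported as no-trend rather than an
error. Epochs follow the two-period convention split at 2010 (inclusive at
both ends, 2010 in both periods); runs mapping fewer than five years use a
single epoch.

Transition matrices are exact paired-pixel tallies between a base-year and
end-year map, so the grand total equals the region area to the pixel.
Deforestation drivers aggregate {forest, secondary} → {grassland, crop,
palm, settlement}; reforestation aggregates {grassland, crop, palm} →
secondary (settlement has no reforestation counterpart). Bare ground is
tallied for conservation but excluded from trend and transition summaries.
Drivers are measured base-vs-end only; interannual paths remain available
in the refined maps but are not summarized.

## Accuracy machinery

Confusion matrices cross-tabulate reference (rows) against prediction
(columns); kappa is (pₒ−pₑ)/(1−pₑ); omission is the per-class miss rate
against the reference marginal, commission the false-alarm rate against
the predicted marginal. Kappa bands: poor < 0.4 ≤ good ≤ 0.75 < excellent,
with both boundaries assigned to "good" (the band edges are stated
ambiguously in common usage; the convention here is closed on the lower
side and configurable). Per-year kappas are summarized as mean ± sd.

## Orchestration and determinism

The pipeline runs generate → filter → sample → classify → split → account
→ assess. One global seed fans out to per-stage seeds via a SHA-256 hash
of `"{seed}:{stage}"` (truncated below 2³¹), so stages are independently
reproducible; two runs with the same configuration produce byte-identical
artifacts and manifest (the manifest carries no timestamps; wall-times go
to the log). Categorical rasters are written as ESRI ASCII grids, the
composite cube as NetCDF, sites as CSV/GeoJSON, tables as CSV, and the
manifest lists every artifact with its SHA-256 digest.

## Problem sizes

Default scene: 200 × 200 pixels (≈ 2,140 km², fine grid 600 × 600) over
2001–2015 — large enough for ~1,500+ training sites after thinning and for
stable per-class trends, while a full run stays in the minutes range on a
single core. Unit tests use 15–60 pixel grids and 3–6 year records; the
contamination and transition recovery checks use 100 × 100 and 200 × 200
scenes respectively.

## Known limitations

* Clustered (multi-composite) cloud runs evade the outlier detector; see
  the filter section.
* The split rule has no tolerance for single-year misclassification;
  secondary-vegetation accuracy is a steep function of per-year map error.
* Spectra are majority-class pure; classification difficulty on real
  mixed pixels is understated.
* The pixel-size constant is carried as 231.3 m everywhere; the source
  elevation product was resampled at a slightly different nominal size
  (231.35 m), a discrepancy we standardize away.
* Permutation p-values are Monte-Carlo (10⁴ draws), so values below
  ~10⁻⁴ saturate at 1/(N+1).
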