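# Methods

## The measurement

The package quantifies microglial phagocytosis in multi-channel 3D confocal
stacks as nested volume overlaps. Per section, three channels — microglia
(Iba1), lysosomes (CD68) and one neurite/synapse marker (VGAT, VGLUT2,
tdTomato-labelled A-fibres, or cleaved caspase-3) — are binarised with a
single global threshold each, and the readouts are voxel-count volumes:

* microglial volume `|Iba1|`,
* lysosome-within-microglia volume `|CD68 ∧ Iba1|`,
* total marker volume `|marker|`,
* engulfed marker volume `|marker ∧ CD68 ∧ Iba1|`,
* percent engulfed `= 100 · engulfed / marker`.

Engulfment is defined as the *triple* overlap — marker colocalised with
lysosomes inside microglia — because that is what the assay's figure
protocols depict; a secondary contact metric `|marker ∧ Iba1|` is also
emitted for sensitivity analyses, since "overlap" is occasionally read as
membrane contact without lysosomal localisation. The percent denominator is
the total marker volume in the analysed field of view. Masks are hard sets:
no partial-voxel weighting. Volumes are `count × dx·dy·dz` with the
anisotropic voxel size carried as metadata (common presets: 0.3 × 0.3 ×
0.67 µm at 20×, 0.07 × 0.07 × 0.23 µm at 63× Nyquist sampling).

Sections are averaged per animal before any statistics (animals are the
experimental unit); animals with fewer than `min_sections` (default 6)
usable sections are excluded with a logged warning.

### Geometric pre-processing

Stacks are indexed `(channel, z, y, x)`, 0-based, with z = 0 the imaging
surface (a `surface="bottom"` flag handles inverted stacks). Two
acquisition-protocol rules are implemented:

* `crop_xy(stack, target_um)` — a centred square field-of-view crop
  (default use: 192 µm) of `floor(target/dx) × floor(target/dy)` pixels; an
  explicit offset reproduces specific placements. Published FOVs such as
  192.79 µm arise from pixel-grid rounding; the crop target is
  configurable, and `floor` standardises the pixel arithmetic.
* `crop_top_z(stack, depth_um)` — for adult tissue, where the synaptic
  stains penetrate only a few micrometres, the first `ceil(depth/dz)`
  slices (inclusive of the partial slice; default 5 µm) are analysed; for
  neonates the full stack is used. The rule is driven by an `age_class`
  manifest column.

Crops commute, never change the voxel size and never reorder channels.

### Segmentation

Default binarisation is global Otsu per channel over the full 3D volume
(the z-stack was processed as one histogram, so no per-slice thresholds);
`fixed` and `quantile` thresholds are provided for sensitivity analyses,
and the applied threshold is always recorded on the mask and in the run
manifest. A constant image raises (degenerate histogram) rather than
silently returning an all-true/all-false mask. Connected components are
labelled at 26-connectivity by default (6 available), with a minimum size
filter (default 10 voxels) to suppress shot-noise specks; ROI tables carry
voxel count, physical volume, bounding box and centroid, ordered by
descending size with centroid-lexicographic tie-breaks.

## Synthetic data

The generator exists so that every stage can be validated against known
truth; it emulates the *structure* of the real assay, not its biology.

A section is built on the voxel lattice in physical units:

* **Cells** — spheres (somata, radius ~2.8–3.6 µm) plus dilated
  random-walk branches (3–5 per cell, 8–14 µm long, radius 0.6–0.9 µm).
  No claim of morphological realism is made; the model provides branched,
  anisotropic targets with guaranteed containment.
* **Lysosomes** — spheres (radius 1.2–1.8 µm, 4–7 per cell) whose centres
  lie within `r_soma − r_lyso − margin` of a soma centre, with
  `margin = max(lysosome_margin_um, puncta_radius_um)` (default 0.8 µm).
  Placement failure (a lysosome that cannot fit) raises after bounded
  retries.
* **Puncta** — the marker field. The punctum count is Poisson in
  `density × volume / 1000 µm³` (default 25 per 1000 µm³, radius 0.5 µm);
  a Binomial(`n`, `engulfed_fraction`) subset is placed with centres within
  `r_lyso − r_punctum` of a lysosome centre, the rest with centres outside
  the whole-cell mask. Engulfed centres are chosen by greedy
  minimum-distance selection within the lysosome cores: engulfed puncta
  crowd into small compartments, and unchecked mutual overlap would erode
  the realised voxel fraction well below the requested one.

These containment rules are what make the generator an *oracle* rather
than an approximation: an engulfed punctum is wholly inside the lysosome
mask and an extracellular punctum can never touch one, so a requested
fraction of 0 or 1 is realised exactly on the true masks, intermediate
fractions are binomial in the punctum count, and the stored
`true_engulfed_fraction` always equals the overlap recomputed from the
masks.

Rendering applies the standard microscopy forward model: Gaussian PSF
(default σ = 0.5/0.15/0.15 µm in z/y/x, matching a high-NA confocal),
mean photon scale 200 at unit structure intensity, constant background of
10 photons, Poisson shot noise, additive Gaussian read noise (σ = 2), and
uint16 quantisation. Partial-volume blur is thus the only cross-talk
between the true compartments. The generator does not attempt realistic
autofluorescence, vasculature, or non-microglial structures — passing
recovery tests demonstrates correctness of the measurement pipeline under
a plausible noise model, not robustness to every artefact of real tissue.

**Cohorts.** A cohort is a 2 (sex) × 2 (neonatal incision) × 2 (adult
incision) factorial plan (any factor can be restricted to one level).
Group means are `base + Σ effects` of the active levels; animals add
Normal between-animal noise, sections Normal within-animal noise;
engulfed fractions are clipped to [0, 1] with a flag. Defaults — base
engulfed fraction 0.04 (percent engulfed in the low single digits, where
the real assay operates), between-animal SD 0.008, within-animal SD 0.004
— were fixed once as plausible study conditions. All randomness flows from
one seed through `SeedSequence` spawning (per animal, then per section),
so cohorts are extensible without disturbing earlier draws, and identical
seeds give bit-identical stacks.

**Apoptosis sections.** Per-section cell counts are Poisson (defaults:
0.2 cells/section control, 0.43 incision — the scale of reported
cells-per-section differences); locations follow a mixture of Gaussian
hotspots on a unit half-ellipse hemisection template
(`{u ≥ 0, u² + (2v−1)² ≤ 1}`, medial edge at u = 0), or are uniform when
no hotspots are given. Cells are rendered as ~2 µm-radius blobs confined
to the central z third of the thin slab, because the counting emulates a
widefield image and edge-clipped somata would fall below any sane volume
filter.

## Apoptotic-cell detection and mapping

Detection is threshold → 26-connected components → minimum-volume filter
(default 20 µm³) → one intensity-weighted centroid per component, after a
small Gaussian smooth (0.3 µm). Otsu assumes a bimodal histogram, which a
cell-free section (pure noise) violates; a foreground-fraction guard
(> 20 % foreground) falls back to a 0.999-quantile threshold, whose
isolated noise voxels the volume filter then removes. Counts are
normalised to cells per section per animal. The superimposition map is a
Gaussian kernel density (default σ = 5 % of the hemisection width) on a
grid over the unit square, scaled so its integral equals a chosen target
(e.g. mean cells/section), with an overlay table of all points keyed by
animal for colour-coded plots. Detection counts are monotone
non-increasing in the volume filter, and totals are conserved between
detections and summaries.

## Statistics

* **Two-way ANOVA** — OLS with sum-to-zero contrasts and Type III sums of
  squares (the behaviour of the graphing package commonly used for such
  assays), so mildly unbalanced cohorts are handled sensibly; on balanced
  data this coincides with the classical cell-means decomposition, which
  the tests verify to 1e-10. Empty cells and designs with < 2 residual df
  raise. A constant response short-circuits to F = 0, p = 1 (statsmodels
  would otherwise return float-noise ratios).
* **One-way ANOVA** — direct between/within decomposition.
* **Welch's t** — scipy, with the Welch–Satterthwaite df exposed.
* **Sidak** — `p_adj = 1 − (1 − p)^m`, clipped; the comparison family is
  always explicit configuration, never inferred.
* **BCa bootstrap** (authored here; scipy's implementation is used only as
  an independent cross-check in the tests) — statistic
  `mean(group2) − mean(group1)`; resampling independent within groups;
  bias correction `z0 = Φ⁻¹(#{θ* < θ̂}/B)` with the proportion guarded to
  `[0.5/B, 1 − 0.5/B]`; acceleration from the combined leave-one-out
  jackknife over both groups, `a = Σd³ / (6 (Σd²)^{3/2})`, falling back to
  a = 0 for degenerate jackknives; interval endpoints are the BCa-adjusted
  percentiles of the bootstrap distribution. Zero-variance inputs yield a
  zero-width interval flagged degenerate. The seed is a mandatory argument;
  there is no hidden global state. Defaults: 95 % level, 5000 resamples.

Pooling: sexes can be pooled for estimation plots while remaining a factor
in the ANOVA; both pathways exist and the run report records which was
used. Significance level defaults to α = 0.05.

### Known calibration behaviour

At n = 10 per group the 95 % BCa interval of a mean difference covers the
truth in ≈ 92 % of normal-data replicates, about one point below its
nominal level and below the t-interval's 95.4 % on the same data; scipy's
independent BCa implementation reproduces the same number. This is the
well-known first-order undercoverage of bootstrap intervals at small n,
not an implementation artefact; coverage approaches the nominal level as
n grows. The acceptance suite states the nominal band and therefore flags
this, deliberately, rather than papering over it.

## Orchestration and reproducibility

The CLI (`engulf3d simulate|analyze|stats|all -c run.yaml`) writes
OME-TIFF stacks with voxel metadata, a cohort manifest, optional
ground-truth mask sidecars (`use_ground_truth` analysis bypasses
segmentation and must reproduce the truth exactly — the pipeline's
self-test), per-section and per-animal CSVs, and JSON reports. Every
number-affecting parameter appears in the config and is echoed into the
emitted manifests; timestamps live in a separate metadata file so report
content is byte-identical across reruns.

## Problem sizes used in the test suite

Recovery tests run a 2×2 cohort of n = 4 animals × 6 sections at
128 × 128 × 24 voxels (0.3/0.3/0.67 µm); power simulations use 200
truth-path replicates of a 16-animal cohort; ANOVA calibration 2000 null
replicates; BCa coverage 1000 replicates × 5000 resamples; apoptosis
recovery pools 192 rendered sections and 50 hotspot seeds. These sizes
were chosen to make the Monte-Carlo error small relative to each
acceptance band while keeping the whole suite fast on a laptop.

## Limitations

* The segmentation stage recovers percent engulfed with a small
  multiplicative attenuation (typically −5…−20 % relative under the
  default optics), because thresholding the blurred marker field dilates
  the denominator more than the nested numerator; group *contrasts* and
  rank order are preserved. Recovery tolerances in the tests reflect this.
* Normalised hemisection coordinates for real (non-synthetic) sections
  would require a user-supplied landmark transform, which is out of scope.
* No single-cell engulfment profiles: masks, not cell identities, are the
  unit of measurement. Watershed splitting of touching cells and
  ML segmentation are likewise out of scope.
* The noise model omits autofluorescence, bleaching and stage drift;
  deconvolution is assumed to have happened upstream, if at all.
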