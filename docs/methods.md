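# Methods

This note documents the models, parameter choices, numerical conventions and
limitations of the `bmrisk` pipeline. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Spatial substrate and conventions

All volumes are plain numpy arrays over an isotropic `Grid` (default 2 mm,
96³; 1 mm is supported but slower). The physical coordinate of voxel
`(i, j, k)` is `origin + (i + 0.5)·spacing` — the voxel-center convention.
Every geometric operation uses this one rule: the ellipsoid renderer and the
contour rasterizer include a voxel iff its *center* lies inside the shape
(even-odd rule for polygons, with multiple same-plane polygons combined by
XOR so holes are representable), centroids are means of voxel centers, and
distance maps measure distances between voxel centers. Simulated and
rasterized inputs are therefore interchangeable.

## The phantom

The phantom stands in for a population-template brain with overlay atlases.
It is built deterministically from a seed, with all geometry expressed in
fractions of the physical field of view (any grid ≥ 32³ works; if a
mandatory structure digitizes to zero voxels a configuration error is
raised).

- **Cerebrum**: ellipsoid with a cortical gray shell (thickness
  max(5 mm, 2.5 voxels)) over a white interior. **Cerebellum**: a separate
  posterior-inferior ellipsoid with its own thinner shell. **Brainstem**: a
  vertical capsule, counted as white-matter-like parenchyma.
- **Deep gray nuclei** (paired thalamus, caudate, putamen, pallidus,
  hippocampus, amygdala) are ellipsoids carved from cerebral white matter
  and assigned to the gray class — so the gray–white interface includes
  deep-nucleus borders, as it does in segmentation-derived interfaces.
  **Ventricles** are inside the brain but belong to neither tissue class;
  parenchyma = gray ∪ white is the support of lesion formation.
- **Atlases**: coarse (24 labels: 8 lobes L/R, cerebellum L/R, 12 nuclei,
  brainstem, ventricles, with laterality partner labels), fine (lobes and
  cerebellum split inferior/superior), functional (motor, sensory, visual,
  default-mode bands plus the subcortical network), vascular (anterior,
  middle-left/right, posterior territories).
- **Perfusion**: piecewise tissue baseline (gray 62, white 28, deep gray 55,
  ventricles 8, arbitrary units) smoothed with a Gaussian (σ = 1.2 voxels)
  and modulated by ±12% seeded smooth noise; gray mean exceeds white mean by
  construction, as in cerebral blood-flow maps.

Region tables record both total and parenchymal label volumes; densities use
the parenchymal column (below).

## Cohort generator

The generator's defaults are the study conditions used throughout the
analyses and tests.

- **Lesion counts**: zero-truncated negative binomial. The summary
  statistics to emulate, typical of multi-center radiosurgery series, are a
  per-patient median of 2–3 with means near 4 and maxima near 50; numerical
  calibration gives dispersion r = 0.5
  and untruncated mean 2.0 (truncated median 2, truncated mean ≈ 3.6,
  99.5th percentile ≈ 20), clipped at 50.
- **Volumes**: log-normal, median 0.2 cc, σ_log = 1.3, clipped to
  [0.002, 62] cc — right-skewed with most lesions below 0.5 cc.
- **Placement**: centers are drawn from the discrete intensity
  λ(x) ∝ m(region)·exp(−d/τ)·p_norm(x)^γ over parenchymal voxels, with
  sub-voxel jitter. Defaults: τ = 15 mm, γ = 1, multipliers 1. τ was
  calibrated by scanning so that ≈74% of placement mass lies within 5 mm of
  the interface against this phantom's 52% tissue null, matching the
  ~72%-within-5-mm proximity reported for clinical cohorts. τ = 3 mm is a
  deliberately strong bias used only as the power-analysis scenario.
- **Rendering**: each lesion is an axis-aligned digitized ellipsoid of the
  drawn volume with per-axis log-normal anisotropy (σ = 0.55, normalized to
  preserve volume), giving continuum Wadell sphericity mean ≈ 0.87 with most
  lesions above 0.75. Rendered voxels are clipped to the brain mask; a lesion
  that captures no voxel center keeps its center voxel.
- **Constraints**: within a patient, a center is re-drawn (≤ 20 attempts) if
  its ellipsoid would overlap an earlier lesion of the same patient —
  clinically, lesions are delineated as distinct; overlap across patients is
  allowed and is what the risk map accumulates. Patients are assigned
  round-robin to sites (default 4) so per-site statistics are well defined
  at small n; primaries are drawn from a fixed mix (lung 46%, breast 20%,
  melanoma 14%, other 20%).

The simulation is a pure function of (phantom, config) including the seed.

What the generator does *not* emulate: cortical folding (the interface is
smooth, so the tissue null is less concentrated than in a convoluted brain),
registration error, MR signal characteristics, delineation artifacts such as
superior-inferior "caps", and per-primary differences beyond the label
itself. Passing tests therefore demonstrate correctness of the *pipeline*
under a known generative model, not clinical reproduction.

## Risk maps and regional statistics

Accumulation sums binary lesion masks voxelwise; it is exactly additive and
permutation-invariant, and conserves the total lesion voxel count (checked
as an integer identity). Per-site maps sum to the total map.

Lesions are assigned to one region each by centroid membership; a centroid
on background is rescued to the nearest label within 5 mm, otherwise the
lesion is "unassigned" and reported separately (never silently dropped).
Percent contributions are over assigned lesions and sum to 100.

**Density** is a dimensionless enrichment ratio: a region's share of lesions
divided by its share of *parenchymal* labeled volume. Using parenchymal
rather than total label volume makes the ratio 1 under uniform seeding in
every region where it is defined, and leaves it undefined (excluded and
logged) for non-parenchymal labels such as the ventricles. A plain
volume-share denominator would bias every ratio by the non-parenchymal
fraction.

95% intervals on percentages are t-intervals over per-site values
(mean ± t₀.₉₇₅,ₙ₋₁·SE); with 4 sites a t-interval is the defensible choice.
Laterality is tested per mirrored label pair by Welch's t over the per-site
percentages; when both site vectors are constant and different the statistic
is unbounded and p is reported as NaN. Expansion sensitivity re-assigns
memberships after dilating every label by 5/10 mm (Euclidean in mm, overlaps
resolved by nearest original region: each background voxel within the margin
takes the label of its nearest labeled voxel); margin 0 is the identity.

## Interface-proximity null test

Observed and null histograms use 0.5 mm bins from 0 to the 99.5th percentile
of parenchymal interface distances (rounding up to a bin edge; mass beyond
is clipped into the last bin). The observed series bins lesion-centroid
distances (pooled and per site); the null series bins parenchymal voxel
volume. Over-representation is the observed-minus-null cumulative fraction
within 5 mm, in percentage points; the earth mover's distance is the sum of
absolute CDF differences times the bin width.

**Wilcoxon pairing.** Pairing the two series per bin is structurally
conservative: bin fractions of a multinomial sample are negatively
correlated and sum to zero, which shrinks the variance of the rank statistic
— measured type-I rate 0.000 at α = 0.05 over 500 uniform replicates. The
primary test therefore uses a randomized probability-integral transform:
each observed distance is mapped through the null CDF with uniform
randomization within its discrete atom (seeded), which yields exactly i.i.d.
Uniform(0,1) values when lesions are seeded uniformly over tissue; the
signed-rank test of those values against 0.5 is exactly calibrated (measured
type-I 0.032–0.038 over 500 replicates) and rejects with probability 1.0 at
τ = 3 mm with 200 patients. The per-bin pairing remains available as a
fallback when only binned series exist, documented as conservative.

The Wilcoxon statistic itself is computed exactly for n ≤ 25 nonzero
differences (zeros dropped, ties midranked, null distribution by convolution
over doubled ranks) and by a tie- and continuity-corrected normal
approximation above.

## Perfusion analyses

Perfusion maps are normalized by the 99th percentile of in-brain values and
clipped to [0, 1] — percentile scaling is robust to hot-spot outliers.
Subspace occupancy is evaluated per lesion voxel (volume-weighted), since
the claim it operationalizes concerns lesion *volume*; it is monotone in
both bounds. Joint histograms conserve total brain volume and total lesion
volume exactly. Arterial-territory contributions reuse the regional
statistics with the vascular atlas — no separate code path. The per-region
perfusion–density trend reports Spearman's ρ between volume-weighted mean
normalized perfusion and the density ratio; note that planted regional
multipliers (cerebellar enrichment, subcortical sparing) deliberately create
off-trend outliers in the study configuration.

## Sparing targets and coverage

A sparing plan is brain minus the spared-structure union dilated by an
isotropic margin (default 3 mm). Dilation thresholds the Euclidean distance
transform at the margin — exact in millimetres and independent of voxel
size, unlike iterated structuring elements. Coverage counts lesions by
centroid (default; consistent with the pipeline's centroid-based region
accounting) or by lesion volume; both are reported. The whole-brain plan
covers any in-brain cohort at exactly 100%; nested spared sets give monotone
non-increasing coverage; under uniform seeding, centroid coverage equals
100 × (1 − spared parenchymal volume fraction) up to sampling error.

## Numerical choices

- **Sphericity surface area**: the default is a marching-cubes isosurface.
  On binary volumes the marching-cubes mesh carries a near-constant
  staircase inflation of surface area — measured 1.0946–1.0953 for
  digitized balls of radius 3–10 voxels and 1.087 for a 2:1 spheroid — so
  areas are divided by a calibrated constant 1.095; a digitized ball then
  scores 1.00 and a 2:1 prolate spheroid matches its closed form within
  0.7%. Mesh values are clipped at 1; exposed-voxel-face counting is kept as
  an exactly testable fallback (it overestimates area, biasing sphericity
  low: a single voxel scores (π/6)^{1/3} ≈ 0.806), and is used automatically
  (flagged) when a lesion is too small to mesh.
- **Connectivity**: 26 for lesion components; interface adjacency is
  6-connected; the distance transform is the exact Euclidean EDT with the
  grid spacing as sampling.
- **Degenerate inputs**: empty masks give empty lesion lists; an all-spared
  plan is flagged degenerate and covers 0%; constant perfusion and
  gray/white masks with no adjacency raise errors; off-grid lesions name the
  offending patient and lesion.
- **Determinism**: every stochastic step flows from explicit
  `numpy.random.default_rng` seeds; the pipeline writes byte-identical
  tables when re-run with the same config and seed.

## Problem sizes

The analyses and tests run on a 96³ phantom at 2 mm with cohorts of 50–500
patients, 500 replicates for the type-I calibration and 200 for power —
sizes at which every calibration band in the test suite is a ≥ 2.8σ
statement while the whole suite completes in well under a minute of compute
for the heavy fixtures. Density-ratio recovery bands are asserted only for
regions whose expected lesion count under the relevant configuration is
≥ 100 (the cerebral lobes, cerebellum); a 1-cc nucleus expects ~1 lesion at
this scale, so its ratio is checked collectively through the χ²
goodness-of-fit with standard pooling of small expected counts.

## Known limitations

- The phantom's smooth interface understates the tissue null concentration
  of a folded cortex; absolute over-representation numbers are therefore
  phantom-specific and not comparable to clinical values.
- The perfusion–distance subspace fraction depends strongly on the phantom's
  perfusion histogram; the pipeline reports it but no clinical value should
  be expected from synthetic data.
- Centroid-based region assignment apportions a large lesion entirely to one
  region; a volume-apportioned variant is a natural extension but is not
  implemented.
- The interface distance of a lesion defaults to its centroid's distance
  (a boundary-minimum variant exists as an option), so large lesions
  touching the interface can still report positive distances.
- DICOM/DICOM-RT ingestion, registration, bias correction, dose calculation
  and DVH analysis are out of scope; inputs are atlas-space NIfTI volumes or
  the repository's JSON contour format.
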