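# Methods

This note documents the models, estimators and numerical choices behind
`epiderm`, in the spirit of a package methods appendix: what is simulated,
what is measured, which constants matter, and what a green test does and
does not establish.

## 1. The synthetic skin volume

A subject volume is a voxel grid (default pitch 1 µm isotropic; the
z step of the emulated acquisition is 1 µm and its lateral resolution
~1 µm, the lateral pixel pitch being configurable) containing, top to
bottom: background, stratum corneum (SC), viable epidermis (VE), dermis.
Voxels are labeled by which depth interval contains their center, so an
extracted interface index is an unbiased estimator of the continuous
interface depth (error uniform in ±½ voxel).

**Surfaces.** The skin surface is a plane with a small random tilt
(default ±2 µm across the field) and a sub-voxel random offset. The tilt
has a numerical purpose: it dithers the voxel quantization laterally, so
per-subject mean thicknesses are estimated far below the voxel size. The
SC–VE interface is parallel to the surface at the drawn SC thickness.

**DEJ.** The dermal–epidermal junction is the VE base plane plus a
zero-mean Gaussian random field, synthesized spectrally (white noise
filtered with a Gaussian spectrum, correlation length default 50 µm — the
scale of rete-ridge relief). The field amplitude is calibrated by
bisection until the *measured* undulation statistic of the realized map is
within 10 % (relative) of the subject's target; calibration failure raises
an error reporting achieved vs target. No claim is made that real DEJ
geometry is Gaussian; only its undulation statistic is specified by the
emulated study, so the geometry is an explicit stand-in validated by
recovery.

**Nuclei.** Keratinocyte nuclei are axis-aligned oblate spheroids
(flattened along z, as epidermal nuclei are, increasingly so toward the
surface). Per-nucleus volumes are log-normal with the subject's (mean,
within-subject SD) for the band — log-normality keeps volumes positive at
the large printed dispersions (e.g. 97 µm³ SD on a 208 µm³ mean) — and
compactness is Normal, clipped to [0.30, 0.98]. The polar/equatorial axis
ratio is obtained by numerically inverting the closed-form oblate
sphericity (tabulated once, interpolated), so the drawn compactness is the
analytic sphericity of the generated shape.

**Layer structure.** The lateral plane is partitioned into 50 µm patches;
each patch draws an integer local layer count `L = round(N(m, s'))` around
the subject's mean layer number, with `s'² = s² − 1/12` so the realized
integer field has the subject's target tile SD after rounding noise.
Layers are equally spaced depth shells at normalized depths
`(i + ½)/L`, following the local DEJ/SC–VE surfaces, with a small z jitter
(SD 0.25 µm, clipped at ±0.5 µm). Per-band counts are allocated so that
each maturation band's expected surface density equals the subject's CSD
draw regardless of how many shells fall inside the band (the band total is
split evenly over its shells).

**Packing.** Within a shell, nuclei sit on a jittered lattice (a
quasi-regular epithelial arrangement). At the realistic band densities,
flattened superficial nuclei reach ~40–50 % lateral disc coverage — around
the jamming limit of plain rejection sampling, which stalls there — while
a jittered lattice reaches them deterministically. A pairwise ellipsoid
overlap check (cell-hashed) is retained; the rare irresolvable conflicts
(adjacent 3×-volume atypical redraws) are tolerated and truncated by the
no-overwrite rasterizer. A disc-coverage pre-check raises a packing error
naming the infeasible band. Rasterization marks a voxel when its center
lies inside the ellipsoid, so the expected voxel count equals the analytic
volume (random sub-voxel centers), and never paints outside the VE.

**Hierarchy of randomness.** All subject-level quantities (thicknesses,
undulation target, layer numbers, per-band CSD / NV / NC means and
within-SDs, atypical fraction) are drawn from Normals truncated at ±3 SD
via inverse-CDF on a fixed-order uniform stream; a separate stream drives
the surfaces and another the nuclei. Replicate volumes of the same subject
reuse the subject-level stream and redraw the structural streams,
emulating repeated acquisitions of one site. Per-subject seeds are a
stable hash of (master seed, site, group, index), below 2³¹.

**Atypia contamination.** A per-band fraction of nuclei (defaults: the
published per-band atypia rates) is re-drawn with 3× volume and flagged in
the ground truth. Consequence: the *measured* band volume mean of a
default cohort exceeds the typical-population parameter by roughly
`(1 + 2f)` — the volume-recovery tests therefore run with the atypical
fraction at zero, and report tables from default cohorts describe the
contaminated mixture, not the typical population.

## 2. The measurement chain

**Heightmaps.** Interface depth per lateral column is the first z crossing
of the label transition (first voxel of the deeper layer), in µm. Columns
missing a transition, or excluded by the follicle/ROI mask, are masked out
of all three maps; >50 % missing raises a degenerate-volume error.

**Thickness** is the mean *vertical* distance between two maps over their
joint mask — the pixel-count definition along z, deliberately not the
surface-normal distance. It is additive across stacked interfaces.

**Undulation.** `%U_DEJ = (S_DEJ/S_ROI − 1) × 100` with `S_DEJ` the area
of the triangulated heightmap (two triangles per grid cell in physical
coordinates) and `S_ROI` the projected area of the valid cells. Cells with
any masked corner leave both areas, so follicle exclusion is consistent in
numerator and denominator. Triangulation (rather than voxel-face
counting) makes the statistic exact for planes and refinement-consistent
for smooth fields. Maps extracted from voxel labels are quantized to the
z step; the staircase alone would inflate `%U` by several points at
physiological slopes, so the pipeline pre-smooths extracted maps with a
2 µm Gaussian (masked/normalized convolution). The smoothing attenuates
genuine relief mildly (~10 % at a 50 µm correlation length), which is
acceptable for a statistic whose physiological range here is 0–3 % and
whose headline use is a flatness bound.

**Morphometrics.** Volume = voxel count × voxel volume (unbiased, see
rasterization). Surface area comes from marching cubes on the padded
instance mask after a light Gaussian smoothing whose sigma adapts to the
object's smallest bounding-box extent (0.35–0.7 voxel): large objects
tolerate more smoothing (a digitized r = 8 µm ball then recovers its
analytic area to ~1 % and sphericity ≥ 0.97), while a 3-voxel-thick
granular nucleus would be rounded into a blob by a fixed 0.7. Residual
compactness bias at 1 µm voxels is about ±0.03 for nucleus-sized objects —
an irreducible resolution effect that the emulated instrument shares.
Instances touching the volume boundary are flagged and excluded from
volume/compactness statistics (censored shapes) but kept for counting.

**Maturation bands.** Normalized depth d of the centroid, clamped to
[0, 1]; bands are the quintiles, half-open below and closed at the top
(d = 0.2 → M2, d = 1.0 → M5). Centroids outside the VE by more than one
voxel are excluded with a warning. Band assignment uses the centroid only
(deterministic, fast).

**Layer counting.** Per 50 µm tile, centroids are sorted by *normalized*
depth and greedily clustered: a new layer opens when the gap exceeds
0.6 × (mean nucleus z extent)/(median VE thickness). Normalized depth is
essential: with raw z, DEJ relief within a tile smears the layers and
overcounts by ~0.2 layers at 3 % undulation. Empty tiles are excluded from
the mean and SD. The algorithm is a stand-in (no published counterpart);
its validation is exact recovery of the generator's integer layer field.

**Atypia.** Per nucleus, features (log NV, NC); score = Euclidean norm of
robust z against the median/MAD (scaled, floored) of its k = 15 nearest
same-band neighbors within 60 µm (symmetrized graph; depth is *not* a
feature — banding already conditions on it). The flag threshold 2.75 is a
calibration constant, fixed once by simulation so that a homogeneous
Gaussian population is flagged at ~0.10 — the young-skin magnitude of the
emulated tables — and stored in `AtypiaConfig`, not hard-coded. Log-volume
features make CNA exactly invariant to global volume rescaling. Known
limitation: as contamination grows beyond ~15 %, neighborhood medians and
MADs absorb the outliers and the CNA response saturates near 0.13–0.14
(masking); recovery is quantitative at the 0.10 design point and
monotone below ~0.15, and only scale and monotonic behavior — not absolute
comparability to any trained scorer — are claimed.

**Group statistics.** One-way group-means fit; Shapiro–Wilk on the pooled
residuals at the 10 % level selects ANOVA (p ≥ 0.10) or Kruskal–Wallis.
Pairwise comparisons run only when the omnibus is significant at α = 0.05
(otherwise dashes): Tukey HSD on the ANOVA path; on the KW path Dunn
pairwise rank z-tests with midranks, the standard tie correction and Holm
adjustment (a Nemenyi/Tukey-on-ranks switch is provided; for two groups
both reduce exactly to the asymptotic Mann–Whitney test, which the test
suite uses as an independent oracle). Letters come from the
insert-and-absorb algorithm, ordered so the smallest group mean carries
'a'; the display is asserted against the p matrix (share a letter ⇔
p_adj ≥ α) on every call. Constant data raises rather than fabricating a
p-value.

## 3. Cohort experiments and variance reduction

The headline quantities (percent thickness changes between extreme age
groups, cohort-mean layer count, site-mean undulation) are recomputed by
`epiderm.experiments` through the full volume pipeline at a reduced
lateral field (300 × 150 µm; grid depth auto-sized to hold the stack at
+3 SD). Two standard Monte-Carlo designs keep the estimates' sampling
noise far below the reported precision:

* **Quantile pairing (common random numbers):** subject i occupies the
  same population quantile in the young and old cohort — the percent
  change is evaluated on matched percentiles, the longitudinal reading of
  a cross-sectional table. Without pairing, the i.i.d. sampling SD of a
  50-per-group percent-change estimate (:about 1.4 points) would exceed
  the one-point reporting precision; with pairing and stratification it
  falls to ~0.1 points.
* **Randomized stratification:** subject-level quantiles are
  `u_i = (i + v_i)/n` with `v_i` uniform — every subject is still a draw
  from the stated truncated Normal, but the cohort is a low-variance,
  unbiased sample of it.

Each subject keeps its own independent surfaces, DEJ field and nuclei.
Cellular-metric cohorts (layer counts, densities) use plain draws apart
from stratifying the subject-mean layer target.

## 4. What the synthetic world does and does not establish

The generator reproduces the *statistics* the emulated study reports —
thickness distributions, an undulation-calibrated DEJ, band densities,
log-normal nucleus volumes, discrete layer structure, atypical-volume
contamination — on a geometry chosen for testability: flat parallel upper
surfaces, Gaussian DEJ relief, spheroidal nuclei on jittered lattices,
no optical speckle or intensity model, no hair follicles (only an optional
ROI exclusion mask), no dermal content. A green recovery test therefore
establishes that the estimators are unbiased and correctly scaled on
label volumes with known truth; it does not validate any image
segmentation, nor that real skin satisfies the geometric assumptions.
Published-value comparisons (percent changes, layer counts, flatness
bound) establish consistency of the whole chain with the printed tables
the generator was parameterized from — they are recovery checks, not an
independent reproduction of the human cohort.

## 5. Defaults that matter

| Constant | Value | Where | Why |
|---|---|---|---|
| Voxel pitch | 1 µm isotropic | `VoxelSpec` | acquisition z step; lateral pitch configurable |
| Lateral field (full) | 1200 × 500 µm | `VoxelSpec` | emulated field of view; experiments use 300 × 150 |
| DEJ correlation length | 50 µm | `SubjectParams` | rete-ridge scale; calibration makes %U insensitive to it |
| Undulation calibration tol. | 10 % relative | `generate_dej_heightmap` | matches estimator tolerance downstream |
| Undulation pre-smoothing | 2 µm | pipeline / `dej_undulation` | removes quantization staircase (see §2) |
| Patch / tile size | 50 µm | generator & `layer_counts` | ≥ 2 nucleus diameters; aligned generator/estimator |
| Layer-gap factor | 0.6 × mean z extent | `layer_counts` | separates 8–10 µm shells from ±0.5 µm jitter |
| Atypia k / radius / threshold | 15 / 60 µm / 2.75 | `AtypiaConfig` | threshold calibrated to 0.10 homogeneous base rate |
| Atypical volume factor | 3× | `SubjectParams` | contamination design point of the detector checks |
| α / normality α | 0.05 / 0.10 | stats chain | reporting convention of the emulated analysis |
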