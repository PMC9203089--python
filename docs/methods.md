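# Methods

`biliphone` re-implements the computational stack of a mobile-phone
transcutaneous bilirubinometer (TcB): the Monte-Carlo (MC) photon-transport
model used to design the phone's snap-on optical adapter, the raw-image
calibration pipeline, the two-stage arc-ROI + gamma-GLM algorithm that
estimates total serum bilirubin (TSB) from filtered RGB reflectance images,
the agreement statistics used to evaluate it, and a synthetic-cohort
generator that supplies ground-truthed capture data for end-to-end testing.

## Adapter geometry

All spatial quantities live in a frame whose origin is the centre of the
illumination spot's projection on the skin, with +x toward the camera field
of view (FOV).  The FOV is a 9 mm x 12 mm rectangle whose proximal edge sits
`spot_radius + edge_offset` from the origin; the two configurations of
interest place the beam-edge-to-FOV-edge gap at 1.6 mm and 0.0 mm, putting
the source-centre-to-FOV-centre distance at 9.1 mm and 7.5 mm respectively
(`center_offset = spot_radius + edge_offset + fov_width/2`).  The
illumination beam is modelled as a uniform (top-hat) disk of radius 1.5 mm
incident at 30° from normal, tilted toward the FOV; the spot radius is
back-derived from the printed centre offsets and FOV width, since the
physical spot diameter is a property of the specific adapter build.
Collection is restricted to exit directions within a 21° half-angle cone
(the illumination channel's half-angle after its pinhole; the collection
optics' true NA is configurable).

## Skin optical model

Neonatal skin is a three-layer stack — epidermis (60 µm), dermis (1.2 mm),
semi-infinite subcutis — with refractive index 1.4 and Henyey-Greenstein
anisotropy g = 0.85 throughout.  Absorption is linear chromophore mixing:

* epidermis: melanosome fractional volume `f_mel` times the melanosome
  interior coefficient `51.9 (λ/500 nm)^-3.48 mm^-1`; `f_mel = 0.10`
  is the darkly pigmented reference condition;
* dermis: whole-blood hemoglobin (150 g/L, 75% oxygenated by default) at a
  blood volume fraction of 0.5%, plus bilirubin at a dermal concentration
  equal to 5% of the serum value (the dermal partition factor maps the
  mg/dL serum scale onto skin; it is a model constant, not a measured
  quantity), plus a flat 0.01 mm^-1 baseline;
* scattering: reduced scattering `4.6 (λ/500 nm)^-1.5 mm^-1` in every
  layer.

The molar extinction tables (oxy/deoxy-hemoglobin, albumin-bound bilirubin,
400–700 nm at 10 nm steps) shipped in `data/chromophores.csv` are smoothed
representative composites of standard reference spectra.  They are
deliberately documented as defaults rather than device constants — the real
device's optical constants are not public — and every coefficient and layer
parameter is overridable.  Bilirubin extinction is zero beyond ~545 nm, so
TSB moves the blue (474 ± 10 nm) channel strongly, the green (554 ± 10 nm)
channel negligibly and the red (635 ± 10 nm) channel not at all.

## Monte-Carlo transport

The kernel is classic layered (MCML-style) weighted-packet transport:
exponential optical-depth sampling, continuous absorption weight deposition
(`Δw = w μa/μt` per event), Henyey-Greenstein deflection, Fresnel
reflection/refraction at every index-mismatched boundary, and Russian
roulette below a weight of 1e-4 with survival probability 0.1.  Layered
rather than voxelized transport suffices because the skin model is
laterally homogeneous.  Three numerical choices worth noting:

* **Exact weight bookkeeping.**  Roulette is folded into the absorbed tally
  with signed adjustments (kills deposit the packet weight, survivals
  subtract the boost), so specular + diffuse-reflected + transmitted +
  absorbed sums to the launched weight to float rounding — a conservation
  check independent of sampling noise.
* **Determinism.**  Each (seed, wavelength-index) pair seeds its own
  generator stream, so identical inputs give bit-identical maps, and
  two-geometry comparisons are run paired-seed.
* **Binning.**  FOV exit weight is tallied into 0.25 mm bins, half-open
  `[lo, hi)`, only for exits inside both the FOV rectangle and the
  acceptance cone.

Channel integration averages the spectral maps over each filter passband
with uniform weights (the physical filter shape is unpublished).
"Normalized reflectance" outputs divide by the global maximum across the
configurations being compared.

The two-geometry report gives each channel's gain from shrinking the edge
offset in two forms: the relative gain `100·(R_B − R_A)/R_A` and the gain in
normalized-reflectance points `100·(R_B − R_A)/max`.  The rankings
genuinely differ: the most strongly attenuated channel (blue, in pigmented
skin) always has the largest *relative* gain, while the brightest channel
(red) gains the most *points*.  Both are reported so either reading of a
"percent increase" is available.

### Diffusion oracle

The verification oracle is the extrapolated-boundary dipole: an isotropic
source at `z0 = 1/(μa + μs')` and its image mirrored about the boundary at
`-2zb`, `zb = 2AD`, with the internal-reflection parameter A from the
Groenhuis polynomial and `μeff = sqrt(3 μa (μa + μs'))`.  The
oracle-equivalence test runs at matched refractive index (n_rel = 1,
g = 0.9, μs' = 1/mm, μa = 0.01/mm), where the plain dipole is accurate to a
few percent; with an n = 1.4 boundary the dipole itself carries a known
15–25% amplitude bias, which would test the oracle rather than the kernel.
A lossless matched-boundary medium (μa = 0) must return all weight; because
first passage back to the surface is heavy-tailed, this check uses a modest
photon count (the weight-based tally is exact regardless) with a step cap
whose leakage is ~4e-4, far inside the ±0.005 band.

## Capture pipeline

Each measurement is 3 flash-on + 3 flash-off 16-bit frames of tissue plus a
paired set of an HDPE white calibration standard.  The chain per frame
list: bilinear per-plane demosaic (RGGB default; planar input passes
through), quarter-area resize (2×2 block mean; the pixel pitch is declared
as FOV width over image width), kNN-distance outlier rejection, pixelwise
averaging.  The calibration step is

    R = (tissue_on − tissue_off) / (cal_on − cal_off)

with pixels masked (not clipped) where the denominator falls below 1e-6 of
full scale, where any contributing raw flash-on pixel reached 98% of full
scale (the invalid region is dilated one pixel for the demosaic
neighbourhood, and block-resize ANDs validity), giving a single calibrated
RGB reflectance image per patient with a usability mask.

Outlier frames are detected on per-frame summary features (per-channel mean
and standard deviation, spread-normalized): a frame is dropped when its
mean distance to its k nearest neighbours (k = 1 for triplets) exceeds
median + 3·MAD of all such distances; the most central frame is always
retained.  When the MAD degenerates to zero (e.g. two identical frames), a
relative margin around the median distance substitutes.  Whole-image
distances would also work; summary features are cheaper and insensitive to
pixel noise.  All frames passing rejection are pooled into the average.

These identities hold by construction and are asserted as tests:
self-calibration gives R ≡ 1; global gain changes and global dark-offset
shifts cancel; frame order is irrelevant; raising the saturation limit
never shrinks the valid area.

## Arc-ROI features, gamma GLM, two-stage estimation

Features are mean calibrated reflectance over arc-shaped ROIs: annular
segments around the source centre parameterized by mid-arc radius, radial
width and angular centre θ (span fixed at 90°, θ = 0 toward the FOV
centre).  The default set has 9 ROIs — 4 blue, 3 green, 2 red — reflecting
each channel's unsaturated area (blue, weakest, is usable closest to the
source); initial placements are evenly spaced radii per channel.  Box
bounds: radius 2–13 mm, width 0.5–4 mm, θ ±60°.

TSB is strictly positive and right-skewed, so it is modelled with a gamma
GLM, log link by default (guaranteeing positive predictions; inverse link
selectable).  The fit is iteratively reweighted least squares with the
minimum-norm `lstsq` solve, which keeps the fit defined when the design has
more columns than rows — stage 1 fits 9 features + intercept on 8 training
patients, so every stage-1 fit interpolates and the held-out test error
carries all the signal.  Convergence is a relative-deviance change below
1e-8; dispersion is Pearson χ²/dof.  An independent maximum-likelihood fit
(statsmodels) serves as the cross-check oracle on well-posed designs.

**Stage 1** repeats, over many resamples: draw a TSB-stratified split —
4 clinical bins (0–5, 5.01–10, 10.01–15, 15.01–25 mg/dL), 2 train per bin
(8 train) and 2/2/2/1 test (7 test) — then minimize the *test-set* sum of
squared prediction errors over all 27 ROI parameters by bounded
generalized pattern search (poll ±1 mesh step per coordinate, first
improvement accepted, mesh ×2 on success and ×0.5 on failure, iterates
clipped to the box, stop at the evaluation budget or mesh < 1e-3).
Evaluating the SSE on the held-out resample is the only reading that gives
the test resample a role, and the only one that is not trivially zero given
the interpolating fit.  Infeasible arcs (outside the FOV or fully
saturated) return +inf — barrier semantics.  The per-resample optima are
aggregated parameter-wise by the median (lower-median convention for even
counts).  The published procedure's 900 s wall-clock budget per resample is
replaced by an evaluation-count budget (default 500) for reproducibility.

**Stage 2** freezes the median ROIs and cross-validates: per iteration,
hold out 1 patient from each of 5 bins (0–3.5, 3.51–6.5, 6.51–10, 10.01–15,
15.01–25 mg/dL), fit on the remainder, record held-out predictions; each
patient's estimate is the median of their predictions across all
iterations in which they were held out.  Reference sizes: 3000 resamples
and 10000 iterations; the test suite runs a scaled profile (50 resamples,
budget 100, 500 iterations) that completes in under a minute and exercises
the identical code path.

## Agreement statistics

The paired difference is **prediction − TSB** (negative bias =
under-prediction); limits of agreement are bias ± 1.96 times the sample
(n−1) SD; RMSE is reported per TSB range (default split at 10 mg/dL) and
per skin group; the group comparison is Welch's unequal-variance two-sided
t-test on absolute errors between the two largest groups (groups with
fewer than 2 members are excluded with a warning).

## Synthetic cohorts

The clinical images are not public, so end-to-end validation runs on
synthetic cohorts.  TSB is drawn from a gamma(shape 3.2, scale 2.9)
truncated to (0, 25] — mode ~6.4 mg/dL, bulk 5–10 mg/dL, tail reaching ~24
mg/dL; pigmentation is two melanosome fractions (2.5% "light", 10% "dark")
with even weights, recorded as the skin-group label.  At the default
n = 37, TSB draws are redrawn (deterministically under the seed) until
every clinical stratum can support both stages' splits.

Per patient, the noiseless reflectance field over the FOV factors each
channel into an epidermal double-pass Beer-Lambert transmission (melanin is
a thin filter: it darkens the image but barely changes the lateral decay)
times the extrapolated-boundary dipole profile at the channel's
depth-averaged dermal (μa, μs').  The same closed form drives the MC
verification, but cohort generation never runs the MC kernel — the dipole
keeps a 60-patient cohort under 5 s.  Calibration captures render the HDPE
standard's own dipole field (μa = 5e-4, μs' = 2.5 mm^-1): a flat
unit-reflectance standard would share no units with the per-area tissue
field, whereas the HDPE profile makes the calibrated image exactly
"reflectance relative to the standard" at realistic count levels.

The sensor model applies gain (default 3.2e6 counts per field unit,
putting the HDPE peak at ~75% of full scale — the fixed-exposure compromise
the real protocol makes), a dark offset of 800 counts, Poisson-scaled shot
noise plus Gaussian read noise, 16-bit clipping, forced saturation within
`saturation_radius` of the source (default 2.5 mm), optional RGGB
mosaicking, and, with probability 0.03 per flash-on tissue frame, a
near-dark "non-contact" corrupted frame whose index is recorded in the
ground truth.

What the cohorts do **not** emulate: skin texture and curvature, contact
pressure, ambient-light leakage, lens shading, chromatic aberration, or
any lateral heterogeneity.  Passing tests therefore demonstrate algorithmic
correctness and self-consistency, not clinical accuracy.

### What the recovery test does and does not show

The end-to-end recovery check (`recovery_cohort_config`) uses n = 60,
fixed light pigmentation, low noise.  With pigmentation held constant the
gamma GLM on raw ROI means is an essentially correctly specified inverse
of the forward model, and the two-stage estimator recovers TSB nearly
exactly (R² ≈ 0.99, |bias| < 0.1 mg/dL at the scaled stage sizes).  With
pigmentation groups mixed, a linear predictor in *raw* means cannot
normalize the multiplicative melanin filter (that would need ratios or
logs), and pooled accuracy drops substantially — the same structural
limitation visible in the modest clinical correlation of raw-mean TcB
regressions.  The recovery test is a parameter-recovery check of the
estimator machinery, not a claim about mixed-pigmentation performance.

## Problem sizes used in the shipped checks

Simulation sizes in the test and acceptance suites are chosen to exercise
every code path at desk scale: MC checks use 1e4–3e5 photons (the
conservation check is exact at any count), channel comparisons use in-band
wavelength grids, and the two-stage estimator runs the scaled profile
above.  All sizes are plain function arguments; the reference-scale runs
are a matter of passing larger numbers.

## Known limitations

* The MC kernel's absolute spectra depend on the shipped representative
  optical constants; figure-level curve values from any specific device
  are not reproducible from public information, and only trends and
  orderings are asserted.
* The diffusion forward model in the cohort generator is a smooth
  approximation; it shares structure with the analysis pipeline's physics
  (by design, for invertibility), so recovery tests do not probe model
  mismatch between skin and estimator.
* The gamma GLM inherits the raw-mean feature choice of the method it
  implements; pigmentation normalization is out of scope.
* Stage-1 arc spans are fixed at 90°; freeing the span would add a fourth
  parameter per ROI but has no published reference behaviour.
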