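# Methods

`spectpvc` implements a desk-scale analogue of a quantitative ¹⁷⁷Lu-SPECT
partial-volume-correction and lesion-dosimetry study: a digital NEMA IEC
phantom stands in for the physical phantom measurement, an image-space
blur(+noise) forward model stands in for acquisition and reconstruction,
and a synthetic patient cohort with known kinetics stands in for the
clinical series.  Everything downstream of the forward model — matched-filter
PSF calibration, Richardson–Lucy deconvolution, recovery-coefficient
modelling, voxel dosimetry — is the method under study and is implemented
exactly as it would be applied to real data.

## Digital phantom

The NEMA IEC body phantom is modelled as an axis-aligned elliptical cylinder
(semi-axes 150 × 110 mm, length 180 mm; no lung insert) holding six spheres
of inner diameter 10, 13, 17, 22, 28 and 37 mm (0.5–26.5 mL) on a coplanar
ring of 114.4 mm diameter.  Default fill is 237 kBq/mL foreground over
30 kBq/mL background (8:1).  The default grid is 128³ voxels at 4.8 mm
isotropic (voxel volume 0.1106 mL) — the standard pixel size for a 128×128
SPECT matrix on this camera class; it is configurable.

Painting uses fractional occupancy: voxel value = occ·fg + (1−occ)·bg
inside the body, 0 outside.  Occupancy is computed with an exact chord
integral along z and midpoint supersampling transverse, with the transverse
subcell refined to ≤ r/(2·ss); at the default supersampling of 4 per axis
the rasterized sphere volumes match the analytic 4πr³/3 to < 0.5 % down to
the 10 mm sphere, and total painted activity matches the analytic
body+spheres value to ≈ 0.1 %.

Four spherical background VOIs (radius 15 mm) sit on a 45 mm ring offset
55 mm axially from the sphere plane, rotated 45° against the insert
positions.  The physical study does not describe its background-VOI
geometry; this placement keeps them clear of every insert and is a
documented assumption.

Measurement caveat: sphere VOI statistics use the arithmetic mean over
voxels whose centres fall inside the sphere.  At 4.8 mm voxels this mask
unavoidably includes partial-occupancy edge voxels, so even the *unblurred*
phantom measures hard-mask recovery of 0.80–0.91 (pure rasterization; the
painted foreground is exact — every fully interior voxel carries exactly
237 kBq/mL, which the tests assert on the full-occupancy core).

## Forward model and noise

"Reconstruction" is an image-space blur with an isotropic Gaussian PSF
(default σ = 6.0 mm, FWHM 2√(2 ln 2)·σ = 14.1 mm), kernel truncated at 4σ
and renormalized, zero padding at the grid boundary.  Phantom and cohort
objects are kept ≥ 4σ from the boundary so the padding choice is
immaterial.  Projection-space physics (attenuation, scatter, detector
response, reconstruction iterations) is deliberately out of scope.

Noise is Poisson on a counts scale: expected counts = concentration ×
`counts_per_kBqmL_per_voxel`, drawn per voxel, converted back.  The default
order draws counts on the *unblurred* grid and lets the PSF smooth them,
giving the spatially correlated texture of reconstructed SPECT.  The
calibration default 0.002 counts/(kBq/mL)/voxel was chosen once so that the
blurred-background coefficient of variation lands at ≈ 0.41, inside the
0.3–0.5 band implied by the phantom-table SNRs (≈ 11 for the 26.5 mL
sphere); it was not revisited afterwards.  A consequence worth knowing: the
blur leaves only ~3 effectively independent samples inside the 26.5 mL
sphere VOI, so a single-seed VOI mean carries a standard error of several
percent, and seed-pooled means are used wherever a stable estimate matters.

### The Gaussian-surrogate recovery gap

A Gaussian blur at σ = 6.0 mm *cannot* reproduce the recovery coefficients
the physical system measures.  The closed-form volume-averaged blurred
sphere indicator (the oracle used in the tests) gives RC = 0.67 for the
37 mm sphere at 8:1 contrast, against 0.75 measured on the real
OSEM-with-resolution-modelling reconstruction; the gap grows for smaller
spheres.  The matched-filter σ is fitted on edge-dominated RMSE and the
real system restores sphere edges better than any single Gaussian predicts.
The simulation therefore reproduces the *structure* of the study (RC
ordering, iteration trade-offs, dose directions) but its absolute RCs sit
below the scanner's, and the corresponding absolute benchmark is reported
as computed, not adjusted.

## Matched-filter resolution analysis

The ground truth is blurred with candidate Gaussians (default grid 0–48 mm
in 0.48 mm steps, endpoints inclusive) and the σ minimizing the RMSE
against the reconstruction is taken as the system resolution.  The RMSE
domain is the union of the four largest-sphere VOIs (2.6–26.5 mL); the two
smallest spheres are excluded as they are invisible at SPECT resolution.
No intensity renormalization is applied (both images are quantitative); a
scale-fit option exists but defaults off.  Ties break toward smaller σ.
Because the grid quantizes σ (and 6.0 mm is not a multiple of 0.48 mm), a
parabolic refinement through the three points around the arg-min is
reported alongside the raw grid value; an arg-min at a grid endpoint is
returned unrefined with a warning flag.  Downstream stages take σ as
explicit configuration (default 6.0 mm).

For efficiency the blur is evaluated on a crop extending one kernel
half-width beyond the evaluation VOIs — exactly equivalent to blurring the
full volume for the evaluated voxels.

## Richardson–Lucy deconvolution

The multiplicative update

    u⁽ᵏ⁺¹⁾ = u⁽ᵏ⁾ · [ ( d / max(u⁽ᵏ⁾ ⊛ P, ε) ) ⊛ P̃ ],  ε = 10⁻¹²

runs for a configured number of iterations (default 4) with the Gaussian
PSF P (default σ 6.0 mm) and its reflection P̃; ratios where the re-blurred
estimate falls below ε contribute 0.  Negative inputs are clipped to zero
with a logged count; estimates are clipped non-negative each iteration.

Initialization is the load-bearing choice.  The default is a **uniform
constant** (the input mean): the constant cancels in the first ratio, so
iteration 1 returns the observed image *re-blurred* — recovery first drops
below the uncorrected value and then climbs past it, which is exactly the
iteration-1 dip the phantom table shows and which matches the behaviour of
the widely used reference implementation (constant initial estimate).  The
`observed-image` initialization is offered for the flux-conservation use
case: with it, total activity of an interior object is conserved to well
under 0.5 % per iteration (tested).  Deconvolution is applied independently
per timepoint image in dosimetry.

Identities used as test oracles: σ = 0 is an exact fixed point;
constant-init iteration 1 equals d ⊛ P exactly for data whose support stays
a kernel half-width clear of the boundary; 4-iteration output matches an
independent reference implementation to 1e-5 on a random volume; for a
noiseless, matched-PSF, compactly supported phantom the voxel RMSE to truth
is non-increasing over at least the first 10 iterations.

## Recovery coefficients and the volume model

RC_s = (mean concentration in the known-volume sphere VOI) / (true fill
concentration); VOIs come from ground-truth geometry and are never
re-segmented.  SNR_s = (mean_s − mean_bkg) / SD_bkg with background mean
and voxelwise SD pooled over the four background VOIs.  The physical study
never prints its SNR formula; the background-subtracted numerator is the
package default and mean/SD is available behind a flag for sensitivity
analysis.

Volume dependence is modelled as f_RC(V) = 1 − (1 + (V/b)^y)⁻¹, fitted by
bounded least squares (b, y > 0; deterministic initialization b = median
volume, y = 1).  f_RC(b) = 0.5 for any y, the curve rises strictly from 0
to 1, and its convergence to full recovery is slow — which is why
volume-derived corrections stay substantial even for tens of mL.  The
dose correction applies the *fitted curve* (not nearest-sphere lookup):
OR+RC dose = OR dose / f_RC(lesion volume).

## Synthetic cohort

Each patient carries 1–8 spherical lesions placed without overlap (8 mm
clearance) in the elliptical-cylinder body.  Per-lesion draws:

| quantity | distribution | default | rationale |
|---|---|---|---|
| volume | log-normal, clipped 0.5–180 mL | median 3.5 mL, σ_log 0.9 | per-site medians ≈ 2–20 mL, ranges 0.5–230 mL |
| TBR | log-normal | mean 9.2, σ_log 0.4 | reported cohort average 9.2 |
| effective half-life | log-normal, capped at 160.8 h | mean 60 h, σ_log 0.3 | typical lesion effective half-lives; cap = physical ¹⁷⁷Lu decay (6.7 d), since biology only accelerates clearance |
| injected activity | normal | 7308 ± 132 MBq | reported DOTA-TATE arm (7499 ± 162 for the PSMA arm) |

Background follows 30 kBq/mL at t = 0 with a 40 h effective half-life.
Every voxel follows a single monoexponential from t = 0 (no uptake phase —
the same model the dosimetry fits); the lesion concentration at the first
imaging timepoint (24 h) is TBR × background.  Observed images apply the
phantom's blur(+noise) model per timepoint (24/48/72 h); series are
inherently co-registered.  The default cohort grid is 96×96×64 at 4.8 mm —
the body fits with ≥ 4σ boundary margin and a full 128³ grid would add
nothing to the synthetic study.

What the generator does **not** emulate: irregular lesion shapes and
heterogeneous uptake, inter-timepoint registration error, attenuation and
scatter, uptake-phase kinetics, organ backgrounds.  Passing cohort tests
therefore demonstrate the pipeline's internal correctness and the
*direction* of corrections under the stated model, not clinical accuracy on
real scans.

## Dosimetry

* **Segmentation** — region-growing threshold on the uncorrected 24 h
  image: fixed fraction (default 0.4) of the regional maximum (component
  and maximum alternated to a fixed point), or an absolute concentration
  threshold.  The connected component containing the seed is kept.  Masks
  are fixed on the uncorrected image for all three dose variants.  Lesions
  whose seed falls below threshold (dim lesion beside a bright one) are
  excluded with a warning, mirroring the visibility requirement for lesion
  inclusion.
* **TBR** — lesion mean over the average of four lesion-sized spherical
  VOIs placed just outside the boundary (first four valid of ±x, ±y, ±z;
  VOIs clipped by the grid or overlapping the lesion are rejected).
* **TAC fit** — per-voxel log-linear least squares of A0·exp(−λt).  Voxels
  with all samples positive get the free fit; a fitted λ at or below the
  physical ¹⁷⁷Lu constant (ln 2 / 160.8 h) triggers a floor-constrained
  amplitude refit (flagged), preventing divergent integrals from
  noise-flattened voxels; voxels with some non-positive samples but ≥ 2
  positive ones use the floored refit on the positive samples; fewer than
  2 positive samples excludes the voxel (zero TIA).
* **TIA** — analytic 0→∞ integral: A0 · voxel volume · 1000 / λ (Bq·h per
  voxel).  No trapezoid head/tail handling; the monoexponential-from-zero
  model is exact for the generator and is the fitted model regardless.
* **Dose** — FFT convolution of the TIA map with a voxel S-value kernel
  (Gy per Bq·h).  The default kernel is local deposition: the mean β energy
  per ¹⁷⁷Lu decay (133.3 keV) absorbed entirely in the source voxel
  (appropriate for 4.8 mm voxels against the ~0.7 mm β range; photon
  cross-dose omitted).  Published kernels load from CSV (odd cube,
  row-major, spacing in the header; full-precision round-trip).
* **Comparison** — per lesion: mean dose in the fixed mask per GBq injected
  under OR, OR+LRD and OR+RC = OR / f_RC(segmented volume).  Percent
  differences are stored signed (100·(AD_x − AD_OR)/AD_OR); summary tables
  report mean ± SD of their magnitudes, matching absolute-difference
  reporting conventions.

## Determinism and problem sizes

All randomness flows from a single seed (per-patient and per-timepoint
streams are spawned from it); phantom generation is fully deterministic.
Re-running a configuration reproduces every CSV bit-identically on the same
platform.  Default problem sizes — 128³ phantom grid, 96×96×64 cohort grid,
10 patients, 10 noise seeds for pooled phantom estimates — were chosen as
the smallest sizes at which the measured quantities are grid- and
noise-stable; tests use the same sizes except where a closed-form identity
allows a small synthetic volume.

## Known limitations

* The Gaussian forward model under-recovers relative to the physical
  resolution-modelled reconstruction (see above); absolute RCs and any
  quantity derived from them sit below the scanner's measured values.
* Percent-difference statistics depend on their definition (signed vs
  absolute, OR-denominator); the definition here is documented and
  configurable but cannot be validated against the clinical tables, whose
  definition is unstated.
* Sphere-based recovery corrections assume the phantom's contrast and
  geometry; real lesions vary in both, which is precisely the limitation
  the deconvolution branch is meant to sidestep.
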