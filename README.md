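# spectpvc

Partial-volume correction and lesion dosimetry for quantitative ¹⁷⁷Lu-SPECT,
as a fully synthetic, end-to-end tested pipeline.

## The problem

¹⁷⁷Lu radionuclide therapies (DOTA-TATE for neuroendocrine tumors,
PSMA ligands for prostate cancer) are monitored with quantitative SPECT at
multiple timepoints post-injection to estimate lesion absorbed doses.  SPECT
resolution is 10–25 mm FWHM, so small lesions lose apparent activity to
spill-out (the partial volume effect) and their absorbed doses are
underestimated.  Two standard remedies are compared here:

* **OR + LRD** — Richardson–Lucy deconvolution of each reconstructed volume
  with the system PSF, as a post-processing step;
* **OR + RC** — scaling the uncorrected dose by a phantom-derived,
  volume-dependent recovery-coefficient correction.

This package implements the full workflow for anyone studying such
corrections without scanner access: a digital NEMA IEC body phantom and a
synthetic patient cohort replace the measurements, and every downstream
stage (PSF calibration, deconvolution, recovery modelling, voxel dosimetry)
is real, reusable code.

## The models

**PSF calibration (matched-filter analysis).** The phantom ground truth g is
blurred with candidate Gaussians and compared against the reconstruction d:

    σ̂ = argmin_σ RMSE( g ⊛ G_σ , d )   over the visible sphere VOIs,

swept over σ = 0–48 mm in 0.48 mm steps (FWHM = 2√(2 ln 2) σ; the adopted
σ = 6.0 mm corresponds to 14.1 mm FWHM).

**Richardson–Lucy deconvolution.** With P the Gaussian PSF kernel and P̃ its
reflection, the estimate is updated multiplicatively,

    u⁽ᵏ⁺¹⁾ = u⁽ᵏ⁾ · [ ( d / (u⁽ᵏ⁾ ⊛ P) ) ⊛ P̃ ],

from a uniform initial estimate (4 iterations by default).  Total activity
is conserved and recovery rises with iterations while SNR falls — the
trade-off that fixes the iteration count.

**Recovery model.** Sphere recovery coefficients RC(V) = measured/true
concentration are fitted with

    f_RC(V) = 1 − (1 + (V/b)^y)⁻¹,

and the volume-derived dose correction is 1 / f_RC(V) (factor 2 at V = b).

**Dosimetry.** Per voxel: monoexponential fit A₀e^(−λt) to the 24/48/72 h
series (λ floored at the physical ¹⁷⁷Lu decay constant, half-life 6.7 d),
analytic time-integrated activity A₀/λ, convolution with a voxel S-value
kernel (default: local deposition of the 133.3 keV mean β energy), mean
lesion dose per GBq injected.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The two analysis drivers reproduce the study end-to-end:

```bash
python analysis/01_phantom_calibration.py --seed 0
python analysis/02_cohort_dosimetry.py   --seed 0
```

The first generates the digital phantom (237:30 kBq/mL), simulates its
reconstruction (σ = 6.0 mm blur + Poisson noise), runs the matched-filter
sweep and the iteration sweep, and fits the recovery curve.  With seed 0 it
prints:

```
Matched-filter analysis: best sigma 6.24 mm (FWHM 14.7 mm), parabolic refinement 6.23 mm

Per-iteration recovery coefficients and SNRs (iteration 0 = uncorrected reconstruction):
 iteration  rc_2.6mL  snr_2.6mL  rc_5.6mL  snr_5.6mL  rc_11.5mL  snr_11.5mL  rc_26.5mL  snr_26.5mL
         0      0.40       6.17      0.63      10.87       0.54        9.11       0.60       10.31
         1      0.29       6.87      0.44      12.48       0.43       12.02       0.50       14.57
         2      0.40       7.29      0.64      13.12       0.56       11.22       0.63       12.94
         4      0.52       7.40      0.82      12.74       0.65        9.77       0.70       10.63
         6      0.58       7.10      0.90      11.89       0.68        8.70       0.72        9.24

Recovery model fit: f_RC(V) = 1 - (1+(V/b)^y)^-1 with b = 4.31 mL, y = 0.27
```

Reading it: the sweep recovers the generating PSF within one grid step
(6.24 vs 6.0 mm); iteration 1 *drops* recovery below the uncorrected row
(the uniform initialization re-blurs the data) before climbing past it,
while the larger spheres' SNR peaks at iteration 1–2 and falls thereafter —
the pattern that motivates stopping at 4 iterations.  Values carry a few
percent of seed-to-seed noise; pooled estimates are used wherever a stable
number matters.

The second driver simulates a 10-patient cohort (1–8 spherical lesions
each, mean tumor-to-background ratio 9.2), runs the three-way dosimetry and
summarizes percent dose differences against the uncorrected reconstruction;
with seed 0 it reports 29 measurable lesions, deconvolution raising the
lesion dose in 29/29 of them, and

```
Mean ± SD absolute percent dose difference vs the uncorrected reconstruction:
variant  n_lesions  mean_abs_pct_diff  sd_abs_pct_diff
 OR+LRD         29               27.2             10.0
  OR+RC         29               87.5             32.9
```

i.e. deconvolution raises lesion doses by ~20 % on average while the
volume-derived recovery correction, which aims at *full* recovery, applies
much larger factors — largest for the smallest lesions.  Outputs land in
`results/phantom/` and `results/cohort/` as CSV.

The same stages are scriptable through a CLI (`spectpvc phantom generate`,
`spectpvc mfa run`, `spectpvc lrd apply|sweep`, `spectpvc recovery
compute|fit`, `spectpvc cohort simulate`, `spectpvc dose`, `spectpvc study
phantom|cohort`), with volumes as NIfTI/MetaImage and VOI geometry as JSON.

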