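"""Synthetic patient cohort with known lesion kinetics.

Emulates a radionuclide-therapy cohort imaged at 24, 48 and 72 h
post-injection: spherical lesions of variable volume (log-normal, median a
few mL) and tumor-to-background ratio (mean 9.2) placed in an
elliptical-cylinder body, every voxel following a monoexponential
time-activity curve from t = 0 (no uptake phase).  Observed images are
produced by the same blur(+noise) forward model as the phantom, per
timepoint, so the full ground truth (masks, A0, lambda_eff) is available
for recovery tests.

Generation is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Image3D, PSFModel, Units, VOI, rasterize_sphere
from .phantom import NoiseModel, PhantomSpec, body_occupancy, simulate_reconstruction

__all__ = ["CohortSpec", "LesionTruth", "GroundTruthStudy", "PatientStudy",
           "CohortGenerationError", "simulate_cohort"]

from .dosimetry import LU177_LAMBDA_PHYS


class CohortGenerationError(RuntimeError):
    """Lesions could not be placed without overlap within the retry budget."""


@dataclass
class CohortSpec:
    """Declarative description of the synthetic cohort.

    Volume and TBR distributions are log-normal; ``tbr_mean`` is the
    distribution mean (default 9.2).  Lesion effective half-lives are capped
    at the physical Lu-177 half-life when ``enforce_physical_decay`` is on
    (biological clearance can only speed decay up).  Injected activities are
    normal (default mean 7308 MBq, the DOTA-TATE arm; 7499 for the PSMA arm).
    """

    n_patients: int = 10
    lesions_per_patient: tuple[int, int] = (1, 8)
    volume_lognormal_median_mL: float = 3.5
    volume_lognormal_sigma: float = 0.9
    volume_range_mL: tuple[float, float] = (0.5, 180.0)
    tbr_mean: float = 9.2
    tbr_lognormal_sigma: float = 0.4
    lesion_half_life_mean_h: float = 60.0
    lesion_half_life_sigma: float = 0.3
    bkg_conc_kBq_per_mL: float = 30.0  # at t = 0
    bkg_half_life_h: float = 40.0
    timepoints_h: tuple[float, ...] = (24.0, 48.0, 72.0)
    injected_MBq_mean: float = 7308.0
    injected_MBq_sd: float = 132.0
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: float = 4.8
    body_semi_axes_mm: tuple[float, float] = (150.0, 110.0)
    body_length_mm: float = 250.0
    enforce_physical_decay: bool = True
    placement_margin_mm: float = 8.0
    max_placement_retries: int = 500

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints_h)
        if len(tp) < 3 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be >= 3 strictly increasing values")
        self.timepoints_h = tp

    def grid(self) -> Image3D:
        return Image3D(
            np.zeros(self.grid_shape), (self.spacing_mm,) * 3, Units.KBQ_PER_ML
        )

    def bkg_lambda(self) -> float:
        return np.log(2.0) / self.bkg_half_life_h

    def bkg_conc(self, t_h: float) -> float:
        return self.bkg_conc_kBq_per_mL * np.exp(-self.bkg_lambda() * t_h)


@dataclass
class LesionTruth:
    """Ground-truth parameters of one synthetic lesion."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    volume_mL: float
    tbr: float          # lesion/background concentration ratio at the first timepoint
    A0_kBq_per_mL: float  # lesion concentration at t = 0
    lambda_eff: float   # 1/h
    voi: VOI

    def conc(self, t_h: float) -> float:
        return self.A0_kBq_per_mL * np.exp(-self.lambda_eff * t_h)


@dataclass
class GroundTruthStudy:
    """Everything the generator knows about one synthetic patient."""

    patient_id: str
    lesions: list[LesionTruth]
    injected_MBq: float
    spec: CohortSpec

    def true_image(self, t_h: float, body_occ: np.ndarray,
                   grid: Image3D) -> Image3D:
        """Paint the true activity distribution at time t (kBq/mL)."""
        vals = body_occ * self.spec.bkg_conc(t_h)
        bg = self.spec.bkg_conc(t_h)
        for les in self.lesions:
            vals = vals + les.voi.occupancy * (les.conc(t_h) - bg)
        return grid.with_values(np.maximum(vals, 0.0))


@dataclass
class PatientStudy:
    """Observed (blurred, noisy) multi-timepoint series of one patient."""

    patient_id: str
    timepoints_h: tuple[float, ...]
    images: list[Image3D]
    injected_MBq: float


def _draw_lesion_params(spec: CohortSpec, rng: np.random.Generator):
    mu_v = np.log(spec.volume_lognormal_median_mL)
    volume = float(np.clip(rng.lognormal(mu_v, spec.volume_lognormal_sigma),
                           *spec.volume_range_mL))
    # lognormal with the requested arithmetic mean
    mu_tbr = np.log(spec.tbr_mean) - spec.tbr_lognormal_sigma**2 / 2.0
    tbr = float(rng.lognormal(mu_tbr, spec.tbr_lognormal_sigma))
    mu_hl = np.log(spec.lesion_half_life_mean_h) - spec.lesion_half_life_sigma**2 / 2.0
    half_life = float(rng.lognormal(mu_hl, spec.lesion_half_life_sigma))
    lam = np.log(2.0) / half_life
    if spec.enforce_physical_decay:
        lam = max(lam, LU177_LAMBDA_PHYS)
    return volume, tbr, lam


def _place_lesions(spec: CohortSpec, radii: list[float], grid: Image3D,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Random non-overlapping lesion centres inside the body compartment."""
    cx, cy, cz = (n * s / 2.0 for n, s in zip(grid.shape, grid.spacing_mm))
    ax, ay = spec.body_semi_axes_mm
    half_len = spec.body_length_mm / 2.0
    margin = spec.placement_margin_mm
    centers: list[np.ndarray] = []
    for r in radii:
        for _ in range(spec.max_placement_retries):
            u, v = rng.uniform(-1, 1, 2)
            if u * u + v * v > 1:
                continue
            c = np.array([
                cx + u * (ax - r - margin),
                cy + v * (ay - r - margin),
                cz + rng.uniform(-(half_len - r - margin), half_len - r - margin),
            ])
            # re-check the ellipse with the shrunken semi-axes
            if ((c[0] - cx) / (ax - r - margin)) ** 2 + (
                (c[1] - cy) / (ay - r - margin)
            ) ** 2 > 1:
                continue
            if all(
                np.linalg.norm(c - c2) > r + r2 + margin
                for c2, r2 in zip(centers, radii)
            ):
                centers.append(c)
                break
        else:
            raise CohortGenerationError(
                f"could not place lesion of radius {r:.1f} mm after "
                f"{spec.max_placement_retries} retries"
            )
    return centers


def simulate_cohort(
    spec: CohortSpec,
    psf: PSFModel,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[tuple[GroundTruthStudy, PatientStudy]]:
    """Generate the cohort: ground truth plus observed multi-timepoint series.

    Every voxel of a lesion follows ``A0 exp(-lambda_eff t)`` exactly; the
    lesion concentration at the first imaging timepoint is TBR x background.
    Observed images apply the blur(+noise) forward model per timepoint.  The
    Poisson noise seed is derived per patient and timepoint from ``seed``.
    """
    grid = spec.grid()
    # body container reused across patients (same geometry)
    body_spec = PhantomSpec(
        body_semi_axes_mm=spec.body_semi_axes_mm,
        body_length_mm=spec.body_length_mm,
    )
    body_occ = body_occupancy(body_spec, grid, supersampling=2)

    master = np.random.default_rng(seed)
    out: list[tuple[GroundTruthStudy, PatientStudy]] = []
    t_ref = spec.timepoints_h[0]

    for p in range(spec.n_patients):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        n_lesions = int(rng.integers(spec.lesions_per_patient[0],
                                     spec.lesions_per_patient[1] + 1))
        params = [_draw_lesion_params(spec, rng) for _ in range(n_lesions)]
        radii = [
            (3.0 * v * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0) for v, _, _ in params
        ]
        centers = _place_lesions(spec, radii, grid, rng)

        lesions = []
        for (volume, tbr, lam), r, c in zip(params, radii, centers):
            voi = rasterize_sphere(c, r, grid, supersampling=4, label="lesion")
            conc_ref = tbr * spec.bkg_conc(t_ref)
            A0 = conc_ref * np.exp(lam * t_ref)
            lesions.append(
                LesionTruth(tuple(c), r, volume, tbr, A0, lam, voi)
            )

        injected = float(rng.normal(spec.injected_MBq_mean, spec.injected_MBq_sd))
        truth = GroundTruthStudy(f"patient{p:02d}", lesions, injected, spec)

        images = []
        for t in spec.timepoints_h:
            true_img = truth.true_image(t, body_occ, grid)
            nm = None
            if noise is not None:
                nm = NoiseModel(
                    counts_per_kBqmL_per_voxel=noise.counts_per_kBqmL_per_voxel,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    order=noise.order,
                )
            images.append(simulate_reconstruction(true_img, psf, nm))
        out.append(
            (truth, PatientStudy(truth.patient_id, spec.timepoints_h, images, injected))
        )
    return out
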