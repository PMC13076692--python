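"""Digital NEMA IEC body phantom and the image-space SPECT forward model.

The physical phantom holds six fillable spheres (inner diameters 10, 13, 17,
22, 28 and 37 mm, i.e. 0.5–26.5 mL) on a coplanar ring inside a torso-shaped
background compartment.  The digital counterpart used here simplifies the
body to an axis-aligned elliptical cylinder (no lung insert) and paints the
fill concentrations — by default the 8:1 foreground-to-background ratio,
237:30 kBq/mL — with fractional-occupancy antialiasing so that total
activity matches the analytic value.

The "reconstruction" stand-in is an image-space forward model: Gaussian blur
at the system PSF, optionally with Poisson noise drawn on a counts scale and
smoothed by the same blur (producing the correlated noise texture of
reconstructed SPECT).  Projection-space physics (attenuation, scatter,
detector response) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    EmptyVOIError,
    Image3D,
    PSFModel,
    Units,
    VOI,
    convolve,
    make_gaussian_kernel,
    rasterize_sphere,
)

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "PhantomSpecError",
    "default_grid",
    "generate_phantom",
    "body_occupancy",
    "simulate_reconstruction",
    "DEFAULT_SPHERE_DIAMETERS_MM",
]

#: NEMA IEC sphere inner diameters (mm); volumes 0.5, 1.2, 2.6, 5.6, 11.5, 26.5 mL
DEFAULT_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

#: diameter of the coplanar ring the sphere centres sit on (mm)
DEFAULT_RING_DIAMETER_MM = 114.4


class PhantomSpecError(ValueError):
    """Invalid phantom specification (overlapping spheres, sphere outside body...)."""


@dataclass
class PhantomSpec:
    """Declarative description of the digital NEMA IEC phantom.

    Defaults reproduce the standard fill: six spheres on a 114.4 mm ring in
    one axial plane, foreground 237 kBq/mL, background 30 kBq/mL (8:1).
    ``body_semi_axes_mm`` are the (x, y) semi-axes of the elliptical-cylinder
    body compartment and ``body_length_mm`` its axial (z) extent.
    """

    sphere_diameters_mm: tuple[float, ...] = DEFAULT_SPHERE_DIAMETERS_MM
    sphere_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    fg_conc_kBq_per_mL: float = 237.0
    bg_conc_kBq_per_mL: float = 30.0
    body_semi_axes_mm: tuple[float, float] = (150.0, 110.0)
    body_length_mm: float = 180.0
    ring_diameter_mm: float = DEFAULT_RING_DIAMETER_MM
    bkg_voi_radius_mm: float = 15.0
    bkg_voi_ring_radius_mm: float = 45.0
    bkg_voi_z_offset_mm: float = -55.0

    def sphere_volumes_mL(self) -> np.ndarray:
        d = np.asarray(self.sphere_diameters_mm)
        return 4.0 / 3.0 * np.pi * (d / 2.0) ** 3 / 1000.0

    def centers_for_grid(self, grid: Image3D) -> list[tuple[float, float, float]]:
        """Sphere centres in mm; default is a coplanar ring around the grid centre."""
        if self.sphere_centers_mm is not None:
            return [tuple(c) for c in self.sphere_centers_mm]
        cx, cy, cz = (n * s / 2.0 for n, s in zip(grid.shape, grid.spacing_mm))
        r = self.ring_diameter_mm / 2.0
        angles = np.deg2rad(90 + 60 * np.arange(len(self.sphere_diameters_mm)))
        return [
            (cx + r * np.cos(a), cy + r * np.sin(a), cz) for a in angles
        ]

    def validate(self, grid: Image3D) -> None:
        if self.fg_conc_kBq_per_mL < 0 or self.bg_conc_kBq_per_mL < 0:
            raise PhantomSpecError("concentrations must be non-negative")
        centers = np.asarray(self.centers_for_grid(grid))
        radii = np.asarray(self.sphere_diameters_mm) / 2.0
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
                if gap <= 0:
                    raise PhantomSpecError(
                        f"spheres {i} and {j} overlap (gap {gap:.1f} mm)"
                    )
        # spheres must lie inside the body compartment
        cx, cy, cz = (n * s / 2.0 for n, s in zip(grid.shape, grid.spacing_mm))
        ax, ay = self.body_semi_axes_mm
        for c, r in zip(centers, radii):
            u = ((c[0] - cx) / (ax - r)) ** 2 + ((c[1] - cy) / (ay - r)) ** 2
            if u > 1 or abs(c[2] - cz) + r > self.body_length_mm / 2.0:
                raise PhantomSpecError(f"sphere at {tuple(c)} r={r} exits the body")


def default_grid(
    shape: tuple[int, int, int] = (128, 128, 128),
    spacing_mm: float | tuple[float, float, float] = 4.8,
    units: str = Units.KBQ_PER_ML,
) -> Image3D:
    """Empty image on the default SPECT grid (128^3 at 4.8 mm isotropic)."""
    if np.isscalar(spacing_mm):
        spacing_mm = (spacing_mm,) * 3
    return Image3D(np.zeros(shape), spacing_mm, units)


def body_occupancy(spec: PhantomSpec, grid: Image3D, supersampling: int = 2) -> np.ndarray:
    """Fractional occupancy of the elliptical-cylinder body on the grid.

    Midpoint-sampled transverse (the ellipse cross-section), exact overlap
    along z (the cylinder is an axis-aligned slab there).
    """
    cx, cy, cz = (n * s / 2.0 for n, s in zip(grid.shape, grid.spacing_mm))
    ax, ay = spec.body_semi_axes_mm
    half_len = spec.body_length_mm / 2.0
    spacing = grid.spacing_mm
    base = [np.arange(n) * s for n, s in zip(grid.shape, spacing)]
    z0, z1 = base[2], base[2] + spacing[2]
    frac_z = np.clip(
        np.minimum(z1, cz + half_len) - np.maximum(z0, cz - half_len), 0.0, None
    ) / spacing[2]
    ellipse = np.zeros(grid.shape[:2])
    offs = (np.arange(supersampling) + 0.5) / supersampling
    for ox in offs:
        x = base[0] + ox * spacing[0]
        for oy in offs:
            y = base[1] + oy * spacing[1]
            ellipse += ((x[:, None] - cx) / ax) ** 2 + ((y[None, :] - cy) / ay) ** 2 <= 1
    ellipse /= supersampling**2
    return ellipse[:, :, None] * frac_z[None, None, :]


def generate_phantom(
    spec: PhantomSpec,
    grid: Image3D | None = None,
    supersampling: int = 4,
) -> tuple[Image3D, list[VOI], list[VOI]]:
    """Paint the digital phantom ground truth and place measurement VOIs.

    Voxel value = occ_sphere * fg + (1 - occ_sphere) * bg inside the body,
    0 outside (occupancies are fractional, so total activity matches the
    analytic body-plus-spheres value to < 0.5 %).  Returns the truth image,
    one known-volume sphere VOI per insert (labelled by nominal volume), and
    four spherical background VOIs on a ring offset axially from the sphere
    plane, clear of every insert.

    Deterministic given spec + grid.
    """
    if grid is None:
        grid = default_grid()
    spec.validate(grid)

    body = body_occupancy(spec, grid, supersampling=max(2, supersampling // 2))
    values = body * spec.bg_conc_kBq_per_mL

    centers = spec.centers_for_grid(grid)
    volumes = spec.sphere_volumes_mL()
    sphere_vois: list[VOI] = []
    for c, d, v in zip(centers, spec.sphere_diameters_mm, volumes):
        voi = rasterize_sphere(c, d / 2.0, grid, supersampling=supersampling,
                               label=f"{v:.1f}mL")
        values += voi.occupancy * (spec.fg_conc_kBq_per_mL - spec.bg_conc_kBq_per_mL)
        sphere_vois.append(voi)

    cx, cy, cz = (n * s / 2.0 for n, s in zip(grid.shape, grid.spacing_mm))
    bkg_vois: list[VOI] = []
    rb = spec.bkg_voi_ring_radius_mm
    for i, a in enumerate(np.deg2rad([45, 135, 225, 315])):
        bkg_vois.append(
            rasterize_sphere(
                (cx + rb * np.cos(a), cy + rb * np.sin(a), cz + spec.bkg_voi_z_offset_mm),
                spec.bkg_voi_radius_mm, grid, supersampling=2, label=f"bkg{i}",
            )
        )

    truth = grid.with_values(values, units=Units.KBQ_PER_ML)
    return truth, sphere_vois, bkg_vois


@dataclass
class NoiseModel:
    """Poisson noise stand-in for acquisition/reconstruction noise.

    ``counts_per_kBqmL_per_voxel`` converts concentration to expected counts
    per voxel; counts are drawn Poisson and converted back.  The default
    order ``poisson-then-blur`` draws counts on the unblurred grid and lets
    the PSF smooth them, giving the spatially correlated noise texture of
    reconstructed SPECT.  A fixed seed gives bit-identical output.
    """

    counts_per_kBqmL_per_voxel: float = 0.002
    seed: int = 0
    order: str = "poisson-then-blur"

    def __post_init__(self) -> None:
        if self.counts_per_kBqmL_per_voxel <= 0:
            raise ValueError("calibration must be > 0")
        if self.order not in ("poisson-then-blur", "blur-then-poisson"):
            raise ValueError(f"unknown noise order {self.order!r}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        c = self.counts_per_kBqmL_per_voxel
        return rng.poisson(np.maximum(values, 0.0) * c).astype(float) / c


def simulate_reconstruction(
    truth: Image3D,
    psf: PSFModel,
    noise: NoiseModel | None = None,
) -> Image3D:
    """Image-space forward model: Gaussian blur at the system PSF + noise.

    With ``noise=None`` and ``sigma=0`` the output is identical to the
    truth.  Units (kBq/mL) are preserved; the Poisson draw is unbiased, so
    VOI means agree with the noiseless image in expectation.
    """
    kernel = make_gaussian_kernel(psf, truth.spacing_mm)
    if noise is None:
        return convolve(truth, kernel)
    if noise.order == "poisson-then-blur":
        noisy = truth.with_values(noise.apply(truth.values))
        return convolve(noisy, kernel)
    blurred = convolve(truth, kernel)
    return blurred.with_values(noise.apply(blurred.values))
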