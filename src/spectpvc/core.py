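"""Volumetric data model, Gaussian PSF construction and convolution primitives.

Conventions used throughout the package:

* A volume lives on a regular 3D lattice with per-axis voxel edge length
  ``spacing_mm``; the centre of voxel ``(i, j, k)`` sits at the continuous
  coordinate ``((i + 0.5) s_x, (j + 0.5) s_y, (k + 0.5) s_z)`` mm.  All
  regions of interest are specified in mm, never in indices, so phantom and
  cohort specs are independent of the sampling grid.
* Convolution uses zero padding outside the grid.  Objects of interest are
  kept at least the kernel truncation radius away from the boundary, so the
  padding choice is immaterial for every measurement made here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "Units",
    "Image3D",
    "PSFModel",
    "VOI",
    "GeometryError",
    "EmptyVOIError",
    "sigma_to_fwhm",
    "fwhm_to_sigma",
    "make_gaussian_kernel",
    "convolve",
    "rasterize_sphere",
    "mean_in_voi",
    "sd_in_voi",
]

#: full width at half maximum of a unit-sigma Gaussian
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class Units:
    """Enumerated unit tags for :class:`Image3D`."""

    KBQ_PER_ML = "kBq/mL"
    COUNTS = "counts"
    BQ_H_PER_VOXEL = "Bq·h_per_voxel"
    GY = "Gy"
    DIMENSIONLESS = "dimensionless"

    ALL = (KBQ_PER_ML, COUNTS, BQ_H_PER_VOXEL, GY, DIMENSIONLESS)


class GeometryError(ValueError):
    """Invalid grid geometry (non-positive spacing, mismatched lattices...)."""


class EmptyVOIError(ValueError):
    """A VOI holds no voxels of the reference grid."""


@dataclass
class Image3D:
    """A 3D scalar volume with voxel spacing in mm and a units tag.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; finite.  Activity-concentration and dose images must
        be non-negative.
    spacing_mm : sequence of 3 floats
        Per-axis voxel edge length in mm, all strictly positive.
    units : str
        One of the tags in :class:`Units`.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str = Units.DIMENSIONLESS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(f"expected 3D values, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        if units := self.units:
            if units not in Units.ALL:
                raise ValueError(f"unknown units tag {units!r}; expected one of {Units.ALL}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.units in (Units.KBQ_PER_ML, Units.GY) and np.any(self.values < 0):
            raise ValueError(f"{self.units} images must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mL(self) -> float:
        """Voxel volume in mL (product of mm spacings / 1000, exact)."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Image3D":
        """New image on the same grid with different values (and optionally units)."""
        return Image3D(values, self.spacing_mm, self.units if units is None else units)

    def same_grid(self, other: "Image3D") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, rtol=0, atol=1e-9
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D arrays of voxel-centre coordinates (mm) along each axis."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.spacing_mm)
        )

    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class PSFModel:
    """Isotropic 3D Gaussian point-spread function.

    ``sigma_mm`` is the Gaussian standard deviation in mm; the discretized
    kernel support extends ``truncation_sigmas`` standard deviations from the
    centre in each axis (at least 3; default 4, losing < 1e-4 of the mass
    before renormalization).
    """

    sigma_mm: float
    truncation_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_mm < 0:
            raise ValueError(f"sigma_mm must be >= 0, got {self.sigma_mm}")
        if self.truncation_sigmas < 3:
            raise ValueError(f"truncation_sigmas must be >= 3, got {self.truncation_sigmas}")

    @property
    def fwhm_mm(self) -> float:
        return sigma_to_fwhm(self.sigma_mm)


@dataclass
class VOI:
    """A volume of interest on a reference grid.

    Carries a hard boolean ``mask`` (used for measurements) and, for sphere
    VOIs, a fractional-occupancy lattice ``occupancy`` (used for painting
    ground truth).  ``center_mm``/``radius_mm`` are set for spheres.
    """

    label: str
    mask: np.ndarray
    kind: str = "explicit-mask"
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mL(self, reference: Image3D) -> float:
        """Hard-mask volume (voxel count x voxel volume)."""
        return self.n_voxels * reference.voxel_volume_mL

    def fractional_volume_mL(self, reference: Image3D) -> float:
        """Volume from the fractional-occupancy lattice (spheres only)."""
        if self.occupancy is None:
            return self.volume_mL(reference)
        return float(self.occupancy.sum()) * reference.voxel_volume_mL


# ---------------------------------------------------------------------------
# sigma <-> FWHM

def sigma_to_fwhm(sigma_mm: float) -> float:
    """FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian (14.13 mm for sigma 6.0 mm)."""
    if sigma_mm < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma_mm}")
    return FWHM_PER_SIGMA * sigma_mm


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Inverse of :func:`sigma_to_fwhm`."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    return fwhm_mm / FWHM_PER_SIGMA


# ---------------------------------------------------------------------------
# Gaussian kernel and convolution

def make_gaussian_kernel(
    psf: PSFModel, spacing_mm: Sequence[float]
) -> np.ndarray:
    """Discretize an isotropic Gaussian PSF on a voxel lattice.

    The kernel is the separable product of 1D Gaussians sampled at voxel
    centres, truncated at ``psf.truncation_sigmas`` standard deviations
    (odd support per axis) and renormalized to sum exactly 1.  ``sigma_mm
    = 0`` yields the single-voxel identity kernel.
    """
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GeometryError(f"spacing must be 3 positive floats, got {spacing}")
    if psf.sigma_mm == 0:
        return np.ones((1, 1, 1))
    axes = []
    for s in spacing:
        half = int(np.ceil(psf.truncation_sigmas * psf.sigma_mm / s))
        x = np.arange(-half, half + 1) * s
        axes.append(np.exp(-0.5 * (x / psf.sigma_mm) ** 2))
    kernel = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return kernel / kernel.sum()


def convolve(img: Image3D, kernel: np.ndarray) -> Image3D:
    """Linear convolution with zero padding, cropped to the input grid.

    For a normalized kernel and an object at least the kernel half-width
    away from the boundary the total sum is conserved to ~1e-12 relative.
    Units are unchanged.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 3:
        raise GeometryError("kernel must be 3D")
    if any(ks > ns for ks, ns in zip(kernel.shape, img.shape)):
        raise GeometryError(
            f"kernel shape {kernel.shape} exceeds image shape {img.shape}"
        )
    out = fftconvolve(img.values, kernel, mode="same")
    # FFT round-off can push exact zeros slightly negative
    if np.all(kernel >= 0) and np.all(img.values >= 0):
        np.maximum(out, 0.0, out=out)
    return img.with_values(out)


# ---------------------------------------------------------------------------
# Sphere rasterization and VOI statistics

def rasterize_sphere(
    center_mm: Sequence[float],
    radius_mm: float,
    reference: Image3D,
    supersampling: int = 4,
    label: str = "sphere",
) -> VOI:
    """Rasterize a sphere onto the reference grid.

    Returns a :class:`VOI` carrying both a hard boolean mask (voxel centres
    inside the sphere — used for measurements) and a fractional-occupancy
    lattice computed by subdividing each voxel ``supersampling`` times per
    axis (used for ground-truth painting).  At ``supersampling=4`` the
    fractional volume matches the analytic sphere volume to < 0.5 %.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be > 0, got {radius_mm}")
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    center = np.asarray(center_mm, dtype=float)
    spacing = np.asarray(reference.spacing_mm)
    shape = np.asarray(reference.shape)

    lo_idx = np.maximum(np.floor((center - radius_mm) / spacing - 1).astype(int), 0)
    hi_idx = np.minimum(np.ceil((center + radius_mm) / spacing + 1).astype(int), shape)
    if np.any(lo_idx >= hi_idx):
        raise EmptyVOIError(f"sphere at {center_mm} r={radius_mm} lies outside the grid")

    occ = _fractional_occupancy_sphere(center, radius_mm, spacing, lo_idx, hi_idx,
                                       supersampling)
    occupancy = np.zeros(reference.shape)
    sl = tuple(slice(lo, hi) for lo, hi in zip(lo_idx, hi_idx))
    occupancy[sl] = occ

    centers = [
        (np.arange(lo, hi) + 0.5) * s for lo, hi, s in zip(lo_idx, hi_idx, spacing)
    ]
    d2 = (
        (centers[0][:, None, None] - center[0]) ** 2
        + (centers[1][None, :, None] - center[1]) ** 2
        + (centers[2][None, None, :] - center[2]) ** 2
    )
    mask = np.zeros(reference.shape, dtype=bool)
    mask[sl] = d2 <= radius_mm**2

    if occupancy.sum() == 0:
        raise EmptyVOIError(f"sphere at {center_mm} r={radius_mm} covers no voxels")
    return VOI(label=label, mask=mask, kind="sphere",
               center_mm=tuple(center), radius_mm=float(radius_mm),
               occupancy=occupancy)


def _fractional_occupancy_sphere(center, radius, spacing, lo_idx, hi_idx, ss):
    """Sub-voxel occupancy of a sphere within an index box.

    Midpoint sampling transverse (x, y) with an exact chord-overlap integral
    along z.  The transverse subcell is refined to at most ``radius/(2 ss)``
    so that the volume error at ``ss = 4`` stays below 0.5 % even for
    spheres comparable to the voxel size.
    """
    # transverse subdivisions per axis; floor keeps subcell <= r/(2 ss)
    n_t = [
        max(ss, int(np.ceil(2.0 * ss * s / radius))) for s in spacing[:2]
    ]
    base = [np.arange(lo, hi) * s for lo, hi, s in zip(lo_idx, hi_idx, spacing)]
    z0 = base[2]
    z1 = base[2] + spacing[2]
    occ = np.zeros(tuple(hi_idx - lo_idx))
    r2 = radius * radius
    offs_x = (np.arange(n_t[0]) + 0.5) / n_t[0] * spacing[0]
    offs_y = (np.arange(n_t[1]) + 0.5) / n_t[1] * spacing[1]
    for ox in offs_x:
        dx2 = (base[0] + ox - center[0]) ** 2
        for oy in offs_y:
            dy2 = (base[1] + oy - center[1]) ** 2
            s2 = r2 - (dx2[:, None] + dy2[None, :])
            half_chord = np.sqrt(np.maximum(s2, 0.0))
            lo = center[2] - half_chord
            hi = center[2] + half_chord
            overlap = np.clip(
                np.minimum(hi[:, :, None], z1[None, None, :])
                - np.maximum(lo[:, :, None], z0[None, None, :]),
                0.0,
                None,
            )
            occ += overlap / spacing[2]
    return occ / (n_t[0] * n_t[1])


def mean_in_voi(img: Image3D, voi: VOI) -> float:
    """Arithmetic mean of the image over the VOI's hard mask."""
    _check_voi(img, voi)
    return float(img.values[voi.mask].mean())


def sd_in_voi(img: Image3D, voi: VOI) -> float:
    """Population standard deviation of the image over the VOI's hard mask."""
    _check_voi(img, voi)
    return float(img.values[voi.mask].std(ddof=0))


def _check_voi(img: Image3D, voi: VOI) -> None:
    if voi.mask.shape != img.shape:
        raise GeometryError(
            f"VOI mask shape {voi.mask.shape} does not match image {img.shape}"
        )
    if not voi.mask.any():
        raise EmptyVOIError(f"VOI {voi.label!r} is empty")
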