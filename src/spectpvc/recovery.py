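"""Recovery coefficients, sphere SNR and the volume-dependent RC model.

The recovery coefficient of a known-volume sphere is the measured mean
activity concentration divided by the true fill concentration.  Its volume
dependence is modelled by

    f_RC(V) = 1 - (1 + (V / b)^y)^(-1)

with volume-scale parameter ``b`` (mL; f_RC(b) = 0.5 for any y) and shape
exponent ``y``.  For b, y > 0 the curve rises strictly monotonically from 0
to 1, approaching full recovery only slowly at large volumes.  The inverse,
1 / f_RC(V), is the volume-derived correction factor applied to uncorrected
doses (the "OR + RC" branch).

The sphere SNR uses background-subtracted signal over the pooled background
standard deviation, measured in four background VOIs; the alternative
definition mean/SD is available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import EmptyVOIError, Image3D, VOI, mean_in_voi

__all__ = [
    "RCCurve",
    "RCFitError",
    "f_rc",
    "compute_rc",
    "compute_snr",
    "rc_table",
    "fit_rc_curve",
    "rc_correction_factor",
]


class RCFitError(RuntimeError):
    """RC-curve fit failed to converge."""


def f_rc(volume_mL, b: float, y: float):
    """Volume-dependent recovery model f_RC(V) = 1 - (1 + (V/b)^y)^-1."""
    v = np.asarray(volume_mL, dtype=float)
    return 1.0 - 1.0 / (1.0 + (v / b) ** y)


@dataclass
class RCCurve:
    """Fitted f_RC parameters with diagnostics."""

    b: float
    y: float
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    covariance: np.ndarray | None = None

    def __call__(self, volume_mL):
        return f_rc(volume_mL, self.b, self.y)


def compute_rc(
    img: Image3D, sphere_vois: list[VOI], true_fg_conc: float
) -> pd.DataFrame:
    """Per-sphere recovery coefficients.

    RC_s = mean_in_voi(img, s) / true_fg_conc, using the known-volume sphere
    VOIs placed from ground-truth geometry (never re-segmented).
    """
    if true_fg_conc <= 0:
        raise ValueError("true_fg_conc must be > 0")
    rows = []
    for voi in sphere_vois:
        if not voi.mask.any():
            raise EmptyVOIError(f"sphere VOI {voi.label!r} is empty")
        mean = mean_in_voi(img, voi)
        rows.append(
            {
                "label": voi.label,
                "volume_mL": voi.fractional_volume_mL(img),
                "mean_conc": mean,
                "rc": mean / true_fg_conc,
            }
        )
    return pd.DataFrame(rows)


def _pooled_background(img: Image3D, background_vois: list[VOI]) -> tuple[float, float]:
    if len(background_vois) < 2:
        raise ValueError("need at least 2 background VOIs")
    vals = np.concatenate([img.values[v.mask] for v in background_vois])
    if vals.size == 0:
        raise EmptyVOIError("background VOIs are empty")
    return float(vals.mean()), float(vals.std(ddof=0))


def compute_snr(
    img: Image3D,
    sphere_voi: VOI,
    background_vois: list[VOI],
    background_subtracted: bool = True,
) -> float:
    """Sphere signal-to-noise ratio.

    SNR = (mean_sphere - mean_bkg) / SD_bkg with the background mean and
    voxelwise SD pooled over all background VOIs.  Set
    ``background_subtracted=False`` for the mean_sphere / SD_bkg variant.
    """
    mean_b, sd_b = _pooled_background(img, background_vois)
    if sd_b == 0:
        raise ZeroDivisionError("background SD is zero; SNR undefined")
    mean_s = mean_in_voi(img, sphere_voi)
    return (mean_s - mean_b) / sd_b if background_subtracted else mean_s / sd_b


def rc_table(
    img: Image3D,
    sphere_vois: list[VOI],
    background_vois: list[VOI],
    true_fg_conc: float,
    background_subtracted: bool = True,
) -> pd.DataFrame:
    """Combined per-sphere RC and SNR table plus pooled background stats."""
    tab = compute_rc(img, sphere_vois, true_fg_conc)
    mean_b, sd_b = _pooled_background(img, background_vois)
    if sd_b == 0:
        raise ZeroDivisionError("background SD is zero; SNR undefined")
    if background_subtracted:
        tab["snr"] = (tab["mean_conc"] - mean_b) / sd_b
    else:
        tab["snr"] = tab["mean_conc"] / sd_b
    tab["bkg_mean"] = mean_b
    tab["bkg_sd"] = sd_b
    return tab


def fit_rc_curve(volumes_mL, rcs) -> RCCurve:
    """Least-squares fit of f_RC with positivity bounds on (b, y).

    Deterministic given the inputs: initialization is b = median volume,
    y = 1.  Requires at least 3 points, positive volumes and RCs in (0, 1.2].
    """
    v = np.asarray(volumes_mL, dtype=float)
    r = np.asarray(rcs, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 (volume, RC) points")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    if np.any(r <= 0) or np.any(r > 1.2):
        raise ValueError("RCs must lie in (0, 1.2]")
    p0 = (float(np.median(v)), 1.0)
    try:
        popt, pcov = curve_fit(
            f_rc, v, r, p0=p0, bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RCFitError(f"RC-curve fit did not converge: {exc}") from exc
    curve = RCCurve(b=float(popt[0]), y=float(popt[1]), covariance=pcov)
    curve.residuals = r - curve(v)
    return curve


def rc_correction_factor(curve: RCCurve, volume_mL: float) -> float:
    """Volume-derived correction factor 1 / f_RC(V); monotone decreasing in V."""
    if volume_mL <= 0:
        raise ValueError("volume must be > 0")
    f = float(curve(volume_mL))
    if f <= 0:
        raise ZeroDivisionError(f"f_RC({volume_mL}) <= 0; correction undefined")
    return 1.0 / f
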