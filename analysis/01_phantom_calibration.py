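#!/usr/bin/env python
"""Phantom calibration study: estimate the system PSF and pick the
deconvolution iteration count.

Steps (all on the digital NEMA IEC phantom, 237:30 kBq/mL, 4.8 mm grid):

1. simulate the "reconstructed" phantom (Gaussian blur sigma 6.0 mm +
   Poisson noise),
2. matched-filter resolution analysis over sigma 0-48 mm in 0.48 mm steps
   (RMSE on the four visible spheres),
3. Richardson-Lucy iteration sweep (1-6 iterations) tabulating per-sphere
   recovery coefficients and SNRs,
4. fit the volume-dependent recovery model f_RC(V) to the uncorrected RCs.

Writes results/phantom/{rmse_curve.csv, mfa.json, rc_table.csv, curve.json}
and a figure of the RMSE curve.

Run:  python analysis/01_phantom_calibration.py [--seed 0]
"""

import argparse
import json
import logging
from pathlib import Path

import pandas as pd

from spectpvc.pipeline import PipelineConfig, run_phantom_study

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results/phantom"))
    args = parser.parse_args()

    config = PipelineConfig(seed=args.seed)
    out = run_phantom_study(config, args.outdir)

    mfa = out["mfa_summary"]
    print(
        f"\nMatched-filter analysis: best sigma {mfa['best_sigma_mm']:.2f} mm "
        f"(FWHM {mfa['best_fwhm_mm']:.1f} mm), parabolic refinement "
        f"{mfa['refined_sigma_mm']:.2f} mm"
    )
    print("\nPer-iteration recovery coefficients and SNRs "
          "(iteration 0 = uncorrected reconstruction):")
    print(out["sweep"].round(2).to_string(index=False))
    curve = out["curve"]
    print(f"\nRecovery model fit: f_RC(V) = 1 - (1+(V/b)^y)^-1 with "
          f"b = {curve.b:.2f} mL, y = {curve.y:.2f} "
          f"(half recovery at {curve.b:.1f} mL)")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rmse = pd.read_csv(args.outdir / "rmse_curve.csv")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(rmse["sigma_mm"], rmse["rmse"])
        ax.axvline(mfa["best_sigma_mm"], ls="--", c="k", lw=0.8)
        ax.set_xlabel("sigma (mm)")
        ax.set_ylabel("RMSE (kBq/mL)")
        ax.set_title("Matched-filter resolution analysis")
        fig.tight_layout()
        fig.savefig(args.outdir / "rmse_curve.png", dpi=120)
        print(f"\nwrote {args.outdir}/rmse_curve.png")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
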