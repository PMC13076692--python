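#!/usr/bin/env python
"""Cohort dosimetry study: effect of deconvolution and recovery correction
on lesion absorbed dose.

Simulates the default synthetic cohort (10 patients, 1-8 spherical lesions
each, mean tumor-to-background ratio 9.2, imaging at 24/48/72 h) and runs
voxel dosimetry three ways per lesion: uncorrected reconstruction (OR),
after Richardson-Lucy deconvolution (OR+LRD, sigma 6.0 mm, 4 iterations),
and OR scaled by the phantom-derived volume correction 1/f_RC(V) (OR+RC).

Requires the recovery curve from analysis/01_phantom_calibration.py
(results/phantom/curve.json); recomputes it if missing.

Writes results/cohort/{lesion_doses.csv, summary.csv}.

Run:  python analysis/02_cohort_dosimetry.py [--seed 0]
"""

import argparse
import json
import logging
from pathlib import Path

from spectpvc.pipeline import PipelineConfig, run_cohort_study
from spectpvc.recovery import RCCurve

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--curve", type=Path, default=Path("results/phantom/curve.json"))
    parser.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    curve = None
    if args.curve.exists():
        params = json.loads(args.curve.read_text())
        curve = RCCurve(b=params["b"], y=params["y"])
        print(f"using recovery curve b = {curve.b:.2f} mL, y = {curve.y:.2f}")
    else:
        print(f"{args.curve} not found; rerunning the phantom calibration")

    config = PipelineConfig(seed=args.seed)
    out = run_cohort_study(config, args.outdir, curve=curve)

    report = out["report"]
    print(f"\n{len(report)} measurable lesions across "
          f"{report['patient_id'].nunique()} patients")
    print(report.round(2).to_string(index=False))

    n_up = int((report["pct_lrd"] > 0).sum())
    print(f"\nDeconvolution raised the lesion dose in {n_up}/{len(report)} lesions.")
    print("\nMean ± SD absolute percent dose difference vs the uncorrected "
          "reconstruction:")
    print(out["summary"].round(1).to_string(index=False))


if __name__ == "__main__":
    main()
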