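#!/usr/bin/env python
"""Assemble the dissociation curve and interpolate % ssDNA at 1.1 mm.

Joins widths (02) with % ssDNA (03) on droplet index, restricts to the
620-1200 µm region of interest, fits the linear dissociation trend and
evaluates it at the 1.1 mm reference width.  Writes
results/04_curve.csv and results/04_roi_fit.json.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from lilbid.curves import assemble_curve, filter_roi, fit_and_interpolate
from lilbid.imaging import WidthMeasurement
from lilbid.synthetic import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
widths_df = pd.read_csv(ROOT / "results" / "02_widths.csv")
pct_df = pd.read_csv(ROOT / "results" / "03_pct_ss.csv")

widths = [
    WidthMeasurement(int(r.droplet_index), r.width_um, r.width_err_um, r.threshold, r.top_fraction)
    for r in widths_df.itertuples()
]
points = assemble_curve(widths, list(zip(pct_df["droplet_index"], pct_df["pct_ss"])))
points.to_csv(ROOT / "results" / "04_curve.csv", index=False)

roi_points = filter_roi(points)
fit = fit_and_interpolate(roi_points)
with open(ROOT / "results" / "04_roi_fit.json", "w") as fh:
    json.dump(dataclasses.asdict(fit), fh, indent=2, default=str)

truth = SyntheticConfig().truth_pct_ss(1100.0)
print(f"{len(points)} droplets assembled, {fit.n_points} in ROI {fit.roi}")
print(f"%ssDNA at 1.1 mm = {fit.pct_ss_at_ref:.2f} ± {fit.pct_ss_se:.2f} "
      f"(truth {truth:.1f}; slope {fit.slope:.4f} %/µm)")
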