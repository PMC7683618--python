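#!/usr/bin/env python
"""Fit the York calibration models and predict the held-out affinities.

Uses the packaged reference table: nine model duplexes for the T_m line,
the seven of those with ITC values for the log K_d line (errors in both
axes, s.d. = s.e.m.*sqrt(n)).  Evaluates both models at the three
held-out samples' % ssDNA means and benchmarks against the UV/ITC
cross-model.  Writes results/05_models.json and
results/05_predictions.csv.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from lilbid.datasets import affinity_reference, kd_training_data, tm_training_data
from lilbid.models import (
    build_model,
    confidence_band,
    cross_model,
    log10_kd_molar,
    predict,
    sd_from_sem,
)

ROOT = Path(__file__).resolve().parents[1]
warnings.simplefilter("ignore", UserWarning)  # held-out x values extrapolate slightly

tm_model = build_model(tm_training_data(), "tm")
kd_model = build_model(kd_training_data(), "log_kd")

artifacts = {}
for name, model in (("tm", tm_model), ("log_kd", kd_model)):
    f = model.fit
    band_lo, band_hi = confidence_band(f, np.array([f.x_weighted_mean]))
    artifacts[name] = {
        "slope": f.slope, "slope_se": f.slope_se,
        "intercept": f.intercept, "intercept_se": f.intercept_se,
        "n": f.n, "iterations": f.iterations, "chi2_reduced": f.chi2_reduced,
        "band_halfwidth_at_centroid": float((band_hi[0] - band_lo[0]) / 2),
        "training_samples": list(model.training_samples),
    }
    print(f"{name} model (n={f.n}): slope {f.slope:.4f} ± {f.slope_se:.4f}, "
          f"intercept {f.intercept:.2f} ± {f.intercept_se:.2f}")

# cross-model benchmark: predict log K_d directly from UV T_m
ref = affinity_reference()
paired = ref[(ref["role"] == "model") & ref["itc_kd_nm"].notna()]
tm_data, kd_data = [], []
for s, r in paired.iterrows():
    tm_data.append((s, r["uv_tm_c"], sd_from_sem(r["uv_tm_sem_c"], int(r["n_uv"]))))
    y, sy = log10_kd_molar(r["itc_kd_nm"], sd_from_sem(r["itc_kd_sem_nm"], int(r["n_itc"])))
    kd_data.append((s, y, sy))
uv_model = cross_model(tm_data, kd_data, "kd_from_tm")

rows = []
for sample, r in ref[ref["role"] == "test"].iterrows():
    pct = r["pct_ss_1p1mm"]
    rows.append({
        "sample": sample,
        "uv_tm_measured_c": r["uv_tm_c"],
        "tm_predicted_from_lilbid_c": predict(tm_model, pct),
        "log_kd_measured": log10_kd_molar(r["itc_kd_nm"]),
        "log_kd_predicted_from_lilbid": predict(kd_model, pct),
        "log_kd_predicted_from_uv": predict(uv_model, r["uv_tm_c"]),
    })
pred = pd.DataFrame(rows).set_index("sample")
pred.to_csv(ROOT / "results" / "05_predictions.csv", float_format="%.3f")
with open(ROOT / "results" / "05_models.json", "w") as fh:
    json.dump(artifacts, fh, indent=2)

print("\nheld-out predictions:")
print(pred.round(2).to_string())
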