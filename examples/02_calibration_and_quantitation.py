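"""Simulate a calibration sequence, fit 1/x-weighted curves, and quantify.

Generates the 19-level standard series (run at sequence start and end) for a
small synthetic panel, fits weighted calibration curves with LOD and linear
range per entity, and back-calculates a simulated study cohort against the
curves. The printed report mirrors a method-validation table: R² of the
weighted fit on the selected linear range, LLOQ–ULOQ, and the S/N-based LOD.
"""

import numpy as np

import srmquant as sq
from srmquant.simulate import CohortEffectSpec, ResponseModel

panel = sq.synthetic_panel(5)
model = ResponseModel(proportional_cv=0.05, baseline_noise_sd=200.0)

cal_peaks, _ = sq.simulate_calibration_series(panel, models=model, seed=42)
curves = sq.calibrate_panel(cal_peaks, panel)
print(sq.calibration_report(curves)[
    ["entity", "r_squared", "linear_range", "lod_ng_per_ml"]
].to_string(index=False))

spec = CohortEffectSpec(n_per_group=10, replicate_cv=0.05)
clinical, truth, study_peaks = sq.simulate_cohort(panel, spec, seed=42, models=model)
conc = sq.quantify_study(study_peaks, panel, curves)

merged = conc.merge(truth.concentrations, on=["sample_id", "entity"])
ok = merged[merged["flag"] == "ok"]
rel_err = np.abs(ok["concentration"] / ok["true_concentration"] - 1)
print(f"\nquantified {len(ok)} in-range replicate injections; "
      f"median |error| vs ground truth = {100 * rel_err.median():.1f}% "
      f"(proportional noise was 5%)")
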