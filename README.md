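# srmquant

Targeted SRM/MRM metabolite-panel quantitation and cohort association, as a
tested, reusable Python pipeline.

Clinical metabolomics labs quantify small panels of plasma metabolites
(amino acids, bile acids, small organic acids) by UHPLC-MS/MS in selected
reaction monitoring mode, then relate the measured concentrations to patient
phenotypes — for example, stratifying diabetes patients by kidney
complications (albuminuria). Between the instrument's picked peak areas and
a clinical conclusion sits a chain of well-defined computations, and that
chain is what this package implements:

1. **Panel registry** — analytes, quantifier/qualifier SRM transitions,
   internal-standard (ISTD) pairing, and co-quantified isomer groups. Ships
   with a builtin 34-analyte / 33-ISTD diabetes biomarker panel that
   resolves to 30 quantification entities (four unresolved isomer pairs are
   quantified together; three analytes are quantified without ISTD
   normalization).
2. **ISTD normalization** — response = analyte area / ISTD area per
   injection, cancelling matrix and instrument drift.
3. **Weighted calibration** — per entity, weighted least squares of response
   on nominal concentration with weights *w* = 1/*x*, solved exactly from
   the 2-parameter normal equations:

       slope = (S₀·Sxy − Sx·Sy) / (S₀·Sxx − Sx²),   S₀ = Σw, Sx = Σwx, …

   with at least five levels (a 19-level series from 2.5 to 75,000
   ng mL⁻¹ run at sequence start and end, pooled). LOD is the lowest level
   reaching median S/N ≥ 3; the linear range (LLOQ–ULOQ) is the largest
   contiguous level run in which every level back-calculates within the
   80–120% accuracy band; R² is reported on the selected run.
4. **Method validation** — intra-day (4 consecutive runs) and inter-day
   (3 runs × 5 days, pooled) %RSD = 100·sd/mean of retention times and
   normalized responses at QC levels 100 / 1,000 / 10,000 ng mL⁻¹.
5. **Balanced cohort selection** — a minimax random search: draw many
   stratified k+k subsamples, score each by the highest |Pearson r| between
   any clinical covariate and the group indicator, keep the least-confounded
   draw.
6. **Association** — metabolites detected in >70% of samples are modeled
   one at a time: log₁₀ concentration ~ clinical fixed effects (albuminuria
   group, age, BMI, eGFR, HbA1c, sex, systolic blood pressure, total
   cholesterol, total triglycerides) with a random intercept per participant
   over the triplicate injections (REML). Benjamini–Hochberg correction is
   applied per term across metabolites; significant coefficients become a
   bipartite clinical-variable ↔ metabolite edge list.

Because real instrument runs are not reproducible at a desk, the package
includes a first-class synthetic-data generator
(`srmquant.simulate`) with proportional-plus-additive area noise, ISTD
variability, per-day response shifts, planted cohort effects, and full
ground truth — every stage is tested against what the generator planted.

## Worked example

```python
import srmquant as sq
from srmquant.simulate import CohortEffectSpec, ResponseModel

panel = sq.synthetic_panel(5)
model = ResponseModel(proportional_cv=0.05, baseline_noise_sd=200.0)

cal_peaks, _ = sq.simulate_calibration_series(panel, models=model, seed=42)
curves = sq.calibrate_panel(cal_peaks, panel)
print(sq.calibration_report(curves)[["entity", "r_squared", "linear_range",
                                     "lod_ng_per_ml"]])
```

prints

```
entity  r_squared linear_range lod_ng_per_ml
   M01   0.996145    7.5–75000           7.5
   M02   0.997893      5–75000           7.5
   M03   0.998131    7.5–75000           7.5
   M04   0.998896      5–75000           7.5
   M05   0.998786    7.5–75000           7.5
```

— one weighted calibration per entity: R² of the fit on the retained levels,
the validated linear range (LLOQ–ULOQ, ng mL⁻¹), and the S/N-based detection
limit. Quantifying a simulated cohort against these curves and comparing to
the generator's ground truth gives a median back-calculation error of ~4.5%
under 5% proportional noise (see `examples/02_calibration_and_quantitation.py`).

The `examples/` directory holds one short narrative script per capability:
panel registry, calibration + quantitation, repeatability validation,
balanced cohort selection, and the association network. Each builds its own
small input, runs the method, and prints what the numbers mean.

A thin CLI wraps the same library functions:

```bash
srmquant --seed 1 --out-dir out run-all          # full synthetic pipeline
srmquant quantify --peaks cal.csv --study-peaks study.csv
srmquant select-cohort --clinical clinical.csv --k 25 --draws 1000000
```

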