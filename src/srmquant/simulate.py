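"""Ground-truthed synthetic SRM data generator.

Emulates the inputs of a targeted UHPLC-MS/MS panel study so that every
downstream stage (normalization, calibration, validation, cohort selection,
association) can be exercised against a known truth:

* **Calibration series** at 19 standard levels spanning 2.5–75,000 ng mL^-1,
  run once at sequence start and once at sequence end, plus blank injections.
* **QC replicates** at 100 / 1,000 / 10,000 ng mL^-1: an intra-day block of
  four consecutive runs and an inter-day block of three runs on five days,
  with a per-day multiplicative shift so inter-day dispersion exceeds
  intra-day dispersion.
* **A cohort** of two participant groups with clinical covariates, planted
  (log10-scale) group and covariate effects on metabolite concentration, and
  three technical replicate injections per sample.

The noise model on peak areas is proportional-plus-additive Gaussian,

    area = rf * c * (1 + e_prop) + e_base,
    e_prop ~ N(0, proportional_cv^2),  e_base ~ N(0, baseline_noise_sd^2),

the simplest model that yields both the heteroscedasticity motivating
1/x-weighted calibration and finite signal-to-noise driven detection limits;
S/N is reported as area / baseline_noise_sd. ISTD channels are generated at
the panel's ISTD MIX concentration with their own CV.

All randomness flows from a single integer seed. Each generator derives an
independent stream as ``default_rng([seed, tag])`` with tags 0 (calibration),
1 (QC), 2 (cohort), so the three data sets are mutually independent yet fully
reproducible from one seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AnalytePanel, AnalyteDef, IstdDef, QuantEntity, Transition

__all__ = [
    "DEFAULT_LEVELS",
    "DEFAULT_QC_LEVELS",
    "PEAK_COLUMNS",
    "ResponseModel",
    "CohortEffectSpec",
    "GroundTruth",
    "default_response_models",
    "synthetic_panel",
    "simulate_calibration_series",
    "simulate_qc_replicates",
    "simulate_cohort",
]

#: the 19 standard concentration levels of the calibration series (ng mL^-1)
DEFAULT_LEVELS: tuple[float, ...] = (
    2.5, 5.0, 7.5, 10.0, 25.0, 50.0, 75.0, 100.0, 250.0, 500.0, 750.0,
    1000.0, 2500.0, 5000.0, 7500.0, 10_000.0, 25_000.0, 50_000.0, 75_000.0,
)

#: QC standard levels for the repeatability study (ng mL^-1)
DEFAULT_QC_LEVELS: tuple[float, ...] = (100.0, 1000.0, 10_000.0)

PEAK_COLUMNS = [
    "sample_id", "injection_index", "entity", "channel",
    "retention_time_min", "peak_area", "signal_to_noise",
]

_CAL_TAG, _QC_TAG, _COHORT_TAG = 0, 1, 2

#: binary clinical covariates (Bernoulli(0.5) by default)
BINARY_COVARIATES = ("sex", "smoking", "antihypertensive_medication", "statin_medication")

#: continuous clinical covariates: (name, mean, sd, lower truncation)
CONTINUOUS_COVARIATES = (
    ("age", 55.0, 10.0, 18.0),              # years
    ("bmi", 25.0, 4.0, 15.0),               # kg m^-2
    ("hba1c", 64.0, 12.0, 20.0),            # mmol mol^-1
    ("egfr", 85.0, 20.0, 5.0),              # mL min^-1 1.73m^-2
    ("sbp", 135.0, 15.0, 80.0),             # mmHg
    ("total_cholesterol", 4.8, 1.0, 2.0),   # mmol L^-1
    ("total_triglycerides", 1.5, 0.8, 0.2), # mmol L^-1
    ("diabetes_duration", 25.0, 10.0, 0.0), # years
    ("insulin_dose", 50.0, 15.0, 5.0),      # IU day^-1
)


@dataclass(frozen=True)
class ResponseModel:
    """Instrument response model for one quantification entity.

    ``response_factor`` converts concentration (ng mL^-1) to peak area;
    ``istd_stable=False`` marks entities whose labeled standard signal is not
    repeatable — their ISTD areas are drawn with the inflated
    ``unstable_istd_cv`` instead of ``istd_cv``.
    """

    response_factor: float = 100.0
    istd_response_factor: float = 100.0
    proportional_cv: float = 0.05
    baseline_noise_sd: float = 500.0
    istd_cv: float = 0.03
    istd_stable: bool = True
    unstable_istd_cv: float = 0.30
    rt_minutes: float = 5.0
    rt_jitter_sd: float = 0.005

    def __post_init__(self) -> None:
        if not self.response_factor > 0:
            raise ValueError("response_factor must be positive")
        if not (0 <= self.proportional_cv < 1):
            raise ValueError("proportional_cv must be in [0, 1)")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")

    @property
    def effective_istd_cv(self) -> float:
        return self.istd_cv if self.istd_stable else self.unstable_istd_cv


@dataclass(frozen=True)
class CohortEffectSpec:
    """Design of the simulated cohort and its planted effects.

    ``group_effect_log10`` and entries of ``covariate_effects`` may be a
    single float (applied to all entities) or a mapping entity → coefficient.
    Continuous covariates act through their z-score so coefficients are
    comparable across covariates. ``missingness_rate`` forces that fraction
    of (sample, entity) values below detection to exercise the >70%
    detection filter downstream.
    """

    n_per_group: int = 25
    group_effect_log10: float | Mapping[str, float] = 0.0
    covariate_effects: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    residual_sd_log10: float = 0.2
    replicate_cv: float = 0.05
    missingness_rate: float | Mapping[str, float] = 0.0
    baseline_log10: float | Mapping[str, float] = 3.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not self.residual_sd_log10 > 0:
            raise ValueError("residual_sd_log10 must be positive")
        rates = (
            self.missingness_rate.values()
            if isinstance(self.missingness_rate, Mapping)
            else [self.missingness_rate]
        )
        for r in rates:
            if not 0 <= r <= 1:
                raise ValueError("missingness_rate must be in [0, 1]")

    def per_entity(self, value, entity: str, default: float = 0.0) -> float:
        if isinstance(value, Mapping):
            return float(value.get(entity, default))
        return float(value)


@dataclass
class GroundTruth:
    """True concentrations per (sample, entity) plus the generating parameters."""

    concentrations: pd.DataFrame  # columns: sample_id, entity, true_concentration, [masked]
    parameters: dict

    def lookup(self, sample_id: str, entity: str) -> float:
        df = self.concentrations
        m = (df["sample_id"] == sample_id) & (df["entity"] == entity)
        return float(df.loc[m, "true_concentration"].iloc[0])


def default_response_models(
    panel: AnalytePanel,
    *,
    proportional_cv: float = 0.05,
    baseline_noise_sd: float = 500.0,
) -> dict[str, ResponseModel]:
    """A per-entity model dict; entities without an ISTD are marked unstable."""
    models: dict[str, ResponseModel] = {}
    for ent in panel.entities():
        models[ent.name] = ResponseModel(
            proportional_cv=proportional_cv,
            baseline_noise_sd=baseline_noise_sd,
            istd_stable=ent.has_istd,
        )
    return models


def synthetic_panel(n_entities: int, *, with_istd: bool = True) -> AnalytePanel:
    """A programmatic n-entity panel of stand-alone analytes, for studies/tests."""
    analytes = []
    istds = []
    for i in range(n_entities):
        abbrev = f"M{i + 1:02d}"
        istd_abbrev = f"{abbrev}-d3" if with_istd else None
        analytes.append(
            AnalyteDef(
                abbreviation=abbrev,
                name=f"Metabolite {i + 1}",
                group="other",
                transitions=(
                    Transition(200.0 + i, 100.0 + i, "negative", "quantifier"),
                ),
                istd_abbreviation=istd_abbrev,
            )
        )
        if with_istd:
            istds.append(IstdDef(abbreviation=istd_abbrev, mix_concentration=1000.0))
    return AnalytePanel(analytes=analytes, istds=istds)


# -- internals -------------------------------------------------------------


def _resolve_models(
    panel: AnalytePanel,
    models: Mapping[str, ResponseModel] | ResponseModel | None,
) -> dict[str, ResponseModel]:
    entities = panel.entities()
    if models is None:
        return default_response_models(panel)
    if isinstance(models, ResponseModel):
        return {e.name: models for e in entities}
    resolved = {}
    for e in entities:
        resolved[e.name] = models.get(e.name, ResponseModel())
    return resolved


def _snr(area: np.ndarray, baseline_sd: float) -> np.ndarray:
    if baseline_sd == 0:
        return np.full_like(area, np.inf)
    return area / baseline_sd


def _entity_rows(
    rng: np.random.Generator,
    *,
    sample_id: str,
    injection_index: int,
    entity: QuantEntity,
    model: ResponseModel,
    concentration: float,
    istd_concentration: float | None,
) -> list[dict]:
    e_prop = rng.normal(0.0, model.proportional_cv) if model.proportional_cv else 0.0
    e_base = rng.normal(0.0, model.baseline_noise_sd) if model.baseline_noise_sd else 0.0
    area = max(model.response_factor * concentration * (1.0 + e_prop) + e_base, 0.0)
    rt = model.rt_minutes + (rng.normal(0.0, model.rt_jitter_sd) if model.rt_jitter_sd else 0.0)
    rows = [
        {
            "sample_id": sample_id,
            "injection_index": injection_index,
            "entity": entity.name,
            "channel": "analyte",
            "retention_time_min": rt,
            "peak_area": area,
            "signal_to_noise": float(_snr(np.asarray(area), model.baseline_noise_sd)),
        }
    ]
    if istd_concentration is not None:
        cv = model.effective_istd_cv
        e_istd = rng.normal(0.0, cv) if cv else 0.0
        istd_area = max(model.istd_response_factor * istd_concentration * (1.0 + e_istd), 0.0)
        rows.append(
            {
                "sample_id": sample_id,
                "injection_index": injection_index,
                "entity": entity.name,
                "channel": "istd",
                "retention_time_min": rt,
                "peak_area": istd_area,
                "signal_to_noise": float(_snr(np.asarray(istd_area), model.baseline_noise_sd)),
            }
        )
    return rows


def _istd_conc(panel: AnalytePanel, entity: QuantEntity) -> float | None:
    if entity.istd_abbreviation is None:
        return None
    return panel.istd_mix_concentration(entity.istd_abbreviation)


# -- generators ------------------------------------------------------------


def simulate_calibration_series(
    panel: AnalytePanel,
    levels: Sequence[float] | None = None,
    models: Mapping[str, ResponseModel] | ResponseModel | None = None,
    seed: int = 0,
    *,
    n_blanks: int = 3,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the calibration standards, run at sequence start and end.

    Returns a long-format peak table (one analyte row and, where an ISTD is
    paired, one ISTD row per injection) and the ground truth. Sample ids are
    ``CAL_<series>_L<level index>``; a ``series`` column flags ``start`` /
    ``end``, ``sample_type`` distinguishes standards from blanks, and
    ``nominal_concentration`` carries the standard level.
    """
    levels = tuple(DEFAULT_LEVELS if levels is None else levels)
    if any(not (lv > 0 and math.isfinite(lv)) for lv in levels):
        raise ValueError("calibration levels must be positive and finite")
    if list(levels) != sorted(set(levels)):
        raise ValueError("calibration levels must be strictly increasing")
    model_map = _resolve_models(panel, models)
    rng = np.random.default_rng([seed, _CAL_TAG])
    entities = panel.entities()

    rows: list[dict] = []
    meta: list[dict] = []
    truth_rows: list[dict] = []
    injection = 0
    for series in ("start", "end"):
        for i, level in enumerate(levels, start=1):
            injection += 1
            sample_id = f"CAL_{series}_L{i:02d}"
            for ent in entities:
                for r in _entity_rows(
                    rng,
                    sample_id=sample_id,
                    injection_index=injection,
                    entity=ent,
                    model=model_map[ent.name],
                    concentration=level,
                    istd_concentration=_istd_conc(panel, ent),
                ):
                    r.update(series=series, sample_type="standard", nominal_concentration=level)
                    rows.append(r)
                truth_rows.append(
                    {"sample_id": sample_id, "entity": ent.name, "true_concentration": level}
                )
        for b in range(n_blanks):
            injection += 1
            sample_id = f"BLANK_{series}_{b + 1}"
            for ent in entities:
                for r in _entity_rows(
                    rng,
                    sample_id=sample_id,
                    injection_index=injection,
                    entity=ent,
                    model=model_map[ent.name],
                    concentration=0.0,
                    istd_concentration=_istd_conc(panel, ent),
                ):
                    r.update(series=series, sample_type="blank", nominal_concentration=0.0)
                    rows.append(r)
                truth_rows.append(
                    {"sample_id": sample_id, "entity": ent.name, "true_concentration": 0.0}
                )

    peaks = pd.DataFrame(rows)
    truth = GroundTruth(
        concentrations=pd.DataFrame(truth_rows),
        parameters={"levels": levels, "seed": seed, "kind": "calibration"},
    )
    return peaks, truth


def simulate_qc_replicates(
    panel: AnalytePanel,
    qc_levels: Sequence[float] | None = None,
    intra_n: int = 4,
    days: int = 5,
    runs_per_day: int = 3,
    models: Mapping[str, ResponseModel] | ResponseModel | None = None,
    seed: int = 0,
    *,
    day_shift_cv: float = 0.08,
) -> pd.DataFrame:
    """Simulate the QC repeatability study.

    The intra-day block holds ``intra_n`` consecutive runs on one day; the
    inter-day block holds ``runs_per_day`` runs on each of ``days`` days. A
    per-day multiplicative shift (CV ``day_shift_cv``) on analyte areas makes
    inter-day dispersion exceed intra-day dispersion, as observed in practice.
    Columns ``block`` (intra/inter), ``day``, ``run``, and
    ``nominal_concentration`` label each injection.
    """
    if min(intra_n, days, runs_per_day) < 1:
        raise ValueError("intra_n, days, and runs_per_day must be >= 1")
    qc_levels = tuple(DEFAULT_QC_LEVELS if qc_levels is None else qc_levels)
    model_map = _resolve_models(panel, models)
    rng = np.random.default_rng([seed, _QC_TAG])
    entities = panel.entities()

    # day shifts per (entity, day); day 0 is the intra-day block's day
    day_shift = {
        (ent.name, d): (1.0 + rng.normal(0.0, day_shift_cv) if day_shift_cv else 1.0)
        for ent in entities
        for d in range(days + 1)
    }

    rows: list[dict] = []
    injection = 0

    def _emit(block: str, day: int, run: int, level: float) -> None:
        nonlocal injection
        injection += 1
        sample_id = f"QC_{level:g}_{block}_d{day}_r{run}"
        for ent in entities:
            model = model_map[ent.name]
            for r in _entity_rows(
                rng,
                sample_id=sample_id,
                injection_index=injection,
                entity=ent,
                model=model,
                concentration=level * day_shift[(ent.name, day)],
                istd_concentration=_istd_conc(panel, ent),
            ):
                r.update(
                    block=block, day=day, run=run,
                    sample_type="qc", nominal_concentration=level,
                )
                rows.append(r)

    for level in qc_levels:
        for run in range(1, intra_n + 1):
            _emit("intra", 0, run, level)
    for level in qc_levels:
        for day in range(1, days + 1):
            for run in range(1, runs_per_day + 1):
                _emit("inter", day, run, level)

    return pd.DataFrame(rows)


def simulate_cohort(
    panel: AnalytePanel,
    spec: CohortEffectSpec | None = None,
    seed: int = 0,
    models: Mapping[str, ResponseModel] | ResponseModel | None = None,
) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Simulate a two-group cohort with technical replicate injections.

    Per participant, log10 true concentration of each entity is

        baseline + group_effect * group + sum_j beta_j * z(covariate_j)
                 + N(0, residual_sd_log10^2),

    with three (by default) replicate injections per sample drawn through the
    entity's response model at replicate CV ``spec.replicate_cv``. A fraction
    ``missingness_rate`` of (sample, entity) values is forced below detection
    (areas reduced to baseline noise; truth records ``masked=True``).

    Returns ``(clinical, truth, peaks)``.
    """
    spec = spec or CohortEffectSpec()
    model_map = _resolve_models(panel, models)
    rng = np.random.default_rng([seed, _COHORT_TAG])
    entities = panel.entities()
    n = 2 * spec.n_per_group

    participant_ids = [f"P{i + 1:03d}" for i in range(n)]
    group = np.repeat([0, 1], spec.n_per_group)

    clinical = pd.DataFrame({"participant_id": participant_ids, "group": group})
    clinical["albuminuria_group"] = np.where(group == 1, "macro", "normo")
    for name, mean, sd, lower in CONTINUOUS_COVARIATES:
        clinical[name] = np.maximum(rng.normal(mean, sd, size=n), lower)
    for name in BINARY_COVARIATES:
        clinical[name] = rng.integers(0, 2, size=n)

    # z-scores of continuous covariates for the effect model
    zscores: dict[str, np.ndarray] = {}
    for name, *_ in CONTINUOUS_COVARIATES:
        x = clinical[name].to_numpy(dtype=float)
        s = x.std(ddof=0)
        zscores[name] = (x - x.mean()) / s if s > 0 else np.zeros_like(x)
    for name in BINARY_COVARIATES:
        zscores[name] = clinical[name].to_numpy(dtype=float)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    injection = 0
    per_entity_truth: dict[str, np.ndarray] = {}
    per_entity_mask: dict[str, np.ndarray] = {}
    for ent in entities:
        base = spec.per_entity(spec.baseline_log10, ent.name, 3.0)
        g_eff = spec.per_entity(spec.group_effect_log10, ent.name)
        log10_c = base + g_eff * group + rng.normal(0.0, spec.residual_sd_log10, size=n)
        for cov, betas in spec.covariate_effects.items():
            beta = spec.per_entity(betas, ent.name)
            if beta:
                log10_c = log10_c + beta * zscores[cov]
        conc = 10.0 ** log10_c
        rate = spec.per_entity(spec.missingness_rate, ent.name)
        masked = rng.random(n) < rate if rate > 0 else np.zeros(n, dtype=bool)
        conc = np.where(masked, 0.0, conc)
        per_entity_truth[ent.name] = conc
        per_entity_mask[ent.name] = masked

    # replicate-level measurement noise replaces the model's proportional CV
    rep_models = {
        name: dataclasses.replace(model, proportional_cv=spec.replicate_cv)
        for name, model in model_map.items()
    }
    for i, pid in enumerate(participant_ids):
        for rep in range(1, spec.n_replicates + 1):
            injection += 1
            for ent in entities:
                rep_model = rep_models[ent.name]
                for r in _entity_rows(
                    rng,
                    sample_id=pid,
                    injection_index=rep,
                    entity=ent,
                    model=rep_model,
                    concentration=per_entity_truth[ent.name][i],
                    istd_concentration=_istd_conc(panel, ent),
                ):
                    r.update(sample_type="study", participant_id=pid, replicate=rep)
                    rows.append(r)

    for ent in entities:
        for i, pid in enumerate(participant_ids):
            truth_rows.append(
                {
                    "sample_id": pid,
                    "entity": ent.name,
                    "true_concentration": per_entity_truth[ent.name][i],
                    "masked": bool(per_entity_mask[ent.name][i]),
                }
            )

    truth = GroundTruth(
        concentrations=pd.DataFrame(truth_rows),
        parameters={"spec": spec, "seed": seed, "kind": "cohort"},
    )
    return clinical, truth, pd.DataFrame(rows)
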