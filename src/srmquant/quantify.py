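"""ISTD normalization, 1/x-weighted calibration, and back-calculation.

The processing chain implemented here mirrors routine targeted-MS practice:

1. **Normalization** — each analyte peak area is divided by the area of its
   paired internal standard in the same injection; entities without a usable
   ISTD pass through as raw areas, tagged unnormalized.
2. **Calibration** — per entity, weighted least squares of response on
   nominal concentration with weights 1/x, solved exactly from the
   2-parameter weighted normal equations. At least five levels are required
   unless explicitly overridden (a documented 3-point fallback exists for
   analytes with high detection limits). Start- and end-of-sequence series
   are pooled into one fit by default.
3. **Detection limit** — the LOD is the lowest standard level whose median
   S/N across series reaches 3; if the lowest measured level already
   qualifies, the LOD is reported as below the lowest level ("< 2.5" style).
4. **Linear range** — the largest contiguous run of levels (>= the minimum
   point count) in which every level's back-calculated concentration, under
   the fit restricted to that run, falls within the 80–120% accuracy band.
   LLOQ/ULOQ are the run's endpoints; the curve is refit on the selected run.
5. **Back-calculation** — concentration = (response − intercept) / slope,
   flagged ok / below_lod / below_lloq / above_uloq against the curve limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AnalytePanel, QuantEntity

__all__ = [
    "CalibrationError",
    "NoLinearRangeError",
    "LodResult",
    "CalibrationCurve",
    "normalize_to_istd",
    "weighted_linear_fit",
    "fit_calibration",
    "determine_lod",
    "determine_linear_range",
    "apply_calibration",
    "calibrate_panel",
    "quantify_study",
    "calibration_report",
]

ACCURACY_BAND = (0.80, 1.20)
MIN_POINTS = 5
SNR_LOD_THRESHOLD = 3.0

FLAG_OK = "ok"
FLAG_BELOW_LOD = "below_lod"
FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_ULOQ = "above_uloq"

STATUS_OK = "ok"
STATUS_MISSING_ISTD = "missing_istd"
STATUS_ZERO_ISTD = "zero_istd"


class CalibrationError(ValueError):
    """Raised for unusable calibration input (too few levels, bad slope, ...)."""


class NoLinearRangeError(CalibrationError):
    """Raised when no contiguous level run satisfies the accuracy band."""


@dataclass(frozen=True)
class LodResult:
    """Limit of detection at S/N >= 3.

    ``status`` is ``"value"`` (LOD equals ``concentration``),
    ``"below_lowest"`` (the lowest measured level already reaches S/N 3;
    ``concentration`` holds that lowest level) or ``"above_highest"`` (no
    level reaches S/N 3; ``concentration`` holds the highest level).
    """

    status: str
    concentration: float

    def __str__(self) -> str:
        if self.status == "below_lowest":
            return f"< {self.concentration:g}"
        if self.status == "above_highest":
            return f"> {self.concentration:g}"
        return f"{self.concentration:g}"

    @property
    def detection_threshold(self) -> float:
        """Concentration above which a back-calculated value counts as detected."""
        return 0.0 if self.status == "below_lowest" else self.concentration


@dataclass(frozen=True)
class CalibrationCurve:
    """A per-entity weighted linear calibration with its usable range."""

    entity: str
    slope: float
    intercept: float
    r_squared: float
    levels_used: tuple[float, ...]
    weighting: str = "one_over_x"
    lod: LodResult | None = None
    lloq: float | None = None
    uloq: float | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.lloq is not None and self.uloq is not None and self.lloq > self.uloq:
            raise CalibrationError(f"{self.entity}: LLOQ exceeds ULOQ")

    def back_calculate(self, response: float | np.ndarray) -> float | np.ndarray:
        return (response - self.intercept) / self.slope


# -- normalization ---------------------------------------------------------


def normalize_to_istd(peaks: pd.DataFrame, panel: AnalytePanel) -> pd.DataFrame:
    """Compute per-injection analyte/ISTD response ratios.

    Returns one row per (sample_id, injection_index, entity) with columns
    ``response`` (area ratio, or raw area for ISTD-free entities),
    ``normalized`` (bool) and ``status``: ``ok``, ``missing_istd`` (the ISTD
    row is absent for an ISTD-bearing entity) or ``zero_istd`` (ISTD area is
    zero, leaving the injection unquantifiable). Rows with non-ok status
    carry NaN responses and are never silently dropped.

    Metadata columns present on the analyte rows (series, sample_type,
    nominal_concentration, ...) are carried through.
    """
    entities = {e.name: e for e in panel.entities()}
    unknown = set(peaks["entity"]) - set(entities)
    if unknown:
        raise KeyError(f"peak table contains entities not in the panel: {sorted(unknown)}")

    keys = ["sample_id", "injection_index", "entity"]
    analyte = peaks[peaks["channel"] == "analyte"].copy()
    istd = peaks[peaks["channel"] == "istd"]
    istd_area = istd.set_index(keys)["peak_area"]
    dup = istd_area.index.duplicated()
    if dup.any():
        raise ValueError("duplicate ISTD rows for the same (sample, injection, entity)")

    merged = analyte.merge(
        istd_area.rename("istd_area"), how="left", left_on=keys, right_index=True
    )

    has_istd = merged["entity"].map(lambda e: entities[e].has_istd)
    istd_missing = has_istd & merged["istd_area"].isna()
    istd_zero = has_istd & (merged["istd_area"] == 0)

    response = np.where(
        has_istd, merged["peak_area"] / merged["istd_area"], merged["peak_area"]
    )
    response = np.where(istd_missing | istd_zero, np.nan, response)

    out = merged.drop(columns=["channel", "istd_area"])
    out["response"] = response
    out["normalized"] = has_istd.to_numpy()
    out["status"] = np.select(
        [istd_missing, istd_zero], [STATUS_MISSING_ISTD, STATUS_ZERO_ISTD], STATUS_OK
    )
    return out.reset_index(drop=True)


# -- weighted fit ----------------------------------------------------------


def weighted_linear_fit(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, float]:
    """Exact solution of the weighted 2-parameter normal equations.

    Returns (slope, intercept, weighted R^2). R^2 uses the weighted mean of
    ``y`` as the null model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    s0 = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = s0 * sxx - sx * sx
    if denom == 0:
        raise CalibrationError("degenerate design: all concentrations identical")
    slope = (s0 * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / s0
    resid = y - (intercept + slope * x)
    ss_res = (w * resid**2).sum()
    ybar = sy / s0
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    entity: str = "",
    *,
    min_points: int = MIN_POINTS,
    weighting: str = "one_over_x",
    normalized: bool = True,
) -> CalibrationCurve:
    """Weighted least-squares calibration of response on nominal concentration.

    ``levels`` / ``responses`` are parallel arrays over all calibration
    points (replicate injections and pooled series included). The number of
    *distinct* levels with finite responses must reach ``min_points``; lower
    ``min_points`` explicitly for documented few-point exceptions.
    """
    if weighting != "one_over_x":
        raise ValueError(f"unsupported weighting {weighting!r}")
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.any(x <= 0):
        raise CalibrationError(f"{entity}: non-positive concentration in calibration data")
    n_levels = np.unique(x).size
    if n_levels < min_points:
        raise CalibrationError(
            f"{entity}: {n_levels} distinct calibration levels available, "
            f"need at least {min_points}"
        )
    slope, intercept, r2 = weighted_linear_fit(x, y, 1.0 / x)
    return CalibrationCurve(
        entity=entity,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        levels_used=tuple(np.unique(x)),
        weighting=weighting,
        normalized=normalized,
    )


# -- LOD -------------------------------------------------------------------


def determine_lod(
    levels: Sequence[float],
    snr: Sequence[float],
    *,
    threshold: float = SNR_LOD_THRESHOLD,
) -> LodResult:
    """LOD = lowest nominal level whose median S/N across series reaches 3.

    ``levels``/``snr`` are parallel arrays over all standard injections
    (replicates at the same level are aggregated by median, robust to a
    single noisy injection).
    """
    x = np.asarray(levels, dtype=float)
    s = np.asarray(snr, dtype=float)
    if x.size == 0:
        raise ValueError("no standard S/N data supplied")
    distinct = np.unique(x)
    medians = np.array([np.median(s[x == lv]) for lv in distinct])
    passing = distinct[medians >= threshold]
    if passing.size == 0:
        return LodResult(status="above_highest", concentration=float(distinct[-1]))
    lod = float(passing.min())
    if lod == float(distinct[0]):
        return LodResult(status="below_lowest", concentration=lod)
    return LodResult(status="value", concentration=lod)


# -- linear range ----------------------------------------------------------


def _run_accuracy_ok(
    x: np.ndarray,
    y: np.ndarray,
    run_levels: np.ndarray,
    band: tuple[float, float],
) -> tuple[bool, CalibrationCurve | None]:
    """Fit on the points within the run; check per-level back-calc accuracy.

    A level passes if the back-calculated concentration of its mean response
    lies within ``band`` of nominal.
    """
    in_run = np.isin(x, run_levels)
    xs, ys = x[in_run], y[in_run]
    try:
        slope, intercept, r2 = weighted_linear_fit(xs, ys, 1.0 / xs)
    except CalibrationError:
        return False, None
    if slope <= 0:
        return False, None
    for lv in run_levels:
        mean_resp = ys[xs == lv].mean()
        back = (mean_resp - intercept) / slope
        if not (band[0] * lv <= back <= band[1] * lv):
            return False, None
    curve = CalibrationCurve(
        entity="",
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        levels_used=tuple(run_levels),
    )
    return True, curve


def determine_linear_range(
    levels: Sequence[float],
    responses: Sequence[float],
    entity: str = "",
    *,
    min_points: int = MIN_POINTS,
    accuracy_band: tuple[float, float] = ACCURACY_BAND,
    normalized: bool = True,
) -> CalibrationCurve:
    """Find the widest contiguous run of levels meeting the accuracy band.

    All contiguous runs of distinct sorted levels with at least
    ``min_points`` members are scanned; a run qualifies when every one of its
    levels back-calculates within ``accuracy_band`` under the fit restricted
    to that run. The longest qualifying run wins; ties break toward the
    lower starting level, then the lower top level. The returned curve is
    refit on the selected run, with LLOQ/ULOQ set to the run endpoints.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    distinct = np.unique(x)
    if distinct.size < min_points:
        raise CalibrationError(
            f"{entity}: {distinct.size} distinct levels, need at least {min_points}"
        )
    best_curve: CalibrationCurve | None = None
    best_span: tuple[int, int] | None = None
    for start in range(distinct.size):
        for stop in range(start + min_points, distinct.size + 1):
            run = distinct[start:stop]
            passed, curve = _run_accuracy_ok(x, y, run, accuracy_band)
            if not passed:
                continue
            length = stop - start
            if best_span is None:
                better = True
            else:
                b_len = best_span[1] - best_span[0]
                better = (length, -start, -stop) > (b_len, -best_span[0], -best_span[1])
            if better:
                best_span = (start, stop)
                best_curve = curve
    if best_curve is None or best_span is None:
        raise NoLinearRangeError(
            f"{entity}: no contiguous run of >= {min_points} levels meets the "
            f"{accuracy_band[0]:.0%}–{accuracy_band[1]:.0%} accuracy band"
        )
    run = distinct[best_span[0]:best_span[1]]
    return replace(
        best_curve,
        entity=entity,
        lloq=float(run[0]),
        uloq=float(run[-1]),
        normalized=normalized,
    )


# -- back-calculation ------------------------------------------------------


def apply_calibration(ratios: pd.DataFrame, curve: CalibrationCurve) -> pd.DataFrame:
    """Back-calculate concentrations for one entity's response ratios.

    ``ratios`` needs columns sample_id, injection_index, entity, response.
    Output columns: sample_id, injection_index, entity, concentration, flag.
    Rows flagged ``below_lod`` (including negative back-calculations and
    unquantifiable responses) carry no concentration; ``below_lloq`` and
    ``above_uloq`` rows keep their value so downstream detection filtering
    and modeling can use them.
    """
    if curve.slope <= 0:
        raise CalibrationError(f"{curve.entity}: non-positive calibration slope")
    resp = ratios["response"].to_numpy(dtype=float)
    conc = (resp - curve.intercept) / curve.slope

    lod_threshold = curve.lod.detection_threshold if curve.lod is not None else 0.0
    lloq = curve.lloq if curve.lloq is not None else -np.inf
    uloq = curve.uloq if curve.uloq is not None else np.inf

    below_lod = ~np.isfinite(conc) | (conc <= 0) | (conc < lod_threshold)
    below_lloq = ~below_lod & (conc < lloq)
    above_uloq = ~below_lod & (conc > uloq)

    flag = np.select(
        [below_lod, below_lloq, above_uloq],
        [FLAG_BELOW_LOD, FLAG_BELOW_LLOQ, FLAG_ABOVE_ULOQ],
        FLAG_OK,
    )
    out = ratios[["sample_id", "injection_index", "entity"]].copy()
    out["concentration"] = np.where(below_lod, np.nan, conc)
    out["flag"] = flag
    return out


# -- orchestration ---------------------------------------------------------


def calibrate_panel(
    calibration_peaks: pd.DataFrame,
    panel: AnalytePanel,
    *,
    min_points: int = MIN_POINTS,
    min_points_overrides: Mapping[str, int] | None = None,
    accuracy_band: tuple[float, float] = ACCURACY_BAND,
) -> dict[str, CalibrationCurve]:
    """Fit calibration curves (with LOD and linear range) for every entity.

    ``calibration_peaks`` must carry a ``nominal_concentration`` column and
    both analyte and ISTD channels; blank rows (nominal 0) are ignored for
    the fit. Entities for which no linear range qualifies are omitted from
    the result (callers can detect them by absence).
    """
    overrides = dict(min_points_overrides or {})
    ratios = normalize_to_istd(calibration_peaks, panel)
    std = ratios[(ratios["nominal_concentration"] > 0) & (ratios["status"] == STATUS_OK)]
    snr_src = calibration_peaks[
        (calibration_peaks["channel"] == "analyte")
        & (calibration_peaks["nominal_concentration"] > 0)
    ]
    curves: dict[str, CalibrationCurve] = {}
    for ent in panel.entities():
        sub = std[std["entity"] == ent.name]
        if sub.empty:
            continue
        mp = overrides.get(ent.name, min_points)
        try:
            curve = determine_linear_range(
                sub["nominal_concentration"],
                sub["response"],
                ent.name,
                min_points=mp,
                accuracy_band=accuracy_band,
                normalized=ent.has_istd,
            )
        except NoLinearRangeError:
            continue
        snr_sub = snr_src[snr_src["entity"] == ent.name]
        lod = determine_lod(
            snr_sub["nominal_concentration"], snr_sub["signal_to_noise"]
        )
        curves[ent.name] = replace(curve, lod=lod)
    return curves


def quantify_study(
    study_peaks: pd.DataFrame,
    panel: AnalytePanel,
    curves: Mapping[str, CalibrationCurve],
) -> pd.DataFrame:
    """Normalize and back-calculate study samples against fitted curves.

    Technical replicates are quantified independently. Entities without a
    curve are skipped. Returns the concatenated concentration table.
    """
    ratios = normalize_to_istd(study_peaks, panel)
    parts = []
    for name, curve in curves.items():
        sub = ratios[ratios["entity"] == name]
        if sub.empty:
            continue
        parts.append(apply_calibration(sub, curve))
    if not parts:
        return pd.DataFrame(
            columns=["sample_id", "injection_index", "entity", "concentration", "flag"]
        )
    return pd.concat(parts, ignore_index=True)


def calibration_report(curves: Mapping[str, CalibrationCurve]) -> pd.DataFrame:
    """A method-report table: one row per entity with R², range, and LOD."""
    rows = []
    for name in sorted(curves):
        c = curves[name]
        rows.append(
            {
                "entity": name,
                "r_squared": c.r_squared,
                "lloq_ng_per_ml": c.lloq,
                "uloq_ng_per_ml": c.uloq,
                "linear_range": f"{c.lloq:g}–{c.uloq:g}" if c.lloq is not None else "",
                "lod_ng_per_ml": str(c.lod) if c.lod is not None else "",
                "n_levels_used": len(c.levels_used),
                "slope": c.slope,
                "intercept": c.intercept,
                "normalized": c.normalized,
            }
        )
    return pd.DataFrame(rows)
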