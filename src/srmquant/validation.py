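"""Intra- and inter-day repeatability metrics (method-validation report).

Repeatability is summarized as the relative standard deviation
%RSD = 100 * sd / mean (sample standard deviation, n-1 denominator, suited
to the small QC replicate counts). The intra-day block pools the consecutive
runs of a single day; the inter-day block pools all runs across days rather
than averaging daily means, so the reported n equals the total injection
count. The area metric uses ISTD-normalized response ratios wherever the
entity has an internal standard and raw areas otherwise (reported with
``normalized=False``); retention-time %RSD always comes from the analyte
channel.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import AnalytePanel
from .quantify import STATUS_OK, normalize_to_istd

__all__ = ["RsdError", "rsd", "repeatability_report"]

logger = logging.getLogger(__name__)


class RsdError(ValueError):
    """Raised when %RSD is undefined (n < 2 or zero mean)."""


def rsd(values: Sequence[float] | np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * sd(n-1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise RsdError(f"need at least 2 values for %RSD, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise RsdError("non-finite values in %RSD input")
    mean = x.mean()
    if mean == 0:
        raise RsdError("%RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def repeatability_report(
    qc_peaks: pd.DataFrame,
    panel: AnalytePanel,
) -> pd.DataFrame:
    """Per (entity, QC level) repeatability table.

    Expects the QC peak-table layout produced by
    :func:`srmquant.simulate.simulate_qc_replicates`: columns ``block``
    (intra/inter), ``day``, ``run`` and ``nominal_concentration`` in addition
    to the canonical peak columns. Entities missing a QC level are omitted
    with a logged warning — never silently.

    Output columns: entity, qc_level, rsd_rt_intra, rsd_area_intra, n_intra,
    rsd_rt_inter, rsd_area_inter, n_inter, normalized.
    """
    required = {"block", "nominal_concentration"}
    missing = required - set(qc_peaks.columns)
    if missing:
        raise ValueError(f"QC peak table is missing columns: {sorted(missing)}")

    ratios = normalize_to_istd(qc_peaks, panel)
    analyte_rows = qc_peaks[qc_peaks["channel"] == "analyte"]
    levels = sorted(qc_peaks["nominal_concentration"].unique())
    entities = panel.entities()

    rows = []
    for ent in entities:
        for level in levels:
            sel = (
                (ratios["entity"] == ent.name)
                & (ratios["nominal_concentration"] == level)
                & (ratios["status"] == STATUS_OK)
            )
            sub = ratios[sel]
            rt_sub = analyte_rows[
                (analyte_rows["entity"] == ent.name)
                & (analyte_rows["nominal_concentration"] == level)
            ]
            intra = sub[sub["block"] == "intra"]
            inter = sub[sub["block"] == "inter"]
            if len(intra) < 2 or len(inter) < 2:
                logger.warning(
                    "entity %s at QC level %g: insufficient QC injections "
                    "(intra=%d, inter=%d); omitted from repeatability report",
                    ent.name, level, len(intra), len(inter),
                )
                continue
            rt_intra = rt_sub[rt_sub["block"] == "intra"]["retention_time_min"]
            rt_inter = rt_sub[rt_sub["block"] == "inter"]["retention_time_min"]
            rows.append(
                {
                    "entity": ent.name,
                    "qc_level": level,
                    "rsd_rt_intra": rsd(rt_intra),
                    "rsd_area_intra": rsd(intra["response"]),
                    "n_intra": len(intra),
                    "rsd_rt_inter": rsd(rt_inter),
                    "rsd_area_inter": rsd(inter["response"]),
                    "n_inter": len(inter),
                    "normalized": ent.has_istd,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "entity", "qc_level", "rsd_rt_intra", "rsd_area_intra", "n_intra",
            "rsd_rt_inter", "rsd_area_inter", "n_inter", "normalized",
        ],
    )
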