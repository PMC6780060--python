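"""Metabolite–phenotype association with mixed-effects models and FDR control.

Pipeline for the quantified cohort:

1. **Detection filter** — a metabolite enters the analysis only if it is
   detected (any replicate injection above the LOD) in *strictly more than*
   70% of samples.
2. **Per-metabolite mixed model** — log10 concentration is regressed on the
   clinical fixed effects (albuminuria group, age, BMI, eGFR, HbA1c, sex,
   systolic blood pressure, total cholesterol, total triglycerides by
   default) with a random intercept per participant absorbing the
   correlation between technical replicate injections; fit by REML, Wald
   two-sided tests per coefficient. Replicates below the LLOQ enter with
   their reported values; below-LOD rows are excluded row-wise.
3. **Multiple testing** — Benjamini–Hochberg step-up applied per fixed-effect
   term across the metabolites (not across terms), significance called at
   adjusted p < 0.05.
4. **Network extraction** — one bipartite edge (clinical term ↔ metabolite)
   per significant coefficient, signed by the coefficient and weighted on a
   log10 strength scale; group and eGFR edges are flagged highlighted.

Variance-moderation schemes (empirical-Bayes shrinkage of per-metabolite
variances) are deliberately not applied; tests are plain mixed-model Wald
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .quantify import FLAG_BELOW_LOD

__all__ = [
    "DEFAULT_MODEL_TERMS",
    "OPTIONAL_MODEL_TERMS",
    "HIGHLIGHTED_TERMS",
    "RankDeficientDesignError",
    "detection_filter",
    "fit_metabolite_model",
    "adjust_bh",
    "run_association",
    "build_network",
    "edges_to_networkx",
]

#: fixed effects of the metabolite model (clinical covariate column names)
DEFAULT_MODEL_TERMS = (
    "group",
    "age",
    "bmi",
    "egfr",
    "hba1c",
    "sex",
    "sbp",
    "total_cholesterol",
    "total_triglycerides",
)

#: extra fixed effects that can be switched on by configuration
OPTIONAL_MODEL_TERMS = ("smoking", "statin_medication", "antihypertensive_medication")

#: terms whose network edges are highlighted (key study variables)
HIGHLIGHTED_TERMS = ("group", "egfr")

ALPHA = 0.05

_PERFECT_FIT_VARIANCE = 1e-12


class RankDeficientDesignError(ValueError):
    """Raised when the fixed-effect design matrix is rank deficient."""


def detection_filter(
    conc: pd.DataFrame, threshold: float = 0.70
) -> list[str]:
    """Entities detected in strictly more than ``threshold`` of samples.

    A sample counts as detected for an entity if *any* of its replicate
    injections carries a flag other than ``below_lod``.
    """
    detected = (
        conc.assign(det=conc["flag"] != FLAG_BELOW_LOD)
        .groupby(["entity", "sample_id"])["det"]
        .any()
        .groupby("entity")
        .mean()
    )
    return sorted(detected.index[detected > threshold])


def _design(
    clinical: pd.DataFrame, terms: Sequence[str]
) -> pd.DataFrame:
    X = clinical[list(terms)].astype(float).copy()
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X)
        raise RankDeficientDesignError(
            f"fixed-effect design is rank deficient; aliased terms: {aliased}"
        )
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns that do not increase the design rank when added left to right."""
    aliased = []
    cols: list[str] = []
    current = 0
    for c in X.columns:
        cand = X[cols + [c]].to_numpy()
        r = np.linalg.matrix_rank(cand)
        if r > current:
            cols.append(c)
            current = r
        else:
            aliased.append(c)
    return aliased


def fit_metabolite_model(
    conc: pd.DataFrame,
    clinical: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_MODEL_TERMS,
    *,
    log10_response: bool = True,
) -> pd.DataFrame:
    """Fit the random-intercept model for one entity's concentration table.

    ``conc`` holds replicate-level rows (sample_id, injection_index,
    concentration, flag) for a single entity; ``sample_id`` identifies the
    participant and is matched to ``clinical['participant_id']``. Below-LOD
    rows are excluded; everything else (including below-LLOQ values) enters
    as reported. The response is log10 concentration unless
    ``log10_response=False``.

    Returns one row per fixed-effect term with columns coefficient,
    std_error, p_value, n_obs, n_participants, converged.
    """
    entity = conc["entity"].iloc[0] if len(conc) else ""
    rows = conc[(conc["flag"] != FLAG_BELOW_LOD) & conc["concentration"].notna()]
    merged = rows.merge(
        clinical, left_on="sample_id", right_on="participant_id", how="inner"
    )
    if merged.empty:
        raise ValueError(f"{entity}: no quantifiable rows matched to clinical table")
    reps = merged.groupby("participant_id")["injection_index"].size()
    if (reps < 2).all():
        raise ValueError(
            f"{entity}: need >= 2 replicates for at least some participants "
            "to identify the random intercept"
        )

    y = merged["concentration"].to_numpy(dtype=float)
    if log10_response:
        if np.any(y <= 0):
            raise ValueError(f"{entity}: non-positive concentration under log10 response")
        y = np.log10(y)
    X = _design(merged, terms)
    groups = merged["participant_id"].to_numpy()

    # Degenerate noise-free input: REML is singular when the fixed effects
    # explain the response exactly; report the exact coefficients directly.
    ols = sm.OLS(y, X).fit()
    if ols.ssr / len(y) < _PERFECT_FIT_VARIANCE:
        out = pd.DataFrame(
            {
                "term": list(terms),
                "coefficient": [ols.params[t] for t in terms],
                "std_error": 0.0,
                "p_value": 0.0,
                "converged": True,
            }
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = MixedLM(y, X, groups=groups).fit(reml=True)
        out = pd.DataFrame(
            {
                "term": list(terms),
                "coefficient": [fit.params[t] for t in terms],
                "std_error": [fit.bse[t] for t in terms],
                "p_value": [fit.pvalues[t] for t in terms],
                "converged": bool(fit.converged),
            }
        )
    out.insert(0, "entity", entity)
    out["n_obs"] = len(merged)
    out["n_participants"] = merged["participant_id"].nunique()
    return out


def adjust_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, for the ascending
    order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m, dtype=float)
    adj[order] = adj_sorted
    return adj


def run_association(
    conc: pd.DataFrame,
    clinical: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_MODEL_TERMS,
    *,
    detection_threshold: float = 0.70,
    alpha: float = ALPHA,
    log10_response: bool = True,
) -> pd.DataFrame:
    """Detection filter → per-metabolite mixed models → BH per term.

    Returns the full association table (entity × term) with columns
    coefficient, std_error, p_value, adj_p_value, significant, converged.
    Metabolites whose model fails to converge are excluded from the BH input
    (their adjusted p is NaN) but remain listed. The BH family size per term
    is the number of converged metabolites, recorded in ``bh_m``.
    """
    retained = detection_filter(conc, detection_threshold)
    results = []
    for entity in retained:
        sub = conc[conc["entity"] == entity]
        results.append(
            fit_metabolite_model(sub, clinical, terms, log10_response=log10_response)
        )
    if not results:
        return pd.DataFrame(
            columns=[
                "entity", "term", "coefficient", "std_error", "p_value",
                "adj_p_value", "significant", "converged", "bh_m",
            ]
        )
    table = pd.concat(results, ignore_index=True)
    table["adj_p_value"] = np.nan
    for term in terms:
        mask = (table["term"] == term) & table["converged"]
        table.loc[mask, "adj_p_value"] = adjust_bh(table.loc[mask, "p_value"].to_numpy())
        table.loc[table["term"] == term, "bh_m"] = int(mask.sum())
    table["significant"] = table["adj_p_value"] < alpha
    return table


def build_network(
    results: pd.DataFrame,
    alpha: float = ALPHA,
    *,
    highlighted_terms: Sequence[str] = HIGHLIGHTED_TERMS,
    width_range: tuple[float, float] = (0.5, 3.0),
) -> pd.DataFrame:
    """Bipartite clinical-term ↔ metabolite edges for significant results.

    One edge per (term, entity) with adjusted p below ``alpha``. ``strength``
    is log10|coefficient|; ``width`` rescales strength linearly into
    ``width_range`` for plotting (mid-range when all strengths are equal).
    Edges for the highlighted terms (albuminuria group and eGFR by default)
    carry ``highlighted=True``.
    """
    sig = results[results["significant"] == True].copy()  # noqa: E712
    if sig.empty:
        return pd.DataFrame(
            columns=[
                "term", "metabolite", "coefficient", "sign", "strength",
                "width", "adj_p_value", "highlighted",
            ]
        )
    strength = np.log10(np.abs(sig["coefficient"].to_numpy(dtype=float)))
    lo, hi = strength.min(), strength.max()
    if hi > lo:
        width = width_range[0] + (strength - lo) / (hi - lo) * (width_range[1] - width_range[0])
    else:
        width = np.full_like(strength, (width_range[0] + width_range[1]) / 2.0)
    edges = pd.DataFrame(
        {
            "term": sig["term"].to_numpy(),
            "metabolite": sig["entity"].to_numpy(),
            "coefficient": sig["coefficient"].to_numpy(),
            "sign": np.where(sig["coefficient"] >= 0, "positive", "negative"),
            "strength": strength,
            "width": width,
            "adj_p_value": sig["adj_p_value"].to_numpy(),
            "highlighted": sig["term"].isin(highlighted_terms).to_numpy(),
        }
    )
    return edges.sort_values(["term", "metabolite"], ignore_index=True)


def edges_to_networkx(edges: pd.DataFrame):
    """The edge list as a networkx bipartite graph (terms vs metabolites)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.term, bipartite="clinical")
        g.add_node(row.metabolite, bipartite="metabolite")
        g.add_edge(
            row.term,
            row.metabolite,
            sign=row.sign,
            strength=row.strength,
            width=row.width,
            highlighted=bool(row.highlighted),
            adj_p_value=row.adj_p_value,
        )
    return g
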