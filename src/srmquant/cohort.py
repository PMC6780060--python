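"""Confound-minimizing random subsample selection.

To compare metabolite levels between two patient groups in a small subset of
a larger cohort without confounding, a balanced subsample is found by pure
random search: draw many stratified subsamples (k participants per group,
uniformly without replacement within each group), score each by the highest
absolute Pearson correlation between any clinical covariate and the 0/1
group indicator over the subsample, and keep the draw with the lowest such
maximum. Binary covariates are encoded 0/1 before correlating (making r a
point-biserial/phi-type coefficient); a covariate that is constant within a
draw cannot confound the comparison and scores r = 0 with a degeneracy flag.

Ties on the maximum correlation break by draw order, so results are fully
reproducible from the seed, and the best score is non-increasing in the draw
budget for a fixed seed stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BALANCE_COVARIATES",
    "BalanceScore",
    "SubsampleResult",
    "score_subsample",
    "select_balanced_subsample",
    "balance_report",
]

#: clinical covariates screened for confounding by default
DEFAULT_BALANCE_COVARIATES = (
    "age",
    "antihypertensive_medication",
    "bmi",
    "diabetes_duration",
    "hba1c",
    "insulin_dose",
    "sex",
    "smoking",
    "sbp",
    "total_cholesterol",
    "total_triglycerides",
)


@dataclass(frozen=True)
class BalanceScore:
    per_variable_r: dict[str, float]
    max_abs_correlation: float
    degenerate: frozenset[str]


@dataclass(frozen=True)
class SubsampleResult:
    selected_ids: tuple[str, ...]
    per_variable_correlation: dict[str, float]
    max_abs_correlation: float
    degenerate: frozenset[str]
    n_draws: int
    seed: int
    best_draw_index: int


def _check_clinical(clinical: pd.DataFrame, covariates: Sequence[str]) -> None:
    if not covariates:
        raise ValueError("covariate list must be non-empty")
    if clinical["participant_id"].duplicated().any():
        raise ValueError("participant_id must be unique")
    groups = sorted(clinical["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"group must have exactly two levels, found {groups}")
    missing = [c for c in covariates if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table is missing covariates: {missing}")


def score_subsample(
    clinical: pd.DataFrame,
    ids: Iterable[str],
    covariates: Sequence[str] = DEFAULT_BALANCE_COVARIATES,
) -> BalanceScore:
    """Pearson r of each covariate against the 0/1 group indicator.

    Zero-variance covariates within the subsample score r = 0 and are
    reported in ``degenerate``.
    """
    _check_clinical(clinical, covariates)
    ids = list(ids)
    sub = clinical.set_index("participant_id").loc[ids]
    g = (sub["group"] == sorted(clinical["group"].unique())[1]).to_numpy(dtype=float)
    if g.std() == 0:
        raise ValueError("subsample contains only one group")
    per_r: dict[str, float] = {}
    degenerate: set[str] = set()
    for cov in covariates:
        x = sub[cov].to_numpy(dtype=float)
        if x.std() == 0:
            per_r[cov] = 0.0
            degenerate.add(cov)
        else:
            per_r[cov] = float(np.corrcoef(x, g)[0, 1])
    max_abs = max(abs(r) for r in per_r.values())
    return BalanceScore(
        per_variable_r=per_r,
        max_abs_correlation=max_abs,
        degenerate=frozenset(degenerate),
    )


def select_balanced_subsample(
    clinical: pd.DataFrame,
    k_per_group: int = 25,
    n_draws: int = 1_000_000,
    seed: int = 0,
    covariates: Sequence[str] = DEFAULT_BALANCE_COVARIATES,
    *,
    chunk_size: int = 4096,
) -> SubsampleResult:
    """Random-search selection of the least-confounded k+k subsample.

    Draws ``n_draws`` stratified subsamples (uniform without replacement
    within each group) and returns the one minimizing the maximum absolute
    covariate–group correlation. Scoring is vectorized over chunks of draws;
    draws are generated sequentially from one seeded stream, so the best
    score over the first m draws is reproducible and non-increasing in m.
    """
    _check_clinical(clinical, covariates)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    lo, hi = sorted(clinical["group"].unique())
    ids0 = clinical.loc[clinical["group"] == lo, "participant_id"].to_numpy()
    ids1 = clinical.loc[clinical["group"] == hi, "participant_id"].to_numpy()
    if k_per_group > min(len(ids0), len(ids1)):
        raise ValueError(
            f"k_per_group={k_per_group} exceeds a group size "
            f"({len(ids0)} vs {len(ids1)})"
        )

    X0 = clinical.loc[clinical["group"] == lo, list(covariates)].to_numpy(dtype=float)
    X1 = clinical.loc[clinical["group"] == hi, list(covariates)].to_numpy(dtype=float)
    n0, n1, k = len(ids0), len(ids1), k_per_group

    rng = np.random.default_rng(seed)
    best_score = np.inf
    best_idx0: np.ndarray | None = None
    best_idx1: np.ndarray | None = None
    best_draw = -1

    done = 0
    while done < n_draws:
        m = min(chunk_size, n_draws - done)
        # Uniform without-replacement draws via random-key argpartition (the k
        # smallest of n iid uniforms index a uniformly random k-subset). One
        # contiguous key block per draw keeps the draw sequence identical for
        # any chunking, so the best score over the first m draws is a
        # well-defined non-increasing function of the draw budget.
        keys = rng.random((m, n0 + n1))
        idx0 = np.argpartition(keys[:, :n0], k - 1, axis=1)[:, :k]
        idx1 = np.argpartition(keys[:, n0:], k - 1, axis=1)[:, :k]
        S0 = X0[idx0]  # (m, k, p)
        S1 = X1[idx1]
        m0 = S0.mean(axis=1)
        m1 = S1.mean(axis=1)
        # pooled (population) sd over the 2k subsample rows
        sq = (np.square(S0).sum(axis=1) + np.square(S1).sum(axis=1)) / (2 * k)
        mean_all = (m0 + m1) / 2.0
        var = np.maximum(sq - mean_all**2, 0.0)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(sd > 0, (m1 - m0) / (2.0 * sd), 0.0)
        scores = np.max(np.abs(r), axis=1)
        j = int(np.argmin(scores))  # argmin takes the first occurrence on ties
        if scores[j] < best_score:
            best_score = float(scores[j])
            best_idx0 = idx0[j].copy()
            best_idx1 = idx1[j].copy()
            best_draw = done + j
        done += m

    assert best_idx0 is not None and best_idx1 is not None
    selected = tuple(sorted([*ids0[best_idx0], *ids1[best_idx1]]))
    score = score_subsample(clinical, selected, covariates)
    return SubsampleResult(
        selected_ids=selected,
        per_variable_correlation=score.per_variable_r,
        max_abs_correlation=score.max_abs_correlation,
        degenerate=score.degenerate,
        n_draws=n_draws,
        seed=seed,
        best_draw_index=best_draw,
    )


def balance_report(
    result: SubsampleResult,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_BALANCE_COVARIATES,
) -> pd.DataFrame:
    """Audit table: per-covariate correlation and group means in the subsample."""
    _check_clinical(clinical, covariates)
    sub = clinical.set_index("participant_id").loc[list(result.selected_ids)]
    lo, hi = sorted(clinical["group"].unique())
    rows = []
    for cov in covariates:
        rows.append(
            {
                "covariate": cov,
                "pearson_r": result.per_variable_correlation[cov],
                "abs_r": abs(result.per_variable_correlation[cov]),
                f"mean_group_{lo}": sub.loc[sub["group"] == lo, cov].mean(),
                f"mean_group_{hi}": sub.loc[sub["group"] == hi, cov].mean(),
                "degenerate": cov in result.degenerate,
            }
        )
    report = pd.DataFrame(rows).sort_values("abs_r", ascending=False, ignore_index=True)
    report.attrs["max_abs_correlation"] = result.max_abs_correlation
    report.attrs["n_draws"] = result.n_draws
    report.attrs["seed"] = result.seed
    return report
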