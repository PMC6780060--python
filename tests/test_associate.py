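"""Association stage: detection filter, mixed models, BH, network edges."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import srmquant as sq
from srmquant.associate import (
    DEFAULT_MODEL_TERMS,
    RankDeficientDesignError,
    adjust_bh,
    build_network,
    detection_filter,
    fit_metabolite_model,
    run_association,
)
from srmquant.simulate import CohortEffectSpec, simulate_cohort, synthetic_panel

from conftest import make_clinical


def _conc_table(detected_per_sample, entity="E", n_samples=50, reps=3):
    """detected_per_sample: number of samples with at least one detected rep."""
    rows = []
    for i in range(n_samples):
        detected = i < detected_per_sample
        for rep in range(1, reps + 1):
            rows.append(
                {
                    "sample_id": f"P{i:03d}",
                    "injection_index": rep,
                    "entity": entity,
                    "concentration": 100.0 if detected else np.nan,
                    "flag": "ok" if detected else "below_lod",
                }
            )
    return pd.DataFrame(rows)


class TestDetectionFilter:
    def test_72_percent_detected_is_retained(self):
        assert detection_filter(_conc_table(36)) == ["E"]

    def test_exactly_70_percent_is_excluded(self):
        # "over 70%" is strict: 35/50 does not qualify
        assert detection_filter(_conc_table(35)) == []

    def test_fully_detected_is_retained(self):
        assert detection_filter(_conc_table(50)) == ["E"]

    def test_sample_detected_if_any_replicate_detected(self):
        conc = _conc_table(0, n_samples=10)
        conc.loc[conc.groupby("sample_id").head(1).index[:8], "flag"] = "below_lloq"
        conc.loc[conc["flag"] == "below_lloq", "concentration"] = 1.0
        assert detection_filter(conc) == ["E"]  # 8/10 samples detected via one rep


def _cohort_conc(spec, seed=0, n_entities=3):
    """Simulate a cohort and convert truth directly to a concentration table."""
    panel = synthetic_panel(n_entities)
    clinical, truth, peaks = simulate_cohort(panel, spec, seed=seed)
    rows = []
    rng = np.random.default_rng(seed + 1)
    for r in truth.concentrations.itertuples(index=False):
        for rep in (1, 2, 3):
            noise = (
                1.0 + rng.normal(0, spec.replicate_cv) if spec.replicate_cv else 1.0
            )
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "injection_index": rep,
                    "entity": r.entity,
                    "concentration": r.true_concentration * noise,
                    "flag": "ok" if r.true_concentration > 0 else "below_lod",
                }
            )
    return panel, clinical, pd.DataFrame(rows)


class TestFitMetaboliteModel:
    def test_recovers_planted_group_effect(self):
        spec = CohortEffectSpec(
            n_per_group=25, group_effect_log10=0.3, residual_sd_log10=0.2,
            replicate_cv=0.05,
        )
        panel, clinical, conc = _cohort_conc(spec, seed=0)
        ent = panel.entities()[0].name
        res = fit_metabolite_model(conc[conc["entity"] == ent], clinical)
        coef = res.loc[res["term"] == "group", "coefficient"].iloc[0]
        assert coef == pytest.approx(0.3, abs=0.1)

    def test_noise_free_recovery_is_exact_with_p_zero(self):
        spec = CohortEffectSpec(
            n_per_group=10, group_effect_log10=0.4, residual_sd_log10=1e-12,
            replicate_cv=0.0,
        )
        panel, clinical, conc = _cohort_conc(spec, seed=1)
        ent = panel.entities()[0].name
        res = fit_metabolite_model(conc[conc["entity"] == ent], clinical)
        row = res[res["term"] == "group"].iloc[0]
        assert row["coefficient"] == pytest.approx(0.4, abs=1e-6)
        assert row["p_value"] == 0.0

    def test_duplicated_covariate_raises_rank_deficiency(self):
        spec = CohortEffectSpec(n_per_group=10)
        panel, clinical, conc = _cohort_conc(spec, seed=2)
        clinical = clinical.copy()
        clinical["age_copy"] = clinical["age"]
        ent = panel.entities()[0].name
        with pytest.raises(RankDeficientDesignError, match="age_copy"):
            fit_metabolite_model(
                conc[conc["entity"] == ent],
                clinical,
                terms=list(DEFAULT_MODEL_TERMS) + ["age_copy"],
            )

    def test_replicate_collapse_equivalence(self):
        """With replicate noise -> 0, the mixed-model group coefficient equals
        OLS on participant means (all fixed effects are participant-level)."""
        import statsmodels.api as sm

        spec = CohortEffectSpec(
            n_per_group=15, group_effect_log10=0.2, residual_sd_log10=0.2,
            replicate_cv=1e-9,
        )
        panel, clinical, conc = _cohort_conc(spec, seed=3)
        ent = panel.entities()[0].name
        sub = conc[conc["entity"] == ent]
        res = fit_metabolite_model(sub, clinical)
        coef = res.loc[res["term"] == "group", "coefficient"].iloc[0]

        means = (
            sub.groupby("sample_id")["concentration"].mean().rename("c").reset_index()
        )
        merged = means.merge(clinical, left_on="sample_id", right_on="participant_id")
        X = sm.add_constant(merged[list(DEFAULT_MODEL_TERMS)].astype(float))
        ols = sm.OLS(np.log10(merged["c"]), X).fit()
        assert coef == pytest.approx(ols.params["group"], abs=1e-6)


class TestAdjustBh:
    def test_single_p_identity(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_stepup_ties_to_common_minimum(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_cap_at_one(self):
        np.testing.assert_allclose(adjust_bh([0.001, 1.0]), [0.002, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    def test_matches_statsmodels_and_invariants(self, pvals, rnd):
        p = np.asarray(pvals)
        adj = adjust_bh(p)
        _, oracle, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(len(p) * p, 1.0) + 1e-12).all()  # <= Bonferroni
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        np.testing.assert_allclose(adjust_bh(p[perm]), adj[perm], atol=1e-15)


class TestRunAssociationAndNetwork:
    def test_edges_match_significant_results(self):
        spec = CohortEffectSpec(
            n_per_group=25,
            group_effect_log10={"M01": 0.5},
            residual_sd_log10=0.15,
            replicate_cv=0.05,
        )
        panel, clinical, conc = _cohort_conc(spec, seed=4, n_entities=6)
        results = run_association(conc, clinical)
        assert results["entity"].nunique() == 6
        # BH applied within term across metabolites
        assert (results.groupby("term")["bh_m"].first() == 6).all()
        edges = build_network(results)
        assert len(edges) == int(results["significant"].sum())
        assert (results["adj_p_value"] >= results["p_value"] - 1e-15).all()
        # the planted effect must surface as a highlighted positive group edge
        planted = edges[(edges["term"] == "group") & (edges["metabolite"] == "M01")]
        assert len(planted) == 1
        assert planted["sign"].iloc[0] == "positive"
        assert bool(planted["highlighted"].iloc[0])

    def test_no_significant_results_gives_empty_edges(self):
        results = pd.DataFrame(
            {
                "entity": ["E"], "term": ["group"], "coefficient": [0.1],
                "std_error": [0.2], "p_value": [0.6], "adj_p_value": [0.9],
                "significant": [False], "converged": [True],
            }
        )
        assert len(build_network(results)) == 0

    def test_negative_egfr_edge_is_highlighted(self):
        results = pd.DataFrame(
            {
                "entity": ["E"], "term": ["egfr"], "coefficient": [-0.05],
                "std_error": [0.01], "p_value": [1e-5], "adj_p_value": [1e-4],
                "significant": [True], "converged": [True],
            }
        )
        edges = build_network(results)
        assert len(edges) == 1
        assert edges["sign"].iloc[0] == "negative"
        assert bool(edges["highlighted"].iloc[0])
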