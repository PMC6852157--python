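import itertools

import numpy as np
import pandas as pd
import pytest

from benthic_encounters.meta_analysis import (ModelStructure,
                                              bootstrap_predictions,
                                              build_meta_table,
                                              enumerate_structures,
                                              fit_structure, select_structure)


def synth_records(n=200, slope_c=0.8, slope_r=0.2, slope_t=0.0,
                  group_sd=0.5, noise_sd=0.5, n_groups=6, seed=0,
                  strategy_offsets=None):
    """Linear mixed-model generator with known fixed effects and a
    random intercept per taxonomic group."""
    rng = np.random.default_rng(seed)
    strategies = ["active-mobile", "active-static", "filter"]
    strategy = rng.choice(strategies, size=n)
    groups = rng.integers(0, n_groups, size=n)
    C = rng.normal(0, 1, n)
    R = rng.normal(0, 1, n)
    T = rng.normal(0, 1, n)
    g_eff = rng.normal(0, group_sd, n_groups)[groups]
    offs = np.zeros(n)
    if strategy_offsets:
        offs = np.array([strategy_offsets.get(s, 0.0) for s in strategy])
    y = (slope_c * C + slope_r * R + slope_t * T + g_eff + offs
         + rng.normal(0, noise_sd, n))
    return pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(n)],
        "log_capture": y, "log_max_feed": y,
        "log_consumer_mass": C, "log_resource_mass": R,
        "log_temperature": T, "strategy": strategy,
        "taxon_group": [f"tax{g}" for g in groups],
        "q": np.zeros(n),
    })


class TestEnumeration:
    def test_exactly_36_structures(self):
        assert len(enumerate_structures()) == 36

    def test_structures_pairwise_distinct(self):
        structures = enumerate_structures()
        assert len(set(structures)) == 36

    def test_marginality_closure(self):
        for s in enumerate_structures():
            for pair in s.interactions:
                assert pair <= s.mains

    def test_null_included_and_strategy_doubles(self):
        structures = enumerate_structures()
        assert ModelStructure() in structures
        with_strategy = sum(s.strategy for s in structures)
        assert with_strategy == 18

    def test_illegal_interaction_rejected(self):
        with pytest.raises(ValueError):
            ModelStructure(mains=frozenset("C"),
                           interactions=frozenset([frozenset("CR")]))

    def test_formula_rendering(self):
        s = ModelStructure(mains=frozenset("CR"),
                           interactions=frozenset([frozenset("CR")]),
                           strategy=True)
        rhs = s.formula_rhs()
        assert "log_consumer_mass" in rhs and "C(strategy)" in rhs
        assert "log_consumer_mass:log_resource_mass" in rhs


class TestFitStructure:
    def test_slope_recovery_within_confidence_intervals(self):
        hits = 0
        n_rep = 10
        struct = ModelStructure(mains=frozenset("CR"))
        for seed in range(n_rep):
            rec = synth_records(seed=seed)
            fit = fit_structure(rec, struct, "capture")
            ci = fit.result.conf_int()
            ok = (ci.loc["log_consumer_mass", 0] <= 0.8
                  <= ci.loc["log_consumer_mass", 1]
                  and ci.loc["log_resource_mass", 0] <= 0.2
                  <= ci.loc["log_resource_mass", 1])
            hits += ok
        assert hits >= 8

    def test_zero_group_variance_detected(self):
        rec = synth_records(group_sd=0.0, seed=1)
        fit = fit_structure(rec, ModelStructure(mains=frozenset("C")),
                            "capture")
        assert fit.group_sd < 0.1

    def test_null_intercept_near_grand_mean(self):
        rec = synth_records(seed=2)
        rec["log_capture"] = ((rec["log_capture"]
                               - rec["log_capture"].mean())
                              / rec["log_capture"].std())
        fit = fit_structure(rec, ModelStructure(), "capture")
        assert abs(fit.fe_params["Intercept"]) < 0.3

    def test_k_counts_fixed_effects_and_variances(self):
        rec = synth_records(seed=3)
        fit = fit_structure(rec, ModelStructure(mains=frozenset("CRT")),
                            "capture")
        # intercept + 3 slopes + group variance + residual variance
        assert fit.k == 6

    def test_single_group_rejected(self):
        rec = synth_records(n_groups=1, seed=4)
        with pytest.raises(ValueError):
            fit_structure(rec, ModelStructure(), "capture")


class TestSelection:
    def test_strong_effects_are_selected(self):
        found = 0
        for seed in range(3):
            rec = synth_records(n=150, slope_c=1.0, slope_r=0.8,
                                noise_sd=0.3, seed=seed,
                                strategy_offsets={"filter": -2.0})
            best, table = select_structure(rec, "capture")
            s = best.structure
            found += ({"C", "R"} <= set(s.mains)) and s.strategy
        assert found >= 2

    def test_pure_noise_keeps_null_competitive(self):
        rec = synth_records(slope_c=0, slope_r=0, group_sd=0.2,
                            noise_sd=1.0, seed=5)
        best, table = select_structure(rec, "capture")
        null_row = table[table["structure"] == "null"].iloc[0]
        assert null_row["delta_AICc"] < 4

    def test_table_aicc_matches_recomputation(self):
        from benthic_encounters import aicc
        rec = synth_records(n=120, seed=6)
        _, table = select_structure(rec, "capture")
        ok = table[~table["failed"]]
        for _, row in ok.head(8).iterrows():
            assert row["AICc"] == pytest.approx(
                aicc(row["loglik"], int(row["k"]), 120), rel=1e-9)


class TestBootstrapPredictions:
    def test_zero_boot_returns_point_predictions(self):
        rec = synth_records(seed=7)
        best = fit_structure(rec, ModelStructure(mains=frozenset("C"),
                                                 strategy=True), "capture")
        bands = bootstrap_predictions(best, rec, n_boot=0, seed=0, n_grid=5)
        assert np.allclose(bands["lo"], bands["fit"])
        assert np.allclose(bands["hi"], bands["fit"])

    def test_bands_contain_point_prediction(self):
        rec = synth_records(seed=8)
        best = fit_structure(rec, ModelStructure(mains=frozenset("C"),
                                                 strategy=True), "capture")
        bands = bootstrap_predictions(best, rec, n_boot=30, seed=1, n_grid=5)
        assert np.all(bands["lo"] <= bands["fit"] + 1e-12)
        assert np.all(bands["hi"] >= bands["fit"] - 1e-12)

    def test_depressed_filter_band_separates(self):
        rec = synth_records(n=240, noise_sd=0.3, group_sd=0.2, seed=9,
                            strategy_offsets={"filter": -3.0})
        best = fit_structure(rec, ModelStructure(mains=frozenset("C"),
                                                 strategy=True), "capture")
        bands = bootstrap_predictions(best, rec, n_boot=40, seed=2, n_grid=7)
        top = bands.groupby("strategy").apply(
            lambda d: d.iloc[-1], include_groups=False)
        assert top.loc["filter", "hi"] < top.loc["active-mobile", "lo"]
        assert top.loc["filter", "hi"] < top.loc["active-static", "lo"]


class TestBuildMetaTable:
    def test_joins_fits_to_covariates(self, small_meta):
        from benthic_encounters import fit_all_variants, select_response
        trials, truth = small_meta
        fits = [select_response(fit_all_variants(t, compute_se=False), t)
                for t in trials]
        records, excluded = build_meta_table(fits, trials)
        assert len(records) + excluded == len(trials)
        assert set(records["strategy"]) <= {"active-mobile", "active-static",
                                            "filter"}
        finite = records["log_capture"].dropna()
        assert np.isfinite(finite).all()

    def test_subzero_celsius_rejected_for_log_transform(self, small_meta):
        from benthic_encounters import FittedResponse, HollingParams
        trials, _ = small_meta
        t = trials[0]
        t.temperature = -1.0
        fit = FittedResponse(params=HollingParams(b=1, h=1), variant="II",
                             loglik=0, k=2, n=10, AICc=0, pair_id=t.pair_id)
        with pytest.raises(ValueError, match="arrhenius"):
            build_meta_table([fit], [t])
        # the Arrhenius axis accepts the same record
        records, _ = build_meta_table([fit], [t],
                                      temp_transform="arrhenius")
        assert len(records) == 1
        t.temperature = 15.0
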