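"""Orchestrated analyses: reports, pooling, strata, duration, sub-cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from nsaidcc import clogit
from nsaidcc.config import CodeLists, ConfounderSpec, DrugSpec, SimulationConfig
from nsaidcc.cohort import build_cohort
from nsaidcc.errors import PipelineError
from nsaidcc.runner import (DURATION_TERMS, AnalysisPlan, exposure_terms,
                            forest_frame, percentage, run_all, run_primary,
                            run_stratified, run_subcohort)


def pipeline_config(**kw):
    base = dict(
        n_persons=4000, seed=23,
        databases=("DB_A", "DB_B"),
        drugs=(
            DrugSpec("diclofenac", "M01AB05", packs=(30,), weight=0.5),
            DrugSpec("rofecoxib", "M01AH02", packs=(30,), weight=0.5),
        ),
        confounders=(
            ConfounderSpec("diabetes_mellitus", "diagnosis", "DX_DM", 0.15,
                           log_rr_event=math.log(1.8),
                           log_rr_initiation=math.log(1.3)),
            ConfounderSpec("osteoarthritis", "diagnosis", "DX_OA", 0.15,
                           log_rr_initiation=math.log(2.0)),
            ConfounderSpec("aspirin", "drug", "RX_ASPIRIN", 0.15,
                           log_rr_event=math.log(1.5), record_every_days=30),
        ),
        baseline_hazard=(((18, 130), 4e-5),),
        initiation_rate=1.5e-3,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="module")
def pipeline():
    cfg = pipeline_config()
    plan = AnalysisPlan(n_controls=5, levels=("class", "substance"),
                        strata=("sex", "age"))
    res = run_all(cfg, seed=23, plan=plan)
    return cfg, plan, res


class TestPercentages:
    @pytest.mark.parametrize("count,denom,pct", [
        (24685, 49118, 50.3),
        (97, 49118, 0.2),
        (0, 49118, 0.0),
        (14160, 49118, 28.8),
    ])
    def test_table_style_rounding(self, count, denom, pct):
        assert percentage(count, denom) == pct

    def test_report_percentages_recomputable_from_counts(self, pipeline):
        _, _, res = pipeline
        rep = res["primary_class"]["pooled"]["report"]
        frame = res["primary_class"]["pooled"]["frame"]
        n_ca = int((frame["is_case"] == 1).sum())
        n_co = int((frame["is_case"] == 0).sum())
        body = rep[rep["term"] != "past_any_reference"]
        for _, row in body.iterrows():
            assert row["pct_cases"] == percentage(row["n_cases"], n_ca)
            assert row["pct_controls"] == percentage(row["n_controls"], n_co)


class TestPrimary:
    def test_pooled_sets_equal_sum_of_databases(self, pipeline):
        _, _, res = pipeline
        pooled = res["primary_class"]["pooled"]
        per_db = res["primary_class"]["per_database"]
        assert per_db  # two databases simulated
        total = sum(blk["adjusted"].n_sets_used for blk in per_db.values()
                    if blk is not None)
        assert pooled["adjusted"].n_sets_used == total

    def test_exposure_terms_protected_from_elimination(self, pipeline):
        cfg, _, res = pipeline
        trace = res["primary_substance"]["pooled"]["trace"]
        terms = set(exposure_terms(cfg, "substance"))
        assert terms.isdisjoint({n for n, _ in trace.removed})

    def test_class_and_substance_variants_share_sets(self, pipeline):
        _, _, res = pipeline
        assert (res["primary_class"]["pooled"]["adjusted"].n_sets_used
                == res["primary_substance"]["pooled"]["adjusted"].n_sets_used)

    def test_zero_current_substance_reported_not_estimable(self):
        cfg = pipeline_config(databases=("DB_A",))
        # rofecoxib never dispensed: weight 0 via a one-drug catalogue, but
        # the report still carries a row for it
        cfg = pipeline_config(
            databases=("DB_A",),
            drugs=(DrugSpec("diclofenac", "M01AB05", packs=(30,), weight=1.0),
                   DrugSpec("rofecoxib", "M01AH02", packs=(30,), weight=0.0)),
        )
        res = run_all(cfg, seed=5, plan=AnalysisPlan(
            n_controls=5, levels=("substance",), strata=(), duration=False))
        rep = res["primary_substance"]["pooled"]["report"]
        row = rep[rep["term"] == "current_rofecoxib"].iloc[0]
        assert row["n_cases"] == 0
        assert row["adjusted_or"] is None or np.isnan(row["adjusted_or"])

    def test_empty_frame_raises(self):
        with pytest.raises(PipelineError):
            run_primary(pd.DataFrame(), ["x"], [], [])


class TestDuration:
    def test_reference_relabel_gives_reciprocal_or(self, pipeline):
        _, _, res = pipeline
        frame = res["duration"]["frame"]
        fit = clogit.fit_clogit(clogit.design_from_frame(frame, DURATION_TERMS))
        # relabel the reference from 7-29 days to <7 days
        alt = frame.copy()
        alt["duration_7_29"] = (alt["duration_cat"] == "7-29").astype(int)
        terms2 = ["duration_7_29", "duration_30_89", "duration_ge90",
                  "recent_any", "past_any"]
        fit2 = clogit.fit_clogit(clogit.design_from_frame(alt, terms2))
        if ("duration_lt7" in fit.columns and "duration_7_29" in fit2.columns
                and fit.converged and fit2.converged):
            b1 = fit.beta[fit.columns.index("duration_lt7")]
            b2 = fit2.beta[fit2.columns.index("duration_7_29")]
            assert b2 == pytest.approx(-b1, abs=1e-5)

    def test_duration_columns_partition_members(self, pipeline):
        _, _, res = pipeline
        frame = res["duration"]["frame"]
        cats = frame[["duration_lt7", "duration_30_89", "duration_ge90",
                      "recent_any", "past_any"]].sum(axis=1)
        is_ref = (frame["duration_cat"] == "7-29")
        assert ((cats == 0) == is_ref).all()
        assert cats.isin([0, 1]).all()


class TestStratified:
    def test_sex_strata_keep_sets_intact(self, pipeline):
        _, _, res = pipeline
        frame0 = res["frames"]["class"]
        usable_sets = res["primary_class"]["pooled"]["adjusted"].n_sets_used
        strat = res["stratified"]["sex"]
        assert sum(e["n_sets"] for e in strat.values()) == usable_sets
        # sex is a matching factor: no set loses members to the stratum cut
        assert all(e["n_sets_dropped"] == 0 or e["n_sets"] == 0
                   for e in strat.values())

    def test_age_strata_counts_bounded_by_total(self, pipeline):
        _, _, res = pipeline
        strat = res["stratified"]["age"]
        total = res["primary_class"]["pooled"]["adjusted"].n_sets_used
        assert sum(e["n_sets"] for e in strat.values()) <= total

    def test_covariate_stratum_may_break_sets(self, pipeline):
        cfg, _, res = pipeline
        frame0 = res["frames"]["class"]
        terms = exposure_terms(cfg, "class")
        strat = run_stratified(frame0, frame0["diabetes_mellitus"].astype(str),
                               terms, terms + ["aspirin_90d"])
        dropped = sum(e["n_sets_dropped"] for e in strat.values())
        assert dropped > 0  # diabetes varies within sets

    def test_forest_frame_layout(self, pipeline):
        cfg, _, res = pipeline
        f = forest_frame(res["stratified"]["sex"], exposure_terms(cfg, "class"))
        assert list(f.columns) == ["term", "or", "lcl", "ucl", "stratum"]
        assert set(f["stratum"]) <= {"F", "M"}
        assert (f["lcl"] <= f["or"]).all() and (f["or"] <= f["ucl"]).all()


class TestCharacteristics:
    def test_counts_and_percentages(self, pipeline):
        _, _, res = pipeline
        tab = res["characteristics"]
        assert (tab["n_cases"] >= 0).all()
        for _, row in tab.iterrows():
            assert row["pct_cases"] == percentage(row["n_cases"],
                                                  tab.attrs["n_cases"])


class TestSubcohort:
    def test_filter_restricts_to_flagged_persons(self):
        cfg = pipeline_config(databases=("DB_A",))
        res = run_subcohort(cfg, "oa_or_ra", seed=23, plan=AnalysisPlan(
            n_controls=5, levels=("class",), strata=(), duration=False))
        # every cohort member carries the osteoarthritis baseline flag
        coh = res["cohort"]
        tabs = res["tables"]
        from nsaidcc.runner import subcohort_mask
        mask = subcohort_mask(coh, tabs["diagnoses"], tabs["dispensings"],
                              "oa_or_ra")
        assert mask.all()
        full = run_all(cfg, seed=23, plan=AnalysisPlan(
            n_controls=5, levels=("class",), strata=(), duration=False))
        assert len(coh) < len(full["cohort"])

    def test_unknown_filter_raises(self, pipeline):
        _, _, res = pipeline
        with pytest.raises(PipelineError):
            run_subcohort(pipeline_config(), "weekend_warriors", seed=1)


class TestEndToEnd:
    def test_one_seed_fixes_every_report_cell(self):
        cfg = pipeline_config(n_persons=1500, databases=("DB_A",))
        plan = AnalysisPlan(n_controls=5, levels=("class",), strata=("sex",))
        r1 = run_all(cfg, seed=9, plan=plan)
        r2 = run_all(cfg, seed=9, plan=plan)
        pd.testing.assert_frame_equal(r1["primary_class"]["pooled"]["report"],
                                      r2["primary_class"]["pooled"]["report"])
        pd.testing.assert_frame_equal(r1["characteristics"],
                                      r2["characteristics"])

    def test_outputs_written(self, tmp_path):
        cfg = pipeline_config(n_persons=1500, databases=("DB_A",))
        plan = AnalysisPlan(n_controls=5, levels=("class",), strata=("sex",))
        run_all(cfg, seed=9, plan=plan, out_dir=str(tmp_path))
        for name in ("persons.csv", "enrollment.csv", "dispensings.csv",
                     "diagnoses.csv", "cohort.csv", "matched_sets.csv",
                     "covariates.csv",
                     "report_primary_class.csv", "report_duration.csv",
                     "characteristics.csv", "forest.csv",
                     "elimination_trace.csv", "run_manifest.yaml"):
            assert (tmp_path / name).exists(), name


class TestIORoundTrip:
    def test_claims_survive_csv_round_trip(self, tmp_path):
        from nsaidcc import io as io_mod
        cfg = pipeline_config(n_persons=300, databases=("DB_A",))
        from nsaidcc.simulate import simulate
        t = simulate(cfg)
        io_mod.write_claims(t, str(tmp_path))
        back = io_mod.read_claims(str(tmp_path))
        assert (back["persons"]["birth_day"].to_numpy()
                == t["persons"]["birth_day"].to_numpy()).all()
        assert (back["dispensings"]["date"].to_numpy()
                == t["dispensings"]["date"].to_numpy()).all()
        # cohorts built from disk equal cohorts built in memory
        c1 = build_cohort(t["persons"], t["enrollment"], t["dispensings"],
                          t["diagnoses"], CodeLists())
        c2 = build_cohort(back["persons"], back["enrollment"],
                          back["dispensings"], back["diagnoses"], CodeLists())
        pd.testing.assert_frame_equal(
            c1[["person_id", "entry", "exit", "exit_reason"]],
            c2[["person_id", "entry", "exit", "exit_reason"]])


class TestCLI:
    def test_simulate_build_sample_chain(self, tmp_path):
        from click.testing import CliRunner
        from nsaidcc.cli import main
        from nsaidcc.config import save_config
        cfg = pipeline_config(n_persons=800, databases=("DB_A",))
        cfg_path = tmp_path / "cfg.yaml"
        save_config(cfg, cfg_path)
        runner = CliRunner()
        out = tmp_path / "claims"
        r = runner.invoke(main, ["simulate", "--config", str(cfg_path),
                                 "--out", str(out), "--seed", "23"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["build-cohort", "--in", str(out),
                                 "--out", str(tmp_path / "cohort.csv"),
                                 "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["sample", "--in", str(out),
                                 "--cohort", str(tmp_path / "cohort.csv"),
                                 "--out", str(tmp_path / "sets.csv"),
                                 "--seed", "7", "--n-controls", "5"])
        assert r.exit_code == 0, r.output
        sets = pd.read_csv(tmp_path / "sets.csv")
        assert set(sets.columns) == {"set_id", "role", "person_id", "index_date"}
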