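"""Analysis orchestration and table-style reporting.

Primary contrast: current use of individual NSAIDs (or of the coxib/tNSAID
classes) versus past use of any NSAID as reference, estimated per database
and on the pooled case-control sets, as a matched-only and a
confounder-adjusted conditional-logistic model.  Further analyses: duration
of continuous use (reference 7-29 days), stratified refits, characteristics
tables, and sensitivity sub-cohorts (inflammatory arthropathies).

Subjects current on two or more substances are carried by a separate
"current, multiple NSAIDs" indicator so single-substance contrasts stay
uncontaminated.  Stratified refits reuse the pooled model's retained
covariates for comparability across strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clogit, exposure, sampling, simulate as simulate_mod
from ._time import age_years
from .config import CodeLists, SimulationConfig
from .covariates import (A_PRIORI, CANDIDATE, assess_covariates,
                         default_catalogue, synthetic_code_map)
from .errors import PipelineError

DEFAULT_AGE_BINS = (18, 60, 70, 80)  # 18-59, 60-69, 70-79, >=80 at index


@dataclass
class AnalysisPlan:
    levels: tuple[str, ...] = ("class", "substance")
    n_controls: int = 100
    alpha_stay: float = 0.05
    eliminate: bool = True
    per_database: bool = True
    duration: bool = True
    age_bins: tuple[int, ...] = DEFAULT_AGE_BINS
    strata: tuple[str, ...] = ("sex", "age")
    subcohorts: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# exposure design columns


def exposure_columns(members: pd.DataFrame, dispensings: pd.DataFrame,
                     config: SimulationConfig, level: str = "substance",
                     nsaid_prefix: str = "M01A") -> pd.DataFrame:
    """Exposure-state indicator columns for every matched-set member.

    Reference (all-zero) state is past use of any NSAID.  Emits
    ``current_<substance-or-class>`` columns, ``current_multiple``,
    ``recent_any``, plus duration-of-continuous-use columns
    (``duration_lt7``, ``duration_30_89``, ``duration_ge90``, reference
    7-29 days current, with ``recent_any``/``past_any`` completing the
    partition) and a ``duration_cat`` label.
    """
    nsaid = dispensings[exposure.startswith_mask(dispensings["substance"], nsaid_prefix)]
    # only set members' histories matter for classification
    nsaid = nsaid[nsaid["person_id"].isin(pd.unique(members["person_id"]))]
    pres = exposure.episodes_from_dispensings(nsaid)
    sub = exposure.stitch_episodes(pres, scope="substance")
    # stitching is associative: derive any-scope from the substance episodes
    any_epi = exposure.stitch_episodes(
        sub.rename(columns={"scope": "substance"}), scope="any")
    cls = exposure.classify_exposure_table(
        sub, any_epi, members[["person_id", "index_day"]])

    code_to_name = {d.code: d.name for d in config.drugs}
    out = members.reset_index(drop=True).copy()
    state = cls["state"].to_numpy()
    ncur = cls["n_current"].to_numpy()
    multiple = cls["current_multiple"].to_numpy()

    if level == "substance":
        labels = [code_to_name.get(t[0], t[0]) if n == 1 else None
                  for t, n in zip(cls["current_substances"], ncur)]
        level_names = [d.name for d in config.drugs]
    elif level == "class":
        labels = [exposure.drug_class_of(t[0], config.drugs) if n == 1 else None
                  for t, n in zip(cls["current_substances"], ncur)]
        level_names = ["coxib", "tNSAID"]
    else:
        raise ValueError(f"unknown level: {level!r}")

    for name in level_names:
        out[f"current_{name}"] = np.where(
            (state == "current") & ~multiple
            & (np.array([l == name for l in labels])), 1, 0)
    out["current_multiple"] = np.where((state == "current") & multiple, 1, 0)
    out["recent_any"] = np.where(state == "recent", 1, 0)
    out["exposure_state"] = state

    # duration of continuous use among current users
    dur = cls["current_duration"].to_numpy()
    cat = np.array([
        exposure.duration_category(d) if np.isfinite(d) else ""
        for d in dur])
    out["duration_cat"] = cat
    out["duration_lt7"] = (cat == "<7").astype(int)
    out["duration_30_89"] = (cat == "30-89").astype(int)
    out["duration_ge90"] = (cat == ">=90").astype(int)
    out["past_any"] = np.where(state == "past", 1, 0)
    return out


def exposure_terms(config: SimulationConfig, level: str) -> list[str]:
    if level == "substance":
        names = [d.name for d in config.drugs]
    else:
        names = ["coxib", "tNSAID"]
    return [f"current_{n}" for n in names] + ["current_multiple", "recent_any"]


DURATION_TERMS = ["duration_lt7", "duration_30_89", "duration_ge90",
                  "recent_any", "past_any"]


# ---------------------------------------------------------------------------
# reporting helpers


def percentage(count: float, denom: float) -> float:
    """Table-style percentage: 100*count/denom, half-up to 1 decimal."""
    if denom == 0:
        return 0.0
    return clogit.round_half_up(100.0 * count / denom, 1)


def _drop_unusable_sets(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep sets with their case and at least one control."""
    g = frame.groupby("set_id")
    ok = g["is_case"].transform("sum").eq(1) & g["is_case"].transform("size").ge(2)
    kept = frame[ok]
    return kept, frame.loc[~ok, "set_id"].nunique()


def _exposure_report(frame: pd.DataFrame, terms: list[str],
                     matched: clogit.FitResult | None,
                     adjusted: clogit.FitResult | None) -> pd.DataFrame:
    n_cases = int((frame["is_case"] == 1).sum())
    n_controls = int((frame["is_case"] == 0).sum())
    ms = matched.summary().set_index("term") if matched is not None else None
    asum = adjusted.summary().set_index("term") if adjusted is not None else None
    rows = [{"term": "past_any_reference", "n_cases": None, "pct_cases": None,
             "n_controls": None, "pct_controls": None,
             "matched_or": 1.0, "matched_lcl": None, "matched_ucl": None,
             "adjusted_or": 1.0, "adjusted_lcl": None, "adjusted_ucl": None}]
    for t in terms:
        ca = int(frame.loc[frame["is_case"] == 1, t].sum())
        co = int(frame.loc[frame["is_case"] == 0, t].sum())
        row = {"term": t, "n_cases": ca, "pct_cases": percentage(ca, n_cases),
               "n_controls": co, "pct_controls": percentage(co, n_controls)}
        for prefix, s in (("matched", ms), ("adjusted", asum)):
            if s is not None and t in s.index and np.isfinite(s.loc[t, "or"]):
                row[f"{prefix}_or"] = clogit.round_half_up(s.loc[t, "or"], 2)
                row[f"{prefix}_lcl"] = clogit.round_half_up(s.loc[t, "lcl"], 2)
                row[f"{prefix}_ucl"] = clogit.round_half_up(s.loc[t, "ucl"], 2)
            else:
                row[f"{prefix}_or"] = None
                row[f"{prefix}_lcl"] = None
                row[f"{prefix}_ucl"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_characteristics(frame: pd.DataFrame,
                              covariate_names: list[str]) -> pd.DataFrame:
    """Case/control counts and percentages per covariate.

    Denominators are the total case rows and total control rows; the
    percentages are recomputable from the printed counts.
    """
    n_cases = int((frame["is_case"] == 1).sum())
    n_controls = int((frame["is_case"] == 0).sum())
    rows = []
    for name in covariate_names:
        ca = int(frame.loc[frame["is_case"] == 1, name].sum())
        co = int(frame.loc[frame["is_case"] == 0, name].sum())
        rows.append({"characteristic": name,
                     "n_cases": ca, "pct_cases": percentage(ca, n_cases),
                     "n_controls": co, "pct_controls": percentage(co, n_controls)})
    out = pd.DataFrame(rows)
    out.attrs["n_cases"] = n_cases
    out.attrs["n_controls"] = n_controls
    return out


# ---------------------------------------------------------------------------
# model runs


def _fit_block(frame: pd.DataFrame, terms: list[str], a_priori: list[str],
               candidates: list[str], alpha_stay: float, eliminate: bool):
    """Matched-only and adjusted fits on one block of sets."""
    usable, n_dropped = _drop_unusable_sets(frame)
    if usable.empty:
        raise PipelineError("no usable matched sets (need a case and a control)")
    design_m = clogit.design_from_frame(usable, terms)
    matched = clogit.fit_clogit(design_m)
    cols = terms + a_priori + candidates
    design_a = clogit.design_from_frame(usable, cols)
    if eliminate and candidates:
        adjusted, trace = clogit.backward_eliminate(
            design_a, a_priori_columns=a_priori, candidate_columns=candidates,
            alpha_stay=alpha_stay)
    else:
        adjusted = clogit.fit_clogit(clogit.design_from_frame(usable, terms + a_priori))
        trace = clogit.EliminationTrace(retained=terms + a_priori)
    return {"matched": matched, "adjusted": adjusted, "trace": trace,
            "frame": usable, "n_sets_dropped": n_dropped}


def run_primary(frame: pd.DataFrame, terms: list[str], a_priori: list[str],
                candidates: list[str], alpha_stay: float = 0.05,
                per_database: bool = True, eliminate: bool = True) -> dict:
    """Per-database and pooled primary models plus a table-style report."""
    if frame.empty:
        raise PipelineError("empty matched-set frame")
    out: dict = {"per_database": {}}
    pooled = _fit_block(frame, terms, a_priori, candidates, alpha_stay, eliminate)
    pooled["report"] = _exposure_report(pooled["frame"], terms,
                                        pooled["matched"], pooled["adjusted"])
    out["pooled"] = pooled
    if per_database and frame["database"].nunique() > 1:
        for db, sub in frame.groupby("database"):
            try:
                blk = _fit_block(sub, terms, a_priori, candidates, alpha_stay, eliminate)
                blk["report"] = _exposure_report(blk["frame"], terms,
                                                 blk["matched"], blk["adjusted"])
                out["per_database"][db] = blk
            except (PipelineError, clogit.EstimationError):
                out["per_database"][db] = None
    return out


def run_duration_analysis(frame: pd.DataFrame, a_priori: list[str],
                          candidates: list[str], alpha_stay: float = 0.05,
                          eliminate: bool = True) -> dict:
    """Risk by duration of continuous use; reference: current 7-29 days."""
    res = _fit_block(frame, DURATION_TERMS, a_priori, candidates,
                     alpha_stay, eliminate)
    res["report"] = _exposure_report(res["frame"], DURATION_TERMS,
                                     res["matched"], res["adjusted"])
    return res


def run_stratified(frame: pd.DataFrame, stratum: pd.Series, terms: list[str],
                   adjusted_columns: list[str]) -> dict:
    """Adjusted refits within strata of a member-level variable.

    Sets are retained only if the case and at least one control remain in
    the stratum.  The adjusted covariate set is reused as passed (no fresh
    elimination within strata).
    """
    results: dict = {}
    covs = [c for c in adjusted_columns if c not in terms]
    for value in pd.unique(stratum):
        sub = frame[stratum.to_numpy() == value]
        usable, n_dropped = _drop_unusable_sets(sub)
        entry = {"n_sets": usable["set_id"].nunique() if len(usable) else 0,
                 "n_sets_dropped": int(n_dropped), "fit": None}
        if len(usable):
            try:
                fit = clogit.fit_clogit(
                    clogit.design_from_frame(usable, terms + covs))
                entry["fit"] = fit
            except Exception:
                pass
        results[value] = entry
    return results


def forest_frame(stratified: dict, terms: list[str]) -> pd.DataFrame:
    """Flatten stratified fits to (term, or, lcl, ucl, stratum) rows."""
    rows = []
    for stratum, entry in stratified.items():
        fit = entry.get("fit")
        if fit is None:
            continue
        s = fit.summary().set_index("term")
        for t in terms:
            if t in s.index and np.isfinite(s.loc[t, "or"]):
                rows.append({"term": t, "or": s.loc[t, "or"],
                             "lcl": s.loc[t, "lcl"], "ucl": s.loc[t, "ucl"],
                             "stratum": stratum})
    return pd.DataFrame(rows, columns=["term", "or", "lcl", "ucl", "stratum"])


# ---------------------------------------------------------------------------
# sub-cohort sensitivity analyses

SUBCOHORT_FILTERS = {
    # inflammatory arthropathies or RA pharmacotherapy
    "ra_or_ra_drugs": ("ra_inflammatory_polyarthritis", "ra_drugs"),
    # chronic arthropathies with presumably little OTC NSAID use
    "oa_or_ra": ("osteoarthritis", "ra_inflammatory_polyarthritis"),
}


def subcohort_mask(cohort: pd.DataFrame, diagnoses: pd.DataFrame,
                   dispensings: pd.DataFrame, filter_name: str,
                   catalogue=None) -> pd.Series:
    """Baseline filter flags for every cohort member (assessed at entry)."""
    if filter_name not in SUBCOHORT_FILTERS:
        raise PipelineError(f"unknown sub-cohort filter: {filter_name!r}")
    wanted = SUBCOHORT_FILTERS[filter_name]
    if catalogue is None:
        catalogue = default_catalogue(synthetic_code_map())
    specs = [s for s in catalogue if s.name in wanted]
    pseudo = cohort[["person_id"]].copy()
    pseudo["set_id"] = np.arange(len(pseudo))
    pseudo["role"] = "cohort"
    pseudo["index_day"] = cohort["entry"].to_numpy()
    flags = assess_covariates(pseudo, cohort, diagnoses, dispensings, specs)
    mask = np.zeros(len(cohort), dtype=bool)
    for s in specs:
        mask |= flags[s.name].to_numpy() == 1
    return pd.Series(mask, index=cohort.index)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_all(config: SimulationConfig, seed: int | None = None,
            plan: AnalysisPlan | None = None, out_dir: str | None = None,
            tables: dict | None = None, cohort_filter: pd.Series | None = None) -> dict:
    """simulate -> build cohort -> sample -> assess -> fit -> report.

    One seed fixes the simulation and the control sampling, hence every
    report cell.  ``tables`` may supply pre-generated claims to skip the
    simulation step (e.g. when analysing a sub-cohort of the same data).
    """
    from . import cohort as cohort_mod

    plan = plan or AnalysisPlan()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if tables is None:
        tables = simulate_mod.simulate(config, seed=seed)
    code_lists = CodeLists()
    cohort = cohort_mod.build_cohort(
        tables["persons"], tables["enrollment"], tables["dispensings"],
        tables["diagnoses"], code_lists,
        study_windows=(config.study_start, config.study_end))
    if cohort_filter is not None:
        cohort = cohort[cohort_filter.to_numpy()].reset_index(drop=True)
        if cohort.empty:
            raise PipelineError("sub-cohort filter matched nobody")
    cases = sampling.find_cases(cohort)
    sets = sampling.sample_matched_sets(cases, cohort,
                                        n_controls=plan.n_controls, seed=rng)
    if sets.empty:
        raise PipelineError("no cases observed; nothing to analyse")

    catalogue = default_catalogue(synthetic_code_map())
    cov = assess_covariates(sets, cohort, tables["diagnoses"],
                            tables["dispensings"], catalogue)
    cov["is_case"] = (cov["role"] == "case").astype(int)
    cov = cov.merge(cohort[["person_id", "database", "sex", "birth_day"]],
                    on="person_id", how="left")
    cov["age_index"] = age_years(cov["index_day"], cov["birth_day"])

    a_priori = [s.name for s in catalogue if s.tier == A_PRIORI]
    candidates = [s.name for s in catalogue if s.tier == CANDIDATE]

    results: dict = {"cohort": cohort, "cases": cases, "sets": sets,
                     "tables": tables, "covariates": cov,
                     "n_cases": sets.attrs["n_cases"],
                     "n_unmatched": sets.attrs["n_unmatched"]}
    frames = {}
    for level in plan.levels:
        frame = exposure_columns(cov, tables["dispensings"], config, level=level)
        frames[level] = frame
        terms = exposure_terms(config, level)
        results[f"primary_{level}"] = run_primary(
            frame, terms, a_priori, candidates, alpha_stay=plan.alpha_stay,
            per_database=plan.per_database, eliminate=plan.eliminate)
    results["frames"] = frames

    level0 = plan.levels[0]
    frame0 = frames[level0]
    terms0 = exposure_terms(config, level0)
    retained = results[f"primary_{level0}"]["pooled"]["trace"].retained
    adj_cols = [c for c in retained if c not in terms0]

    if plan.duration:
        results["duration"] = run_duration_analysis(
            frame0, a_priori, candidates, alpha_stay=plan.alpha_stay,
            eliminate=plan.eliminate)

    strat_results = {}
    for name in plan.strata:
        if name == "sex":
            stratum = frame0["sex"]
        elif name == "age":
            bins = list(plan.age_bins) + [200]
            labels = [f"{bins[i]}-{bins[i+1]-1}" for i in range(len(bins) - 2)]
            labels.append(f">={bins[-2]}")
            stratum = pd.cut(frame0["age_index"], bins=bins, labels=labels,
                             right=False).astype(str)
        elif name in frame0.columns:
            stratum = frame0[name].astype(str)
        else:
            continue
        strat_results[name] = run_stratified(frame0, stratum, terms0,
                                             terms0 + adj_cols)
    results["stratified"] = strat_results
    results["characteristics"] = summarize_characteristics(
        _drop_unusable_sets(frame0)[0], a_priori + candidates)

    # manifest: counts, seeds, elimination trace
    pooled0 = results[f"primary_{level0}"]["pooled"]
    results["manifest"] = {
        "seed": int(seed),
        "n_persons": int(len(tables["persons"])),
        "n_cohort": int(len(cohort)),
        "n_cases": int(sets.attrs["n_cases"]),
        "n_cases_matched": int(sets.attrs["n_matched"]),
        "n_cases_unmatched": int(sets.attrs["n_unmatched"]),
        "n_sets_used": int(pooled0["adjusted"].n_sets_used),
        "eliminated": [(c, (None if not np.isfinite(p) else float(p)))
                       for c, p in pooled0["trace"].removed],
        "not_estimable": list(pooled0["adjusted"].dropped_columns),
    }

    if out_dir is not None:
        _write_outputs(results, frames, level0, out_dir, tables)
    return results


def _write_outputs(results, frames, level0, out_dir, tables):
    import os

    import yaml

    from . import io as io_mod
    os.makedirs(out_dir, exist_ok=True)
    io_mod.write_claims(tables, out_dir)
    io_mod.write_cohort(results["cohort"], os.path.join(out_dir, "cohort.csv"))
    io_mod.write_matched_sets(results["sets"], os.path.join(out_dir, "matched_sets.csv"))
    io_mod.write_covariates(results["covariates"],
                            os.path.join(out_dir, "covariates.csv"))
    for level, frame in frames.items():
        key = f"primary_{level}"
        results[key]["pooled"]["report"].to_csv(
            os.path.join(out_dir, f"report_primary_{level}.csv"), index=False)
        results[key]["pooled"]["adjusted"].summary().to_csv(
            os.path.join(out_dir, f"fit_results_{level}.csv"), index=False)
    if "duration" in results:
        results["duration"]["report"].to_csv(
            os.path.join(out_dir, "report_duration.csv"), index=False)
    results["characteristics"].to_csv(
        os.path.join(out_dir, "characteristics.csv"), index=False)
    terms0 = [c for c in results[f"primary_{level0}"]["pooled"]["matched"].columns]
    forests = []
    for name, strat in results["stratified"].items():
        f = forest_frame(strat, terms0)
        f["variable"] = name
        forests.append(f)
    if forests:
        pd.concat(forests, ignore_index=True).to_csv(
            os.path.join(out_dir, "forest.csv"), index=False)
    trace = results[f"primary_{level0}"]["pooled"]["trace"]
    pd.DataFrame(trace.removed, columns=["removed", "wald_p"]).to_csv(
        os.path.join(out_dir, "elimination_trace.csv"), index=False)
    with open(os.path.join(out_dir, "run_manifest.yaml"), "w") as fh:
        yaml.safe_dump(results["manifest"], fh, sort_keys=False)


def run_subcohort(config: SimulationConfig, filter_name: str,
                  seed: int | None = None, plan: AnalysisPlan | None = None,
                  tables: dict | None = None) -> dict:
    """Restrict the cohort by a baseline filter, then re-run the pipeline."""
    from . import cohort as cohort_mod
    if tables is None:
        tables = simulate_mod.simulate(config, seed=config.seed if seed is None else seed)
    full = cohort_mod.build_cohort(
        tables["persons"], tables["enrollment"], tables["dispensings"],
        tables["diagnoses"], CodeLists(),
        study_windows=(config.study_start, config.study_end))
    mask = subcohort_mask(full, tables["diagnoses"], tables["dispensings"], filter_name)
    if not mask.any():
        raise PipelineError(f"sub-cohort filter {filter_name!r} matched nobody")
    return run_all(config, seed=seed, plan=plan, tables=tables,
                   cohort_filter=mask)
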