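"""Incidence-density (risk-set) sampling of matched controls.

Cases are cohort members whose follow-up ends in ischemic stroke; their
index date is the event date.  For each case, up to ``n_controls`` controls
are sampled uniformly without replacement from the risk set: cohort members
of the same database and sex whose age at cohort entry is within +/- 1 year
of the case's, who entered on or before the index date and are still at risk
(exit strictly after the index date).  A future case may serve as a control
strictly before its own index day; controls may recur across sets.  Sets
with no eligible control are emitted flagged as unmatched.

Under this sampling scheme the conditional-logistic odds ratio estimates the
incidence rate ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError

MATCH_AGE_TOL_YEARS = 1.0
DEFAULT_N_CONTROLS = 100


def find_cases(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cases: cohort members exiting with IS; index date = exit date.

    An IS on the entry day itself counts (index = entry).
    """
    cases = cohort[cohort["exit_reason"] == "IS"].copy()
    cases = cases.rename(columns={"exit": "index_day"})
    cases = cases.sort_values(["index_day", "person_id"], kind="mergesort")
    return cases[["person_id", "database", "sex", "birth_day",
                  "entry", "index_day", "age_entry"]].reset_index(drop=True)


def eligible_controls(case_row, cohort: pd.DataFrame,
                      age_tol_years: float = MATCH_AGE_TOL_YEARS) -> pd.DataFrame:
    """Brute-force eligible risk set for one case (reference for audits)."""
    idx = case_row["index_day"]
    c = cohort
    mask = (
        (c["database"] == case_row["database"])
        & (c["sex"] == case_row["sex"])
        & ((c["age_entry"] - case_row["age_entry"]).abs() <= age_tol_years + 1e-12)
        & (c["entry"] <= idx)
        & (c["exit"] > idx)
        & (c["person_id"] != case_row["person_id"])
    )
    return c[mask]


def sample_matched_sets(cases: pd.DataFrame, cohort: pd.DataFrame,
                        n_controls: int = DEFAULT_N_CONTROLS,
                        age_tol_years: float = MATCH_AGE_TOL_YEARS,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Sample matched sets; returns a long table of set members.

    Columns: ``set_id, role ('case'|'control'), person_id, index_day``.
    Unmatched sets (no eligible control) carry only their case row and are
    reported via the frame's ``attrs['n_unmatched']``.  The RNG seed is a
    required input; identical seed and inputs reproduce the sets exactly.
    """
    if n_controls < 1:
        raise ContractError("n_controls must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    age = cohort["age_entry"].to_numpy(np.float64)
    entry = cohort["entry"].to_numpy(np.int64)
    exit_ = cohort["exit"].to_numpy(np.int64)
    pid = cohort["person_id"].to_numpy()

    # pre-stratify by (database, sex) with age-sorted members; the age caliper
    # then reduces each risk-set scan to a binary-searched slice
    strat_key = (cohort["database"].astype(str) + "|" + cohort["sex"].astype(str)).to_numpy()
    strata: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key in pd.unique(strat_key):
        members = np.flatnonzero(strat_key == key)
        members = members[np.argsort(age[members], kind="stable")]
        strata[key] = (members, age[members])

    rows = {"set_id": [], "role": [], "person_id": [], "index_day": []}
    n_unmatched = 0
    cases = cases.sort_values(["index_day", "person_id"], kind="mergesort").reset_index(drop=True)
    for set_id, case in enumerate(cases.itertuples(index=False)):
        idx = case.index_day
        members, m_age = strata.get(f"{case.database}|{case.sex}",
                                    (np.array([], dtype=np.int64), np.array([])))
        lo = np.searchsorted(m_age, case.age_entry - age_tol_years - 1e-12, "left")
        hi = np.searchsorted(m_age, case.age_entry + age_tol_years + 1e-12, "right")
        cand = members[lo:hi]
        mask = (entry[cand] <= idx) & (exit_[cand] > idx) & (pid[cand] != case.person_id)
        pool = np.sort(cand[mask])
        if pool.size > n_controls:
            chosen = rng.choice(pool, size=n_controls, replace=False)
            chosen = np.sort(chosen)
        else:
            chosen = pool
        rows["set_id"].append(np.full(1 + chosen.size, set_id))
        rows["role"].append(np.concatenate([["case"], np.full(chosen.size, "control")]))
        rows["person_id"].append(np.concatenate([[case.person_id], pid[chosen]]))
        rows["index_day"].append(np.full(1 + chosen.size, idx, dtype=np.int64))
        if chosen.size == 0:
            n_unmatched += 1

    if rows["set_id"]:
        out = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
        out["set_id"] = out["set_id"].astype(np.int64)
        out["index_day"] = out["index_day"].astype(np.int64)
    else:
        out = pd.DataFrame(columns=["set_id", "role", "person_id", "index_day"])
    out.attrs["n_cases"] = len(cases)
    out.attrs["n_unmatched"] = n_unmatched
    out.attrs["n_matched"] = len(cases) - n_unmatched
    return out
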