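"""New-user NSAID cohort construction.

Eligibility for cohort entry at an NSAID dispensing on day ``d``:

* age >= 18 at ``d``,
* one enrollment span covers the whole year ``[d-365, d]``,
* no NSAID dispensing in ``[d-365, d-1]``,
* no malignant-cancer diagnosis (non-melanoma skin cancer excepted) in
  ``[d-365, d-1]``,
* ``d`` inside the (database-specific) study window.

Entry is the first qualifying dispensing; a person failing at one
dispensing may qualify at a later one.  Exit is the earliest of: study end,
first ischemic stroke on/after entry, end of the covering enrollment span,
first malignant-cancer diagnosis, death — with same-day ties broken by the
priority IS > death > cancer > disenrollment > study_end.  A prior stroke
before entry does not exclude; it becomes a history covariate.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from ._time import age_years, day
from .config import CodeLists
from .errors import DataError, SchemaError

LOOKBACK_DAYS = 365
MIN_AGE_YEARS = 18.0

DEFAULT_STUDY_WINDOW = ("1999-07-01", "2010-12-31")

#: same-day exit tie-break, most important first
EXIT_PRIORITY = ("IS", "death", "cancer", "disenrollment", "study_end")


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {missing}")


def _check_spans(enrollment: pd.DataFrame) -> None:
    e = enrollment.sort_values(["person_id", "start"], kind="mergesort")
    same = e["person_id"].to_numpy()[1:] == e["person_id"].to_numpy()[:-1]
    overlap = e["start"].to_numpy()[1:] <= e["end"].to_numpy()[:-1]
    if np.any(same & overlap):
        raise DataError("overlapping enrollment spans for at least one person")


def compute_exit(candidates: Mapping[str, int | None]) -> tuple[int, str]:
    """Earliest exit cause; ties broken by the fixed priority order.

    ``candidates`` maps reason -> day (None when the cause never occurs);
    ``study_end`` must be present.
    """
    if candidates.get("study_end") is None:
        raise ValueError("study_end exit candidate is required")
    best_day, best_reason = None, None
    for reason in EXIT_PRIORITY:
        d = candidates.get(reason)
        if d is None:
            continue
        if best_day is None or d < best_day:
            best_day, best_reason = int(d), reason
    return best_day, best_reason


def _normalise_windows(study_windows, databases) -> dict:
    if study_windows is None:
        study_windows = DEFAULT_STUDY_WINDOW
    if isinstance(study_windows, dict):
        out = {}
        for db in databases:
            lo, hi = study_windows.get(db, DEFAULT_STUDY_WINDOW)
            out[db] = (day(lo), day(hi))
        return out
    lo, hi = study_windows
    return {db: (day(lo), day(hi)) for db in databases}


def build_cohort(persons: pd.DataFrame, enrollment: pd.DataFrame,
                 dispensings: pd.DataFrame, diagnoses: pd.DataFrame,
                 code_lists: CodeLists = CodeLists(),
                 study_windows=None) -> pd.DataFrame:
    """One row per eligible new user: entry, exit and exit reason.

    Day columns are integer day numbers.  ``study_windows`` is a global
    ``(start, end)`` pair or a per-database dict; the default window is
    1999-07-01 to 2010-12-31.
    """
    _require(persons, ["person_id", "database", "sex", "birth_day"], "persons")
    _require(enrollment, ["person_id", "start", "end"], "enrollment")
    _require(dispensings, ["person_id", "substance", "date"], "dispensings")
    _require(diagnoses, ["person_id", "code", "date"], "diagnoses")
    _check_spans(enrollment)

    windows = _normalise_windows(study_windows, persons["database"].unique())
    win = persons[["person_id", "database"]].copy()
    win["win_start"] = [windows[db][0] for db in win["database"]]
    win["win_end"] = [windows[db][1] for db in win["database"]]

    from .exposure import startswith_mask
    nsaid = dispensings[
        startswith_mask(dispensings["substance"], code_lists.nsaid_prefix)
    ][["person_id", "date"]]
    if nsaid.empty:
        return pd.DataFrame(columns=["person_id", "database", "sex", "birth_day",
                                     "entry", "exit", "exit_reason", "age_entry"])

    # candidate entries: distinct (person, date) NSAID dispensing days with a
    # clean 365-day lookback (the only condition needing the full history)
    cand = nsaid.drop_duplicates().sort_values(["person_id", "date"], kind="mergesort")
    cand = cand.reset_index(drop=True)
    prev = cand.groupby("person_id")["date"].shift(1)
    clean = (prev.isna() | (cand["date"] - prev > LOOKBACK_DAYS)).to_numpy()
    cand = cand[clean].reset_index(drop=True)
    clean_lookback = pd.Series(True, index=cand.index)

    # one-to-one left merges preserve candidate order and length
    cand = cand.merge(persons[["person_id", "birth_day"]], on="person_id", how="left")
    cand = cand.merge(win[["person_id", "win_start", "win_end"]], on="person_id", how="left")
    adult = age_years(cand["date"], cand["birth_day"]) >= MIN_AGE_YEARS
    in_window = (cand["date"] >= cand["win_start"]) & (cand["date"] <= cand["win_end"])

    # one enrollment span must cover [d-365, d]
    m = cand[["person_id", "date"]].reset_index().merge(enrollment, on="person_id")
    covered_idx = m.loc[
        (m["start"] <= m["date"] - LOOKBACK_DAYS) & (m["end"] >= m["date"]), "index"
    ].unique()
    covered = pd.Series(False, index=cand.index)
    covered.loc[covered_idx] = True

    # malignant cancer (except NMSC) in the lookback year excludes
    cancer_codes = set(code_lists.cancer) - set(code_lists.nmsc)
    ca = diagnoses[diagnoses["code"].isin(cancer_codes)][["person_id", "date"]]
    if len(ca):
        mc = cand[["person_id", "date"]].reset_index().merge(
            ca.rename(columns={"date": "ca_date"}), on="person_id")
        bad_idx = mc.loc[
            (mc["ca_date"] >= mc["date"] - LOOKBACK_DAYS) & (mc["ca_date"] < mc["date"]),
            "index"].unique()
        cancer_free = pd.Series(True, index=cand.index)
        cancer_free.loc[bad_idx] = False
    else:
        cancer_free = pd.Series(True, index=cand.index)

    ok = clean_lookback.to_numpy() & adult & in_window.to_numpy() \
        & covered.to_numpy() & cancer_free.to_numpy()
    entries = cand[ok].groupby("person_id", as_index=False).first()
    if entries.empty:
        return pd.DataFrame(columns=["person_id", "database", "sex", "birth_day",
                                     "entry", "exit", "exit_reason", "age_entry"])
    entries = entries.rename(columns={"date": "entry"})[
        ["person_id", "entry", "win_end"]]

    # ---- exit ------------------------------------------------------------
    def first_dx_on_after(codes, hospital_only=False):
        dx = diagnoses[diagnoses["code"].isin(set(codes))]
        if hospital_only and "setting" in diagnoses.columns:
            dx = dx[dx["setting"] == "hospital"]
        m = entries[["person_id", "entry"]].merge(dx[["person_id", "date"]], on="person_id")
        m = m[m["date"] >= m["entry"]]
        return m.groupby("person_id")["date"].min()

    is_day = first_dx_on_after(code_lists.ischemic_stroke,
                               hospital_only=code_lists.is_hospital_only)
    death_day = first_dx_on_after(code_lists.death)
    cancer_day = first_dx_on_after(cancer_codes)

    # end of the span covering entry
    me = entries[["person_id", "entry"]].merge(enrollment, on="person_id")
    me = me[(me["start"] <= me["entry"]) & (me["end"] >= me["entry"])]
    span_end = me.groupby("person_id")["end"].min()

    idx = entries["person_id"]
    big = np.int64(2**60)

    def aligned(s: pd.Series) -> np.ndarray:
        v = s.reindex(idx).to_numpy(np.float64)
        return np.where(np.isnan(v), big, v).astype(np.int64)

    cand_days = np.column_stack([
        aligned(is_day), aligned(death_day), aligned(cancer_day),
        aligned(span_end), entries["win_end"].to_numpy(np.int64),
    ])
    # argmin is stable: first column (highest priority) wins ties
    which = np.argmin(cand_days, axis=1)
    exit_day = cand_days[np.arange(len(entries)), which]
    reason = np.array(EXIT_PRIORITY)[which]

    out = entries[["person_id", "entry"]].copy()
    out["exit"] = exit_day
    out["exit_reason"] = reason
    out = out.merge(persons[["person_id", "database", "sex", "birth_day"]], on="person_id")
    out["age_entry"] = age_years(out["entry"], out["birth_day"])
    return out[["person_id", "database", "sex", "birth_day",
                "entry", "exit", "exit_reason", "age_entry"]].reset_index(drop=True)
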