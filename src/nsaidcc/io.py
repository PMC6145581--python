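"""CSV interfaces with fixed headers and ISO-8601 dates.

Internal tables carry integer day numbers; on disk every date column is an
ISO date string.  Headers are stable contracts:

* persons.csv      person_id,database,sex,birthdate
* enrollment.csv   person_id,start,end
* dispensings.csv  person_id,substance,date,quantity_ddd,recorded_duration
* diagnoses.csv    person_id,code,date,setting
* cohort.csv       person_id,entry_date,exit_date,exit_reason
* matched_sets.csv set_id,role,person_id,index_date
"""

from __future__ import annotations

import os

import pandas as pd

from ._time import days_col, iso_col
from .errors import SchemaError


def _need(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def write_claims(tables: dict[str, pd.DataFrame], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    p = tables["persons"].copy()
    p["birthdate"] = iso_col(p.pop("birth_day").to_numpy())
    p[["person_id", "database", "sex", "birthdate"]].to_csv(
        os.path.join(out_dir, "persons.csv"), index=False)

    e = tables["enrollment"].copy()
    e["start"] = iso_col(e["start"].to_numpy())
    e["end"] = iso_col(e["end"].to_numpy())
    e[["person_id", "start", "end"]].to_csv(
        os.path.join(out_dir, "enrollment.csv"), index=False)

    d = tables["dispensings"].copy()
    if len(d):
        d["date"] = iso_col(d["date"].to_numpy())
    d = d.reindex(columns=["person_id", "substance", "date", "quantity_ddd",
                           "recorded_duration"])
    d.to_csv(os.path.join(out_dir, "dispensings.csv"), index=False)

    g = tables["diagnoses"].copy()
    if len(g):
        g["date"] = iso_col(g["date"].to_numpy())
    g = g.reindex(columns=["person_id", "code", "date", "setting"])
    g.to_csv(os.path.join(out_dir, "diagnoses.csv"), index=False)


def read_claims(in_dir: str) -> dict[str, pd.DataFrame]:
    persons = pd.read_csv(os.path.join(in_dir, "persons.csv"), dtype={"person_id": str})
    _need(persons, ["person_id", "database", "sex", "birthdate"], "persons.csv")
    persons["birth_day"] = days_col(persons.pop("birthdate"))

    enrollment = pd.read_csv(os.path.join(in_dir, "enrollment.csv"), dtype={"person_id": str})
    _need(enrollment, ["person_id", "start", "end"], "enrollment.csv")
    enrollment["start"] = days_col(enrollment["start"])
    enrollment["end"] = days_col(enrollment["end"])

    dispensings = pd.read_csv(os.path.join(in_dir, "dispensings.csv"), dtype={"person_id": str})
    _need(dispensings, ["person_id", "substance", "date", "quantity_ddd",
                        "recorded_duration"], "dispensings.csv")
    if len(dispensings):
        dispensings["date"] = days_col(dispensings["date"])

    diagnoses = pd.read_csv(os.path.join(in_dir, "diagnoses.csv"), dtype={"person_id": str})
    _need(diagnoses, ["person_id", "code", "date", "setting"], "diagnoses.csv")
    if len(diagnoses):
        diagnoses["date"] = days_col(diagnoses["date"])

    return {"persons": persons, "enrollment": enrollment,
            "dispensings": dispensings, "diagnoses": diagnoses}


def write_cohort(cohort: pd.DataFrame, path: str) -> None:
    out = cohort.copy()
    out["entry_date"] = iso_col(out["entry"].to_numpy())
    out["exit_date"] = iso_col(out["exit"].to_numpy())
    out[["person_id", "entry_date", "exit_date", "exit_reason"]].to_csv(path, index=False)


def read_cohort(path: str, persons: pd.DataFrame) -> pd.DataFrame:
    from ._time import age_years
    df = pd.read_csv(path, dtype={"person_id": str})
    _need(df, ["person_id", "entry_date", "exit_date", "exit_reason"], "cohort.csv")
    df["entry"] = days_col(df.pop("entry_date"))
    df["exit"] = days_col(df.pop("exit_date"))
    df = df.merge(persons[["person_id", "database", "sex", "birth_day"]], on="person_id")
    df["age_entry"] = age_years(df["entry"], df["birth_day"])
    return df


def write_episodes(episodes: pd.DataFrame, path: str) -> None:
    """episodes.csv: person_id,scope,substance,start,end,n_prescriptions."""
    out = episodes.copy()
    if "scope" not in out.columns:
        out["scope"] = "any"
    if "substance" not in out.columns:
        out["substance"] = out["scope"]
    out["start"] = iso_col(out["start"].to_numpy())
    out["end"] = iso_col(out["end"].to_numpy())
    out[["person_id", "scope", "substance", "start", "end",
         "n_prescriptions"]].to_csv(path, index=False)


def write_covariates(cov: pd.DataFrame, path: str) -> None:
    """covariates.csv: set_id,person_id,role plus one 0/1 column each."""
    lead = ["set_id", "person_id", "role"]
    rest = [c for c in cov.columns
            if c not in lead + ["index_day", "entry"]]
    cov[lead + rest].to_csv(path, index=False)


def write_matched_sets(sets: pd.DataFrame, path: str) -> None:
    out = sets.copy()
    out["index_date"] = iso_col(out.pop("index_day").to_numpy())
    out[["set_id", "role", "person_id", "index_date"]].to_csv(path, index=False)


def read_matched_sets(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    _need(df, ["set_id", "role", "person_id", "index_date"], "matched_sets.csv")
    df["index_day"] = days_col(df.pop("index_date"))
    return df
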