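"""Confounder indicators in their assessment windows.

Diagnosis-type covariates are assessed in the twelve months before cohort
entry (``[entry-365, entry]``); prior-use drug covariates likewise; drugs
with a potential pharmacological interaction with NSAIDs are assessed
concurrently, in the 90 days (or, for acute treatments, 30 days) before the
index date, the index day itself excluded (``[index-k, index-1]``).

The a-priori tier is always kept in adjusted models; the candidate tier is
subjected to backward elimination.  Code lists are configuration: the
synthetic stream uses one sentinel code per concept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

BASELINE = "baseline_12m_before_entry"
RX90 = "rx_90d_before_index"
RX30 = "rx_30d_before_index"

BASELINE_DAYS = 365

A_PRIORI = "a_priori"
CANDIDATE = "candidate"


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str        # "diagnosis" | "drug"
    codes: tuple[str, ...]
    window: str      # BASELINE | RX90 | RX30
    tier: str        # A_PRIORI | CANDIDATE


def _sent(kind: str, concept: str) -> tuple[str, ...]:
    prefix = "DX" if kind == "diagnosis" else "RX"
    return (f"{prefix}_{concept.upper()}",)


def default_catalogue(codes: dict[str, tuple[str, ...]] | None = None) -> list[CovariateSpec]:
    """The confounder catalogue of the primary analysis.

    A-priori risk factors (always retained): prior history of stroke, TIA,
    acute myocardial infarction, heart failure, atrial fibrillation/flutter,
    diabetes mellitus, hyperlipidemia, hypertension and smoking; prior use of
    ACE inhibitors / AT-II antagonists, calcium channel blockers,
    beta-blockers, cardiac glycosides and other antihypertensives; concurrent
    use of lipid-modifying agents, aspirin (90- and 30-day windows),
    anticoagulants and platelet aggregation inhibitors.  Candidates (tested
    by backward elimination) cover further comorbidity, lifestyle proxies and
    co-medication, including diuretics, nitrates, CYP2C9 inhibitors,
    glucocorticoids and hormonal therapy.

    ``codes`` overrides the sentinel code list of any named covariate.
    """
    specs: list[CovariateSpec] = []

    def add(name, kind, window, tier, concept=None):
        cl = _sent(kind, concept or name)
        if codes and name in codes:
            cl = tuple(codes[name])
        specs.append(CovariateSpec(name, kind, cl, window, tier))

    # a-priori: baseline diagnoses
    for name in ("stroke", "transient_ischemic_attack", "acute_myocardial_infarction",
                 "heart_failure", "atrial_fibrillation", "diabetes_mellitus",
                 "hyperlipidemia", "hypertension", "smoking"):
        add(name, "diagnosis", BASELINE, A_PRIORI)
    # a-priori: baseline (prior-use) drugs
    for name in ("ace_inhibitor_at2", "calcium_channel_blockers", "beta_blockers",
                 "cardiac_glycosides", "other_antihypertensives"):
        add(name, "drug", BASELINE, A_PRIORI)
    # a-priori: concurrent drugs
    for name in ("lipid_modifying_agents", "aspirin_90d", "anticoagulants",
                 "platelet_aggregation_inhibitors"):
        concept = name.replace("_90d", "")
        add(name, "drug", RX90, A_PRIORI, concept=concept)
    add("aspirin_30d", "drug", RX30, A_PRIORI, concept="aspirin")

    # candidates: baseline diagnoses
    for name in ("ischemic_heart_disease", "other_cardiovascular_disease",
                 "peripheral_arterial_disease", "alcohol_abuse", "obesity",
                 "other_cerebrovascular_disease", "migraine", "osteoarthritis",
                 "ra_inflammatory_polyarthritis", "chronic_liver_disease",
                 "kidney_failure", "coagulation_disorders"):
        add(name, "diagnosis", BASELINE, CANDIDATE)
    add("ra_drugs", "drug", BASELINE, CANDIDATE)
    # candidates: concurrent drugs
    for name in ("diuretics", "nitrates", "cyp2c9_inhibitors_90d", "glucocorticoids",
                 "postmenopausal_hormones", "oral_contraceptives"):
        concept = name.replace("_90d", "")
        add(name, "drug", RX90, CANDIDATE, concept=concept)
    add("cyp2c9_inhibitors_30d", "drug", RX30, CANDIDATE, concept="cyp2c9_inhibitors")

    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        raise ConfigError("covariate names must be unique")
    return specs


def synthetic_code_map() -> dict[str, tuple[str, ...]]:
    """Map catalogue names onto the sentinel codes the generator emits."""
    return {
        "diabetes_mellitus": ("DX_DM",),
        "hypertension": ("DX_HT",),
        "aspirin_90d": ("RX_ASPIRIN",),
        "aspirin_30d": ("RX_ASPIRIN",),
        "osteoarthritis": ("DX_OA",),
        "stroke": ("DX_STROKE_HX",),
    }


def assess_covariates(members: pd.DataFrame, cohort: pd.DataFrame,
                      diagnoses: pd.DataFrame, dispensings: pd.DataFrame,
                      catalogue: list[CovariateSpec] | None = None) -> pd.DataFrame:
    """Binary covariate vector for every matched-set member.

    ``members`` has ``set_id, role, person_id, index_day``; ``cohort``
    provides each member's entry day.  Returns ``members`` plus one 0/1
    column per catalogue covariate.  Baseline covariates depend only on the
    person's entry and are therefore constant across that person's sets;
    concurrent covariates vary with the index date.
    """
    if catalogue is None:
        catalogue = default_catalogue(synthetic_code_map())
    out = members.merge(cohort[["person_id", "entry"]], on="person_id", how="left")
    if out["entry"].isna().any():
        raise ConfigError("matched-set member missing from the cohort table")
    out = out.reset_index(drop=True)
    key = out.index.to_numpy()

    def flag(records: pd.DataFrame, lo: pd.Series, hi: pd.Series) -> np.ndarray:
        """1 iff the member has a record dated within [lo, hi]."""
        if records.empty:
            return np.zeros(len(out), dtype=np.int8)
        m = out[["person_id"]].assign(_k=key, _lo=lo, _hi=hi).merge(
            records[["person_id", "date"]], on="person_id")
        hit = m.loc[(m["date"] >= m["_lo"]) & (m["date"] <= m["_hi"]), "_k"].unique()
        v = np.zeros(len(out), dtype=np.int8)
        v[hit] = 1
        return v

    for spec in catalogue:
        source = diagnoses if spec.kind == "diagnosis" else dispensings
        code_col = "code" if spec.kind == "diagnosis" else "substance"
        rec = source[source[code_col].isin(set(spec.codes))]
        if spec.window == BASELINE:
            lo = out["entry"] - BASELINE_DAYS
            hi = out["entry"]
        elif spec.window == RX90:
            lo = out["index_day"] - 90
            hi = out["index_day"] - 1
        elif spec.window == RX30:
            lo = out["index_day"] - 30
            hi = out["index_day"] - 1
        else:
            raise ConfigError(f"unknown assessment window: {spec.window!r}")
        out[spec.name] = flag(rec, lo, hi)
    return out
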