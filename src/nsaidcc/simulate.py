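"""Synthetic longitudinal claims generator.

Emulates a multi-database claims population: adults with one continuous
enrollment span inside the study window, NSAID dispensing chains (initiation,
refills with configurable gaps, pack-size quantities), chronic confounders
that are recorded repeatedly while enrolled and shift both the NSAID
initiation rate (confounding by indication) and the ischemic-stroke hazard,
and an IS event process whose per-day probability is

    baseline(sex, age band) x exp(confounder log RRs + exposure-state log RR)

where the exposure state of each day (current on a substance / recent /
past-or-never) is derived with the same episode algebra the analysis uses,
so parameter recovery tests the estimator rather than convention mismatch.
Past use is the reference state (multiplier 1), as is the never-yet-exposed
person-time before first use, which the nested design never samples.

Everything is driven by one ``numpy`` Generator; identical config + seed
gives byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import exposure
from ._time import DAYS_PER_YEAR
from .config import (CANCER_CODE, DEATH_CODE, IS_CODE, NMSC_CODE,
                     SimulationConfig)
from .errors import ConfigError

_BIG = np.int64(2**40)

DISPENSING_COLUMNS = ["person_id", "substance", "date", "quantity_ddd",
                      "recorded_duration", "new_chain"]
DIAGNOSIS_COLUMNS = ["person_id", "code", "date", "setting"]


def _geometric(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    """Waiting time (>= 1 day) to the first success of a per-day Bernoulli."""
    if p <= 0:
        return np.full(n, _BIG, dtype=np.int64)
    return rng.geometric(p, size=n).astype(np.int64)


# ---------------------------------------------------------------------------
# population


def generate_population(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw persons and their enrollment spans.

    Returns ``(persons, enrollment)`` DataFrames.  ``persons`` carries, next
    to the public columns (person_id, database, sex, birth_day), internal
    simulation columns: latent censoring days (``_death_day``, ``_cancer_day``,
    ``_nmsc_day``) and one 0/1 flag per configured confounder
    (``conf_<name>``).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_persons
    if n == 0:
        persons = pd.DataFrame(columns=["person_id", "database", "sex", "birth_day"])
        enrollment = pd.DataFrame(columns=["person_id", "start", "end"])
        return persons, enrollment

    person_id = np.array([f"P{i:07d}" for i in range(n)])
    database = rng.choice(np.array(config.databases), size=n)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    lo, hi = config.age_range
    age0 = rng.uniform(lo, hi, size=n)
    birth_day = config.start_day - np.round(age0 * DAYS_PER_YEAR).astype(np.int64)

    lag = rng.integers(0, config.enrollment_lag_max_days + 1, size=n)
    start = config.start_day + lag
    start = np.minimum(start, config.end_day - 1)
    death_day = start + _geometric(rng, config.death_rate, n)
    disenroll = start + _geometric(rng, config.disenroll_rate, n)
    end = np.minimum.reduce([np.full(n, config.end_day, dtype=np.int64),
                             disenroll, death_day])
    cancer_day = start + _geometric(rng, config.cancer_rate, n)
    nmsc_day = start + _geometric(rng, config.nmsc_rate, n)

    persons = pd.DataFrame({
        "person_id": person_id,
        "database": database,
        "sex": sex,
        "birth_day": birth_day,
        "_death_day": death_day,
        "_cancer_day": cancer_day,
        "_nmsc_day": nmsc_day,
    })
    for conf in config.confounders:
        persons[f"conf_{conf.name}"] = (rng.random(n) < conf.prevalence).astype(np.int8)
    enrollment = pd.DataFrame({"person_id": person_id, "start": start, "end": end})
    return persons, enrollment


# ---------------------------------------------------------------------------
# dispensings


def _recurring_dates(rng, starts, ends, interval):
    """Record dates every ``interval`` days from a jittered first visit."""
    first = starts + rng.integers(0, interval, size=len(starts))
    counts = np.maximum(0, (ends - first) // interval + 1)
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    owner = np.repeat(np.arange(len(starts)), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    dates = np.repeat(first, counts) + offsets * interval
    return owner, dates


def generate_dispensings(persons: pd.DataFrame, enrollment: pd.DataFrame,
                         config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate NSAID dispensing chains plus co-medication dispensings.

    Chains: a per-day initiation probability (scaled per person by the
    confounder initiation effects) starts a chain; each dispensing supplies
    ``pack x DDD-per-unit`` DDD (one DDD per day), refills follow with
    probability ``refill_prob`` after a uniform end-to-fill gap.  A new chain
    can only begin after the previous one ends.  ``new_chain`` marks chain
    starts (internal column, not exported).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(persons)
    out = {k: [] for k in DISPENSING_COLUMNS}

    if n:
        span_start = enrollment["start"].to_numpy(np.int64)
        span_end = enrollment["end"].to_numpy(np.int64)
        pid = persons["person_id"].to_numpy()

        rate = np.full(n, config.initiation_rate, dtype=np.float64)
        for conf in config.confounders:
            col = f"conf_{conf.name}"
            if col in persons and conf.log_rr_initiation:
                rate *= np.exp(conf.log_rr_initiation * persons[col].to_numpy(np.float64))
        rate = np.clip(rate, 0.0, 0.5)

        weights = np.array([d.weight for d in config.drugs], dtype=np.float64)
        weights = weights / weights.sum()
        if config.substance_per_person:
            person_drug = rng.choice(len(config.drugs), size=n, p=weights)

        codes = np.array([d.code for d in config.drugs])
        ddd_per_unit = np.array([d.ddd_per_unit for d in config.drugs])

        def draw_packs(drug_idx):
            qty = np.empty(len(drug_idx), dtype=np.float64)
            for k, d in enumerate(config.drugs):
                m = drug_idx == k
                if m.any():
                    packs = np.array(d.packs, dtype=np.float64)
                    qty[m] = rng.choice(packs, size=int(m.sum())) * ddd_per_unit[k]
            return qty

        active = np.flatnonzero((rate > 0) & (span_end >= span_start))
        t_cur = span_start - 1  # day after which the next initiation wait starts
        while active.size:
            # per-person rates differ: geometric draw via uniform inversion
            u = rng.random(active.size)
            r = rate[active]
            waits = np.floor(np.log1p(-u) / np.log1p(-r)).astype(np.int64) + 1
            t_init = t_cur[active] + waits
            ok = t_init <= span_end[active]
            active = active[ok]
            t_init = t_init[ok]
            if not active.size:
                break
            if config.substance_per_person:
                drug_idx = person_drug[active]
            else:
                drug_idx = rng.choice(len(config.drugs), size=active.size, p=weights)
            # chain loop
            chain_idx = active
            chain_drug = drug_idx
            date = t_init
            first_fill = True
            last_end = t_cur.copy()
            while chain_idx.size:
                qty = draw_packs(chain_drug)
                dur = np.round(qty).astype(np.int64)
                rec = rng.random(chain_idx.size) < config.recorded_duration_prob
                recorded = np.where(rec, dur.astype(np.float64), np.nan)
                out["person_id"].append(pid[chain_idx])
                out["substance"].append(codes[chain_drug])
                out["date"].append(date)
                out["quantity_ddd"].append(qty)
                out["recorded_duration"].append(recorded)
                out["new_chain"].append(np.full(chain_idx.size, first_fill))
                end = date + dur - 1
                last_end[chain_idx] = end
                refill = rng.random(chain_idx.size) < config.refill_prob
                gap = rng.integers(config.refill_gap[0], config.refill_gap[1] + 1,
                                   size=chain_idx.size)
                nxt = end + gap
                keep = refill & (nxt <= span_end[chain_idx])
                chain_idx = chain_idx[keep]
                chain_drug = chain_drug[keep]
                date = nxt[keep]
                first_fill = False
            t_cur = np.maximum(t_cur, last_end)

        # co-medication: persistent drug-kind confounders dispense regularly
        for conf in config.confounders:
            col = f"conf_{conf.name}"
            if conf.kind != "drug" or col not in persons:
                continue
            users = np.flatnonzero(persons[col].to_numpy() == 1)
            owner, dates = _recurring_dates(
                rng, span_start[users], span_end[users], conf.record_every_days
            )
            k = len(dates)
            out["person_id"].append(pid[users][owner])
            out["substance"].append(np.full(k, conf.code))
            out["date"].append(dates)
            out["quantity_ddd"].append(np.full(k, float(conf.record_every_days)))
            out["recorded_duration"].append(np.full(k, np.nan))
            out["new_chain"].append(np.full(k, True))

    cols = {k: (np.concatenate(v) if v else np.array([])) for k, v in out.items()}
    df = pd.DataFrame(cols)
    if df.empty:
        return pd.DataFrame(columns=DISPENSING_COLUMNS)
    df["date"] = df["date"].astype(np.int64)
    df["quantity_ddd"] = df["quantity_ddd"].astype(np.float64)
    # person ids are zero-padded, so positional order equals lexicographic
    pos = pd.Index(persons["person_id"]).get_indexer(df["person_id"])
    sub_codes, _ = pd.factorize(df["substance"], sort=True)
    order = np.lexsort((sub_codes, df["date"].to_numpy(), pos))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# events


def _band_hazard(config, age):
    """Per-day baseline hazard for fractional ages (vectorised lookup)."""
    out = np.zeros(len(age), dtype=np.float64)
    for (lo, hi), h in config.baseline_hazard:
        out = np.where((age >= lo) & (age <= hi), h, out)
    # ages below the first band keep 0 hazard (children do not stroke here)
    return out


def simulate_events(persons: pd.DataFrame, enrollment: pd.DataFrame,
                    dispensings: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw IS events and emit the diagnosis stream.

    The stream contains: recurring confounder diagnoses, one cancer / NMSC /
    death record when the latent censoring day falls inside enrollment, and
    the first IS event per person, drawn from a piecewise-constant per-day
    hazard (segments bounded by exposure-state changes, age-band crossings
    and the enrollment span).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    if len(persons) == 0:
        return pd.DataFrame(columns=DIAGNOSIS_COLUMNS)

    pid = persons["person_id"].to_numpy()
    span_start = enrollment["start"].to_numpy(np.int64)
    span_end = enrollment["end"].to_numpy(np.int64)

    # recurring confounder diagnoses
    for conf in config.confounders:
        col = f"conf_{conf.name}"
        if conf.kind != "diagnosis" or col not in persons:
            continue
        users = np.flatnonzero(persons[col].to_numpy() == 1)
        owner, dates = _recurring_dates(
            rng, span_start[users], span_end[users], conf.record_every_days
        )
        frames.append(pd.DataFrame({
            "person_id": pid[users][owner], "code": conf.code,
            "date": dates, "setting": "ambulatory",
        }))

    # censoring streams
    for col, code in (("_death_day", DEATH_CODE), ("_cancer_day", CANCER_CODE),
                      ("_nmsc_day", NMSC_CODE)):
        d = persons[col].to_numpy(np.int64)
        inside = (d >= span_start) & (d <= span_end)
        frames.append(pd.DataFrame({
            "person_id": pid[inside], "code": code,
            "date": d[inside], "setting": "hospital",
        }))

    # IS events from the piecewise-constant hazard
    ev = _draw_is_events(persons, enrollment, dispensings, config, rng)
    frames.append(ev)

    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        return pd.DataFrame(columns=DIAGNOSIS_COLUMNS)
    df["date"] = df["date"].astype(np.int64)
    df = df.sort_values(["person_id", "date", "code"], kind="mergesort").reset_index(drop=True)
    return df


def _draw_is_events(persons, enrollment, dispensings, config, rng) -> pd.DataFrame:
    n = len(persons)
    pindex = pd.Index(persons["person_id"])
    span_start = enrollment["start"].to_numpy(np.int64)
    span_end = enrollment["end"].to_numpy(np.int64)
    birth = persons["birth_day"].to_numpy(np.int64)
    male = (persons["sex"].to_numpy() == "M")

    conf_mult = np.ones(n, dtype=np.float64)
    for conf in config.confounders:
        col = f"conf_{conf.name}"
        if col in persons and conf.log_rr_event:
            conf_mult *= np.exp(conf.log_rr_event * persons[col].to_numpy(np.float64))

    code_to_name = {d.code: d.name for d in config.drugs}
    nsaid = dispensings[
        exposure.startswith_mask(dispensings["substance"], "M01A")
    ] if len(dispensings) else dispensings
    deltas = []  # (person_row, day, d_logcur, d_ncur, d_nrec)

    if len(nsaid):
        pres = exposure.episodes_from_dispensings(nsaid)
        sub = exposure.stitch_episodes(pres, scope="substance")
        # stitching is associative: any-scope episodes from the substance ones
        any_epi = exposure.stitch_episodes(
            sub.rename(columns={"scope": "substance"}), scope="any")
        prow = pindex.get_indexer(sub["person_id"]).astype(np.int64)
        rr_by_code = {d.code: config.log_rr_current(d.name) for d in config.drugs}
        s_codes, s_uniq = pd.factorize(np.asarray(sub["scope"]))
        rr_uniq = np.array([rr_by_code.get(s, config.log_rr_current(s))
                            for s in s_uniq])
        logrr = rr_uniq[s_codes]
        s0 = sub["start"].to_numpy(np.int64)
        s1 = sub["end"].to_numpy(np.int64) + exposure.GRACE_DAYS + 1
        deltas.append((prow, s0, logrr, np.ones(len(sub)), np.zeros(len(sub))))
        deltas.append((prow, s1, -logrr, -np.ones(len(sub)), np.zeros(len(sub))))
        arow = pindex.get_indexer(any_epi["person_id"]).astype(np.int64)
        a1 = any_epi["end"].to_numpy(np.int64)
        deltas.append((arow, a1 + exposure.GRACE_DAYS + 1, np.zeros(len(any_epi)),
                       np.zeros(len(any_epi)), np.ones(len(any_epi))))
        deltas.append((arow, a1 + exposure.RECENT_MAX_DAYS + 1, np.zeros(len(any_epi)),
                       np.zeros(len(any_epi)), -np.ones(len(any_epi))))

    # zero-delta breakpoints: enrollment start and age-band crossings
    band_lows = sorted({lo for (lo, _hi), _h in config.baseline_hazard})
    bp_rows, bp_days = [np.arange(n)], [span_start]
    for lo in band_lows:
        d = birth + np.round(lo * DAYS_PER_YEAR).astype(np.int64)
        inside = (d > span_start) & (d <= span_end)
        bp_rows.append(np.flatnonzero(inside))
        bp_days.append(d[inside])
    bp_rows = np.concatenate(bp_rows)
    bp_days = np.concatenate(bp_days)
    z = np.zeros(len(bp_rows))
    deltas.append((bp_rows, bp_days, z, z, z))

    prow = np.concatenate([d[0] for d in deltas]).astype(np.int64)
    day = np.concatenate([d[1] for d in deltas]).astype(np.int64)
    dlog = np.concatenate([d[2] for d in deltas])
    dcur = np.concatenate([d[3] for d in deltas])
    drec = np.concatenate([d[4] for d in deltas])

    order = np.lexsort((day, prow))
    prow, day, dlog, dcur, drec = (a[order] for a in (prow, day, dlog, dcur, drec))
    cums = pd.DataFrame({"l": dlog, "c": dcur, "r": drec}).groupby(prow).cumsum()
    cum_log = cums["l"].to_numpy()
    cum_cur = cums["c"].to_numpy()
    cum_rec = cums["r"].to_numpy()

    # collapse equal (person, day): the last row carries the settled state
    nxt_differs = np.ones(len(prow), dtype=bool)
    nxt_differs[:-1] = (prow[1:] != prow[:-1]) | (day[1:] != day[:-1])
    keep = nxt_differs
    prow, day = prow[keep], day[keep]
    cum_log, cum_cur, cum_rec = cum_log[keep], cum_cur[keep], cum_rec[keep]

    # segment ends: next breakpoint - 1, else enrollment end
    seg_end = np.empty(len(prow), dtype=np.int64)
    seg_end[:-1] = np.where(prow[:-1] == prow[1:], day[1:] - 1, span_end[prow[:-1]])
    if len(prow):
        seg_end[-1] = span_end[prow[-1]]
    seg_start = np.maximum(day, span_start[prow])
    seg_end = np.minimum(seg_end, span_end[prow])
    ok = seg_end >= seg_start
    prow, seg_start, seg_end = prow[ok], seg_start[ok], seg_end[ok]
    cum_log, cum_cur, cum_rec = cum_log[ok], cum_cur[ok], cum_rec[ok]

    age = (seg_start - birth[prow]) / DAYS_PER_YEAR
    base = _band_hazard(config, age)
    base = base * np.where(male[prow], config.male_hazard_ratio, 1.0)
    state = np.where(cum_cur > 0.5, np.exp(cum_log),
                     np.where(cum_rec > 0.5, np.exp(config.log_rr_recent), 1.0))
    p = base * conf_mult[prow] * state
    if np.any(p >= 1.0):
        raise ConfigError("per-day event probability reached 1; lower the hazards")

    u = rng.random(len(p))
    with np.errstate(divide="ignore"):
        gdraw = np.where(p > 0,
                         np.floor(np.log1p(-u) / np.log1p(-np.minimum(p, 1 - 1e-12))),
                         _BIG).astype(np.int64)
    length = seg_end - seg_start + 1
    hit = gdraw < length
    ev_row = prow[hit]
    ev_day = seg_start[hit] + gdraw[hit]
    if len(ev_row) == 0:
        return pd.DataFrame(columns=DIAGNOSIS_COLUMNS)
    first = pd.Series(ev_day).groupby(ev_row).min()
    return pd.DataFrame({
        "person_id": persons["person_id"].to_numpy()[first.index.to_numpy()],
        "code": IS_CODE,
        "date": first.to_numpy(np.int64),
        "setting": "hospital",
    })


# ---------------------------------------------------------------------------
# orchestrator


def simulate(config: SimulationConfig, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Full synthetic claims run: persons, enrollment, dispensings, diagnoses."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    persons, enrollment = generate_population(config, rng)
    dispensings = generate_dispensings(persons, enrollment, config, rng)
    diagnoses = simulate_events(persons, enrollment, dispensings, config, rng)
    return {
        "persons": persons,
        "enrollment": enrollment,
        "dispensings": dispensings,
        "diagnoses": diagnoses,
    }
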