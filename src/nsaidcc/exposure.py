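"""Drug-exposure episode algebra.

Dispensings become *prescription episodes* (closed day intervals of supply:
the recorded duration wins if present, otherwise one DDD per day), episodes
are *stitched* into continuous-use episodes whenever the gap between the end
of one supply and the start of the next is less than 14 days, and exposure
at an index date is classified as

* ``current``  — a supply overlaps the index date or ended within the 14 days
  before it (end in ``[index-14, index-1]``),
* ``recent``   — the latest supply ended between 15 and 183 days before the
  index date,
* ``past``     — the latest supply ended more than 183 days before.

All intervals are closed and measured in whole days; the stitching gap is
``next.start - prev.end`` and merges when strictly below 14.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import COXIBS, DEFAULT_ATC, DrugSpec
from .errors import ContractError, DataError

#: grace period: a supply ending within this many days before index is current,
#: and gaps strictly below it are stitched.
GRACE_DAYS = 14
#: a supply ending between GRACE_DAYS+1 and RECENT_MAX_DAYS before index is recent.
RECENT_MAX_DAYS = 183

DURATION_LABELS = ("<7", "7-29", "30-89", ">=90")


def startswith_mask(values: pd.Series, prefix: str) -> np.ndarray:
    """Fast prefix test on a low-cardinality string column."""
    codes, uniq = pd.factorize(np.asarray(values))
    m = np.array([str(u).startswith(prefix) for u in uniq], dtype=bool)
    return m[codes] if len(uniq) else np.zeros(len(values), dtype=bool)


@dataclass(frozen=True)
class PrescriptionEpisode:
    person_id: str
    substance: str
    start: int  # day number
    end: int    # last supplied day, inclusive

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ContinuousUseEpisode:
    person_id: str
    scope: str  # substance name, class name, or "any"
    start: int
    end: int
    n_prescriptions: int


@dataclass(frozen=True)
class ExposureState:
    state: str  # "current" | "recent" | "past"
    current_substances: frozenset = field(default_factory=frozenset)
    current_multiple: bool = False
    recent_any: bool = False


# ---------------------------------------------------------------------------
# prescription episodes


def compute_end_date(start, quantity_ddd=None, recorded_duration=None) -> tuple[int, int]:
    """Supply interval of one dispensing: (start, last supplied day).

    The recorded prescribed duration wins when present; otherwise the
    quantity in DDD is taken as the duration, assuming one DDD per day.
    """
    if recorded_duration is not None and not (
        isinstance(recorded_duration, float) and np.isnan(recorded_duration)
    ):
        dur = int(recorded_duration)
    elif quantity_ddd is not None and not (
        isinstance(quantity_ddd, float) and np.isnan(quantity_ddd)
    ):
        dur = int(round(float(quantity_ddd)))
    else:
        raise DataError("dispensing has neither quantity nor recorded duration")
    if dur <= 0:
        raise DataError(f"non-positive supply duration: {dur}")
    start = int(start)
    return start, start + dur - 1


def episodes_from_dispensings(dispensings: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ``compute_end_date`` over a dispensing table.

    Expects columns ``person_id, substance, date`` (int day numbers) and
    ``quantity_ddd`` / ``recorded_duration`` (NaN where absent).  Returns a
    frame with ``person_id, substance, start, end``.
    """
    q = dispensings.get("quantity_ddd")
    r = dispensings.get("recorded_duration")
    q = pd.to_numeric(q, errors="coerce") if q is not None else pd.Series(np.nan, index=dispensings.index)
    r = pd.to_numeric(r, errors="coerce") if r is not None else pd.Series(np.nan, index=dispensings.index)
    dur = r.where(r.notna(), q)
    if dur.isna().any() or (dur <= 0).any():
        bad = dispensings.loc[dur.isna() | (dur <= 0)]
        raise DataError(
            f"{len(bad)} dispensing(s) with neither positive recorded duration "
            "nor positive quantity"
        )
    start = dispensings["date"].to_numpy(np.int64)
    out = pd.DataFrame(
        {
            "person_id": dispensings["person_id"].to_numpy(),
            "substance": dispensings["substance"].to_numpy(),
            "start": start,
            "end": start + np.round(dur.to_numpy(np.float64)).astype(np.int64) - 1,
        }
    )
    return out


# ---------------------------------------------------------------------------
# stitching


def stitch_episodes(episodes: pd.DataFrame, scope: str = "substance",
                    catalogue: tuple[DrugSpec, ...] | None = None) -> pd.DataFrame:
    """Merge prescription episodes into continuous-use episodes.

    ``scope`` is ``"substance"`` (stitch within person+substance), ``"class"``
    (person + coxib/tNSAID class) or ``"any"`` (person, any NSAID).  Episodes
    merge when ``next.start - prev.end < 14``; overlaps always merge; the
    merged end is the running maximum of ends.
    """
    if episodes.empty:
        base = {"person_id": [], "start": [], "end": [], "n_prescriptions": []}
        if scope != "any":
            base["scope"] = []
        return pd.DataFrame(base)
    df = episodes.copy()
    if scope == "substance":
        df["scope"] = df["substance"]
        keys = ["person_id", "scope"]
    elif scope == "class":
        df["scope"] = [drug_class_of(s, catalogue) for s in df["substance"]]
        keys = ["person_id", "scope"]
    elif scope == "any":
        keys = ["person_id"]
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    # numeric sort keys: person (and scope) codes ordered lexicographically
    pid_arr = np.asarray(df["person_id"])
    p_codes, p_uniq = pd.factorize(pid_arr)
    if scope != "any":
        s_arr = np.asarray(df["scope"])
        s_codes, s_uniq = pd.factorize(s_arr)
        order = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(),
                            s_codes, p_codes))
        gid = p_codes * (len(s_uniq) + 1) + s_codes
    else:
        order = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(), p_codes))
        gid = p_codes
    gid = gid[order]
    start = df["start"].to_numpy(np.int64)[order]
    end = df["end"].to_numpy(np.int64)[order]
    first = np.empty(len(df), dtype=bool)
    first[0] = True
    first[1:] = gid[1:] != gid[:-1]
    # running max of ends within each contiguous group (overlaps always merge):
    # adding gid * K makes the accumulated max reset at group boundaries
    K = np.int64(1) << 32
    run_end_grp = np.maximum.accumulate(end + gid * K) - gid * K
    prev_end = np.empty(len(df), dtype=np.int64)
    prev_end[1:] = run_end_grp[:-1]
    prev_end[0] = np.iinfo(np.int64).min // 2
    prev_end[first] = np.iinfo(np.int64).min // 2
    new_episode = first | (start - prev_end >= GRACE_DAYS)
    starts_idx = np.flatnonzero(new_episode)
    bounds = np.r_[starts_idx, len(df)]
    if "n_prescriptions" in df.columns:
        # re-stitching already-stitched episodes keeps prescription counts
        npres = np.add.reduceat(df["n_prescriptions"].to_numpy(np.int64)[order],
                                starts_idx)
    else:
        npres = np.diff(bounds)
    out = pd.DataFrame({
        "person_id": pid_arr[order][starts_idx],
        "start": start[starts_idx],
        "end": np.maximum.reduceat(end, starts_idx),
        "n_prescriptions": npres,
    })
    if scope != "any":
        out.insert(1, "scope", s_arr[order][starts_idx])
    return out


# ---------------------------------------------------------------------------
# classification at an index date


def classify_exposure_table(sub_episodes: pd.DataFrame, any_episodes: pd.DataFrame,
                            pairs: pd.DataFrame) -> pd.DataFrame:
    """Classify exposure for many ``(person_id, index_day)`` pairs at once.

    ``sub_episodes``/``any_episodes`` are stitched episode tables (substance
    and any-NSAID scope).  Returns one row per pair: ``state``,
    ``current_substances`` (tuple), ``current_multiple``, ``recent_any``,
    ``current_duration`` (days of the current any-NSAID continuous episode,
    truncated at index; NaN unless current).
    """
    p = pairs.reset_index(drop=True).copy()
    p["_pair"] = np.arange(len(p))

    m = p.merge(any_episodes, on="person_id", how="left")
    started = m["start"].notna() & (m["start"] <= m["index_day"])
    m = m[started]
    if len(np.unique(m["_pair"])) < len(p):
        missing = set(p["_pair"]) - set(m["_pair"])
        raise ContractError(
            f"{len(missing)} subject(s) have no NSAID episode on or before their "
            "index date; exposure classification requires a new-user history"
        )
    cur = m["end"] >= m["index_day"] - GRACE_DAYS
    g = m.groupby("_pair", sort=True)
    last_end = g["end"].max()
    current_any = cur.groupby(m["_pair"]).any()
    # duration of the current continuous episode, truncated at index
    mc = m[cur.to_numpy()]
    if len(mc):
        # the current episode is the latest-starting current one
        idxmax = mc.groupby("_pair")["start"].idxmax()
        ce = mc.loc[idxmax]
        cur_dur = pd.Series(
            np.minimum(ce["end"].to_numpy(np.int64), ce["index_day"].to_numpy(np.int64))
            - ce["start"].to_numpy(np.int64) + 1,
            index=ce["_pair"].to_numpy(),
        )
    else:
        cur_dur = pd.Series(dtype=np.float64)

    out = pd.DataFrame(index=pd.RangeIndex(len(p)))
    out["person_id"] = p["person_id"].to_numpy()
    out["index_day"] = p["index_day"].to_numpy()
    ca = current_any.reindex(out.index, fill_value=False).to_numpy()
    le = last_end.reindex(out.index).to_numpy(np.float64)
    days_since = out["index_day"].to_numpy(np.float64) - le
    recent = ~ca & (days_since >= GRACE_DAYS + 1) & (days_since <= RECENT_MAX_DAYS)
    out["state"] = np.where(ca, "current", np.where(recent, "recent", "past"))
    out["recent_any"] = recent
    out["current_duration"] = cur_dur.reindex(out.index).to_numpy(np.float64)

    # per-substance current sets
    ms = p.merge(sub_episodes, on="person_id", how="left")
    sc = (
        ms["start"].notna()
        & (ms["start"] <= ms["index_day"])
        & (ms["end"] >= ms["index_day"] - GRACE_DAYS)
    )
    ms = ms[sc]
    subs = ms.groupby("_pair")["scope"].agg(lambda s: tuple(sorted(set(s))))
    subs = subs.reindex(out.index)
    out["current_substances"] = [t if isinstance(t, tuple) else () for t in subs]
    out["n_current"] = [len(t) for t in out["current_substances"]]
    out["current_multiple"] = out["n_current"] >= 2
    return out


def classify_exposure(sub_episodes, any_episodes, index_day: int) -> ExposureState:
    """Scalar exposure classification for one person at one index date.

    Episode arguments are stitched episode frames for a single person
    (substance scope with a ``scope`` column, and any-NSAID scope).
    """
    pid = None
    for frame in (any_episodes, sub_episodes):
        if frame is not None and len(frame):
            pid = frame["person_id"].iloc[0]
            break
    if pid is None:
        raise ContractError("no episodes on or before the index date")
    pairs = pd.DataFrame({"person_id": [pid], "index_day": [int(index_day)]})
    row = classify_exposure_table(sub_episodes, any_episodes, pairs).iloc[0]
    return ExposureState(
        state=row["state"],
        current_substances=frozenset(row["current_substances"]),
        current_multiple=bool(row["current_multiple"]),
        recent_any=bool(row["recent_any"]),
    )


# ---------------------------------------------------------------------------
# duration of continuous use


def duration_category(days) -> str:
    """Categorise a continuous-use duration in days: <7, 7-29, 30-89, >=90."""
    d = int(days)
    if d < 1:
        raise ContractError(f"duration must be a positive number of days, got {d}")
    if d < 7:
        return DURATION_LABELS[0]
    if d < 30:
        return DURATION_LABELS[1]
    if d < 90:
        return DURATION_LABELS[2]
    return DURATION_LABELS[3]


def duration_category_at(episode_start: int, episode_end: int, index_day: int) -> str:
    """Category of a continuous-use episode current at ``index_day``.

    The duration is truncated at the index date: future supply cannot affect
    exposure duration at the event.
    """
    if episode_start > index_day or episode_end < index_day - GRACE_DAYS:
        raise ContractError("episode is not current at the index date")
    return duration_category(min(episode_end, index_day) - episode_start + 1)


# ---------------------------------------------------------------------------
# drug classes


def drug_class_of(substance: str, catalogue: tuple[DrugSpec, ...] | None = None) -> str:
    """coxib / tNSAID lookup by substance name or ATC-style code."""
    name = substance
    if catalogue is not None:
        for d in catalogue:
            if substance in (d.name, d.code):
                name = d.name
                break
        else:
            raise KeyError(f"substance not in catalogue: {substance!r}")
    else:
        if substance in DEFAULT_ATC:
            name = substance
        else:
            by_code = {v: k for k, v in DEFAULT_ATC.items()}
            if substance in by_code:
                name = by_code[substance]
            else:
                raise KeyError(f"unknown substance: {substance!r}")
    return "coxib" if name in COXIBS else "tNSAID"
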