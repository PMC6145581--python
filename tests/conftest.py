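import pandas as pd

from nsaidcc._time import day


def d(iso: str) -> int:
    return day(iso)



def persons_frame(rows):
    """rows: (person_id, database, sex, birth_iso)"""
    return pd.DataFrame(
        [(p, db, s, d(b)) for p, db, s, b in rows],
        columns=["person_id", "database", "sex", "birth_day"],
    )


def enrollment_frame(rows):
    """rows: (person_id, start_iso, end_iso)"""
    return pd.DataFrame(
        [(p, d(a), d(b)) for p, a, b in rows],
        columns=["person_id", "start", "end"],
    )


def dispensing_frame(rows):
    """rows: (person_id, substance, date_iso, quantity_ddd, recorded_duration)"""
    return pd.DataFrame(
        [(p, s, d(dt), q, r) for p, s, dt, q, r in rows],
        columns=["person_id", "substance", "date", "quantity_ddd",
                 "recorded_duration"],
    )


def diagnosis_frame(rows):
    """rows: (person_id, code, date_iso, setting)"""
    return pd.DataFrame(
        [(p, c, d(dt), st) for p, c, dt, st in rows],
        columns=["person_id", "code", "date", "setting"],
    )
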