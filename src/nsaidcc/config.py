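"""Simulation and study configuration.

The simulation config encodes the *study conditions*: a multi-database claims
population of adults followed over a fixed calendar window, with time-varying
NSAID exposure, chronic confounders that raise both the chance of receiving an
NSAID (confounding by indication) and the ischemic-stroke hazard, and an event
hazard multiplied by exposure-state-specific rate ratios (reference state:
past use of any NSAID).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

from ._time import day
from .errors import ConfigError

#: COX-2-selective inhibitors; every other NSAID is a traditional NSAID.
COXIBS = frozenset(
    {"celecoxib", "etoricoxib", "lumiracoxib", "rofecoxib", "valdecoxib"}
)

#: ATC-style substance codes (all NSAIDs carry the M01A prefix).
DEFAULT_ATC = {
    "diclofenac": "M01AB05",
    "ibuprofen": "M01AE01",
    "naproxen": "M01AE02",
    "ketoprofen": "M01AE03",
    "indometacin": "M01AB01",
    "ketorolac": "M01AB15",
    "piroxicam": "M01AC01",
    "meloxicam": "M01AC06",
    "nimesulide": "M01AX17",
    "celecoxib": "M01AH01",
    "rofecoxib": "M01AH02",
    "valdecoxib": "M01AH03",
    "etoricoxib": "M01AH05",
    "lumiracoxib": "M01AH06",
}

# Sentinel event/censoring codes used by the synthetic stream.
IS_CODE = "DX_IS"
DEATH_CODE = "DX_DEATH"
CANCER_CODE = "DX_CANCER"
NMSC_CODE = "DX_NMSC"


@dataclass(frozen=True)
class DrugSpec:
    """One NSAID in the catalogue.

    ``packs`` are dispensable pack sizes in units; quantity in DDD is
    ``units * ddd_per_unit``.  ``weight`` is the market-share sampling weight.
    """

    name: str
    code: str
    ddd_per_unit: float = 1.0
    packs: tuple[int, ...] = (30,)
    weight: float = 1.0

    @property
    def drug_class(self) -> str:
        return "coxib" if self.name in COXIBS else "tNSAID"


@dataclass(frozen=True)
class ConfounderSpec:
    """A chronic baseline condition or persistent co-medication.

    A flagged person receives a record (diagnosis or dispensing, depending on
    ``kind``) roughly every ``record_every_days`` while enrolled, multiplies
    the NSAID initiation rate by ``exp(log_rr_initiation)`` and the IS hazard
    by ``exp(log_rr_event)``.
    """

    name: str
    kind: str  # "diagnosis" | "drug"
    code: str
    prevalence: float
    log_rr_event: float = 0.0
    log_rr_initiation: float = 0.0
    record_every_days: int = 180


def default_drugs() -> tuple[DrugSpec, ...]:
    return (
        DrugSpec("diclofenac", DEFAULT_ATC["diclofenac"], packs=(20, 30, 60), weight=0.30),
        DrugSpec("ibuprofen", DEFAULT_ATC["ibuprofen"], packs=(20, 30, 50), weight=0.30),
        DrugSpec("naproxen", DEFAULT_ATC["naproxen"], packs=(30, 60), weight=0.20),
        DrugSpec("celecoxib", DEFAULT_ATC["celecoxib"], packs=(30, 60), weight=0.10),
        DrugSpec("rofecoxib", DEFAULT_ATC["rofecoxib"], packs=(30,), weight=0.10),
    )


def default_confounders() -> tuple[ConfounderSpec, ...]:
    # Prevalences and effect sizes chosen as typical of an elderly claims
    # population; initiation effects induce confounding by indication.
    return (
        ConfounderSpec("diabetes_mellitus", "diagnosis", "DX_DM", 0.12,
                       log_rr_event=math.log(1.8), log_rr_initiation=math.log(1.3)),
        ConfounderSpec("hypertension", "diagnosis", "DX_HT", 0.25,
                       log_rr_event=math.log(1.4), log_rr_initiation=math.log(1.2)),
        ConfounderSpec("aspirin", "drug", "RX_ASPIRIN", 0.15,
                       log_rr_event=math.log(1.6), log_rr_initiation=math.log(1.2),
                       record_every_days=30),
        ConfounderSpec("osteoarthritis", "diagnosis", "DX_OA", 0.10,
                       log_rr_event=0.0, log_rr_initiation=math.log(2.0)),
    )


#: Default per-day ischemic-stroke hazard by age band (closed bands, years).
DEFAULT_BASELINE_HAZARD = (
    ((18, 59), 2.0e-6),
    ((60, 69), 8.0e-6),
    ((70, 79), 2.0e-5),
    ((80, 130), 4.0e-5),
)


@dataclass
class SimulationConfig:
    n_persons: int = 50_000
    study_start: str = "1999-07-01"
    study_end: str = "2010-12-31"
    databases: tuple[str, ...] = ("DB_A",)
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drugs)
    confounders: tuple[ConfounderSpec, ...] = field(default_factory=default_confounders)

    female_fraction: float = 0.5
    age_range: tuple[float, float] = (18.0, 85.0)  # age at enrollment start
    enrollment_lag_max_days: int = 2000  # enrollment start uniform in [start, start+lag]

    initiation_rate: float = 1.0e-3  # per person-day, first/new prescription
    refill_prob: float = 0.6
    refill_gap: tuple[int, int] = (1, 13)  # days from supply end to next fill, uniform
    recorded_duration_prob: float = 0.3

    baseline_hazard: tuple = DEFAULT_BASELINE_HAZARD
    male_hazard_ratio: float = 1.3
    #: keys: "current:<substance name>", "recent_any"; missing keys mean 0.
    log_rate_ratios: dict = field(default_factory=dict)

    disenroll_rate: float = 2.0e-4  # per person-day
    cancer_rate: float = 3.0e-5
    nmsc_rate: float = 1.0e-5
    death_rate: float = 5.0e-5

    substance_per_person: bool = True  # each person sticks to one NSAID
    seed: int = 0

    # -- helpers ---------------------------------------------------------
    @property
    def start_day(self) -> int:
        return day(self.study_start)

    @property
    def end_day(self) -> int:
        return day(self.study_end)

    def drug_by_name(self, name: str) -> DrugSpec:
        for d in self.drugs:
            if d.name == name or d.code == name:
                return d
        raise ConfigError(f"unknown substance: {name!r}")

    def log_rr_current(self, name: str) -> float:
        return float(self.log_rate_ratios.get(f"current:{name}", 0.0))

    @property
    def log_rr_recent(self) -> float:
        return float(self.log_rate_ratios.get("recent_any", 0.0))

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be >= 0")
        if self.start_day >= self.end_day:
            raise ConfigError("study_start must precede study_end")
        if not self.databases:
            raise ConfigError("at least one database label required")
        for p, what in (
            (self.female_fraction, "female_fraction"),
            (self.initiation_rate, "initiation_rate"),
            (self.refill_prob, "refill_prob"),
            (self.recorded_duration_prob, "recorded_duration_prob"),
            (self.disenroll_rate, "disenroll_rate"),
            (self.cancer_rate, "cancer_rate"),
            (self.nmsc_rate, "nmsc_rate"),
            (self.death_rate, "death_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{what} must be a probability in [0, 1]")
        if not self.drugs:
            raise ConfigError("drug catalogue is empty")
        for d in self.drugs:
            if d.ddd_per_unit <= 0:
                raise ConfigError(f"{d.name}: DDD-per-unit must be > 0")
            if not d.packs or any(p <= 0 for p in d.packs):
                raise ConfigError(f"{d.name}: pack sizes must be positive")
            if not d.code.startswith("M01A"):
                raise ConfigError(f"{d.name}: NSAID codes must carry the M01A prefix")
        for c in self.confounders:
            if not 0.0 <= c.prevalence <= 1.0:
                raise ConfigError(f"{c.name}: prevalence must be in [0, 1]")
            if c.kind not in ("diagnosis", "drug"):
                raise ConfigError(f"{c.name}: kind must be diagnosis or drug")
        if self.refill_gap[0] < 1 or self.refill_gap[1] < self.refill_gap[0]:
            raise ConfigError("refill_gap must satisfy 1 <= lo <= hi")
        # probability overflow: per-day event probability must stay below 1
        # under the most hazardous attainable state.
        max_base = max(h for _, h in self.baseline_hazard) * max(1.0, self.male_hazard_ratio)
        max_state = max(
            [self.log_rr_recent, 0.0]
            + [self.log_rr_current(d.name) for d in self.drugs]
        )
        max_conf = sum(max(0.0, c.log_rr_event) for c in self.confounders)
        if max_base * math.exp(max_state + max_conf) >= 1.0:
            raise ConfigError(
                "baseline hazard times the maximal rate-ratio product reaches 1 "
                "per day; event probabilities would overflow"
            )


@dataclass(frozen=True)
class CodeLists:
    """Outcome/censoring code lists used by cohort construction.

    Code lists are configuration, not code: real terminologies are replaced
    by sentinel codes in the synthetic stream.
    """

    nsaid_prefix: str = "M01A"
    ischemic_stroke: tuple[str, ...] = (IS_CODE,)
    cancer: tuple[str, ...] = (CANCER_CODE,)
    nmsc: tuple[str, ...] = (NMSC_CODE,)
    death: tuple[str, ...] = (DEATH_CODE,)
    #: IS is operationalised as a hospital discharge diagnosis.
    is_hospital_only: bool = True


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["drugs"] = [dataclasses.asdict(x) for x in cfg.drugs]
    d["confounders"] = [dataclasses.asdict(x) for x in cfg.confounders]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "drugs" in d:
        d["drugs"] = tuple(
            DrugSpec(**{**x, "packs": tuple(x.get("packs", (30,)))}) for x in d["drugs"]
        )
    if "confounders" in d:
        d["confounders"] = tuple(ConfounderSpec(**x) for x in d["confounders"])
    for key in ("databases",):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("age_range", "refill_gap"):
        if key in d:
            d[key] = tuple(d[key])
    if "baseline_hazard" in d:
        d["baseline_hazard"] = tuple(
            (tuple(band), float(h)) for band, h in d["baseline_hazard"]
        )
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
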