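"""Timeline of the episodic thermoneutral / heat-stress growth experiment.

The experiment alternates thermoneutral (TN) and 4-day heat-stress (HS)
periods over 52 days: TN1, HS1, TN2, HS2, TN3, HS3, TN4.  Body weight is
weighed one day before each period boundary; backfat and loin-eye area are
scanned at the end of TN1 and TN4; pigs are slaughtered three days after
TN4.  Everything downstream (phenotype derivation, mixed models) is driven
by the schedule objects defined here.

Day coordinates are 1-based experiment days.  Periods are half-open
``[start, end)`` so that ``span == end - start`` and the printed "(d 8-20)"
interval of TN1 has span 12.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

TN = "TN"
HS = "HS"

#: Printed net-energy / metabolisable-energy contents (kcal/kg, as-is) of the
#: four experimental diets; used only as constants.
DIET_ENERGY = {
    ("commercial", "low_fiber"): {"ne_kcal_kg": 2590.0, "me_kcal_kg": 3358.0},
    ("commercial", "high_fiber"): {"ne_kcal_kg": 2534.0, "me_kcal_kg": 3372.0},
    ("rfi", "low_fiber"): {"ne_kcal_kg": 2604.0, "me_kcal_kg": 3358.0},
    ("rfi", "high_fiber"): {"ne_kcal_kg": 2603.0, "me_kcal_kg": 3447.0},
}

#: Room climate targets (mean, SD) for temperature (degC) and relative
#: humidity (%) under each condition, used by the default climate-log
#: generator.
CLIMATE_TARGETS = {
    (1, TN): {"t": (21.9, 1.1), "rh": (71.1, 6.1)},
    (2, TN): {"t": (23.3, 1.1), "rh": (73.1, 5.5)},
    (1, HS): {"t": (31.8, 2.1), "rh": (55.6, 8.6)},
    (2, HS): {"t": (31.8, 1.8), "rh": (61.3, 7.5)},
}


class ScheduleError(ValueError):
    """Invalid period layout or schedule parameters."""


def diet_ne_me_ratio(line_group: str, fiber: str) -> float:
    """NE:ME ratio of a diet from its printed energy contents.

    ``line_group`` is ``"commercial"`` or ``"rfi"``; ``fiber`` is
    ``"low_fiber"`` or ``"high_fiber"``.
    """
    e = DIET_ENERGY[(line_group, fiber)]
    return e["ne_kcal_kg"] / e["me_kcal_kg"]


@dataclass(frozen=True)
class PeriodSpec:
    """One TN or HS period: half-open day interval ``[start_day, end_day)``."""

    label: str
    climate: str
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.end_day <= self.start_day:
            raise ScheduleError(
                f"period {self.label}: end_day {self.end_day} must exceed "
                f"start_day {self.start_day}"
            )
        if self.climate not in (TN, HS):
            raise ScheduleError(f"period {self.label}: climate must be TN or HS")

    @property
    def span(self) -> int:
        return self.end_day - self.start_day

    @property
    def days(self) -> range:
        return range(self.start_day, self.end_day)


@dataclass
class ExperimentSchedule:
    """Ordered TN/HS periods plus measurement-day conventions."""

    periods: list[PeriodSpec]
    bw_days: list[int]
    scan_days: tuple[int, int]
    slaughter_day: int
    adaptation_span: tuple[int, int] = (1, 8)

    def __post_init__(self):
        self.bw_days = sorted(int(d) for d in self.bw_days)
        self.scan_days = tuple(int(d) for d in self.scan_days)
        prev_end = None
        prev_climate = None
        for p in self.periods:
            if prev_end is not None:
                if p.start_day != prev_end:
                    raise ScheduleError(
                        f"periods must tile contiguously; {p.label} starts at "
                        f"{p.start_day}, previous ended at {prev_end}"
                    )
                if prev_climate == p.climate:
                    raise ScheduleError("periods must alternate TN and HS")
            prev_end = p.end_day
            prev_climate = p.climate
        for b in self.boundary_days:
            near = min(abs(b - d) for d in self.bw_days) if self.bw_days else 99
            if near > 1:
                raise ScheduleError(
                    f"no measured BW within 1 day of period boundary day {b}"
                )

    # -- convenience views -------------------------------------------------

    @property
    def boundary_days(self) -> list[int]:
        """All period start/end days, in order, without duplicates."""
        out = [self.periods[0].start_day]
        out.extend(p.end_day for p in self.periods)
        return out

    @property
    def estimated_bw_days(self) -> list[int]:
        """Boundary days with no measured BW (filled by the phenotype stage)."""
        measured = set(self.bw_days)
        return [d for d in self.boundary_days if d not in measured]

    @property
    def hs_cycles(self) -> list[str]:
        return [p.label for p in self.periods if p.climate == HS]

    def period(self, label: str) -> PeriodSpec:
        for p in self.periods:
            if p.label == label:
                return p
        raise KeyError(label)

    def tn_hs_pairs(self) -> list[tuple[str, str]]:
        """(TN, following HS) period-label pairs, one per HS cycle."""
        pairs = []
        for i, p in enumerate(self.periods[:-1]):
            nxt = self.periods[i + 1]
            if p.climate == TN and nxt.climate == HS:
                pairs.append((p.label, nxt.label))
        return pairs

    def climate_of_day(self, day: int) -> str | None:
        for p in self.periods:
            if p.start_day <= day < p.end_day:
                return p.climate
        return None

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "periods": [
                {
                    "label": p.label,
                    "climate": p.climate,
                    "start_day": p.start_day,
                    "end_day": p.end_day,
                }
                for p in self.periods
            ],
            "bw_days": list(self.bw_days),
            "scan_days": list(self.scan_days),
            "slaughter_day": self.slaughter_day,
            "adaptation_span": list(self.adaptation_span),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSchedule":
        return cls(
            periods=[PeriodSpec(**p) for p in d["periods"]],
            bw_days=d["bw_days"],
            scan_days=tuple(d["scan_days"]),
            slaughter_day=d["slaughter_day"],
            adaptation_span=tuple(d.get("adaptation_span", (1, 8))),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentSchedule":
        return cls.from_dict(yaml.safe_load(text))


def build_default_schedule() -> ExperimentSchedule:
    """The study's seven-period layout.

    TN1 [8,20), HS1 [20,24), TN2 [24,31), HS2 [31,35), TN3 [35,42),
    HS3 [42,46), TN4 [46,53); BW weighed on days 1, 8, 19, 23, 30, 34, 41,
    45 and 52; ultrasound scans on days 19 and 52; slaughter on day 55.
    """
    return build_custom_schedule(n_cycles=3, tn_span=7, hs_span=4, tn1_span=12)


def build_custom_schedule(
    n_cycles: int, tn_span: int = 7, hs_span: int = 4, tn1_span: int = 12
) -> ExperimentSchedule:
    """Alternating TN/HS schedule with ``n_cycles`` HS periods.

    TN1 starts on day 8 (after the d1-8 adaptation span) and lasts
    ``tn1_span`` days; each HS period lasts ``hs_span`` days and each
    recovery TN period ``tn_span`` days.  Measured BW days sit one day
    before each period boundary, mirroring the default convention; days 1
    and 8 are always measured.
    """
    if n_cycles < 0:
        raise ScheduleError("n_cycles must be >= 0")
    for name, v in (("tn_span", tn_span), ("hs_span", hs_span), ("tn1_span", tn1_span)):
        if v < 1:
            raise ScheduleError(f"{name} must be a positive number of days")
    start = 8
    periods = [PeriodSpec("TN1", TN, start, start + tn1_span)]
    day = start + tn1_span
    for c in range(1, n_cycles + 1):
        periods.append(PeriodSpec(f"HS{c}", HS, day, day + hs_span))
        day += hs_span
        periods.append(PeriodSpec(f"TN{c + 1}", TN, day, day + tn_span))
        day += tn_span
    bw_days = sorted({1, start} | {p.end_day - 1 for p in periods})
    scan_days = (periods[0].end_day - 1, periods[-1].end_day - 1)
    return ExperimentSchedule(
        periods=periods,
        bw_days=bw_days,
        scan_days=scan_days,
        slaughter_day=periods[-1].end_day + 2,
    )


def summarize_climate(
    log: pd.DataFrame, schedule: ExperimentSchedule
) -> pd.DataFrame:
    """Per-room, per-climate mean and sample SD of temperature and RH.

    ``log`` columns: ``room, day, temperature_c, rh_pct``.  Only days inside
    TN or HS periods contribute; a missing room-day raises a warning and is
    excluded from the averages.
    """
    log = log.copy()
    log["climate"] = [schedule.climate_of_day(d) for d in log["day"]]
    log = log[log["climate"].notna()]
    period_days = {d for p in schedule.periods for d in p.days}
    for room in sorted(log["room"].unique()):
        have = set(log.loc[log["room"] == room, "day"])
        missing = sorted(period_days - have)
        if missing:
            warnings.warn(
                f"room {room}: no climate record for days {missing}; "
                "excluded from summary",
                stacklevel=2,
            )
    out = (
        log.groupby(["room", "climate"])
        .agg(
            t_mean=("temperature_c", "mean"),
            t_sd=("temperature_c", lambda s: s.std(ddof=1)),
            rh_mean=("rh_pct", "mean"),
            rh_sd=("rh_pct", lambda s: s.std(ddof=1)),
            n_days=("day", "size"),
        )
        .reset_index()
    )
    return out


def default_climate_log(
    schedule: ExperimentSchedule, seed: int = 0
) -> pd.DataFrame:
    """Synthetic daily room-climate log matching the study's summary values."""
    rng = np.random.default_rng(seed)
    rows = []
    for room in (1, 2):
        for p in schedule.periods:
            tgt = CLIMATE_TARGETS[(room, p.climate)]
            for day in p.days:
                rows.append(
                    {
                        "room": room,
                        "day": day,
                        "temperature_c": rng.normal(*tgt["t"]),
                        "rh_pct": float(np.clip(rng.normal(*tgt["rh"]), 0, 100)),
                    }
                )
    return pd.DataFrame(rows)


def read_climate_log(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    expected = ["room", "day", "temperature_c", "rh_pct"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"climate log missing columns {missing}")
    bad = df[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)]
    if len(bad):
        raise ValueError("relative humidity outside [0, 100]")
    return df


def write_climate_log(df: pd.DataFrame, path_or_buf) -> None:
    df.to_csv(path_or_buf, index=False)
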