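"""Core data structures and CSV schemas for pelleted-seed emergence trials.

The experimental unit is the *seed lot*: one species × provenance combination
sown under two treatments (bare seed vs pellet), each treatment arm consisting
of ``n_replicates`` replicates of ``seeds_per_replicate`` grouped seeds. A
replicate is scored as emerged on the first weekly census at which any of its
seeds has produced a seedling; post-emergence survival is recorded only for
emerged replicates.

This module also embeds the published per-lot performance table as a packaged
fixture (``data/table1.csv``) and provides the exact inversion of printed,
integer-rounded percentages back to counts, which is what makes the published
summary table usable as test data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GROWTH_FORMS",
    "TREATMENTS",
    "DORMANCY_TREATMENTS",
    "TrialDataError",
    "CensusSchedule",
    "SeedLot",
    "ReplicateRecord",
    "ArmMetrics",
    "Table1Row",
    "counts_from_percent",
    "percent_from_count",
    "load_replicate_csv",
    "write_replicate_csv",
    "records_to_frame",
    "frame_to_records",
    "load_table1_fixture",
    "table1_frame",
]

GROWTH_FORMS = frozenset({"tree", "shrub", "herb", "graminoid"})
TREATMENTS = ("bare", "pellet")
DORMANCY_TREATMENTS = frozenset({"none", "hot_water", "scarification", "smoke_water"})

REPLICATE_COLUMNS = [
    "species",
    "provenance",
    "growth_form",
    "treatment",
    "replicate_id",
    "emergence_day",
    "survived",
]


class TrialDataError(ValueError):
    """Raised when trial data violate the schema or an invariant."""


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def counts_from_percent(pct: float, n: int) -> int:
    """Recover an integer count from a rounded percentage.

    Returns ``round(pct * n / 100)`` (half-up). When ``pct`` was produced by
    integer-rounding the true percentage ``100 * c / n`` and ``n < 100``, the
    recovery is exact: the rounding error on the percentage is at most 0.5
    point, which maps back to an error of at most ``n / 200 < 0.5`` counts.
    """
    if not 0 <= pct <= 100:
        raise TrialDataError(f"percentage {pct!r} outside [0, 100]")
    if n < 1:
        raise TrialDataError(f"denominator {n!r} must be >= 1")
    return _round_half_up(pct * n / 100)


def percent_from_count(count: int, n: int) -> int:
    """Integer-rounded (half-up) percentage ``100 * count / n``."""
    if n < 1:
        raise TrialDataError(f"denominator {n!r} must be >= 1")
    if not 0 <= count <= n:
        raise TrialDataError(f"count {count!r} outside [0, {n}]")
    return _round_half_up(100 * count / n)


@dataclass(frozen=True)
class CensusSchedule:
    """Ordered census days (days after sowing) and the trial end day.

    The study design scores emergence weekly for 18 weeks: census days
    7, 14, ..., 126, with the trial closing on day 126.
    """

    census_days: tuple[int, ...] = tuple(range(7, 127, 7))
    trial_end_day: int = 126

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.census_days)
        object.__setattr__(self, "census_days", days)
        if not days:
            raise TrialDataError("census schedule must have at least one day")
        if any(d <= 0 for d in days):
            raise TrialDataError("census days must be positive")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise TrialDataError("census days must be strictly increasing")
        if self.trial_end_day < days[-1]:
            raise TrialDataError("trial_end_day precedes the last census day")

    def __contains__(self, day: object) -> bool:
        return day in self.census_days

    def snap_up(self, t: float) -> int | None:
        """First census day >= ``t``, or None if ``t`` falls after the last one."""
        for d in self.census_days:
            if t <= d:
                return d
        return None


@dataclass(frozen=True)
class SeedLot:
    """One species × provenance unit of the trial (both treatment arms)."""

    species: str
    growth_form: str
    provenance: int | None = None
    n_replicates: int = 50
    seeds_per_replicate: int = 3
    dormancy_treatment: str = "none"

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise TrialDataError(f"unknown growth form {self.growth_form!r}")
        if self.n_replicates < 1 or self.seeds_per_replicate < 1:
            raise TrialDataError("replicate and seed counts must be >= 1")
        if self.dormancy_treatment not in DORMANCY_TREATMENTS:
            raise TrialDataError(f"unknown dormancy treatment {self.dormancy_treatment!r}")

    @property
    def key(self) -> tuple[str, int | None]:
        return (self.species, self.provenance)


@dataclass(frozen=True)
class ReplicateRecord:
    """One replicate's outcome in one treatment arm.

    ``emergence_day`` is the census day on which the replicate's first
    seedling was observed (None if it never emerged by trial end);
    ``survived`` is defined only for emerged replicates.
    """

    species: str
    provenance: int | None
    growth_form: str
    treatment: str
    replicate_id: str
    emergence_day: int | None
    survived: bool | None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise TrialDataError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.growth_form not in GROWTH_FORMS:
            raise TrialDataError(f"unknown growth form {self.growth_form!r}")
        if (self.emergence_day is None) != (self.survived is None):
            raise TrialDataError(
                "survived must be present exactly when emergence_day is present "
                f"(replicate {self.replicate_id!r})"
            )
        if self.emergence_day is not None and self.emergence_day <= 0:
            raise TrialDataError(f"emergence_day must be positive (replicate {self.replicate_id!r})")

    @property
    def emerged(self) -> bool:
        return self.emergence_day is not None

    @property
    def arm_key(self) -> tuple[str, int | None, str]:
        return (self.species, self.provenance, self.treatment)


def _parse_cell(raw: object) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    return s or None


def _parse_record(row: dict, idx: int, schedule: CensusSchedule | None) -> ReplicateRecord:
    species = _parse_cell(row.get("species"))
    growth_form = _parse_cell(row.get("growth_form"))
    treatment = _parse_cell(row.get("treatment"))
    replicate_id = _parse_cell(row.get("replicate_id"))
    if not species or not growth_form or not treatment or not replicate_id:
        raise TrialDataError("species, growth_form, treatment and replicate_id are required")
    prov_raw = _parse_cell(row.get("provenance"))
    provenance = int(prov_raw) if prov_raw is not None else None
    day_raw = _parse_cell(row.get("emergence_day"))
    emergence_day = None
    if day_raw is not None:
        emergence_day = int(float(day_raw))
        if schedule is not None and emergence_day not in schedule:
            raise TrialDataError(f"emergence_day {emergence_day} not on the census schedule")
    surv_raw = _parse_cell(row.get("survived"))
    survived: bool | None = None
    if surv_raw is not None:
        low = surv_raw.lower()
        if low in {"true", "1", "yes"}:
            survived = True
        elif low in {"false", "0", "no"}:
            survived = False
        else:
            raise TrialDataError(f"cannot parse survived value {surv_raw!r}")
    return ReplicateRecord(
        species=species,
        provenance=provenance,
        growth_form=growth_form,
        treatment=treatment,
        replicate_id=replicate_id,
        emergence_day=emergence_day,
        survived=survived,
    )


def load_replicate_csv(path, schedule: CensusSchedule | None = None) -> list[ReplicateRecord]:
    """Read replicate-level trial records from CSV.

    Empty ``emergence_day``/``survived`` cells encode a never-emerged
    replicate. All rows are validated; a single error message names every
    offending row (0-based data row index).
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in REPLICATE_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialDataError(f"replicate CSV missing columns: {missing}")
    return frame_to_records(frame, schedule=schedule)


def frame_to_records(frame: pd.DataFrame, schedule: CensusSchedule | None = None) -> list[ReplicateRecord]:
    records: list[ReplicateRecord] = []
    errors: list[str] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(_parse_record(row, idx, schedule))
        except (TrialDataError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise TrialDataError("invalid replicate rows:\n" + "\n".join(errors))
    return records


def records_to_frame(records: Iterable[ReplicateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "provenance": "" if r.provenance is None else str(r.provenance),
                "growth_form": r.growth_form,
                "treatment": r.treatment,
                "replicate_id": r.replicate_id,
                "emergence_day": "" if r.emergence_day is None else str(r.emergence_day),
                "survived": "" if r.survived is None else str(r.survived).upper(),
            }
        )
    return pd.DataFrame(rows, columns=REPLICATE_COLUMNS)


def write_replicate_csv(records: Iterable[ReplicateRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


@dataclass(frozen=True)
class ArmMetrics:
    """Published per-arm performance metrics for one lot (printed precision)."""

    emergence_pct: float
    survival_pct: float
    mean_days: float
    eri: float
    tse_days: float

    def __post_init__(self) -> None:
        if not 0 <= self.emergence_pct <= 100:
            raise TrialDataError(f"emergence percentage {self.emergence_pct} outside [0, 100]")
        if not 0 <= self.survival_pct <= 100:
            raise TrialDataError(f"survival percentage {self.survival_pct} outside [0, 100]")
        if self.eri < 0 or self.tse_days < 0:
            raise TrialDataError("eri and tse must be non-negative")

    def n_emerged(self, n_sown: int = 50) -> int:
        return counts_from_percent(self.emergence_pct, n_sown)

    def n_survived(self, n_sown: int = 50) -> int:
        n_em = self.n_emerged(n_sown)
        if n_em == 0:
            return 0
        return counts_from_percent(self.survival_pct, n_em)


@dataclass(frozen=True)
class Table1Row:
    """One printed seed lot: per-treatment metrics, None where the published
    table shows a grey bar (no emergence recorded for that treatment)."""

    species: str
    growth_form: str
    provenance: int | None = None
    bare: ArmMetrics | None = None
    pellet: ArmMetrics | None = None
    n_sown: int = 50

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise TrialDataError(f"unknown growth form {self.growth_form!r}")
        if self.bare is None and self.pellet is None:
            raise TrialDataError(f"{self.species}: at least one arm must be present")

    def arm(self, treatment: str) -> ArmMetrics | None:
        if treatment not in TREATMENTS:
            raise TrialDataError(f"unknown treatment {treatment!r}")
        return self.bare if treatment == "bare" else self.pellet


_TABLE1_RESOURCE = "table1.csv"


def table1_frame() -> pd.DataFrame:
    """The packaged published summary table, as printed (one row per lot)."""
    with resources.files("seedpellet.data").joinpath(_TABLE1_RESOURCE).open("r") as fh:
        return pd.read_csv(fh)


def load_table1_fixture(validate: bool = True) -> list[Table1Row]:
    """Load the packaged published per-lot performance table.

    Grey bars (arms with no recorded emergence) become ``None`` arms. With
    ``validate`` (default), checks that every printed emergence percentage is
    an even integer — forced by the n=50 denominator, so an odd value flags a
    transcription error.
    """
    frame = table1_frame()
    rows: list[Table1Row] = []
    for rec in frame.to_dict(orient="records"):
        arms: dict[str, ArmMetrics | None] = {}
        for arm in TREATMENTS:
            vals = [
                rec[f"{arm}_emergence_pct"],
                rec[f"{arm}_survival_pct"],
                rec[f"{arm}_mean_days"],
                rec[f"{arm}_eri"],
                rec[f"{arm}_tse_days"],
            ]
            present = [not (isinstance(v, float) and math.isnan(v)) for v in vals]
            if not any(present):
                arms[arm] = None
                continue
            if not all(present):
                raise TrialDataError(f"{rec['species']}: partially missing {arm} arm")
            if validate:
                pct = float(vals[0])
                if pct != int(pct) or int(pct) % 2 != 0:
                    raise TrialDataError(
                        f"{rec['species']}: {arm} emergence {pct}% not an even integer "
                        "(impossible with n=50; transcription error?)"
                    )
            arms[arm] = ArmMetrics(
                emergence_pct=float(vals[0]),
                survival_pct=float(vals[1]),
                mean_days=float(vals[2]),
                eri=float(vals[3]),
                tse_days=float(vals[4]),
            )
        prov = rec.get("provenance")
        rows.append(
            Table1Row(
                species=str(rec["species"]),
                growth_form=str(rec["growth_form"]),
                provenance=None if (prov is None or (isinstance(prov, float) and math.isnan(prov))) else int(prov),
                bare=arms["bare"],
                pellet=arms["pellet"],
            )
        )
    return rows
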