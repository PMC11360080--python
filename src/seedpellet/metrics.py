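"""Emergence performance metrics for one lot-treatment arm.

Five quantities summarise an arm of ``n`` sown replicates:

* total emergence — percentage of replicates with any recorded emergence;
* survival — percentage of *emerged* replicates alive after the species'
  emergence plateau (denominator is emerged, not sown);
* time to emergence — minimum, arithmetic mean (MTE) and maximum of the
  emerged replicates' emergence days;
* emergence rate index (ERI) — Maguire's speed index
  ``sum_i n_i / t_i`` over census days, where ``n_i`` replicates first
  emerged on day ``t_i``; higher is faster. A percent basis
  (``sum_i 100 n_i / (n_sown t_i)``) is available via ``eri_basis``;
* time spread of emergence (TSE) — days between first and last emergence.

The speed metrics are undefined (None) for an arm with no emergents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import ReplicateRecord, TrialDataError

__all__ = [
    "EmergenceSummary",
    "total_emergence",
    "survival",
    "emergence_times_summary",
    "emergence_rate_index",
    "summarize_arm",
    "summarize_records",
    "summaries_to_table",
]


@dataclass(frozen=True)
class EmergenceSummary:
    """The five performance metrics for one lot-treatment arm."""

    species: str
    provenance: int | None
    growth_form: str
    treatment: str
    n_sown: int
    n_emerged: int
    total_emergence_pct: float
    n_survived: int | None
    survival_pct: float | None
    t_first: int | None
    mean_days: float | None
    t_last: int | None
    eri: float | None
    tse_days: float | None

    def __post_init__(self) -> None:
        if self.n_emerged > self.n_sown:
            raise TrialDataError("n_emerged exceeds n_sown")
        if self.n_emerged == 0:
            for name in ("survival_pct", "t_first", "mean_days", "t_last", "eri", "tse_days"):
                if getattr(self, name) is not None:
                    raise TrialDataError(f"{name} must be None when no replicate emerged")


def _check_one_arm(records: Sequence[ReplicateRecord]) -> None:
    if not records:
        raise TrialDataError("no records supplied")
    keys = {r.arm_key for r in records}
    if len(keys) > 1:
        raise TrialDataError(f"records span multiple lot-treatment arms: {sorted(keys)}")


def total_emergence(records: Sequence[ReplicateRecord]) -> tuple[int, float]:
    """(number emerged, percent emerged of sown replicates)."""
    _check_one_arm(records)
    n_emerged = sum(r.emerged for r in records)
    return n_emerged, 100.0 * n_emerged / len(records)


def survival(records: Sequence[ReplicateRecord]) -> tuple[int, float]:
    """(number surviving, percent surviving of *emerged* replicates)."""
    _check_one_arm(records)
    emerged = [r for r in records if r.emerged]
    if not emerged:
        raise TrialDataError("survival undefined: no replicate emerged")
    n_survived = sum(bool(r.survived) for r in emerged)
    return n_survived, 100.0 * n_survived / len(emerged)


def emergence_times_summary(
    records: Sequence[ReplicateRecord],
) -> tuple[int, float, int, int]:
    """(first, mean, last, spread) of emergence days over emerged replicates."""
    _check_one_arm(records)
    days = sorted(r.emergence_day for r in records if r.emerged)
    if not days:
        raise TrialDataError("emergence times undefined: no replicate emerged")
    t_first, t_last = days[0], days[-1]
    return t_first, sum(days) / len(days), t_last, t_last - t_first


def emergence_rate_index(records: Sequence[ReplicateRecord], basis: str = "count") -> float:
    """Maguire-type emergence rate index, sum of newly-emerged over day.

    ``basis="count"`` sums replicate counts (emergents per day);
    ``basis="percent"`` sums the percentage of sown replicates instead,
    matching a %/day reading of the index.
    """
    _check_one_arm(records)
    if basis not in {"count", "percent"}:
        raise TrialDataError(f"unknown ERI basis {basis!r}")
    days = [r.emergence_day for r in records if r.emerged]
    if not days:
        raise TrialDataError("ERI undefined: no replicate emerged")
    if min(days) <= 0:
        raise TrialDataError("emergence days must be positive")
    scale = 1.0 if basis == "count" else 100.0 / len(records)
    per_day: dict[int, int] = {}
    for d in days:
        per_day[d] = per_day.get(d, 0) + 1
    return sum(scale * n / t for t, n in per_day.items())


def summarize_arm(records: Sequence[ReplicateRecord], eri_basis: str = "count") -> EmergenceSummary:
    """Compose the emergence metrics for one arm into a summary row."""
    _check_one_arm(records)
    ref = records[0]
    n_emerged, pct = total_emergence(records)
    if n_emerged == 0:
        return EmergenceSummary(
            species=ref.species,
            provenance=ref.provenance,
            growth_form=ref.growth_form,
            treatment=ref.treatment,
            n_sown=len(records),
            n_emerged=0,
            total_emergence_pct=0.0,
            n_survived=None,
            survival_pct=None,
            t_first=None,
            mean_days=None,
            t_last=None,
            eri=None,
            tse_days=None,
        )
    n_survived, surv_pct = survival(records)
    t_first, mean_days, t_last, tse = emergence_times_summary(records)
    return EmergenceSummary(
        species=ref.species,
        provenance=ref.provenance,
        growth_form=ref.growth_form,
        treatment=ref.treatment,
        n_sown=len(records),
        n_emerged=n_emerged,
        total_emergence_pct=pct,
        n_survived=n_survived,
        survival_pct=surv_pct,
        t_first=t_first,
        mean_days=mean_days,
        t_last=t_last,
        eri=emergence_rate_index(records, basis=eri_basis),
        tse_days=float(tse),
    )


def summarize_records(
    records: Iterable[ReplicateRecord], eri_basis: str = "count"
) -> list[EmergenceSummary]:
    """One summary per lot-treatment arm, ordered by (species, provenance, treatment)."""
    arms: dict[tuple, list[ReplicateRecord]] = {}
    for r in records:
        arms.setdefault(r.arm_key, []).append(r)
    order = sorted(arms, key=lambda k: (k[0], k[1] if k[1] is not None else -1, k[2]))
    return [summarize_arm(arms[k], eri_basis=eri_basis) for k in order]


def summaries_to_table(summaries: Iterable[EmergenceSummary]) -> pd.DataFrame:
    """Wide per-lot table mirroring the published layout (one row per lot,
    bare and pellet metric columns side by side; empty cells for arms with
    no emergence)."""
    by_lot: dict[tuple, dict] = {}
    for s in summaries:
        lot = by_lot.setdefault(
            (s.species, s.provenance),
            {"species": s.species, "provenance": s.provenance, "growth_form": s.growth_form},
        )
        prefix = s.treatment
        lot[f"{prefix}_emergence_pct"] = s.total_emergence_pct if s.n_emerged else None
        lot[f"{prefix}_survival_pct"] = s.survival_pct
        lot[f"{prefix}_mean_days"] = s.mean_days
        lot[f"{prefix}_eri"] = s.eri
        lot[f"{prefix}_tse_days"] = s.tse_days
    cols = ["species", "provenance", "growth_form"] + [
        f"{arm}_{m}"
        for m in ("emergence_pct", "survival_pct", "mean_days", "eri", "tse_days")
        for arm in ("bare", "pellet")
    ]
    frame = pd.DataFrame(list(by_lot.values()))
    for c in cols:
        if c not in frame.columns:
            frame[c] = None
    return frame[cols].sort_values(["species", "provenance"], na_position="first").reset_index(drop=True)
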