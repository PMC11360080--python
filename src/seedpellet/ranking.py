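"""Rule-based species performance classification.

Amenability to pelleting combines the per-species treatment directions for
total emergence and survival:

* **high** — both responses improved or not significantly different in
  pellets;
* **medium** — exactly one response significantly worse in pellets;
* **low** — both responses significantly worse in pellets.

Emergence speed combines up to three per-metric ranks (mean time to
emergence by significance-bearing contrast; ERI and TSE by value at working
precision): a species is **faster**/**slower** when at least two defined
metrics agree, **equal** otherwise (including the three-way one-each tie,
resolved to the least assertive label).

Species-level aggregation pools two-provenance lots before testing: emerged
and survivor counts are summed, and lot-level speed metrics are averaged
weighted by each lot's emerged count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .datamodel import Table1Row, TrialDataError, counts_from_percent
from .metrics import EmergenceSummary
from .stats import ComparisonResult, Direction

__all__ = [
    "Amenability",
    "SpeedRank",
    "PerformanceRank",
    "SpeciesAggregate",
    "amenability_rank",
    "speed_rank_per_metric",
    "overall_speed_rank",
    "species_level_aggregation",
    "table1_to_summaries",
    "summarize_classifications",
]


class Amenability(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


class SpeedRank(str, Enum):
    FASTER = "faster"
    SLOWER = "slower"
    EQUAL = "equal"


_OK = {Direction.PELLET_HIGHER, Direction.NO_DIFFERENCE}


def amenability_rank(
    emergence: Direction, survival: Direction
) -> tuple[Amenability, str]:
    """Apply the amenability decision rule; returns (label, rule trace)."""
    good = [d in _OK for d in (emergence, survival)]
    trace = f"emergence={emergence.value}, survival={survival.value}"
    if all(good):
        return Amenability.HIGH, trace + " -> both improved-or-NS -> high"
    if not any(good):
        return Amenability.LOW, trace + " -> both significantly worse -> low"
    return Amenability.MEDIUM, trace + " -> exactly one significantly worse -> medium"


def speed_rank_per_metric(
    metric: str,
    bare: float | None = None,
    pellet: float | None = None,
    contrast: ComparisonResult | None = None,
    ndigits: int = 2,
) -> SpeedRank | None:
    """Faster/slower/equal rank for one speed metric.

    ``mean_time`` requires a significance-bearing ``contrast`` (pellet minus
    bare): significantly shorter time = faster. ``eri`` and ``tse`` are
    compared by value at ``ndigits`` working precision (the published table's
    printed precision): higher pellet ERI = faster, shorter pellet TSE =
    faster. Returns None when the metric is undefined for either arm.
    """
    if metric == "mean_time":
        if contrast is None:
            return None
        if contrast.direction is Direction.NO_DIFFERENCE:
            return SpeedRank.EQUAL
        return SpeedRank.SLOWER if contrast.direction is Direction.PELLET_HIGHER else SpeedRank.FASTER
    if metric not in {"eri", "tse"}:
        raise TrialDataError(f"unknown speed metric {metric!r}")
    if bare is None or pellet is None:
        return None
    b, p = round(float(bare), ndigits), round(float(pellet), ndigits)
    if p == b:
        return SpeedRank.EQUAL
    if metric == "eri":
        return SpeedRank.FASTER if p > b else SpeedRank.SLOWER
    return SpeedRank.FASTER if p < b else SpeedRank.SLOWER


def overall_speed_rank(ranks: dict[str, SpeedRank | None]) -> SpeedRank | None:
    """Majority label over the defined per-metric ranks.

    Needs at least two defined metrics (else None = excluded). When no label
    reaches a count of two (one each of faster/slower/equal), the species is
    called equal.
    """
    defined = [r for r in ranks.values() if r is not None]
    if len(defined) < 2:
        return None
    counts = Counter(defined)
    label, n = counts.most_common(1)[0]
    return label if n >= 2 else SpeedRank.EQUAL


@dataclass(frozen=True)
class SpeciesAggregate:
    """Species-level test inputs after pooling provenances."""

    species: str
    growth_form: str
    n_lots: int
    bare_sown: int
    pellet_sown: int
    bare_emerged: int
    pellet_emerged: int
    bare_survived: int | None
    pellet_survived: int | None
    bare_mean_days: float | None
    pellet_mean_days: float | None
    bare_eri: float | None
    pellet_eri: float | None
    bare_tse: float | None
    pellet_tse: float | None


def table1_to_summaries(rows: list[Table1Row]) -> list[EmergenceSummary]:
    """Per-lot arm summaries reconstructed from the printed table.

    Counts are recovered exactly from the rounded percentages
    (:func:`~seedpellet.datamodel.counts_from_percent`); grey-bar arms become
    zero-emergence summaries. First/last emergence days are not printed and
    stay None.
    """
    out: list[EmergenceSummary] = []
    for row in rows:
        for treatment in ("bare", "pellet"):
            arm = row.arm(treatment)
            if arm is None:
                out.append(
                    EmergenceSummary(
                        species=row.species,
                        provenance=row.provenance,
                        growth_form=row.growth_form,
                        treatment=treatment,
                        n_sown=row.n_sown,
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
                )
                continue
            n_em = arm.n_emerged(row.n_sown)
            n_sv = arm.n_survived(row.n_sown)
            out.append(
                EmergenceSummary(
                    species=row.species,
                    provenance=row.provenance,
                    growth_form=row.growth_form,
                    treatment=treatment,
                    n_sown=row.n_sown,
                    n_emerged=n_em,
                    total_emergence_pct=arm.emergence_pct,
                    n_survived=n_sv,
                    survival_pct=arm.survival_pct,
                    t_first=None,
                    mean_days=arm.mean_days,
                    t_last=None,
                    eri=arm.eri,
                    tse_days=arm.tse_days,
                )
            )
    return out


def _pool_metric(values: list[tuple[float | None, int]]) -> float | None:
    """Emergence-weighted mean of per-lot metric values; None if undefined."""
    defined = [(v, w) for v, w in values if v is not None and w > 0]
    if not defined:
        return None
    total = sum(w for _, w in defined)
    return sum(v * w for v, w in defined) / total


def species_level_aggregation(summaries: list[EmergenceSummary]) -> list[SpeciesAggregate]:
    """Pool per-lot arm summaries to species level.

    Counts (sown, emerged, survived) are summed across provenances; speed
    metrics are weighted means (weights = each lot's emerged count).
    Single-provenance species pass through unchanged.
    """
    by_species: dict[str, dict[str, list[EmergenceSummary]]] = {}
    forms: dict[str, str] = {}
    for s in summaries:
        by_species.setdefault(s.species, {"bare": [], "pellet": []})[s.treatment].append(s)
        forms[s.species] = s.growth_form
    out: list[SpeciesAggregate] = []
    for species in sorted(by_species):
        arms = by_species[species]
        lots = {s.provenance for arm in arms.values() for s in arm}
        vals: dict[str, object] = {}
        for treatment in ("bare", "pellet"):
            arm = arms[treatment]
            sown = sum(s.n_sown for s in arm)
            emerged = sum(s.n_emerged for s in arm)
            survived = (
                sum(s.n_survived for s in arm if s.n_survived is not None)
                if any(s.n_survived is not None for s in arm)
                else None
            )
            vals[f"{treatment}_sown"] = sown
            vals[f"{treatment}_emerged"] = emerged
            vals[f"{treatment}_survived"] = survived
            vals[f"{treatment}_mean_days"] = _pool_metric([(s.mean_days, s.n_emerged) for s in arm])
            vals[f"{treatment}_eri"] = _pool_metric([(s.eri, s.n_emerged) for s in arm])
            vals[f"{treatment}_tse"] = _pool_metric([(s.tse_days, s.n_emerged) for s in arm])
        out.append(
            SpeciesAggregate(
                species=species, growth_form=forms[species], n_lots=len(lots), **vals
            )
        )
    return out


@dataclass(frozen=True)
class PerformanceRank:
    """Amenability and emergence-speed labels for one species, with the
    directions and the rule clause that fired."""

    species: str
    growth_form: str
    amenability: Amenability | None
    speed: SpeedRank | None
    directions: dict[str, Direction | None] = field(default_factory=dict)
    metric_ranks: dict[str, SpeedRank | None] = field(default_factory=dict)
    rule_trace: str = ""


def summarize_classifications(ranks: list[PerformanceRank]) -> pd.DataFrame:
    """Counts and percentages per label, overall and per growth form."""
    rows = []
    amen = [r for r in ranks if r.amenability is not None]
    speed = [r for r in ranks if r.speed is not None]
    for scope, items, labels, get in (
        ("amenability", amen, list(Amenability), lambda r: r.amenability),
        ("speed", speed, list(SpeedRank), lambda r: r.speed),
    ):
        if not items:
            continue
        groups = [("all", items)] + [
            (gf, [r for r in items if r.growth_form == gf])
            for gf in sorted({r.growth_form for r in items})
        ]
        for group, members in groups:
            counts = Counter(get(r) for r in members)
            for label in labels:
                n = counts.get(label, 0)
                rows.append(
                    {
                        "classification": scope,
                        "growth_form": group,
                        "label": label.value,
                        "n": n,
                        "pct_of_group": 100.0 * n / len(members) if members else 0.0,
                        "n_analyzed": len(members),
                    }
                )
    return pd.DataFrame(rows)
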