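"""End-to-end orchestration: summaries -> comparisons -> classifications.

Two entry points cover the two kinds of input:

* :func:`classify_summaries` works from per-lot arm summaries (including the
  packaged published table via :func:`~seedpellet.ranking.table1_to_summaries`);
  mean-time speed ranks need replicate-level data and are absent here, so the
  overall speed label rests on the ERI and TSE value comparisons.
* :func:`classify_records` works from replicate-level records and adds the
  mixed-model mean-time contrasts.

Defaults (alpha 0.05, Yates-corrected chi-squared, provenances pooled,
count-basis ERI, 2-decimal working precision for value comparisons)
reproduce the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .datamodel import Table1Row, load_table1_fixture
from .metrics import EmergenceSummary, summarize_records
from .ranking import (
    Amenability,
    PerformanceRank,
    SpeedRank,
    amenability_rank,
    overall_speed_rank,
    species_level_aggregation,
    speed_rank_per_metric,
    summarize_classifications,
    table1_to_summaries,
)
from .stats import (
    ComparisonResult,
    Direction,
    SpeciesDropped,
    compare_emergence,
    compare_survival,
    time_to_emergence_model,
)

__all__ = [
    "RunConfig",
    "ClassificationReport",
    "classify_summaries",
    "classify_records",
    "classify_table1",
    "trial_emergence_totals",
    "correction_sensitivity",
    "classification_frame",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; the defaults are the published analysis."""

    alpha: float = 0.05
    correction: bool = True  # Yates continuity correction on 2x2 tables
    provenance_mode: str = "pooled"  # or "per_lot"
    eri_basis: str = "count"  # or "percent"
    precision: int = 2  # working precision for ERI/TSE value comparisons
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.provenance_mode not in {"pooled", "per_lot"}:
            raise ValueError(f"unknown provenance mode {self.provenance_mode!r}")
        if self.eri_basis not in {"count", "percent"}:
            raise ValueError(f"unknown ERI basis {self.eri_basis!r}")


@dataclass(frozen=True)
class ClassificationReport:
    """Per-species comparisons and labels plus the trial-wide summary."""

    ranks: list[PerformanceRank]
    comparisons: list[ComparisonResult]
    dropped_species: tuple[str, ...]
    config: RunConfig

    @property
    def summary(self) -> pd.DataFrame:
        return summarize_classifications(self.ranks)

    def count(self, kind: str, label: str) -> int:
        if kind == "amenability":
            return sum(1 for r in self.ranks if r.amenability is not None and r.amenability.value == label)
        return sum(1 for r in self.ranks if r.speed is not None and r.speed.value == label)

    def metric_rank_count(self, metric: str, label: str) -> int:
        return sum(
            1
            for r in self.ranks
            if r.metric_ranks.get(metric) is not None and r.metric_ranks[metric].value == label
        )


def classify_summaries(
    summaries: list[EmergenceSummary],
    config: RunConfig = RunConfig(),
    mean_time_contrasts: dict[str, ComparisonResult] | None = None,
) -> ClassificationReport:
    """Classify species from per-lot arm summaries.

    In ``per_lot`` provenance mode each lot is treated as its own unit
    (species label suffixed with the provenance); the default pools
    provenances first. ``mean_time_contrasts`` (per species), when supplied,
    contribute the third speed metric.
    """
    if config.provenance_mode == "per_lot":
        summaries = [
            replace(
                s,
                species=(s.species if s.provenance is None else f"{s.species} [{s.provenance}]"),
                provenance=None,
            )
            for s in summaries
        ]
    aggregates = species_level_aggregation(summaries)
    contrasts = mean_time_contrasts or {}
    ranks: list[PerformanceRank] = []
    comparisons: list[ComparisonResult] = []
    dropped: list[str] = []
    for agg in aggregates:
        directions: dict[str, Direction | None] = {}
        trace_parts: list[str] = []
        try:
            em = compare_emergence(
                agg.species,
                agg.bare_emerged,
                agg.bare_sown,
                agg.pellet_emerged,
                agg.pellet_sown,
                alpha=config.alpha,
                correction=config.correction,
            )
            comparisons.append(em)
            directions["emergence"] = em.direction
        except SpeciesDropped:
            dropped.append(agg.species)
            continue
        try:
            sv = compare_survival(
                agg.species,
                agg.bare_survived or 0,
                agg.bare_emerged,
                agg.pellet_survived or 0,
                agg.pellet_emerged,
                alpha=config.alpha,
                correction=config.correction,
            )
            comparisons.append(sv)
            directions["survival"] = sv.direction
        except SpeciesDropped:
            directions["survival"] = None

        if directions["survival"] is not None:
            amen, trace = amenability_rank(directions["emergence"], directions["survival"])
            trace_parts.append(trace)
        else:
            amen = None
            trace_parts.append("survival undefined -> amenability excluded")

        mt_contrast = contrasts.get(agg.species)
        if mt_contrast is not None:
            directions["mean_time"] = mt_contrast.direction
            comparisons.append(mt_contrast)
        metric_ranks = {
            "mean_time": speed_rank_per_metric("mean_time", contrast=mt_contrast),
            "eri": speed_rank_per_metric(
                "eri", agg.bare_eri, agg.pellet_eri, ndigits=config.precision
            ),
            "tse": speed_rank_per_metric(
                "tse", agg.bare_tse, agg.pellet_tse, ndigits=config.precision
            ),
        }
        speed = overall_speed_rank(metric_ranks)
        defined = {m: r.value for m, r in metric_ranks.items() if r is not None}
        trace_parts.append(f"speed metrics {defined} -> {speed.value if speed else 'excluded'}")
        ranks.append(
            PerformanceRank(
                species=agg.species,
                growth_form=agg.growth_form,
                amenability=amen,
                speed=speed,
                directions=directions,
                metric_ranks=metric_ranks,
                rule_trace="; ".join(trace_parts),
            )
        )
    return ClassificationReport(
        ranks=ranks,
        comparisons=comparisons,
        dropped_species=tuple(dropped),
        config=config,
    )


def classify_table1(
    rows: list[Table1Row] | None = None, config: RunConfig = RunConfig()
) -> ClassificationReport:
    """Run the classification pipeline on the packaged published table.

    Speed-metric arms behind grey bars are undefined, and the one-arm
    species drop out of the survival (hence amenability) analysis exactly as
    in the published species counts.
    """
    if rows is None:
        rows = load_table1_fixture()
    return classify_summaries(table1_to_summaries(rows), config=config)


def classify_records(
    records,
    config: RunConfig = RunConfig(),
    include_time_model: bool = True,
) -> ClassificationReport:
    """Classify species from replicate-level records (adds mean-time contrasts)."""
    summaries = summarize_records(records, eri_basis=config.eri_basis)
    contrasts = None
    if include_time_model:
        result = time_to_emergence_model(records, alpha=config.alpha)
        contrasts = {c.species: c for c in result.contrasts}
    return classify_summaries(summaries, config=config, mean_time_contrasts=contrasts)


def trial_emergence_totals(rows: list[Table1Row] | None = None) -> dict[str, int]:
    """Trial-wide emerged replicate totals per treatment, reconstructed from
    the printed per-lot percentages (grey bars contribute zero)."""
    if rows is None:
        rows = load_table1_fixture()
    totals = {"bare": 0, "pellet": 0}
    for row in rows:
        for treatment in totals:
            arm = row.arm(treatment)
            if arm is not None:
                totals[treatment] += arm.n_emerged(row.n_sown)
    return totals


def correction_sensitivity(
    rows: list[Table1Row] | None = None, config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Species whose emergence/survival direction depends on the Yates flag.

    Returns one row per (species, response) whose direction changes between
    the corrected and uncorrected chi-squared, with both p-values. Any listed
    species necessarily has one p-value on each side of alpha.
    """
    if rows is None:
        rows = load_table1_fixture()
    with_c = classify_table1(rows, replace(config, correction=True))
    without_c = classify_table1(rows, replace(config, correction=False))

    def index(report: ClassificationReport) -> dict[tuple[str, str], ComparisonResult]:
        return {
            (c.species, c.response): c
            for c in report.comparisons
            if c.response in ("emergence", "survival")
        }

    a, b = index(with_c), index(without_c)
    out = []
    for key in sorted(set(a) & set(b)):
        ca, cb = a[key], b[key]
        if ca.direction != cb.direction:
            out.append(
                {
                    "species": key[0],
                    "response": key[1],
                    "direction_corrected": ca.direction.value,
                    "p_corrected": ca.p_value,
                    "direction_uncorrected": cb.direction.value,
                    "p_uncorrected": cb.p_value,
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "species",
            "response",
            "direction_corrected",
            "p_corrected",
            "direction_uncorrected",
            "p_uncorrected",
        ],
    )


def classification_frame(report: ClassificationReport) -> pd.DataFrame:
    """Flat per-species table of labels, directions and rule traces."""
    rows = []
    for r in report.ranks:
        rows.append(
            {
                "species": r.species,
                "growth_form": r.growth_form,
                "amenability": r.amenability.value if r.amenability else "",
                "speed": r.speed.value if r.speed else "",
                "dir_emergence": r.directions.get("emergence").value
                if r.directions.get("emergence")
                else "",
                "dir_survival": r.directions.get("survival").value
                if r.directions.get("survival")
                else "",
                "dir_mean_time": r.directions.get("mean_time").value
                if r.directions.get("mean_time")
                else "",
                "rank_mean_time": r.metric_ranks.get("mean_time").value
                if r.metric_ranks.get("mean_time")
                else "",
                "rank_eri": r.metric_ranks.get("eri").value if r.metric_ranks.get("eri") else "",
                "rank_tse": r.metric_ranks.get("tse").value if r.metric_ranks.get("tse") else "",
                "rule_trace": r.rule_trace,
            }
        )
    return pd.DataFrame(rows)
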