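"""Decision rules, provenance pooling, and classification summaries."""

import pytest

from seedpellet.datamodel import load_table1_fixture
from seedpellet.ranking import (
    Amenability,
    SpeedRank,
    amenability_rank,
    overall_speed_rank,
    species_level_aggregation,
    speed_rank_per_metric,
    summarize_classifications,
    table1_to_summaries,
)
from seedpellet.stats import ComparisonResult, Direction

H, L, ND = Direction.PELLET_HIGHER, Direction.PELLET_LOWER, Direction.NO_DIFFERENCE


class TestAmenabilityRule:
    @pytest.mark.parametrize(
        "emergence,survival,expected",
        [
            (H, ND, Amenability.HIGH),
            (ND, ND, Amenability.HIGH),
            (H, H, Amenability.HIGH),
            (ND, L, Amenability.MEDIUM),
            (L, H, Amenability.MEDIUM),
            (L, ND, Amenability.MEDIUM),
            (L, L, Amenability.LOW),
        ],
    )
    def test_rule_table(self, emergence, survival, expected):
        label, trace = amenability_rank(emergence, survival)
        assert label is expected
        assert emergence.value in trace and survival.value in trace

    def test_monotone_in_each_direction(self):
        # improving either response (lower -> ND -> higher) never lowers the rank
        order = [L, ND, H]
        rank_order = {Amenability.LOW: 0, Amenability.MEDIUM: 1, Amenability.HIGH: 2}
        for a in order:
            for i in range(len(order) - 1):
                worse, _ = amenability_rank(a, order[i])
                better, _ = amenability_rank(a, order[i + 1])
                assert rank_order[better] >= rank_order[worse]
                worse, _ = amenability_rank(order[i], a)
                better, _ = amenability_rank(order[i + 1], a)
                assert rank_order[better] >= rank_order[worse]


def _contrast(direction, p=0.01):
    return ComparisonResult(
        species="sp",
        response="mean_time",
        direction=direction,
        statistic=0.0,
        p_value=p,
        n_bare=10,
        n_pellet=10,
        method="lmm",
    )


class TestSpeedRankPerMetric:
    def test_eri_exact_tie_is_equal(self):
        # Panicum simile prints 0.09 in both arms
        assert speed_rank_per_metric("eri", 0.09, 0.09) is SpeedRank.EQUAL

    def test_eri_higher_pellet_is_faster(self):
        assert speed_rank_per_metric("eri", 0.15, 0.6) is SpeedRank.FASTER

    def test_tse_shorter_pellet_is_faster(self):
        # Bursaria spinosa: spread 89 days bare vs 12 days pellet
        assert speed_rank_per_metric("tse", 89, 12) is SpeedRank.FASTER
        assert speed_rank_per_metric("tse", 12, 89) is SpeedRank.SLOWER

    def test_working_precision_rounds_before_compare(self):
        assert speed_rank_per_metric("eri", 0.09, 0.094) is SpeedRank.EQUAL
        assert speed_rank_per_metric("eri", 0.09, 0.096) is SpeedRank.FASTER

    def test_mean_time_uses_contrast_significance(self):
        assert speed_rank_per_metric("mean_time", contrast=_contrast(ND, p=0.5)) is SpeedRank.EQUAL
        assert speed_rank_per_metric("mean_time", contrast=_contrast(H)) is SpeedRank.SLOWER
        assert speed_rank_per_metric("mean_time", contrast=_contrast(L)) is SpeedRank.FASTER

    def test_undefined_arm_excludes_metric(self):
        assert speed_rank_per_metric("eri", None, 0.5) is None
        assert speed_rank_per_metric("mean_time", contrast=None) is None


class TestOverallSpeedRank:
    F, S, E = SpeedRank.FASTER, SpeedRank.SLOWER, SpeedRank.EQUAL

    @pytest.mark.parametrize(
        "ranks,expected",
        [
            ({"mean_time": F, "eri": F, "tse": S}, F),
            ({"mean_time": E, "eri": E, "tse": F}, E),
            ({"mean_time": F, "eri": S, "tse": E}, E),  # three-way tie -> least assertive
            ({"mean_time": S, "eri": S, "tse": None}, S),
            ({"mean_time": None, "eri": F, "tse": None}, None),  # < 2 defined -> excluded
        ],
    )
    def test_majority_rule(self, ranks, expected):
        assert overall_speed_rank(ranks) is expected


class TestSpeciesAggregation:
    def test_acacia_falcata_counts_pooled(self, table1_rows):
        summaries = table1_to_summaries(table1_rows)
        agg = next(
            a for a in species_level_aggregation(summaries) if a.species == "Acacia falcata"
        )
        # provenances 94% + 90% of 50 bare, 48% + 30% of 50 pellet
        assert (agg.bare_emerged, agg.bare_sown) == (92, 100)
        assert (agg.pellet_emerged, agg.pellet_sown) == (39, 100)
        assert agg.n_lots == 2

    def test_single_provenance_passthrough(self, table1_rows):
        summaries = table1_to_summaries(table1_rows)
        agg = next(
            a for a in species_level_aggregation(summaries) if a.species == "Acacia decurrens"
        )
        assert (agg.bare_emerged, agg.bare_sown, agg.pellet_emerged) == (50, 50, 35)
        assert agg.bare_eri == pytest.approx(3.57)

    def test_conflicting_eri_resolved_by_weighted_average(self, table1_rows):
        # E. crebra provenances disagree in direction; pooling weights by emergents
        summaries = table1_to_summaries(table1_rows)
        agg = next(
            a for a in species_level_aggregation(summaries) if a.species == "Eucalyptus crebra"
        )
        bare_expected = (1.28 * 39 + 0.83 * 50) / 89
        pellet_expected = (0.66 * 43 + 0.89 * 50) / 93
        assert agg.bare_eri == pytest.approx(bare_expected)
        assert agg.pellet_eri == pytest.approx(pellet_expected)
        assert agg.pellet_eri < agg.bare_eri  # weighted average resolves direction

    def test_grey_bar_arm_has_no_metrics(self, table1_rows):
        summaries = table1_to_summaries(table1_rows)
        agg = next(
            a for a in species_level_aggregation(summaries) if a.species == "Lomandra longifolia"
        )
        assert agg.pellet_emerged == 0
        assert agg.pellet_eri is None and agg.pellet_tse is None


class TestClassificationSummary:
    def test_labels_partition_analyzed_species(self, table1_report):
        n_amen = sum(1 for r in table1_report.ranks if r.amenability is not None)
        assert (
            table1_report.count("amenability", "high")
            + table1_report.count("amenability", "medium")
            + table1_report.count("amenability", "low")
            == n_amen
        )
        n_speed = sum(1 for r in table1_report.ranks if r.speed is not None)
        assert (
            table1_report.count("speed", "faster")
            + table1_report.count("speed", "slower")
            + table1_report.count("speed", "equal")
            == n_speed
        )

    def test_summary_table_counts_match_report(self, table1_report):
        summary = table1_report.summary
        all_amen = summary[
            (summary.classification == "amenability") & (summary.growth_form == "all")
        ]
        for label in ("high", "medium", "low"):
            row = all_amen[all_amen.label == label].iloc[0]
            assert row.n == table1_report.count("amenability", label)
            assert row.pct_of_group == pytest.approx(100 * row.n / row.n_analyzed)

    def test_growth_form_rows_sum_to_all(self, table1_report):
        summary = table1_report.summary
        amen = summary[summary.classification == "amenability"]
        per_form = amen[amen.growth_form != "all"].groupby("label")["n"].sum()
        overall = amen[amen.growth_form == "all"].set_index("label")["n"]
        for label in overall.index:
            assert per_form.get(label, 0) == overall[label]

    def test_empty_input_gives_empty_table(self):
        assert summarize_classifications([]).empty


class TestTreatmentRelabelSymmetry:
    def test_amenability_flips_on_decisive_directions(self):
        # with both directions decisive (no ND), swapping arms maps high<->low
        flip = {H: L, L: H}
        for e in (H, L):
            for s in (H, L):
                label, _ = amenability_rank(e, s)
                mirrored, _ = amenability_rank(flip[e], flip[s])
                expected = {
                    Amenability.HIGH: Amenability.LOW,
                    Amenability.LOW: Amenability.HIGH,
                    Amenability.MEDIUM: Amenability.MEDIUM,
                }[label]
                assert mirrored is expected

    def test_fixture_pipeline_flips_directions_and_speed(self, table1_rows, table1_report):
        """Swapping the two arms everywhere flips every per-response direction
        and maps faster<->slower (equal fixed) in the overall speed label."""
        import warnings

        from seedpellet.datamodel import Table1Row
        from seedpellet.pipeline import classify_table1

        swapped = [
            Table1Row(
                species=r.species,
                growth_form=r.growth_form,
                provenance=r.provenance,
                bare=r.pellet,
                pellet=r.bare,
                n_sown=r.n_sown,
            )
            for r in table1_rows
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mirrored = classify_table1(swapped)
        original = table1_report
        for response in ("emergence", "survival"):
            orig = {
                c.species: c for c in original.comparisons if c.response == response
            }
            mirr = {
                c.species: c for c in mirrored.comparisons if c.response == response
            }
            assert set(orig) == set(mirr)
            flip = {H: L, L: H, ND: ND}
            for sp in orig:
                assert mirr[sp].direction is flip[orig[sp].direction]
                assert mirr[sp].p_value == pytest.approx(orig[sp].p_value)
        assert original.count("speed", "faster") == mirrored.count("speed", "slower")
        assert original.count("speed", "slower") == mirrored.count("speed", "faster")
        assert original.count("speed", "equal") == mirrored.count("speed", "equal")
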