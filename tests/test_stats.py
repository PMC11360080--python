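"""Chi-squared comparisons and mixed-model treatment tests."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps
from scipy.stats import chi2_contingency

from seedpellet.simulate import ArmSim, LotSimConfig, simulate_cohort
from seedpellet.stats import (
    DegenerateTableWarning,
    Direction,
    SpeciesDropped,
    compare_emergence,
    compare_survival,
    lot_level_treatment_test,
    pearson_chi2_2x2,
    time_to_emergence_model,
)
from seedpellet.metrics import summarize_records


def oracle_chi2(a, b, c, d):
    """Independent Sum (O-E)^2 / E computation from expected cells."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows, cols, n = obs.sum(1), obs.sum(0), obs.sum()
    exp = np.outer(rows, cols) / n
    return float(((obs - exp) ** 2 / exp).sum())


class TestPearsonChi2:
    def test_closed_form_example(self):
        # 100 * 750^2 / (50 * 50 * 85 * 15)
        x2, p = pearson_chi2_2x2(50, 0, 35, 15, correction=False)
        assert x2 == pytest.approx(17.647, abs=1e-3)
        assert p < 0.001

    def test_identical_arms(self):
        x2, p = pearson_chi2_2x2(20, 30, 20, 30, correction=False)
        assert (x2, p) == (0.0, 1.0)

    def test_small_table_matches_observed_vs_expected_oracle(self):
        x2, _ = pearson_chi2_2x2(3, 2, 1, 4, correction=False)
        assert x2 == pytest.approx(oracle_chi2(3, 2, 1, 4), abs=1e-12)

    def test_random_tables_match_scipy(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 60, size=4)
            if a + b == 0 or c + d == 0:
                continue
            table = np.array([[a, b], [c, d]])
            if (table.sum(0) == 0).any():
                continue
            for correction in (False, True):
                x2, p = pearson_chi2_2x2(a, b, c, d, correction=correction)
                ref = chi2_contingency(table, correction=correction)
                assert x2 == pytest.approx(ref.statistic, abs=1e-9)
                assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_yates_shrinks_statistic(self):
        plain, _ = pearson_chi2_2x2(30, 20, 20, 30, correction=False)
        corrected, _ = pearson_chi2_2x2(30, 20, 20, 30, correction=True)
        assert corrected < plain

    def test_degenerate_margin_warns_p1(self):
        with pytest.warns(DegenerateTableWarning):
            x2, p = pearson_chi2_2x2(10, 0, 12, 0)
        assert (x2, p) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(Exception):
            pearson_chi2_2x2(-1, 5, 2, 3)


class TestCompareEmergence:
    def test_acacia_decurrens_pellet_lower(self):
        res = compare_emergence("Acacia decurrens", 50, 50, 35, 50, correction=False)
        assert res.direction is Direction.PELLET_LOWER
        assert res.p_value < 0.05

    def test_equal_counts_no_difference(self):
        res = compare_emergence("sp", 20, 50, 20, 50)
        assert res.direction is Direction.NO_DIFFERENCE

    def test_1_vs_2_of_50_no_difference(self):
        res = compare_emergence("sp", 1, 50, 2, 50, correction=False)
        # oracle: the chi-squared p for this table is far above 0.05
        _, p_ref, _, _ = chi2_contingency([[1, 49], [2, 48]], correction=False)
        assert p_ref > 0.05 and res.direction is Direction.NO_DIFFERENCE

    def test_both_arms_zero_dropped(self):
        with pytest.raises(SpeciesDropped):
            compare_emergence("sp", 0, 50, 0, 50)

    def test_swapping_arms_flips_direction_preserves_p(self):
        a = compare_emergence("sp", 40, 50, 20, 50)
        b = compare_emergence("sp", 20, 50, 40, 50)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.direction is Direction.PELLET_LOWER
        assert b.direction is Direction.PELLET_HIGHER


class TestCompareSurvival:
    def test_pellet_lower_example(self):
        res = compare_survival("sp", 50, 50, 23, 35, correction=False)
        _, p_ref, _, _ = chi2_contingency([[50, 0], [23, 12]], correction=False)
        assert res.p_value == pytest.approx(p_ref)
        assert res.direction is Direction.PELLET_LOWER

    def test_all_alive_degenerate(self):
        with pytest.warns(DegenerateTableWarning):
            res = compare_survival("sp", 50, 50, 35, 35)
        assert res.direction is Direction.NO_DIFFERENCE
        assert res.p_value == 1.0

    def test_0_of_6_vs_9_of_13_follows_oracle(self):
        res = compare_survival("sp", 0, 6, 9, 13, correction=False)
        _, p_ref, _, _ = chi2_contingency([[0, 6], [9, 4]], correction=False)
        expected = Direction.PELLET_HIGHER if p_ref < 0.05 else Direction.NO_DIFFERENCE
        assert res.direction is expected

    def test_zero_emergence_arm_excluded(self):
        with pytest.raises(SpeciesDropped):
            compare_survival("sp", 0, 0, 9, 13)


def _delay_cohort(n_species=6, delayed=3, delay=10.0, seed=3):
    configs = [
        LotSimConfig(
            species=f"s{i}",
            bare=ArmSim(p_seed=0.5, median_days=20.0, log_sd=0.2),
            pellet=ArmSim(p_seed=0.5, median_days=20.0 + (delay if i < delayed else 0.0), log_sd=0.2),
        )
        for i in range(n_species)
    ]
    records, _ = simulate_cohort(configs, seed)
    return records


class TestTimeToEmergenceModel:
    def test_recovers_designed_delay(self):
        records = _delay_cohort()
        res = time_to_emergence_model(records)
        by_species = {c.species: c.direction for c in res.contrasts}
        assert all(by_species[f"s{i}"] is Direction.PELLET_HIGHER for i in range(3))
        assert all(by_species[f"s{i}"] is Direction.NO_DIFFERENCE for i in range(3, 6))
        assert res.global_p < 0.001

    def test_single_species_matches_welch(self):
        records = [r for r in _delay_cohort(n_species=1, delayed=1) if r.species == "s0"]
        res = time_to_emergence_model(records)
        (contrast,) = res.contrasts
        bare = [r.emergence_day for r in records if r.treatment == "bare" and r.emerged]
        pellet = [r.emergence_day for r in records if r.treatment == "pellet" and r.emerged]
        _, p_welch = sps.ttest_ind(pellet, bare, equal_var=False)
        # same decision and a p-value in the same regime
        assert contrast.direction is Direction.PELLET_HIGHER
        assert p_welch < 0.01 and contrast.p_value < 0.01

    def test_sparse_species_dropped(self):
        records = _delay_cohort(n_species=4, delayed=0)
        sparse = [
            r
            for r in records
            if not (r.species == "s3" and r.treatment == "pellet" and r.emerged)
        ]
        res = time_to_emergence_model(sparse, min_emerged=4)
        assert "s3" in res.dropped_species
        assert all(c.species != "s3" for c in res.contrasts)


class TestLotLevelTest:
    def test_no_effect_on_identical_metrics(self):
        records = _delay_cohort(n_species=5, delayed=0, seed=11)
        summaries = summarize_records(records)
        est, p = lot_level_treatment_test(summaries, "eri")
        assert p > 0.05

    def test_detects_eri_shift(self):
        # large per-seed probability difference shifts ERI strongly
        configs = [
            LotSimConfig(
                species=f"s{i}",
                bare=ArmSim(p_seed=0.2, median_days=20.0, log_sd=0.2),
                pellet=ArmSim(p_seed=0.8, median_days=20.0, log_sd=0.2),
            )
            for i in range(10)
        ]
        records, _ = simulate_cohort(configs, 5)
        est, p = lot_level_treatment_test(summarize_records(records), "eri")
        assert est > 0 and p < 0.01

    def test_requires_two_complete_species(self):
        records = _delay_cohort(n_species=1, delayed=0)
        with pytest.raises(Exception):
            lot_level_treatment_test(summarize_records(records), "tse")

    def test_rejects_unknown_metric(self):
        with pytest.raises(Exception):
            lot_level_treatment_test([], "mean_time")
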