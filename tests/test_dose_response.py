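"""Dose-response estimation against closed forms and a grid-search oracle."""

import numpy as np
import pytest
from helpers import loglogistic_grid_oracle
from hypothesis import given, settings
from hypothesis import strategies as st

from beetox.dose_response import (
    BoundaryMortalityError,
    MortalityRecord,
    NonEstimableError,
    abbott_correct,
    ci_overlap_groups,
    fit_dose_response,
    ld50_with_ci,
    pooled_geometric_mean_ld50,
    qc_control_mortality,
)
from beetox.endpoints import SpeciesEndpoint
from beetox.synthetic import AssaySimConfig, generate_acute_test


def make_records(doses, deaths, n=10, control_deaths=0, control_n=10):
    """One cage per dose plus one control cage."""
    recs = [
        MortalityRecord("sp", "F", "r1", "ctrl", 0.0, control_n, control_deaths)
    ]
    for i, (d, k) in enumerate(zip(doses, deaths)):
        recs.append(MortalityRecord("sp", "F", "r1", f"c{i}", d, n, k))
    return recs


class TestAbbott:
    @pytest.mark.parametrize(
        "p_obs, p_control, expected",
        [(0.6, 0.2, 0.5), (0.37, 0.0, 0.37), (0.22, 0.22, 0.0), (0.1, 0.3, 0.0)],
    )
    def test_known_values(self, p_obs, p_control, expected):
        assert abbott_correct(p_obs, p_control) == pytest.approx(expected)

    def test_full_control_mortality_is_undefined(self):
        with pytest.raises(ValueError):
            abbott_correct(0.5, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        p1=st.floats(0, 1),
        p2=st.floats(0, 1),
        c=st.floats(0, 0.99),
    )
    def test_monotone_in_observed_and_identity_at_zero_control(self, p1, p2, c):
        lo, hi = sorted((p1, p2))
        assert abbott_correct(lo, c) <= abbott_correct(hi, c)
        assert abbott_correct(p1, 0.0) == pytest.approx(p1)


class TestFit:
    def test_matches_grid_oracle_on_hand_data(self):
        doses = (1.0, 2.0, 4.0, 8.0, 16.0)
        deaths = (1, 2, 5, 8, 9)
        fit = fit_dose_response(make_records(doses, deaths))
        ll_oracle, _, m_oracle = loglogistic_grid_oracle(doses, [10] * 5, deaths)
        assert fit.loglik >= ll_oracle - 1e-6  # optimizer at least as good as the grid
        assert abs(fit.loglik - ll_oracle) < 1e-3
        assert fit.ld50 == pytest.approx(10**m_oracle, rel=0.01)

    def test_matches_grid_oracle_with_background_mortality(self):
        doses = (0.5, 1.0, 2.0, 4.0)
        deaths = (3, 4, 7, 9)
        recs = make_records(doses, deaths, control_deaths=2, control_n=10)
        fit = fit_dose_response(recs, families=("log-logistic-2p",))
        ll_oracle, _, _ = loglogistic_grid_oracle(doses, [10] * 4, deaths, c=0.2)
        assert abs(fit.loglik - ll_oracle) < 1e-3

    def test_recovers_simulated_truth(self):
        cfg = AssaySimConfig(
            true_ld50=5.13, hill_slope=2.0, control_mortality=0.0,
            doses=(1.25, 2.5, 5.0, 10.0, 20.0), n_cages=50, bees_per_cage=10, seed=3,
        )
        fit = fit_dose_response(generate_acute_test(cfg))
        assert fit.ld50 == pytest.approx(5.13, rel=0.10)

    def test_step_data_brackets_ld50(self):
        fit = fit_dose_response(make_records((1, 2, 4, 8, 16), (0, 0, 0, 10, 10)))
        assert 4.0 < fit.ld50 < 8.0

    def test_ld50_scale_equivariance(self):
        doses = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        deaths = (1, 3, 5, 8, 9)
        fit1 = fit_dose_response(make_records(doses, deaths))
        fit7 = fit_dose_response(make_records(7.0 * doses, deaths))
        assert fit7.ld50 == pytest.approx(7.0 * fit1.ld50, rel=1e-3)
        assert fit7.slope == pytest.approx(fit1.slope, rel=1e-3)

    def test_needs_three_distinct_doses(self):
        with pytest.raises(NonEstimableError):
            fit_dose_response(make_records((1.0, 2.0), (2, 8)))

    def test_boundary_mortality_is_rejected_with_direction(self):
        with pytest.raises(BoundaryMortalityError, match="above"):
            fit_dose_response(make_records((1, 2, 4), (0, 0, 0)))
        with pytest.raises(BoundaryMortalityError, match="below"):
            fit_dose_response(make_records((1, 2, 4), (10, 10, 10)))

    def test_missing_control_group_is_rejected(self):
        recs = [MortalityRecord("sp", "F", "r1", f"c{i}", d, 10, k)
                for i, (d, k) in enumerate(zip((1, 2, 4), (2, 5, 8)))]
        with pytest.raises(NonEstimableError, match="control"):
            fit_dose_response(recs)

    def test_aic_selects_loglogistic_on_loglogistic_truth(self):
        # families separate only when the design covers the tails at large n
        doses = tuple(10.0 ** z for z in np.linspace(-3, 3, 9))
        wins = 0
        for i in range(10):
            cfg = AssaySimConfig(
                true_ld50=1.0, hill_slope=1.0, doses=doses,
                n_cages=100, bees_per_cage=10, seed=500 + i,
            )
            fit = fit_dose_response(generate_acute_test(cfg))
            wins += fit.model_family == "log-logistic-2p"
        assert wins >= 8


class TestConfidenceInterval:
    def test_interval_contains_point_estimate(self):
        fit = fit_dose_response(make_records((1, 2, 4, 8, 16), (1, 2, 5, 8, 9)))
        lo, hi = fit.ld50_ci
        assert lo <= fit.ld50 <= hi

    def test_doubling_n_shrinks_log_width_by_sqrt2(self):
        doses, deaths = (1, 2, 4, 8, 16), (1, 2, 5, 8, 9)
        fit1 = fit_dose_response(make_records(doses, deaths, n=10))
        fit2 = fit_dose_response(
            make_records(doses, tuple(2 * k for k in deaths), n=20, control_n=20)
        )
        w1 = np.log10(fit1.ld50_ci[1]) - np.log10(fit1.ld50_ci[0])
        w2 = np.log10(fit2.ld50_ci[1]) - np.log10(fit2.ld50_ci[0])
        assert w2 / w1 == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_wider_confidence_gives_wider_interval(self):
        fit = fit_dose_response(make_records((1, 2, 4, 8, 16), (1, 2, 5, 8, 9)))
        lo90, hi90 = ld50_with_ci(fit, 0.90)
        lo99, hi99 = ld50_with_ci(fit, 0.99)
        assert lo99 < lo90 < hi90 < hi99


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((2.0, 8.0), 4.0),                            # sqrt(16)
            ((5.0,), 5.0),                                # single value
            ((3.9, 4.3, 4.7), (3.9 * 4.3 * 4.7) ** (1 / 3)),  # cube root of product
        ],
    )
    def test_known_values(self, values, expected):
        assert pooled_geometric_mean_ld50(values) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_and_empty(self):
        with pytest.raises(ValueError):
            pooled_geometric_mean_ld50([1.0, 0.0])
        with pytest.raises(ValueError):
            pooled_geometric_mean_ld50([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8))
    def test_never_exceeds_arithmetic_mean(self, values):
        gm = pooled_geometric_mean_ld50(values)
        assert gm <= np.mean(values) * (1 + 1e-12)


class TestCIOverlap:
    def test_clearly_separated_species_differ(self):
        a = SpeciesEndpoint("Lasioglossum malachurum", 0.20, ld50_ci=(0.16, 0.24))
        b = SpeciesEndpoint("Bombus terrestris", 5.13, ld50_ci=(4.10, 6.15))
        comparisons, groups = ci_overlap_groups([a, b], alpha=0.05)
        assert comparisons[0].significant
        assert groups["Lasioglossum malachurum"] != groups["Bombus terrestris"]

    def test_overlapping_species_do_not_differ(self):
        a = SpeciesEndpoint("Andrena flavipes", 0.73, ld50_ci=(0.07, 1.39))
        b = SpeciesEndpoint("Colletes hederae", 1.14, ld50_ci=(0.72, 1.57))
        comparisons, groups = ci_overlap_groups([a, b], alpha=0.05)
        assert not comparisons[0].significant
        assert groups["Andrena flavipes"] == groups["Colletes hederae"]

    def test_identical_intervals_never_differ(self):
        a = SpeciesEndpoint("a", 1.0, ld50_ci=(0.8, 1.2))
        b = SpeciesEndpoint("b", 1.0, ld50_ci=(0.8, 1.2))
        comparisons, _ = ci_overlap_groups([a, b])
        assert not comparisons[0].significant

    def test_bonferroni_adjustment_widens_with_more_comparisons(self):
        # a pair disjoint at the plain level can overlap once adjusted for m pairs
        a = SpeciesEndpoint("a", 1.0, ld50_ci=(0.80, 1.25))
        b = SpeciesEndpoint("b", 1.8, ld50_ci=(1.30, 2.49))
        pair_only, _ = ci_overlap_groups([a, b])
        assert pair_only[0].significant
        extra = [
            SpeciesEndpoint(f"x{i}", 10.0 + i, ld50_ci=(9.0 + i, 11.0 + i))
            for i in range(4)
        ]
        many, _ = ci_overlap_groups([a, b] + extra)
        ab = next(c for c in many if set(c.pair) == {"a", "b"})
        assert not ab.significant
        assert ab.adjusted_confidence > pair_only[0].adjusted_confidence

    def test_endpoint_without_ci_excluded_with_warning(self):
        a = SpeciesEndpoint("a", 1.0, ld50_ci=(0.8, 1.2))
        b = SpeciesEndpoint("b", 5.0, ld50_ci=(4.0, 6.0))
        c = SpeciesEndpoint("c", 2.0)
        with pytest.warns(UserWarning, match="'c'"):
            comparisons, groups = ci_overlap_groups([a, b, c])
        assert len(comparisons) == 1
        assert "c" not in groups


class TestControlMortalityQC:
    def _records(self, rate, n=100):
        dead = round(rate * n)
        return [
            MortalityRecord("sp", "F", "r1", "ctrl", 0.0, n, dead),
            MortalityRecord("sp", "F", "r1", "c1", 1.0, 10, 5),
        ]

    @pytest.mark.parametrize("rate, flagged", [(0.13, True), (0.22, True), (0.0, False), (0.10, False)])
    def test_threshold_flagging(self, rate, flagged):
        report = qc_control_mortality(self._records(rate))
        assert report.loc[0, "control_mortality"] == pytest.approx(rate)
        assert bool(report.loc[0, "flagged"]) is flagged

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValueError, match="control"):
            qc_control_mortality([MortalityRecord("sp", "F", "r1", "c1", 1.0, 10, 5)])
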