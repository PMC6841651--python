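import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.integrate import quad

import phrex
from phrex.kpis import phase_occupancy, round_half_up, transient_matrix_exp
from phrex.model import MODE_ORDER, StrokeType

from conftest import random_params

# Published destination percentages by age and stroke type (regression fixture).
TABLE3 = {
    (65, "Haemorrhagic"): (38.5, 4.0, 57.5),
    (65, "Cerebral infarction"): (19.4, 5.2, 75.5),
    (65, "TIA"): (1.3, 1.0, 97.7),
    (75, "Haemorrhagic"): (45.1, 5.8, 49.1),
    (75, "Cerebral infarction"): (20.5, 8.4, 71.1),
    (75, "TIA"): (3.0, 2.4, 94.6),
    (85, "Haemorrhagic"): (52.5, 7.3, 40.1),
    (85, "Cerebral infarction"): (21.9, 12.0, 66.1),
    (85, "TIA"): (6.6, 5.4, 88.0),
}

# Published mean LOS (days) by age, stroke type and destination, plus overall.
TABLE4 = {
    (65, "Haemorrhagic"): (18.6, 81.3, 33.7, 29.8),
    (65, "Cerebral infarction"): (38.2, 77.4, 29.8, 33.9),
    (65, "TIA"): (58.3, 58.3, 7.2, 8.4),
    (75, "Haemorrhagic"): (19.0, 78.5, 38.6, 32.1),
    (75, "Cerebral infarction"): (44.2, 73.4, 33.5, 39.0),
    (75, "TIA"): (58.3, 58.3, 9.3, 12.0),
    (85, "Haemorrhagic"): (19.0, 75.4, 45.3, 33.7),
    (85, "Cerebral infarction"): (49.7, 68.9, 38.9, 44.8),
    (85, "TIA"): (58.3, 58.3, 14.3, 19.6),
}


@pytest.fixture(scope="module")
def gens(ref_params):
    return {
        (st, age): phrex.build_generator(st, age, ref_params)
        for st in StrokeType for age in (65, 75, 85)
    }


class TestMatrixExponential:
    def test_against_scipy_on_random_parameter_sets(self):
        """Closed-form exp(Ty) vs scipy's scaling-and-squaring, 100 draws."""
        rng = np.random.default_rng(101)
        for _ in range(100):
            params = random_params(rng)
            st = list(StrokeType)[rng.integers(3)]
            gen = phrex.build_generator(st, rng.uniform(40, 100), params)
            y = rng.uniform(1e-3, 1.0)
            np.testing.assert_allclose(
                transient_matrix_exp(gen, y), scipy.linalg.expm(gen.T * y),
                rtol=1e-8, atol=1e-12)

    def test_near_tied_rates(self, ref_params):
        # force Lambda_2 == Lambda_3 to machine precision (confluent branch)
        r3 = ref_params.mu3 + ref_params.nu3 + ref_params.rho3
        p = ref_params.with_values(gamma2=-30.0, beta2=0.0,
                                   rho2=r3 - ref_params.mu2)
        gen = phrex.build_generator("haemorrhagic", 75, p)
        assert abs(gen.Lambda[1] - gen.Lambda[2]) < 1e-10
        np.testing.assert_allclose(
            transient_matrix_exp(gen, 0.2), scipy.linalg.expm(gen.T * 0.2),
            rtol=1e-8, atol=1e-12)


class TestDensityAndCdf:
    def test_density_integrates_to_one(self, gens):
        for gen in gens.values():
            total, _ = quad(lambda y: phrex.los_density(y, gen), 0, np.inf,
                            limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_matches_quadrature_of_density(self, gens):
        gen = gens[(StrokeType.CEREBRAL_INFARCTION, 75)]
        for y in (5.0, 30.0, 120.0):
            integral, _ = quad(lambda t: phrex.los_density(t, gen), 0, y,
                               limit=200, epsabs=1e-12)
            assert phrex.los_cdf(y, gen) == pytest.approx(integral, abs=1e-8)

    def test_density_is_negative_survival_derivative(self, gens):
        gen = gens[(StrokeType.HAEMORRHAGIC, 65)]
        h = 1e-4
        for y in (2.0, 20.0, 90.0):
            fd = -(phrex.survival(y + h, gen) - phrex.survival(y - h, gen)) / (2 * h)
            assert phrex.los_density(y, gen) == pytest.approx(fd, rel=1e-6)

    def test_cdf_boundaries_and_monotone(self, gens):
        gen = gens[(StrokeType.TIA, 85)]
        assert phrex.los_cdf(0.0, gen) == 0.0
        assert phrex.survival(0.0, gen) == pytest.approx(1.0)
        assert phrex.los_cdf(5000.0, gen) == pytest.approx(1.0, abs=1e-9)
        grid = phrex.los_cdf(np.linspace(0, 400, 200), gen)
        assert np.all(np.diff(grid) >= 0)

    def test_negative_stay_rejected(self, gens):
        gen = gens[(StrokeType.TIA, 65)]
        with pytest.raises(ValueError):
            phrex.los_density(-1.0, gen)

    def test_exponential_special_case(self, ref_params):
        """Degenerate start in phase 4: LOS is exactly Exp(rho4)."""
        gen = phrex.build_generator("tia", 20, ref_params.with_values(
            theta0=-800.0, theta1=0.0))
        assert gen.alpha[3] == pytest.approx(1.0)
        rho4 = ref_params.rho4 / phrex.DAYS_PER_YEAR  # per day
        for y in (0.5, 3.0, 10.0):
            assert phrex.los_density(y, gen) == pytest.approx(
                rho4 * np.exp(-rho4 * y), rel=1e-12)
        assert phrex.mean_los(gen) == pytest.approx(
            phrex.DAYS_PER_YEAR / ref_params.rho4, rel=1e-12)


class TestAbsorption:
    def test_rows_stochastic(self, gens):
        for gen in gens.values():
            P = phrex.absorption_probs(gen).P
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((P >= 0) & (P <= 1))

    def test_phase4_only_discharges_home(self, gens):
        P = phrex.absorption_probs(gens[(StrokeType.TIA, 75)]).P
        np.testing.assert_allclose(P[3], [0.0, 0.0, 1.0], atol=1e-15)

    def test_published_destination_rows(self, ref_params):
        row = phrex.destination_percentages(75, "haemorrhagic", ref_params)
        np.testing.assert_allclose(row / 100, (0.451, 0.058, 0.491), atol=5e-4)
        row = phrex.destination_percentages(65, "cerebral_infarction", ref_params)
        np.testing.assert_allclose(row / 100, (0.194, 0.052, 0.755), atol=5e-4)


class TestMeans:
    def test_law_of_total_expectation(self, gens):
        for gen in gens.values():
            P = phrex.absorption_probs(gen).P
            reach = gen.alpha @ P
            total = sum(
                reach[i] * phrex.mean_los_by_destination(gen, m)
                for i, m in enumerate(MODE_ORDER))
            assert total == pytest.approx(phrex.mean_los(gen), abs=1e-10)

    def test_unreachable_mode_rejected(self, ref_params):
        gen = phrex.build_generator("tia", 20, ref_params.with_values(
            theta0=-800.0, theta1=0.0))
        with pytest.raises(ValueError, match="unreachable"):
            phrex.mean_los_by_destination(gen, "death")

    def test_mean_residual_at_zero_is_mean_los(self, gens):
        for gen in gens.values():
            assert phrex.mean_residual(0.0, gen) == pytest.approx(
                phrex.mean_los(gen), rel=1e-12)

    def test_mean_residual_limit_is_phase3_mean(self, ref_params, gens):
        limit = phrex.DAYS_PER_YEAR / (
            ref_params.mu3 + ref_params.nu3 + ref_params.rho3)
        assert limit == pytest.approx(58.3, abs=0.05)
        for st in StrokeType:
            gen = gens[(st, 75)]
            assert phrex.mean_residual(2000.0, gen) == pytest.approx(
                limit, rel=1e-6)

    def test_tia_residual_rises_after_mild_cases_leave(self, gens):
        gen = gens[(StrokeType.TIA, 75)]
        assert phrex.mean_residual(10.0, gen) > phrex.mean_residual(0.0, gen)


class TestConditionalDestination:
    def test_at_zero_equals_alpha_P(self, gens):
        gen = gens[(StrokeType.CEREBRAL_INFARCTION, 85)]
        np.testing.assert_allclose(
            phrex.destination_probs_given_stay(0.0, gen),
            gen.alpha @ phrex.absorption_probs(gen).P, rtol=1e-12)

    def test_rows_sum_to_one_with_expected_death_trends(self, gens):
        grid = np.linspace(0.0, 300.0, 40)
        for st in StrokeType:
            probs = phrex.destination_probs_given_stay(grid, gens[(st, 75)])
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        early = np.linspace(0.0, 15.0, 10)
        # haemorrhagic survivors escape the high-mortality phase 1: the
        # death share falls steeply and never exceeds its admission value
        haem = phrex.destination_probs_given_stay(
            early, gens[(StrokeType.HAEMORRHAGIC, 75)])
        assert np.all(np.diff(haem[:, 0]) < 0)
        full = phrex.destination_probs_given_stay(
            grid, gens[(StrokeType.HAEMORRHAGIC, 75)])
        assert np.all(full[1:, 0] <= full[0, 0] + 1e-12)
        # TIA survivors are increasingly the severe (phase-3) subgroup:
        # their death share rises with incurred stay
        tia = phrex.destination_probs_given_stay(
            early, gens[(StrokeType.TIA, 75)])
        assert np.all(np.diff(tia[:, 0]) > 0)

    def test_long_stay_limit_is_phase3_row(self, gens):
        gen = gens[(StrokeType.HAEMORRHAGIC, 65)]
        P = phrex.absorption_probs(gen).P
        np.testing.assert_allclose(
            phrex.destination_probs_given_stay(2500.0, gen), P[2], rtol=1e-6)


class TestSubDistribution:
    def test_starts_at_zero_and_sums_to_cdf(self, gens):
        grid = np.linspace(0.0, 250.0, 30)
        for st in StrokeType:
            gen = gens[(st, 65)]
            total = sum(
                phrex.cumulative_discharge_by_mode(grid, gen, m)
                for m in MODE_ORDER)
            np.testing.assert_allclose(total, phrex.los_cdf(grid, gen),
                                       atol=1e-12)
            for m in MODE_ORDER:
                curve = phrex.cumulative_discharge_by_mode(grid, gen, m)
                assert curve[0] == pytest.approx(0.0, abs=1e-15)
                assert np.all(np.diff(curve) >= -1e-12)

    def test_limit_is_reach_probability(self, gens):
        gen = gens[(StrokeType.TIA, 85)]
        P = phrex.absorption_probs(gen).P
        for i, m in enumerate(MODE_ORDER):
            assert phrex.cumulative_discharge_by_mode(4000.0, gen, m) == \
                pytest.approx(float(gen.alpha @ P[:, i]), abs=1e-9)

    def test_matches_quadrature_of_mode_density(self, gens):
        gen = gens[(StrokeType.CEREBRAL_INFARCTION, 75)]
        col = gen.tA[:, 0]  # death

        def mode_density(y):
            return float(
                phase_occupancy(gen, y / phrex.DAYS_PER_YEAR) @ col
            ) / phrex.DAYS_PER_YEAR

        for y in (10.0, 60.0):
            integral, _ = quad(mode_density, 0, y, limit=200, epsabs=1e-12)
            assert phrex.cumulative_discharge_by_mode(y, gen, "death") == \
                pytest.approx(integral, abs=1e-9)


class TestReportTables:
    def test_destination_table_regression(self, ref_params):
        table = phrex.make_table3([65, 75, 85], ref_params, rounded=False)
        for (age, label), expected in TABLE3.items():
            np.testing.assert_allclose(
                table.loc[(age, label)].to_numpy(), expected, atol=0.1)
            assert table.loc[(age, label)].sum() == pytest.approx(100, abs=0.1)

    def test_mean_los_table_regression(self, ref_params):
        table = phrex.make_table4([65, 75, 85], ref_params, rounded=False)
        for (age, label), expected in TABLE4.items():
            np.testing.assert_allclose(
                table.loc[(age, label)].to_numpy(), expected, atol=0.1)

    def test_rounding_half_up(self):
        np.testing.assert_array_equal(
            round_half_up(np.array([1.25, 1.24, -1.25])), [1.3, 1.2, -1.3])
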