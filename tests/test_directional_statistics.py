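"""Horizon-crossing directions, Rayleigh test, nested ANOVA and the
incidence chi-square."""

import numpy as np
import pytest
from scipy import stats

from qpicell.dirstats import (
    gradient_component_anova,
    gradient_displacement_components,
    horizon_directions,
    incidence_chi_square,
    nested_anova,
    rayleigh_test,
)


class TestHorizonDirections:
    def test_straight_track_along_x(self):
        path = np.column_stack([np.linspace(0, 100, 21), np.zeros(21)])
        sample = horizon_directions([path], horizon_um=70.0)
        assert sample.n_reaching == 1
        assert sample.angles_rad[0] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_track_crossing_point(self):
        path = np.column_stack([np.linspace(0, 100, 51)] * 2)
        sample = horizon_directions([path], horizon_um=70.0)
        assert sample.angles_rad[0] == pytest.approx(np.pi / 4, abs=1e-9)

    def test_l_shaped_track_interpolated_crossing(self):
        # 60 um along +x then 60 um along +y; crossing at distance 70
        # happens on the second leg at y* = sqrt(70^2 - 60^2)
        path = np.array([[0.0, 0.0], [60.0, 0.0], [60.0, 60.0]])
        sample = horizon_directions([path], horizon_um=70.0)
        y_star = np.sqrt(70.0 ** 2 - 60.0 ** 2)
        expected = np.arctan2(y_star, 60.0)
        assert sample.angles_rad[0] == pytest.approx(expected, abs=1e-12)
        # dense numeric sampling of the same path agrees
        dense = np.concatenate([
            np.column_stack([np.linspace(0, 60, 6001), np.zeros(6001)]),
            np.column_stack([np.full(6001, 60.0), np.linspace(0, 60, 6001)]),
        ])
        dense_sample = horizon_directions([dense], horizon_um=70.0)
        assert dense_sample.angles_rad[0] == pytest.approx(expected, abs=1e-4)

    def test_non_reaching_track_excluded(self):
        short = np.column_stack([np.linspace(0, 30, 10), np.zeros(10)])
        sample = horizon_directions([short], horizon_um=70.0)
        assert sample.n_reaching == 0
        assert sample.n_total_cells == 1

    def test_points_after_crossing_irrelevant(self):
        base = np.column_stack([np.linspace(0, 80, 9), np.zeros(9)])
        extended = np.vstack([base, [[0.0, 500.0], [-300.0, -300.0]]])
        a = horizon_directions([base], 70.0).angles_rad
        b = horizon_directions([extended], 70.0).angles_rad
        assert np.array_equal(a, b)


class TestRayleighTest:
    def test_identical_angles_maximal_concentration(self):
        res = rayleigh_test(np.full(10, 0.7))
        assert res.mean_resultant_length == pytest.approx(1.0)
        assert res.z_statistic == pytest.approx(10.0)
        assert res.p_value < 1e-4
        assert res.mean_direction_rad == pytest.approx(0.7)

    def test_symmetric_angles_give_zero_resultant(self):
        res = rayleigh_test(np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3]))
        assert res.mean_resultant_length == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_p_value_invariant_under_rotation(self):
        rng = np.random.default_rng(0)
        angles = rng.vonmises(0.5, 1.2, size=40)
        a = rayleigh_test(angles)
        b = rayleigh_test(np.mod(angles + 1.234 + np.pi, 2 * np.pi) - np.pi)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)
        assert b.mean_resultant_length == pytest.approx(
            a.mean_resultant_length, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([0.1, 0.2]))

    def test_concentrated_sample_ci_contains_true_direction(self):
        rng = np.random.default_rng(1)
        angles = rng.vonmises(0.8, 4.0, size=60)
        res = rayleigh_test(angles)
        assert abs(np.angle(np.exp(1j * (res.mean_direction_rad - 0.8)))) \
            < res.ci95_halfwidth_rad


class TestNestedAnova:
    def test_identical_populations_null(self):
        movie = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])]
        res = nested_anova([movie, [m.copy() for m in movie]])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_movie_population_rejected(self):
        with pytest.raises(ValueError, match="single movie"):
            nested_anova([[np.array([1.0, 2.0])],
                          [np.array([1.0]), np.array([2.0])]])

    def test_balanced_case_matches_movie_mean_anova(self):
        # In a balanced design, testing the population effect against the
        # between-movie stratum is exactly a one-way ANOVA on movie means:
        # an independent closed-form oracle for F and p.
        rng = np.random.default_rng(2)
        pops = []
        for i in range(3):
            pops.append([
                rng.normal(0.5 * i, 1.0, size=8) + rng.normal(0, 0.5)
                for _ in range(4)
            ])
        res = nested_anova(pops)
        means = [[m.mean() for m in movies] for movies in pops]
        ref = stats.f_oneway(*means)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.df_num == 2 and res.df_den == 9

    def test_unbalanced_sums_match_explicit_decomposition(self):
        # brute-force sums of squares on an unbalanced layout
        rng = np.random.default_rng(5)
        pops = [
            [rng.normal(0.0, 1.0, size=n) for n in (5, 9, 3)],
            [rng.normal(0.8, 1.0, size=n) for n in (7, 4)],
        ]
        res = nested_anova(pops)
        allv = np.concatenate([np.concatenate(m) for m in pops])
        grand = allv.mean()
        ss_pop = sum(
            len(np.concatenate(m)) * (np.concatenate(m).mean() - grand) ** 2
            for m in pops
        )
        ss_mov = sum(
            len(mv) * (mv.mean() - np.concatenate(movies).mean()) ** 2
            for movies in pops for mv in movies
        )
        f_expected = (ss_pop / 1) / (ss_mov / 3)
        assert res.f_statistic == pytest.approx(f_expected, rel=1e-12)

    def test_drift_detected_with_high_power(self):
        # 0 vs 5 um/h drift along the gradient, 4 movies x 20 cells
        rng = np.random.default_rng(3)
        n_reject = 0
        n_rep = 100
        for _ in range(n_rep):
            groups = []
            for drift in (0.0, 5.0):
                movies = []
                for _ in range(4):
                    cells = rng.normal(drift, 3.0, size=20)
                    movies.append(cells + rng.normal(0, 0.5))
                groups.append(movies)
            if nested_anova(groups).p_value < 0.05:
                n_reject += 1
        assert n_reject / n_rep >= 0.90

    def test_gradient_components_per_cell(self):
        # straight-line tracks: the mean step projection is the step itself
        tracks = [
            np.column_stack([np.linspace(0, 10, 11), np.zeros(11)]),
            np.column_stack([np.zeros(11), np.linspace(0, 10, 11)]),
        ]
        comp = gradient_displacement_components(tracks, 0.0)
        assert comp == pytest.approx([1.0, 0.0])

    def test_grouped_interface_with_reference_contrasts(self):
        rng = np.random.default_rng(4)

        def movie(drift):
            return [
                np.cumsum(rng.normal([drift / 6, 0], 0.5, size=(10, 2)), axis=0)
                for _ in range(15)
            ]

        grouped = {
            "K2": [movie(0.0) for _ in range(3)],
            "A297": [movie(3.0) for _ in range(3)],
        }
        out = gradient_component_anova(grouped, 0.0, reference="K2")
        assert "A297" in out["contrasts"]
        assert out["contrasts"]["A297"].p_value < 0.05


class TestIncidenceChiSquare:
    def test_independent_table_is_zero(self):
        chi2, p = incidence_chi_square(5, 5, 5, 5)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy_contingency(self):
        chi2, p = incidence_chi_square(3, 17, 11, 9)
        ref = stats.chi2_contingency([[3, 17], [11, 9]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_metastasis_incidence_tables_significant(self):
        # 0/20 vs 9/24 and 0/20 vs 9/10 animals with metastasis
        chi2_t15, p_t15 = incidence_chi_square(0, 20, 9, 15)
        assert chi2_t15 == pytest.approx(9.4286, abs=2e-4)
        assert p_t15 == pytest.approx(2.1e-3, rel=0.05)
        _, p_a297 = incidence_chi_square(0, 20, 9, 1)
        assert p_t15 < 0.01 and p_a297 < 0.01

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            incidence_chi_square(0, 0, 5, 5)

    def test_yates_correction_reduces_statistic(self):
        plain, _ = incidence_chi_square(2, 8, 7, 3)
        corrected, _ = incidence_chi_square(2, 8, 7, 3, yates=True)
        assert corrected < plain
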