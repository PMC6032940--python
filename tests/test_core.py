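"""Unit and property tests for the DEB-IPM demographic functions and the
kernel discretisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from debipm.core import (
    DEBParams,
    SizeGrid,
    build_kernel,
    default_grid,
    dominant_eigenvalue,
    fecundity,
    growth_density,
    growth_mean,
    growth_sd,
    maturation_length,
    offspring_column,
    survival_prob,
    ultimate_length,
    vb_growth_rate,
)


class TestParams:
    def test_defaults_match_published_table(self, params):
        assert params.L_b == 0.166
        assert params.L_m == 1.008
        assert params.kappa == 0.083
        assert params.mu == 0.03
        assert params.R_m == 16
        assert params.sigma_Y == 0.3
        assert params.lp_coeff == 0.539
        assert (params.rb_c0, params.rb_c1) == (151.0, 137.8)
        assert params.sigma_Lb == 0.0

    @pytest.mark.parametrize(
        "bad",
        [
            {"kappa": 0.0},
            {"kappa": 1.0},
            {"mu": -0.1},
            {"L_b": -1.0},
            {"L_b": 2.0},  # above L_m
            {"lp_coeff": 1.5},
            {"rb_c1": 160.0},  # growth-rate denominator goes negative
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            DEBParams(**bad)

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        assert DEBParams.from_yaml(path) == params


class TestRateRules:
    """The derived-rate rules linking feeding level to lengths and growth."""

    def test_ultimate_length_values(self, params):
        assert ultimate_length(1.0, params) == pytest.approx(1.008)
        assert ultimate_length(0.36, params) == pytest.approx(0.36288)
        assert ultimate_length(1e-9, params) < 1e-8

    def test_ultimate_length_rejects_out_of_range(self, params):
        for bad in (0.0, -0.2, 1.2):
            with pytest.raises(ValueError):
                ultimate_length(bad, params)

    def test_maturation_length_values(self, params):
        assert maturation_length(1.0, params) == pytest.approx(0.543312)
        assert maturation_length(0.60, params) == pytest.approx(0.3259872)

    def test_zero_maturation_coefficient_means_mature_at_birth(self, params):
        p = params.replace(lp_coeff=1e-12)
        assert maturation_length(0.5, p) == pytest.approx(0.0, abs=1e-9)

    def test_growth_rate_values(self, params):
        assert vb_growth_rate(1.0, params) == pytest.approx(0.082661, abs=1e-6)
        # L_inf -> 0 limit: 1 / rb_c0
        assert vb_growth_rate(1e-9, params) == pytest.approx(1 / 151.0, rel=1e-6)

    def test_growth_rate_increases_with_feeding(self, params):
        assert vb_growth_rate(0.8, params) > vb_growth_rate(0.4, params)


class TestSurvival:
    def test_background_survival_below_starvation_bound(self, params):
        assert survival_prob(0.5, 0.5, params) == pytest.approx(math.exp(-0.03))

    def test_starvation_above_bound(self, params):
        # bound = 1.008 * 0.08 / 0.083 = 0.9715 < 1.0
        assert survival_prob(1.0, 0.08, params) == 0.0

    def test_zero_mortality(self, params):
        assert survival_prob(0.5, 0.5, params.replace(mu=0.0)) == 1.0

    def test_rejects_non_positive_length(self, params):
        with pytest.raises(ValueError):
            survival_prob(0.0, 0.5, params)


class TestGrowth:
    @settings(max_examples=20, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=1.0))
    def test_asymptote_is_a_fixed_point(self, ey):
        params = DEBParams()
        linf = ultimate_length(ey, params)
        assert growth_mean(linf, ey, params) == pytest.approx(linf, rel=1e-12)

    def test_newborn_daily_increment(self, params):
        assert growth_mean(0.166, 1.0, params) == pytest.approx(0.232801, abs=1e-5)

    def test_shrinking_above_asymptote(self, params):
        assert growth_mean(1.008, 0.5, params) < 1.008

    def test_growth_sd_value_and_degenerate_case(self, params):
        assert growth_sd(1.0, params) == pytest.approx(0.023991, abs=1e-5)
        assert growth_sd(0.7, params.replace(sigma_Y=0.0)) == 0.0
        assert growth_sd(0.8, params) > growth_sd(0.4, params)

    def test_density_peak_symmetry_and_normalisation(self, params):
        ey, L = 0.6, 0.3
        sd = growth_sd(ey, params)
        mean = growth_mean(L, ey, params)
        peak = growth_density(mean, L, ey, params)
        assert peak == pytest.approx(1.0 / (math.sqrt(2 * math.pi) * sd))
        d = 0.37 * sd
        assert growth_density(mean + d, L, ey, params) == pytest.approx(
            growth_density(mean - d, L, ey, params)
        )
        xs = np.linspace(mean - 8 * sd, mean + 8 * sd, 4001)
        assert np.trapezoid(growth_density(xs, L, ey, params), xs) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_density_refuses_degenerate_sd(self, params):
        with pytest.raises(ValueError):
            growth_density(0.2, 0.2, 0.5, params.replace(sigma_Y=0.0))


class TestReproduction:
    def test_maximum_rate_at_maximum_length(self, params):
        assert fecundity(1.008, 1.0, params) == pytest.approx(16.0)

    def test_juveniles_do_not_reproduce(self, params):
        # L_p(0.60) = 0.32599
        assert fecundity(0.30, 0.60, params) == 0.0

    def test_adult_rate(self, params):
        assert fecundity(0.50, 0.60, params) == pytest.approx(2.36206, abs=1e-5)

    def test_starving_lengths_are_sterile(self, params):
        ey = 0.08  # starvation bound 0.9715 mm
        assert fecundity(1.0, ey, params) == 0.0


class TestOffspringColumn:
    def test_point_mass_at_birth_length(self, params, grid):
        col = offspring_column(0.9, 1.0, grid, params)
        assert col.sum() == pytest.approx(1.0)
        (support,) = np.nonzero(col)
        assert len(support) == 1
        idx = support[0]
        assert grid.edges[idx] <= params.L_b <= grid.edges[idx + 1]

    def test_immature_parent_contributes_nothing(self, params, grid):
        assert not offspring_column(0.3, 1.0, grid, params).any()

    def test_gaussian_offspring_normalised(self, params, grid):
        col = offspring_column(0.9, 1.0, grid, params.replace(sigma_Lb=0.01))
        assert col.sum() == pytest.approx(1.0)

    def test_birth_length_outside_grid_is_configuration_error(self, params):
        grid = SizeGrid(0.5, 1.0, 10)
        with pytest.raises(ValueError):
            offspring_column(0.9, 1.0, grid, params)


def quadrature_kernel_oracle(ey, grid, params):
    """Independent midpoint-rule evaluation, entry by entry.

    Recomputes every kernel entry from the scalar demographic functions in
    plain Python loops — a deliberately different code path from the
    vectorised builder.
    """
    n = grid.n_bins
    A = np.zeros((n, n))
    sd = growth_sd(ey, params)
    lp = maturation_length(ey, params)
    ib = grid.bin_index(params.L_b)
    for j in range(n):
        Lj = grid.midpoints[j]
        s = survival_prob(Lj, ey, params)
        for i in range(n):
            Li = grid.midpoints[i]
            A[i, j] += growth_density(Li, Lj, ey, params) * s * grid.bin_width
        if Lj >= lp:
            A[ib, j] += fecundity(Lj, ey, params)
    return A


class TestKernel:
    def test_matches_independent_quadrature_on_coarse_grid(self, params, coarse_grid):
        for ey in (0.36, 0.7):
            k = build_kernel(ey, coarse_grid, params)
            oracle = quadrature_kernel_oracle(ey, coarse_grid, params)
            assert np.allclose(k.matrix, oracle, rtol=1e-10, atol=1e-12)

    def test_parts_sum_and_are_non_negative(self, params, grid):
        k = build_kernel(0.45, grid, params)
        assert np.allclose(k.matrix, k.fecundity_part + k.survival_part)
        assert (k.matrix >= 0).all()

    def test_no_reproduction_no_survival_empties_kernel(self, params, grid):
        k = build_kernel(0.5, grid, params.replace(R_m=0.0, mu=50.0))
        assert np.abs(k.matrix).max() < 1e-15

    def test_fecundity_linearity_in_R_m(self, params, grid):
        k1 = build_kernel(0.5, grid, params)
        k2 = build_kernel(0.5, grid, params.replace(R_m=32.0))
        assert np.allclose(k2.fecundity_part, 2.0 * k1.fecundity_part)
        assert np.allclose(k2.survival_part, k1.survival_part)

    def test_survivor_weighted_fecundity_variant(self, params, grid):
        base = build_kernel(0.5, grid, params)
        weighted = build_kernel(0.5, grid, params, fecundity_survival_weighted=True)
        assert np.allclose(
            weighted.fecundity_part, base.fecundity_part * math.exp(-params.mu)
        )

    @pytest.mark.parametrize("ey", [0.36, 0.5, 0.75, 1.0])
    def test_growth_conserves_mass_in_interior_columns(self, params, grid, ey):
        """Columns whose growth mean sits well inside the domain must pass
        on (nearly) exactly the per-day survival probability."""
        k = build_kernel(ey, grid, params)
        sd = growth_sd(ey, params)
        means = growth_mean(grid.midpoints, ey, params)
        interior = (means > grid.lower + 4 * sd) & (means < grid.upper - 4 * sd)
        col_sums = k.survival_part.sum(axis=0)[interior]
        expected = math.exp(-params.mu)
        assert col_sums.min() >= 0.999 * expected
        assert col_sums.max() <= 1.001 * expected

    def test_column_survival_never_exceeds_background(self, params, grid):
        """Growth redistributes or truncates mass, never creates it.

        At low feeding levels the growth SD drops below the bin width and
        the midpoint rule aliases by up to ~1%, so the bound carries that
        quadrature tolerance; at moderate feeding it is essentially exact.
        """
        for ey in (0.2, 0.5, 1.0):
            k = build_kernel(ey, grid, params)
            tol = 1.01 if ey < 0.36 else 1.0001
            assert k.survival_part.sum(axis=0).max() <= math.exp(-params.mu) * tol

    def test_eigenvalue_monotone_at_moderate_to_high_feeding(self, params, grid):
        """Above the feeding level where maturation stops interfering with
        the birth size (E(Y) ~ 0.4), more food means faster growth."""
        eys = np.linspace(0.45, 0.90, 10)
        lams = [dominant_eigenvalue(build_kernel(e, grid, params)) for e in eys]
        assert np.all(np.diff(lams) > 0)

    def test_export_round_trip(self, params, coarse_grid, tmp_path):
        k = build_kernel(0.42, coarse_grid, params)
        path = tmp_path / "kernel.txt"
        k.save(path)
        loaded = type(k).load(path)
        assert loaded.ey == 0.42
        assert loaded.grid == coarse_grid
        assert np.allclose(loaded.matrix, k.matrix)


class TestSizeGrid:
    def test_geometry(self, grid, params):
        assert grid.n_bins == 200
        assert grid.lower == pytest.approx(0.9 * params.L_b)
        assert grid.upper == params.L_m
        assert np.all(np.diff(grid.midpoints) > 0)
        assert grid.bin_width == pytest.approx((grid.upper - grid.lower) / 200)

    def test_bin_index_brackets_value(self, grid):
        for L in (0.166, 0.5, grid.upper):
            i = grid.bin_index(L)
            assert grid.edges[i] <= L <= grid.edges[i + 1]
        with pytest.raises(ValueError):
            grid.bin_index(0.01)
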