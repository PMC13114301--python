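"""TG-43 point-source engine against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from ldrtox.dosimetry import (
    BEST_2301,
    GENERIC_I125,
    DoseGrid,
    R_MIN_CM,
    SeedImplant,
    compute_dose_grid,
    initial_dose_rate,
    total_dose,
)
from ldrtox.geometry import VoxelGrid


def grid_cube(extent_mm: float = 50.0, spacing: float = 2.0) -> VoxelGrid:
    n = int(extent_mm / spacing)
    return VoxelGrid(
        origin=(-extent_mm / 2, -extent_mm / 2, -extent_mm / 2),
        spacing=(spacing,) * 3,
        dims=(n, n, n),
    )


class TestInitialDoseRate:
    def test_reference_point_identity(self):
        """At r = 1 cm with g(1) = 1 and unit anisotropy the rate is Sk * Lambda."""
        imp = SeedImplant(seeds=[[0, 0, 0]], air_kerma_strength=1.0,
                          source_model=GENERIC_I125)
        rate = initial_dose_rate([0, 0, 0], [[10.0, 0.0, 0.0]], imp)[0]
        assert rate == pytest.approx(GENERIC_I125.dose_rate_constant, rel=1e-12)

    def test_inverse_square_with_table_factors(self):
        sm = BEST_2301
        imp = SeedImplant(seeds=[[0, 0, 0]], air_kerma_strength=2.0, source_model=sm)
        rate = initial_dose_rate([0, 0, 0], [[20.0, 0.0, 0.0]], imp)[0]
        expected = (
            2.0 * sm.dose_rate_constant * 0.25
            * sm.radial_dose_function(np.array([2.0]))[0]
            * sm.anisotropy_factor(np.array([2.0]))[0]
        )
        assert rate == pytest.approx(expected, rel=1e-12)

    def test_tables_match_log_linear_interpolation_oracle(self):
        sm = BEST_2301
        rng = np.random.default_rng(0)
        radii = rng.uniform(0.12, 9.5, size=40)
        for r in radii:
            table = sm.radial_dose_table
            rs = np.array([p[0] for p in table])
            vs = np.array([p[1] for p in table])
            i = np.searchsorted(rs, r) - 1
            w = (np.log(r) - np.log(rs[i])) / (np.log(rs[i + 1]) - np.log(rs[i]))
            expected = vs[i] + w * (vs[i + 1] - vs[i])
            assert sm.radial_dose_function(np.array([r]))[0] == pytest.approx(
                expected, rel=1e-12
            )

    def test_minimum_radius_clamp(self):
        imp = SeedImplant(seeds=[[0, 0, 0]], air_kerma_strength=1.0)
        near = initial_dose_rate([0, 0, 0], [[0.2, 0.0, 0.0]], imp)[0]
        at_clamp = initial_dose_rate([0, 0, 0], [[R_MIN_CM * 10, 0.0, 0.0]], imp)[0]
        assert np.isfinite(near)
        assert near == pytest.approx(at_clamp, rel=1e-12)

    def test_beyond_table_continues_with_inverse_square_only(self):
        sm = BEST_2301
        imp = SeedImplant(seeds=[[0, 0, 0]], air_kerma_strength=1.0, source_model=sm)
        r_far, r_last = 15.0, 10.0
        rate_far = initial_dose_rate([0, 0, 0], [[r_far * 10, 0, 0]], imp)[0]
        rate_last = initial_dose_rate([0, 0, 0], [[r_last * 10, 0, 0]], imp)[0]
        assert rate_far == pytest.approx(rate_last * (r_last / r_far) ** 2, rel=1e-12)


class TestTotalDose:
    def test_decay_integral_matches_numerical_quadrature(self):
        """Permanent-implant dose = rate * T_half/ln2, checked against direct
        integration of the exponentially decaying rate."""
        sm = BEST_2301
        rate = 7.0  # cGy/h
        lam = np.log(2) / (sm.half_life_days * 24.0)
        numeric, _ = quad(lambda t: rate * np.exp(-lam * t), 0, np.inf)
        closed = total_dose(np.array([rate]), sm)[0]
        assert closed == pytest.approx(numeric / 100.0, rel=1e-9)
        assert closed == pytest.approx(144.0, rel=0.01)  # ~144 Gy at 7 cGy/h

    def test_zero_rate_zero_dose_and_linearity(self):
        sm = BEST_2301
        assert total_dose(np.zeros(3), sm).sum() == 0.0
        r = np.array([1.0, 2.0, 5.0])
        assert np.allclose(total_dose(2 * r, sm), 2 * total_dose(r, sm))

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            total_dose(np.array([np.inf]), BEST_2301)


class TestComputeDoseGrid:
    def test_single_seed_isotropic(self):
        grid = grid_cube(40.0, 2.0)
        imp = SeedImplant(seeds=[[1.0, 1.0, 1.0]], air_kerma_strength=0.5)
        dose = compute_dose_grid(imp, grid)
        pts = grid.flat_centers()
        r = np.linalg.norm(pts - np.array([1.0, 1.0, 1.0]), axis=1)
        # equal radii -> equal dose under the 1-D formalism
        order = np.argsort(r)
        r_sorted, d_sorted = r[order], dose.dose_gy[order]
        same = np.abs(np.diff(r_sorted)) < 1e-9
        assert np.allclose(np.diff(d_sorted)[same], 0.0, atol=1e-12)

    def test_superposition_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        seeds = rng.uniform(-15, 15, size=(60, 3))
        grid = grid_cube(50.0, 5.0)
        imp = SeedImplant(seeds=seeds, air_kerma_strength=0.43)
        dose = compute_dose_grid(imp, grid)

        pts = grid.flat_centers()
        oracle = np.zeros(len(pts))
        for s in seeds:
            oracle += initial_dose_rate(s, pts, imp)
        oracle = total_dose(oracle, imp.source_model)
        assert np.allclose(dose.dose_gy, oracle, rtol=1e-9, atol=0)

    def test_two_identical_seeds_double_one(self):
        grid = grid_cube(40.0, 4.0)
        one = compute_dose_grid(
            SeedImplant(seeds=[[0, 0, 0]], air_kerma_strength=0.5), grid
        )
        two = compute_dose_grid(
            SeedImplant(seeds=[[0, 0, 0], [0, 0, 0]], air_kerma_strength=0.5), grid
        )
        assert np.allclose(two.dose_gy, 2 * one.dose_gy, rtol=1e-12)

    def test_doubling_strength_doubles_dose(self):
        grid = grid_cube(40.0, 4.0)
        lo = compute_dose_grid(SeedImplant(seeds=[[2, 3, 1]], air_kerma_strength=0.4), grid)
        hi = compute_dose_grid(SeedImplant(seeds=[[2, 3, 1]], air_kerma_strength=0.8), grid)
        assert np.allclose(hi.dose_gy, 2 * lo.dose_gy, rtol=1e-12)

    def test_monotone_falloff_along_ray(self):
        imp = SeedImplant(seeds=[[0, 0, 0]], air_kerma_strength=1.0)
        radii_mm = np.linspace(2.0, 90.0, 200)
        pts = np.column_stack([radii_mm, np.zeros_like(radii_mm), np.zeros_like(radii_mm)])
        rates = initial_dose_rate([0, 0, 0], pts, imp)
        assert np.all(np.diff(rates) <= 1e-12)

    def test_translation_leaves_doses_unchanged(self):
        shift = np.array([7.0, -4.0, 3.0])
        grid = grid_cube(40.0, 4.0)
        moved = VoxelGrid(
            origin=tuple(np.array(grid.origin) + shift),
            spacing=grid.spacing,
            dims=grid.dims,
        )
        seeds = np.array([[1.0, 2.0, -3.0], [-5.0, 0.0, 4.0]])
        d0 = compute_dose_grid(SeedImplant(seeds=seeds, air_kerma_strength=0.5), grid)
        d1 = compute_dose_grid(
            SeedImplant(seeds=seeds + shift, air_kerma_strength=0.5), moved
        )
        assert np.allclose(d0.dose_gy, d1.dose_gy, rtol=1e-12)

    def test_seed_outside_grid_warns_but_sums(self):
        grid = grid_cube(20.0, 4.0)
        imp = SeedImplant(seeds=[[100.0, 0.0, 0.0]], air_kerma_strength=1.0)
        with pytest.warns(UserWarning, match="outside grid"):
            dose = compute_dose_grid(imp, grid)
        assert dose.dose_gy.max() > 0

    def test_percent_representation(self):
        grid = grid_cube(20.0, 10.0)
        dose = DoseGrid(grid=grid, dose_gy=np.full(grid.n_voxels, 55.0),
                        prescription_gy=110.0)
        assert np.allclose(dose.dose_pct, 50.0)
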