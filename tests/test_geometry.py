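"""Subzone geometry: the 48-name catalogue, the 1:2:1 axial split and the
three partition families."""

import numpy as np
import pytest

from ldrtox.geometry import (
    ProstateAnatomy,
    axial_partition,
    build_grid,
    enumerate_zone_names,
    label_voxels,
    zones_overlap,
)
from ldrtox.synthetic import GeneratorConfig, generate_anatomy

from conftest import circle_polygon, stacked_anatomy

INDIVIDUAL = {
    "Prostate", "Anterior", "Posterior", "Urethra", "Urethra10mm",
    "Peripheral", "Base", "MidGland", "Apex",
}


class TestZoneNames:
    def test_catalogue_counts(self):
        names = enumerate_zone_names()
        assert len(names) == 48
        assert len(set(names)) == 48
        assert set(names[:9]) == INDIVIDUAL

    @pytest.mark.parametrize(
        "name",
        ["Apex_Anterior_Urethra", "Apex_Anterior_Urethra10mm",
         "MidGland_Posterior_Urethra", "Base_Urethra10mm",
         "Anterior_Peripheral", "Posterior_Urethra10mm"],
    )
    def test_expected_composites_present(self, name):
        assert name in enumerate_zone_names()

    def test_family_breakdown(self):
        names = enumerate_zone_names()
        per_axial = [n for n in names if n.startswith(("Base_", "MidGland_", "Apex_"))]
        per_coronal = [n for n in names if n.startswith(("Anterior_", "Posterior_"))]
        assert len(per_axial) == 33  # 11 per axial region
        assert len(per_coronal) == 6  # 3 per coronal region

    def test_overlap_rule(self):
        assert zones_overlap("Apex_Urethra10mm", "Apex_Anterior_Urethra10mm")
        assert zones_overlap("Prostate", "Apex_Urethra10mm")
        assert not zones_overlap("Apex_Urethra10mm", "Base_Urethra10mm")
        assert not zones_overlap("Apex_Urethra10mm", "Apex_Peripheral")


class TestAxialPartition:
    @pytest.mark.parametrize(
        "z_start,z_stop,expected",
        [
            (0.0, 40.0, ((0, 10), (10, 30), (30, 40))),
            (0.0, 8.0, ((0, 2), (2, 6), (6, 8))),
        ],
    )
    def test_one_two_one_split(self, z_start, z_stop, expected):
        anatomy = stacked_anatomy(z_start=z_start, z_stop=z_stop, dz=(z_stop - z_start) / 8)
        apex, mid, base = axial_partition(anatomy)
        for got, want in zip((apex, mid, base), expected):
            assert got == pytest.approx(want)

    def test_boundary_owned_by_superior_zone(self):
        """A voxel exactly on the apex/mid boundary belongs to the mid gland."""
        anatomy = stacked_anatomy(z_start=0.0, z_stop=40.0, dz=2.5)
        grid = build_grid(anatomy, (2.0, 2.0, 1.0))
        zones = label_voxels(anatomy, grid)
        zc = grid.axis_centers(2)
        k = int(np.argmin(np.abs(zc - 10.0)))
        assert zc[k] == pytest.approx(10.0)  # 1 mm spacing puts a center at 10.0
        nx, ny, nz = grid.dims
        plane = np.zeros((nx, ny, nz), dtype=bool)
        plane[:, :, k] = True
        member = zones.member_mask.reshape(nx, ny, nz)
        mid = zones.zone_masks["MidGland"].reshape(nx, ny, nz)
        assert np.array_equal(mid & plane, member & plane)


class TestBuildGrid:
    def test_margin_spans_single_slice(self, single_slice_anatomy):
        grid = build_grid(single_slice_anatomy, 1.0)
        span_x = grid.spacing[0] * grid.dims[0]
        span_y = grid.spacing[1] * grid.dims[1]
        assert span_x >= 60.0 and span_y >= 60.0  # 2 * (20 + 10) mm

    def test_dims_cover_anatomy_with_margin(self):
        anatomy = stacked_anatomy(radius=20.0, z_start=0.0, z_stop=40.0)
        grid = build_grid(anatomy, (1.0, 1.0, 1.0))
        assert grid.dims[0] >= 60 and grid.dims[1] >= 60 and grid.dims[2] >= 42

    def test_empty_anatomy_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ProstateAnatomy(slices=[], urethra_centers=[])

    def test_missing_urethra_center_names_the_gap(self):
        with pytest.raises(ValueError, match="urethra center"):
            ProstateAnatomy(
                slices=[(0.0, circle_polygon(20.0)), (2.5, circle_polygon(20.0))],
                urethra_centers=[(0.0, 0.0)],
            )


@pytest.fixture(scope="module")
def labeled(cylinder_anatomy):
    grid = build_grid(cylinder_anatomy, 1.0)
    return grid, label_voxels(cylinder_anatomy, grid)


class TestLabeling:
    def _flat_index(self, grid, x, y, z):
        idx = [
            int(np.argmin(np.abs(grid.axis_centers(ax) - v)))
            for ax, v in enumerate((x, y, z))
        ]
        return np.ravel_multi_index(idx, grid.dims)

    @pytest.mark.parametrize(
        "x,y,expected_radial",
        [(3.0, 0.0, "Urethra"), (8.5, 0.0, "Urethra10mm"), (14.0, 0.0, "Peripheral")],
    )
    def test_radial_labels(self, labeled, x, y, expected_radial):
        grid, zones = labeled
        j = self._flat_index(grid, x, y, 20.0)
        for radial in ("Urethra", "Urethra10mm", "Peripheral"):
            assert zones.zone_masks[radial][j] == (radial == expected_radial)

    def test_anterior_posterior_split_by_urethral_center(self, labeled):
        grid, zones = labeled
        ant = self._flat_index(grid, 12.0, 2.0, 20.0)  # 2 mm anterior of center
        post = self._flat_index(grid, 12.0, -2.0, 20.0)
        assert zones.zone_masks["Anterior"][ant]
        assert zones.zone_masks["Posterior"][post]

    def test_urethra_kept_outside_prostate_polygon(self):
        # urethra center near the boundary: part of its 7 mm disc pokes out
        anatomy = stacked_anatomy(radius=20.0, urethra_center=(16.0, 0.0))
        grid = build_grid(anatomy, 1.0)
        zones = label_voxels(anatomy, grid)
        j = np.ravel_multi_index(
            [
                int(np.argmin(np.abs(grid.axis_centers(0) - 22.0))),
                int(np.argmin(np.abs(grid.axis_centers(1) - 0.0))),
                int(np.argmin(np.abs(grid.axis_centers(2) - 20.0))),
            ],
            grid.dims,
        )
        assert not zones.zone_masks["Prostate"][j]  # outside the 20 mm circle
        assert zones.zone_masks["Urethra"][j]  # but inside the urethra disc


class TestPartitionInvariants:
    FAMILIES = (
        ("Base", "MidGland", "Apex"),
        ("Anterior", "Posterior"),
        ("Urethra", "Urethra10mm", "Peripheral"),
    )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_families_partition_membership(self, seed):
        rng = np.random.default_rng(seed)
        anatomy = generate_anatomy(GeneratorConfig(), rng)
        grid = build_grid(anatomy, 2.0)
        zones = label_voxels(anatomy, grid)
        member = zones.member_mask
        for family in self.FAMILIES:
            combined = np.zeros_like(member, dtype=int)
            for name in family:
                combined += zones.zone_masks[name]
            assert np.array_equal(combined > 0, member), family
            assert combined.max() == 1, f"{family} overlaps"

    @pytest.mark.parametrize("seed", [3, 4])
    def test_composites_are_intersections(self, seed):
        rng = np.random.default_rng(seed)
        anatomy = generate_anatomy(GeneratorConfig(), rng)
        grid = build_grid(anatomy, 2.5)
        zones = label_voxels(anatomy, grid)
        for name, mask in zones.zone_masks.items():
            parts = name.split("_")
            if len(parts) == 1:
                continue
            expected = zones.zone_masks[parts[0]].copy()
            for p in parts[1:]:
                expected &= zones.zone_masks[p]
            assert np.array_equal(mask, expected), name

    def test_axial_volumes_sum_to_total(self):
        rng = np.random.default_rng(9)
        anatomy = generate_anatomy(GeneratorConfig(), rng)
        grid = build_grid(anatomy, 2.0)
        zones = label_voxels(anatomy, grid)
        total = zones.member_mask.sum()
        parts = sum(zones.zone_masks[z].sum() for z in ("Base", "MidGland", "Apex"))
        assert parts == total

    def test_isotropic_scaling_scales_volumes_cubically(self):
        factor = 1.3
        base = stacked_anatomy(radius=15.0, z_start=0.0, z_stop=30.0)
        scaled = ProstateAnatomy(
            slices=[(z * factor, poly * factor) for z, poly in base.slices],
            urethra_centers=[(0.0, 0.0)] * len(base.slices),
            urethra_radius=base.urethra_radius * factor,
            nearzone_outer_radius=base.nearzone_outer_radius * factor,
        )
        vols = {}
        for tag, anatomy in (("base", base), ("scaled", scaled)):
            grid = build_grid(anatomy, 0.8)
            zones = label_voxels(anatomy, grid)
            vols[tag] = {z: zones.volume_cc(z) for z in ("Prostate", "Apex", "Urethra10mm")}
        for z in vols["base"]:
            ratio = vols["scaled"][z] / vols["base"][z]
            # one-voxel-layer boundary effects on the quarter-length apex
            # dominate the error at 0.8 mm spacing
            assert ratio == pytest.approx(factor**3, rel=0.10), z
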