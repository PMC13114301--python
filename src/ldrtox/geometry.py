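"""Prostate subzone geometry.

Builds a voxel grid around a contoured prostate and labels every voxel with
its membership in three anatomical partition families:

* axial       — Apex / MidGland / Base, a 1:2:1 split of the gland's
                superior–inferior extent (apex inferior, base superior);
* coronal     — Anterior / Posterior, split per slice by the coronal plane
                through the urethral center;
* radial      — Urethra (< 7 mm from the urethral center), Urethra10mm
                (the 7–10 mm annulus) and Peripheral (beyond 10 mm).

The 9 individual zones plus their pairwise/triple intersections give the
48-zone catalogue used for spatial dose featurization.

Coordinate conventions: distances in mm; +y is anterior; z increases toward
the superior (base) end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "ProstateAnatomy",
    "VoxelGrid",
    "ZoneCatalogue",
    "build_grid",
    "axial_partition",
    "label_voxels",
    "enumerate_zone_names",
    "zones_overlap",
]

AXIAL_ZONES = ("Base", "MidGland", "Apex")
CORONAL_ZONES = ("Anterior", "Posterior")
RADIAL_ZONES = ("Urethra", "Urethra10mm", "Peripheral")

#: radial components in catalogue order (Peripheral listed first in composites)
_RADIAL_ORDER = ("Peripheral", "Urethra", "Urethra10mm")


@dataclass
class ProstateAnatomy:
    """Contour stack for one patient.

    Parameters
    ----------
    slices
        Ordered list of ``(z_mm, polygon)`` pairs; each polygon is an
        ``(n, 2)`` array of in-plane vertices (closed implicitly).
    urethra_centers
        Per-slice urethral center ``(x_mm, y_mm)``, same length/order as
        ``slices``.
    urethra_radius
        Radius of the circular urethra surrogate (mm).
    nearzone_outer_radius
        Outer radius of the urethra-near annulus (mm).
    """

    slices: list[tuple[float, np.ndarray]]
    urethra_centers: list[tuple[float, float]]
    urethra_radius: float = 7.0
    nearzone_outer_radius: float = 10.0

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("anatomy must contain at least one contoured slice")
        if len(self.urethra_centers) != len(self.slices):
            missing = len(self.slices) - len(self.urethra_centers)
            raise ValueError(
                f"every contoured slice needs a urethra center ({missing} missing)"
            )
        zs = self.z_positions
        if np.any(np.diff(zs) <= 0):
            raise ValueError("slice z positions must be strictly increasing")
        if not 0 < self.urethra_radius < self.nearzone_outer_radius:
            raise ValueError("require 0 < urethra_radius < nearzone_outer_radius")
        for i, (z, poly) in enumerate(self.slices):
            p = Polygon(np.asarray(poly, dtype=float))
            if not p.is_valid or p.area <= 0:
                raise ValueError(f"slice {i} at z={z} mm: polygon is not simple")

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices], dtype=float)

    @property
    def z_extent(self) -> tuple[float, float]:
        zs = self.z_positions
        return float(zs[0]), float(zs[-1])

    def urethra_center_at(self, z: float | np.ndarray) -> np.ndarray:
        """Urethral center linearly interpolated in z (clamped at the ends)."""
        zs = self.z_positions
        cx = np.array([c[0] for c in self.urethra_centers])
        cy = np.array([c[1] for c in self.urethra_centers])
        return np.stack([np.interp(z, zs, cx), np.interp(z, zs, cy)], axis=-1)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice; voxel centers at origin + (i + 1/2) * spacing."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.spacing[axis]

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays (1-D per axis, x/y/z)."""
        return self.axis_centers(0), self.axis_centers(1), self.axis_centers(2)

    def flat_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel centers in C (x-fastest-last) order."""
        xs, ys, zs = self.centers()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class ZoneCatalogue:
    """Named voxel masks for the 48 individual and composite subzones."""

    grid: VoxelGrid
    zone_masks: dict[str, np.ndarray]  # name -> flat boolean mask, len n_voxels
    axial_boundaries: tuple[float, float]  # (apex/mid boundary z, mid/base boundary z)

    def __post_init__(self) -> None:
        expected = enumerate_zone_names()
        if list(self.zone_masks) != expected:
            raise ValueError("zone catalogue must contain exactly the 48 named zones")

    @property
    def zone_names(self) -> list[str]:
        return list(self.zone_masks)

    def volume_cc(self, name: str) -> float:
        return float(self.zone_masks[name].sum()) * self.grid.voxel_volume_mm3 / 1000.0

    @property
    def member_mask(self) -> np.ndarray:
        """Union of prostate and urethra voxels (the labeled set)."""
        return self.zone_masks["Prostate"] | self.zone_masks["Urethra"]


def enumerate_zone_names() -> list[str]:
    """The 48 zone names: 9 individual, 11 per axial region, 3 per coronal."""
    names = [
        "Prostate", "Anterior", "Posterior", "Urethra", "Urethra10mm",
        "Peripheral", "Base", "MidGland", "Apex",
    ]
    for axial in AXIAL_ZONES:
        for coronal in CORONAL_ZONES:
            names.append(f"{axial}_{coronal}")
            for radial in _RADIAL_ORDER:
                names.append(f"{axial}_{coronal}_{radial}")
        for radial in _RADIAL_ORDER:
            names.append(f"{axial}_{radial}")
    for coronal in CORONAL_ZONES:
        for radial in _RADIAL_ORDER:
            names.append(f"{coronal}_{radial}")
    assert len(names) == 48
    return names


def zone_components(name: str) -> dict[str, str | None]:
    """Split a zone name into its axial/coronal/radial components (None = all)."""
    comps: dict[str, str | None] = {"axial": None, "coronal": None, "radial": None}
    if name == "Prostate":
        return comps
    for part in name.split("_"):
        if part in AXIAL_ZONES:
            comps["axial"] = part
        elif part in CORONAL_ZONES:
            comps["coronal"] = part
        elif part in RADIAL_ZONES:
            comps["radial"] = part
        else:
            raise ValueError(f"unknown zone component {part!r} in {name!r}")
    return comps


def zones_overlap(a: str, b: str) -> bool:
    """True when two zones can share voxels (per-family components compatible)."""
    ca, cb = zone_components(a), zone_components(b)
    return all(
        ca[f] is None or cb[f] is None or ca[f] == cb[f]
        for f in ("axial", "coronal", "radial")
    )


def build_grid(
    anatomy: ProstateAnatomy,
    spacing: float | Sequence[float] = 1.0,
) -> VoxelGrid:
    """Voxel grid covering the anatomy with a margin of ``nearzone_outer_radius``
    in-plane and one slice thickness axially."""
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    dx, dy, dz = (float(s) for s in spacing)

    pts = np.vstack([np.asarray(poly, dtype=float) for _, poly in anatomy.slices])
    centers = np.asarray(anatomy.urethra_centers, dtype=float)
    r_out = anatomy.nearzone_outer_radius
    xy_min = np.minimum(pts.min(axis=0), centers.min(axis=0) - r_out) - r_out
    xy_max = np.maximum(pts.max(axis=0), centers.max(axis=0) + r_out) + r_out

    zs = anatomy.z_positions
    slab = float(np.diff(zs).max()) if len(zs) > 1 else dz
    z_min, z_max = zs[0] - slab, zs[-1] + slab

    lo = np.array([xy_min[0], xy_min[1], z_min])
    hi = np.array([xy_max[0], xy_max[1], z_max])
    sp = np.array([dx, dy, dz])
    dims = np.maximum(np.ceil((hi - lo) / sp).astype(int), 1)
    return VoxelGrid(origin=tuple(lo), spacing=(dx, dy, dz), dims=tuple(int(d) for d in dims))


def axial_partition(
    anatomy: ProstateAnatomy,
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """1:2:1 apex/midgland/base z-intervals on the contoured extent.

    Internal boundaries are half-open and owned by the superior zone:
    apex ``[z0, z0+L/4)``, midgland ``[z0+L/4, z0+3L/4)``, base the rest.
    """
    z0, z1 = anatomy.z_extent
    length = z1 - z0
    if length <= 0:
        raise ValueError("prostate superior-inferior extent must be positive")
    b1 = z0 + length / 4.0
    b2 = z0 + 3.0 * length / 4.0
    return (z0, b1), (b1, b2), (b2, z1)


def _prostate_mask_2d(
    poly: np.ndarray, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Boolean (nx, ny) center-point-in-polygon mask for one slice."""
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = shapely.points(gx.ravel(), gy.ravel())
    p = Polygon(np.asarray(poly, dtype=float))
    shapely.prepare(p)
    inside = shapely.contains(p, pts)
    return inside.reshape(len(xs), len(ys))


def label_voxels(anatomy: ProstateAnatomy, grid: VoxelGrid) -> ZoneCatalogue:
    """Assign every prostate/urethra voxel one label per partition family and
    materialize all 48 masks.

    Voxel membership is decided by the voxel center: a voxel belongs to the
    labeled set when its center falls inside the nearest contoured prostate
    polygon or within the urethra disc of its plane. Urethra voxels are kept
    even outside the prostate contour, since the urethra is its own subzone.
    """
    xs, ys, zvals = grid.centers()
    nx, ny, nz = grid.dims
    zs = anatomy.z_positions
    slice_half_gap = (float(np.diff(zs).max()) if len(zs) > 1 else grid.spacing[2]) / 2.0

    prostate = np.zeros((nx, ny, nz), dtype=bool)
    radial_r = np.full((nx, ny, nz), np.inf)
    anterior = np.zeros((nx, ny, nz), dtype=bool)

    # per-plane labeling: nearest contoured polygon, interpolated urethra center
    nearest = np.clip(np.searchsorted(zs, zvals), 0, len(zs) - 1)
    left = np.clip(nearest - 1, 0, len(zs) - 1)
    use_left = np.abs(zvals - zs[left]) <= np.abs(zs[nearest] - zvals)
    nearest_idx = np.where(use_left, left, nearest)
    in_axial_range = np.abs(zvals - zs[nearest_idx]) <= slice_half_gap

    centers = anatomy.urethra_center_at(zvals)  # (nz, 2)
    poly_masks: dict[int, np.ndarray] = {}
    for k in range(nz):
        if not in_axial_range[k]:
            continue
        si = int(nearest_idx[k])
        if si not in poly_masks:
            poly_masks[si] = _prostate_mask_2d(anatomy.slices[si][1], xs, ys)
        prostate[:, :, k] = poly_masks[si]
        ux, uy = centers[k]
        rr = np.hypot(xs[:, None] - ux, ys[None, :] - uy)
        radial_r[:, :, k] = rr
        anterior[:, :, k] = ys[None, :] > uy

    urethra = (radial_r < anatomy.urethra_radius) & in_axial_range[None, None, :]
    member = prostate | urethra

    # axial family on the contoured extent; voxels beyond the extent (from the
    # nearest-slice extension) are clamped into the end zones
    (a0, b1), (_, b2), _ = axial_partition(anatomy)
    z3 = np.broadcast_to(zvals[None, None, :], member.shape)
    apex = z3 < b1
    base = z3 >= b2
    mid = ~apex & ~base

    near = (radial_r >= anatomy.urethra_radius) & (
        radial_r < anatomy.nearzone_outer_radius
    )
    peripheral = radial_r >= anatomy.nearzone_outer_radius

    fam_axial = {"Apex": apex, "MidGland": mid, "Base": base}
    fam_coronal = {"Anterior": anterior, "Posterior": ~anterior}
    fam_radial = {"Urethra": urethra, "Urethra10mm": near, "Peripheral": peripheral}

    individual: dict[str, np.ndarray] = {"Prostate": prostate}
    for fam in (fam_axial, fam_coronal, fam_radial):
        for name, m in fam.items():
            individual[name] = m & member

    masks: dict[str, np.ndarray] = {}
    for name in enumerate_zone_names():
        if name in individual:
            masks[name] = individual[name].ravel()
        else:
            comps = name.split("_")
            m = individual[comps[0]].copy()
            for c in comps[1:]:
                m &= individual[c]
            masks[name] = m.ravel()

    return ZoneCatalogue(grid=grid, zone_masks=masks, axial_boundaries=(b1, b2))
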