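"""Shared fixtures: small deterministic anatomies and one reusable cohort."""

from __future__ import annotations

import numpy as np
import pytest

from ldrtox.geometry import ProstateAnatomy
from ldrtox.synthetic import GeneratorConfig, generate_cohort


def circle_polygon(radius: float, n: int = 48, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def stacked_anatomy(
    radius: float = 20.0,
    z_start: float = 0.0,
    z_stop: float = 40.0,
    dz: float = 2.5,
    urethra_center=(0.0, 0.0),
) -> ProstateAnatomy:
    """Cylindrical prostate: same circular slice repeated along z."""
    zs = np.arange(z_start, z_stop + dz / 2, dz)
    return ProstateAnatomy(
        slices=[(float(z), circle_polygon(radius)) for z in zs],
        urethra_centers=[urethra_center] * len(zs),
    )


@pytest.fixture(scope="session")
def single_slice_anatomy() -> ProstateAnatomy:
    return ProstateAnatomy(
        slices=[(0.0, circle_polygon(20.0))], urethra_centers=[(0.0, 0.0)]
    )


@pytest.fixture(scope="session")
def cylinder_anatomy() -> ProstateAnatomy:
    return stacked_anatomy()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort on a coarse grid, shared across tests."""
    return generate_cohort(
        GeneratorConfig(n_patients=12, voxel_mm=2.5, master_seed=42)
    )
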