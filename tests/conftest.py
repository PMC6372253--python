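"""Shared fixtures: hand-built geometries and small seeded phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from protonkbp.cases import BeamField, Case, Structure, TargetLevel, VoxelGrid
from protonkbp.phantoms import CohortSpec, generate_case


def make_slab_case(spacing: float = 4.0) -> Case:
    """Axis-aligned slab target in a small grid, single anterior field.

    The beam (gantry 0) travels along +y, so depth equals the y coordinate
    and every ray either misses the slab or crosses it in one interval —
    the geometry for which the 1-D closed form is exact.
    """
    grid = VoxelGrid((20, 24, 8), (spacing,) * 3, (-38.0, -46.0, -14.0))
    mask = np.zeros(grid.dims, dtype=bool)
    mask[6:14, 8:14, 2:6] = True
    target = Structure("ptv_b", mask, role="target")
    comp = Structure("ptv_comp", mask.copy(), role="composite")
    return Case(
        id="slab",
        grid=grid,
        targets=[TargetLevel(target, 70.0)],
        oars=[],
        fields=[BeamField(0.0, comp)],
    )


def make_horseshoe_case(spacing: float = 4.0) -> Case:
    """Horseshoe (C-shaped) target opening along -y around a central gap.

    A lateral beam (gantry 90/270) crosses both arms in two disjoint runs
    with the gap in between, exercising the sub-target rule.
    """
    grid = VoxelGrid((24, 24, 8), (spacing,) * 3, (-46.0, -46.0, -14.0))
    X, Y = np.meshgrid(grid.axis_coords(0), grid.axis_coords(1), indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    ring2d = (r >= 18.0) & (r <= 38.0) & ~((np.abs(X) < 10.0) & (Y < 0))
    mask = np.zeros(grid.dims, dtype=bool)
    mask[..., 2:6] = ring2d[..., None]
    target = Structure("ptv_b", mask, role="target")
    comp = Structure("ptv_comp", mask.copy(), role="composite")
    return Case(
        id="horseshoe",
        grid=grid,
        targets=[TargetLevel(target, 70.0)],
        oars=[],
        fields=[BeamField(90.0, comp)],
    )


@pytest.fixture(scope="session")
def slab_case() -> Case:
    return make_slab_case()


@pytest.fixture(scope="session")
def horseshoe_case() -> Case:
    return make_horseshoe_case()


@pytest.fixture(scope="session")
def phantom_case() -> Case:
    case, _ = generate_case(CohortSpec(n_cases=1, seed=7, spacing_mm=4.0), 0)
    return case


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_cases=6, seed=11, spacing_mm=4.0)
    return [generate_case(spec, i) for i in range(spec.n_cases)]
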