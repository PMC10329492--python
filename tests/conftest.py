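"""Shared fixtures: slab concavity fields and the brute-force probe oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

import ablandscape as ab
from ablandscape.concavity import ProbeSweep
from ablandscape.geometry import collect_atoms, coords_of

SWEEP = ProbeSweep()


def slab_field(spec: ab.SlabSpec, spacing: float = 0.8):
    """Concavity field of a slab with uniform atom radii."""
    slab = ab.make_slab(spec)
    refs = collect_atoms(slab)
    field = ab.compute_field(
        slab, sweep=SWEEP, spacing=spacing, radii=np.full(len(refs), spec.atom_radius)
    )
    return slab, field


def brute_force_rinaccess(
    coords: np.ndarray,
    atom_radius: float,
    points: np.ndarray,
    field,
    sweep: ProbeSweep = SWEEP,
    fine: float = 0.4,
) -> np.ndarray:
    """Independent R_inaccess oracle: test every ball placement on a fine grid.

    A point is accessible to a probe of radius r when some fine-grid center
    exists with clearance >= r (exact distance to atom surfaces) within r of
    the point; placements are enumerated by brute force with KD-trees, with
    no morphology involved. The center grid is anchored to the field origin
    so both sides quantize candidate placements identically. Valid for open
    fixtures such as slabs, where every fitting probe position communicates
    with bulk solvent trivially.
    """
    pad = sweep.cap + 1.0
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    axes = []
    for d in range(3):
        k0 = int(np.floor((lo[d] - field.origin[d]) / fine))
        k1 = int(np.ceil((hi[d] - field.origin[d]) / fine))
        axes.append(field.origin[d] + fine * np.arange(k0, k1 + 1))
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = cKDTree(coords).query(centers)
    clearance = d - atom_radius

    values = np.full(len(points), sweep.cap)
    unassigned = np.ones(len(points), dtype=bool)
    for r in sweep.radii:
        valid = centers[clearance >= r]
        if len(valid):
            dd, _ = cKDTree(valid).query(points)
            accessible = dd <= r
        else:
            accessible = np.zeros(len(points), dtype=bool)
        values[unassigned & ~accessible] = r
        unassigned &= accessible
    return values


def pocket_voxel_points(spec: ab.SlabSpec, field) -> tuple[np.ndarray, np.ndarray]:
    """Voxel centers strictly inside the ideal cavity, with their field values."""
    shape = field.shape
    axes = [field.origin[d] + field.spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vals = field.values.ravel()
    center = np.array([0.0, 0.0, spec.surface_z])
    inside = (
        (np.linalg.norm(pts - center, axis=1) < spec.pocket_radius - 0.2)
        & (pts[:, 2] < spec.surface_z)
        & ~np.isnan(vals)
    )
    return pts[inside], vals[inside]


@pytest.fixture(scope="session")
def flat_slab_and_field():
    return slab_field(ab.SlabSpec(extent=40.0))


@pytest.fixture(scope="session")
def crevice_field():
    """Shaft too narrow for the smallest sweep probe (mouth radius 1.2 A)."""
    spec = ab.SlabSpec(extent=40.0, pocket_radius=1.2, pocket_depth=8.0)
    return spec, *slab_field(spec)


@pytest.fixture(scope="session")
def toy_pocket_complex():
    """Toy VHH complex whose H3 tip dips into a 3 A antigen pocket."""
    spec = ab.ToyComplexSpec(pocket_radius=3.0, seed=1)
    record, truth = ab.make_toy_complex(spec)
    return spec, record, truth


@pytest.fixture(scope="session")
def toy_flat_complex():
    spec = ab.ToyComplexSpec(pocket_radius=0.0, seed=2)
    record, truth = ab.make_toy_complex(spec)
    return spec, record, truth


def slab_coords(slab) -> np.ndarray:
    return coords_of(collect_atoms(slab))
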