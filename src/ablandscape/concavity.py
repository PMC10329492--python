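"""Multiscale probe-inaccessibility field (R_inaccess) and its summaries.

The concavity of a point in space over a molecule's surface is quantified as
the radius of the *smallest* spherical probe, drawn from an ascending sweep
(default 2.5, 3.5, ..., 10.5 A), that cannot reach the point from bulk
solvent. A value at the sweep cap (10.5 A) means every probe reaches the
point — a flat surface; the sweep floor (2.5 A) marks space so enclosed that
no probe of the sweep enters (deep crevices and interior cavities).

The field is computed on a voxel grid by mathematical morphology. For each
probe radius r, the solvent region accessible to that probe is the
morphological opening of the protein-complement by a ball of radius r,
restricted to the connected component in contact with the box boundary
(bulk solvent):

* erosion: probe-center voxels are those whose Euclidean distance to the
  nearest protein-occupied voxel is at least r (one distance transform);
* bulk restriction: 6-connected components of the center set touching a box
  face;
* dilation: the swept volume is every voxel within r of a retained center
  (a second distance transform, measured from the center set).

Accessible sets are intersected cumulatively along the ascending sweep, so
the nesting property accessible(r2) ⊆ accessible(r1) for r2 > r1 holds
exactly and R_inaccess is single-valued: the smallest r whose accessible set
excludes the voxel.

The field is always computed from the binding *partner* only: antibody atoms
are sampled in the antigen's field and vice versa. Per-residue values take
the minimum ("deepest") and mean ("average") over the residue's atoms, and
per-group summaries average either the per-complex deepest residue
("deepest use") or the per-complex mean over interface residues
("average use") across complexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import collect_atoms, coords_of, radii_of
from .radii import RadiiTable
from .structure import ResidueKey

__all__ = [
    "ProbeSweep",
    "ConcavityField",
    "AtomConcavity",
    "ResidueConcavity",
    "compute_field",
    "sample_atoms",
    "summarize_residue",
    "summarize_group",
]

DEFAULT_SPACING = 0.8


@dataclass(frozen=True)
class ProbeSweep:
    """Ascending probe radii; the largest radius is the cap."""

    radii: tuple[float, ...] = (2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5)

    def __post_init__(self) -> None:
        r = self.radii
        if len(r) < 1 or any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("probe radii must be strictly ascending")
        if r[0] < 1.0:
            raise ValueError("smallest probe radius is unphysically small")

    @property
    def floor(self) -> float:
        return self.radii[0]

    @property
    def cap(self) -> float:
        return self.radii[-1]


@dataclass
class ConcavityField:
    origin: np.ndarray          # grid origin (A)
    spacing: float              # voxel edge (A)
    values: np.ndarray          # per-voxel R_inaccess (A); NaN on protein voxels
    occupied: np.ndarray        # protein occupancy mask
    sweep: ProbeSweep

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_index(self, point) -> tuple[int, int, int] | None:
        idx = np.rint((np.asarray(point, dtype=float) - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return None
        return tuple(idx)

    def value_at(self, point) -> float:
        """Field value at the voxel nearest a point (cap outside the grid)."""
        idx = self.voxel_index(point)
        if idx is None:
            warnings.warn(f"point {point} outside concavity grid; assigning cap")
            return self.sweep.cap
        if self.occupied[idx]:
            warnings.warn(f"point {point} clashes with the partner molecule; assigning floor")
            return self.sweep.floor
        return float(self.values[idx])


@dataclass
class AtomConcavity:
    residue_key: ResidueKey
    atom_name: str
    r_inaccess: float
    aa: str = ""
    cdr_label: str = ""


@dataclass
class ResidueConcavity:
    residue_key: ResidueKey
    deepest: float   # min over the residue's atoms
    average: float   # mean over the residue's atoms
    n_atoms: int
    aa: str = ""
    cdr_label: str = ""


def _clearance(coords: np.ndarray, radii: np.ndarray, origin: np.ndarray,
               shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    """Distance (A) from each voxel center to the nearest atom vdW surface.

    Computed exactly from atom centers (not from a voxelized mask, which
    would overestimate clearance by up to half a voxel diagonal). Negative
    values mark voxel centers inside an atom. With non-uniform radii the
    minimum of (center distance - radius) over the k nearest atoms is used;
    protein radii span ~0.5 A, so k=12 neighbours bound the true minimum.
    """
    from scipy.spatial import cKDTree

    ax = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(coords)
    if np.ptp(radii) < 1e-9:
        d, _ = tree.query(pts, k=1)
        clear = d - radii[0]
    else:
        k = min(12, len(coords))
        d, idx = tree.query(pts, k=k)
        d = np.atleast_2d(d.reshape(len(pts), -1))
        idx = np.atleast_2d(idx.reshape(len(pts), -1))
        clear = (d - radii[idx]).min(axis=1)
    return clear.reshape(shape)


_FACES_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _bulk_centers(fits: np.ndarray) -> np.ndarray:
    """Restrict probe-center voxels to components touching a box face."""
    labels, n = ndimage.label(fits, structure=_FACES_STRUCT)
    if n == 0:
        return np.zeros_like(fits)
    boundary_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    boundary_labels = boundary_labels[boundary_labels > 0]
    if boundary_labels.size == 0:
        return np.zeros_like(fits)
    return np.isin(labels, boundary_labels)


def compute_field(
    partner_atoms,
    sweep: ProbeSweep = ProbeSweep(),
    spacing: float = DEFAULT_SPACING,
    radii: np.ndarray | None = None,
    radii_table: RadiiTable | None = None,
    padding: float | None = None,
    probe_slack: float = 0.0,
) -> ConcavityField:
    """Compute the R_inaccess field over a molecule's surroundings.

    ``partner_atoms`` is a ComplexRecord, chain list, or atom-ref list for
    the molecule whose surface forms the pockets (the *partner* of whatever
    will be sampled). The grid covers the partner's bounding box padded by
    the cap radius plus the largest vdW radius, so every probe relevant to
    surface points fits inside the box.
    """
    if spacing > min(r for r in sweep.radii):
        raise ValueError("grid spacing must not exceed the smallest probe radius")
    refs = partner_atoms if isinstance(partner_atoms, list) and partner_atoms and isinstance(partner_atoms[0], tuple) else collect_atoms(partner_atoms)
    if not refs:
        raise ValueError("partner atom set is empty")
    coords = coords_of(refs)
    if radii is None:
        radii = radii_of(refs, radii_table)
    radii = np.asarray(radii, dtype=float)

    pad = padding if padding is not None else sweep.cap + float(radii.max())
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    origin = lo

    # exact distance from voxel centers to the nearest atom vdW surface
    clearance = _clearance(coords, radii, origin, shape, spacing)
    occupied = clearance < 0.0

    values = np.full(shape, np.nan)
    unassigned = ~occupied
    accessible_prev = np.ones(shape, dtype=bool)
    # probe centers are voxel-constrained; ``probe_slack`` optionally relaxes
    # the fit threshold to stand for off-center placements inside a voxel
    # (default 0: a probe fits only where the exact clearance reaches r)
    for r in sweep.radii:
        fits = clearance >= r - probe_slack
        centers = _bulk_centers(fits)
        if centers.any():
            reach = ndimage.distance_transform_edt(~centers, sampling=spacing)
            accessible = (reach <= r) & accessible_prev
        else:
            accessible = np.zeros(shape, dtype=bool)
        newly_blocked = unassigned & ~accessible
        values[newly_blocked] = r
        unassigned &= accessible
        accessible_prev = accessible
    values[unassigned] = sweep.cap  # reachable by every probe of the sweep
    values[occupied] = np.nan
    return ConcavityField(origin=np.asarray(origin), spacing=spacing, values=values,
                          occupied=occupied, sweep=sweep)


def sample_atoms(field: ConcavityField, query_atoms, cdr_of=None) -> list[AtomConcavity]:
    """Sample the field at each query atom's nearest voxel.

    The field must have been computed from the *partner* molecule only.
    Atoms inside the partner's occupancy mask receive the sweep floor with a
    clash warning; atoms outside the grid receive the cap with a warning.
    Values are categorical radii, so nearest-voxel lookup is used (no
    interpolation).
    """
    refs = query_atoms if isinstance(query_atoms, list) and query_atoms and isinstance(query_atoms[0], tuple) else collect_atoms(query_atoms)
    cdr_of = cdr_of or {}
    out = []
    for _, res, atom in refs:
        value = field.value_at(atom.coords)
        out.append(
            AtomConcavity(
                residue_key=res.key,
                atom_name=atom.name,
                r_inaccess=value,
                aa=res.aa,
                cdr_label=cdr_of.get(res.key, ""),
            )
        )
    return out


def summarize_residue(atom_values: list[AtomConcavity]) -> list[ResidueConcavity]:
    """Per-residue summaries: deepest = min over atoms, average = mean.

    The deepest value is the analysis default because residue averages are
    dominated by shallow backbone atoms and underestimate side-chain
    concavity use. Residues with no sampled atoms are simply absent.
    """
    grouped: dict[ResidueKey, list[AtomConcavity]] = {}
    for av in atom_values:
        grouped.setdefault(av.residue_key, []).append(av)
    out = []
    for key, values in grouped.items():
        rs = [v.r_inaccess for v in values]
        out.append(
            ResidueConcavity(
                residue_key=key,
                deepest=float(min(rs)),
                average=float(np.mean(rs)),
                n_atoms=len(rs),
                aa=values[0].aa,
                cdr_label=values[0].cdr_label,
            )
        )
    return out


def summarize_group(
    residue_table: pd.DataFrame,
    grouping: str,
    mode: str = "deepest",
    value_column: str = "deepest",
) -> pd.DataFrame:
    """Cross-complex group summary of residue concavity values.

    ``residue_table`` needs columns: complex_id, the grouping column
    (``cdr_label``, ``aa``, or ``imgt_position``), and ``value_column``.

    mode="deepest" ("deepest use"): per complex take the minimum residue
    value within the group, then average over complexes. mode="average"
    ("average use"): per complex take the mean over the group's interface
    residues, then average over complexes. Complexes lacking a group are
    skipped for that group.
    """
    if grouping not in residue_table.columns:
        raise ValueError(f"grouping column {grouping!r} not in table")
    if mode not in {"deepest", "average"}:
        raise ValueError("mode must be 'deepest' or 'average'")
    agg = "min" if mode == "deepest" else "mean"
    per_complex = (
        residue_table.groupby(["complex_id", grouping])[value_column].agg(agg).reset_index()
    )
    summary = (
        per_complex.groupby(grouping)[value_column]
        .agg(mean="mean", min="min", max="max", n_complexes="count")
        .reset_index()
    )
    summary["range"] = summary["max"] - summary["min"]
    summary["mode"] = f"{mode}-use"
    return summary
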