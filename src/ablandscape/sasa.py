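"""Interface detection, solvent accessible surface area, and buried surface area.

Interface residues are defined by a heavy-atom distance criterion: a residue
is interfacial iff any of its atoms lies within ``cutoff`` (default 5.0 A,
closed interval) of any atom of the partner side. Paratope residues carry a
CDR label ("H1".."L3") or "framework".

SASA uses the Shrake-Rupley quadrature: each atom's sphere (vdW radius +
probe) is covered with a deterministic Fibonacci spiral of ``n_points``
quasi-uniform points; the accessible fraction is the share of points outside
every neighbour's expanded sphere. Radii follow the packaged NACCESS-style
table. No random numbers are involved, so results are bit-reproducible.

Buried surface area of a complex is the SASA lost on binding::

    BSA = SASA(antibody alone) + SASA(antigen alone) - SASA(complex)

computed on the full chains of each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import AtomRef, collect_atoms, coords_of, radii_of
from .radii import RadiiTable
from .structure import ComplexRecord, ResidueKey, cdr_label_of

__all__ = [
    "InterfaceSet",
    "SASAResult",
    "BSAResult",
    "find_interface",
    "compute_sasa",
    "compute_bsa",
    "fibonacci_sphere",
    "interface_table",
]

DEFAULT_CUTOFF = 5.0
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class InterfaceSet:
    """Paratope/epitope residue keys of one complex (IMGT-keyed)."""

    paratope: list[tuple[ResidueKey, str]]  # (residue key, CDR label or "framework")
    epitope: list[ResidueKey]
    cutoff: float = DEFAULT_CUTOFF
    #: (side, imgt_position, insertion, aa) tuples used for cross-complex
    #: similarity; includes the amino-acid type so mutated contacts differ.
    similarity_keys: frozenset = frozenset()

    @property
    def paratope_keys(self) -> list[ResidueKey]:
        return [k for k, _ in self.paratope]

    @property
    def is_empty(self) -> bool:
        return not self.paratope and not self.epitope


@dataclass
class SASAResult:
    per_atom: np.ndarray  # A^2, aligned with the atom refs used
    refs: list[AtomRef]
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class BSAResult:
    bsa: float
    sasa_ab: float
    sasa_ag: float
    sasa_complex: float


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def find_interface(
    record: ComplexRecord,
    cutoff: float = DEFAULT_CUTOFF,
    windows=None,
) -> InterfaceSet:
    """Identify interface residues of a complex at a heavy-atom cutoff.

    The cutoff is a closed interval (a pair at exactly ``cutoff`` counts).
    Hydrogens are absent from the model by construction. An empty interface
    (chains too far apart) is valid and returned as such.
    """
    ab_refs = collect_atoms(record, roles=("heavy", "light"))
    ag_refs = collect_atoms(record, roles=("antigen",))
    if not ab_refs or not ag_refs:
        raise ValueError("complex requires at least one antibody and one antigen chain")
    ab_tree = cKDTree(coords_of(ab_refs))
    ag_tree = cKDTree(coords_of(ag_refs))
    pairs = ab_tree.query_ball_tree(ag_tree, r=cutoff)

    paratope_keys: dict[ResidueKey, str] = {}
    epitope_keys: dict[ResidueKey, None] = {}
    aa_of: dict[ResidueKey, str] = {}
    for i, hits in enumerate(pairs):
        if not hits:
            continue
        _, res_ab, _ = ab_refs[i]
        paratope_keys.setdefault(res_ab.key, "")
        aa_of[res_ab.key] = res_ab.aa
        for j in hits:
            _, res_ag, _ = ag_refs[j]
            epitope_keys.setdefault(res_ag.key, None)
            aa_of[res_ag.key] = res_ag.aa

    kwargs = {} if windows is None else {"windows": windows}
    paratope = [(k, cdr_label_of(record, k, **kwargs)) for k in paratope_keys]
    epitope = list(epitope_keys)
    sim_keys = frozenset(
        ("paratope", k[1], k[2], aa_of[k]) for k in paratope_keys
    ) | frozenset(("epitope", k[1], k[2], aa_of[k]) for k in epitope_keys)
    return InterfaceSet(
        paratope=paratope, epitope=epitope, cutoff=cutoff, similarity_keys=sim_keys
    )


def compute_sasa(
    atoms,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: np.ndarray | None = None,
    radii_table: RadiiTable | None = None,
) -> SASAResult:
    """Shrake-Rupley SASA of an atom set.

    ``atoms`` may be a ComplexRecord, a list of Chains, or a list of
    (chain, residue, atom) refs. Explicit per-atom ``radii`` override the
    table lookup.
    """
    refs = atoms if atoms and isinstance(atoms, list) and isinstance(atoms[0], tuple) else collect_atoms(atoms)
    coords = coords_of(refs)
    if radii is None:
        radii = radii_of(refs, radii_table)
    radii = np.asarray(radii, dtype=float)
    n = len(refs)
    areas = np.zeros(n)
    if n == 0:
        return SASAResult(areas, refs, probe, n_points)

    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    neighbours = tree.query_ball_tree(tree, r=max_reach)
    block = 16
    for i in range(n):
        ri = expanded[i]
        js = np.array([j for j in neighbours[i] if j != i], dtype=int)
        if js.size:
            dists = np.linalg.norm(coords[js] - coords[i], axis=1)
            keep = dists < ri + expanded[js]
            js = js[keep][np.argsort(dists[keep])]  # closest first: kill points early
        if js.size == 0:
            areas[i] = 4.0 * np.pi * ri * ri
            continue
        pts = coords[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for s in range(0, js.size, block):
            jb = js[s:s + block]
            live = np.flatnonzero(accessible)
            if live.size == 0:
                break
            diff = pts[live, None, :] - coords[jb][None, :, :]
            d2 = np.einsum("pjk,pjk->pj", diff, diff)
            covered = (d2 <= expanded[jb][None, :] ** 2).any(axis=1)
            accessible[live[covered]] = False
        areas[i] = accessible.mean() * 4.0 * np.pi * ri * ri
    return SASAResult(areas, refs, probe, n_points)


def compute_bsa(
    record: ComplexRecord,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: RadiiTable | None = None,
) -> BSAResult:
    """Buried surface area between the antibody and antigen sides."""
    ab_refs = collect_atoms(record, roles=("heavy", "light"))
    ag_refs = collect_atoms(record, roles=("antigen",))
    if not ab_refs or not ag_refs:
        raise ValueError("both an antibody side and an antigen side are required")
    kw = dict(probe=probe, n_points=n_points, radii_table=radii_table)
    sasa_ab = compute_sasa(ab_refs, **kw).total
    sasa_ag = compute_sasa(ag_refs, **kw).total
    sasa_complex = compute_sasa(ab_refs + ag_refs, **kw).total
    return BSAResult(
        bsa=sasa_ab + sasa_ag - sasa_complex,
        sasa_ab=sasa_ab,
        sasa_ag=sasa_ag,
        sasa_complex=sasa_complex,
    )


def interface_table(
    record: ComplexRecord,
    interface: InterfaceSet,
    bsa: BSAResult | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> pd.DataFrame:
    """Per-residue free/bound SASA table for the interface residues."""
    ab_refs = collect_atoms(record, roles=("heavy", "light"))
    ag_refs = collect_atoms(record, roles=("antigen",))
    free_ab = compute_sasa(ab_refs, probe=probe, n_points=n_points)
    free_ag = compute_sasa(ag_refs, probe=probe, n_points=n_points)
    bound = compute_sasa(ab_refs + ag_refs, probe=probe, n_points=n_points)

    def per_residue(result: SASAResult) -> dict[ResidueKey, float]:
        acc: dict[ResidueKey, float] = {}
        for area, (_, res, _) in zip(result.per_atom, result.refs):
            acc[res.key] = acc.get(res.key, 0.0) + float(area)
        return acc

    free = {**per_residue(free_ab), **per_residue(free_ag)}
    bound_by_res = per_residue(bound)
    cdr_of = dict(interface.paratope)
    rows = []
    for key, side in [(k, "paratope") for k in interface.paratope_keys] + [
        (k, "epitope") for k in interface.epitope
    ]:
        rows.append(
            dict(
                chain_id=key[0],
                imgt_position=key[1],
                insertion=key[2],
                side=side,
                cdr_label=cdr_of.get(key, "antigen"),
                sasa_free=free.get(key, 0.0),
                sasa_bound=bound_by_res.get(key, 0.0),
            )
        )
    df = pd.DataFrame(rows)
    if bsa is not None:
        df.attrs["bsa"] = bsa.bsa
    return df
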