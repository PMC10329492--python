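"""Small shared geometry utilities: atom collection and radius lookup."""

from __future__ import annotations

import numpy as np

from .radii import RadiiTable, default_radii
from .structure import Atom, Chain, ComplexRecord, Residue, ONE_TO_THREE

__all__ = ["collect_atoms", "coords_of", "radii_of"]

AtomRef = tuple[Chain, Residue, Atom]


def collect_atoms(source, roles=None) -> list[AtomRef]:
    """Flatten a ComplexRecord / list of Chains into (chain, residue, atom) refs."""
    if isinstance(source, ComplexRecord):
        return list(source.iter_atoms(roles))
    refs: list[AtomRef] = []
    for chain in source:
        if roles is not None and chain.role not in set(roles):
            continue
        for res in chain.residues:
            for atom in res.atoms:
                refs.append((chain, res, atom))
    return refs


def coords_of(refs: list[AtomRef]) -> np.ndarray:
    if not refs:
        return np.zeros((0, 3))
    return np.array([a.coords for _, _, a in refs], dtype=float)


def radii_of(refs: list[AtomRef], table: RadiiTable | None = None) -> np.ndarray:
    table = table or default_radii()
    return np.array(
        [table.radius(ONE_TO_THREE.get(r.aa, "UNK"), a.name, a.element) for _, r, a in refs],
        dtype=float,
    )
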