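"""Geometric classification of interfacial interatomic interactions.

A deliberately compact, configuration-exposed rule set covering the
interaction classes consumed by the landscape analysis: hydrogen bonds and
other polar contacts, hydrophobic (apolar carbon-carbon) contacts, aromatic
ring-ring contacts, directional ring-atom contacts, and their cation-pi
subset. Structures at typical crystallographic resolution carry no
hydrogens, so hydrogen bonding is distance-only over a shipped per-residue
donor/acceptor atom-role table.

Directionality follows ring ownership: a ``ring_atom`` record pairs an
antibody-owned aromatic ring with an antigen atom; ``atom_ring`` pairs an
antibody atom with an antigen-owned ring. The cation-pi subset (LYS NZ or
ARG NE/NH1/NH2 facing a ring) is flagged on the ring-class record and also
reported as its own profile count.

Counts are normalized to interactions per 100 A^2 of buried surface area so
complexes of different interface size are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import collect_atoms
from .sasa import BSAResult, InterfaceSet
from .structure import ComplexRecord, ONE_TO_THREE, ResidueKey

__all__ = [
    "GeometryRules",
    "AromaticRing",
    "InteractionRecord",
    "InteractionProfile",
    "detect_rings",
    "classify",
    "normalize",
    "INTERACTION_TYPES",
]

INTERACTION_TYPES = (
    "hydrogen_bond",
    "polar_contact",
    "hydrophobic",
    "ring_ring",
    "ring_atom",
    "atom_ring",
    "cation_pi",
)


@dataclass(frozen=True)
class GeometryRules:
    """Distance/angle cutoffs for each interaction class (A / degrees)."""

    hydrogen_bond_dist: float = 3.5
    polar_dist: float = 4.0
    hydrophobic_dist: float = 4.5
    ring_ring_dist: float = 6.0
    ring_atom_dist: float = 4.5
    ring_atom_angle: float = 45.0


# --- per-residue atom role tables (heavy atoms only) -----------------------

_BACKBONE_DONOR = {"N"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}

_SIDE_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDE_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"},
}

#: Carbons bonded only to carbon/hydrogen/sulfur (hydrophobic contacts).
_APOLAR_CARBONS = {
    "ALA": {"CB"}, "ARG": {"CB", "CG"}, "ASN": {"CB"}, "ASP": {"CB"},
    "CYS": {"CB"}, "GLN": {"CB", "CG"}, "GLU": {"CB", "CG"}, "GLY": set(),
    "HIS": {"CB"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "LYS": {"CB", "CG", "CD"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"}, "SER": set(), "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"},
}

_CATIONS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}

_RING_TEMPLATES = {
    "PHE": [("6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "HIS": [("5", ("CG", "ND1", "CD2", "CE1", "NE2"))],
    "TRP": [
        ("5", ("CG", "CD1", "NE1", "CE2", "CD2")),
        ("6", ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    ],
}


def _roles(aa1: str, atom_name: str) -> tuple[bool, bool, bool]:
    """(is_donor, is_acceptor, is_apolar_carbon) for a heavy atom."""
    res = ONE_TO_THREE.get(aa1, "UNK")
    donor = atom_name in _BACKBONE_DONOR and res != "PRO"
    donor |= atom_name in _SIDE_DONORS.get(res, ())
    acceptor = atom_name in _BACKBONE_ACCEPTOR or atom_name in _SIDE_ACCEPTORS.get(res, ())
    apolar = atom_name in _APOLAR_CARBONS.get(res, ())
    return donor, acceptor, apolar


@dataclass
class AromaticRing:
    ring_id: str
    residue_key: ResidueKey
    side: str                 # "antibody" | "antigen"
    member_atoms: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray        # unit vector


@dataclass
class InteractionRecord:
    type: str
    source: str               # atom key or ring id (antibody side)
    target: str               # atom key or ring id (antigen side)
    source_residue: ResidueKey
    target_residue: ResidueKey
    distance: float
    direction: str            # "ab_to_ag" | "ag_to_ab"
    cation_pi: bool = False
    angle: float | None = None


@dataclass
class InteractionProfile:
    raw: dict[str, int]
    normalized: dict[str, float]  # per 100 A^2 BSA
    bsa: float


def detect_rings(record: ComplexRecord, interface: InterfaceSet | None = None) -> list[AromaticRing]:
    """Detect aromatic rings from residue templates (TRP yields two).

    Rings with missing member atoms are skipped with a warning. When an
    interface is given, only rings on interface residues are returned.
    """
    import warnings

    keys_ab = set(interface.paratope_keys) if interface else None
    keys_ag = set(interface.epitope) if interface else None
    rings: list[AromaticRing] = []
    for chain, res, _ in _iter_first_atoms(record):
        res3 = ONE_TO_THREE.get(res.aa, "UNK")
        if res3 not in _RING_TEMPLATES:
            continue
        side = "antigen" if chain.role == "antigen" else "antibody"
        if interface is not None:
            wanted = keys_ag if side == "antigen" else keys_ab
            if res.key not in wanted:
                continue
        atom_by_name = {a.name: a for a in res.atoms}
        for tag, members in _RING_TEMPLATES[res3]:
            missing = [m for m in members if m not in atom_by_name]
            if missing:
                warnings.warn(
                    f"incomplete {res3} ring on {res.key}: missing {missing}; skipped"
                )
                continue
            pts = np.array([atom_by_name[m].coords for m in members])
            centroid = pts.mean(axis=0)
            # best-fit plane normal = smallest singular vector
            _, _, vt = np.linalg.svd(pts - centroid)
            normal = vt[2] / np.linalg.norm(vt[2])
            rings.append(
                AromaticRing(
                    ring_id=f"{res.key[0]}:{res.key[1]}{res.key[2]}:{tag}",
                    residue_key=res.key,
                    side=side,
                    member_atoms=members,
                    centroid=centroid,
                    normal=normal,
                )
            )
    return rings


def _iter_first_atoms(record: ComplexRecord):
    for chain in record.chains:
        for res in chain.residues:
            if res.atoms:
                yield chain, res, res.atoms[0]


def _atom_key(res: ResidueKey, name: str) -> str:
    return f"{res[0]}:{res[1]}{res[2]}:{name}"


def classify(
    record: ComplexRecord,
    interface: InterfaceSet,
    rules: GeometryRules = GeometryRules(),
) -> list[InteractionRecord]:
    """Classify interfacial interactions under the geometric rule set.

    Both endpoints must belong to interface residues. Within atom-atom
    pairs the precedence is hydrogen bond > polar contact > hydrophobic,
    and each atom pair yields at most one record. Ring-class records are
    enumerated over (ring, atom) and (ring, ring) pairs; cation-pi is a
    flag on the ring-atom-class record it refines. The output ordering is
    canonical (independent of input atom order).
    """
    para = set(interface.paratope_keys)
    epi = set(interface.epitope)
    ab_refs = [r for r in collect_atoms(record, roles=("heavy", "light")) if r[1].key in para]
    ag_refs = [r for r in collect_atoms(record, roles=("antigen",)) if r[1].key in epi]
    records: list[InteractionRecord] = []
    if ab_refs and ag_refs:
        ab_xyz = np.array([a.coords for _, _, a in ab_refs])
        ag_xyz = np.array([a.coords for _, _, a in ag_refs])
        pairs = cKDTree(ab_xyz).query_ball_tree(cKDTree(ag_xyz), r=rules.hydrophobic_dist)
        for i, hits in enumerate(pairs):
            _, res_a, atom_a = ab_refs[i]
            don_a, acc_a, apol_a = _roles(res_a.aa, atom_a.name)
            for j in hits:
                _, res_g, atom_g = ag_refs[j]
                d = float(np.linalg.norm(ab_xyz[i] - ag_xyz[j]))
                don_g, acc_g, apol_g = _roles(res_g.aa, atom_g.name)
                itype = None
                direction = "ab_to_ag"
                if d <= rules.hydrogen_bond_dist and (don_a and acc_g):
                    itype = "hydrogen_bond"
                elif d <= rules.hydrogen_bond_dist and (don_g and acc_a):
                    itype, direction = "hydrogen_bond", "ag_to_ab"
                elif d <= rules.polar_dist and (don_a or acc_a) and (don_g or acc_g):
                    itype = "polar_contact"
                elif d <= rules.hydrophobic_dist and apol_a and apol_g:
                    itype = "hydrophobic"
                if itype is not None:
                    records.append(
                        InteractionRecord(
                            type=itype,
                            source=_atom_key(res_a.key, atom_a.name),
                            target=_atom_key(res_g.key, atom_g.name),
                            source_residue=res_a.key,
                            target_residue=res_g.key,
                            distance=d,
                            direction=direction,
                        )
                    )

    rings = detect_rings(record, interface)
    ab_rings = [r for r in rings if r.side == "antibody"]
    ag_rings = [r for r in rings if r.side == "antigen"]

    for ra in ab_rings:
        for rg in ag_rings:
            d = float(np.linalg.norm(ra.centroid - rg.centroid))
            if d <= rules.ring_ring_dist:
                records.append(
                    InteractionRecord(
                        type="ring_ring",
                        source=ra.ring_id,
                        target=rg.ring_id,
                        source_residue=ra.residue_key,
                        target_residue=rg.residue_key,
                        distance=d,
                        direction="ab_to_ag",
                    )
                )

    cos_cut = np.cos(np.radians(rules.ring_atom_angle))
    for ring, partner_refs, rtype, direction in (
        [(r, ag_refs, "ring_atom", "ab_to_ag") for r in ab_rings]
        + [(r, ab_refs, "atom_ring", "ag_to_ab") for r in ag_rings]
    ):
        for _, res_p, atom_p in partner_refs:
            res3 = ONE_TO_THREE.get(res_p.aa, "UNK")
            don, acc, _ = _roles(res_p.aa, atom_p.name)
            is_cation = (res3, atom_p.name) in _CATIONS
            if not (don or acc or is_cation):
                continue
            v = np.asarray(atom_p.coords) - ring.centroid
            d = float(np.linalg.norm(v))
            if d == 0.0 or d > rules.ring_atom_dist:
                continue
            cos_angle = abs(float(np.dot(v / d, ring.normal)))
            if cos_angle < cos_cut:
                continue
            if rtype == "ring_atom":
                src, tgt = ring.ring_id, _atom_key(res_p.key, atom_p.name)
                src_res, tgt_res = ring.residue_key, res_p.key
            else:
                src, tgt = _atom_key(res_p.key, atom_p.name), ring.ring_id
                src_res, tgt_res = res_p.key, ring.residue_key
            records.append(
                InteractionRecord(
                    type=rtype,
                    source=src,
                    target=tgt,
                    source_residue=src_res,
                    target_residue=tgt_res,
                    distance=d,
                    direction=direction,
                    cation_pi=is_cation,
                    angle=float(np.degrees(np.arccos(min(cos_angle, 1.0)))),
                )
            )

    records.sort(key=lambda r: (r.type, r.source, r.target))
    return records


def normalize(records: list[InteractionRecord], bsa: BSAResult | float) -> InteractionProfile:
    """Count interactions per type and per 100 A^2 of buried surface area.

    ``cation_pi`` counts the flagged subset of the ring-atom classes (those
    records are not double-counted in the per-type totals). Hydrophobic
    contacts carry a known enumeration bias (many pairwise carbon contacts
    per true packing interaction) and are therefore reported as their own
    class, never merged with others.
    """
    bsa_value = bsa.bsa if isinstance(bsa, BSAResult) else float(bsa)
    raw = {t: 0 for t in INTERACTION_TYPES}
    for rec in records:
        raw[rec.type] += 1
        if rec.cation_pi:
            raw["cation_pi"] += 1
    total = sum(v for k, v in raw.items() if k != "cation_pi")
    if total and bsa_value <= 0:
        raise ValueError("nonempty interaction set with non-positive BSA")
    if bsa_value > 0:
        normalized = {t: 100.0 * n / bsa_value for t, n in raw.items()}
    else:
        normalized = {t: 0.0 for t in raw}
    return InteractionProfile(raw=raw, normalized=normalized, bsa=bsa_value)
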