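"""Synthetic structures, sequences, and manifests with known ground truth.

Every generator is a pure function of its spec and seed, and each fixture is
emitted together with its ground-truth labels (paratope/epitope membership,
cluster identity, exclusion category) so downstream stages can be tested
without recomputing the truth from the fixture itself.

Generators
----------
``make_slab``
    A multi-layer atomic lattice ("antigen" slab) with an optional cavity in
    its top face: a hemispherical pocket of chosen radius, or — when the
    requested depth exceeds the radius — a narrow hemisphere-bottomed shaft
    that no probe of the sweep can enter. These give analytically known
    concavity fields (flat face -> cap value; pocket bottom -> smallest probe
    radius exceeding the pocket radius; sub-probe crevice -> sweep floor).
``make_toy_complex``
    An antibody-like chain with IMGT-numbered CDR loops hovering above a slab
    antigen, one CDR residue protruding toward (or into) the antigen surface.
``make_sequence_family``
    Sequence sets with controlled pairwise identity to a reference.
``make_filter_manifest`` / ``make_dedup_manifest``
    Accounting fixtures reproducing the exclusion-category and
    redundancy-workflow bookkeeping at full dataset scale (counts only; no
    atomic coordinates involved).

The toy residues use real amino-acid heavy-atom name sets (including planar
fused rings for TRP) so side-chain logic, radii lookup, and interaction
typing are exercised on realistic atom names. No attempt is made at
physically realistic backbone geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .structure import Atom, Chain, ComplexRecord, ManifestRow, Residue, ResidueKey

__all__ = [
    "SlabSpec",
    "ToyComplexSpec",
    "ToyGroundTruth",
    "make_slab",
    "make_probe_ligand",
    "make_toy_complex",
    "make_residue",
    "make_sequence_family",
    "make_filter_manifest",
    "make_dedup_manifest",
    "PAPER_FILTER_COUNTS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Slabs


@dataclass(frozen=True)
class SlabSpec:
    """Flat atomic slab with an optional cavity carved into the top face.

    extent
        Side length (A) of the square lattice. Large enough that a probe
        resting over the center sees a locally flat plane.
    atom_spacing
        Lattice constant (A); must not exceed twice the atom radius so no
        probe can leak between lattice atoms.
    atom_radius
        Uniform van der Waals radius (A) of the lattice atoms.
    pocket_radius / pocket_depth
        Zero for a flat slab. When ``pocket_depth <= pocket_radius`` a
        hemispherical cavity of ``pocket_radius`` is carved into the top
        face center. When ``pocket_depth > pocket_radius`` the cavity is a
        vertical shaft of radius ``pocket_radius`` with a hemispherical
        bottom, total depth ``pocket_depth`` (a crevice fixture).
    """

    extent: float = 40.0
    atom_spacing: float = 1.5
    atom_radius: float = 1.8
    pocket_radius: float = 0.0
    pocket_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.atom_spacing > 2 * self.atom_radius:
            raise ValueError(
                "atom_spacing must be <= 2 * atom_radius (lattice would be porous)"
            )
        if self.pocket_radius < 0 or self.pocket_depth < 0:
            raise ValueError("pocket dimensions must be non-negative")

    @property
    def surface_z(self) -> float:
        """z of the top van der Waals surface (atom centers sit at z=0)."""
        return self.atom_radius

    @property
    def total_depth(self) -> float:
        if self.pocket_radius == 0:
            return 0.0
        return max(self.pocket_radius, self.pocket_depth)


def _carved(spec: SlabSpec, xyz: np.ndarray) -> np.ndarray:
    """Boolean mask of lattice points removed by the cavity.

    An atom is removed when its vdW sphere would intersect the ideal cavity
    volume, so the effective cavity radius at the wall equals the requested
    radius.
    """
    if spec.pocket_radius == 0:
        return np.zeros(len(xyz), dtype=bool)
    center = np.array([0.0, 0.0, spec.surface_z])
    reach = spec.pocket_radius + spec.atom_radius
    d = xyz - center
    if spec.total_depth <= spec.pocket_radius:  # hemisphere
        return np.linalg.norm(d, axis=1) < reach
    # shaft with hemispherical bottom
    shaft_bottom = spec.surface_z - (spec.total_depth - spec.pocket_radius)
    radial = np.hypot(d[:, 0], d[:, 1])
    in_shaft = (radial < reach) & (xyz[:, 2] > shaft_bottom - 1e-9)
    bottom_center = np.array([0.0, 0.0, shaft_bottom])
    in_bottom = np.linalg.norm(xyz - bottom_center, axis=1) < reach
    return in_shaft | in_bottom


def make_slab(spec: SlabSpec, chain_id: str = "A") -> ComplexRecord:
    """Build a slab antigen as a single-chain ComplexRecord.

    Each lattice atom is wrapped in its own glycine-like residue (atom name
    CA) so residue-level machinery works uniformly. Deterministic: identical
    specs give bit-identical coordinates.
    """
    n = int(math.floor(spec.extent / spec.atom_spacing)) + 1
    half = (n - 1) * spec.atom_spacing / 2.0
    xs = np.arange(n) * spec.atom_spacing - half
    # slab occupies z in [z_min, 0]; deep enough that no cavity pierces through
    z_min = -(2 * spec.atom_spacing + spec.total_depth + 2 * spec.atom_spacing)
    n_layers = int(math.floor(-z_min / spec.atom_spacing)) + 1
    zs = -np.arange(n_layers) * spec.atom_spacing
    gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
    xyz = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    xyz = xyz[~_carved(spec, xyz)]

    # one alanine-like residue per lattice atom: a lone CB is a real apolar
    # side-chain carbon, so interaction typing and radii lookups see a
    # legitimate (residue, atom) pair
    residues = [
        Residue(
            chain_id=chain_id,
            imgt_position=i + 1,
            imgt_insertion="",
            author_number=i + 1,
            aa="A",
            atoms=[
                Atom(serial=i + 1, name="CB", element="C", coords=tuple(map(float, p)))
            ],
        )
        for i, p in enumerate(xyz)
    ]
    return ComplexRecord(
        pdb_id="slab",
        ab_format="other",
        chains=[Chain(chain_id=chain_id, role="antigen", residues=residues)],
    )


def make_probe_ligand(position: Sequence[float], chain_id: str = "Z") -> Chain:
    """Single-atom 'binder' chain used to sample a concavity field."""
    residue = Residue(
        chain_id=chain_id,
        imgt_position=1,
        imgt_insertion="",
        author_number=1,
        aa="G",
        atoms=[Atom(serial=1, name="CA", element="C", coords=tuple(map(float, position)))],
    )
    return Chain(chain_id=chain_id, role="heavy", residues=[residue])


def position_clashes(position: Sequence[float], record: ComplexRecord, radius: float = 1.8) -> bool:
    """True when a point lies inside any partner atom's vdW sphere."""
    pts = np.array([a.coords for _, _, a in record.iter_atoms()])
    return bool(np.any(np.linalg.norm(pts - np.asarray(position, dtype=float), axis=1) < radius))


# ---------------------------------------------------------------------------
# Amino-acid atom templates (local frame: side chain grows along +z)

_RC6 = 1.39                       # aromatic 6-ring circumradius
_RC5 = 1.37 / (2 * math.sin(math.pi / 5))  # pentagon circumradius, side 1.37


def _hexagon(names: list[str], start_deg: float) -> dict[str, np.ndarray]:
    out = {}
    for i, name in enumerate(names):
        a = math.radians(start_deg - 60 * i)
        out[name] = np.array([_RC6 * math.cos(a), 0.0, _RC6 * math.sin(a)])
    return out


def _six_ring() -> dict[str, np.ndarray]:
    """PHE/TYR-style ring in the local xz-plane, CG nearest CB."""
    # order around the ring: CG, CD1, CE1, CZ, CE2, CD2; CG at angle -90
    ring = _hexagon(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], start_deg=-90)
    shift = np.array([0.0, 0.0, _RC6 + 2.95])
    return {k: v + shift for k, v in ring.items()}


def _trp_rings() -> dict[str, np.ndarray]:
    """Fused 5/6 rings of tryptophan sharing the CD2-CE2 edge, in xz-plane."""
    hexa = _hexagon(["CE3", "CZ3", "CH2", "CZ2", "CE2", "CD2"], start_deg=-150)
    cd2, ce2 = hexa["CD2"], hexa["CE2"]
    mid = (cd2 + ce2) / 2.0
    nrm = mid / np.linalg.norm(mid)  # outward from hexagon center (origin)
    apothem5 = _RC5 * math.cos(math.pi / 5)
    c5 = mid + apothem5 * nrm
    def ang(p):
        d = p - c5
        return math.atan2(d[2], d[0])
    # pentagon order: CD2 -> CG -> CD1 -> NE1 -> CE2 -> (CD2)
    a_cd2 = ang(cd2)
    a_ce2 = ang(ce2)
    step = (a_ce2 - a_cd2) % (2 * math.pi)
    sign = 1.0 if abs(step - 4 * 2 * math.pi / 5) < abs((-step) % (2 * math.pi) - 4 * 2 * math.pi / 5) else -1.0
    out = dict(hexa)
    for i, name in enumerate(["CG", "CD1", "NE1"], start=1):
        a = a_cd2 + sign * i * 2 * math.pi / 5
        out[name] = c5 + _RC5 * np.array([math.cos(a), 0.0, math.sin(a)])
    # put CG nearest CB (lowest z among the three new atoms) by flipping if needed
    if out["CG"][2] > out["NE1"][2]:
        out["CG"], out["NE1"] = out["NE1"], out["CG"]
    shift = np.array([0.0, 0.0, 2.95]) - np.array([out["CG"][0], 0.0, out["CG"][2]])
    return {k: v + shift for k, v in out.items()}


def _his_ring() -> dict[str, np.ndarray]:
    names = ["CG", "ND1", "CE1", "NE2", "CD2"]
    out = {}
    for i, name in enumerate(names):
        a = math.radians(-90 + 72 * i)
        out[name] = np.array([_RC5 * math.cos(a), 0.0, _RC5 * math.sin(a)])
    shift = np.array([0.0, 0.0, _RC5 + 2.95])
    return {k: v + shift for k, v in out.items()}


def _linear_chain(names: list[str]) -> dict[str, np.ndarray]:
    """Zig-zag side chain climbing +z from CB."""
    out = {}
    for i, name in enumerate(names):
        x = 0.45 if i % 2 else -0.45
        out[name] = np.array([x, 0.0, 2.95 + 1.35 * i])
    return out


def _sidechain_template(aa: str) -> dict[str, np.ndarray]:
    cb = {"CB": np.array([0.0, 0.0, 1.53])}
    if aa == "G":
        return {}
    if aa in "FY":
        t = {**cb, **_six_ring()}
        if aa == "Y":
            cz = t["CZ"]
            t["OH"] = cz + np.array([0.0, 0.0, 1.38])
        return t
    if aa == "W":
        return {**cb, **_trp_rings()}
    if aa == "H":
        return {**cb, **_his_ring()}
    chains = {
        "A": [], "S": ["OG"], "C": ["SG"], "T": ["OG1"], "V": ["CG1"],
        "L": ["CG", "CD1"], "I": ["CG1", "CD1"], "M": ["CG", "SD", "CE"],
        "D": ["CG", "OD1"], "N": ["CG", "OD1"], "E": ["CG", "CD", "OE1"],
        "Q": ["CG", "CD", "OE1"], "K": ["CG", "CD", "CE", "NZ"],
        "R": ["CG", "CD", "NE", "CZ", "NH1"], "P": ["CG", "CD"],
    }[aa]
    t = {**cb, **_linear_chain(chains)}
    # branch atoms off the main zig-zag
    extra = {
        "T": [("CG2", "CB", np.array([1.2, 0.8, 0.6]))],
        "V": [("CG2", "CB", np.array([1.2, 0.8, 0.6]))],
        "I": [("CG2", "CB", np.array([1.2, 0.8, 0.6]))],
        "L": [("CD2", "CG", np.array([1.2, 0.8, 0.6]))],
        "D": [("OD2", "CG", np.array([1.1, 0.8, 0.3]))],
        "N": [("ND2", "CG", np.array([1.1, 0.8, 0.3]))],
        "E": [("OE2", "CD", np.array([1.1, 0.8, 0.3]))],
        "Q": [("NE2", "CD", np.array([1.1, 0.8, 0.3]))],
        "R": [("NH2", "CZ", np.array([1.1, 0.8, 0.3]))],
    }
    for name, parent, off in extra.get(aa, []):
        t[name] = t[parent] + off
    return t


_BACKBONE = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.13, 1.06, 0.0]),
}


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking local +z to the given direction."""
    z = np.asarray(direction, dtype=float)
    z = z / np.linalg.norm(z)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def make_residue(
    aa: str,
    chain_id: str,
    imgt_position: int,
    *,
    imgt_insertion: str = "",
    author_number: int | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    start_serial: int = 1,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> Residue:
    """Place a single residue with its CA at ``origin`` and side chain along
    ``direction``. Aromatic residues get planar (fused) ring geometry."""
    R = _rotation_to(np.asarray(direction, dtype=float))
    atoms = []
    serial = start_serial
    template = {**_BACKBONE, **_sidechain_template(aa)}
    for name, local in template.items():
        pos = np.asarray(origin, dtype=float) + R @ local
        if rng is not None and jitter > 0:
            pos = pos + rng.normal(0.0, jitter, size=3)
        element = name[0] if name[0] in "CNOS" else "C"
        atoms.append(Atom(serial=serial, name=name, element=element, coords=tuple(pos)))
        serial += 1
    return Residue(
        chain_id=chain_id,
        imgt_position=imgt_position,
        imgt_insertion=imgt_insertion,
        author_number=author_number if author_number is not None else imgt_position,
        aa=aa,
        atoms=atoms,
    )


# ---------------------------------------------------------------------------
# Toy antibody-antigen complexes


@dataclass(frozen=True)
class ToyComplexSpec:
    """Antibody-like chain(s) with IMGT-numbered CDR loops over a slab antigen.

    ``cdr_lengths`` maps region labels ("H1".."H3", "L1".."L3") to residue
    counts; the middle residue of ``protrude`` (default H3) carries a side
    chain reaching toward the antigen face, into the pocket when
    ``pocket_radius > 0``. Deterministic for a fixed seed.
    """

    cdr_lengths: dict = dc_field(default_factory=lambda: {"H1": 8, "H2": 8, "H3": 13})
    pocket_radius: float = 0.0
    seed: int = 0
    protrude: str = "H3"
    # methionine: a linear side chain whose terminal carbons are genuinely
    # apolar, so the protruding tip registers hydrophobic contacts
    protrude_aa: str = "M"
    slab_extent: float = 30.0
    jitter: float = 0.03

    @property
    def ab_format(self) -> str:
        return "Fab" if any(k.startswith("L") for k in self.cdr_lengths) else "VHH"


@dataclass
class ToyGroundTruth:
    paratope: list[ResidueKey]
    epitope: list[ResidueKey]
    cdr_of_paratope: dict


_WINDOW_OF = {"1": (27, 38), "2": (56, 65), "3": (105, 117)}
_FRAMEWORK_POSITIONS = [20, 22, 24, 40, 42, 44, 68, 70, 72, 98, 100, 102, 120, 122, 124]


def _cdr_positions(label: str, length: int) -> list[tuple[int, str]]:
    lo, hi = _WINDOW_OF[label[1]]
    width = hi - lo + 1
    if length > width + 26:
        raise ValueError(f"CDR length {length} does not fit IMGT window for {label}")
    base = [(lo + i, "") for i in range(min(length, width))]
    extra = length - len(base)
    # insertion codes at the window midpoint, lexicographic: 111A, 111B, ...
    mid = (lo + hi) // 2
    for i in range(extra):
        base.append((mid, chr(ord("A") + i)))
    base.sort(key=lambda t: (t[0], t[1]))
    return base


def make_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexRecord, ToyGroundTruth]:
    """Build a toy complex plus its ground-truth interface labels.

    The antibody backbone floats ~8 A above the slab's vdW surface (outside
    the 5 A interface shell); only the protruding residue approaches the
    surface (tip ~3.5 A above it) or enters the pocket, so the ground-truth
    paratope is exactly that residue.
    """
    rng = np.random.default_rng(spec.seed)
    slab_spec = SlabSpec(
        extent=spec.slab_extent,
        pocket_radius=spec.pocket_radius,
        pocket_depth=spec.pocket_radius,
    )
    slab = make_slab(slab_spec, chain_id="A")
    z_surf = slab_spec.surface_z
    z_back = z_surf + 8.0

    serial = 1
    aas = "SGTYVNADE"

    def build_chain(chain_id: str, labels: list[str], x0: float) -> tuple[Chain, Residue | None]:
        nonlocal serial
        residues: list[Residue] = []
        protruding: Residue | None = None
        x = x0
        for pos in _FRAMEWORK_POSITIONS:
            res = make_residue(
                aas[pos % len(aas)], chain_id, pos,
                origin=(x, -9.0, z_back + 2.0), direction=(0, 0, 1),
                start_serial=serial, rng=rng, jitter=spec.jitter,
            )
            serial += len(res.atoms)
            residues.append(res)
            x += 2.2
        for label in labels:
            length = spec.cdr_lengths[label]
            positions = _cdr_positions(label, length)
            mid_idx = length // 2
            for i, (pos, ins) in enumerate(positions):
                is_tip = label == spec.protrude and i == mid_idx
                if is_tip:
                    aa = spec.protrude_aa
                    n_side = len(_sidechain_template(aa))
                    side_len = 2.95 + 1.35 * max(n_side - 2, 0)
                    # flat face: tip 2.2 A above the vdW surface (4.0 A from the
                    # nearest atom center, inside the 5 A interface shell)
                    tip_z = (z_surf - 0.55 * spec.pocket_radius) if spec.pocket_radius > 0 else z_surf + 2.2
                    origin = (0.0, 0.0, tip_z + side_len)
                    res = make_residue(
                        aa, chain_id, pos, imgt_insertion=ins,
                        origin=origin, direction=(0, 0, -1),
                        start_serial=serial, rng=rng, jitter=spec.jitter,
                    )
                    protruding = res
                else:
                    offset = (i - mid_idx)
                    res = make_residue(
                        aas[(pos + i) % len(aas)], chain_id, pos, imgt_insertion=ins,
                        origin=(x0 + 2.2 * offset, 3.0 * (1 if label[0] == "H" else -1) * (int(label[1])), z_back + 1.5 + 0.3 * abs(offset)),
                        direction=(0, 0, 1),
                        start_serial=serial, rng=rng, jitter=spec.jitter,
                    )
                serial += len(res.atoms)
                residues.append(res)
        residues.sort(key=lambda r: (r.imgt_position, r.imgt_insertion))
        # unique author numbers so PDB serialization round-trips insertions
        for k, res in enumerate(residues, start=1):
            res.author_number = k
        return Chain(chain_id=chain_id, role="heavy" if chain_id == "H" else "light", residues=residues), protruding

    heavy_labels = sorted(k for k in spec.cdr_lengths if k.startswith("H"))
    light_labels = sorted(k for k in spec.cdr_lengths if k.startswith("L"))
    chains = [slab.chains[0]]
    heavy, protruding = build_chain("H", heavy_labels, x0=-8.0)
    chains.append(heavy)
    if light_labels:
        light, lp = build_chain("L", light_labels, x0=6.0)
        chains.append(light)
        protruding = protruding or lp

    record = ComplexRecord(
        pdb_id=f"toy{spec.seed:04d}",
        ab_format=spec.ab_format,
        chains=chains,
        resolution=2.0,
    )

    # ground truth from construction: paratope = the protruding residue;
    # epitope = slab residues with an atom within 5 A of any tip atom
    assert protruding is not None
    tip_pts = np.array([a.coords for a in protruding.atoms])
    epitope: list[ResidueKey] = []
    for res in slab.chains[0].residues:
        p = np.array(res.atoms[0].coords)
        if np.min(np.linalg.norm(tip_pts - p, axis=1)) <= 5.0:
            epitope.append(res.key)
    truth = ToyGroundTruth(
        paratope=[protruding.key],
        epitope=epitope,
        cdr_of_paratope={protruding.key: spec.protrude},
    )
    return record, truth


# ---------------------------------------------------------------------------
# Sequence families


def make_sequence_family(
    n: int, identity: float, length: int = 100, seed: int = 0
) -> list[str]:
    """One reference sequence plus n-1 mutants at the requested identity.

    Substitution positions are drawn without replacement; substituted
    residues are uniform over the 19 non-identical amino acids. Pairwise
    identity of each mutant to the reference is within 1/length of the
    requested fraction.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be within [0, 1]")
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    n_sub = round((1.0 - identity) * length)
    family = [ref]
    for _ in range(n - 1):
        seq = list(ref)
        for pos in rng.choice(length, size=n_sub, replace=False):
            alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
            seq[pos] = alternatives[rng.integers(len(alternatives))]
        family.append("".join(seq))
    return family


# ---------------------------------------------------------------------------
# Accounting fixtures


#: Exclusion-category counts of the curated antibody-antigen dataset:
#: 4915 database entries reduced to 2417 retained complexes.
PAPER_FILTER_COUNTS = {
    "unbound_or_nonprotein": 409,
    "duplicate_entry": 222,
    "low_resolution": 1851,
    "unk_residues": 3,
    "fll_format": 13,
}
PAPER_RETAINED_FORMATS = {"Fab": 1753, "scFv": 73, "VHH": 591}


def make_filter_manifest(
    counts: dict[str, int] | None = None,
    retained_formats: dict[str, int] | None = None,
    seed: int = 0,
) -> list[ManifestRow]:
    """Accounting manifest reproducing the dataset exclusion categories.

    Each excluded row fails exactly one rule (and passes all earlier rules),
    so per-rule counts are reproduced exactly; retained rows pass all rules.
    """
    counts = dict(PAPER_FILTER_COUNTS if counts is None else counts)
    retained_formats = dict(
        PAPER_RETAINED_FORMATS if retained_formats is None else retained_formats
    )
    rng = np.random.default_rng(seed)
    rows: list[ManifestRow] = []

    def res_ok() -> float:
        return float(rng.uniform(1.2, 3.0))

    i = 0
    for _ in range(counts.get("unbound_or_nonprotein", 0)):
        unbound = rng.random() < 0.5
        rows.append(
            ManifestRow(
                pdb_id=f"s{i:04d}",
                ab_format="unbound" if unbound else "Fab",
                antigen_kind="protein" if unbound else "non-protein",
                resolution=res_ok(),
            )
        )
        i += 1
    for _ in range(counts.get("duplicate_entry", 0)):
        rows.append(ManifestRow(pdb_id=f"s{i:04d}", resolution=res_ok(), is_duplicate=True))
        i += 1
    for _ in range(counts.get("low_resolution", 0)):
        rows.append(ManifestRow(pdb_id=f"s{i:04d}", resolution=float(rng.uniform(3.05, 4.5))))
        i += 1
    for _ in range(counts.get("unk_residues", 0)):
        rows.append(ManifestRow(pdb_id=f"s{i:04d}", resolution=res_ok(), has_unk=True))
        i += 1
    for _ in range(counts.get("fll_format", 0)):
        rows.append(ManifestRow(pdb_id=f"s{i:04d}", ab_format="Fll", resolution=res_ok()))
        i += 1
    for fmt, n in retained_formats.items():
        for _ in range(n):
            rows.append(ManifestRow(pdb_id=f"s{i:04d}", ab_format=fmt, resolution=res_ok()))
            i += 1
    order = rng.permutation(len(rows))
    return [rows[k] for k in order]


def make_dedup_manifest(
    n_representatives: int = 670,
    n_reinstated: int = 553,
    n_true_redundant: int = 664,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, frozenset]]:
    """Redundancy-workflow accounting fixture.

    Builds labelled complexes whose interface key sets force the two-stage
    workflow to produce exactly ``n_representatives`` stage-1 representatives
    and ``n_reinstated`` reinstated complexes (distinct binding sites within
    a sequence-identical label group), with ``n_true_redundant`` complexes
    whose interfaces duplicate their representative's.

    Returns (entries, interfaces): entries is an ordered list of
    (complex_id, label); interfaces maps complex id to a frozen set of
    interface residue keys.
    """
    if n_reinstated > n_representatives:
        raise ValueError("cannot reinstate more groups than representatives exist")
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str]] = []
    interfaces: dict[str, frozenset] = {}

    def keyset(group: int, variant: int) -> frozenset:
        # disjoint-by-construction synthetic interface keys
        return frozenset(
            ("heavy", 105 + k, "", AMINO_ACIDS[(group + variant + k) % 20], group, variant)
            for k in range(10)
        )

    for g in range(n_representatives):
        cid = f"c{g:04d}_0"
        entries.append((cid, f"L{g:04d}"))
        interfaces[cid] = keyset(g, 0)
    for g in range(n_reinstated):
        cid = f"c{g:04d}_1"
        entries.append((cid, f"L{g:04d}"))
        interfaces[cid] = keyset(g, 1)  # disjoint from variant 0 -> similarity 0
    host_groups = list(range(n_reinstated, n_representatives)) or list(range(n_representatives))
    for j in range(n_true_redundant):
        g = host_groups[j % len(host_groups)]
        cid = f"c{g:04d}_d{j:04d}"
        entries.append((cid, f"L{g:04d}"))
        interfaces[cid] = keyset(g, 0)  # identical to the representative
    tail = entries[n_representatives:]
    order = rng.permutation(len(tail))
    entries = entries[:n_representatives] + [tail[k] for k in order]
    return entries, interfaces
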