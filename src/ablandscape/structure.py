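"""Hierarchical structure model for antibody-antigen complexes.

Complexes are represented as ``ComplexRecord`` -> ``Chain`` -> ``Residue`` ->
``Atom``. Every chain carries a *role* (heavy / light / antigen) and every
residue a position in the IMGT numbering scheme (integer plus optional
insertion letter, e.g. 111A), which is the key used for all cross-complex
comparisons. IMGT numbers are consumed from a sidecar table, never computed
from sequence.

The module also implements CDR annotation from configurable IMGT windows and
the dataset filtering rules used to assemble a curated complex set
(antigen type, duplicate entries, resolution, unknown residues, light-chain
dimers), with per-rule exclusion accounting.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexRecord",
    "CDRRegion",
    "ManifestRow",
    "FilterResult",
    "IMGT_WINDOWS",
    "THREE_TO_ONE",
    "SIDECHAIN_EXCLUDED",
    "read_structure",
    "write_structure",
    "load_sidecar",
    "assign_cdrs",
    "filter_complexes",
    "write_filter_manifest",
]

#: Default IMGT CDR windows (inclusive position ranges).
IMGT_WINDOWS: dict[int, tuple[int, int]] = {1: (27, 38), 2: (56, 65), 3: (105, 117)}

#: Atom names treated as main-chain for side-chain classification.
#: CA is deliberately main-chain (it is not part of the functional side chain).
SIDECHAIN_EXCLUDED = {"N", "CA", "C", "O", "OXT"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

ResidueKey = tuple[str, int, str]


class StructureParseError(ValueError):
    """Raised when an input structure file cannot be interpreted."""


class ConfigurationError(ValueError):
    """Raised when sidecar/role information does not cover the structure."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_sidechain(self) -> bool:
        return self.name not in SIDECHAIN_EXCLUDED

    def __post_init__(self) -> None:
        x, y, z = self.coords
        if not all(abs(v) < 1e8 and v == v for v in (x, y, z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has no element symbol")


@dataclass
class Residue:
    chain_id: str
    imgt_position: int
    imgt_insertion: str
    author_number: int
    aa: str  # one-letter code, or "X" for UNK
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.imgt_position, self.imgt_insertion)

    @property
    def imgt_label(self) -> str:
        return f"{self.imgt_position}{self.imgt_insertion}"

    @property
    def is_unknown(self) -> bool:
        return self.aa == "X"


@dataclass
class Chain:
    chain_id: str
    role: str  # heavy | light | antigen
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __post_init__(self) -> None:
        if self.role not in {"heavy", "light", "antigen"}:
            raise ValueError(f"unknown chain role {self.role!r}")
        seen = Counter(r.key for r in self.residues)
        dups = [k for k, n in seen.items() if n > 1]
        if dups:
            raise ValueError(f"duplicate IMGT keys in chain {self.chain_id}: {dups[:3]}")


@dataclass
class ComplexRecord:
    pdb_id: str
    ab_format: str  # Fab | scFv | VHH | Fll | unbound | other
    chains: list[Chain]
    resolution: float | None = None
    antigen_kind: str = "protein"  # protein | peptide | non-protein
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        roles = {c.role for c in self.chains}
        if self.ab_format in {"Fab", "scFv"} and not {"heavy", "light"} <= roles:
            raise ValueError(f"{self.ab_format} complex requires heavy and light chains")
        if self.ab_format == "VHH" and "heavy" not in roles:
            raise ValueError("VHH complex requires a heavy chain")
        if self.ab_format != "unbound" and "antigen" not in roles:
            raise ValueError("bound complex requires at least one antigen chain")

    def chains_by_role(self, *roles: str) -> list[Chain]:
        return [c for c in self.chains if c.role in roles]

    @property
    def antibody_chains(self) -> list[Chain]:
        return self.chains_by_role("heavy", "light")

    @property
    def antigen_chains(self) -> list[Chain]:
        return self.chains_by_role("antigen")

    @property
    def has_unknown_residues(self) -> bool:
        return any(r.is_unknown for c in self.chains for r in c.residues)

    def iter_atoms(self, roles: Iterable[str] | None = None):
        """Yield (chain, residue, atom) triples, optionally restricted to roles."""
        wanted = set(roles) if roles is not None else None
        for chain in self.chains:
            if wanted is not None and chain.role not in wanted:
                continue
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain, res, atom


@dataclass
class CDRRegion:
    chain_role: str  # heavy | light
    region: int      # 1 | 2 | 3
    label: str       # e.g. "H3"
    residues: list[Residue]

    @property
    def length(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Sidecar table + structure reading


def load_sidecar(path: str | Path) -> pd.DataFrame:
    """Read the chain-role / IMGT-numbering sidecar TSV.

    Columns: pdb_id, chain_id, role, ab_format, author_number, imgt_number,
    insertion. One row per residue; rows with empty author_number describe a
    chain's role only (numbering is then copied from author numbers).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = {"pdb_id", "chain_id", "role", "ab_format"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"sidecar table missing columns: {sorted(missing)}")
    return df


def _sidecar_maps(roles) -> tuple[dict[str, str], str, dict[tuple[str, int], tuple[int, str]]]:
    """Normalize a roles argument (dict or sidecar DataFrame).

    Returns (chain_id -> role, ab_format, (chain_id, author_number) -> imgt key).
    """
    if isinstance(roles, Mapping):
        return dict(roles), "other", {}
    df = roles
    chain_roles = dict(df.drop_duplicates("chain_id")[["chain_id", "role"]].values)
    ab_format = df["ab_format"].iloc[0] if len(df) else "other"
    numbering: dict[tuple[str, int], tuple[int, str]] = {}
    for col in ("author_number", "imgt_number", "insertion"):
        if col not in df.columns:
            return chain_roles, ab_format, numbering
    for _, row in df.iterrows():
        if str(row["author_number"]).strip() == "":
            continue
        numbering[(row["chain_id"], int(row["author_number"]))] = (
            int(row["imgt_number"]),
            str(row["insertion"]).strip(),
        )
    return chain_roles, ab_format, numbering


def _dedup_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep exactly one altloc per atom name: highest occupancy, ties by altloc."""
    best: dict[str, Atom] = {}
    for atom in atoms:
        prev = best.get(atom.name)
        if prev is None or (atom.occupancy, -ord(atom.altloc or "~")) > (
            prev.occupancy, -ord(prev.altloc or "~")
        ):
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str | Path,
    roles,
    *,
    antigen_kind: str = "protein",
    pdb_id: str | None = None,
) -> ComplexRecord:
    """Read a PDB/mmCIF file into a ``ComplexRecord``.

    Parameters
    ----------
    roles
        Either a ``{chain_id: role}`` mapping or a sidecar DataFrame from
        :func:`load_sidecar` (which additionally supplies the antibody format
        and per-residue IMGT numbering). When no IMGT numbering is supplied,
        author numbering is copied verbatim.

    Heteroatoms and waters are dropped; hydrogen atoms are dropped; exactly
    one alternate location is kept per atom position (highest occupancy).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on malformed input
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    chain_roles, ab_format, numbering = _sidecar_maps(roles)

    chains: list[Chain] = []
    model = st[0]
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = info is not None and info.is_amino_acid()
            if not (is_aa or gres.name == "UNK"):
                continue  # waters, ligands, ions
            atoms = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name.upper(),
                        coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                    )
                )
            if not atoms:
                continue
            author = gres.seqid.num
            imgt_pos, imgt_ins = numbering.get(
                (gchain.name, author), (author, gres.seqid.icode.strip())
            )
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    imgt_position=imgt_pos,
                    imgt_insertion=imgt_ins,
                    author_number=author,
                    aa=THREE_TO_ONE.get(gres.name, "X"),
                    atoms=_dedup_altlocs(atoms),
                )
            )
        if not residues:
            continue
        if gchain.name not in chain_roles:
            raise ConfigurationError(
                f"chain {gchain.name!r} in {path.name} missing from role table"
            )
        chains.append(Chain(chain_id=gchain.name, role=chain_roles[gchain.name], residues=residues))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return ComplexRecord(
        pdb_id=pdb_id or (st.name.lower() if st.name else path.stem),
        ab_format=ab_format,
        chains=chains,
        resolution=resolution,
        antigen_kind=antigen_kind,
    )


def write_structure(record: ComplexRecord, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a ComplexRecord as a PDB file (plus optional sidecar TSV)."""
    st = gemmi.Structure()
    st.name = record.pdb_id
    if record.resolution is not None:
        st.resolution = record.resolution
    model = gemmi.Model("1")
    for chain in record.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.author_number, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.serial = atom.serial
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.write_pdb(str(path))
    if sidecar is not None:
        rows = []
        for chain in record.chains:
            for res in chain.residues:
                rows.append(
                    dict(
                        pdb_id=record.pdb_id,
                        chain_id=chain.chain_id,
                        role=chain.role,
                        ab_format=record.ab_format,
                        author_number=res.author_number,
                        imgt_number=res.imgt_position,
                        insertion=res.imgt_insertion,
                    )
                )
        pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CDR assignment


def assign_cdrs(
    record: ComplexRecord,
    windows: Mapping[int, tuple[int, int]] = IMGT_WINDOWS,
) -> list[CDRRegion]:
    """Annotate CDR loops on heavy/light chains from IMGT position windows.

    Insertion-coded residues inside a window are included. A VHH complex
    simply yields no light-chain regions. Regions are returned even when
    empty so CDR lengths of zero are observable.
    """
    regions: list[CDRRegion] = []
    for chain in record.chains:
        if chain.role not in {"heavy", "light"}:
            continue
        prefix = "H" if chain.role == "heavy" else "L"
        for region, (lo, hi) in sorted(windows.items()):
            members = [r for r in chain.residues if lo <= r.imgt_position <= hi]
            regions.append(
                CDRRegion(chain_role=chain.role, region=region, label=f"{prefix}{region}", residues=members)
            )
    return regions


def cdr_label_of(record: ComplexRecord, residue_key: ResidueKey,
                 windows: Mapping[int, tuple[int, int]] = IMGT_WINDOWS) -> str:
    """CDR label ("H3", "L1", ...) for a residue key, else "framework"."""
    chain_id, pos, _ = residue_key
    for chain in record.chains:
        if chain.chain_id != chain_id or chain.role not in {"heavy", "light"}:
            continue
        prefix = "H" if chain.role == "heavy" else "L"
        for region, (lo, hi) in windows.items():
            if lo <= pos <= hi:
                return f"{prefix}{region}"
    return "framework"


# ---------------------------------------------------------------------------
# Dataset filtering


@dataclass
class ManifestRow:
    """Lightweight accounting row standing in for a full structure record."""

    pdb_id: str
    ab_format: str = "Fab"
    antigen_kind: str = "protein"
    resolution: float | None = None
    has_unk: bool = False
    is_duplicate: bool = False


#: Exclusion rules in their fixed application order. A record failing several
#: rules is counted only against the first.
FILTER_RULES = (
    "unbound_or_nonprotein",
    "duplicate_entry",
    "low_resolution",
    "unk_residues",
    "fll_format",
)

RESOLUTION_CUTOFF = 3.0


@dataclass
class FilterResult:
    retained: list
    excluded_by: dict[str, str]          # pdb_id -> rule
    counts: dict[str, int]               # rule -> count

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _as_manifest_row(item) -> ManifestRow:
    if isinstance(item, ManifestRow):
        return item
    return ManifestRow(
        pdb_id=item.pdb_id,
        ab_format=item.ab_format,
        antigen_kind=item.antigen_kind,
        resolution=item.resolution,
        has_unk=item.has_unknown_residues,
        is_duplicate=getattr(item, "is_duplicate", False),
    )


def _failing_rule(row: ManifestRow) -> str | None:
    if row.ab_format == "unbound" or row.antigen_kind == "non-protein":
        return "unbound_or_nonprotein"
    if row.is_duplicate:
        return "duplicate_entry"
    if row.resolution is None:
        warnings.warn(f"{row.pdb_id}: missing resolution, treated as low-resolution")
        return "low_resolution"
    if row.resolution > RESOLUTION_CUTOFF:
        return "low_resolution"
    if row.has_unk:
        return "unk_residues"
    if row.ab_format == "Fll":
        return "fll_format"
    return None


def filter_complexes(manifest: Sequence) -> FilterResult:
    """Apply the dataset exclusion rules, in order, with full accounting.

    Accepts either ``ComplexRecord`` or ``ManifestRow`` items. Rules (in
    order): unbound antibody or non-protein/peptide antigen; duplicate
    database entry; resolution above 3.0 A (missing counts as failing);
    any UNK residue; light-chain-dimer (Fll) format. The sum of per-rule
    exclusion counts plus the retained count always equals the input count.
    """
    retained = []
    excluded_by: dict[str, str] = {}
    counts = {rule: 0 for rule in FILTER_RULES}
    for item in manifest:
        rule = _failing_rule(_as_manifest_row(item))
        if rule is None:
            retained.append(item)
        else:
            excluded_by[_as_manifest_row(item).pdb_id] = rule
            counts[rule] += 1
    return FilterResult(retained=retained, excluded_by=excluded_by, counts=counts)


def write_filter_manifest(manifest: Sequence, result: FilterResult, path: str | Path) -> None:
    """Write one row per input complex with its ``excluded_by`` rule (or empty)."""
    rows = []
    for item in manifest:
        row = _as_manifest_row(item)
        rows.append(
            dict(
                pdb_id=row.pdb_id,
                ab_format=row.ab_format,
                antigen_kind=row.antigen_kind,
                resolution="" if row.resolution is None else row.resolution,
                has_unk=row.has_unk,
                is_duplicate=row.is_duplicate,
                excluded_by=result.excluded_by.get(row.pdb_id, ""),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
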