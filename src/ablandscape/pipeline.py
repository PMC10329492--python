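"""End-to-end orchestration: simulate -> filter -> interface/SASA/BSA ->
concavity -> interactions -> dedup -> stats.

A run is driven by a ``RunConfig`` (round-trippable through YAML). Every
stage writes self-describing TSVs into the output directory: each file
carries header comments with the configuration hash and column units, so a
rerun with the same configuration is bit-identical and verifiable by
checksum. The single RNG seed governs only the synthetic fixtures; the
analysis stages themselves are deterministic.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concavity as conc
from . import interactions as inter
from . import redundancy as red
from . import sasa as sasa_mod
from . import stats as stats_mod
from . import synthetic as syn
from .structure import (
    ComplexRecord,
    assign_cdrs,
    filter_complexes,
    load_sidecar,
    read_structure,
    write_filter_manifest,
    write_structure,
)

__all__ = ["RunConfig", "ValidationError", "StageError", "run_pipeline", "simulate"]

log = logging.getLogger("ablandscape")


class ValidationError(ValueError):
    """Configuration rejected before any computation."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    structures_dir: str = "structures"
    output_dir: str = "out"
    sweep_radii: tuple[float, ...] = (2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5)
    grid_spacing: float = 0.8
    interface_cutoff: float = 5.0
    identity_threshold: float = 0.95
    similarity_threshold: float = 0.90
    sasa_n_points: int = 960
    hydrogen_bond_dist: float = 3.5
    polar_dist: float = 4.0
    hydrophobic_dist: float = 4.5
    ring_ring_dist: float = 6.0
    ring_atom_dist: float = 4.5
    ring_atom_angle: float = 45.0
    seed: int = 0
    n_complexes: int = 6  # simulate stage only

    def validate(self) -> None:
        radii = tuple(self.sweep_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValidationError("sweep radii must be strictly ascending")
        if self.grid_spacing > min(radii):
            raise ValidationError("grid spacing must not exceed the smallest probe radius")
        if not 0 < self.identity_threshold <= 1:
            raise ValidationError("identity threshold must be in (0, 1]")
        if not 0 < self.similarity_threshold <= 1:
            raise ValidationError("similarity threshold must be in (0, 1]")
        if self.interface_cutoff <= 0:
            raise ValidationError("interface cutoff must be positive")
        if self.sasa_n_points < 16:
            raise ValidationError("SASA quadrature needs at least 16 points")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["sweep_radii"] = list(self.sweep_radii)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = yaml.safe_load(text)
        payload["sweep_radii"] = tuple(payload.get("sweep_radii", cls().sweep_radii))
        return cls(**payload)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (not of where outputs land)."""
        payload = asdict(self)
        payload["sweep_radii"] = list(self.sweep_radii)
        payload.pop("output_dir")
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def rules(self) -> inter.GeometryRules:
        return inter.GeometryRules(
            hydrogen_bond_dist=self.hydrogen_bond_dist,
            polar_dist=self.polar_dist,
            hydrophobic_dist=self.hydrophobic_dist,
            ring_ring_dist=self.ring_ring_dist,
            ring_atom_dist=self.ring_atom_dist,
            ring_atom_angle=self.ring_atom_angle,
        )

    def sweep(self) -> conc.ProbeSweep:
        return conc.ProbeSweep(radii=tuple(self.sweep_radii))


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, units: str) -> None:
    header = (
        f"# ablandscape stage output\n"
        f"# config_hash={config.config_hash}\n"
        f"# units: {units}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def simulate(config: RunConfig) -> list[Path]:
    """Write a deterministic set of toy complexes (PDB + sidecar + truth).

    H3 length varies across complexes and the antigen pocket narrows as H3
    grows, so the set carries a built-in negative length-concavity trend.
    Every complex passes the dataset filters (protein antigen, 2.0 A).
    """
    config.validate()
    out = Path(config.structures_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    paths = []
    truths = []
    for i in range(config.n_complexes):
        h3 = 11 + (i % 6)
        pocket = max(0.0, 5.8 - 0.45 * (h3 - 11))
        spec = syn.ToyComplexSpec(
            cdr_lengths={"H1": 8, "H2": 8, "H3": h3},
            pocket_radius=pocket,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        record, truth = syn.make_toy_complex(spec)
        record.pdb_id = f"toy{i:04d}"
        pdb = out / f"{record.pdb_id}.pdb"
        write_structure(record, pdb, sidecar=out / f"{record.pdb_id}.roles.tsv")
        truths.append(
            dict(pdb_id=record.pdb_id, h3_length=h3, pocket_radius=pocket,
                 paratope=";".join(f"{k[0]}:{k[1]}{k[2]}" for k in truth.paratope))
        )
        paths.append(pdb)
    pd.DataFrame(truths).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return paths


def _load_structures(config: RunConfig) -> list[ComplexRecord]:
    sdir = Path(config.structures_dir)
    records = []
    for pdb in sorted(sdir.glob("*.pdb")):
        sidecar = sdir / f"{pdb.stem}.roles.tsv"
        roles = load_sidecar(sidecar) if sidecar.exists() else None
        if roles is None:
            raise StageError(f"[read] no sidecar table for {pdb.name}")
        records.append(read_structure(pdb, roles, pdb_id=pdb.stem))
    if not records:
        raise StageError(f"[read] no structures found under {sdir}")
    return records


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the output directory.

    Outputs (all TSV, self-describing): filtered.tsv, interfaces.tsv,
    bsa.tsv, concavity_atoms.tsv, concavity_residues.tsv,
    concavity_summary.tsv, interactions.tsv, profiles.tsv, clusters.tsv,
    labels.tsv, nonredundant.tsv, cdr_lengths.tsv, correlations.tsv,
    plus run.log and the config itself.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    t0 = time.time()

    def stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        stage("read")
        records = _load_structures(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[read] {exc}") from exc

    try:
        stage("filter")
        result = filter_complexes(records)
        write_filter_manifest(records, result, outdir / "filtered.tsv")
        kept: list[ComplexRecord] = result.retained
    except Exception as exc:
        raise StageError(f"[filter] {exc}") from exc

    sweep = config.sweep()
    rules = config.rules()
    interface_rows, bsa_rows, atom_rows, res_rows = [], [], [], []
    inter_rows, profile_rows = [], []
    interfaces: dict[str, sasa_mod.InterfaceSet] = {}
    ab_ag_rows = []
    cdr_rows = []

    try:
        for record in kept:
            stage(f"complex {record.pdb_id}")
            cdrs = assign_cdrs(record)
            for region in cdrs:
                cdr_rows.append(
                    dict(complex_id=record.pdb_id, ab_format=record.ab_format,
                         cdr_label=region.label, length=region.length)
                )
            iface = sasa_mod.find_interface(record, cutoff=config.interface_cutoff)
            interfaces[record.pdb_id] = iface
            for key, label in iface.paratope:
                interface_rows.append(
                    dict(complex_id=record.pdb_id, side="paratope", chain_id=key[0],
                         imgt_position=key[1], insertion=key[2], cdr_label=label)
                )
            for key in iface.epitope:
                interface_rows.append(
                    dict(complex_id=record.pdb_id, side="epitope", chain_id=key[0],
                         imgt_position=key[1], insertion=key[2], cdr_label="antigen")
                )

            bsa = sasa_mod.compute_bsa(record, n_points=config.sasa_n_points)
            bsa_rows.append(
                dict(complex_id=record.pdb_id, bsa=bsa.bsa, sasa_ab=bsa.sasa_ab,
                     sasa_ag=bsa.sasa_ag, sasa_complex=bsa.sasa_complex)
            )

            cdr_of = dict(iface.paratope)
            para_keys = set(iface.paratope_keys)
            epi_keys = set(iface.epitope)
            sides = {}
            for side_name, field_roles, query_roles, keys, labels in (
                ("antibody", ("antigen",), ("heavy", "light"), para_keys, cdr_of),
                ("antigen", ("heavy", "light"), ("antigen",), epi_keys, {}),
            ):
                field = conc.compute_field(
                    record.chains_by_role(*field_roles), sweep=sweep,
                    spacing=config.grid_spacing,
                )
                refs = [
                    r for r in _refs(record, query_roles) if r[1].key in keys
                ]
                atoms = conc.sample_atoms(field, refs, cdr_of=labels)
                residues = conc.summarize_residue(atoms)
                sides[side_name] = residues
                for av in atoms:
                    atom_rows.append(
                        dict(complex_id=record.pdb_id, side=side_name,
                             chain_id=av.residue_key[0], imgt_position=av.residue_key[1],
                             insertion=av.residue_key[2], atom=av.atom_name, aa=av.aa,
                             cdr_label=av.cdr_label, r_inaccess=av.r_inaccess)
                    )
                for rv in residues:
                    res_rows.append(
                        dict(complex_id=record.pdb_id, side=side_name,
                             chain_id=rv.residue_key[0], imgt_position=rv.residue_key[1],
                             insertion=rv.residue_key[2], aa=rv.aa, cdr_label=rv.cdr_label,
                             deepest=rv.deepest, average=rv.average, n_atoms=rv.n_atoms)
                    )
            if sides["antibody"] and sides["antigen"]:
                ab_ag_rows.append(
                    dict(complex_id=record.pdb_id, ab_format=record.ab_format,
                         ab_deepest=min(r.deepest for r in sides["antibody"]),
                         ag_deepest=min(r.deepest for r in sides["antigen"]))
                )

            recs = inter.classify(record, iface, rules=rules)
            for rec in recs:
                inter_rows.append(
                    dict(complex_id=record.pdb_id, type=rec.type, source=rec.source,
                         target=rec.target, distance=round(rec.distance, 3),
                         direction=rec.direction, cation_pi=rec.cation_pi)
                )
            profile = inter.normalize(recs, bsa)
            profile_rows.append(
                dict(complex_id=record.pdb_id, bsa=bsa.bsa,
                     **{f"raw_{t}": profile.raw[t] for t in inter.INTERACTION_TYPES},
                     **{f"per100_{t}": profile.normalized[t] for t in inter.INTERACTION_TYPES})
            )
    except Exception as exc:
        raise StageError(f"[analysis] {exc}") from exc

    try:
        stage("dedup")
        clusters = {}
        cluster_rows = []
        for role in ("heavy", "light", "antigen"):
            seqs = {}
            for record in kept:
                for chain in record.chains_by_role(role):
                    seqs[f"{record.pdb_id}:{chain.chain_id}"] = chain.sequence
            if seqs:
                clusters[role] = red.greedy_cluster(
                    seqs, threshold=config.identity_threshold, role=role
                )
                for sid, cid in clusters[role].cluster_of.items():
                    cluster_rows.append(dict(role=role, sequence_id=sid, cluster=cid))
        entries = []
        label_rows = []
        for record in kept:
            def cluster_ids(role):
                return [
                    clusters[role].cluster_of[f"{record.pdb_id}:{c.chain_id}"]
                    for c in record.chains_by_role(role)
                ] if role in clusters else []
            heavy = cluster_ids("heavy")
            light = cluster_ids("light")
            label = red.label_complex(
                heavy[0] if heavy else None,
                light[0] if light else None,
                cluster_ids("antigen"),
            )
            entries.append((record.pdb_id, label))
            label_rows.append(dict(complex_id=record.pdb_id, label=label))
        dedup = red.deduplicate(entries, interfaces, threshold=config.similarity_threshold)
    except Exception as exc:
        raise StageError(f"[dedup] {exc}") from exc

    try:
        stage("stats")
        res_df = pd.DataFrame(res_rows)
        summaries = []
        ab_rows = res_df[(res_df["side"] == "antibody") & (res_df["cdr_label"] != "")]
        if len(ab_rows):
            for grouping in ("cdr_label", "aa"):
                for mode in ("deepest", "average"):
                    s = conc.summarize_group(ab_rows, grouping, mode=mode)
                    s.insert(0, "grouping", grouping)
                    summaries.append(s.rename(columns={grouping: "group"}))
        summary_df = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()

        cdr_df = pd.DataFrame(cdr_rows)
        lengths = stats_mod.cdr_length_table(cdr_df) if len(cdr_df) else pd.DataFrame()

        corr_rows = []
        if len(ab_rows):
            deepest_h3 = (
                ab_rows[ab_rows["cdr_label"] == "H3"]
                .groupby("complex_id")["deepest"].min().rename("deepest")
            )
            h3_len = cdr_df[cdr_df["cdr_label"] == "H3"].set_index("complex_id")["length"]
            joined = pd.concat([deepest_h3, h3_len], axis=1).dropna().reset_index()
            joined["cdr_label"] = "H3"
            for label, res in stats_mod.length_concavity_correlation(joined).items():
                corr_rows.append(
                    dict(kind="length_vs_deepest", group=label, r=res.r, p=res.p_value,
                         n=res.n, slope=res.slope, flag=res.flag)
                )
        if ab_ag_rows:
            for fmt, res in stats_mod.ab_ag_concavity_coupling(pd.DataFrame(ab_ag_rows)).items():
                corr_rows.append(
                    dict(kind="ab_ag_coupling", group=fmt, r=res.r, p=res.p_value,
                         n=res.n, slope=res.slope, flag=res.flag)
                )
    except Exception as exc:
        raise StageError(f"[stats] {exc}") from exc

    units_residue = "r_inaccess/deepest/average in A; positions IMGT"
    _write_tsv(pd.DataFrame(interface_rows), outdir / "interfaces.tsv", config, "IMGT positions")
    _write_tsv(pd.DataFrame(bsa_rows), outdir / "bsa.tsv", config, "areas in A^2")
    _write_tsv(pd.DataFrame(atom_rows), outdir / "concavity_atoms.tsv", config, units_residue)
    _write_tsv(pd.DataFrame(res_rows), outdir / "concavity_residues.tsv", config, units_residue)
    _write_tsv(summary_df, outdir / "concavity_summary.tsv", config, "mean/min/max/range in A")
    _write_tsv(pd.DataFrame(inter_rows), outdir / "interactions.tsv", config, "distance in A")
    _write_tsv(pd.DataFrame(profile_rows), outdir / "profiles.tsv", config,
               "per100_* = interactions per 100 A^2 BSA")
    _write_tsv(pd.DataFrame(cluster_rows), outdir / "clusters.tsv", config, "cluster ids per role")
    _write_tsv(pd.DataFrame(label_rows), outdir / "labels.tsv", config, "complex labels")
    _write_tsv(
        pd.DataFrame(
            [dict(complex_id=cid, status="nonredundant") for cid in dedup.nonredundant]
            + [dict(complex_id=cid, status="redundant") for cid in dedup.redundant]
            + [dict(complex_id="TOTAL", status=f"stage1={dedup.stage1_representatives};"
                    f"reinstated={dedup.reinstated};final={dedup.final_total}")]
        ),
        outdir / "nonredundant.tsv", config, "accounting in last row",
    )
    _write_tsv(lengths, outdir / "cdr_lengths.tsv", config, "lengths in residues")
    _write_tsv(pd.DataFrame(corr_rows), outdir / "correlations.tsv", config, "Pearson r")
    (outdir / "run.log").write_text(
        f"config_hash={config.config_hash}\nn_input={len(records)}\n"
        f"n_retained={len(kept)}\nn_nonredundant={dedup.final_total}\n"
        f"elapsed_s={time.time() - t0:.1f}\n"
    )
    stage("done")
    return outdir


def _refs(record: ComplexRecord, roles):
    from .geometry import collect_atoms

    return collect_atoms(record, roles=roles)
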