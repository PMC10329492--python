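"""Interaction typing: rings, classification rules, precedence, profiles."""

import numpy as np
import pytest

import ablandscape as ab
from ablandscape.interactions import GeometryRules, normalize
from ablandscape.sasa import find_interface
from ablandscape.structure import Atom, Chain, ComplexRecord, Residue
from ablandscape.synthetic import make_residue


def _complex(heavy_residues, antigen_residues):
    return ComplexRecord(
        "fix", "VHH",
        [Chain("H", "heavy", heavy_residues), Chain("A", "antigen", antigen_residues)],
    )


def _shift_residue(res, target_atom, target_pos):
    anchor = next(a for a in res.atoms if a.name == target_atom)
    shift = np.asarray(target_pos, dtype=float) - np.asarray(anchor.coords)
    for a in res.atoms:
        a.coords = tuple(np.asarray(a.coords) + shift)
    return res


class TestDetectRings:
    def test_tyr_centroid_is_the_ring_mean(self):
        tyr = make_residue("Y", "A", 5)
        rec = _complex([make_residue("K", "H", 110, origin=(30, 0, 0))], [tyr])
        (ring,) = [r for r in ab.detect_rings(rec) if r.side == "antigen"]
        members = {a.name: np.array(a.coords) for a in tyr.atoms}
        expected = np.mean([members[m] for m in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")], axis=0)
        assert np.allclose(ring.centroid, expected, atol=1e-9)
        assert np.isclose(np.linalg.norm(ring.normal), 1.0)

    def test_trp_yields_two_rings(self):
        rec = _complex([make_residue("W", "H", 110)], [make_residue("G", "A", 1, origin=(30, 0, 0))])
        rings = [r for r in ab.detect_rings(rec) if r.side == "antibody"]
        assert len(rings) == 2
        shared = set(rings[0].member_atoms) & set(rings[1].member_atoms)
        assert shared == {"CD2", "CE2"}

    def test_non_aromatic_chain_has_no_rings(self):
        rec = _complex([make_residue("G", "H", 110)], [make_residue("A", "A", 1, origin=(30, 0, 0))])
        assert ab.detect_rings(rec) == []

    def test_incomplete_ring_is_skipped_with_warning(self):
        tyr = make_residue("Y", "A", 5)
        tyr.atoms = [a for a in tyr.atoms if a.name != "CZ"]
        rec = _complex([make_residue("G", "H", 110, origin=(30, 0, 0))], [tyr])
        with pytest.warns(UserWarning, match="incomplete"):
            rings = ab.detect_rings(rec)
        assert rings == []


class TestClassify:
    def test_cation_on_ring_normal_is_cation_pi_atom_ring(self):
        tyr = make_residue("Y", "A", 5)
        rec0 = _complex([make_residue("K", "H", 110, origin=(30, 0, 0))], [tyr])
        (ring,) = [r for r in ab.detect_rings(rec0) if r.side == "antigen"]
        lys = _shift_residue(
            make_residue("K", "H", 110), "NZ", ring.centroid + 3.0 * ring.normal
        )
        rec = _complex([lys], [tyr])
        records = ab.classify(rec, find_interface(rec))
        ring_recs = [r for r in records if r.type in ("ring_atom", "atom_ring")]
        assert len(ring_recs) == 1
        rec_ = ring_recs[0]
        assert rec_.type == "atom_ring"          # antigen owns the ring
        assert rec_.direction == "ag_to_ab"
        assert rec_.cation_pi
        assert rec_.distance == pytest.approx(3.0, abs=1e-6)

    def test_parallel_rings_across_interface_are_ring_ring(self):
        tyr_ag = make_residue("Y", "A", 5)
        rec0 = _complex([make_residue("G", "H", 110, origin=(30, 0, 0))], [tyr_ag])
        (ring,) = [r for r in ab.detect_rings(rec0) if r.side == "antigen"]
        tyr_ab = make_residue("Y", "H", 110)
        # translate the antibody ring so its centroid sits 4 A along the
        # antigen ring normal: parallel stacking
        c0 = np.mean(
            [a.coords for a in tyr_ab.atoms if a.name in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
            axis=0,
        )
        shift = ring.centroid + 4.0 * ring.normal - c0
        for a in tyr_ab.atoms:
            a.coords = tuple(np.asarray(a.coords) + shift)
        rec = _complex([tyr_ab], [tyr_ag])
        records = ab.classify(rec, find_interface(rec))
        assert sum(r.type == "ring_ring" for r in records) == 1
        (rr,) = [r for r in records if r.type == "ring_ring"]
        assert rr.distance == pytest.approx(4.0, abs=1e-6)
        assert rr.direction == "ab_to_ag"

    def test_apolar_pair_beyond_cutoff_yields_nothing(self):
        a = Residue("A", 1, "", 1, "A", [Atom(1, "CB", "C", (0.0, 0.0, 0.0))])
        h = Residue("H", 110, "", 1, "A", [Atom(1, "CB", "C", (4.6, 0.0, 0.0))])
        rec = _complex([h], [a])
        iface = find_interface(rec)  # 4.6 < 5 A, so both are interface residues
        assert ab.classify(rec, iface) == []

    def test_donor_acceptor_inside_cutoff_is_a_hydrogen_bond(self):
        ser = Residue("H", 110, "", 1, "S", [Atom(1, "OG", "O", (0.0, 0.0, 0.0))])
        bb = Residue("A", 1, "", 1, "G", [Atom(1, "O", "O", (3.0, 0.0, 0.0))])
        rec = _complex([ser], [bb])
        records = ab.classify(rec, find_interface(rec))
        assert [r.type for r in records] == ["hydrogen_bond"]
        assert records[0].direction == "ab_to_ag"  # SER OG donates

    def test_polar_pair_outside_hbond_distance_is_polar_contact(self):
        ser = Residue("H", 110, "", 1, "S", [Atom(1, "OG", "O", (0.0, 0.0, 0.0))])
        bb = Residue("A", 1, "", 1, "G", [Atom(1, "O", "O", (3.8, 0.0, 0.0))])
        rec = _complex([ser], [bb])
        records = ab.classify(rec, find_interface(rec))
        assert [r.type for r in records] == ["polar_contact"]

    def test_donor_donor_pair_is_polar_not_hydrogen_bond(self):
        lys = Residue("H", 110, "", 1, "K", [Atom(1, "NZ", "N", (0.0, 0.0, 0.0))])
        trp = Residue("A", 1, "", 1, "W", [Atom(1, "NE1", "N", (3.2, 0.0, 0.0))])
        rec = _complex([lys], [trp])
        records = ab.classify(rec, find_interface(rec))
        assert [r.type for r in records] == ["polar_contact"]

    def test_each_atom_pair_yields_at_most_one_record(self, toy_pocket_complex):
        _, record, _ = toy_pocket_complex
        iface = find_interface(record)
        records = ab.classify(record, iface)
        atom_pairs = [
            (r.source, r.target) for r in records
            if r.type in ("hydrogen_bond", "polar_contact", "hydrophobic")
        ]
        assert len(atom_pairs) == len(set(atom_pairs))

    def test_classification_is_independent_of_atom_order(self, toy_pocket_complex):
        import copy

        _, record, _ = toy_pocket_complex
        iface = find_interface(record)
        baseline = ab.classify(record, iface)
        shuffled = copy.deepcopy(record)
        rng = np.random.default_rng(0)
        for chain in shuffled.chains:
            for res in chain.residues:
                rng.shuffle(res.atoms)
        again = ab.classify(shuffled, find_interface(shuffled))
        assert [(r.type, r.source, r.target) for r in baseline] == [
            (r.type, r.source, r.target) for r in again
        ]

    def test_direction_bookkeeping_of_ring_classes(self):
        # one antibody ring facing an antigen donor, and vice versa
        tyr_ab = make_residue("Y", "H", 110)
        rec0 = _complex([tyr_ab], [make_residue("G", "A", 1, origin=(30, 0, 0))])
        (ring_ab,) = [r for r in ab.detect_rings(rec0) if r.side == "antibody"]
        ser_ag = _shift_residue(
            Residue("A", 1, "", 1, "S", [Atom(1, "OG", "O", (0, 0, 0))]),
            "OG", ring_ab.centroid + 3.2 * ring_ab.normal,
        )
        rec = _complex([tyr_ab], [ser_ag])
        records = ab.classify(rec, find_interface(rec))
        ring_classes = [r for r in records if r.type in ("ring_atom", "atom_ring")]
        n_ab_owned = sum(r.type == "ring_atom" for r in ring_classes)
        n_ag_owned = sum(r.type == "atom_ring" for r in ring_classes)
        assert n_ab_owned + n_ag_owned == len(ring_classes)
        assert n_ab_owned == 1  # antibody TYR ring, antigen atom


class TestNormalize:
    def _records(self, n):
        return [
            ab.InteractionRecord(
                type="hydrophobic", source=f"H:110:C{i}", target="A:1:CB",
                source_residue=("H", 110, ""), target_residue=("A", 1, ""),
                distance=4.0, direction="ab_to_ag",
            )
            for i in range(n)
        ]

    def test_fourteen_records_per_700_bsa_is_two(self):
        profile = normalize(self._records(14), 700.0)
        assert profile.normalized["hydrophobic"] == pytest.approx(2.0)

    def test_empty_records_normalize_to_zero(self):
        profile = normalize([], 500.0)
        assert all(v == 0 for v in profile.raw.values())
        assert all(v == 0.0 for v in profile.normalized.values())

    def test_doubling_bsa_halves_every_normalized_count(self):
        p1 = normalize(self._records(10), 400.0)
        p2 = normalize(self._records(10), 800.0)
        for t in p1.normalized:
            assert p2.normalized[t] == pytest.approx(p1.normalized[t] / 2)

    def test_zero_bsa_with_records_is_inconsistent(self):
        with pytest.raises(ValueError, match="BSA"):
            normalize(self._records(1), 0.0)

    def test_cation_pi_counts_the_flagged_subset(self):
        recs = self._records(2)
        recs.append(
            ab.InteractionRecord(
                type="atom_ring", source="H:110:NZ", target="A:1:ring",
                source_residue=("H", 110, ""), target_residue=("A", 1, ""),
                distance=3.0, direction="ag_to_ab", cation_pi=True,
            )
        )
        profile = normalize(recs, 100.0)
        assert profile.raw["atom_ring"] == 1
        assert profile.raw["cation_pi"] == 1


class TestShellRestriction:
    def test_restricting_to_interface_shell_preserves_counts(self, toy_pocket_complex):
        """Dropping residues outside the 5 A shell (+margin) changes nothing."""
        _, record, _ = toy_pocket_complex
        iface = find_interface(record)
        baseline = ab.classify(record, iface)

        keep = set(iface.paratope_keys) | set(iface.epitope)
        from ablandscape.geometry import collect_atoms, coords_of

        kept_xyz = coords_of([r for r in collect_atoms(record) if r[1].key in keep])
        trimmed_chains = []
        for chain in record.chains:
            residues = []
            for res in chain.residues:
                pts = np.array([a.coords for a in res.atoms])
                d = np.linalg.norm(
                    pts[:, None, :] - kept_xyz[None, :, :], axis=-1
                ).min()
                if res.key in keep or d <= 1.5:
                    residues.append(res)
            if residues:
                trimmed_chains.append(Chain(chain.chain_id, chain.role, residues))
        trimmed = ComplexRecord(record.pdb_id, record.ab_format, trimmed_chains)
        again = ab.classify(trimmed, find_interface(trimmed))
        assert [(r.type, r.source, r.target) for r in baseline] == [
            (r.type, r.source, r.target) for r in again
        ]
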