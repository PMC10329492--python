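"""Synthetic generators: determinism, carving geometry, ground-truth labels."""

import numpy as np
import pytest

import ablandscape as ab
from ablandscape.geometry import collect_atoms, coords_of
from ablandscape.synthetic import make_residue, position_clashes

from conftest import slab_coords


class TestMakeSlab:
    def test_identical_specs_give_bit_identical_coordinates(self):
        spec = ab.SlabSpec(extent=24.0, pocket_radius=3.0, pocket_depth=3.0)
        a = slab_coords(ab.make_slab(spec))
        b = slab_coords(ab.make_slab(spec))
        assert np.array_equal(a, b)

    def test_flat_slab_top_face_is_a_plane(self):
        slab = ab.make_slab(ab.SlabSpec(extent=24.0))
        xyz = slab_coords(slab)
        top = xyz[xyz[:, 2] == xyz[:, 2].max()]
        # full square lattice on the top face, symmetric about the center
        n = int(round(np.sqrt(len(top))))
        assert n * n == len(top)
        assert np.allclose(top[:, :2].mean(axis=0), 0.0, atol=1e-9)

    def test_pocket_carves_a_cavity_of_the_requested_radius(self):
        spec = ab.SlabSpec(extent=24.0, atom_spacing=1.0, pocket_radius=4.0, pocket_depth=4.0)
        xyz = slab_coords(ab.make_slab(spec))
        center = np.array([0.0, 0.0, spec.surface_z])
        d = np.linalg.norm(xyz - center, axis=1)
        # nearest wall atom surface sits at the carved radius
        assert d.min() - spec.atom_radius == pytest.approx(4.0, abs=0.1)
        # mouth diameter: top-face atoms within the mouth circle are gone
        top = xyz[np.abs(xyz[:, 2]) < 1e-9]
        radial = np.hypot(top[:, 0], top[:, 1])
        assert radial.min() > 4.0

    def test_porous_lattice_spec_is_rejected(self):
        with pytest.raises(ValueError, match="atom_spacing"):
            ab.SlabSpec(atom_spacing=4.0, atom_radius=1.8)

    def test_crevice_depth_exceeds_radius(self):
        spec = ab.SlabSpec(extent=24.0, pocket_radius=1.2, pocket_depth=8.0)
        xyz = slab_coords(ab.make_slab(spec))
        # shaft interior is empty all the way down
        axis = np.hypot(xyz[:, 0], xyz[:, 1])
        in_shaft = (axis < 1.2 + spec.atom_radius) & (xyz[:, 2] > spec.surface_z - 8.0)
        assert not in_shaft.any()


class TestProbeLigand:
    def test_single_atom_at_requested_position(self):
        chain = ab.make_probe_ligand((1.0, 2.0, 3.0))
        assert len(chain.residues) == 1
        assert chain.residues[0].atoms[0].coords == (1.0, 2.0, 3.0)

    def test_interior_position_is_flagged_as_clashing(self):
        slab = ab.make_slab(ab.SlabSpec(extent=24.0))
        assert position_clashes((0.0, 0.0, -1.5), slab)
        assert not position_clashes((0.0, 0.0, 6.0), slab)


class TestToyComplex:
    def test_ground_truth_paratope_is_the_protruding_h3_residue(self, toy_pocket_complex):
        spec, record, truth = toy_pocket_complex
        assert len(truth.paratope) == 1
        (chain_id, pos, ins), = truth.paratope
        assert chain_id == "H" and 105 <= pos <= 117
        assert truth.cdr_of_paratope[truth.paratope[0]] == "H3"

    def test_two_seeds_differ_in_coordinates_not_topology(self):
        rec1, _ = ab.make_toy_complex(ab.ToyComplexSpec(seed=10))
        rec2, _ = ab.make_toy_complex(ab.ToyComplexSpec(seed=11))
        keys1 = [r.key for c in rec1.chains for r in c.residues]
        keys2 = [r.key for c in rec2.chains for r in c.residues]
        assert keys1 == keys2
        a1 = coords_of(collect_atoms(rec1.chains_by_role("heavy")))
        a2 = coords_of(collect_atoms(rec2.chains_by_role("heavy")))
        assert not np.allclose(a1, a2)

    def test_fixed_seed_is_deterministic(self):
        a = coords_of(collect_atoms(ab.make_toy_complex(ab.ToyComplexSpec(seed=3))[0]))
        b = coords_of(collect_atoms(ab.make_toy_complex(ab.ToyComplexSpec(seed=3))[0]))
        assert np.array_equal(a, b)

    def test_fab_spec_builds_heavy_and_light_chains(self):
        spec = ab.ToyComplexSpec(
            cdr_lengths={"H1": 8, "H2": 8, "H3": 12, "L1": 6, "L2": 6, "L3": 9},
            seed=4,
        )
        record, _ = ab.make_toy_complex(spec)
        assert record.ab_format == "Fab"
        assert {c.role for c in record.chains} == {"heavy", "light", "antigen"}
        lengths = {r.label: r.length for r in ab.assign_cdrs(record)}
        assert lengths == {"H1": 8, "H2": 8, "H3": 12, "L1": 6, "L2": 6, "L3": 9}

    def test_oversized_cdr_is_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            ab.make_toy_complex(ab.ToyComplexSpec(cdr_lengths={"H3": 45}, seed=0))


class TestResidueTemplates:
    @pytest.mark.parametrize("aa,n_rings", [("W", 2), ("Y", 1), ("F", 1), ("H", 1)])
    def test_aromatic_rings_are_planar(self, aa, n_rings):
        from ablandscape.interactions import _RING_TEMPLATES
        from ablandscape.structure import ONE_TO_THREE

        res = make_residue(aa, "H", 110)
        atom_by_name = {a.name: np.array(a.coords) for a in res.atoms}
        templates = _RING_TEMPLATES[ONE_TO_THREE[aa]]
        assert len(templates) == n_rings
        for _, members in templates:
            pts = np.array([atom_by_name[m] for m in members])
            centered = pts - pts.mean(axis=0)
            rms = np.sqrt((np.linalg.svd(centered)[1][2] ** 2) / len(pts))
            assert rms < 0.1

    def test_trp_rings_share_the_cd2_ce2_edge(self):
        from ablandscape.interactions import _RING_TEMPLATES

        five, six = (set(m) for _, m in _RING_TEMPLATES["TRP"])
        assert five & six == {"CD2", "CE2"}

    def test_side_chain_follows_direction(self):
        res = make_residue("K", "H", 110, origin=(0, 0, 0), direction=(0, 0, -1))
        nz = next(a for a in res.atoms if a.name == "NZ")
        ca = next(a for a in res.atoms if a.name == "CA")
        assert nz.coords[2] < ca.coords[2]


class TestSequenceFamily:
    def test_identity_one_gives_identical_sequences(self):
        fam = ab.make_sequence_family(3, 1.0, length=50, seed=0)
        assert len(set(fam)) == 1

    def test_requested_identity_is_realized(self):
        fam = ab.make_sequence_family(2, 0.90, length=100, seed=1)
        ref, mut = fam
        n_diff = sum(a != b for a, b in zip(ref, mut))
        assert n_diff == 10

    @pytest.mark.parametrize("identity", [0.8, 0.93, 0.97])
    def test_identity_within_one_position(self, identity):
        fam = ab.make_sequence_family(4, identity, length=80, seed=2)
        for mut in fam[1:]:
            realized = sum(a == b for a, b in zip(fam[0], mut)) / 80
            assert abs(realized - identity) <= 1 / 80 + 1e-9

    def test_seed_reproducibility(self):
        assert ab.make_sequence_family(3, 0.9, 60, seed=7) == ab.make_sequence_family(3, 0.9, 60, seed=7)

    def test_invalid_identity_rejected(self):
        with pytest.raises(ValueError):
            ab.make_sequence_family(2, 1.5)


class TestAccountingFixtures:
    def test_filter_manifest_counts_are_exact(self):
        manifest = ab.make_filter_manifest(seed=3)
        assert len(manifest) == 4915
        assert sum(1 for r in manifest if r.is_duplicate) == 222
        assert sum(1 for r in manifest if r.has_unk) == 3
        assert sum(1 for r in manifest if r.ab_format == "Fll") == 13

    def test_dedup_manifest_counts_and_disjointness(self):
        entries, interfaces = ab.make_dedup_manifest(
            n_representatives=12, n_reinstated=5, n_true_redundant=7, seed=0
        )
        assert len(entries) == 12 + 5 + 7
        by_label = {}
        for cid, label in entries:
            by_label.setdefault(label, []).append(cid)
        # reinstatable members are disjoint from their representative
        for g in range(5):
            rep, other = f"c{g:04d}_0", f"c{g:04d}_1"
            assert not interfaces[rep] & interfaces[other]
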