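"""Concavity field: anchors, pocket recovery vs the brute-force oracle,
nesting, sampling, and residue/group summaries."""

import numpy as np
import pandas as pd
import pytest

import ablandscape as ab
from ablandscape.concavity import (
    AtomConcavity,
    ProbeSweep,
    _bulk_centers,
    summarize_group,
    summarize_residue,
)
from ablandscape.geometry import collect_atoms

from conftest import (
    SWEEP,
    brute_force_rinaccess,
    pocket_voxel_points,
    slab_coords,
    slab_field,
)


class TestProbeSweep:
    def test_radii_must_ascend(self):
        with pytest.raises(ValueError):
            ProbeSweep(radii=(2.5, 2.5, 3.5))

    def test_default_sweep_endpoints(self):
        assert SWEEP.floor == 2.5 and SWEEP.cap == 10.5

    def test_spacing_larger_than_smallest_probe_rejected(self):
        slab = ab.make_slab(ab.SlabSpec(extent=24.0))
        with pytest.raises(ValueError, match="spacing"):
            ab.compute_field(slab, spacing=3.0)


class TestAnchors:
    def test_flat_plane_reads_the_cap(self, flat_slab_and_field):
        _, field = flat_slab_and_field
        assert field.value_at((0.0, 0.0, 4.8)) == SWEEP.cap

    def test_flat_limit_holds_over_the_face_center(self, flat_slab_and_field):
        slab, field = flat_slab_and_field
        # 2 A shell of voxels starting just above the vdW surface
        zs = np.arange(2.2, 4.2, field.spacing)
        xs = np.arange(-4.0, 4.0, field.spacing)
        values = [
            field.value_at((x, y, z)) for x in xs for y in xs for z in zs
        ]
        assert np.mean(np.array(values) == SWEEP.cap) >= 0.99

    def test_sub_probe_crevice_reads_the_floor(self, crevice_field):
        spec, _, field = crevice_field
        assert field.value_at((0.0, 0.0, spec.surface_z - 5.0)) == SWEEP.floor


class TestPocketRecovery:
    @pytest.mark.parametrize("radius", [3.0, 4.5, 6.0, 8.0])
    def test_pocket_value_and_oracle_agreement(self, radius):
        # grid spacing matches the oracle's 0.4 A placement resolution so
        # both sides quantize candidate probe centers identically
        spec = ab.SlabSpec(
            extent=40.0, atom_spacing=1.0, pocket_radius=radius, pocket_depth=radius
        )
        slab, field = slab_field(spec, spacing=0.4)
        coords = slab_coords(slab)

        # near the pocket bottom only probes that fit the cavity reach in:
        # the value is the smallest sweep radius exceeding the pocket radius
        sample = (0.0, 0.0, spec.surface_z - radius + 0.8)
        expected = min(r for r in SWEEP.radii if r > radius)
        assert field.value_at(sample) == expected

        # voxel-by-voxel agreement with the brute-force ball-placement oracle
        points, values = pocket_voxel_points(spec, field)
        assert len(points) > 20
        oracle = brute_force_rinaccess(coords, spec.atom_radius, points, field)
        assert np.mean(values == oracle) >= 0.95


class TestFieldProperties:
    def test_accessible_sets_nest_across_the_sweep(self):
        """The field's accessible sets are nested, so R_inaccess is
        single-valued; the raw per-radius openings (before the cumulative
        intersection that enforces nesting) may violate it only on a
        negligible fringe of voxels."""
        from scipy import ndimage

        spec = ab.SlabSpec(extent=24.0, atom_spacing=1.0, pocket_radius=4.5, pocket_depth=4.5)
        slab, field = slab_field(spec)
        from ablandscape.concavity import _clearance

        solvent = ~field.occupied
        vals = np.where(solvent, field.values, 0.0)
        for r, next_r in zip(SWEEP.radii, SWEEP.radii[1:]):
            # accessible(r) = voxels whose assigned value exceeds r
            acc_r = solvent & (vals > r)
            acc_next = solvent & (vals > next_r)
            assert not (acc_next & ~acc_r).any()

        coords = slab_coords(slab)
        clearance = _clearance(
            coords, np.full(len(coords), spec.atom_radius), field.origin,
            field.shape, field.spacing,
        )
        prev = None
        n_solvent = int(solvent.sum())
        for r in SWEEP.radii:
            centers = _bulk_centers(clearance >= r)
            if centers.any():
                reach = ndimage.distance_transform_edt(~centers, sampling=field.spacing)
                acc = reach <= r
            else:
                acc = np.zeros(field.shape, dtype=bool)
            if prev is not None:
                violations = int((acc & ~prev & solvent).sum())
                assert violations / n_solvent < 0.05
            prev = acc

    def test_values_come_only_from_the_sweep(self, flat_slab_and_field):
        _, field = flat_slab_and_field
        vals = field.values[~np.isnan(field.values)]
        assert set(np.unique(vals)) <= set(SWEEP.radii)

    def test_grid_refinement_is_stable(self):
        """Halving the spacing moves few atom-level values by more than one
        sweep step. Sampled at positions a real atom center could occupy
        (clearance >= a probe radius from the partner surface)."""
        from scipy.spatial import cKDTree

        spec = ab.SlabSpec(extent=24.0, atom_spacing=1.0, pocket_radius=4.5, pocket_depth=4.5)
        slab, coarse = slab_field(spec, spacing=0.8)
        _, fine = slab_field(spec, spacing=0.4)
        coords = slab_coords(slab)
        tree = cKDTree(coords)
        rng = np.random.default_rng(0)
        half = spec.extent / 2 - 1.0
        pts = np.column_stack([
            rng.uniform(-half, half, 600),
            rng.uniform(-half, half, 600),
            rng.uniform(-2.5, 6, 600),
        ])
        clearance = tree.query(pts)[0] - spec.atom_radius
        pts = pts[clearance >= 1.4]
        assert len(pts) >= 100
        step = 1.0  # sweep step
        deltas = np.array([abs(coarse.value_at(p) - fine.value_at(p)) for p in pts])
        assert np.mean(deltas > step + 1e-9) <= 0.05


class TestSampling:
    def test_ligand_over_flat_face_reads_cap(self, flat_slab_and_field):
        slab, field = flat_slab_and_field
        ligand = ab.make_probe_ligand((0.0, 0.0, 4.8))
        (av,) = ab.sample_atoms(field, [ligand])
        assert av.r_inaccess == SWEEP.cap

    def test_ligand_in_pocket_matches_field_value(self):
        spec = ab.SlabSpec(extent=40.0, atom_spacing=1.0, pocket_radius=4.5, pocket_depth=4.5)
        _, field = slab_field(spec)
        pos = (0.0, 0.0, spec.surface_z - 4.5 + field.spacing)
        ligand = ab.make_probe_ligand(pos)
        (av,) = ab.sample_atoms(field, [ligand])
        assert av.r_inaccess == field.value_at(pos)

    def test_two_atoms_in_one_voxel_get_identical_values(self, flat_slab_and_field):
        _, field = flat_slab_and_field
        eps = field.spacing / 10
        a = ab.sample_atoms(field, [ab.make_probe_ligand((0.0, 0.0, 4.8))])[0]
        b = ab.sample_atoms(field, [ab.make_probe_ligand((eps, eps, 4.8 + eps))])[0]
        assert a.r_inaccess == b.r_inaccess

    def test_clashing_atom_gets_floor_and_warning(self, flat_slab_and_field):
        _, field = flat_slab_and_field
        with pytest.warns(UserWarning, match="clash"):
            (av,) = ab.sample_atoms(field, [ab.make_probe_ligand((0.0, 0.0, -1.5))])
        assert av.r_inaccess == SWEEP.floor

    def test_atom_outside_grid_gets_cap_and_warning(self, flat_slab_and_field):
        _, field = flat_slab_and_field
        with pytest.warns(UserWarning, match="outside"):
            (av,) = ab.sample_atoms(field, [ab.make_probe_ligand((0.0, 0.0, 500.0))])
        assert av.r_inaccess == SWEEP.cap


def _atom_values(values, key=("H", 110, ""), aa="W"):
    return [
        AtomConcavity(residue_key=key, atom_name=f"A{i}", r_inaccess=v, aa=aa)
        for i, v in enumerate(values)
    ]


class TestResidueSummary:
    def test_tryptophan_worked_example_deepest(self):
        # side-chain atomic values spanning 2.87-8.31 A
        values = [2.87, 3.5, 4.1, 5.0, 5.9, 6.6, 7.2, 7.8, 8.1, 8.31]
        (res,) = summarize_residue(_atom_values(values))
        assert res.deepest == pytest.approx(2.87)
        assert res.n_atoms == 10

    def test_single_atom_residue(self):
        (res,) = summarize_residue(_atom_values([4.5]))
        assert res.deepest == res.average == 4.5

    def test_min_and_mean(self):
        (res,) = summarize_residue(_atom_values([3.5, 4.5]))
        assert res.deepest == 3.5 and res.average == 4.0

    def test_deepest_never_exceeds_average(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = rng.uniform(2.5, 10.5, size=rng.integers(1, 12))
            (res,) = summarize_residue(_atom_values(list(vals)))
            assert res.deepest <= res.average + 1e-12


class TestGroupSummary:
    def _table(self):
        return pd.DataFrame(
            [
                dict(complex_id="c1", cdr_label="H3", deepest=3.0),
                dict(complex_id="c1", cdr_label="H3", deepest=5.0),
                dict(complex_id="c2", cdr_label="H3", deepest=4.0),
                dict(complex_id="c2", cdr_label="H3", deepest=6.0),
            ]
        )

    def test_deepest_use_takes_per_complex_minimum(self):
        s = summarize_group(self._table(), "cdr_label", mode="deepest", value_column="deepest")
        assert s.loc[0, "mean"] == pytest.approx((3 + 4) / 2)

    def test_average_use_takes_per_complex_mean(self):
        s = summarize_group(self._table(), "cdr_label", mode="average", value_column="deepest")
        assert s.loc[0, "mean"] == pytest.approx((4 + 5) / 2)

    def test_single_complex_group_equals_its_statistic(self):
        table = self._table().query("complex_id == 'c1'")
        s = summarize_group(table, "cdr_label", mode="deepest", value_column="deepest")
        assert s.loc[0, "mean"] == 3.0 and s.loc[0, "n_complexes"] == 1

    def test_deepest_use_never_exceeds_average_use(self):
        rng = np.random.default_rng(2)
        rows = [
            dict(complex_id=f"c{c}", cdr_label=lbl, deepest=float(rng.uniform(2.5, 10.5)))
            for c in range(6) for lbl in ("H1", "H3") for _ in range(rng.integers(1, 5))
        ]
        table = pd.DataFrame(rows)
        deep = summarize_group(table, "cdr_label", mode="deepest", value_column="deepest")
        avg = summarize_group(table, "cdr_label", mode="average", value_column="deepest")
        merged = deep.merge(avg, on="cdr_label", suffixes=("_deep", "_avg"))
        assert (merged["mean_deep"] <= merged["mean_avg"] + 1e-12).all()
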