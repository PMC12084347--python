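"""Unit and property tests for the trajectory observables."""

import numpy as np
import pandas as pd
import pytest

import diolphase as dp
from diolphase.trajectory import (
    DEFAULT_SEPARATION_BINS,
    minimum_image_distance,
    replica_sem,
)

from conftest import (
    brute_force_cosolvent_contacts,
    brute_force_residue_contacts,
    make_trajectory,
)


class TestMinimumImage:
    def test_wrap_across_boundary(self):
        assert minimum_image_distance((0, 0, 0), (9, 0, 0), (10, 10, 10)) == pytest.approx(1.0)

    def test_coincident_points(self):
        assert minimum_image_distance((1, 2, 3), (1, 2, 3), (10, 10, 10)) == 0.0

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            minimum_image_distance((0, 0, 0), (1, 0, 0), (0, 10, 10))

    def test_invariant_under_integer_box_shifts(self, rng):
        box = np.array([7.0, 11.0, 13.0])
        a = rng.uniform(0, 20, size=(1000, 3))
        b = rng.uniform(0, 20, size=(1000, 3))
        shifts = rng.integers(-3, 4, size=(1000, 3)) * box
        d0 = minimum_image_distance(a, b, box)
        d1 = minimum_image_distance(a, b + shifts, box)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_triclinic_matches_orthorhombic_special_case(self, rng):
        edges = np.array([8.0, 9.0, 10.0])
        a = rng.uniform(-20, 20, size=(200, 3))
        b = rng.uniform(-20, 20, size=(200, 3))
        d_orth = minimum_image_distance(a, b, edges)
        d_tric = minimum_image_distance(a, b, np.diag(edges))
        np.testing.assert_allclose(d_orth, d_tric, atol=1e-9)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        t = make_trajectory([{}], [[[5.0, 5.0, 5.0]]])
        assert dp.radius_of_gyration(t).per_frame[0] == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        t = make_trajectory(
            [{"mass": 1.0}, {"mass": 1.0, "atom_name": "B"}],
            [[[0.0, 0, 0], [2.0, 0, 0]]],
        )
        assert dp.radius_of_gyration(t).per_frame[0] == pytest.approx(1.0)

    def test_collinear_chain_closed_form(self):
        # 4 unit masses at 1 A spacing: Rg^2 = b^2 (N^2 - 1) / 12 = 1.25
        coords = [[[float(i), 0, 0] for i in range(4)]]
        t = make_trajectory(
            [{"mass": 1.0, "atom_name": f"A{i}"} for i in range(4)], coords
        )
        assert dp.radius_of_gyration(t).per_frame[0] == pytest.approx(np.sqrt(1.25))

    def test_empty_selection_raises(self):
        t = make_trajectory([{}], [[[0.0, 0, 0]]])
        with pytest.raises(ValueError, match="empty"):
            dp.radius_of_gyration(t, selection=np.array([], dtype=int))


class TestIntrachainDistances:
    def test_straight_chain_exact(self):
        b = 2.5
        coords = [[[i * b, 0, 0] for i in range(6)]]
        t = make_trajectory(
            [{"residue_index": i + 1} for i in range(6)], coords
        )
        prof = dp.intrachain_distances(t)
        np.testing.assert_allclose(prof.profile, b * prof.separations)
        for s in range(1, 6):
            np.testing.assert_allclose(
                np.diagonal(prof.mean_distance, offset=s), b * s
            )

    def test_single_replica_sem_is_nan(self):
        coords = [[[i * 1.0, 0, 0] for i in range(4)]]
        t = make_trajectory([{"residue_index": i + 1} for i in range(4)], coords)
        prof = dp.intrachain_distances(t)
        assert np.all(np.isnan(prof.profile_sem))

    def test_two_residue_minimum(self):
        t = make_trajectory([{"residue_index": 1}], [[[0.0, 0, 0]]])
        with pytest.raises(ValueError):
            dp.intrachain_distances(t)


def _random_system(rng, n_frames=5, n_res=20, n_mol=6, box=25.0):
    rows = []
    for r in range(1, n_res + 1):
        rows.append({"residue_index": r, "atom_name": "BB"})
        rows.append(
            {"residue_index": r, "atom_name": "S1", "sidechain": True}
        )
    for m in range(1, n_mol + 1):
        for a in range(3):
            rows.append(
                {
                    "residue_index": 0,
                    "residue_type": "HD6",
                    "atom_name": f"C{a}",
                    "molecule_id": m,
                    "molecule_kind": "cosolvent",
                }
            )
    n_atoms = len(rows)
    coords = rng.uniform(0, box, size=(n_frames, n_atoms, 3))
    return make_trajectory(rows, coords, box_edge=box)


class TestContactMap:
    def test_inclusive_cutoff_boundary(self):
        # heavy-atom pairs at 4.0, exactly 4.5, and 4.6 A
        for dist, expected in [(4.0, 1.0), (4.5, 1.0), (4.6, 0.0)]:
            t = make_trajectory(
                [
                    {"residue_index": 1},
                    {"residue_index": 2, "atom_name": "BB2"},
                ],
                [[[0.0, 0, 0], [dist, 0, 0]]],
            )
            cm = dp.residue_contact_map(t, cutoff=4.5)
            assert cm.frequency[0, 1] == expected

    def test_matches_brute_force_on_random_frames(self, rng):
        t = _random_system(rng, n_frames=20)
        cm = dp.residue_contact_map(t, cutoff=4.5)
        oracle = brute_force_residue_contacts(t, 4.5)
        np.testing.assert_array_equal(
            np.nan_to_num(cm.frequency), np.nan_to_num(oracle)
        )

    def test_monotone_in_cutoff(self, rng):
        t = _random_system(rng)
        f1 = dp.residue_contact_map(t, cutoff=3.0).frequency
        f2 = dp.residue_contact_map(t, cutoff=5.0).frequency
        assert np.all(np.nan_to_num(f2) >= np.nan_to_num(f1))

    def test_translation_invariance(self, rng):
        t = _random_system(rng, n_frames=4)
        shifted = t.translated([13.7, -8.1, 40.0])
        a = dp.residue_contact_map(t, cutoff=4.5).frequency
        b = dp.residue_contact_map(shifted, cutoff=4.5).frequency
        np.testing.assert_array_equal(np.nan_to_num(a), np.nan_to_num(b))

    def test_cutoff_validation(self, rng):
        t = _random_system(rng, n_frames=1)
        with pytest.raises(ValueError):
            dp.residue_contact_map(t, cutoff=-1.0)
        with pytest.raises(ValueError, match="minimum-image"):
            dp.residue_contact_map(t, cutoff=20.0)

    def test_diagonal_masked_and_symmetric(self, rng):
        t = _random_system(rng, n_frames=3)
        f = dp.residue_contact_map(t, cutoff=4.5).frequency
        assert np.all(np.isnan(np.diag(f)))
        np.testing.assert_array_equal(np.nan_to_num(f), np.nan_to_num(f.T))


class TestContactsBySeparation:
    def test_uniform_map_gives_constant_bins(self):
        n = 120
        f = np.full((n, n), 0.37)
        np.fill_diagonal(f, np.nan)
        cm = dp.trajectory.ContactMap(frequency=f, frame_count=1, cutoff=4.5)
        out = dp.contacts_by_separation(cm)
        assert np.allclose(out["mean"], 0.37)

    def test_long_range_only_map(self):
        n = 120
        f = np.zeros((n, n))
        i, j = np.triu_indices(n, k=101)
        f[i, j] = f[j, i] = 1.0
        np.fill_diagonal(f, np.nan)
        cm = dp.trajectory.ContactMap(frequency=f, frame_count=1, cutoff=4.5)
        out = dp.contacts_by_separation(cm)
        assert np.allclose(out["mean"][:-1], 0.0)
        assert out["mean"].iloc[-1] == 1.0

    def test_matches_brute_force_group_means(self, rng):
        n = 60
        f = rng.random((n, n))
        f = (f + f.T) / 2
        np.fill_diagonal(f, np.nan)
        cm = dp.trajectory.ContactMap(frequency=f, frame_count=1, cutoff=4.5)
        out = dp.contacts_by_separation(cm)
        for _, row in out.iterrows():
            hi = row["hi"] if row["hi"] is not None else n - 1
            vals = [
                f[i, j]
                for i in range(n)
                for j in range(i + 1, n)
                if row["lo"] <= j - i <= hi
            ]
            if vals:
                assert row["mean"] == pytest.approx(np.mean(vals))

    def test_empty_bin_flagged_not_zero(self):
        f = np.full((5, 5), 0.5)
        np.fill_diagonal(f, np.nan)
        cm = dp.trajectory.ContactMap(frequency=f, frame_count=1, cutoff=4.5)
        out = dp.contacts_by_separation(cm, bins=[(1, 4), (101, None)])
        assert bool(out["empty"].iloc[1]) and np.isnan(out["mean"].iloc[1])


class TestCosolventContacts:
    def test_no_cosolvent_gives_zero_profile(self):
        t = make_trajectory(
            [{"residue_index": i + 1} for i in range(5)],
            [[[i * 10.0, 0, 0] for i in range(5)]],
        )
        prof = dp.cosolvent_contacts(t)
        assert np.all(prof.per_residue == 0.0)

    def test_single_pinned_molecule(self):
        rows = [{"residue_index": i + 1, "residue_type": "G"} for i in range(12)]
        rows.append(
            {
                "residue_index": 0,
                "residue_type": "HD6",
                "atom_name": "C0",
                "molecule_id": 1,
                "molecule_kind": "cosolvent",
            }
        )
        coords = [[[i * 10.0, 0, 0] for i in range(12)] + [[9 * 10.0, 4.0, 0]]]
        t = make_trajectory(rows, np.repeat(np.array(coords), 3, axis=0), box_edge=200.0)
        prof = dp.cosolvent_contacts(t)
        expected = np.zeros(12)
        expected[9] = 1.0  # residue index 10
        np.testing.assert_array_equal(prof.per_residue, expected)

    def test_matches_brute_force(self, rng):
        t = _random_system(rng, n_frames=10)
        prof = dp.cosolvent_contacts(t, cutoff=4.5)
        np.testing.assert_allclose(
            prof.per_residue, brute_force_cosolvent_contacts(t, 4.5)
        )

    def test_type_bins_partition_residues(self, rng):
        t = _random_system(rng, n_frames=2)
        prof = dp.cosolvent_contacts(t)
        assert prof.by_type["n"].sum() == t.n_residues()


class TestAtomisticContactMap:
    def _toy(self, cos_xyz):
        rows = [
            {"residue_index": 1, "residue_type": "Y", "atom_name": "BB"},
            {"residue_index": 1, "residue_type": "Y", "atom_name": "S1",
             "sidechain": True},
            {"residue_index": 0, "residue_type": "HD6", "atom_name": "C0",
             "molecule_id": 1, "molecule_kind": "cosolvent"},
        ]
        coords = [[[0.0, 0, 0], [2.0, 0, 0], list(cos_xyz)]]
        return make_trajectory(rows, coords, box_edge=50.0)

    def test_single_pair_within_cutoff(self):
        amap = dp.atomistic_contact_map(self._toy([4.0, 0, 0]), "Y")
        assert amap.matrix.shape == (1, 1)
        assert amap.matrix[0, 0] == 1.0

    def test_marginals_equal_sums(self, rng):
        t = _random_system(rng, n_frames=4)
        rtype = t.topology[t.topology.molecule_kind == "protein"].residue_type.iloc[0]
        amap = dp.atomistic_contact_map(t, rtype)
        np.testing.assert_allclose(amap.row_marginal, amap.matrix.sum(axis=1))
        np.testing.assert_allclose(amap.col_marginal, amap.matrix.sum(axis=0))

    def test_absent_residue_type_lists_available(self):
        with pytest.raises(ValueError, match="available"):
            dp.atomistic_contact_map(self._toy([4.0, 0, 0]), "W")

    def test_no_cosolvent_all_zero(self):
        t = make_trajectory(
            [
                {"residue_index": 1, "residue_type": "Y", "atom_name": "S1",
                 "sidechain": True},
            ],
            [[[0.0, 0, 0]]],
        )
        amap = dp.atomistic_contact_map(t, "Y")
        assert amap.matrix.size == 0 or np.all(amap.matrix == 0)


class TestRDF:
    def test_single_pair_direct_formula(self):
        rows = [
            {"residue_index": 1, "residue_type": "Y", "atom_name": "S1",
             "sidechain": True},
            {"residue_index": 0, "residue_type": "HD6", "atom_name": "C0",
             "molecule_id": 1, "molecule_kind": "cosolvent"},
        ]
        box = 30.0
        t = make_trajectory(rows, [[[5.0, 5, 5], [10.0, 5, 5]]], box_edge=box)
        res = dp.rdf_sidechain_com(t, "Y", r_max=12.0, dr=0.1)
        k = np.searchsorted(res.bin_edges, 5.0, side="right") - 1
        r_mid = res.r_mid[k]
        expected = 1.0 / (4 * np.pi * r_mid**2 * 0.1 * (1.0 / box**3))
        assert res.g[k] == pytest.approx(expected)
        assert res.counts.sum() == 1

    def test_count_conservation(self, rng):
        t = _random_system(rng, n_frames=6)
        rtype = t.topology[t.topology.molecule_kind == "protein"].residue_type.iloc[0]
        res = dp.rdf_sidechain_com(t, rtype, r_max=10.0, dr=0.25)
        # recount with the brute-force minimum-image distance
        hc = t.cosolvent_heavy()
        sc = t.topology[
            (t.topology.molecule_kind == "protein")
            & (t.topology.residue_type == rtype)
            & t.topology.sidechain
        ]
        n_direct = 0
        for f in range(t.n_frames):
            for _, grp in sc.groupby("residue_index"):
                com = t.coords[f, np.asarray(grp.index)].mean(axis=0)
                d = minimum_image_distance(
                    com, t.coords[f, hc], t.box[f]
                )
                n_direct += int(np.sum(d <= 10.0))
        assert res.counts.sum() == n_direct

    def test_r_max_beyond_half_box_raises(self, rng):
        t = _random_system(rng, n_frames=1, box=20.0)
        rtype = t.topology[t.topology.molecule_kind == "protein"].residue_type.iloc[0]
        with pytest.raises(ValueError, match="minimum-image"):
            dp.rdf_sidechain_com(t, rtype, r_max=15.0)


class TestDensityAndSEM:
    def test_unit_conversion(self):
        t = make_trajectory(
            [{"mass": 602.2}], [[[1.0, 1, 1]]], box_edge=10.0
        )  # 602.2 Da in 1000 A^3
        assert dp.solution_density(t).mean == pytest.approx(1.0, rel=1e-4)

    def test_linearity_in_mass(self):
        t1 = make_trajectory([{"mass": 100.0}], [[[0.0, 0, 0]]], box_edge=10.0)
        t2 = make_trajectory([{"mass": 200.0}], [[[0.0, 0, 0]]], box_edge=10.0)
        assert dp.solution_density(t2).mean == pytest.approx(
            2 * dp.solution_density(t1).mean
        )

    def test_replica_sem_hand_arithmetic(self):
        mean, sem = replica_sem([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / np.sqrt(3))

    def test_replica_sem_identical_replicas(self):
        mean, sem = replica_sem([np.ones(4), np.ones(4)])
        np.testing.assert_array_equal(sem, 0.0)

    def test_replica_sem_single_replica_flagged(self):
        _, sem = replica_sem([np.ones(3)])
        assert np.all(np.isnan(sem))

    def test_replica_sem_shape_mismatch(self):
        with pytest.raises(ValueError):
            replica_sem([np.ones(3), np.ones(4)])
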