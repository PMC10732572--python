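"""Interface census: contacts vs brute force, H-bond geometry, SASA."""

import numpy as np
import pytest

from bindfit.interface import (
    Atom,
    Structure,
    buried_area,
    contact_share,
    count_contacts,
    detect_hbonds,
    interface_stats,
    read_structure,
    write_structure,
)
from bindfit.synth import gen_toy_complex


def brute_force_contacts(struct, idx_a, idx_b, cutoff):
    return sum(
        1
        for i in idx_a
        for j in idx_b
        if np.linalg.norm(struct.coords[i] - struct.coords[j]) <= cutoff
    )


def two_atoms(distance):
    return Structure([
        Atom("A", 1, "", "ALA", "CA", "C", (0.0, 0.0, 0.0)),
        Atom("B", 1, "", "ALA", "CA", "C", (distance, 0.0, 0.0)),
    ])


class TestReadWrite:
    def test_minimal_two_atom_file(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00 10.00           C\n"
            "ATOM      2  CB  ALA A   1       1.500   0.000   0.000"
            "  1.00 10.00           C\n"
            "END\n"
        )
        st = read_structure(str(pdb))
        assert len(st) == 2
        assert st.atoms[0].name == "CA" and st.atoms[0].res_name == "ALA"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.30 10.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000"
            "  0.70 10.00           C\n"
            "END\n"
        )
        st = read_structure(str(pdb))
        assert len(st) == 1
        assert st.atoms[0].xyz[0] == pytest.approx(2.0)
        assert st.atoms[0].occupancy == pytest.approx(0.70)

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_bytes(b"\x00\x01\x02 not a pdb at all\n" * 3)
        with pytest.raises(ValueError):
            read_structure(str(bad))

    def test_toy_complex_round_trip(self, tmp_path):
        st, _ = gen_toy_complex(60, 10, seed=7)
        path = tmp_path / "toy.pdb"
        write_structure(st, str(path))
        st2 = read_structure(str(path))

        def key(a):
            return (a.chain, a.res_seq, a.icode, a.name, a.res_name,
                    a.element, a.xyz)

        assert sorted(map(key, st.atoms)) == sorted(map(key, st2.atoms))


class TestCountContacts:
    def test_cutoff_boundary(self):
        assert count_contacts(two_atoms(4.30), "A", "B").n_contacts == 0
        assert count_contacts(two_atoms(4.10), "A", "B").n_contacts == 1

    def test_random_toy_complex_matches_brute_force(self):
        st, n_true = gen_toy_complex(200, 30, seed=11)
        cs = count_contacts(st, "A", "B")
        bf = brute_force_contacts(st, st.select("A"), st.select("B"), 4.2)
        assert cs.n_contacts == bf == n_true

    def test_symmetric_in_selections(self):
        st, _ = gen_toy_complex(80, 12, seed=2)
        assert (count_contacts(st, "A", "B").n_contacts
                == count_contacts(st, "B", "A").n_contacts)

    def test_rigid_motion_invariance(self):
        st, _ = gen_toy_complex(120, 15, seed=5)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = Structure([
            Atom(a.chain, a.res_seq, a.icode, a.res_name, a.name, a.element,
                 tuple(rot @ np.array(a.xyz) + np.array([11.0, -3.0, 42.0])))
            for a in st.atoms
        ])
        assert (count_contacts(moved, "A", "B").n_contacts
                == count_contacts(st, "A", "B").n_contacts)

    def test_empty_or_overlapping_selection_rejected(self):
        st = two_atoms(3.0)
        with pytest.raises(ValueError, match="empty"):
            count_contacts(st, "Z", "B")
        with pytest.raises(ValueError, match="disjoint"):
            count_contacts(st, ["A", "B"], "B")


class TestHbonds:
    def test_ideal_pair_detected(self):
        st = Structure([
            Atom("A", 1, "", "SER", "OG", "O", (0, 0, 0)),
            Atom("B", 1, "", "ASP", "OD1", "O", (2.9, 0, 0)),
        ])
        assert len(detect_hbonds(st, "A", "B")) == 1

    def test_long_pair_rejected(self):
        st = Structure([
            Atom("A", 1, "", "SER", "OG", "O", (0, 0, 0)),
            Atom("B", 1, "", "ASP", "OD1", "O", (3.6, 0, 0)),
        ])
        assert len(detect_hbonds(st, "A", "B")) == 0

    def test_angle_criterion_with_explicit_hydrogen(self):
        # hydrogen pointing away from the acceptor: angle ~0, rejected
        st = Structure([
            Atom("A", 1, "", "SER", "OG", "O", (0, 0, 0)),
            Atom("A", 1, "", "SER", "HG", "H", (-0.95, 0, 0)),
            Atom("B", 1, "", "ASP", "OD1", "O", (2.9, 0, 0)),
        ])
        assert len(detect_hbonds(st, "A", "B")) == 0
        # hydrogen between donor and acceptor: near-linear, accepted
        st2 = Structure([
            Atom("A", 1, "", "SER", "OG", "O", (0, 0, 0)),
            Atom("A", 1, "", "SER", "HG", "H", (0.95, 0, 0)),
            Atom("B", 1, "", "ASP", "OD1", "O", (2.9, 0, 0)),
        ])
        assert len(detect_hbonds(st2, "A", "B")) == 1

    def test_water_mediated_bridge(self):
        st = Structure([
            Atom("A", 1, "", "SER", "OG", "O", (0, 0, 0)),
            Atom("W", 1, "", "HOH", "O", "O", (2.8, 0, 0), hetero=True),
            Atom("B", 1, "", "ASP", "OD1", "O", (5.7, 0, 0)),
        ])
        direct = detect_hbonds(st, "A", "B")
        assert len(direct) == 0
        bridged = detect_hbonds(st, "A", "B", water_mediated=True)
        assert len(bridged) == 1 and bridged[0].water_mediated

    def test_unknown_residue_skipped_with_warning(self):
        st = Structure([
            Atom("A", 1, "", "XYZ", "O1", "O", (0, 0, 0)),
            Atom("B", 1, "", "ASP", "OD1", "O", (2.9, 0, 0)),
        ])
        with pytest.warns(UserWarning, match="unknown residue"):
            bonds = detect_hbonds(st, "A", "B")
        assert len(bonds) == 0


class TestBuriedArea:
    def test_isolated_atom_sasa(self):
        from bindfit.interface import _sasa

        area = _sasa(np.zeros((1, 3)), np.array([1.70]), 1.4, 960)
        assert area == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_distant_chains_bury_nothing(self):
        st = two_atoms(100.0)
        assert abs(buried_area(st, "A", "B")) < 1e-6

    def test_two_sphere_overlap_matches_cap_formula(self):
        st = Structure([
            Atom("A", 1, "", "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            Atom("B", 1, "", "ALA", "O", "O", (2.5, 0.0, 0.0)),
        ])
        r1, r2, d = 1.70 + 1.4, 1.52 + 1.4, 2.5
        # buried area on each sphere is the spherical cap hidden inside the
        # other; cap height h = r_other^2 - (d - r_self)^2 over 2d
        h1 = (r2**2 - (d - r1) ** 2) / (2 * d)
        h2 = (r1**2 - (d - r2) ** 2) / (2 * d)
        analytic = 0.5 * (2 * np.pi * r1 * h1 + 2 * np.pi * r2 * h2)
        assert buried_area(st, "A", "B") == pytest.approx(analytic, rel=0.01)

    def test_symmetry_and_convergence(self):
        st, _ = gen_toy_complex(40, 8, seed=9)
        b1 = buried_area(st, "A", "B", n_points=960)
        b2 = buried_area(st, "B", "A", n_points=960)
        assert b1 == pytest.approx(b2, rel=1e-9)
        assert b1 >= 0
        b_fine = buried_area(st, "A", "B", n_points=1920)
        assert b_fine == pytest.approx(b1, rel=0.005)

    def test_missing_radius_named(self):
        st = Structure([
            Atom("A", 1, "", "ALA", "X1", "XX", (0, 0, 0)),
            Atom("B", 1, "", "ALA", "CA", "C", (3.0, 0, 0)),
        ])
        with pytest.raises(KeyError, match="XX"):
            buried_area(st, "A", "B")

    def test_cross_check_against_biotite(self):
        """Independent SASA backend agrees on a toy complex within a few
        percent (different point sets and neighbor handling)."""
        biotite_struc = pytest.importorskip("biotite.structure")
        st, _ = gen_toy_complex(30, 5, seed=4)
        idx = st.select("A")
        arr = biotite_struc.AtomArray(idx.size)
        arr.coord = st.coords[idx]
        for field, val in (("chain_id", "A"), ("res_name", "ALA"),
                           ("atom_name", "CA"), ("element", "C")):
            arr.set_annotation(field, np.full(idx.size, val))
        arr.res_id = np.arange(1, idx.size + 1)
        ref = float(np.nansum(biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii=np.full(idx.size, 1.70))))
        from bindfit.interface import _sasa

        mine = _sasa(st.coords[idx], np.full(idx.size, 1.70), 1.4, 960)
        assert mine == pytest.approx(ref, rel=0.03)


class TestContactShare:
    def test_full_and_empty_subsets(self):
        st, _ = gen_toy_complex(80, 10, seed=6)
        cs = count_contacts(st, "A", "B")
        all_res = {a.residue_id for a in st.atoms}
        assert contact_share(cs, all_res) == 1.0
        assert contact_share(cs, set()) == 0.0

    def test_hot_spot_share_matches_brute_force(self):
        st, _ = gen_toy_complex(80, 10, seed=6)
        cs = count_contacts(st, "A", "B")
        subset = {cs.structure.atoms[cs.pairs[0][0]].residue_id}
        manual = sum(
            1 for ia, ib, _ in cs.pairs
            if st.atoms[ia].residue_id in subset or st.atoms[ib].residue_id in subset
        )
        assert contact_share(cs, subset) == pytest.approx(manual / cs.n_contacts)

    def test_unknown_residue_rejected(self):
        st, _ = gen_toy_complex(40, 5, seed=6)
        cs = count_contacts(st, "A", "B")
        with pytest.raises(KeyError):
            contact_share(cs, {("Q", 999, "")})


def test_interface_stats_census():
    st, n_true = gen_toy_complex(100, 20, seed=8)
    stats = interface_stats(st, "A", "B")
    assert stats.n_contacts == n_true
    assert stats.buried_area > 0
    assert sum(stats.per_residue_shares.values()) == pytest.approx(1.0)
    assert stats.method["cutoff_A"] == 4.2
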