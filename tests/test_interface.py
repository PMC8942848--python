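import numpy as np
import pytest

from dimerstate.errors import ConfigurationError, DimerRequiredError, DimerStateError
from dimerstate.interface import (
    buried_interface_area,
    contact_persistence,
    detect_contacts,
    interface_interaction_energy,
    interface_report,
    ligand_contact_residues,
    shrake_rupley_sasa,
)
from dimerstate.model import concatenate
from dimerstate.params import ForcefieldParams
from dimerstate.synthetic import SyntheticSpec, make_ideal_helix, plant_contact_series


def two_sphere_accessible_area(r1, r2, d, probe):
    """Closed-form accessible area of two overlapping solvent-expanded spheres."""
    e1, e2 = r1 + probe, r2 + probe
    if d >= e1 + e2:
        return 4 * np.pi * (e1**2 + e2**2)
    h1 = e1 - (d**2 + e1**2 - e2**2) / (2 * d)
    h2 = e2 - (d**2 + e2**2 - e1**2) / (2 * d)
    return 4 * np.pi * e1**2 - 2 * np.pi * e1 * h1 + 4 * np.pi * e2**2 - 2 * np.pi * e2 * h2


class TestSasa:
    def test_single_atom_analytic(self, build):
        m = build([("A", 1, "ALA", "CA", "C", (0, 0, 0))])
        res = shrake_rupley_sasa(m, probe=1.4, n_points=960)
        assert res.total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_distant_atoms_additive(self, build):
        m = build(
            [("A", 1, "ALA", "CA", "C", (0, 0, 0)), ("A", 2, "ALA", "CA", "C", (100, 0, 0))]
        )
        res = shrake_rupley_sasa(m)
        assert res.total == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=0.01)

    def test_two_overlapping_spheres_closed_form(self, build):
        for d in (2.0, 4.0, 5.5):
            m = build(
                [("A", 1, "ALA", "C1", "C", (0, 0, 0)), ("A", 1, "ALA", "O1", "O", (d, 0, 0))]
            )
            res = shrake_rupley_sasa(m, probe=1.4, n_points=2000)
            expected = two_sphere_accessible_area(1.70, 1.52, d, 1.4)
            assert res.total == pytest.approx(expected, rel=0.01)

    def test_per_residue_sums_match_atoms(self, build):
        m = build(
            [("A", 1, "ALA", "CA", "C", (0, 0, 0)), ("A", 1, "ALA", "CB", "C", (1.5, 0, 0)),
             ("A", 2, "ALA", "CA", "C", (5, 0, 0))]
        )
        res = shrake_rupley_sasa(m)
        assert res.residue_area[("A", 1, "")] == pytest.approx(res.atom_area[:2].sum())
        assert sum(res.residue_area.values()) == pytest.approx(res.total)

    def test_unknown_element_errors(self, build):
        m = build([("A", 1, "UNK", "X1", "XX", (0, 0, 0))])
        with pytest.raises(ConfigurationError, match="XX"):
            shrake_rupley_sasa(m)

    def test_all_areas_nonnegative(self, build):
        helix = make_ideal_helix(15, with_cb=True)
        res = shrake_rupley_sasa(helix)
        assert (res.atom_area >= 0).all()


class TestBuriedArea:
    def test_distant_protomers_zero(self, build):
        atoms = [("R", i, "ALA", "CA", "C", (i * 3.8, 0, 0)) for i in range(1, 6)]
        atoms += [("S", i, "ALA", "CA", "C", (i * 3.8, 100, 0)) for i in range(1, 6)]
        m = build(atoms, protomer_map={"R": "A", "S": "B"})
        assert buried_interface_area(m) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_dimer_symmetric_burial(self):
        a = make_ideal_helix(15, chain_id="R")
        b = make_ideal_helix(15, chain_id="S", origin=(7.0, 0.0, 0.0))
        dimer = concatenate([a, b])
        dimer.protomer_map = {"R": "A", "S": "B"}
        area = buried_interface_area(dimer)
        assert area > 50
        sasa_a = shrake_rupley_sasa(dimer.subset(dimer.chain_ids == "R")).total
        sasa_b = shrake_rupley_sasa(dimer.subset(dimer.chain_ids == "S")).total
        assert sasa_a == pytest.approx(sasa_b, rel=1e-6)

    def test_monotone_as_protomers_separate(self):
        a = make_ideal_helix(15, chain_id="R")
        areas = []
        for dx in (6.0, 8.0, 10.0, 14.0):
            b = make_ideal_helix(15, chain_id="S", origin=(dx, 0.0, 0.0))
            dimer = concatenate([a, b])
            dimer.protomer_map = {"R": "A", "S": "B"}
            areas.append(buried_interface_area(dimer))
        assert all(x >= y - 1e-9 for x, y in zip(areas, areas[1:]))
        assert all(a >= 0 for a in areas)

    def test_monomer_rejected(self):
        a = make_ideal_helix(10)
        with pytest.raises(DimerRequiredError):
            buried_interface_area(a)


class TestContacts:
    def test_salt_bridge_detected(self, build):
        m = build(
            [
                ("R", 1, "LYS", "NZ", "N", (0, 0, 0)),
                ("S", 1, "ASP", "OD1", "O", (3.5, 0, 0)),
            ]
        )
        recs = detect_contacts(m, [("R", 1)], [("S", 1)])
        types = {r.type for r in recs}
        assert "salt_bridge" in types

    def test_backbone_hydrogen_bond(self, build):
        m = build(
            [
                ("R", 1, "ALA", "O", "O", (0, 0, 0)),
                ("S", 1, "ALA", "N", "N", (2.9, 0, 0)),
            ]
        )
        recs = detect_contacts(m, [("R", 1)], [("S", 1)])
        assert "hydrogen_bond" in {r.type for r in recs}

    def test_hbond_angle_filter_with_explicit_hydrogen(self, build):
        # H placed between donor and acceptor: near-linear, accepted
        good = build(
            [
                ("R", 1, "ALA", "N", "N", (0, 0, 0)),
                ("R", 1, "ALA", "H", "H", (1.0, 0, 0)),
                ("S", 1, "ALA", "O", "O", (2.9, 0, 0)),
            ]
        )
        assert "hydrogen_bond" in {
            r.type for r in detect_contacts(good, [("R", 1)], [("S", 1)])
        }
        # H pointing away: D-H...A angle < 110, rejected
        bad = build(
            [
                ("R", 1, "ALA", "N", "N", (0, 0, 0)),
                ("R", 1, "ALA", "H", "H", (-1.0, 0, 0)),
                ("S", 1, "ALA", "O", "O", (2.9, 0, 0)),
            ]
        )
        assert "hydrogen_bond" not in {
            r.type for r in detect_contacts(bad, [("R", 1)], [("S", 1)])
        }

    def test_cation_pi_detected(self, build):
        ring = {
            "CG": (0.00, 1.40, 0.0), "CD1": (1.21, 0.70, 0.0), "CD2": (-1.21, 0.70, 0.0),
            "CE1": (1.21, -0.70, 0.0), "CE2": (-1.21, -0.70, 0.0), "CZ": (0.00, -1.40, 0.0),
        }
        atoms = [("S", 1, "PHE", n, "C", xyz) for n, xyz in ring.items()]
        atoms.append(("R", 1, "LYS", "NZ", "N", (0, 0, 4.0)))  # on ring normal
        m = build(atoms)
        assert "cation_pi" in {r.type for r in detect_contacts(m, [("R", 1)], [("S", 1)])}

    def test_groups_must_be_disjoint(self, build):
        m = build([("R", 1, "ALA", "CA", "C", (0, 0, 0))])
        with pytest.raises(ConfigurationError):
            detect_contacts(m, [("R", 1)], [("R", 1)])

    def test_empty_group_warns(self, build):
        m = build([("R", 1, "ALA", "CA", "C", (0, 0, 0))])
        with pytest.warns(UserWarning):
            assert detect_contacts(m, [("R", 1)], [("Z", 9)]) == []

    def test_symmetric_in_group_order(self, build):
        m = build(
            [
                ("R", 1, "LYS", "NZ", "N", (0, 0, 0)),
                ("S", 1, "ASP", "OD1", "O", (3.0, 0, 0)),
                ("S", 2, "ALA", "CA", "C", (3.5, 1, 0)),
            ]
        )
        fwd = {(r.res_a, r.res_b, r.type) for r in detect_contacts(m, [("R", 1)], [("S", 1), ("S", 2)])}
        rev = {(r.res_b, r.res_a, r.type) for r in detect_contacts(m, [("S", 1), ("S", 2)], [("R", 1)])}
        assert fwd == rev

    def test_matches_brute_force_oracle(self, build):
        # brute-force all-atom-pairs re-implementation (vdW + salt bridge +
        # distance-only H-bond; no hydrogens in fixture)
        from dimerstate.params import VDW_RADII

        rng = np.random.default_rng(17)
        names = [("LYS", "NZ", "N"), ("ASP", "OD1", "O"), ("ALA", "CA", "C"),
                 ("SER", "OG", "O"), ("ALA", "O", "O"), ("ALA", "N", "N")]
        atoms = []
        for chain in "RS":
            offset = np.array([0.0, 0.0, 0.0]) if chain == "R" else np.array([4.0, 0, 0])
            for res in range(1, 16):
                rn, an, el = names[rng.integers(len(names))]
                xyz = rng.uniform(-6, 6, 3) + offset
                atoms.append((chain, res, rn, an, el, tuple(xyz)))
        m = build(atoms)
        ga = [("R", r) for r in range(1, 16)]
        gb = [("S", r) for r in range(1, 16)]
        got = {(r.res_a, r.res_b, r.type) for r in detect_contacts(m, ga, gb)}

        donors = {("ALA", "N"), ("SER", "OG"), ("LYS", "NZ")}
        acceptors = {("ALA", "O"), ("SER", "OG"), ("ASP", "OD1")}
        expected = set()
        for i in range(len(atoms)):
            for j in range(len(atoms)):
                ci, cj = atoms[i][0], atoms[j][0]
                if ci != "R" or cj != "S":
                    continue
                d = np.linalg.norm(np.array(atoms[i][5]) - np.array(atoms[j][5]))
                key_i = ("R", atoms[i][1], "")
                key_j = ("S", atoms[j][1], "")
                ri = VDW_RADII[atoms[i][4]]
                rj = VDW_RADII[atoms[j][4]]
                if 0 < d <= ri + rj + 0.5:
                    expected.add((key_i, key_j, "van_der_waals"))
                pi = (atoms[i][2], atoms[i][3])
                pj = (atoms[j][2], atoms[j][3])
                if 0 < d <= 3.5 and (
                    (pi in donors and pj in acceptors) or (pj in donors and pi in acceptors)
                ):
                    expected.add((key_i, key_j, "hydrogen_bond"))
                if 0 < d <= 4.0 and (
                    (pi == ("LYS", "NZ") and pj == ("ASP", "OD1"))
                    or (pi == ("ASP", "OD1") and pj == ("LYS", "NZ"))
                ):
                    expected.add((key_i, key_j, "salt_bridge"))
        assert got == expected


class TestPersistence:
    def test_planted_frequencies(self):
        spec = SyntheticSpec(n_frames=100, contact_plants=[0.70, 0.50, 0.60, 0.0], seed=4)
        traj, truth = plant_contact_series(spec)
        result = contact_persistence(
            traj, [("R", i) for i in range(1, 5)], [("S", i) for i in range(1, 5)], 0.60
        )
        freqs = {pair: f for pair, f in result.frequencies.items()}
        assert freqs[(("R", 1, ""), ("S", 1, ""))] == pytest.approx(0.70)
        assert freqs[(("R", 2, ""), ("S", 2, ""))] == pytest.approx(0.50)
        assert freqs[(("R", 3, ""), ("S", 3, ""))] == pytest.approx(0.60)
        assert (("R", 4, ""), ("S", 4, "")) not in freqs
        persistent = {pair for pair, _ in result.persistent}
        # strict inequality: 0.70 in, 0.60 and 0.50 out
        assert persistent == {(("R", 1, ""), ("S", 1, ""))}

    def test_frequencies_in_unit_interval(self):
        spec = SyntheticSpec(n_frames=50, contact_plants=[0.5, 1.0], seed=1)
        traj, _ = plant_contact_series(spec)
        result = contact_persistence(traj, [("R", 1), ("R", 2)], [("S", 1), ("S", 2)])
        assert all(0.0 <= f <= 1.0 for f in result.frequencies.values())

    def test_zero_frames_error(self, build):
        with pytest.raises(DimerStateError):
            contact_persistence([], [("R", 1)], [("S", 1)])


class TestEnergy:
    def test_coulomb_closed_form(self, build):
        m = build(
            [("A", 1, "XXA", "Q1", "C", (0, 0, 0)), ("B", 1, "XXB", "Q2", "C", (10, 0, 0))]
        )
        ff = ForcefieldParams(
            charge_overrides={"XXA:Q1": 1.0, "XXB:Q2": -1.0},
            lj_overrides={"XXA:Q1": (0.0, 3.4), "XXB:Q2": (0.0, 3.4)},
        )
        vdw, coul, total = interface_interaction_energy(m, [("A", 1)], [("B", 1)], ff)
        assert vdw == 0.0
        assert coul == pytest.approx(-33.20636, abs=1e-4)

    def test_lj_minimum(self, build):
        sigma = 3.4
        r = 2 ** (1 / 6) * sigma
        m = build(
            [("A", 1, "XXA", "Q1", "C", (0, 0, 0)), ("B", 1, "XXB", "Q2", "C", (r, 0, 0))]
        )
        ff = ForcefieldParams(
            charge_overrides={"XXA:Q1": 0.0, "XXB:Q2": 0.0},
            lj_overrides={"XXA:Q1": (0.25, sigma), "XXB:Q2": (0.25, sigma)},
        )
        vdw, coul, total = interface_interaction_energy(m, [("A", 1)], [("B", 1)], ff)
        assert coul == 0.0
        assert vdw == pytest.approx(-0.25, abs=1e-9)

    def test_beyond_cutoff_zero(self, build):
        m = build(
            [("A", 1, "LYS", "NZ", "N", (0, 0, 0)), ("B", 1, "ASP", "OD1", "O", (20, 0, 0))]
        )
        assert interface_interaction_energy(m, [("A", 1)], [("B", 1)]) == (0.0, 0.0, 0.0)

    def test_coulomb_halves_when_distance_doubles(self, build):
        def energy(d):
            m = build(
                [("A", 1, "XXA", "Q1", "C", (0, 0, 0)), ("B", 1, "XXB", "Q2", "C", (d, 0, 0))]
            )
            ff = ForcefieldParams(
                charge_overrides={"XXA:Q1": 1.0, "XXB:Q2": -1.0},
                lj_overrides={"XXA:Q1": (0.0, 3.4), "XXB:Q2": (0.0, 3.4)},
            )
            return interface_interaction_energy(m, [("A", 1)], [("B", 1)], ff, cutoff=1e6)[1]

        assert energy(8.0) == pytest.approx(2 * energy(16.0), rel=1e-9)


class TestLigandContacts:
    def test_distant_ligand_no_contacts(self, build):
        atoms = [("R", i, "ALA", "CA", "C", (i * 3.8, 0, 0)) for i in range(1, 6)]
        atoms.append(("P", 1, "TRP", "CA", "C", (0, 50, 0), True))
        m = build(atoms, protomer_map={"R": "A"})
        assert ligand_contact_residues(m, "P") == []

    def test_touching_exactly_three(self, build):
        atoms = [("R", i, "ALA", "CA", "C", (i * 10.0, 0, 0)) for i in range(1, 6)]
        for k, res in enumerate((1, 3, 5)):
            atoms.append(("P", k + 1, "TRP", "CA", "C", (res * 10.0, 3.0, 0), True))
        m = build(atoms, protomer_map={"R": "A"})
        residues = ligand_contact_residues(m, "P")
        assert [r[1] for r in residues] == [1, 3, 5]

    def test_missing_ligand_chain_errors(self, build):
        m = build([("R", 1, "ALA", "CA", "C", (0, 0, 0))], protomer_map={"R": "A"})
        with pytest.raises(ConfigurationError):
            ligand_contact_residues(m, "P")


def test_interface_report_end_to_end():
    a = make_ideal_helix(15, chain_id="R", with_cb=True)
    b = make_ideal_helix(15, chain_id="S", origin=(8.0, 0.0, 0.0), with_cb=True)
    dimer = concatenate([a, b])
    dimer.protomer_map = {"R": "A", "S": "B"}
    report = interface_report(dimer)
    payload = report.as_dict()
    assert payload["buried_interface_area_A2"] >= 0
    assert payload["interaction_energy_kcal_mol"]["forcefield"] == "reduced_forcefield"
    assert set(payload["interfacial_residues"]) == {"A", "B"}
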