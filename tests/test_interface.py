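"""Receptor/G-alpha interface contact detection and alpha5 geometry."""

import math

import numpy as np
import pytest
from conftest import brute_force_contacts, random_rigid_transform, transform_structure

from gpcrprofile import synthetic
from gpcrprofile.interface import alpha5_tilt, detect_contacts, pocket_composition
from gpcrprofile.structio import Atom, ResidueKey, Structure


def two_residue_fixture(distance, r_name="SER", r_atom="OG", g_name="ALA", g_atom="O"):
    """One receptor residue and one G-alpha residue with a single close pair."""
    st = Structure()
    rk = ResidueKey("R", 1, "", r_name)
    gk = ResidueKey("A", 1, "", g_name)
    st.add_atom(rk, Atom("CA", "C", [0.0, 0.0, -8.0]))
    st.add_atom(rk, Atom(r_atom, "O", [0.0, 0.0, 0.0]))
    st.add_atom(gk, Atom("CA", "C", [0.0, 0.0, distance + 8.0]))
    st.add_atom(gk, Atom(g_atom, "O", [0.0, 0.0, distance]))
    return st


class TestDetectContacts:
    def test_single_planted_hbond(self):
        """A backbone-carbonyl to side-chain-hydroxyl pair at 2.9 A is exactly
        one hydrogen-bond record."""
        st = two_residue_fixture(2.9)
        report = detect_contacts(st, "R", "A")
        assert report.hbond_count == 1 and report.vdw_count == 0
        rec = report.contacts[0]
        assert rec.contact_type == "hbond"
        assert rec.min_distance == pytest.approx(2.9)
        assert set(rec.atom_pair) == {"OG", "O"}

    def test_vdw_cutoff_boundary(self):
        """Two leucines at 4.0 A give one vdW record; at 4.6 A none."""
        def leu_pair(d):
            st = Structure()
            rk = ResidueKey("R", 1, "", "LEU")
            gk = ResidueKey("A", 1, "", "LEU")
            st.add_atom(rk, Atom("CD1", "C", [0.0, 0.0, 0.0]))
            st.add_atom(gk, Atom("CD1", "C", [0.0, 0.0, d]))
            return st

        near = detect_contacts(leu_pair(4.0), "R", "A")
        assert near.vdw_count == 1 and near.hbond_count == 0
        far = detect_contacts(leu_pair(4.6), "R", "A")
        assert len(far.contacts) == 0

    def test_planted_complex_matches_ledger_exactly(self, complex_result):
        report = detect_contacts(
            complex_result.structure, "R", "A", complex_result.bw_map, complex_result.cgn_map
        )
        assert report.hbond_count == complex_result.ledger["hbond_count"] == 4
        assert report.vdw_count == complex_result.ledger["vdw_count"] == 6
        got = {
            (c.receptor_res.seq_number, c.ga_res.seq_number): (c.contact_type, c.min_distance)
            for c in report.contacts
        }
        for planted in complex_result.ledger["contacts"]:
            kind, dist = got[(planted["receptor_seq"], planted["ga_seq"])]
            assert kind == planted["type"]
            assert dist == pytest.approx(planted["distance"], abs=1e-9)

    def test_hbond_partner_labels_match_construction(self, complex_result):
        report = detect_contacts(
            complex_result.structure, "R", "A", complex_result.bw_map, complex_result.cgn_map
        )
        pairs = set(report.hbond_partner_labels())
        assert ("6.30", "H5.13") in pairs
        assert ("8.47", "H5.26") in pairs
        assert ("ICL1.134", "H5.22") in pairs
        assert ("ICL2.208", "H5.19") in pairs

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_randomized_interface_matches_brute_force(self, seed):
        st = synthetic.make_random_interface(seed, n_per_chain=10)
        report = detect_contacts(st, "R", "A")
        got = {
            (c.receptor_res.seq_number, c.ga_res.seq_number): c.contact_type
            for c in report.contacts
        }
        assert got == brute_force_contacts(st, "R", "A")

    def test_invariant_under_rigid_transform(self, complex_result):
        rng = np.random.default_rng(17)
        rot, trans = random_rigid_transform(rng)
        moved = transform_structure(complex_result.structure, rot, trans)
        report = detect_contacts(moved, "R", "A")
        assert report.hbond_count == 4 and report.vdw_count == 6

    def test_vdw_cutoff_monotonicity(self, complex_result):
        small = detect_contacts(complex_result.structure, "R", "A", vdw_cutoff=4.0)
        large = detect_contacts(complex_result.structure, "R", "A", vdw_cutoff=4.5)
        keys = lambda rep: {
            (c.receptor_res.seq_number, c.ga_res.seq_number) for c in rep.contacts
        }
        assert keys(small) <= keys(large)

    def test_no_pair_double_counted(self, complex_result):
        report = detect_contacts(complex_result.structure, "R", "A")
        pairs = [(c.receptor_res.seq_number, c.ga_res.seq_number) for c in report.contacts]
        assert len(pairs) == len(set(pairs))

    def test_salt_bridge_flagged_in_notes(self, complex_result):
        report = detect_contacts(complex_result.structure, "R", "A")
        # planted R318(NH1)..D341(OD1) at 2.9 A is an ionic pair
        rec = next(
            c for c in report.contacts
            if (c.receptor_res.seq_number, c.ga_res.seq_number) == (318, 341)
        )
        assert rec.notes == "salt bridge"

    def test_same_chain_rejected(self, complex_result):
        with pytest.raises(ValueError):
            detect_contacts(complex_result.structure, "R", "R")


class TestPocketComposition:
    def test_planted_pocket_is_exact(self, complex_result):
        labels = pocket_composition(
            complex_result.structure, "R", "A", complex_result.bw_map, complex_result.cgn_map
        )
        assert labels == {"3.54", "5.61", "5.65", "6.33", "6.37", "7.56"}

    def test_distant_probe_gives_empty_set(self, complex_result):
        labels = pocket_composition(
            complex_result.structure, "R", "A",
            complex_result.bw_map, complex_result.cgn_map,
            ga_labels=("H5.12",),  # helix end far from every planted site
        )
        assert labels == set()

    def test_unmapped_probe_label_rejected(self, complex_result):
        with pytest.raises(KeyError):
            pocket_composition(
                complex_result.structure, "R", "A",
                complex_result.bw_map, complex_result.cgn_map, ga_labels=("H9.99",),
            )


class TestAlpha5Tilt:
    @staticmethod
    def a5_ca(result):
        return np.array(
            [a.coord for k, a in result.structure.atoms() if k.chain_id == "A" and a.name == "CA"]
        )

    def test_parallel_helix_zero_tilt(self):
        res = synthetic.make_complex(synthetic.ComplexSpec(seed=3, alpha5_tilt_deg=0.0))
        assert alpha5_tilt(self.a5_ca(res), np.array([0.0, 0.0, 1.0])) == pytest.approx(0.0, abs=1e-9)

    def test_planted_tilt_recovered(self):
        res = synthetic.make_complex(synthetic.ComplexSpec(seed=3, alpha5_tilt_deg=25.0))
        assert alpha5_tilt(self.a5_ca(res), np.array([0.0, 0.0, 1.0])) == pytest.approx(25.0, abs=1.0)

    def test_noisy_helix_within_tolerance(self):
        res = synthetic.make_complex(synthetic.ComplexSpec(seed=3, alpha5_tilt_deg=25.0))
        rng = np.random.default_rng(8)
        noisy = self.a5_ca(res) + rng.normal(0, 0.2, size=(len(synthetic.ALPHA5_SEQ), 3))
        assert alpha5_tilt(noisy, np.array([0.0, 0.0, 1.0])) == pytest.approx(25.0, abs=3.0)

    def test_angle_folded_into_first_quadrant(self):
        res = synthetic.make_complex(synthetic.ComplexSpec(seed=3, alpha5_tilt_deg=25.0))
        # flipping the reference axis must not change the reported tilt
        up = alpha5_tilt(self.a5_ca(res), np.array([0.0, 0.0, 1.0]))
        down = alpha5_tilt(self.a5_ca(res), np.array([0.0, 0.0, -1.0]))
        assert up == pytest.approx(down, abs=1e-9)
        assert 0.0 <= up <= 90.0
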