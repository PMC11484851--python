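"""Activation-hallmark metrics on synthetic bundles with planted geometry."""

import json

import numpy as np
import pytest
from conftest import random_rigid_transform, transform_structure

from gpcrprofile import synthetic
from gpcrprofile.hallmarks import (
    HallmarkReport,
    bundle_axis,
    hallmark_report,
    motif_gap,
    salt_bridge_or_hbond,
    tm6_outward,
    tm7_downward,
)


class TestMotifGap:
    def test_planted_wide_gap_no_contact(self, bundle_result):
        """A 7.3 A 3.46-7.53 gap is above the 4.5 A contact rule."""
        d, contact = motif_gap(bundle_result.structure, bundle_result.bw_map)
        assert d == pytest.approx(bundle_result.ledger["gap_346_753"], abs=1e-9)
        assert contact is False

    def test_contact_at_cutoff_boundary(self):
        res = synthetic.make_bundle(synthetic.BundleSpec(seed=1, gap_346_753=4.4))
        d, contact = motif_gap(res.structure, res.bw_map)
        assert d == pytest.approx(4.4, abs=1e-9)
        assert contact is True

    def test_unresolvable_label(self, bundle_result):
        with pytest.raises(KeyError):
            motif_gap(bundle_result.structure, bundle_result.bw_map, label_a="6.99")


class TestPolarPairs:
    def test_planted_salt_bridge_present(self, bundle_result):
        d, present = salt_bridge_or_hbond(
            bundle_result.structure, bundle_result.bw_map, ("3.49", "3.50"), kind="salt_bridge"
        )
        assert d == pytest.approx(2.9, abs=1e-9)
        assert present

    def test_broken_salt_bridge_absent(self):
        res = synthetic.make_bundle(synthetic.BundleSpec(seed=2, dry_salt_bridge=6.0))
        d, present = salt_bridge_or_hbond(
            res.structure, res.bw_map, ("3.49", "3.50"), kind="salt_bridge"
        )
        assert d == pytest.approx(6.0, abs=1e-9)
        assert not present

    def test_planted_hbond_present(self, bundle_result):
        d, present = salt_bridge_or_hbond(
            bundle_result.structure, bundle_result.bw_map, ("3.50", "5.58"), kind="hbond"
        )
        assert d == pytest.approx(2.9, abs=1e-9)
        assert present

    def test_scan_equals_brute_force_polar_minimum(self):
        """Across an ensemble of planted distances the reported minimum always
        equals the planted polar-pair minimum."""
        for seed, d in enumerate([2.7, 3.1, 3.9, 4.6, 5.5]):
            res = synthetic.make_bundle(synthetic.BundleSpec(seed=seed, dry_salt_bridge=d))
            got, present = salt_bridge_or_hbond(
                res.structure, res.bw_map, ("3.49", "3.50"), kind="salt_bridge"
            )
            assert got == pytest.approx(d, abs=1e-9)
            assert present == (d <= 4.0)

    def test_nonpolar_residue_rejected(self, bundle_result):
        with pytest.raises(ValueError, match="polar"):
            salt_bridge_or_hbond(
                bundle_result.structure, bundle_result.bw_map, ("3.46", "7.53"), kind="hbond"
            )


class TestDisplacements:
    def test_reference_vs_itself_is_zero(self, bundle_pair):
        active, inactive, ledger = bundle_pair
        axis = np.array(ledger["bundle_axis"])
        assert tm6_outward(
            inactive.structure, inactive.structure, inactive.bw_map, inactive.bw_map, axis=axis
        ) == pytest.approx(0.0, abs=1e-9)
        assert tm7_downward(
            inactive.structure, inactive.structure, inactive.bw_map, inactive.bw_map, axis=axis
        ) == pytest.approx(0.0, abs=1e-9)

    def test_planted_lateral_and_axial_shifts(self, bundle_pair):
        active, inactive, ledger = bundle_pair
        axis = np.array(ledger["bundle_axis"])
        t6 = tm6_outward(active.structure, inactive.structure, active.bw_map, inactive.bw_map, axis=axis)
        t7 = tm7_downward(active.structure, inactive.structure, active.bw_map, inactive.bw_map, axis=axis)
        assert t6 == pytest.approx(ledger["tm6_outward"], abs=1e-6)
        assert t7 == pytest.approx(ledger["tm7_downward"], abs=1e-6)

    def test_oblique_shift_decomposes_into_components(self):
        """An oblique TM6 shift decomposes exactly: in-plane part to tm6_outward,
        axial part of TM7 to tm7_downward (hand-computed projections)."""
        spec = synthetic.BundleSpec(seed=5, tm6_outward=5.0, tm7_downward=2.0)
        active, inactive, ledger = synthetic.make_bundle_pair(spec)
        axis = np.array(ledger["bundle_axis"])
        lateral = np.array(ledger["tm6_direction"])
        assert np.linalg.norm(lateral) == pytest.approx(5.0, abs=1e-9)
        assert abs(np.dot(lateral, axis)) < 1e-9  # plant is purely in-plane
        t6 = tm6_outward(active.structure, inactive.structure, active.bw_map, inactive.bw_map, axis=axis)
        assert t6 == pytest.approx(np.linalg.norm(lateral - np.dot(lateral, axis) * axis), abs=1e-9)

    def test_metrics_invariant_under_global_rigid_transform(self, bundle_pair):
        active, inactive, ledger = bundle_pair
        rng = np.random.default_rng(99)
        rot, trans = random_rigid_transform(rng)
        active_t = transform_structure(active.structure, rot, trans)
        inactive_t = transform_structure(inactive.structure, rot, trans)
        axis_t = rot @ np.array(ledger["bundle_axis"])
        t6 = tm6_outward(active_t, inactive_t, active.bw_map, inactive.bw_map, axis=axis_t)
        t7 = tm7_downward(active_t, inactive_t, active.bw_map, inactive.bw_map, axis=axis_t)
        assert t6 == pytest.approx(ledger["tm6_outward"], abs=1e-6)
        assert t7 == pytest.approx(ledger["tm7_downward"], abs=1e-6)
        d, _ = motif_gap(active_t, active.bw_map)
        assert d == pytest.approx(ledger["gap_346_753"], abs=1e-6)

    def test_fitted_bundle_axis_close_to_truth(self, bundle_pair):
        _active, inactive, ledger = bundle_pair
        axis = bundle_axis(
            inactive.structure, inactive.bw_map,
            intracellular_point=inactive.intracellular_point,
        )
        # the point-cloud PCA is approximate for unequal helix lengths;
        # orientation must be right and the tilt modest
        assert float(np.dot(axis, ledger["bundle_axis"])) > 0.95


class TestHallmarkReport:
    def test_report_reproduces_every_planted_value(self, bundle_pair):
        active, inactive, ledger = bundle_pair
        report = hallmark_report(
            active.structure, active.bw_map, inactive.structure, inactive.bw_map,
            axis=np.array(ledger["bundle_axis"]),
        )
        assert report.gap_346_753 == pytest.approx(ledger["gap_346_753"], abs=1e-9)
        assert report.contact_346_753 == ledger["contact_346_753"]
        assert report.dry_salt_bridge_distance == pytest.approx(ledger["dry_salt_bridge"], abs=1e-9)
        assert report.r350_y558_hbond_distance == pytest.approx(ledger["r350_y558_hbond"], abs=1e-9)
        assert report.tm6_outward == pytest.approx(ledger["tm6_outward"], abs=1e-6)
        assert report.tm7_downward == pytest.approx(ledger["tm7_downward"], abs=1e-6)

    def test_active_only_leaves_displacements_unset(self, bundle_result):
        report = hallmark_report(bundle_result.structure, bundle_result.bw_map)
        assert report.tm6_outward is None
        assert report.tm7_downward is None
        assert "tm6_tm7" in report.notes

    def test_json_round_trip(self, bundle_result):
        report = hallmark_report(bundle_result.structure, bundle_result.bw_map)
        back = HallmarkReport.from_json(report.to_json())
        assert back == report
        assert json.loads(report.to_json())["schema"] == "hallmark-report/1"

    def test_cavity_residues_include_motif_lining(self, bundle_result):
        report = hallmark_report(bundle_result.structure, bundle_result.bw_map)
        assert "3.46" in report.cavity_residues
        assert "7.53" in report.cavity_residues
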