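"""Arm assignment, apparent-angle fitting, end-to-end estimation, baselines."""

import math

import numpy as np
import pytest

from crossjig import (
    ApparentAngles,
    AssignmentError,
    EstimationConfig,
    MarkerCentroid,
    MisalignmentState,
    PipelineError,
    assign_arms,
    detect_markers,
    estimate_orientation,
    fit_apparent_angles,
    inter_arm_angle,
    simulate_scan,
    subtract_baseline,
)
from crossjig.volume import CTVolume

from conftest import make_mini_params, mini_config


def fake_centroid(i, x, z, y=0.0):
    return MarkerCentroid(
        id=i,
        position=np.array([x, y, z]),
        total_weight=1.0,
        n_voxels=3,
        extent_mm=(1.0, 1.0, 1.0),
        on_boundary=False,
    )


def cross_centroids(phi_deg=0.0, theta_deg=0.0, lever=200.0):
    """Exact cross of five points at prescribed apparent angles.

    Coronal coordinates are (x, u = -z); a longitudinal point at clockwise
    angle phi from vertical sits at (t sin phi, t cos phi), a transverse
    point at theta from horizontal at (t cos theta, -t sin theta).
    """
    p, t = math.radians(phi_deg), math.radians(theta_deg)
    pts = [
        (0.0, 0.0),
        (lever * math.sin(p), lever * math.cos(p)),
        (-lever * math.sin(p), -lever * math.cos(p)),
        (lever * math.cos(t), -lever * math.sin(t)),
        (-lever * math.cos(t), lever * math.sin(t)),
    ]
    return [fake_centroid(i, x, -u) for i, (x, u) in enumerate(pts)]


class TestAssignArms:
    def test_full_scan_splits_23_and_11_plus_center(self, zero_scan):
        asn = assign_arms(detect_markers(zero_scan), key_markers_only=False)
        assert len(asn.longitudinal) == 23  # centre counted as longitudinal
        assert len(asn.transverse) - 1 == 11  # excluding the shared centre
        assert asn.center in asn.longitudinal and asn.center in asn.transverse

    def test_key_marker_mode_keeps_five(self, zero_scan):
        asn = assign_arms(detect_markers(zero_scan), key_markers_only=True)
        assert len(asn.longitudinal) == 3 and len(asn.transverse) == 3
        assert asn.center in asn.longitudinal and asn.center in asn.transverse

    def test_assignment_robust_to_small_tilt(self, mini_jig):
        counts = {}
        for b in (0.0, 2.0):
            vol = simulate_scan(
                mini_jig, MisalignmentState("table", A=0.0, B=b), make_mini_params()
            )
            asn = assign_arms(detect_markers(vol, threshold_hu=1200.0))
            counts[b] = (len(asn.longitudinal), len(asn.transverse))
        assert counts[0.0] == counts[2.0]

    def test_ambiguous_diagonal_marker_rejected(self):
        cents = cross_centroids() + [fake_centroid(9, 100.0, -101.0)]
        with pytest.raises(AssignmentError, match="ambiguous"):
            assign_arms(cents)

    def test_too_few_centroids_rejected(self):
        with pytest.raises(AssignmentError):
            assign_arms(cross_centroids()[:2])


class TestFitApparentAngles:
    def test_collinear_points_give_exact_angle(self):
        asn = assign_arms(cross_centroids(phi_deg=2.0))
        assert fit_apparent_angles(asn).phi == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("phi, theta", [(0.0, 0.0), (2.0, -1.0), (-3.0, 3.0)])
    def test_sign_conventions(self, phi, theta):
        asn = assign_arms(cross_centroids(phi_deg=phi, theta_deg=theta))
        ap = fit_apparent_angles(asn)
        assert ap.phi == pytest.approx(phi, abs=1e-9)
        assert ap.theta == pytest.approx(theta, abs=1e-9)

    def test_order_invariance(self):
        cents = cross_centroids(phi_deg=1.0, theta_deg=2.0)
        a1 = fit_apparent_angles(assign_arms(cents))
        swapped = [cents[0], cents[2], cents[1], cents[4], cents[3]]
        a2 = fit_apparent_angles(assign_arms(swapped))
        assert a1.phi == pytest.approx(a2.phi) and a1.theta == pytest.approx(a2.theta)

    def test_inter_arm_angle_tracks_shear(self):
        assert inter_arm_angle(assign_arms(cross_centroids())) == pytest.approx(90.0)
        # theta - phi = A tilts the crossing to 90 - |A|
        asn = assign_arms(cross_centroids(phi_deg=0.0, theta_deg=2.0))
        assert inter_arm_angle(asn) == pytest.approx(88.0, abs=1e-9)


class TestEstimateOrientation:
    def test_zero_scan_reports_zero(self, zero_scan):
        rep = estimate_orientation(zero_scan, "table")
        assert abs(rep.state_estimate.A) <= 0.02
        assert abs(rep.state_estimate.B) <= 0.02
        assert rep.verdicts == {"A": "pass", "B": "pass"}

    def test_couch_scenario_recovery(self, scan_couch_plus2):
        rep = estimate_orientation(scan_couch_plus2, "table")
        assert rep.state_estimate.A == pytest.approx(2.0, abs=0.05)
        assert rep.state_estimate.B == pytest.approx(0.0, abs=0.05)

    def test_laser_scenario_recovery(self, scan_laser_mixed):
        rep = estimate_orientation(scan_laser_mixed, "laser")
        assert rep.state_estimate.A == pytest.approx(2.0, abs=0.05)
        assert rep.state_estimate.C == pytest.approx(-2.0, abs=0.05)

    def test_couch_angle_is_theta_minus_phi_in_reports(self, scan_couch_plus2, scan_laser_mixed):
        # exact identity under first-order inversion; second-order departure
        # (<= 0.02° at these magnitudes) under the exact default
        for vol, mode in ((scan_couch_plus2, "table"), (scan_laser_mixed, "laser")):
            rep_fo = estimate_orientation(vol, mode, EstimationConfig(inversion="first_order"))
            assert rep_fo.state_estimate.A == rep_fo.apparent.theta - rep_fo.apparent.phi
            rep = estimate_orientation(vol, mode)
            assert rep.state_estimate.A == pytest.approx(
                rep.apparent.theta - rep.apparent.phi, abs=0.02
            )

    def test_estimates_are_odd(self, scan_couch_plus2, scan_couch_minus2):
        r1 = estimate_orientation(scan_couch_plus2, "table")
        r2 = estimate_orientation(scan_couch_minus2, "table")
        assert r1.state_estimate.A == pytest.approx(-r2.state_estimate.A, abs=0.02)
        assert r1.state_estimate.B == pytest.approx(-r2.state_estimate.B, abs=0.02)

    def test_first_order_inversion_flag(self, scan_couch_plus2):
        rep = estimate_orientation(
            scan_couch_plus2, "table", EstimationConfig(inversion="first_order")
        )
        # exact identity between apparent angles and the linear inversion
        assert rep.state_estimate.B == rep.apparent.phi
        assert rep.state_estimate.A == rep.apparent.theta - rep.apparent.phi

    def test_empty_volume_fails_in_detection_stage(self):
        vol = CTVolume(np.full((16, 16, 16), -1000.0, np.float32), (1, 1, 1), (0, 0, 0))
        with pytest.raises(PipelineError) as exc:
            estimate_orientation(vol, "table")
        assert exc.value.stage == "detection"

    def test_unknown_mode_rejected(self, zero_scan):
        with pytest.raises(PipelineError):
            estimate_orientation(zero_scan, "gantry")

    def test_report_serialization(self, zero_scan):
        rep = estimate_orientation(zero_scan, "table")
        d = rep.to_dict()
        assert {"mode", "phi_deg", "theta_deg", "A_deg", "B_deg", "verdicts"} <= set(d)
        assert "config_hash" in d["provenance"]
        assert "A" in rep.to_text()


class TestSubtractBaseline:
    def _report(self, vol, mode="table"):
        return estimate_orientation(vol, mode)

    def test_self_subtraction_is_zero(self, zero_scan):
        rep = self._report(zero_scan)
        corrected = subtract_baseline(rep, rep)
        assert corrected.state_estimate.A == 0.0
        assert corrected.state_estimate.B == 0.0

    def test_inherent_deviation_subtraction(self, scan_couch_plus2):
        rep = self._report(scan_couch_plus2)
        from dataclasses import replace

        baseline = replace(
            rep, state_estimate=MisalignmentState("table", A=0.03, B=-0.02)
        )
        corrected = subtract_baseline(rep, baseline)
        assert corrected.state_estimate.A == pytest.approx(rep.state_estimate.A - 0.03)
        assert corrected.state_estimate.B == pytest.approx(rep.state_estimate.B + 0.02)
        assert corrected.provenance["baseline"]["A_deg"] == 0.03

    def test_zero_baseline_is_identity(self, scan_couch_plus2):
        rep = self._report(scan_couch_plus2)
        from dataclasses import replace

        zero = replace(rep, state_estimate=MisalignmentState("table", A=0.0, B=0.0))
        corrected = subtract_baseline(rep, zero)
        assert corrected.state_estimate.A == rep.state_estimate.A
        assert corrected.state_estimate.B == rep.state_estimate.B

    def test_mode_mismatch_rejected(self, scan_couch_plus2, scan_laser_mixed):
        r1 = estimate_orientation(scan_couch_plus2, "table")
        r2 = estimate_orientation(scan_laser_mixed, "laser")
        with pytest.raises(ValueError, match="mode"):
            subtract_baseline(r1, r2)
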