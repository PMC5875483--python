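"""Arm identification, apparent-angle fitting, and misalignment inversion.

Detected centroids are split into the two arm pencils by the angle of their
coronal offset from the central marker; each arm line is fitted by total
least squares in the coronal plane (image-horizontal vs. longitudinal
coordinates); the apparent angles ``phi`` and ``theta`` are read off the
fitted directions with the clockwise-positive convention and inverted to a
misalignment state (exact inversion by default).  Reports carry residuals,
tolerance verdicts and provenance, and support subtraction of a baseline
(inherent-deviation) report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import geometry
from .detect import MarkerCentroid, detect_markers
from .geometry import ApparentAngles, MisalignmentState
from .jig import JigGeometry
from .volume import CTVolume

__all__ = [
    "ArmAssignment",
    "AssignmentError",
    "PipelineError",
    "EstimationConfig",
    "OrientationReport",
    "assign_arms",
    "fit_apparent_angles",
    "inter_arm_angle",
    "estimate_orientation",
    "subtract_baseline",
]

#: centroids whose coronal offset lies within this many degrees of the 45°
#: bisector cannot be attributed to either arm
_AMBIGUITY_BAND_DEG = 5.0


class AssignmentError(RuntimeError):
    """Arm assignment failed (ambiguous clustering or missing end markers)."""


class PipelineError(RuntimeError):
    """Failure in one stage of the end-to-end analysis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class ArmAssignment:
    """Centroids per arm; the central marker participates in both fits."""

    longitudinal: list[MarkerCentroid]
    transverse: list[MarkerCentroid]
    center: MarkerCentroid

    def __post_init__(self) -> None:
        if len(self.longitudinal) < 2 or len(self.transverse) < 2:
            raise AssignmentError("each arm needs at least two points including the centre")
        lon_ids = {id(c) for c in self.longitudinal}
        tra_ids = {id(c) for c in self.transverse}
        if lon_ids & tra_ids != {id(self.center)}:
            raise AssignmentError("arm lists must be disjoint except for the shared centre")


def assign_arms(
    centroids: list[MarkerCentroid],
    jig: JigGeometry | None = None,
    key_markers_only: bool = False,
) -> ArmAssignment:
    """Split centroids into the two perpendicular arm pencils.

    The centre is the centroid nearest the marker-cloud mean; remaining
    markers are attributed by the angle of their coronal offset from the
    centre (within 40° of the vertical axis: longitudinal; within 40° of the
    horizontal axis: transverse; in between: ambiguous).  With
    ``key_markers_only`` only the centre and the two extreme markers of each
    pencil are kept, mirroring the five-marker analysis.
    """
    needed = 5 if key_markers_only else 3
    if len(centroids) < needed:
        raise AssignmentError(f"need at least {needed} centroids, got {len(centroids)}")

    xz = np.array([[c.x, c.z] for c in centroids])
    cloud = xz.mean(axis=0)
    ci = int(np.argmin(((xz - cloud) ** 2).sum(axis=1)))
    center = centroids[ci]

    longitudinal: list[MarkerCentroid] = [center]
    transverse: list[MarkerCentroid] = [center]
    for i, c in enumerate(centroids):
        if i == ci:
            continue
        dx = c.x - center.x
        dz = c.z - center.z
        ang = np.degrees(np.arctan2(abs(dx), abs(dz)))  # 0 = longitudinal axis
        if abs(ang - 45.0) < _AMBIGUITY_BAND_DEG:
            raise AssignmentError(
                f"centroid {c.id} at {ang:.1f}° from the longitudinal axis is ambiguous"
            )
        (longitudinal if ang < 45.0 else transverse).append(c)

    if len(longitudinal) < 2 or len(transverse) < 2:
        raise AssignmentError("missing end markers on one arm")

    if key_markers_only:
        lon_others = [c for c in longitudinal if c is not center]
        tra_others = [c for c in transverse if c is not center]
        lon_ext = [min(lon_others, key=lambda c: c.z), max(lon_others, key=lambda c: c.z)]
        tra_ext = [min(tra_others, key=lambda c: c.x), max(tra_others, key=lambda c: c.x)]
        if lon_ext[0] is lon_ext[1] or tra_ext[0] is tra_ext[1]:
            raise AssignmentError("missing end markers on one arm")
        longitudinal = [center] + lon_ext
        transverse = [center] + tra_ext

    return ArmAssignment(longitudinal=longitudinal, transverse=transverse, center=center)


def _tls_direction(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares line through 2-D points: (unit direction, RMS residual)."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    resid = float(np.sqrt(np.mean((centered @ vt[1]) ** 2))) if len(points) > 1 else 0.0
    if np.allclose(s, 0.0):
        raise AssignmentError("degenerate (coincident) points in line fit")
    return direction, resid


def _coronal(points: list[MarkerCentroid]) -> np.ndarray:
    # coronal display coordinates: (x, u) with u = -z, clockwise-positive
    return np.array([[c.x, -c.z] for c in points])


def fit_apparent_angles(
    assignment: ArmAssignment, with_details: bool = False
):
    """Fit each arm by total least squares and read off (phi, theta).

    ``phi`` is the signed clockwise angle of the longitudinal-arm line from
    the vertical coronal axis, ``theta`` that of the transverse-arm line
    from the horizontal axis.  With ``with_details`` also returns per-arm
    RMS residuals (mm) and the fitted unit directions.
    """
    d_lon, r_lon = _tls_direction(_coronal(assignment.longitudinal))
    d_tra, r_tra = _tls_direction(_coronal(assignment.transverse))
    if d_lon[1] < 0:
        d_lon = -d_lon
    if d_tra[0] < 0:
        d_tra = -d_tra
    phi = float(np.degrees(np.arctan2(d_lon[0], d_lon[1])))
    theta = float(np.degrees(np.arctan2(-d_tra[1], d_tra[0])))
    angles = ApparentAngles(phi=phi, theta=theta)
    if not with_details:
        return angles
    details = {
        "residual_mm": {"longitudinal": r_lon, "transverse": r_tra},
        "directions": {"longitudinal": d_lon, "transverse": d_tra},
    }
    return angles, details


def inter_arm_angle(assignment: ArmAssignment) -> float:
    """Acute angle (degrees) between the two fitted arm lines.

    Equals 90° for a perfectly aligned scan and 90° − |A| to first order
    under a couch-direction misalignment: the scan shear breaks the
    phantom's right angle on the coronal view.
    """
    d_lon, _ = _tls_direction(_coronal(assignment.longitudinal))
    d_tra, _ = _tls_direction(_coronal(assignment.transverse))
    dot = abs(float(np.dot(d_lon, d_tra)))
    return float(np.degrees(np.arccos(np.clip(dot, 0.0, 1.0))))


@dataclass(frozen=True)
class EstimationConfig:
    """Detection and estimation parameters of the analysis pipeline."""

    threshold_hu: float = 1500.0
    min_voxels: int = 1
    weight_floor: float | str | None = "auto"
    key_markers_only: bool = True
    inversion: str = "exact"  # "exact" | "first_order"
    tolerance_warn_deg: float = 0.3
    tolerance_fail_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.inversion not in ("exact", "first_order"):
            raise ValueError("inversion must be 'exact' or 'first_order'")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class OrientationReport:
    """End-to-end QA result for one scan."""

    mode: str
    apparent: ApparentAngles
    state_estimate: MisalignmentState
    residual_mm: dict
    n_markers_used: int
    inter_arm_angle_deg: float
    verdicts: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "phi_deg": self.apparent.phi,
            "theta_deg": self.apparent.theta,
            "A_deg": self.state_estimate.A,
            f"{self.state_estimate.secondary_name}_deg": self.state_estimate.secondary,
            "residual_mm": self.residual_mm,
            "n_markers": self.n_markers_used,
            "inter_arm_angle_deg": self.inter_arm_angle_deg,
            "verdicts": self.verdicts,
            "provenance": self.provenance,
        }
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        s = self.state_estimate
        lines = [
            f"mode                : {self.mode}",
            f"apparent phi        : {self.apparent.phi:+.3f} deg",
            f"apparent theta      : {self.apparent.theta:+.3f} deg",
            f"A  (couch vs plane) : {s.A:+.3f} deg  [{self.verdicts['A']}]",
        ]
        label = (
            "B  (tabletop)       " if self.mode == "table" else "C  (axial lasers)   "
        )
        lines.append(f"{label}: {s.secondary:+.3f} deg  [{self.verdicts[s.secondary_name]}]")
        lines.append(f"inter-arm angle     : {self.inter_arm_angle_deg:.3f} deg")
        lines.append(f"markers used        : {self.n_markers_used}")
        return "\n".join(lines)


def _verdict(value: float, cfg: EstimationConfig) -> str:
    if abs(value) <= cfg.tolerance_warn_deg:
        return "pass"
    if abs(value) <= cfg.tolerance_fail_deg:
        return "warn"
    return "fail"


def estimate_orientation(
    volume: CTVolume,
    mode: str,
    config: EstimationConfig | None = None,
    jig: JigGeometry | None = None,
) -> OrientationReport:
    """Run detect → assign → fit → invert on a volume; deterministic.

    Errors from individual stages propagate as :class:`PipelineError`
    tagged with the stage name.
    """
    cfg = config or EstimationConfig()
    if mode not in ("table", "laser"):
        raise PipelineError("input", f"unknown mode {mode!r}")

    try:
        centroids = detect_markers(
            volume,
            threshold_hu=cfg.threshold_hu,
            min_voxels=cfg.min_voxels,
            weight_floor=cfg.weight_floor,
        )
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise PipelineError("detection", str(e)) from e

    try:
        assignment = assign_arms(centroids, jig=jig, key_markers_only=cfg.key_markers_only)
    except Exception as e:
        raise PipelineError("assignment", str(e)) from e

    try:
        apparent, details = fit_apparent_angles(assignment, with_details=True)
        interarm = inter_arm_angle(assignment)
    except Exception as e:
        raise PipelineError("fit", str(e)) from e

    try:
        if cfg.inversion == "exact":
            state = geometry.invert_exact(apparent, mode)
        else:
            state = geometry.invert_first_order(apparent, mode)
    except Exception as e:
        raise PipelineError("inversion", str(e)) from e

    n_used = len(assignment.longitudinal) + len(assignment.transverse) - 1
    verdicts = {"A": _verdict(state.A, cfg), state.secondary_name: _verdict(state.secondary, cfg)}
    provenance = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "n_centroids_detected": len(centroids),
        "seed": volume.meta.get("seed"),
        "source": volume.meta.get("source"),
    }
    return OrientationReport(
        mode=mode,
        apparent=apparent,
        state_estimate=state,
        residual_mm=details["residual_mm"],
        n_markers_used=n_used,
        inter_arm_angle_deg=interarm,
        verdicts=verdicts,
        provenance=provenance,
    )


def subtract_baseline(
    report: OrientationReport, baseline: OrientationReport
) -> OrientationReport:
    """Subtract a baseline (inherent-deviation) estimate angle-wise.

    Both reports must share a mode.  The corrected report keeps the
    measured apparent angles; its state estimate and verdicts reflect the
    deviation beyond the scanner's inherent misalignment.
    """
    if report.mode != baseline.mode:
        raise ValueError(f"mode mismatch: {report.mode!r} vs {baseline.mode!r}")
    r, b = report.state_estimate, baseline.state_estimate
    kwargs = {r.secondary_name: r.secondary - b.secondary}
    corrected = MisalignmentState(report.mode, A=r.A - b.A, **kwargs)
    cfg = EstimationConfig(**report.provenance["config"]) if "config" in report.provenance else EstimationConfig()
    verdicts = {
        "A": _verdict(corrected.A, cfg),
        corrected.secondary_name: _verdict(corrected.secondary, cfg),
    }
    provenance = dict(report.provenance)
    provenance["baseline"] = baseline.state_estimate.as_dict()
    return replace(
        report, state_estimate=corrected, verdicts=verdicts, provenance=provenance
    )
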