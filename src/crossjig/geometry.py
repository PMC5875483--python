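"""Angular model of CT-simulator misalignments measured with a cross phantom.

A CT simulation system has four components whose horizontal orientations must
agree: the flat tabletop, the couch longitudinal travel direction, the imaging
(axial) plane, and the external axial lasers.  Three signed angles, in
degrees, describe the possible disagreements:

``A``
    couch travel direction vs. the imaging-plane normal;
``B``
    tabletop longitudinal axis vs. couch travel direction (probed by clamping
    the cross phantom to the tabletop — *table* mode);
``C``
    plane of the external axial lasers vs. the imaging plane (probed by
    aligning the phantom's transverse arm with the lasers — *laser* mode).

All three are positive clockwise in the bird's-eye view of the scanner room.
On the reconstructed coronal view of an axial scan, the phantom's two arms
appear at apparent angles ``phi`` (longitudinal arm vs. the vertical image
axis) and ``theta`` (transverse arm vs. the horizontal image axis), positive
clockwise in that view.  To first order in the angles::

    table mode:  phi = B        theta = A + B
    laser mode:  phi = C - A    theta = C

so in both modes ``A = theta - phi``.  The exact relations follow from the
plane-crossing construction of the scan: writing ``gamma`` for the angle of
the longitudinal arm to the imaging-plane normal (``A + B`` in table mode,
``C`` in laser mode),

    tan(phi)   = sin(gamma - A) / cos(gamma)
    tan(theta) = sin(gamma)     / cos(gamma - A)

which reduces to the linear form as the angles go to zero.  This module
provides both forward maps and both inversions; every public interface is in
degrees, internals are in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MisalignmentState",
    "ApparentAngles",
    "InversionError",
    "VALIDITY_LIMIT_DEG",
    "apparent_angles_first_order",
    "apparent_angles_exact",
    "invert_first_order",
    "invert_exact",
]

#: The small-misalignment model is only claimed for angles strictly inside
#: this bound; larger angles are rejected at construction.
VALIDITY_LIMIT_DEG = 45.0

_MODES = ("table", "laser")


class InversionError(RuntimeError):
    """Raised when the exact numeric inversion fails to converge."""


def _check_angle(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or abs(value) >= VALIDITY_LIMIT_DEG:
        raise ValueError(
            f"|{name}| must be finite and < {VALIDITY_LIMIT_DEG}°, got {value!r}"
        )
    return value


@dataclass(frozen=True)
class MisalignmentState:
    """Ground-truth or estimated misalignment angles of one alignment mode.

    Exactly one of ``B`` (table mode) or ``C`` (laser mode) is present,
    matching ``mode``.  Angles are signed degrees, clockwise-positive in the
    bird's-eye view.
    """

    mode: str
    A: float
    B: float | None = None
    C: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        object.__setattr__(self, "A", _check_angle("A", self.A))
        if self.mode == "table":
            if self.B is None or self.C is not None:
                raise ValueError("table mode requires B and forbids C")
            object.__setattr__(self, "B", _check_angle("B", self.B))
        else:
            if self.C is None or self.B is not None:
                raise ValueError("laser mode requires C and forbids B")
            object.__setattr__(self, "C", _check_angle("C", self.C))

    @property
    def secondary(self) -> float:
        """The mode-specific angle: B in table mode, C in laser mode."""
        return self.B if self.mode == "table" else self.C  # type: ignore[return-value]

    @property
    def secondary_name(self) -> str:
        return "B" if self.mode == "table" else "C"

    @property
    def gamma_deg(self) -> float:
        """Angle of the jig longitudinal arm to the imaging-plane normal.

        ``gamma = A + B`` when the jig is clamped to the tabletop and
        ``gamma = C`` when its transverse arm is aligned to the lasers (the
        laser plane fixes the arm in the room, independent of the couch).
        """
        if self.mode == "table":
            return self.A + self.B  # type: ignore[operator]
        return self.C  # type: ignore[return-value]

    def negated(self) -> "MisalignmentState":
        if self.mode == "table":
            return MisalignmentState("table", -self.A, B=-self.B)
        return MisalignmentState("laser", -self.A, C=-self.C)

    def as_dict(self) -> dict:
        d = {"mode": self.mode, "A_deg": self.A}
        d[f"{self.secondary_name}_deg"] = self.secondary
        return d


@dataclass(frozen=True)
class ApparentAngles:
    """Arm angles measured on the coronal view, clockwise-positive.

    ``phi``: longitudinal arm vs. the vertical image axis.
    ``theta``: transverse arm vs. the horizontal image axis.
    """

    phi: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", _check_angle("phi", self.phi))
        object.__setattr__(self, "theta", _check_angle("theta", self.theta))

    def negated(self) -> "ApparentAngles":
        return ApparentAngles(-self.phi, -self.theta)


def apparent_angles_first_order(state: MisalignmentState) -> ApparentAngles:
    """First-order (linearized) forward map from misalignments to (phi, theta)."""
    if state.mode == "table":
        return ApparentAngles(phi=state.B, theta=state.A + state.B)
    return ApparentAngles(phi=state.C - state.A, theta=state.C)


def apparent_angles_exact(state: MisalignmentState) -> ApparentAngles:
    """Exact trigonometric forward map from misalignments to (phi, theta).

    A point rigidly carried along the couch direction crosses the imaging
    plane sheared by ``tan A`` in-plane and stretched by ``1 / cos A``
    longitudinally; applying that map to the two arm directions gives

        tan(phi)   = sin(gamma - A) / cos(gamma)
        tan(theta) = sin(gamma)     / cos(gamma - A)

    with ``gamma`` as defined on :class:`MisalignmentState`.
    """
    a = math.radians(state.A)
    g = math.radians(state.gamma_deg)
    if abs(g) >= math.pi / 2 or abs(g - a) >= math.pi / 2:
        raise ValueError("state outside exact-model validity (|gamma|, |gamma-A| < 90°)")
    phi = math.atan2(math.sin(g - a), math.cos(g))
    theta = math.atan2(math.sin(g), math.cos(g - a))
    return ApparentAngles(math.degrees(phi), math.degrees(theta))


def invert_first_order(apparent: ApparentAngles, mode: str) -> MisalignmentState:
    """Invert the linearized forward map.  In both modes ``A = theta - phi``."""
    if mode == "table":
        return MisalignmentState("table", A=apparent.theta - apparent.phi, B=apparent.phi)
    if mode == "laser":
        return MisalignmentState("laser", A=apparent.theta - apparent.phi, C=apparent.theta)
    raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def invert_exact(
    apparent: ApparentAngles,
    mode: str,
    *,
    tol_rad: float = 1e-10,
    max_iter: int = 50,
) -> MisalignmentState:
    """Invert the exact forward map by Newton iteration on (A, gamma).

    Seeded from :func:`invert_first_order`; converges in a handful of steps
    for any apparent angles inside the validity region and round-trips
    :func:`apparent_angles_exact` to better than 1e-8 degrees.
    """
    seed = invert_first_order(apparent, mode)
    a = math.radians(seed.A)
    g = math.radians(seed.gamma_deg)
    t_phi = math.tan(math.radians(apparent.phi))
    t_theta = math.tan(math.radians(apparent.theta))

    for _ in range(max_iter):
        f1 = math.sin(g - a) - t_phi * math.cos(g)
        f2 = math.sin(g) - t_theta * math.cos(g - a)
        j11 = -math.cos(g - a)                       # df1/dA
        j12 = math.cos(g - a) + t_phi * math.sin(g)  # df1/dgamma
        j21 = -t_theta * math.sin(g - a)             # df2/dA
        j22 = math.cos(g) + t_theta * math.sin(g - a)  # df2/dgamma
        det = j11 * j22 - j12 * j21
        if det == 0.0:
            raise InversionError("singular Jacobian in exact inversion")
        da = (f1 * j22 - f2 * j12) / det
        dg = (j11 * f2 - j21 * f1) / det
        a -= da
        g -= dg
        if max(abs(da), abs(dg)) < tol_rad:
            break
    else:
        raise InversionError(f"exact inversion did not converge in {max_iter} iterations")

    a_deg = math.degrees(a)
    g_deg = math.degrees(g)
    if mode == "table":
        return MisalignmentState("table", A=a_deg, B=g_deg - a_deg)
    return MisalignmentState("laser", A=a_deg, C=g_deg)
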