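"""Geometry of the cross phantom and its placement in the scanner room.

The phantom is two perpendicular aluminum arms with small radio-opaque
spheres embedded along each: 23 along the longitudinal arm (including the
shared central marker) and 11 along the transverse arm.  Only five markers —
the centre plus the four arm ends, 200 mm out — enter the orientation
analysis; the rest serve distance/scaling checks and are carried here so
simulated scans look like the real phantom.

Lab frame (right-handed): X = image horizontal, Y = vertical (height above
isocenter), Z = imaging-plane normal / nominal couch travel.  All
misalignments are rotations about Y; the jig lies in a horizontal plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import MisalignmentState

__all__ = [
    "MarkerSite",
    "JigGeometry",
    "default_jig",
    "marker_lab_positions",
    "arm_directions",
]

CENTER_ID = "C"


@dataclass(frozen=True)
class MarkerSite:
    """One marker: which arm it sits on and its signed offset along it (mm)."""

    id: str
    arm: str  # "longitudinal" | "transverse" | "center"
    offset: float


@dataclass(frozen=True)
class JigGeometry:
    """Marker layout of the cross phantom (all lengths in mm).

    ``longitudinal_marker_offsets`` includes 0 (the central marker belongs to
    the longitudinal list); ``transverse_marker_offsets`` excludes 0.  End
    markers at ±``arm_half_length`` must be present on both arms.
    """

    arm_half_length: float = 200.0
    marker_diameter: float = 1.5
    longitudinal_marker_offsets: tuple[float, ...] = ()
    transverse_marker_offsets: tuple[float, ...] = ()
    key_marker_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.arm_half_length <= 0 or self.marker_diameter <= 0:
            raise ValueError("arm_half_length and marker_diameter must be positive")
        lon = tuple(float(v) for v in self.longitudinal_marker_offsets)
        tra = tuple(float(v) for v in self.transverse_marker_offsets)
        h = self.arm_half_length
        for name, offs in (("longitudinal", lon), ("transverse", tra)):
            if any(abs(o) > h + 1e-9 for o in offs):
                raise ValueError(f"{name} offsets must lie within ±arm_half_length")
            if len(set(offs)) != len(offs):
                raise ValueError(f"duplicate {name} marker offsets")
            if offs and not ({-h, h} <= set(offs)):
                raise ValueError(f"{name} arm must carry end markers at ±{h} mm")
        if lon and 0.0 not in lon:
            raise ValueError("central marker (offset 0) belongs to the longitudinal list")
        if 0.0 in tra:
            raise ValueError("transverse offsets exclude 0 (centre is on the longitudinal list)")
        object.__setattr__(self, "longitudinal_marker_offsets", lon)
        object.__setattr__(self, "transverse_marker_offsets", tra)
        if not self.key_marker_ids:
            object.__setattr__(
                self,
                "key_marker_ids",
                (CENTER_ID, f"L{-h:+g}", f"L{h:+g}", f"T{-h:+g}", f"T{h:+g}"),
            )

    @property
    def marker_sites(self) -> list[MarkerSite]:
        sites = []
        for o in self.longitudinal_marker_offsets:
            if o == 0.0:
                sites.append(MarkerSite(CENTER_ID, "center", 0.0))
            else:
                sites.append(MarkerSite(f"L{o:+g}", "longitudinal", o))
        for o in self.transverse_marker_offsets:
            sites.append(MarkerSite(f"T{o:+g}", "transverse", o))
        return sites

    @property
    def n_markers(self) -> int:
        return len(self.longitudinal_marker_offsets) + len(self.transverse_marker_offsets)

    # -- plain-config round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "arm_half_length": self.arm_half_length,
            "marker_diameter": self.marker_diameter,
            "longitudinal_marker_offsets": list(self.longitudinal_marker_offsets),
            "transverse_marker_offsets": list(self.transverse_marker_offsets),
            "key_marker_ids": list(self.key_marker_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JigGeometry":
        return cls(
            arm_half_length=d.get("arm_half_length", 200.0),
            marker_diameter=d.get("marker_diameter", 1.5),
            longitudinal_marker_offsets=tuple(d["longitudinal_marker_offsets"]),
            transverse_marker_offsets=tuple(d["transverse_marker_offsets"]),
            key_marker_ids=tuple(d.get("key_marker_ids", ())),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "JigGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_jig() -> JigGeometry:
    """The default cross phantom: 23 + 11 markers, ends 200 mm from centre.

    Longitudinal markers are evenly spaced over ±200 mm (23 points including
    the centre).  Only the five key markers matter to the orientation math;
    the intermediate layout is nominal.  The transverse arm carries the ten
    multiples of 40 mm plus one marker at +20 mm to reach its eleven
    (non-central) markers.
    """
    lon = tuple(np.round(np.linspace(-200.0, 200.0, 23), 6))
    tra = tuple(float(40 * k) for k in range(-5, 0)) + (20.0,) + tuple(
        float(40 * k) for k in range(1, 6)
    )
    return JigGeometry(
        arm_half_length=200.0,
        marker_diameter=1.5,
        longitudinal_marker_offsets=lon,
        transverse_marker_offsets=tra,
    )


def arm_directions(state: MisalignmentState) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors of the two arms in the lab frame for a given placement.

    The longitudinal arm makes the clockwise (bird's-eye) angle ``gamma``
    with the imaging-plane normal Z; the transverse arm is perpendicular to
    it in the horizontal plane.
    """
    g = math.radians(state.gamma_deg)
    d_long = np.array([math.sin(g), 0.0, math.cos(g)])
    d_trans = np.array([math.cos(g), 0.0, -math.sin(g)])
    return d_long, d_trans


def marker_lab_positions(
    jig: JigGeometry,
    state: MisalignmentState,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[tuple[MarkerSite, np.ndarray]]:
    """Rigid-body marker positions (mm) in the lab frame.

    All markers share one horizontal plane (constant Y = ``center[1]``); the
    jig centre sits at ``center``.
    """
    d_long, d_trans = arm_directions(state)
    c = np.asarray(center, dtype=float)
    out = []
    for site in jig.marker_sites:
        d = d_trans if site.arm == "transverse" else d_long
        out.append((site, c + site.offset * d))
    return out
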