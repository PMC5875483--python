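"""Synthetic axial CT acquisition of the cross phantom.

The couch carries the phantom along a direction that may be tilted by ``A``
from the imaging-plane normal.  Each lab point therefore crosses the fixed
imaging plane at a couch displacement of its own, producing the
characteristic coronal shear/scale distortion: the recorded volume position
of a lab point ``p`` is

    ( p_x - p_z * tan A,  p_y,  s0 - p_z / cos A )

with ``s0`` a longitudinal offset placing the phantom inside the scanned
range.  The map is affine, so spheres and boxes render exactly by
inverse-mapping (super-sampled) voxel positions into the lab frame.

Markers render with partial-volume fractions; arms render as solid boxes at
a nominal aluminum-like HU; optional additive Gaussian noise is seeded and
recorded in the volume metadata, so a fixed seed reproduces the volume
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import MisalignmentState
from .jig import JigGeometry, arm_directions, marker_lab_positions
from .volume import CTVolume

__all__ = ["ScanParams", "scan_point", "simulate_scan", "make_battery"]


@dataclass(frozen=True)
class ScanParams:
    """Acquisition and rendering parameters.

    Defaults follow a routine axial protocol: 50 cm field of view, 512
    matrix, 1.25 mm slice thickness with equal increment.  The HU palette is
    synthetic: arms at +800 stay below the +1500 detection threshold while
    markers at +20000 survive partial-volume dilution of a 1.5 mm sphere on
    this grid (see the package methods note).
    """

    fov: float = 500.0
    matrix: int = 512
    slice_thickness: float = 1.25
    background_hu: float = -1000.0
    arm_hu: float = 800.0
    marker_hu: float = 20000.0
    noise_sigma: float = 0.0
    seed: int = 0
    supersampling: int = 6
    arm_width: float = 25.0
    arm_thickness: float = 6.0
    arm_overhang: float = 5.0
    longitudinal_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if self.matrix < 64:
            raise ValueError("matrix must be >= 64")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        if self.fov <= 0:
            raise ValueError("fov must be > 0")

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix


def scan_point(p, A_deg: float, s0: float = 0.0) -> np.ndarray:
    """Volume position (mm) at which a rigidly translated lab point is recorded.

    The point is carried along the couch direction ``u = (sin A, 0, cos A)``
    and crosses the imaging plane ``Z = 0`` at couch displacement
    ``-p_z / cos A``.  Affine in ``p``; vectorized over leading axes.
    """
    p = np.asarray(p, dtype=float)
    a = math.radians(A_deg)
    if abs(A_deg) >= 45.0:
        raise ValueError("|A| must be < 45°")
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] - p[..., 2] * math.tan(a)
    out[..., 1] = p[..., 1]
    out[..., 2] = s0 - p[..., 2] / math.cos(a)
    return out


def _inverse_scan_xz(xv, zv, A_rad: float, s0: float):
    """Lab (x, z) of the material recorded at volume (x, z)."""
    pz = (s0 - zv) * math.cos(A_rad)
    px = xv + (s0 - zv) * math.sin(A_rad)
    return px, pz


def simulate_scan(
    jig: JigGeometry,
    state: MisalignmentState,
    params: ScanParams | None = None,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> CTVolume:
    """Render an axial scan of the phantom under a misalignment state.

    Markers are spheres rendered with partial-volume fractions obtained by
    ``supersampling``^3 sub-voxel sampling through the inverse scan map;
    arms are boxes rendered by voxel-centre membership.  Raises if the
    phantom extends beyond the field of view.
    """
    params = params or ScanParams()
    a = math.radians(state.A)
    cos_a = math.cos(a)
    markers = marker_lab_positions(jig, state, center)
    d_long, d_trans = arm_directions(state)
    c = np.asarray(center, dtype=float)
    half = jig.arm_half_length + params.arm_overhang

    # Longitudinal coverage: place s0 so every structure point maps inside
    # [margin, nz*dz - margin].
    struct = np.array(
        [p for _, p in markers]
        + [c + s * half * d for d in (d_long, d_trans) for s in (-1.0, 1.0)]
    )
    pz_min, pz_max = struct[:, 2].min(), struct[:, 2].max()
    margin = params.longitudinal_margin
    dz = params.slice_thickness
    nz = int(math.ceil(((pz_max - pz_min) / cos_a + 2 * margin) / dz))
    s0 = margin + pz_max / cos_a

    mapped = scan_point(struct, state.A, s0)
    if np.abs(mapped[:, 0]).max() > params.fov / 2 - params.pixel_spacing:
        raise ValueError("phantom extent exceeds the field of view")

    n = params.matrix
    dxy = params.pixel_spacing
    x0 = -params.fov / 2 + dxy / 2
    xc = x0 + np.arange(n) * dxy
    yc = x0 + np.arange(n) * dxy
    zc = dz / 2 + np.arange(nz) * dz

    vol = np.full((n, n, nz), params.background_hu, dtype=np.float32)

    # -- arms: voxel-centre membership within the horizontal slab they occupy
    px, pz = _inverse_scan_xz(xc[:, None], zc[None, :], a, s0)
    qx = px - c[0]
    qz = pz - c[2]
    u = qx * d_long[0] + qz * d_long[2]   # along the longitudinal arm
    v = qx * d_trans[0] + qz * d_trans[2]  # along the transverse arm
    member = ((np.abs(u) <= half) & (np.abs(v) <= params.arm_width / 2)) | (
        (np.abs(v) <= half) & (np.abs(u) <= params.arm_width / 2)
    )
    slab_rows = np.nonzero(np.abs(yc - c[1]) <= params.arm_thickness / 2)[0]
    for iy in slab_rows:
        plane = vol[:, iy, :]
        plane[member] = params.arm_hu

    # -- markers: super-sampled partial volume through the inverse map
    r = jig.marker_diameter / 2
    ss = params.supersampling
    sub = ((np.arange(ss) + 0.5) / ss - 0.5)
    pad_xz = r / cos_a + abs(math.tan(a)) * r + 1e-9
    for site, m in markers:
        mv = scan_point(m, state.A, s0)
        ix0 = max(int(np.floor((mv[0] - pad_xz - x0) / dxy)), 0)
        ix1 = min(int(np.ceil((mv[0] + pad_xz - x0) / dxy)) + 1, n)
        iy0 = max(int(np.floor((m[1] - r - x0) / dxy)), 0)
        iy1 = min(int(np.ceil((m[1] + r - x0) / dxy)) + 1, n)
        iz0 = max(int(np.floor((mv[2] - pad_xz - dz / 2) / dz)), 0)
        iz1 = min(int(np.ceil((mv[2] + pad_xz - dz / 2) / dz)) + 1, nz)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        sx = (xc[ix0:ix1, None] + sub[None, :] * dxy).ravel()
        sy = (yc[iy0:iy1, None] + sub[None, :] * dxy).ravel()
        sz = (zc[iz0:iz1, None] + sub[None, :] * dz).ravel()
        lz = (s0 - sz) * cos_a
        lx = sx[:, None] + (s0 - sz)[None, :] * math.sin(a)
        d2 = (
            (lx - m[0])[:, None, :] ** 2
            + ((sy - m[1]) ** 2)[None, :, None]
            + (((lz - m[2]) ** 2))[None, None, :]
        )
        inside = d2 <= r * r
        frac = (
            inside.reshape(ix1 - ix0, ss, iy1 - iy0, ss, iz1 - iz0, ss)
            .mean(axis=(1, 3, 5))
            .astype(np.float32)
        )
        box = vol[ix0:ix1, iy0:iy1, iz0:iz1]
        box += frac * (params.marker_hu - box)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        vol += params.noise_sigma * rng.standard_normal(vol.shape, dtype=np.float32)
        np.clip(vol, -1024.0, None, out=vol)

    meta = {
        "params": asdict(params),
        "seed": params.seed,
        "noise_sigma": params.noise_sigma,
        "s0": s0,
        "jig_center": list(center),
        "truth": state.as_dict(),
    }
    return CTVolume(vol, spacing=(dxy, dxy, dz), origin=(x0, x0, dz / 2), meta=meta)


def make_battery(
    magnitude: float,
    modes: tuple[str, ...] = ("table", "laser"),
) -> list[tuple[str, MisalignmentState]]:
    """The known-error validation scenarios at one misalignment magnitude.

    Per mode, eight scenarios: the secondary angle alone at ±magnitude, A
    alone at ±magnitude, and the four combinations A = ±magnitude with the
    secondary at ±magnitude.  Both modes give the full sixteen.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    m = float(magnitude)
    combos = [
        (0.0, +m), (0.0, -m),        # secondary alone (step 1)
        (+m, 0.0), (-m, 0.0),        # couch direction alone (step 2)
        (+m, +m), (+m, -m),          # combined, A clockwise (step 3)
        (-m, +m), (-m, -m),          # combined, A counterclockwise (step 4)
    ]
    battery = []
    for mode in modes:
        sec = "B" if mode == "table" else "C"
        for a_val, s_val in combos:
            kwargs = {sec: s_val}
            state = MisalignmentState(mode, A=a_val, **kwargs)
            battery.append((f"{mode}-A{a_val:+g}{sec}{s_val:+g}", state))
    return battery
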