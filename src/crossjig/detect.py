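"""Fiducial marker detection by thresholding and intensity-weighted centroids.

Voxels at or above a preset HU threshold are grouped by 26-connectivity
across slices; each component yields a sub-voxel centroid as the
intensity-weighted mean of voxel-centre positions.  Weights are
``max(HU - floor, 0)`` taken over the component dilated by one voxel: the
dilation recovers the partial-volume tails of a small sphere, and a floor
at the local base HU makes the weight of a marker exactly proportional to
its in-voxel volume fraction whether it sits in air or embedded in denser
material.  By default the floor is estimated per component as the median
HU of a one-voxel shell around the dilated component (``weight_floor=
"auto"``); a fixed floor may be passed instead, and ``weight_floor=None``
falls back to weighting by ``max(HU - threshold, 0)`` on the raw
component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "MarkerCentroid",
    "DetectionError",
    "detect_markers",
    "centroids_to_dataframe",
    "centroid_uncertainty_bound",
]


class DetectionError(RuntimeError):
    """No components found (wrong threshold or empty scan)."""


@dataclass(frozen=True, eq=False)  # identity semantics: position is an array
class MarkerCentroid:
    """One detected marker: sub-voxel position and component statistics."""

    id: int
    position: np.ndarray  # (x, y, z) mm
    total_weight: float
    n_voxels: int
    extent_mm: tuple[float, float, float]
    on_boundary: bool

    @property
    def x(self) -> float:
        return float(self.position[0])

    @property
    def y(self) -> float:
        return float(self.position[1])

    @property
    def z(self) -> float:
        return float(self.position[2])


def detect_markers(
    volume: CTVolume,
    threshold_hu: float = 1500.0,
    min_voxels: int = 1,
    weight_floor: float | str | None = "auto",
) -> list[MarkerCentroid]:
    """Locate all supra-threshold components and their weighted centroids.

    Components with fewer than ``min_voxels`` voxels are discarded;
    components touching the volume boundary are kept but flagged.  Results
    are sorted by longitudinal, then horizontal position.  Raises
    :class:`DetectionError` when nothing exceeds the threshold.
    """
    vox = volume.voxels
    mask = vox >= threshold_hu
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n_comp == 0:
        raise DetectionError(f"no components above {threshold_hu} HU")

    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    shape = np.asarray(vox.shape)
    objects = ndimage.find_objects(labels)

    out = []
    for comp_id, sl in enumerate(objects, start=1):
        comp = labels[sl] == comp_id
        n_vox = int(comp.sum())
        if n_vox < min_voxels:
            continue

        lo = np.array([s.start for s in sl])
        hi = np.array([s.stop for s in sl])
        if weight_floor is None:
            region_slices = sl
            region = comp
            floor = threshold_hu
            region_lo = lo
        else:
            # grow the bounding box by two voxels: one for the dilated
            # weighting region, one more for the local-base shell
            region_lo = np.maximum(lo - 2, 0)
            region_hi = np.minimum(hi + 2, shape)
            region_slices = tuple(slice(a, b) for a, b in zip(region_lo, region_hi))
            padded = np.zeros(tuple(region_hi - region_lo), dtype=bool)
            inner = tuple(slice(a - b, a - b + c.stop - c.start) for a, b, c in zip(lo, region_lo, sl))
            padded[inner] = comp
            struct = np.ones((3, 3, 3), dtype=bool)
            region = ndimage.binary_dilation(padded, structure=struct)
            if weight_floor == "auto":
                shell = ndimage.binary_dilation(region, structure=struct) & ~region
                floor = float(np.median(vox[region_slices][shell])) if shell.any() else threshold_hu
            else:
                floor = float(weight_floor)

        hu = vox[region_slices].astype(np.float64)
        w = np.clip(hu - floor, 0.0, None)
        w[~region] = 0.0
        total = float(w.sum())
        if total <= 0.0:
            continue
        idx = np.indices(w.shape, dtype=np.float64)
        centroid_idx = np.array([(idx[d] * w).sum() / total for d in range(3)]) + region_lo
        pos = origin + centroid_idx * spacing

        out.append(
            MarkerCentroid(
                id=0,  # reassigned after sorting
                position=pos,
                total_weight=total * float(np.prod(spacing)),
                n_voxels=n_vox,
                extent_mm=tuple((hi - lo) * spacing),
                on_boundary=bool(np.any(lo == 0) or np.any(hi == shape)),
            )
        )

    if not out:
        raise DetectionError(f"no components with >= {min_voxels} voxels above {threshold_hu} HU")

    out.sort(key=lambda c: (c.z, c.x))
    return [
        MarkerCentroid(i, c.position, c.total_weight, c.n_voxels, c.extent_mm, c.on_boundary)
        for i, c in enumerate(out)
    ]


def centroids_to_dataframe(centroids: list[MarkerCentroid]) -> pd.DataFrame:
    """Centroid table (id, x, y, z, weight, voxels, boundary flag)."""
    return pd.DataFrame(
        {
            "id": [c.id for c in centroids],
            "x_mm": [c.x for c in centroids],
            "y_mm": [c.y for c in centroids],
            "z_mm": [c.z for c in centroids],
            "weight": [c.total_weight for c in centroids],
            "voxels": [c.n_voxels for c in centroids],
            "on_boundary": [c.on_boundary for c in centroids],
        }
    )


def centroid_uncertainty_bound(
    slice_thickness: float, marker_diameter: float, lever: float
) -> float:
    """Worst-case angular error (degrees) from finite slice thickness.

    When the slice thickness exceeds the marker diameter, a marker can sit
    anywhere within the uncovered gap without changing which slice records
    it, so its longitudinal coordinate carries a worst-case error of
    ``slice_thickness - marker_diameter`` (clamped at zero).  Over a marker
    pair separated by ``lever`` mm this bounds the measured arm angle by
    ``atan(error / lever)``; e.g. 2.5 mm slices with 1.5 mm markers and the
    400 mm end-to-end lever give about 0.14°.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if lever <= 0:
        raise ValueError("lever must be > 0")
    err = max(slice_thickness - marker_diameter, 0.0)
    return math.degrees(math.atan(err / lever))
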