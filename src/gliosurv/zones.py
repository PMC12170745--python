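"""Tumor-related volumetric zones from a segmentation mask.

Four zones are derived from the tumor segmentation by anisotropic Euclidean
distance to the tumor boundary, all clipped to the brain mask:

* ``tumor``      — the segmentation itself;
* ``band_pm5``   — the band straddling the tumor edge, −5 mm to +5 mm;
* ``ptz_0_10``   — the peritumoral zone 0–10 mm outside the tumor;
* ``ptz_10_20``  — the peritumoral zone 10–20 mm outside the tumor.

Distances are center-to-center voxel distances in millimetres (no sub-voxel
surface model): a background voxel carries +d to the nearest tumor voxel,
a tumor voxel carries −d to the nearest background voxel.  The outside
bands are half-open ``(inner, outer]`` so that ptz_0_10 and ptz_10_20
partition ``{0 < d <= 20}`` with no double counting; the straddling band is
closed, ``[-5, +5]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


#: canonical zone inventory, in pipeline order
ZONE_NAMES = ("tumor", "band_pm5", "ptz_0_10", "ptz_10_20")


@dataclass(frozen=True)
class ZoneSpec:
    """A named distance band around the tumor edge.

    ``inner_mm``/``outer_mm`` are ignored for the ``tumor`` zone.  For
    ``band_pm5`` the band is closed on both sides; for the outside zones it
    is half-open ``(inner, outer]``.
    """

    name: str
    inner_mm: float = 0.0
    outer_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.name != "tumor" and not self.inner_mm < self.outer_mm:
            raise ValueError(
                f"zone {self.name!r}: inner_mm ({self.inner_mm}) must be < "
                f"outer_mm ({self.outer_mm})"
            )


#: default band parameters for the four study zones
DEFAULT_ZONES = {
    "tumor": ZoneSpec("tumor"),
    "band_pm5": ZoneSpec("band_pm5", -5.0, 5.0),
    "ptz_0_10": ZoneSpec("ptz_0_10", 0.0, 10.0),
    "ptz_10_20": ZoneSpec("ptz_10_20", 10.0, 20.0),
}


def distance_map(mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Signed anisotropic Euclidean distance (mm) to the mask boundary.

    Background voxels get +(distance to the nearest mask voxel); mask
    voxels get −(distance to the nearest background voxel).  Distances are
    voxel-center to voxel-center.

    Raises
    ------
    ValueError
        If the mask is empty or covers the whole grid (no boundary exists).
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    if not mask.any():
        raise ValueError("distance_map: mask is empty")
    if mask.all():
        raise ValueError("distance_map: mask covers the entire grid")
    # distance_transform_edt measures, at each nonzero voxel, the distance
    # to the nearest zero voxel.
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return np.where(mask, -inside, outside)


def extract_zone(
    tumor: np.ndarray,
    brain: np.ndarray,
    spec: ZoneSpec,
    spacing_mm=(1.0, 1.0, 1.0),
    dmap: np.ndarray | None = None,
) -> np.ndarray:
    """Extract one volumetric zone, clipped to the brain mask.

    Parameters
    ----------
    tumor, brain
        Binary masks on the same grid; ``tumor`` must be contained in
        ``brain``.
    spec
        Band definition.  ``tumor`` returns the segmentation unchanged.
    spacing_mm
        Voxel spacing; ignored when a precomputed ``dmap`` is given.
    dmap
        Optional precomputed output of :func:`distance_map` for ``tumor``
        (lets callers share one transform across the three bands).

    Returns
    -------
    Binary mask of the zone.  An empty result is returned as an all-False
    mask (callers flag it; downstream feature rows become missing).
    """
    tumor = np.asarray(tumor, dtype=bool)
    brain = np.asarray(brain, dtype=bool)
    if tumor.shape != brain.shape:
        raise ValueError("tumor and brain masks must share a grid")
    if (tumor & ~brain).any():
        raise ValueError("tumor mask extends outside the brain mask")
    if spec.name == "tumor":
        return tumor.copy()
    if dmap is None:
        dmap = distance_map(tumor, spacing_mm)
    if spec.name == "band_pm5":
        zone = (dmap >= spec.inner_mm) & (dmap <= spec.outer_mm)
    else:
        zone = (dmap > spec.inner_mm) & (dmap <= spec.outer_mm)
    # everything outside the tumor is clipped to brain; the intratumoral
    # part of band_pm5 is inside the brain by the containment precondition
    zone &= brain
    return zone


def extract_all_zones(tumor, brain, spacing_mm, specs=None) -> dict[str, np.ndarray]:
    """All four study zones from one shared distance transform."""
    specs = specs or DEFAULT_ZONES
    dmap = distance_map(tumor, spacing_mm)
    return {
        name: extract_zone(tumor, brain, spec, spacing_mm, dmap=dmap)
        for name, spec in specs.items()
    }
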