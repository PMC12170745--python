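"""Shape, first-order and gray-level run-length (GLRLM) radiomics features.

Features are computed per (zone, sequence) on unfiltered images, from
explicit IBSI-style definitions:

* **shape** (9): voxel-count volume, face-count surface area, sphericity,
  surface-to-volume ratio, equivalent sphere diameter, maximum 3D diameter
  (Feret, over voxel centers), and maximum in-plane 2D diameter for the
  axial / coronal / sagittal planes.
* **first-order** (16): moments, order statistics, energy, and histogram
  entropy/uniformity on the discretized ROI.
* **GLRLM** (16): the IBSI run-length set computed per each of the 13
  unique 3D directions and averaged with equal weight.

Gray levels are discretized with a fixed bin *count* over the ROI
intensity range (top bin inclusive); the bin count is the only
discretization parameter and is carried by :class:`DiscretizationSpec`.

Array axis convention: axis 0 = sagittal (x), axis 1 = coronal (y),
axis 2 = axial (z); an "axial" 2D diameter is measured within slices of
constant z, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

SEQUENCES = ("t1c", "flair")

#: the 13 unique 3D directions (one representative per +/- pair)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

SHAPE_FEATURES = (
    "volume_ml",
    "surface_area_mm2",
    "sphericity",
    "surface_volume_ratio",
    "equivalent_diameter_mm",
    "max_3d_diameter_mm",
    "max_2d_diameter_axial_mm",
    "max_2d_diameter_coronal_mm",
    "max_2d_diameter_sagittal_mm",
)

FIRST_ORDER_FEATURES = (
    "mean",
    "median",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "rms",
    "minimum",
    "maximum",
    "range",
    "iqr",
    "mad",
    "p10",
    "p90",
    "entropy",
    "uniformity",
)

GLRLM_FEATURES = (
    "sre",
    "lre",
    "gln",
    "glnn",
    "rln",
    "rlnn",
    "rp",
    "glv",
    "rlv",
    "re",
    "lglre",
    "hglre",
    "srlgle",
    "srhgle",
    "lrlgle",
    "lrhgle",
)


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-count discretization over the ROI intensity range."""

    n_bins: int = 32

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Diameter of a point cloud; convex-hull accelerated, brute-force
    equivalent (hull vertices realize the max pairwise distance)."""
    if len(points) < 2:
        return 0.0
    if len(points) > 32:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (flat/collinear) cloud: fall through to brute force
    return float(pdist(points).max())


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one exposed face (6-neighborhood)."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(mask)
    for ax in range(3):
        for shift in (-1, 1):
            sl = [slice(1, -1)] * 3
            sl[ax] = slice(1 + shift, padded.shape[ax] - 1 + shift)
            interior &= padded[tuple(sl)]
    return mask & ~interior


def shape_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """IBSI-style 3D shape descriptors of a binary mask.

    Volume is the voxel count times the voxel volume (reported in ml);
    surface area counts exposed voxel faces, which overestimates a smooth
    surface and is consumed only by sphericity and the surface/volume
    ratio.  Diameters are maximum voxel-center pairwise distances.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    if not mask.any():
        raise ValueError("shape_features: empty mask")

    voxel_volume = float(np.prod(spacing))
    volume_mm3 = mask.sum() * voxel_volume

    # face counting: a face is exposed when the neighbor across it is
    # outside the mask; the face normal to axis `ax` has area prod(other spacings)
    padded = np.pad(mask, 1)
    area = 0.0
    for ax in range(3):
        face_area = voxel_volume / spacing[ax]
        for shift in (-1, 1):
            sl = [slice(1, -1)] * 3
            sl[ax] = slice(1 + shift, padded.shape[ax] - 1 + shift)
            area += (mask & ~padded[tuple(sl)]).sum() * face_area

    boundary = np.argwhere(_boundary_voxels(mask)) * spacing
    max3d = _max_pairwise_distance(boundary)

    # per-plane maxima: plane name refers to the axis held constant
    plane_axis = {"axial": 2, "coronal": 1, "sagittal": 0}
    max2d = {}
    coords = np.argwhere(mask)
    for plane, ax in plane_axis.items():
        in_plane = [a for a in range(3) if a != ax]
        best = 0.0
        for level in np.unique(coords[:, ax]):
            pts = coords[coords[:, ax] == level][:, in_plane] * spacing[in_plane]
            best = max(best, _max_pairwise_distance(pts))
        max2d[plane] = best

    sphericity = np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area
    return {
        "volume_ml": volume_mm3 / 1000.0,
        "surface_area_mm2": area,
        "sphericity": sphericity,
        "surface_volume_ratio": area / volume_mm3,
        "equivalent_diameter_mm": (6 * volume_mm3 / np.pi) ** (1 / 3),
        "max_3d_diameter_mm": max3d,
        "max_2d_diameter_axial_mm": max2d["axial"],
        "max_2d_diameter_coronal_mm": max2d["coronal"],
        "max_2d_diameter_sagittal_mm": max2d["sagittal"],
    }


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def discretize(
    image: np.ndarray, mask: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()
) -> np.ndarray:
    """Fixed-bin-count gray-level discretization of the ROI.

    Returns an integer volume with labels 1..n_bins inside the mask and 0
    outside.  Bins are equal-width on [ROI min, ROI max]; the top edge is
    inclusive.  A constant ROI maps entirely to label 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("discretize: empty mask")
    vals = np.asarray(image, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    labels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        labels[mask] = 1
        return labels
    width = (hi - lo) / spec.n_bins
    binned = np.floor((vals - lo) / width).astype(np.int32) + 1
    labels[mask] = np.minimum(binned, spec.n_bins)
    return labels


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


def first_order_features(
    image: np.ndarray,
    mask: np.ndarray,
    spec: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, float]:
    """First-order intensity statistics on the raw ROI values.

    Entropy (bits) and uniformity are computed on the fixed-bin-count
    histogram from :func:`discretize`.  For a constant ROI the third and
    fourth standardized moments are undefined and reported as 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("first_order_features: empty mask")
    x = np.asarray(image, dtype=float)[mask]

    var = float(np.var(x))
    if var > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x, fisher=False))
    else:
        skew = kurt = 0.0

    labels = discretize(image, mask, spec)[mask]
    p = np.bincount(labels, minlength=spec.n_bins + 1)[1:] / labels.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "mean": float(x.mean()),
        "median": float(med),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "iqr": float(q3 - q1),
        "mad": float(np.abs(x - x.mean()).mean()),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
        "entropy": entropy,
        "uniformity": float((nz**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _shift2d(plane: np.ndarray, dj: int, dk: int, fill=0) -> np.ndarray:
    """Shift a 2D array so out[j,k] = plane[j-dj, k-dk], zero-filled."""
    out = np.full_like(plane, fill)
    js = slice(max(dj, 0), plane.shape[0] + min(dj, 0))
    jt = slice(max(-dj, 0), plane.shape[0] + min(-dj, 0))
    ks = slice(max(dk, 0), plane.shape[1] + min(dk, 0))
    kt = slice(max(-dk, 0), plane.shape[1] + min(-dk, 0))
    out[js, ks] = plane[jt, kt]
    return out


def run_length_matrix(labels: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """GLRLM for one direction: P[g, l] counts maximal runs of gray level g
    (1-based) and length l (1-based); label 0 marks voxels outside the ROI
    and a 0 gap terminates a run.

    Returned matrix has shape (n_levels + 1, max_len + 1) with row 0 and
    column 0 empty, so ``P[g, l]`` indexes naturally.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be 3D")
    d = np.asarray(direction)
    # orient so every component is >= 0 and DP can scan forward
    flip = [ax for ax in range(3) if d[ax] < 0]
    if flip:
        labels = np.flip(labels, axis=flip)
        d = np.abs(d)
    scan_ax = int(np.argmax(d == 1))
    lab = np.moveaxis(labels, scan_ax, 0)
    dj, dk = np.delete(d, scan_ax)

    n = lab.shape[0]
    # run length ending at each voxel, scanning along the direction
    length = np.zeros_like(lab)
    length[0] = (lab[0] > 0).astype(lab.dtype)
    for i in range(1, n):
        prev_lab = _shift2d(lab[i - 1], dj, dk)
        prev_len = _shift2d(length[i - 1], dj, dk)
        cont = (lab[i] > 0) & (lab[i] == prev_lab)
        length[i] = np.where(cont, prev_len + 1, (lab[i] > 0).astype(lab.dtype))

    # a run ends where the next voxel along the direction differs / exits
    next_lab = np.zeros_like(lab)
    next_lab[:-1] = _shift2d_stack(lab[1:], -dj, -dk)
    ends = (lab > 0) & (lab != next_lab)
    g = lab[ends]
    l = length[ends]
    n_levels = int(labels.max())
    max_len = int(l.max()) if l.size else 1
    P = np.zeros((n_levels + 1, max_len + 1), dtype=np.int64)
    np.add.at(P, (g, l), 1)
    return P


def _shift2d_stack(stack: np.ndarray, dj: int, dk: int) -> np.ndarray:
    out = np.zeros_like(stack)
    js = slice(max(dj, 0), stack.shape[1] + min(dj, 0))
    jt = slice(max(-dj, 0), stack.shape[1] + min(-dj, 0))
    ks = slice(max(dk, 0), stack.shape[2] + min(dk, 0))
    kt = slice(max(-dk, 0), stack.shape[2] + min(-dk, 0))
    out[:, js, ks] = stack[:, jt, kt]
    return out


def _glrlm_features_single(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16-feature run-length set from one direction's matrix."""
    Ns = P.sum()
    if Ns == 0:
        raise ValueError("empty run-length matrix")
    g = np.arange(P.shape[0], dtype=float)
    l = np.arange(P.shape[1], dtype=float)
    g[0] = l[0] = 1.0  # rows/cols 0 are empty; avoid 0-division
    Pg = P.sum(axis=1).astype(float)  # runs per gray level
    Pl = P.sum(axis=0).astype(float)  # runs per length
    p = P / Ns
    mu_g = (p.sum(axis=1) * g).sum()
    mu_l = (p.sum(axis=0) * l).sum()
    nz = p[p > 0]
    return {
        "sre": float((Pl / l**2).sum() / Ns),
        "lre": float((Pl * l**2).sum() / Ns),
        "gln": float((Pg**2).sum() / Ns),
        "glnn": float((Pg**2).sum() / Ns**2),
        "rln": float((Pl**2).sum() / Ns),
        "rlnn": float((Pl**2).sum() / Ns**2),
        "rp": float(Ns / n_voxels),
        "glv": float((p * ((g[:, None] - mu_g) ** 2)).sum()),
        "rlv": float((p * ((l[None, :] - mu_l) ** 2)).sum()),
        "re": float(-(nz * np.log2(nz)).sum()),
        "lglre": float((Pg / g**2).sum() / Ns),
        "hglre": float((Pg * g**2).sum() / Ns),
        "srlgle": float((P / (g[:, None] ** 2 * l[None, :] ** 2)).sum() / Ns),
        "srhgle": float((P * g[:, None] ** 2 / l[None, :] ** 2).sum() / Ns),
        "lrlgle": float((P * l[None, :] ** 2 / g[:, None] ** 2).sum() / Ns),
        "lrhgle": float((P * (g[:, None] * l[None, :]) ** 2).sum() / Ns),
    }


def glrlm_features(
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    directions=DIRECTIONS,
    average: bool = True,
):
    """Run-length features over the 13 unique 3D directions.

    Parameters
    ----------
    labels
        Integer volume from :func:`discretize` (0 outside the ROI).
    mask
        Optional binary ROI; defaults to ``labels > 0``.
    average
        If True (default) return the unweighted mean over directions;
        otherwise a list of per-direction feature dicts.
    """
    labels = np.asarray(labels)
    if mask is not None:
        labels = np.where(np.asarray(mask, dtype=bool), labels, 0)
    n_voxels = int((labels > 0).sum())
    if n_voxels == 0:
        raise ValueError("glrlm_features: empty ROI")
    per_dir = [
        _glrlm_features_single(run_length_matrix(labels, d), n_voxels)
        for d in directions
    ]
    if not average:
        return per_dir
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


def feature_columns(
    zones=("tumor", "band_pm5", "ptz_0_10", "ptz_10_20"), sequences=SEQUENCES
) -> list[str]:
    """Canonical column inventory: <zone>_shape_<f>, <zone>_<seq>_<class>_<f>."""
    cols = []
    for zone in zones:
        cols += [f"{zone}_shape_{f}" for f in SHAPE_FEATURES]
        for seq in sequences:
            cols += [f"{zone}_{seq}_firstorder_{f}" for f in FIRST_ORDER_FEATURES]
            cols += [f"{zone}_{seq}_glrlm_{f}" for f in GLRLM_FEATURES]
    return cols


def _bbox(mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def extract_patient_features(
    images: dict[str, np.ndarray],
    zone_masks: dict[str, np.ndarray],
    spacing_mm,
    spec: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, float]:
    """All features for one patient; empty zones yield NaN columns."""
    row: dict[str, float] = {}
    for zone, zmask in zone_masks.items():
        zmask = np.asarray(zmask, dtype=bool)
        for seq, img in images.items():
            if img.shape != zmask.shape:
                raise ValueError(
                    f"geometry mismatch: image {seq} {img.shape} vs zone "
                    f"{zone} {zmask.shape}"
                )
        if not zmask.any():
            for f in SHAPE_FEATURES:
                row[f"{zone}_shape_{f}"] = np.nan
            for seq in images:
                for f in FIRST_ORDER_FEATURES:
                    row[f"{zone}_{seq}_firstorder_{f}"] = np.nan
                for f in GLRLM_FEATURES:
                    row[f"{zone}_{seq}_glrlm_{f}"] = np.nan
            continue
        box = _bbox(zmask)
        sub = zmask[box]
        for f, v in shape_features(sub, spacing_mm).items():
            row[f"{zone}_shape_{f}"] = v
        for seq, img in images.items():
            sub_img = img[box]
            for f, v in first_order_features(sub_img, sub, spec).items():
                row[f"{zone}_{seq}_firstorder_{f}"] = v
            labels = discretize(sub_img, sub, spec)
            for f, v in glrlm_features(labels).items():
                row[f"{zone}_{seq}_glrlm_{f}"] = v
    return row


def extract_feature_table(
    cohort_images: dict[str, dict[str, np.ndarray]],
    cohort_zones: dict[str, dict[str, np.ndarray]],
    spacing_mm,
    spec: DiscretizationSpec = DiscretizationSpec(),
) -> pd.DataFrame:
    """Patients x features table.

    Keys of ``cohort_images``/``cohort_zones`` are patient ids; values map
    sequence -> volume and zone -> mask respectively.  Shape features are
    computed once per zone; first-order and GLRLM per (zone, sequence).
    Empty zones propagate as NaN (explicit missing), never as zeros.
    """
    rows = {}
    for pid, images in cohort_images.items():
        rows[pid] = extract_patient_features(
            images, cohort_zones[pid], spacing_mm, spec
        )
    zone_names = list(next(iter(cohort_zones.values())).keys())
    seqs = list(next(iter(cohort_images.values())).keys())
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table[feature_columns(zone_names, seqs)]
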