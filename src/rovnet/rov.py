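"""Change-point thresholding of variance maps and region-of-variance (ROV)
extraction.

Rather than a parametric significance level, the variance maps are
thresholded at the abrupt transition in their sorted value vector: all map
values are sorted ascending and the single split that minimizes the summed
within-segment squared error (piecewise-constant mean, one change point) is
found by exhaustive search. The value at the start of the upper segment
becomes the threshold. Surviving voxels are grouped into 26-connected
clusters, and each cluster peak seeds a spherical ROV (default radius
10 mm) in world (MNI-style) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from rovnet.grid import GridGeometry
from rovnet.variance import CONNECTIVITY_26, VarianceMap


@dataclass
class Cluster:
    """A connected component of supra-threshold voxels."""

    voxel_ids: np.ndarray  # (n, 3) voxel indices
    size: int
    peak_mm: np.ndarray  # (3,) world coordinates of the peak voxel center
    peak_value: float


@dataclass
class ROV:
    """A labeled spherical region of variance."""

    label: str
    kind: str  # "functional" | "structural"
    center_mm: np.ndarray
    radius_mm: float
    voxel_ids: np.ndarray  # (n, 3)

    def __post_init__(self):
        if self.kind not in ("functional", "structural"):
            raise ValueError(f"unknown ROV kind: {self.kind}")
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if len(self.voxel_ids) == 0:
            raise ValueError(f"ROV {self.label!r} has no member voxels")


def changepoint_threshold(values) -> tuple[float, int]:
    """Threshold a value vector at its single least-squares change point.

    The values are sorted ascending and every split index k in [1, n-1] is
    scored by SSE(left about its mean) + SSE(right about its mean); the
    minimizing split (first index on ties) defines the threshold as the
    first value of the upper segment.

    Returns ``(threshold, change_index)`` where ``change_index`` is the
    number of values in the lower segment. When every value is identical
    there is no change point and ``(inf, n)`` is returned — nothing
    survives such a threshold.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 finite values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x[0] == x[-1]:
        return np.inf, n

    # prefix sums give O(n) exhaustive search over all splits
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    k = np.arange(1, n)
    sse_left = c2[k] - c1[k] ** 2 / k
    sse_right = (c2[n] - c2[k]) - (c1[n] - c1[k]) ** 2 / (n - k)
    split = int(k[np.argmin(sse_left + sse_right)])
    return float(x[split]), split


def apply_threshold(vmap: VarianceMap, threshold: float) -> VarianceMap:
    """Keep voxels whose value meets the threshold; zero the rest.

    Values >= threshold survive, so the detected upper segment itself
    survives its own threshold. NaN (undefined) voxels never survive.
    """
    with np.errstate(invalid="ignore"):
        keep = vmap.values >= threshold
    values = np.where(keep, vmap.values, 0.0)
    return VarianceMap(
        values=values,
        kind=vmap.kind,
        geometry=vmap.geometry,
        threshold=threshold,
        mask=None if vmap.mask is None else vmap.mask.copy(),
    )


def extract_clusters(vmap: VarianceMap, min_size: int = 10) -> list[Cluster]:
    """26-connected clusters of nonzero voxels, sorted by descending peak.

    Each cluster records its peak voxel (maximum value; ties broken by the
    lowest linear voxel index) converted to mm through the grid affine.
    """
    vals = np.nan_to_num(vmap.values, nan=0.0)
    labels, n_comp = ndimage.label(vals != 0, structure=CONNECTIVITY_26)
    clusters: list[Cluster] = []
    for lab in range(1, n_comp + 1):
        member = labels == lab
        size = int(member.sum())
        if size < min_size:
            continue
        # argmax on the flattened masked array → first (lowest linear) max
        flat = np.where(member.ravel(), vals.ravel(), -np.inf)
        peak_lin = int(np.argmax(flat))
        peak_idx = np.unravel_index(peak_lin, vals.shape)
        clusters.append(
            Cluster(
                voxel_ids=np.argwhere(member),
                size=size,
                peak_mm=vmap.geometry.voxel_to_mm(np.array(peak_idx)),
                peak_value=float(vals[peak_idx]),
            )
        )
    clusters.sort(key=lambda c: (-c.peak_value, int(np.ravel_multi_index(tuple(c.voxel_ids[0]), vmap.values.shape))))
    return clusters


def define_rov(
    label: str,
    kind: str,
    center_mm,
    geometry: GridGeometry,
    radius_mm: float = 10.0,
) -> ROV:
    """Spherical ROV: all voxels whose centers lie within radius of center."""
    center_mm = np.asarray(center_mm, dtype=float)
    if not geometry.contains_mm(center_mm):
        raise ValueError(f"ROV center {center_mm} outside the grid bounding box")
    voxels = geometry.sphere_voxels(center_mm, radius_mm)
    if len(voxels) == 0:
        raise ValueError(f"ROV {label!r} at {center_mm} has no member voxels")
    return ROV(label=label, kind=kind, center_mm=center_mm, radius_mm=float(radius_mm), voxel_ids=voxels)


def rovs_from_clusters(
    clusters: list[Cluster],
    kind: str,
    geometry: GridGeometry,
    radius_mm: float = 10.0,
    prefix: str = "ROV",
) -> list[ROV]:
    """One spherical ROV per cluster peak, labeled in peak-rank order."""
    return [
        define_rov(f"{prefix}{i + 1:02d}", kind, c.peak_mm, geometry, radius_mm)
        for i, c in enumerate(clusters)
    ]
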