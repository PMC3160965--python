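"""Microcluster shape descriptors and radial profiles.

Circularity C = 4πa/p² compares a cluster's area a to its perimeter p and is 1
for a perfect circle. The perimeter follows the Benkrid chain-code scheme: the
contour is the closed sequence of links between centers of adjacent edge
pixels, each straight link contributing one pixel dimension and each diagonal
link √2 — not a count of boundary pixels. Clusters are classified as highly
circular (C ≥ 0.66), intermediate (0.66 > C ≥ 0.33) or irregular (C < 0.33).

Radial position is expressed as the normalized distance r̃ of the cluster
centroid from the cell center (0 = center, 1 = cell edge); the actin-rich
periphery is the band 0.7 ≤ r̃ ≤ 1.0. Radial profiles of mean circularity use
bins of width 0.25; actin-type intensity profiles are normalized to their
maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint
from skimage import measure

__all__ = [
    "ClusterShape",
    "CellGeometry",
    "RadialProfile",
    "benkrid_perimeter",
    "circularity",
    "classify_circularity",
    "normalized_radius",
    "periphery_filter",
    "radial_circularity_profile",
    "radial_intensity_profile",
    "measure_shapes",
    "cell_geometry_from_footprint",
]

SQRT2 = math.sqrt(2.0)

# Moore neighborhood in clockwise order starting east, as (drow, dcol)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class CellGeometry:
    center_nm: tuple[float, float]
    radius_nm: float

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("cell radius must be positive")


@dataclass
class ClusterShape:
    label: int
    area_px: float
    perimeter_px: float
    circularity: float
    shape_class: str
    centroid_nm: tuple[float, float]
    r_norm: float = float("nan")


@dataclass
class RadialProfile:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean: np.ndarray  # NaN marks empty bins
    sem: np.ndarray
    counts: np.ndarray


def _trace_chain(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace (8-connected, Jacob's stopping
    criterion); returns the closed sequence of boundary pixel coordinates."""
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    padded = np.pad(mask.astype(bool), 1)

    def fg(p: tuple[int, int]) -> bool:
        return bool(padded[p[0] + 1, p[1] + 1])

    chain = [start]
    # backtrack starts west of the start pixel (start is the topmost-leftmost
    # foreground pixel, so everything above and to its left is background)
    prev_dir = 4  # direction pointing from current pixel to backtrack (west)
    cur = start
    first_move: tuple[int, int, int] | None = None
    for _ in range(8 * mask.size):
        found = False
        # search clockwise starting just after the backtrack direction
        for k in range(1, 9):
            di = (prev_dir + k) % 8
            nb = (cur[0] + _MOORE[di][0], cur[1] + _MOORE[di][1])
            if fg(nb):
                move = (cur[0], cur[1], di)
                if first_move is None:
                    first_move = move
                elif cur == start and di == first_move[2]:
                    return chain
                chain.append(nb)
                prev_dir = (di + 4) % 8  # direction back to where we came from
                cur = nb
                found = True
                break
        if not found:  # isolated pixel
            return chain
    return chain


def benkrid_perimeter(mask: np.ndarray) -> float:
    """Chain-code contour length of one connected binary object.

    Each link between centers of adjacent edge pixels contributes 1 (straight)
    or √2 (diagonal). Degenerate tiny masks use outer-boundary conventions:
    a single pixel gives 4, a 1×2 domino gives 6.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    if measure.label(mask, connectivity=2).max() > 1:
        raise ValueError("mask must be a single connected component")
    if n == 1:
        return 4.0
    if n == 2:
        rows, cols = np.nonzero(mask)
        if abs(rows[0] - rows[1]) + abs(cols[0] - cols[1]) == 1:
            return 6.0  # 4-adjacent domino
    chain = _trace_chain(mask)
    if len(chain) < 2:
        return 4.0
    total = 0.0
    pts = chain + [chain[0]]
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        step = abs(r1 - r0) + abs(c1 - c0)
        if step == 0:
            continue
        total += 1.0 if step == 1 else SQRT2
    return total


def circularity(area: float, perimeter: float) -> float:
    """C = 4πa/p²; 1 for a perfect circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def classify_circularity(c: float) -> str:
    """highly_circular (C ≥ 0.66), intermediate (0.66 > C ≥ 0.33) or
    irregular (C < 0.33); both cut-offs are inclusive on the upper class."""
    if c >= 0.66:
        return "highly_circular"
    if c >= 0.33:
        return "intermediate"
    return "irregular"


def normalized_radius(centroid_nm: tuple[float, float], geometry: CellGeometry) -> float:
    """Centroid-to-cell-center distance over the cell radius; values beyond
    the fitted cell edge are clipped to 1 with a warning."""
    d = math.hypot(
        centroid_nm[0] - geometry.center_nm[0], centroid_nm[1] - geometry.center_nm[1]
    )
    r = d / geometry.radius_nm
    if r > 1.0:
        warnings.warn("cluster centroid beyond the fitted cell edge; r̃ clipped to 1")
        return 1.0
    return r


def periphery_filter(r_norm: float) -> bool:
    """True iff the normalized radius lies in the peripheral band
    0.7 ≤ r̃ ≤ 1.0."""
    return 0.7 <= r_norm <= 1.0


def _profile(values: np.ndarray, radii: np.ndarray, bin_width: float) -> RadialProfile:
    edges = np.arange(0.0, 1.0 + 0.5 * bin_width, bin_width)
    idx = np.clip(np.digitize(radii, edges) - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sem = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = values[idx == b]
        counts[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sem[b] = sel.std(ddof=1) / math.sqrt(sel.size) if sel.size > 1 else 0.0
    return RadialProfile(
        bin_edges=edges,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mean=mean,
        sem=sem,
        counts=counts,
    )


def radial_circularity_profile(
    shapes: list[ClusterShape], bin_width: float = 0.25
) -> RadialProfile:
    """Mean circularity (± s.e.m.) per normalized-radius bin; empty bins are
    reported as NaN, not zero."""
    if not shapes:
        raise ValueError("no shapes")
    vals = np.array([s.circularity for s in shapes])
    radii = np.array([s.r_norm for s in shapes])
    return _profile(vals, radii, bin_width)


def radial_intensity_profile(
    image: np.ndarray,
    geometry: CellGeometry,
    pixel_nm: float,
    bin_width: float = 0.05,
) -> RadialProfile:
    """Radial mean-intensity profile over r̃ bins, normalized to its maximum
    (peak = 1). Pixels outside the cell circle are ignored."""
    image = np.asarray(image, dtype=float)
    if not np.any(image > 0):
        raise ValueError("no signal")
    yy, xx = np.mgrid[0: image.shape[0], 0: image.shape[1]]
    x_nm = (xx + 0.5) * pixel_nm
    y_nm = (yy + 0.5) * pixel_nm
    r = np.hypot(x_nm - geometry.center_nm[0], y_nm - geometry.center_nm[1]) / geometry.radius_nm
    inside = r <= 1.0
    prof = _profile(image[inside].ravel(), r[inside].ravel(), bin_width)
    peak = np.nanmax(prof.mean)
    if peak <= 0:
        raise ValueError("no signal inside the cell")
    prof.mean = prof.mean / peak
    prof.sem = prof.sem / peak
    return prof


def measure_shapes(
    labels: np.ndarray,
    pixel_nm: float,
    geometry: CellGeometry | None = None,
    intensity: np.ndarray | None = None,
) -> list[ClusterShape]:
    """Area, Benkrid perimeter, circularity, class and r̃ for each labeled
    cluster. Centroids are intensity-weighted when an intensity image is
    given (mask centroid otherwise)."""
    labels = np.asarray(labels)
    out: list[ClusterShape] = []
    props = measure.regionprops(labels, intensity_image=intensity)
    for p in props:
        mask = labels == p.label
        per = benkrid_perimeter(mask)
        area = float(p.area)
        c = circularity(area, per)
        cy, cx = p.centroid_weighted if intensity is not None else p.centroid
        centroid = ((cx + 0.5) * pixel_nm, (cy + 0.5) * pixel_nm)
        r_norm = normalized_radius(centroid, geometry) if geometry else float("nan")
        out.append(
            ClusterShape(
                label=int(p.label),
                area_px=area,
                perimeter_px=per,
                circularity=c,
                shape_class=classify_circularity(c),
                centroid_nm=centroid,
                r_norm=r_norm,
            )
        )
    return out


def cell_geometry_from_footprint(
    footprint: np.ndarray, pixel_nm: float, threshold: float = 0.0
) -> CellGeometry:
    """Cell center and radius as the minimum enclosing circle of the
    thresholded footprint (e.g. a TIRF image)."""
    footprint = np.asarray(footprint, dtype=float)
    rows, cols = np.nonzero(footprint > threshold)
    if rows.size == 0:
        raise ValueError("empty footprint")
    pts = MultiPoint(np.column_stack([(cols + 0.5) * pixel_nm, (rows + 0.5) * pixel_nm]))
    circle = shapely.minimum_bounding_circle(pts)
    center = circle.centroid
    radius = math.sqrt(circle.area / math.pi)
    return CellGeometry(center_nm=(center.x, center.y), radius_nm=radius)
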