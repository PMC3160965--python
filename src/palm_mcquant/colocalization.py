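"""Mander's colocalization of dual-channel rendered PALM images.

For per-pixel red/green intensities R_i, G_i on a zero-background rendered
image, the coefficients are

    M1 = Σ R_i,coloc / Σ R_i      M2 = Σ G_i,coloc / Σ G_i

with R_i,coloc = R_i where G_i > 0 (else 0) and symmetrically for G. A
completely colocalized microcluster (MC) pair yields M1 = M2 = 1; disjoint
supports yield 0. Strict positivity defines co-occupancy, which is exact here
because rendered images have identically-zero background.

MC pairs are classified as isolated (M1 = 0 or M2 = 0), overlapping
(max(M1, M2) > 0.66), edge-connected (both nonzero and max < 0.33) or
partially overlapping (the rest). Threshold comparisons are strict, so values
at exactly 0.33 or 0.66 fall to the partial category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .localization import RenderedImage
from .spatial import ClusterMap

__all__ = [
    "DualChannelImage",
    "AssociationResult",
    "PYRecord",
    "manders",
    "classify_association",
    "pair_clusters",
    "evaluate_pairs",
    "association_fractions",
    "relative_py",
    "CATEGORIES",
]

CATEGORIES = ("overlapping", "partial", "edge_connected", "isolated")


@dataclass
class DualChannelImage:
    red: np.ndarray
    green: np.ndarray
    pixel_nm: float

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape:
            raise ValueError("channels must share the pixel grid")

    @classmethod
    def from_rendered(cls, red: RenderedImage, green: RenderedImage) -> "DualChannelImage":
        if red.pixel_nm != green.pixel_nm:
            raise ValueError("channels must share the PALM pixel size")
        return cls(red.pixels, green.pixels, red.pixel_nm)


@dataclass
class AssociationResult:
    pair_id: int
    red_label: int | None
    green_label: int | None
    m1: float
    m2: float
    category: str
    r_norm: float = float("nan")
    periphery: bool = False


@dataclass
class PYRecord:
    mc_mean: float
    background_mean: float
    ratio: float


def manders(image: DualChannelImage, mask: np.ndarray) -> tuple[float, float]:
    """Mander's M1 (red) and M2 (green) over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    r = image.red[mask]
    g = image.green[mask]
    r_tot = float(r.sum())
    g_tot = float(g.sum())
    if r_tot <= 0 or g_tot <= 0:
        raise ValueError("empty channel: Mander's coefficient undefined")
    m1 = float(r[g > 0].sum()) / r_tot
    m2 = float(g[r > 0].sum()) / g_tot
    return m1, m2


def classify_association(m1: float, m2: float) -> str:
    """Category of an MC pair from its Mander's coefficients.

    Precedence: isolated (either coefficient zero), then overlapping
    (max > 0.66), then edge-connected (max < 0.33), else partial.
    """
    for v in (m1, m2):
        if not (0.0 <= v <= 1.0):
            raise ValueError("Mander's coefficients must lie in [0, 1]")
    if m1 == 0.0 or m2 == 0.0:
        return "isolated"
    hi = max(m1, m2)
    if hi > 0.66:
        return "overlapping"
    if hi < 0.33:
        return "edge_connected"
    return "partial"


def pair_clusters(
    red: ClusterMap, green: ClusterMap, max_distance_nm: float = 500.0
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Mutual-nearest-neighbor pairing of red and green cluster centroids.

    Returns (pairs, red_singletons, green_singletons); a pair forms when the
    two centroids are each other's nearest cross-channel neighbor and lie
    within the distance cap.
    """
    if red.n_clusters == 0 or green.n_clusters == 0:
        return [], list(red.table["label"]), list(green.table["label"])
    rc = red.table[["x_c_nm", "y_c_nm"]].to_numpy()
    gc = green.table[["x_c_nm", "y_c_nm"]].to_numpy()
    d_rg, nn_rg = cKDTree(gc).query(rc)  # nearest green for each red
    d_gr, nn_gr = cKDTree(rc).query(gc)  # nearest red for each green
    pairs: list[tuple[int, int]] = []
    paired_r: set[int] = set()
    paired_g: set[int] = set()
    for ri in range(len(rc)):
        gi = int(nn_rg[ri])
        if int(nn_gr[gi]) == ri and d_rg[ri] <= max_distance_nm:
            pairs.append((int(red.table["label"].iat[ri]), int(green.table["label"].iat[gi])))
            paired_r.add(ri)
            paired_g.add(gi)
    red_single = [int(red.table["label"].iat[i]) for i in range(len(rc)) if i not in paired_r]
    green_single = [int(green.table["label"].iat[i]) for i in range(len(gc)) if i not in paired_g]
    return pairs, red_single, green_single


def _pair_region(
    image_shape: tuple[int, int],
    mask_a: np.ndarray | None,
    mask_b: np.ndarray | None,
    dilate_px: int = 2,
) -> np.ndarray:
    """Evaluation region for one MC pair: union bounding box of the pair's
    masks dilated by ``dilate_px`` PALM pixels."""
    union = np.zeros(image_shape, dtype=bool)
    for m in (mask_a, mask_b):
        if m is not None:
            union |= m
    if dilate_px > 0:
        union = ndimage.binary_dilation(
            union, structure=np.ones((2 * dilate_px + 1,) * 2, dtype=bool)
        )
    rows, cols = np.nonzero(union)
    region = np.zeros(image_shape, dtype=bool)
    region[rows.min(): rows.max() + 1, cols.min(): cols.max() + 1] = True
    return region


def evaluate_pairs(
    image: DualChannelImage,
    red: ClusterMap,
    green: ClusterMap,
    max_distance_nm: float = 500.0,
    cell_center_nm: tuple[float, float] | None = None,
    cell_radius_nm: float | None = None,
) -> list[AssociationResult]:
    """Per-pair Mander's coefficients and association categories.

    Mutual-NN pairs are evaluated on the dilated union bounding box of their
    masks; unpaired clusters are evaluated on their own dilated box against
    the other channel and typically land in the isolated category. When the
    cell geometry is given, each result carries the pair's mean-centroid
    normalized radius and the periphery flag (0.7 ≤ r̃ ≤ 1.0).
    """
    pairs, red_single, green_single = pair_clusters(red, green, max_distance_nm)
    results: list[AssociationResult] = []
    centroids_r = {int(r.label): (r.x_c_nm, r.y_c_nm) for r in red.table.itertuples()}
    centroids_g = {int(r.label): (r.x_c_nm, r.y_c_nm) for r in green.table.itertuples()}

    def finish(pid, rl, gl, region, cent):
        try:
            m1, m2 = manders(image, region)
            cat = classify_association(m1, m2)
        except ValueError:
            m1, m2, cat = 0.0, 0.0, "isolated"
        r_norm = float("nan")
        periph = False
        if cell_center_nm is not None and cell_radius_nm:
            r_norm = min(
                math.hypot(cent[0] - cell_center_nm[0], cent[1] - cell_center_nm[1])
                / cell_radius_nm,
                1.0,
            )
            periph = 0.7 <= r_norm <= 1.0
        results.append(AssociationResult(pid, rl, gl, m1, m2, cat, r_norm, periph))

    pid = 0
    for rl, gl in pairs:
        region = _pair_region(image.red.shape, red.labels == rl, green.labels == gl)
        cr, cg = centroids_r[rl], centroids_g[gl]
        finish(pid, rl, gl, region, ((cr[0] + cg[0]) / 2, (cr[1] + cg[1]) / 2))
        pid += 1
    for rl in red_single:
        region = _pair_region(image.red.shape, red.labels == rl, None)
        finish(pid, rl, None, region, centroids_r[rl])
        pid += 1
    for gl in green_single:
        region = _pair_region(image.red.shape, None, green.labels == gl)
        finish(pid, None, gl, region, centroids_g[gl])
        pid += 1
    return results


def association_fractions(
    results: list[AssociationResult], periphery_only: bool = False
) -> dict[str, float]:
    """Category fractions: the three associated categories among pairs with
    M1, M2 > 0 (summing to 1), plus the isolated fraction over all analyzed
    MCs."""
    if periphery_only:
        results = [r for r in results if r.periphery]
    if not results:
        raise ValueError("no pairs in region")
    associated = [r for r in results if r.m1 > 0 and r.m2 > 0]
    out: dict[str, float] = {}
    for cat in ("overlapping", "partial", "edge_connected"):
        out[cat] = (
            sum(r.category == cat for r in associated) / len(associated)
            if associated
            else float("nan")
        )
    out["isolated"] = sum(r.category == "isolated" for r in results) / len(results)
    return out


def relative_py(
    py_image: np.ndarray,
    mc_mask: np.ndarray,
    background_mask: np.ndarray,
    camera_offset: float = 0.0,
) -> PYRecord:
    """Relative phosphotyrosine level: mean MC immunofluorescence divided by
    the mean of an adjacent MC-free area, after camera-offset subtraction."""
    py_image = np.asarray(py_image, dtype=float) - camera_offset
    mc_mask = np.asarray(mc_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not mc_mask.any() or not background_mask.any():
        raise ValueError("both masks must be non-empty")
    if np.any(mc_mask & background_mask):
        raise ValueError("MC and background masks must be disjoint")
    mc_mean = float(py_image[mc_mask].mean())
    bg_mean = float(py_image[background_mask].mean())
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    return PYRecord(mc_mean=mc_mean, background_mean=bg_mean, ratio=mc_mean / bg_mean)
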