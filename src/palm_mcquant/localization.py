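"""Single-molecule detection, 2D Gaussian localization and PALM rendering.

The detection path mirrors the classic sparse-activation pipeline: per frame,
the even background (frame mean) and an opening-based estimate of the uneven
background are subtracted; candidate particles are selected with three
thresholds (T1 picks objects, a minimum pixel count above T2 = 0.7·T1 rejects
single hot pixels from shot noise, a maximum pixel count above T3 = T1 rejects
objects too bright/extended to be one molecule); each surviving candidate is
fitted with a symmetric 2D Gaussian by least squares, initialized at the
candidate's center of mass. The localization uncertainty follows the Thompson
photon-statistics formula with the background term.

Coordinates are continuous and in nm: pixel (row k, col j) covers
[j·s, (j+1)·s) × [k·s, (k+1)·s) nm for pixel size s, with x rightward
(columns) and y downward (rows); pixel membership is half-open.

Rendered PALM images place each molecule as a unit-integral 2D Gaussian of
standard deviation equal to its localization uncertainty, truncated to the
5×5 block of PALM pixels centered on the pixel containing the coordinate,
leaving an exactly-zero background. The truncated kernel is not renormalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import erf
from skimage import measure, morphology

__all__ = [
    "ImageStack",
    "ThresholdSet",
    "Localization",
    "RenderedImage",
    "subtract_background",
    "identify_particles",
    "fit_spot",
    "localize_stack",
    "render_palm",
    "molecules_per_cluster",
    "thompson_uncertainty",
]

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "amplitude", "photons", "sigma_nm",
               "uncertainty_nm", "channel"]


@dataclass
class ImageStack:
    frames: np.ndarray  # (n_frames, h, w)
    pixel_nm: float
    frame_interval_s: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("stack must be (n_frames, h, w)")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class ThresholdSet:
    """Three-threshold particle selection: T2 = 0.7·T1 and T3 = T1 by
    construction."""

    t1: float
    min_above_t2: int = 3
    max_above_t3: int = 30
    t2: float = field(init=False)
    t3: float = field(init=False)

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("T1 must be positive")
        self.t2 = 0.7 * self.t1
        self.t3 = self.t1


@dataclass
class Localization:
    x_nm: float
    y_nm: float
    frame: int
    amplitude: float
    photons: float
    sigma_nm: float
    uncertainty_nm: float
    channel: str = ""


@dataclass
class RenderedImage:
    pixels: np.ndarray
    pixel_nm: float
    channel: str = ""


def suggest_t1(background_level: float, k: float = 5.0) -> float:
    """Default first threshold: ``k`` standard deviations of the background
    shot noise (Poisson: sd = sqrt(level))."""
    return k * math.sqrt(max(background_level, 1e-12))


def subtract_background(frame: np.ndarray, disk_radius: int = 1) -> np.ndarray:
    """Remove the even and uneven background components from one frame.

    The even component is the frame mean; the uneven component is estimated by
    grayscale morphological opening (erosion then dilation) with a disk-shaped
    element of the given radius and subtracted. The result is clipped at 0.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    tmp = frame - frame.mean()
    opened = morphology.opening(tmp, morphology.disk(disk_radius))
    return np.clip(tmp - opened, 0.0, None)


def identify_particles(frame: np.ndarray, thresholds: ThresholdSet) -> list[np.ndarray]:
    """Candidate single-molecule regions on a background-corrected frame.

    An object is an 8-connected component of pixels above T2 containing at
    least one pixel above T1. It is kept iff its pixel count above T2 is at
    least ``min_above_t2`` and its pixel count above T3 at most
    ``max_above_t3``. Returns one boolean mask per accepted candidate.
    """
    frame = np.asarray(frame, dtype=float)
    labels = measure.label(frame > thresholds.t2, connectivity=2)
    out: list[np.ndarray] = []
    if labels.max() == 0:
        return out
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if not np.any(frame[region] > thresholds.t1):
            continue
        if int(region.sum()) < thresholds.min_above_t2:
            continue
        if int(np.count_nonzero(frame[region] > thresholds.t3)) > thresholds.max_above_t3:
            continue
        out.append(region)
    return out


def _gauss2d(params: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    amp, x0, y0, sd, off = params
    return off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sd**2))


def thompson_uncertainty(
    sigma_nm: float, pixel_nm: float, photons: float, bg_sigma_photons: float
) -> float:
    """Thompson localization precision (nm) with the background term:

    var = (s² + a²/12)/N + 8π s⁴ b² / (a² N²)
    """
    if photons <= 0:
        return float("inf")
    s2 = sigma_nm**2
    var = (s2 + pixel_nm**2 / 12.0) / photons + (
        8.0 * math.pi * s2**2 * bg_sigma_photons**2 / (pixel_nm**2 * photons**2)
    )
    return math.sqrt(var)


def fit_spot(
    region: np.ndarray,
    frame: np.ndarray,
    pixel_nm: float,
    frame_index: int = 0,
    bg_sigma: float = 0.0,
    gain: float = 1.0,
    pad: int = 3,
    channel: str = "",
) -> Localization | None:
    """Least-squares symmetric 2D Gaussian fit of one candidate region.

    ``region`` is a boolean mask on ``frame``; the fit runs on the region's
    bounding box padded by ``pad`` pixels, with residuals weighted by the
    inverse shot-noise scale 1/√(counts + background variance) as appropriate
    for Poisson data. The center of mass of the candidate pixels initializes
    the coordinates. Returns None (candidate discarded) when the fit fails to
    converge or the fitted center leaves the crop.
    """
    region = np.asarray(region, dtype=bool)
    npix = int(region.sum())
    if npix < 5:
        raise ValueError("region must have at least 5 pixels (under-determined fit)")
    rows, cols = np.nonzero(region)
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, frame.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, frame.shape[1])
    crop = np.asarray(frame, dtype=float)[r0:r1, c0:c1]
    yy, xx = np.mgrid[r0:r1, c0:c1]
    # center of mass of the candidate pixels (pixel centers at k + 0.5)
    weights = np.clip(frame[rows, cols], 0, None)
    wsum = weights.sum()
    if wsum <= 0:
        weights = np.ones_like(weights)
        wsum = weights.sum()
    cy = float((rows * weights).sum() / wsum)
    cx = float((cols * weights).sum() / wsum)
    off0 = float(np.percentile(crop, 10))
    amp0 = max(float(crop.max()) - off0, 1e-6)
    p0 = np.array([amp0, cx, cy, 1.0, off0])
    lo = np.array([0.0, c0 - 1.0, r0 - 1.0, 0.2, -np.inf])
    hi = np.array([np.inf, c1 + 0.0, r1 + 0.0, 0.5 * max(crop.shape), np.inf])
    weights = 1.0 / np.sqrt(np.clip(crop + bg_sigma**2, 1.0, None))
    try:
        sol = optimize.least_squares(
            lambda p: ((_gauss2d(p, yy, xx) - crop) * weights).ravel(),
            np.clip(p0, lo, hi),
            bounds=(lo, hi),
            method="trf",
        )
    except Exception:
        return None
    if not sol.success:
        return None
    amp, x0, y0, sd, off = sol.x
    if not (c0 <= x0 < c1 and r0 <= y0 < r1):
        return None
    photons = 2.0 * math.pi * amp * sd**2 / gain
    sigma_nm = sd * pixel_nm
    unc = thompson_uncertainty(sigma_nm, pixel_nm, photons, bg_sigma / gain)
    return Localization(
        x_nm=(x0 + 0.5) * pixel_nm,
        y_nm=(y0 + 0.5) * pixel_nm,
        frame=frame_index,
        amplitude=float(amp),
        photons=float(photons),
        sigma_nm=float(sigma_nm),
        uncertainty_nm=float(unc),
        channel=channel,
    )


def localize_stack(
    stack: ImageStack,
    thresholds: ThresholdSet,
    gain: float = 1.0,
    channel: str = "",
    disk_radius: int = 1,
) -> pd.DataFrame:
    """Detect and localize molecules in every frame of a stack.

    Detection runs on the background-corrected frame; the Gaussian fit runs on
    the mean-subtracted frame (free offset), which preserves the full PSF
    shape that the opening-based correction flattens. The per-frame background
    noise scale for the Thompson formula is the robust (MAD) standard
    deviation of the mean-subtracted frame.
    """
    records: list[Localization] = []
    for fi, frame in enumerate(stack.frames):
        corrected = subtract_background(frame, disk_radius=disk_radius)
        fit_frame = frame - frame.mean()
        bg_sigma = 1.4826 * float(np.median(np.abs(fit_frame - np.median(fit_frame))))
        for region in identify_particles(corrected, thresholds):
            if int(region.sum()) < 5:
                continue
            loc = fit_spot(
                region,
                fit_frame,
                stack.pixel_nm,
                frame_index=fi,
                bg_sigma=bg_sigma,
                gain=gain,
                channel=channel,
            )
            if loc is not None:
                records.append(loc)
    if not records:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.DataFrame([vars(l) for l in records])[LOC_COLUMNS]


def _pixel_mass(centers: np.ndarray, mu: float, sd: float, s: float) -> np.ndarray:
    """Integral of a unit 1D Gaussian over pixels [c - s/2, c + s/2]."""
    a = (centers - 0.5 * s - mu) / (math.sqrt(2.0) * sd)
    b = (centers + 0.5 * s - mu) / (math.sqrt(2.0) * sd)
    return 0.5 * (erf(b) - erf(a))


def render_palm(
    locs: pd.DataFrame,
    palm_pixel_nm: float = 20.0,
    shape: tuple[int, int] | None = None,
    channel: str = "",
) -> RenderedImage:
    """Render localizations as truncated Gaussian spots on a PALM pixel grid.

    Each molecule contributes a unit-integral 2D Gaussian with standard
    deviation equal to its localization uncertainty, integrated over the 5×5
    PALM pixels centered on the pixel containing its coordinate; all other
    pixels stay exactly 0. The kernel is not renormalized after truncation.
    """
    if palm_pixel_nm <= 0:
        raise ValueError("pixel size must be positive")
    s = palm_pixel_nm
    if shape is None:
        if len(locs) == 0:
            shape = (1, 1)
        else:
            shape = (
                int(np.floor(locs["y_nm"].max() / s)) + 3,
                int(np.floor(locs["x_nm"].max() / s)) + 3,
            )
    img = np.zeros(shape, dtype=float)
    h, w = shape
    for x_nm, y_nm, unc in zip(
        locs.get("x_nm", []), locs.get("y_nm", []), locs.get("uncertainty_nm", [])
    ):
        sd = max(float(unc), 1e-6)
        col = int(np.floor(x_nm / s))
        row = int(np.floor(y_nm / s))
        rows = np.arange(row - 2, row + 3)
        cols = np.arange(col - 2, col + 3)
        rmask = (rows >= 0) & (rows < h)
        cmask = (cols >= 0) & (cols < w)
        if not rmask.any() or not cmask.any():
            continue
        my = _pixel_mass((rows[rmask] + 0.5) * s, y_nm, sd, s)
        mx = _pixel_mass((cols[cmask] + 0.5) * s, x_nm, sd, s)
        img[np.ix_(rows[rmask], cols[cmask])] += np.outer(my, mx)
    return RenderedImage(pixels=img, pixel_nm=s, channel=channel)


def truncated_kernel_mass(x_nm: float, y_nm: float, uncertainty_nm: float,
                          palm_pixel_nm: float) -> float:
    """Mass of one molecule's truncated rendering kernel (for conservation
    checks)."""
    s = palm_pixel_nm
    sd = max(float(uncertainty_nm), 1e-6)
    col = int(np.floor(x_nm / s))
    row = int(np.floor(y_nm / s))
    my = _pixel_mass((np.arange(row - 2, row + 3) + 0.5) * s, y_nm, sd, s)
    mx = _pixel_mass((np.arange(col - 2, col + 3) + 0.5) * s, x_nm, sd, s)
    return float(my.sum() * mx.sum())


def molecules_per_cluster(
    locs: pd.DataFrame, labels: np.ndarray, pixel_nm: float
) -> pd.Series:
    """Count localizations inside each labeled cluster mask.

    A localization belongs to the mask whose pixel contains its coordinate
    (half-open pixel membership); localizations outside all masks are
    unassigned. Returns counts indexed by label (labels with no molecules
    get 0).
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    counts = pd.Series(0, index=pd.Index(present, name="label"), dtype=int)
    if len(locs) == 0:
        return counts
    cols = np.floor(locs["x_nm"].to_numpy() / pixel_nm).astype(int)
    rows = np.floor(locs["y_nm"].to_numpy() / pixel_nm).astype(int)
    h, w = labels.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    assigned = labels[rows[inside], cols[inside]]
    for lab, cnt in zip(*np.unique(assigned[assigned > 0], return_counts=True)):
        counts.loc[lab] = int(cnt)
    return counts
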