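"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is driven by an explicit config dataclass and a seed and emits
both the simulated data and the ground truth needed to score downstream
analyses: ensemble photoswitching decays (shared forward models with
:mod:`palm_mcquant.photophysics`), sparse-blinking emitter image stacks with
Poisson shot noise and even/uneven background, CSR and disk-cluster point
patterns, dual-color cluster scenes with commanded center offsets, and binary
shape canvases with analytic areas and perimeters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ellipe, erf

from .photophysics import (
    DecayTrace,
    DronpaKinetics,
    TdEosKinetics,
    model_dronpa,
    model_gfp,
    model_tdeos,
)
from .spatial import PointPattern

__all__ = [
    "DecaySimConfig",
    "FrameSimConfig",
    "PatternSimConfig",
    "SceneSimConfig",
    "ShapeSimConfig",
    "ShapeSpec",
    "simulate_decay",
    "simulate_stack",
    "simulate_pattern",
    "simulate_scene",
    "simulate_shapes",
    "match_events",
]


# ---------------------------------------------------------------------------
# photoswitching decays


@dataclass
class DecaySimConfig:
    """Ground-truth photophysics for one simulated ensemble bleaching trace.

    Defaults reflect the measurement design: probes receive a brief 405-nm
    photoactivation pulse before continuous bleaching, so tdEos starts with
    half its pool already red (g0 = r0 = 0.5) and Dronpa with a partially
    activated pool (a0 = 0.3, i0 = 0.7) — a design in which all three Dronpa
    rates leave a visible signature in the ensemble trace. Noise is additive
    Gaussian on the normalized trace, sd 0.01 of the peak.
    """

    scheme: str  # gfp | tdeos | dronpa
    rates: dict[str, float] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    t: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 60.0, 200))
    noise_sd: float = 0.01
    intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("rate constants must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def decay_model(config: DecaySimConfig) -> np.ndarray:
    """Noise-free peak-normalized forward model on the config's grid (shared
    implementation with the photophysics module)."""
    t = config.t
    r = config.rates
    f = config.fractions
    if config.scheme == "gfp":
        return model_gfp(t, r["k_b"])
    if config.scheme == "tdeos":
        return model_tdeos(
            t,
            TdEosKinetics(
                k_ps=r["k_ps"], k_b=r["k_b"], g0=f.get("g0", 0.5), r0=f.get("r0", 0.5)
            ),
        )
    if config.scheme == "dronpa":
        return model_dronpa(
            t,
            DronpaKinetics(
                k_pa=r["k_pa"],
                k_pda=r["k_pda"],
                k_b=r["k_b"],
                i0=f.get("i0", 0.7),
                a0=f.get("a0", 0.3),
            ),
        )
    raise ValueError(f"unknown scheme {config.scheme!r}")


def simulate_decay(config: DecaySimConfig) -> DecayTrace:
    """Exact closed-form decay plus i.i.d. Gaussian noise, re-normalized to
    max = 1."""
    y = decay_model(config)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
    y = np.clip(y, 0.0, None)
    peak = y.max()
    if peak > 0:
        y = y / peak
    return DecayTrace(
        time_s=config.t,
        fluorescence=y,
        intensity=config.intensity,
        probe=config.scheme,
    )


# ---------------------------------------------------------------------------
# sparse-activation image stacks


@dataclass
class FrameSimConfig:
    """Sparse-blinking emitter movie with Gaussian PSF and Poisson noise.

    Defaults emulate EMCCD PALM acquisition: 160 nm pixels, 120 nm PSF sd,
    1000 photons per activation, flat background of 10 counts. Blinking is
    memoryless: each emitter is active in each frame with one probability.
    """

    image_size: tuple[int, int] = (64, 64)  # (h, w) pixels
    pixel_nm: float = 160.0
    psf_sd_nm: float = 120.0
    positions_nm: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    activation_prob: float = 0.05
    photons: float = 1000.0
    background: float = 10.0
    uneven_amplitude: float = 0.0
    uneven_scale_nm: float = 2000.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float).reshape(-1, 2)
        if self.psf_sd_nm <= 0:
            raise ValueError("PSF sd must be positive")
        if self.psf_sd_nm < 0.5 * self.pixel_nm:
            raise ValueError(
                "PSF sd below half a pixel: undersampled configuration rejected"
            )
        if not 0.0 <= self.activation_prob <= 1.0:
            raise ValueError("activation probability must lie in [0, 1]")
        h, w = self.image_size
        if self.positions_nm.size:
            x, y = self.positions_nm[:, 0], self.positions_nm[:, 1]
            if (x.min() < 0 or y.min() < 0 or x.max() > w * self.pixel_nm
                    or y.max() > h * self.pixel_nm):
                raise ValueError("all emitter positions must lie inside the image")


def _pixel_gauss(centers: np.ndarray, mu: float, sd: float, s: float) -> np.ndarray:
    a = (centers - 0.5 * s - mu) / (math.sqrt(2.0) * sd)
    b = (centers + 0.5 * s - mu) / (math.sqrt(2.0) * sd)
    return 0.5 * (erf(b) - erf(a))


def _uneven_field(config: FrameSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency background: a few broad Gaussian bumps, fixed per stack."""
    h, w = config.image_size
    s = config.pixel_nm
    yy, xx = np.mgrid[0:h, 0:w]
    x_nm = (xx + 0.5) * s
    y_nm = (yy + 0.5) * s
    fieldimg = np.zeros((h, w))
    for _ in range(3):
        cx = rng.uniform(0, w * s)
        cy = rng.uniform(0, h * s)
        fieldimg += np.exp(
            -((x_nm - cx) ** 2 + (y_nm - cy) ** 2) / (2.0 * config.uneven_scale_nm**2)
        )
    peak = fieldimg.max()
    return config.uneven_amplitude * fieldimg / peak if peak > 0 else fieldimg


def simulate_stack(config: FrameSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a sparse-activation stack; returns (frames, ground-truth events).

    Active emitters per frame are Bernoulli draws; each active emitter adds
    ``photons`` spread over the pixel grid as an integrated 2D Gaussian; pixel
    values are Poisson draws of signal + background. The truth table lists
    every rendered event (event_id, frame, x_nm, y_nm, photons, channel).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    s = config.pixel_nm
    uneven = (
        _uneven_field(config, rng) if config.uneven_amplitude > 0 else np.zeros((h, w))
    )
    base = config.background + uneven
    col_centers = (np.arange(w) + 0.5) * s
    row_centers = (np.arange(h) + 0.5) * s
    frames = np.empty((config.n_frames, h, w), dtype=np.uint16)
    events = []
    eid = 0
    n_emitters = config.positions_nm.shape[0]
    for fi in range(config.n_frames):
        expect = base.copy()
        if n_emitters:
            active = rng.random(n_emitters) < config.activation_prob
            for k in np.nonzero(active)[0]:
                x, y = config.positions_nm[k]
                mx = _pixel_gauss(col_centers, x, config.psf_sd_nm, s)
                my = _pixel_gauss(row_centers, y, config.psf_sd_nm, s)
                expect += config.photons * np.outer(my, mx)
                events.append(
                    {"event_id": eid, "frame": fi, "x_nm": x, "y_nm": y,
                     "photons": config.photons, "channel": ""}
                )
                eid += 1
        frames[fi] = np.clip(rng.poisson(expect), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        events, columns=["event_id", "frame", "x_nm", "y_nm", "photons", "channel"]
    )
    return frames, truth


def match_events(
    truth: pd.DataFrame, locs: pd.DataFrame, radius_nm: float = 50.0
) -> pd.DataFrame:
    """Greedy per-frame matching of ground-truth events to localizations.

    Within each frame, the closest (event, localization) pairs are matched
    first; each localization matches at most one event and matches beyond the
    radius are discarded. Returns the truth table with a ``matched`` flag and
    the match error in nm.
    """
    truth = truth.copy()
    truth["matched"] = False
    truth["error_nm"] = np.nan
    for frame, tgrp in truth.groupby("frame"):
        lgrp = locs[locs["frame"] == frame]
        if lgrp.empty:
            continue
        t_xy = tgrp[["x_nm", "y_nm"]].to_numpy()
        l_xy = lgrp[["x_nm", "y_nm"]].to_numpy()
        d = np.linalg.norm(t_xy[:, None, :] - l_xy[None, :, :], axis=2)
        used_t: set[int] = set()
        used_l: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for ti, li in order:
            if d[ti, li] > radius_nm:
                break
            if ti in used_t or li in used_l:
                continue
            used_t.add(int(ti))
            used_l.add(int(li))
            truth.loc[tgrp.index[ti], "matched"] = True
            truth.loc[tgrp.index[ti], "error_nm"] = d[ti, li]
    return truth


# ---------------------------------------------------------------------------
# point patterns


@dataclass
class PatternSimConfig:
    """CSR or disk-cluster point pattern in a rectangular window."""

    window: tuple[float, float, float, float] = (0.0, 0.0, 5000.0, 5000.0)
    mode: str = "csr"  # csr | disk-clusters
    n: int = 1000
    n_clusters: int = 10
    cluster_radius_nm: float = 200.0
    points_per_cluster: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise ValueError("window must have positive area")
        if self.mode not in ("csr", "disk-clusters"):
            raise ValueError("mode must be 'csr' or 'disk-clusters'")
        if self.mode == "csr" and self.n < 1:
            raise ValueError("need n >= 1")
        if self.mode == "disk-clusters" and self.cluster_radius_nm <= 0:
            raise ValueError("cluster radius must be positive")


def _disk_points(
    rng: np.random.Generator, center: np.ndarray, radius: float, k: int
) -> np.ndarray:
    r = radius * np.sqrt(rng.random(k))
    theta = rng.uniform(0, 2 * math.pi, k)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_pattern(config: PatternSimConfig) -> PointPattern:
    """CSR: i.i.d. uniform points. Disk clusters: cluster centers uniform in
    the radius-inset window, members uniform on the disk (all points stay
    inside the window)."""
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.window
    if config.mode == "csr":
        pts = np.column_stack(
            [rng.uniform(x0, x1, config.n), rng.uniform(y0, y1, config.n)]
        )
        return PointPattern(pts, config.window)
    r = config.cluster_radius_nm
    if x1 - x0 < 2 * r or y1 - y0 < 2 * r:
        raise ValueError("window too small for the cluster radius")
    centers = np.column_stack(
        [
            rng.uniform(x0 + r, x1 - r, config.n_clusters),
            rng.uniform(y0 + r, y1 - r, config.n_clusters),
        ]
    )
    pts = np.vstack(
        [_disk_points(rng, c, r, config.points_per_cluster) for c in centers]
    )
    return PointPattern(pts, config.window)


# ---------------------------------------------------------------------------
# dual-color scenes


@dataclass
class SceneSimConfig:
    """Dual-color cluster pairs with commanded center offsets.

    Pair k consists of a red cluster and a green cluster whose centers are
    ``offsets_nm[k]`` apart (along +x); offset 0 gives concentric pairs and
    offsets beyond the radii plus rendering-kernel support give disjoint
    rendered footprints. Pair anchor centers are laid out on a coarse grid so
    pairs never interact.
    """

    offsets_nm: tuple[float, ...] = (0.0, 150.0, 300.0, 600.0)
    radius_red_nm: float = 150.0
    radius_green_nm: float = 150.0
    molecules_per_cluster: int = 80
    render_pixel_nm: float = 20.0
    uncertainty_nm: float = 20.0
    pair_spacing_nm: float = 2500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.radius_red_nm, self.radius_green_nm) <= 0:
            raise ValueError("radii must be positive")
        if self.molecules_per_cluster < 1:
            raise ValueError("counts must be >= 1")


def scene_overlap_label(config: SceneSimConfig, offset: float) -> str:
    support = 5 * config.render_pixel_nm  # truncated rendering kernel half-width * 2
    if offset == 0:
        return "concentric"
    if offset >= config.radius_red_nm + config.radius_green_nm + support:
        return "disjoint"
    return "offset"


def simulate_scene(
    config: SceneSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two localization tables (red, green) plus a ground-truth pair table
    with commanded offsets and overlap labels."""
    rng = np.random.default_rng(config.seed)
    n_pairs = len(config.offsets_nm)
    per_row = max(1, int(math.ceil(math.sqrt(n_pairs))))
    margin = config.pair_spacing_nm / 2
    red_rows, green_rows, truth_rows = [], [], []
    for k, offset in enumerate(config.offsets_nm):
        gx = margin + (k % per_row) * config.pair_spacing_nm
        gy = margin + (k // per_row) * config.pair_spacing_nm
        red_center = np.array([gx, gy])
        green_center = np.array([gx + offset, gy])
        red_pts = _disk_points(rng, red_center, config.radius_red_nm,
                               config.molecules_per_cluster)
        green_pts = _disk_points(rng, green_center, config.radius_green_nm,
                                 config.molecules_per_cluster)
        for pts, rows, ch in ((red_pts, red_rows, "red"), (green_pts, green_rows, "green")):
            for x, y in pts:
                rows.append(
                    {"x_nm": x, "y_nm": y, "frame": 0, "channel": ch,
                     "uncertainty_nm": config.uncertainty_nm, "pair_id": k}
                )
        truth_rows.append(
            {
                "pair_id": k,
                "offset_nm": offset,
                "red_x_nm": red_center[0], "red_y_nm": red_center[1],
                "green_x_nm": green_center[0], "green_y_nm": green_center[1],
                "label": scene_overlap_label(config, offset),
            }
        )
    return pd.DataFrame(red_rows), pd.DataFrame(green_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# binary shapes


@dataclass
class ShapeSpec:
    """One shape on the canvas: family ∈ {disk, ellipse, rectangle, star} with
    family-specific size parameters (pixels) and a placement center."""

    family: str
    center_px: tuple[float, float]
    radius: float = 10.0  # disk
    semi_axes: tuple[float, float] = (12.0, 6.0)  # ellipse (a, b)
    size: tuple[int, int] = (10, 10)  # rectangle (w, h)
    n_points: int = 5  # star
    r_outer: float = 12.0
    r_inner: float = 5.0
    rotation_deg: float = 0.0


@dataclass
class ShapeSimConfig:
    canvas_px: tuple[int, int] = (256, 256)  # (h, w)
    shapes: tuple[ShapeSpec, ...] = ()
    cell_center_px: tuple[float, float] | None = None
    cell_radius_px: float | None = None
    seed: int = 0


def _star_vertices(spec: ShapeSpec) -> np.ndarray:
    cx, cy = spec.center_px
    angles = np.arange(2 * spec.n_points) * math.pi / spec.n_points - math.pi / 2
    angles = angles + math.radians(spec.rotation_deg)
    radii = np.where(np.arange(2 * spec.n_points) % 2 == 0, spec.r_outer, spec.r_inner)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def _polygon_area_perimeter(vertices: np.ndarray) -> tuple[float, float]:
    x, y = vertices[:, 0], vertices[:, 1]
    area = 0.5 * abs(
        np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    )  # shoelace
    perim = float(np.linalg.norm(np.roll(vertices, -1, axis=0) - vertices, axis=1).sum())
    return float(area), perim


def _analytic_area_perimeter(spec: ShapeSpec) -> tuple[float, float]:
    if spec.family == "disk":
        return math.pi * spec.radius**2, 2 * math.pi * spec.radius
    if spec.family == "ellipse":
        a, b = spec.semi_axes
        a, b = max(a, b), min(a, b)
        ecc2 = 1.0 - (b / a) ** 2
        return math.pi * a * b, float(4 * a * ellipe(ecc2))
    if spec.family == "rectangle":
        w, h = spec.size
        return float(w * h), float(2 * (w + h))
    if spec.family == "star":
        return _polygon_area_perimeter(_star_vertices(spec))
    raise ValueError(f"unknown shape family {spec.family!r}")


def _rasterize(spec: ShapeSpec, canvas: tuple[int, int]) -> np.ndarray:
    h, w = canvas
    yy, xx = np.mgrid[0:h, 0:w]
    # pixel-center sampling
    px = xx + 0.5
    py = yy + 0.5
    cx, cy = spec.center_px
    if spec.family == "disk":
        return (px - cx) ** 2 + (py - cy) ** 2 <= spec.radius**2
    if spec.family == "ellipse":
        a, b = spec.semi_axes
        th = math.radians(spec.rotation_deg)
        u = (px - cx) * math.cos(th) + (py - cy) * math.sin(th)
        v = -(px - cx) * math.sin(th) + (py - cy) * math.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.family == "rectangle":
        rw, rh = spec.size
        return (np.abs(px - cx) <= rw / 2) & (np.abs(py - cy) <= rh / 2)
    if spec.family == "star":
        from skimage.draw import polygon2mask

        verts = _star_vertices(spec)
        return polygon2mask((h, w), np.column_stack([verts[:, 1], verts[:, 0]]))
    raise ValueError(f"unknown shape family {spec.family!r}")


def simulate_shapes(config: ShapeSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize the configured shapes onto a label canvas.

    Returns (label image, truth table) where the truth table carries each
    shape's analytic area, analytic perimeter and — when the cell geometry is
    configured — the ground-truth normalized radial distance of its center.
    """
    h, w = config.canvas_px
    labels = np.zeros((h, w), dtype=int)
    rows = []
    for i, spec in enumerate(config.shapes, start=1):
        mask = _rasterize(spec, (h, w))
        if not mask.any():
            raise ValueError(f"shape {i} rasterized to nothing")
        edge_rows, edge_cols = np.nonzero(mask)
        if (edge_rows.min() == 0 or edge_cols.min() == 0
                or edge_rows.max() == h - 1 or edge_cols.max() == w - 1):
            raise ValueError(f"shape {i} touches the canvas edge")
        if np.any(labels[mask] != 0):
            raise ValueError(f"shape {i} overlaps an earlier shape")
        labels[mask] = i
        area, perim = _analytic_area_perimeter(spec)
        r_norm = float("nan")
        if config.cell_center_px is not None and config.cell_radius_px:
            d = math.hypot(
                spec.center_px[0] - config.cell_center_px[0],
                spec.center_px[1] - config.cell_center_px[1],
            )
            r_norm = d / config.cell_radius_px
        rows.append(
            {
                "label": i,
                "family": spec.family,
                "area_true": area,
                "perimeter_true": perim,
                "r_norm_true": r_norm,
                "area_px": int(mask.sum()),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["label", "family", "area_true", "perimeter_true", "r_norm_true", "area_px"],
    )
    return labels, truth
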