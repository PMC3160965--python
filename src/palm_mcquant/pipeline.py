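"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` executes simulate → localize → render → (colocalization |
Ripley | shape) on fully synthetic inputs, writes every stage product under
the output directory, echoes the effective configuration next to the outputs
and finishes with a manifest of output files and SHA-256 checksums so reruns
with the same config are auditable (identical checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .colocalization import DualChannelImage, association_fractions, evaluate_pairs
from .localization import ImageStack, ThresholdSet, localize_stack, render_palm
from .morphology import CellGeometry, measure_shapes, radial_circularity_profile
from .spatial import PointPattern, analyze_pattern, identify_clusters
from .synth import (
    FrameSimConfig,
    PatternSimConfig,
    SceneSimConfig,
    simulate_pattern,
    simulate_scene,
    simulate_stack,
)

__all__ = ["RunConfig", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    """Stage selection and parameters for one reproducible run."""

    out_dir: str
    seed: int
    stages: tuple[str, ...] = ("localize", "coloc", "ripley", "shape")
    # localization stage
    n_frames: int = 200
    n_emitters: int = 20
    t1: float = 16.0  # ≈ 5σ shot noise for the default 10-count background
    pixel_nm: float = 160.0
    palm_pixel_nm: float = 20.0
    # coloc / shape stage
    scene_offsets_nm: tuple[float, ...] = (0.0, 100.0, 250.0, 400.0, 800.0)
    cluster_area_threshold_px: int = 50
    # ripley stage
    ripley_n: int = 1000
    ripley_mode: str = "disk-clusters"
    mc_steps: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in data:
            raise ValueError("config must set an explicit seed")
        if "out_dir" not in data:
            raise ValueError("config must set out_dir")
        for key in ("stages", "scene_offsets_nm"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def demo_config(out_dir: str, seed: int = 1) -> RunConfig:
    return RunConfig(out_dir=out_dir, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_localize(cfg: RunConfig, out: Path, report: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    h = w = 64
    margin = 5 * cfg.pixel_nm
    pos = np.column_stack(
        [
            rng.uniform(margin, w * cfg.pixel_nm - margin, cfg.n_emitters),
            rng.uniform(margin, h * cfg.pixel_nm - margin, cfg.n_emitters),
        ]
    )
    sim = FrameSimConfig(
        image_size=(h, w), pixel_nm=cfg.pixel_nm, positions_nm=pos,
        n_frames=cfg.n_frames, seed=cfg.seed,
    )
    frames, truth = simulate_stack(sim)
    pio.write_stack(out / "stack.tif", frames)
    truth.to_csv(out / "stack_truth.csv", index=False)
    stack = ImageStack(frames=frames.astype(float), pixel_nm=cfg.pixel_nm)
    locs = localize_stack(stack, ThresholdSet(t1=cfg.t1))
    pio.write_localizations(out / "localizations.csv", locs)
    rendered = render_palm(locs, cfg.palm_pixel_nm)
    pio.write_rendered(out / "rendered.tif", rendered)
    report["localize"] = {"events_true": int(len(truth)), "localized": int(len(locs))}


def _scene_products(cfg: RunConfig):
    scfg = SceneSimConfig(offsets_nm=cfg.scene_offsets_nm, seed=cfg.seed)
    red_locs, green_locs, truth = simulate_scene(scfg)
    extent_nm = max(
        red_locs[["x_nm", "y_nm"]].to_numpy().max(),
        green_locs[["x_nm", "y_nm"]].to_numpy().max(),
    ) + 10 * scfg.render_pixel_nm
    npx = int(np.ceil(extent_nm / scfg.render_pixel_nm))
    red_img = render_palm(red_locs, scfg.render_pixel_nm, shape=(npx, npx), channel="red")
    green_img = render_palm(green_locs, scfg.render_pixel_nm, shape=(npx, npx), channel="green")
    return scfg, red_locs, green_locs, truth, red_img, green_img


def _stage_coloc(cfg: RunConfig, out: Path, report: dict) -> None:
    scfg, red_locs, green_locs, truth, red_img, green_img = _scene_products(cfg)
    truth.to_csv(out / "scene_truth.csv", index=False)
    pio.write_rendered(out / "scene_red.tif", red_img)
    pio.write_rendered(out / "scene_green.tif", green_img)
    red_cm = identify_clusters(red_img.pixels, scfg.render_pixel_nm,
                               cfg.cluster_area_threshold_px)
    green_cm = identify_clusters(green_img.pixels, scfg.render_pixel_nm,
                                 cfg.cluster_area_threshold_px)
    dual = DualChannelImage.from_rendered(red_img, green_img)
    results = evaluate_pairs(dual, red_cm, green_cm, max_distance_nm=1000.0)
    pd.DataFrame([vars(r) for r in results]).to_csv(out / "coloc_pairs.csv", index=False)
    fracs = association_fractions(results)
    pd.DataFrame([fracs]).to_csv(out / "coloc_fractions.csv", index=False)
    report["coloc"] = {"n_pairs": len(results), **{k: round(v, 4) for k, v in fracs.items()}}


def _stage_ripley(cfg: RunConfig, out: Path, report: dict) -> None:
    pcfg = PatternSimConfig(
        mode=cfg.ripley_mode, n=cfg.ripley_n,
        n_clusters=10, points_per_cluster=cfg.ripley_n // 10, seed=cfg.seed,
    )
    pattern = simulate_pattern(pcfg)
    res = analyze_pattern(pattern, steps=cfg.mc_steps, seed=cfg.seed + 1)
    pd.DataFrame(
        {"r_nm": res.r, "K": res.k, "L_minus_r": res.l_minus_r,
         "normalized": res.normalized}
    ).to_csv(out / "ripley_curve.csv", index=False)
    report["ripley"] = {
        "n": pattern.n, "ci99_nm": res.ci99,
        "r_max_nm": res.r_max if res.r_max is not None else "none",
    }


def _stage_shape(cfg: RunConfig, out: Path, report: dict) -> None:
    scfg, red_locs, green_locs, truth, red_img, green_img = _scene_products(cfg)
    cm = identify_clusters(red_img.pixels, scfg.render_pixel_nm,
                           cfg.cluster_area_threshold_px)
    extent = red_img.pixels.shape[0] * scfg.render_pixel_nm
    geom = CellGeometry(center_nm=(extent / 2, extent / 2), radius_nm=extent / 2)
    shapes = measure_shapes(cm.labels, scfg.render_pixel_nm, geometry=geom,
                            intensity=red_img.pixels)
    pd.DataFrame([vars(s) for s in shapes]).to_csv(out / "shapes.csv", index=False)
    if shapes:
        prof = radial_circularity_profile(shapes)
        pd.DataFrame(
            {"bin_center": prof.bin_centers, "mean_C": prof.mean,
             "sem": prof.sem, "n": prof.counts}
        ).to_csv(out / "shape_radial_profile.csv", index=False)
    report["shape"] = {"n_clusters": len(shapes)}


_STAGES = {
    "localize": _stage_localize,
    "coloc": _stage_coloc,
    "ripley": _stage_ripley,
    "shape": _stage_shape,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns the run report (also written to
    ``report.json``). Raises RuntimeError naming the failing stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            _STAGES[stage](config, out, report)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    # config.yaml is a provenance echo (it embeds out_dir) and is excluded so
    # manifests of identical runs in different directories compare equal
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "config.yaml")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    report["manifest"] = manifest
    return report
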