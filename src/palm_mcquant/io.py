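"""File I/O: TIFF stacks and rendered images, localization and trace CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localization import LOC_COLUMNS, ImageStack, RenderedImage
from .photophysics import DecayTrace

__all__ = [
    "read_stack",
    "write_stack",
    "read_rendered",
    "write_rendered",
    "read_localizations",
    "write_localizations",
    "read_traces",
    "write_trace",
]


def write_stack(path: str | Path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(frames).astype(np.uint16))


def read_stack(path: str | Path, pixel_nm: float, frame_interval_s: float = 0.1) -> ImageStack:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames.astype(float), pixel_nm=pixel_nm,
                      frame_interval_s=frame_interval_s)


def write_rendered(path: str | Path, image: RenderedImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_rendered(path: str | Path, pixel_nm: float, channel: str = "") -> RenderedImage:
    return RenderedImage(pixels=tifffile.imread(str(path)).astype(float),
                         pixel_nm=pixel_nm, channel=channel)


def write_localizations(path: str | Path, locs: pd.DataFrame) -> None:
    locs.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"localization CSV missing columns: {missing}")
    for col in LOC_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "channel" else np.nan
    return df


def write_trace(path: str | Path, trace: DecayTrace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "fluorescence": trace.fluorescence,
            "intensity": trace.intensity,
            "wavelength_nm": trace.wavelength_nm,
            "probe": trace.probe,
        }
    ).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[DecayTrace]:
    """Read one or more decay traces from a CSV with columns time_s,
    fluorescence, intensity, wavelength_nm, probe (grouped by intensity and
    probe)."""
    df = pd.read_csv(path)
    traces = []
    keys = [c for c in ("probe", "intensity") if c in df.columns]
    groups = df.groupby(keys) if keys else [((), df)]
    for _, grp in groups:
        traces.append(
            DecayTrace(
                time_s=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                intensity=float(grp["intensity"].iloc[0]) if "intensity" in grp else 1.0,
                wavelength_nm=float(grp["wavelength_nm"].iloc[0]) if "wavelength_nm" in grp else float("nan"),
                probe=str(grp["probe"].iloc[0]) if "probe" in grp else "",
            )
        )
    return traces
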