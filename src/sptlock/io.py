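"""File formats: TIFF stacks, CSV tables, YAML configuration.

Interchange formats are deliberately plain: multi-page TIFF for image
stacks (one file per spectral channel), CSV with headers for localization,
trajectory and event tables, YAML for run configuration and JSON for
summaries.  Acquisition metadata (pixel size, frame interval) rarely
survives in TIFF tags, so it is supplied through the configuration and
attached on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import FrameStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_localizations",
    "write_localizations",
    "read_config",
    "write_summary",
]

LOCALIZATION_COLUMNS = [
    "frame", "x_um", "y_um", "precision_um", "intensity", "background",
    "channel",
]


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channel: str = "A",
) -> FrameStack:
    """Read a single-channel multi-page TIFF into a :class:`FrameStack`.

    ``pixel_size`` (um) and ``frame_interval`` (s) must be provided when
    absent from the file metadata.
    """
    path = Path(path)
    try:
        pixels = tifffile.imread(path)
    except Exception as exc:  # corrupt or truncated file
        raise ValueError(f"cannot parse TIFF stack {path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError(f"cannot parse TIFF stack {path}: no image data")
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack of identically sized "
            f"pages, got shape {pixels.shape}"
        )
    if pixel_size is None or frame_interval is None:
        raise ValueError(
            "pixel_size and frame_interval are required; supply them via the "
            "configuration (TIFF tags are not trusted for acquisition metadata)"
        )
    return FrameStack(pixels.astype(float), pixel_size, frame_interval, channel)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path), stack.pixels.astype(np.float32), photometric="minisblack"
    )


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"frame", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table lacks columns: {sorted(missing)}")
    return df


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)


def read_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return cfg


def write_summary(summary: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
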