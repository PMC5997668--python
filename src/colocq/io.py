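"""File formats: multi-page TIFF stacks and localization CSV tables.

The localization CSV dialect is ``frame,x_nm,y_nm,precision_nm,photons,
channel``; readers tolerate extra columns (carried through as opaque
extras) and writers round-trip tables bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .paint_locs import REQUIRED_COLUMNS, LocalizationTable
from .save_imaging import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_localizations",
    "write_localizations",
    "write_json",
]


def read_stack(path: str | Path, pixel_nm: float = 160.0) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    The pixel size comes from the caller/config; TIFF metadata is not
    required. Single-page files become one-frame stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt / truncated file
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2D pages, got array of shape {data.shape}")
    return ImageStack(data.astype(float), pixel_nm)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a multi-page 16-bit TIFF (values clipped to range)."""
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


def read_localizations(
    path: str | Path, channel_id: str = "", roi: tuple | None = None
) -> LocalizationTable:
    """Read a localization CSV; unknown columns are retained.

    Raises a schema error naming any missing required column and a
    validation error (with row index) for non-positive precisions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such localization table: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if not channel_id and "channel" in df.columns and len(df):
        channel_id = str(df["channel"].iloc[0])
    return LocalizationTable(df=df, channel_id=channel_id, roi=roi)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write the table as CSV (full float precision, round-trip safe)."""
    df = table.df.copy()
    if "channel" not in df.columns and table.channel_id:
        df["channel"] = table.channel_id
    df.to_csv(Path(path), index=False, float_format="%.17g")


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON output (sorted keys, stable float repr)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
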