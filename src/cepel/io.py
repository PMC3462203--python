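"""File input/output: CSV tables, grayscale images, label maps, JSON results.

Tables are read with pandas behind a dialect sniffer (comma, semicolon or tab
delimited; header row required; blanks and "NA" are missing).  Images are
8-bit grayscale PNG or PGM handled through Pillow, returned as float rasters
in [0, 255]; label maps round-trip as 16-bit PNG.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .kde1d import ValidationError

__all__ = [
    "read_table",
    "write_table",
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
]

_NA_VALUES = ["", "NA", "na", "NaN", "nan", "N/A"]


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table with a header row.

    The delimiter is sniffed among comma, semicolon and tab; numeric columns
    are coerced with blanks/"NA" as missing, everything else stays as text.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        sample = path.open("r", encoding="utf-8-sig").read(8192)
    except UnicodeDecodeError as exc:
        raise IOError(f"{path} is not a text file: {exc}") from exc
    if not sample.strip():
        raise IOError(f"{path} is empty")
    try:
        dialect = csv.Sniffer().sniff(sample, delimiters=",;\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    try:
        df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES,
                         keep_default_na=False, skipinitialspace=True,
                         encoding="utf-8-sig", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise IOError(f"{path}: no columns found")
    return df


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    # repr-precision floats so a write/read round trip is lossless
    pd.DataFrame(df).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/PGM as a float raster in [0, 255]."""
    with Image.open(path) as im:
        if im.mode == "L":
            return np.asarray(im, dtype=float)
        if im.mode in ("P", "1"):
            return np.asarray(im.convert("L"), dtype=float)
        raise IOError(
            f"{path}: unsupported image mode {im.mode!r} "
            "(8-bit grayscale required; convert color images first)")


def write_image(raster: np.ndarray, path) -> None:
    """Write a float raster in [0, 255] (or [0, 1], auto-scaled) as 8-bit
    grayscale; the format follows the file suffix (PNG or PGM)."""
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("raster must be 2-d")
    if arr.size and arr.max() <= 1.0 and arr.min() >= 0.0:
        arr = arr * 255.0
    img = Image.fromarray(np.clip(np.round(arr), 0, 255).astype(np.uint8), "L")
    img.save(path)


def read_label_map(path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("I", "I;16", "L"):
            raise IOError(f"{path}: not a label map (mode {im.mode!r})")
        return np.asarray(im, dtype=np.int64)


def write_label_map(labels: np.ndarray, path) -> None:
    """Label maps are stored as 16-bit PNG (region ids up to 65535)."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValidationError("label map must be 2-d")
    if arr.min() < 0 or arr.max() > 65535:
        raise ValidationError("label ids must lie in [0, 65535]")
    Image.fromarray(arr.astype(np.uint16)).save(path)
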