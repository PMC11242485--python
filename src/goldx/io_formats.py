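"""MRC tilt-stack and marker-table I/O.

All downstream modules work on in-memory :class:`TiltSeries` objects and
pandas marker tables; this module is the only place that touches files.

Conventions
-----------
* Coordinates are 0-based ``(row y, column x)`` with the origin at the
  top-left corner of each 2D section.
* Gold beads are assumed DARKER than the surrounding ice/carbon (bright-field
  TEM contrast).  Stacks stored with the opposite contrast are handled by the
  ``polarity`` parameter of the processing pipeline, not here.
* Stacks are written as 32-bit float MRC2014 regardless of the input mode so
  that statistics-matched replacement patches are not quantized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import mrcfile
import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, ParameterError

MARKER_COLUMNS = ["tilt_index", "y", "x", "score", "label"]


@dataclass
class TiltSeries:
    """A tilt series: ``n_tilts`` aligned 2D projections of one specimen area.

    Parameters
    ----------
    data
        Intensity stack of shape ``(n_tilts, ny, nx)``; dark = high electron
        density in the canonical orientation.
    pixel_size_angstrom
        Pixel size in Angstrom per pixel (> 0).
    tilt_angles_deg
        Optional goniometer angles, one per tilt.
    source_path
        Where the stack came from, if read from disk.
    """

    data: np.ndarray
    pixel_size_angstrom: float
    tilt_angles_deg: Optional[np.ndarray] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ParameterError(
                f"tilt series data must be 2D or 3D, got ndim={self.data.ndim}"
            )
        n, ny, nx = self.data.shape
        if n < 1 or ny < 16 or nx < 16:
            raise ParameterError(
                f"tilt series too small: shape {self.data.shape} "
                "(need n_tilts >= 1 and images of at least 16 x 16)"
            )
        if not self.pixel_size_angstrom > 0:
            raise ParameterError(
                f"pixel size must be positive, got {self.pixel_size_angstrom}"
            )
        if self.tilt_angles_deg is not None:
            self.tilt_angles_deg = np.asarray(self.tilt_angles_deg, dtype=float)
            if self.tilt_angles_deg.shape != (n,):
                raise ParameterError(
                    f"tilt_angles_deg has length {self.tilt_angles_deg.size}, "
                    f"expected {n}"
                )

    @property
    def n_tilts(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape


def read_tilt_series(
    path, pixel_size_override: Optional[float] = None
) -> TiltSeries:
    """Read an MRC image or stack into a :class:`TiltSeries`.

    A single 2D image is promoted to a 1-image stack.  The pixel size is
    taken from the MRC header voxel size unless ``pixel_size_override`` is
    given, which always wins.
    """
    path = Path(path)
    try:
        with mrcfile.open(str(path), permissive=True) as mrc:
            data = np.asarray(mrc.data, dtype=np.float32).copy()
            header_px = float(mrc.voxel_size.x)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header, truncated file, ...
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    if data.ndim not in (2, 3):
        raise FormatError(
            f"{path}: expected a 2D image or 3D stack, got ndim={data.ndim}"
        )
    if pixel_size_override is not None:
        if not pixel_size_override > 0:
            raise ParameterError(
                f"pixel_size_override must be positive, got {pixel_size_override}"
            )
        pixel_size = float(pixel_size_override)
    elif header_px > 0:
        pixel_size = header_px
    else:
        raise ParameterError(
            f"{path}: MRC header has no usable pixel size "
            f"({header_px}); pass an explicit pixel size"
        )
    return TiltSeries(data=data, pixel_size_angstrom=pixel_size,
                      source_path=str(path))


def write_tilt_series(series: TiltSeries, path) -> None:
    """Write a :class:`TiltSeries` as a 32-bit float MRC stack."""
    path = Path(path)
    try:
        with mrcfile.new(str(path), overwrite=True) as mrc:
            mrc.set_data(np.ascontiguousarray(series.data, dtype=np.float32))
            mrc.voxel_size = series.pixel_size_angstrom
    except OSError as exc:
        raise OSError(f"cannot write MRC file {path}: {exc}") from exc


def write_label_stack(labels: np.ndarray, pixel_size_angstrom: float, path) -> None:
    """Write an integer label stack (watershed/dilated masks) as MRC."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    with mrcfile.new(str(Path(path)), overwrite=True) as mrc:
        mrc.set_data(np.ascontiguousarray(labels, dtype=np.int16))
        mrc.voxel_size = pixel_size_angstrom


def empty_marker_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tilt_index": pd.Series(dtype=int),
            "y": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "score": pd.Series(dtype=float),
            "label": pd.Series(dtype=int),
        }
    )


def write_marker_table(table: pd.DataFrame, path) -> None:
    """Write a marker table as CSV, rows sorted by (tilt_index, label)."""
    if len(table) == 0:
        out = empty_marker_table()
    else:
        out = table[MARKER_COLUMNS].sort_values(
            ["tilt_index", "label"], kind="stable"
        )
    out.to_csv(Path(path), index=False)


def read_marker_table(path) -> pd.DataFrame:
    """Read a marker CSV written by :func:`write_marker_table`."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read marker table {path}: {exc}") from exc
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing marker columns {missing}")
    table = table[MARKER_COLUMNS].copy()
    table["tilt_index"] = table["tilt_index"].astype(int)
    table["label"] = table["label"].astype(int)
    return table


def write_overlay_png(
    image: np.ndarray,
    markers: pd.DataFrame,
    path,
    radius: float = 8.0,
) -> None:
    """Render an 8-bit min-max scaled image with red circles at markers.

    A file-based substitute for inspecting location maps in a GUI viewer.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    gray = ((img - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _, row in markers.iterrows():
        r = np.hypot(yy - float(row["y"]), xx - float(row["x"]))
        ring = np.abs(r - radius) < 1.0
        rgb[ring] = (255, 40, 40)
    Image.fromarray(rgb).save(str(Path(path)))
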