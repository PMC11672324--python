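"""Shared containers and file I/O for wound-repair movie analysis.

The two in-memory objects every stage exchanges:

``Movie``
    A calibrated multi-channel time-lapse stack.  Channel 0 carries the
    membrane-impermeable wound dye (influx reports an open wound), channel 1
    the fluorescent event marker rendered as diffraction-limited punctae.
    All geometry is physical (µm); pixels appear only in the raster itself.

``PunctaSet``
    The detected punctate objects of one frame: label, centroid (µm) and
    area (µm²), optionally backed by the frame's label image so that
    mask-overlap colocalization can be computed downstream.

Coordinate convention: pixel centers sit at integer pixel positions, the
origin is the image corner, ``x`` indexes columns and ``y`` rows; everything
reported to the user is in µm (0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Movie",
    "PunctaSet",
    "read_movie",
    "write_movie",
    "punctae_to_frame",
    "write_punctae_csv",
    "read_punctae_csv",
]


@dataclass
class Movie:
    """Calibrated multi-channel time-lapse stack with wound metadata.

    Parameters
    ----------
    data:
        Intensity array indexed ``[frame, channel, y, x]``.
    pixel_size:
        Lateral calibration in µm/pixel (isotropic).
    frame_interval:
        Time between frames in seconds.
    wound_frame:
        Index of the first post-wound frame (so ``wound_frame`` pre-wound
        frames precede it).
    wound_center:
        Wound ROI center ``(x, y)`` in µm.
    wound_area:
        Wound ROI area in µm².
    cell_mask:
        Optional binary image (y, x) marking the wounded cell's footprint.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    wound_frame: int
    wound_center: tuple[float, float]
    wound_area: float
    cell_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("movie data must be [frame, channel, y, x]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0 <= self.wound_frame <= self.n_frames):
            raise ValueError("wound_frame outside the recorded movie")
        x, y = self.wound_center
        h, w = self.data.shape[2:]
        if not (0 <= x <= w * self.pixel_size and 0 <= y <= h * self.pixel_size):
            raise ValueError("wound_center outside the image bounds")
        if self.wound_area < 0:
            raise ValueError("wound_area must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, t = 0 at the wound frame."""
        return (np.arange(self.n_frames) - self.wound_frame) * self.frame_interval


@dataclass
class PunctaSet:
    """Detected punctae of a single frame.

    ``table`` has one row per puncta with columns ``label`` (unique within
    the frame), ``x_um``, ``y_um`` and ``area_um2``.  ``labels_image`` is
    the integer label raster the table was derived from, kept when the
    mask-overlap colocalization rule will be applied.
    """

    frame: int
    table: pd.DataFrame
    labels_image: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        required = {"label", "x_um", "y_um", "area_um2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"puncta table missing columns {sorted(missing)}")
        labels = self.table["label"].to_numpy()
        if len(labels) != len(np.unique(labels)):
            raise ValueError("puncta labels must be unique within a frame")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        """Centroids as an (n, 2) array of (x, y) in µm."""
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)


def write_movie(path: str | Path, movie: Movie) -> Path:
    """Write a movie as multi-page OME-TIFF (dimension order TCYX).

    Pixel size and frame interval are stored in the OME metadata so a
    round-trip through :func:`read_movie` preserves the calibration.
    Wound metadata travels in a JSON sidecar next to the TIFF.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        movie.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TCYX",
            "PhysicalSizeX": movie.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": movie.frame_interval,
            "TimeIncrementUnit": "s",
        },
    )
    sidecar = {
        "wound_frame": int(movie.wound_frame),
        "wound_center_um": [float(movie.wound_center[0]), float(movie.wound_center[1])],
        "wound_area_um2": float(movie.wound_area),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if movie.cell_mask is not None:
        tifffile.imwrite(
            path.with_name(path.stem + "_cellmask.tif"),
            movie.cell_mask.astype(np.uint8),
        )
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a movie written by :func:`write_movie` (OME-TIFF + sidecar)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome = tif.ome_metadata
    if data.ndim == 3:  # single channel stored as TYX
        data = data[:, None]
    pixel_size = 1.0
    frame_interval = 1.0
    if ome:
        import re

        m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', ome)
        if m:
            pixel_size = float(m.group(1))
        m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', ome)
        if m:
            frame_interval = float(m.group(1))
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    mask_path = path.with_name(path.stem + "_cellmask.tif")
    cell_mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return Movie(
        data=data,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        wound_frame=int(meta.get("wound_frame", 0)),
        wound_center=tuple(meta.get("wound_center_um", (0.0, 0.0))),
        wound_area=float(meta.get("wound_area_um2", 0.0)),
        cell_mask=cell_mask,
    )


def punctae_to_frame(punctae: Sequence[PunctaSet]) -> pd.DataFrame:
    """Stack per-frame puncta tables into one long table with a frame column."""
    parts = []
    for ps in punctae:
        if len(ps) == 0:  # all-empty frames would poison concat dtypes
            continue
        t = ps.table.copy()
        t.insert(0, "frame", ps.frame)
        parts.append(t)
    if not parts:
        return pd.DataFrame(columns=["frame", "label", "x_um", "y_um", "area_um2"])
    return pd.concat(parts, ignore_index=True)


def write_punctae_csv(path: str | Path, punctae: Sequence[PunctaSet]) -> Path:
    path = Path(path)
    punctae_to_frame(punctae).to_csv(path, index=False)
    return path


def read_punctae_csv(path: str | Path) -> list[PunctaSet]:
    df = pd.read_csv(path)
    out = []
    for frame, grp in df.groupby("frame", sort=True):
        out.append(
            PunctaSet(frame=int(frame), table=grp.drop(columns="frame").reset_index(drop=True))
        )
    return out
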