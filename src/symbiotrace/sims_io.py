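"""Data model and I/O for ion-count images, compartment masks, and ROI tables.

nanoSIMS acquisitions are rasters of integer secondary-ion counts, one raster
per mass channel. This module defines the in-memory containers used throughout
the package and lossless readers/writers for two plain interchange formats:
multi-page TIFF (one page per channel) and whitespace-separated text matrices
(one file per channel). ROI quantification tables are written as CSV.

Raster convention: row-major, 0-based, origin at the top-left; pixels are
squares of side ``pixel_size`` micrometres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Recognised mass channels: CN- isotopologues carry the nitrogen signal,
#: C2- isotopologues the carbon signal, 32S- tracks protein abundance.
KNOWN_CHANNELS = ("C14N", "C15N", "C2", "C13C", "S32")

#: Compartment classes shared by masks, ground truth, and ROI tables.
CLASS_BACKGROUND = 0
CLASS_HOST_N = 1
CLASS_HOST_MINUS_N = 2
CLASS_DIAZOPLAST = 3

CLASS_NAMES: dict[int, str] = {
    CLASS_BACKGROUND: "background",
    CLASS_HOST_N: "host_N",
    CLASS_HOST_MINUS_N: "host_minusN",
    CLASS_DIAZOPLAST: "diazoplast",
}
CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}


class SimsIOError(ValueError):
    """Raised on malformed images, masks, or tables."""


@dataclass
class IonCountImage:
    """Multi-channel integer ion-count raster on a common grid.

    Parameters
    ----------
    data
        Mapping of channel name to 2-D integer count array. All channels must
        share a shape; counts must be non-negative integers.
    pixel_size
        Pixel edge length in micrometres.
    metadata
        Free-form key/value annotation (cell id, acquisition notes, ...).
    """

    data: dict[str, np.ndarray]
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data:
            raise SimsIOError("image must contain at least one channel")
        shapes = set()
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.data.items():
            if name not in KNOWN_CHANNELS:
                raise SimsIOError(f"unknown channel name: {name!r}")
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise SimsIOError(f"channel {name}: expected 2-D raster")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.mod(arr, 1) == 0):
                    raise SimsIOError(f"channel {name}: non-integer counts")
                arr = arr.astype(np.int64)
            if arr.min(initial=0) < 0:
                raise SimsIOError(f"channel {name}: negative counts")
            shapes.add(arr.shape)
            clean[name] = arr.astype(np.int64, copy=False)
        if len(shapes) != 1:
            raise SimsIOError(f"channels disagree on shape: {sorted(shapes)}")
        if self.pixel_size <= 0:
            raise SimsIOError("pixel_size must be positive")
        self.data = clean

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.data.values())).shape

    def counts(self, channel: str) -> np.ndarray:
        if channel not in self.data:
            raise SimsIOError(f"channel {channel!r} not present")
        return self.data[channel]

    def has_channel(self, channel: str) -> bool:
        return channel in self.data


@dataclass
class CompartmentMask:
    """Pixel-wise compartment classification of one image.

    ``labels`` holds the class code per pixel (see ``CLASS_NAMES``);
    ``provenance`` records the segmentation parameters that produced it.
    """

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SimsIOError("label raster must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise SimsIOError("label raster must be integer")
        unknown = set(np.unique(self.labels)) - set(self.class_map)
        if unknown:
            raise SimsIOError(f"labels outside class map: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_pixels(self, name: str) -> np.ndarray:
        """Boolean raster of pixels assigned to class ``name``."""
        return self.labels == CLASS_CODES[name]


@dataclass
class ROI:
    """One connected region of a single compartment class."""

    cell_id: str
    compartment: str
    roi_id: int
    pixels: tuple[np.ndarray, np.ndarray]  # (row indices, col indices)
    pixel_size: float

    @property
    def area_px(self) -> int:
        return int(self.pixels[0].size)

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixels[0].mean()), float(self.pixels[1].mean()))

    @property
    def equivalent_radius_um(self) -> float:
        """Radius of the circle with the same projected area."""
        return math.sqrt(self.area_um2 / math.pi)


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------


def write_image(image: IonCountImage, path: str | Path, format: str = "tiff") -> Path:
    """Write an image as a multi-page TIFF or as one text matrix per channel.

    TIFF layout: one page per channel, channel order and pixel size stored in
    the ImageDescription tag as JSON. Text layout: ``<stem>.<channel>.txt``
    files of whitespace-separated integers next to ``path``.
    """
    path = Path(path)
    if format == "tiff":
        desc = json.dumps(
            {
                "channels": list(image.channels),
                "pixel_size_um": image.pixel_size,
                "metadata": image.metadata,
            }
        )
        stack = np.stack([image.data[c] for c in image.channels]).astype(np.int32)
        tifffile.imwrite(path, stack, description=desc)
        return path
    if format == "text":
        for ch in image.channels:
            np.savetxt(path.with_suffix(f".{ch}.txt"), image.data[ch], fmt="%d")
        sidecar = {
            "channels": list(image.channels),
            "pixel_size_um": image.pixel_size,
            "metadata": image.metadata,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
        return path
    raise SimsIOError(f"unknown format {format!r}")


def read_image(
    path: str | Path,
    format: str | None = None,
    channels: Sequence[str] | None = None,
    pixel_size: float | None = None,
) -> IonCountImage:
    """Read an ion-count image written by :func:`write_image`.

    ``format`` is inferred from the suffix when omitted. ``channels`` overrides
    the channel names embedded in the file metadata; it is required for bare
    TIFF stacks that carry no description.
    """
    path = Path(path)
    if format is None:
        format = "text" if path.suffix in {".txt", ".yaml"} else "tiff"
    if format == "tiff":
        if not path.exists():
            raise SimsIOError(f"no such file: {path}")
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        meta: dict = {}
        if channels is None:
            if not desc:
                raise SimsIOError("TIFF carries no channel metadata; pass channels=")
            info = json.loads(desc)
            channels = info["channels"]
            pixel_size = pixel_size or info.get("pixel_size_um", 1.0)
            meta = info.get("metadata", {})
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != len(channels):
            raise SimsIOError(
                f"{stack.shape[0]} pages but {len(channels)} channel names"
            )
        data = {c: stack[i] for i, c in enumerate(channels)}
        return IonCountImage(data, pixel_size or 1.0, meta)
    if format == "text":
        side = path.with_suffix(".yaml")
        meta: dict = {}
        if channels is None:
            if not side.exists():
                raise SimsIOError("text image needs a YAML sidecar or channels=")
            info = yaml.safe_load(side.read_text())
            channels = info["channels"]
            pixel_size = pixel_size or info.get("pixel_size_um", 1.0)
            meta = info.get("metadata", {})
        data = {}
        for ch in channels:
            f = path.with_suffix(f".{ch}.txt")
            if not f.exists():
                raise SimsIOError(f"missing channel file {f}")
            arr = np.loadtxt(f, ndmin=2)
            data[ch] = arr
        return IonCountImage(data, pixel_size or 1.0, meta)
    raise SimsIOError(f"unknown format {format!r}")


def write_mask(mask: CompartmentMask, path: str | Path) -> Path:
    """Write a compartment mask as a single-page TIFF with class-map JSON."""
    path = Path(path)
    desc = json.dumps(
        {
            "class_map": {str(k): v for k, v in mask.class_map.items()},
            "provenance": mask.provenance,
        }
    )
    tifffile.imwrite(path, mask.labels.astype(np.uint8), description=desc)
    return path


def read_mask(path: str | Path) -> CompartmentMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray().astype(np.int64)
        desc = tif.pages[0].description
    info = json.loads(desc) if desc else {}
    class_map = {int(k): v for k, v in info.get("class_map", {}).items()} or dict(
        CLASS_NAMES
    )
    return CompartmentMask(labels, class_map, info.get("provenance", {}))


# ---------------------------------------------------------------------------
# ROI tables
# ---------------------------------------------------------------------------

_ROI_COLUMNS = [
    "cell_id",
    "roi_id",
    "compartment",
    "area_px",
    "area_um2",
    "counts_C14N",
    "counts_C15N",
    "counts_C2",
    "counts_C13C",
    "counts_S32",
    "atom15N_pct",
    "se15N_pct",
    "atom13C_pct",
    "se13C_pct",
    "enriched_15N",
    "enriched_13C",
]


def write_roi_table(rois: Iterable, quants: Iterable, path: str | Path) -> Path:
    """Write one CSV row per ROI pairing geometry with isotope quantification.

    ``rois`` and ``quants`` must be parallel sequences (one quant per ROI).
    Duplicate (cell_id, roi_id, compartment) keys are rejected.
    """
    rois = list(rois)
    quants = list(quants)
    if len(rois) != len(quants):
        raise SimsIOError(f"{len(rois)} ROIs but {len(quants)} quants")
    rows = []
    for roi, q in zip(rois, quants):
        row = {
            "cell_id": roi.cell_id,
            "roi_id": roi.roi_id,
            "compartment": roi.compartment,
            "area_px": roi.area_px,
            "area_um2": roi.area_um2,
        }
        for ch in KNOWN_CHANNELS:
            row[f"counts_{ch}"] = q.counts.get(ch, np.nan)
        row["atom15N_pct"] = q.atom15N_pct
        row["se15N_pct"] = q.se15N_pct
        row["atom13C_pct"] = q.atom13C_pct
        row["se13C_pct"] = q.se13C_pct
        row["enriched_15N"] = q.enriched_15N
        row["enriched_13C"] = q.enriched_13C
        rows.append(row)
    df = pd.DataFrame(rows, columns=_ROI_COLUMNS)
    if not df.empty:
        keys = df[["cell_id", "roi_id", "compartment"]]
        if keys.duplicated().any():
            raise SimsIOError("duplicate (cell, ROI) keys in table")
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read an ROI quantification CSV back into a DataFrame."""
    df = pd.read_csv(path)
    missing = set(_ROI_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise SimsIOError(f"ROI table missing columns: {sorted(missing)}")
    return df


def write_yaml(obj: Mapping, path: str | Path) -> Path:
    Path(path).write_text(yaml.safe_dump(dict(obj), sort_keys=True))
    return Path(path)


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
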