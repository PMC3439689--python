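"""Micrograph input/output.

Reads merged RGB fluorescence micrographs (TIFF/PNG, 8- or 16-bit), splits
them into channel planes, and writes the analysis artifacts: rasterized
overlay renderings for visual QC and the per-colony results CSV.

All intensities live on a [0, 1] scale regardless of the source bit depth;
per-channel thresholds are specified on that scale. Coordinates are 0-based
(row, col) with row 0 at the top, everywhere (centroids included).
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import imageio.v3 as iio
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guards for type checkers
    from .calibration import CalibrationModel, NucleusRecord
    from .mhc_mapping import MhcRegion
    from .metrics import ColonyMetrics

logger = logging.getLogger("myocfc")

#: Exact column order of the per-colony results CSV.
RESULTS_COLUMNS = (
    "image_id",
    "total_nuclei",
    "stain_negative_nuclei",
    "mhc_positive_nuclei",
    "df",
    "ui",
    "mono_count",
    "bi_count",
    "multi_count",
)

# Overlay palette: MHC+ cytoplasm is red; DAPI+ regions are colored by size
# class following the calibration histogram (single / doublet-scale / larger).
OVERLAY_MHC = (255, 0, 0)
OVERLAY_SINGLE = (0, 0, 255)
OVERLAY_DOUBLET = (0, 255, 0)
OVERLAY_LARGER = (255, 255, 0)


class Channel(Enum):
    """Fluorescence channel of interest in a merged RGB micrograph."""

    DAPI_BLUE = "dapi_blue"
    MHC_RED = "mhc_red"


class DecodeError(ValueError):
    """Raised when an image file cannot be decoded as an RGB raster."""


class ChannelError(ValueError):
    """Raised when an input lacks the channel structure the analysis needs."""


class ConsistencyError(ValueError):
    """Raised when two pieces of per-image data disagree on dimensions."""


class CsvFormatError(ValueError):
    """Raised when an existing results CSV has an incompatible header."""


@dataclass(frozen=True)
class Micrograph:
    """A merged RGB micrograph with intensities normalized to [0, 1].

    Blue encodes the DAPI nuclear counterstain, red the sarcomeric-myosin
    (MHC) immunostain. The green plane is carried along untouched.
    """

    image_id: str
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image_id must be non-empty")
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ConsistencyError("channel planes must share identical dimensions")
        for plane in (self.red, self.green, self.blue):
            if plane.ndim != 2:
                raise ConsistencyError("channel planes must be 2D")

    @property
    def height(self) -> int:
        return self.blue.shape[0]

    @property
    def width(self) -> int:
        return self.blue.shape[1]


@dataclass(frozen=True)
class ChannelPlane:
    """One channel cut from a parent micrograph."""

    channel: Channel
    pixels: np.ndarray
    source_image_id: str


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Linear map from the source integer range onto [0, 1]."""
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    if np.issubdtype(raw.dtype, np.floating):
        arr = raw.astype(np.float64)
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise DecodeError("float image intensities must already lie in [0, 1]")
        return arr
    raise DecodeError(f"unsupported pixel dtype {raw.dtype!r}")


def read_micrograph(path: str | os.PathLike) -> Micrograph:
    """Read an RGB raster into a :class:`Micrograph`.

    Intensities are scaled to [0, 1] by dividing by the bit-depth maximum of
    the source file. Grayscale inputs are rejected (no blue/red separation is
    possible); an RGBA alpha plane is dropped with a logged warning.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder backends vary
        raise DecodeError(f"cannot decode image file {path}") from exc
    if raw.ndim == 2:
        raise ChannelError(
            f"{path} is grayscale; merged RGB input is required to separate "
            "the DAPI (blue) and MHC (red) channels"
        )
    if raw.ndim != 3 or raw.shape[2] not in (3, 4):
        raise DecodeError(f"{path}: expected an RGB(A) raster, got shape {raw.shape}")
    if raw.shape[2] == 4:
        logger.warning("%s: RGBA input, alpha plane dropped", path)
        raw = raw[:, :, :3]
    norm = _normalize(raw)
    return Micrograph(
        image_id=path.stem,
        red=norm[:, :, 0],
        green=norm[:, :, 1],
        blue=norm[:, :, 2],
    )


def write_micrograph(m: Micrograph, path: str | os.PathLike) -> None:
    """Write a micrograph as an 8-bit RGB raster (PNG or TIFF by extension)."""
    stacked = np.stack([m.red, m.green, m.blue], axis=-1)
    iio.imwrite(Path(path), np.round(stacked * 255.0).astype(np.uint8))


def extract_channel(m: Micrograph, channel: Channel) -> ChannelPlane:
    """Cut the requested analysis plane out of a micrograph.

    Returns the plane untouched (a copy, so downstream filtering never
    mutates the parent); no cross-channel mixing or unmixing is attempted —
    clean separation of the stains into their channels is an assumption of
    the method, not something it enforces.
    """
    if channel is Channel.DAPI_BLUE:
        pixels = m.blue
    elif channel is Channel.MHC_RED:
        pixels = m.red
    else:  # pragma: no cover - exhaustive over the enum
        raise ValueError(f"unknown channel {channel!r}")
    return ChannelPlane(channel=channel, pixels=pixels.copy(), source_image_id=m.image_id)


def _size_class_color(record: "NucleusRecord") -> tuple[int, int, int]:
    if record.in_first_peak:
        return OVERLAY_SINGLE
    rounded = int(np.floor(record.nuclear_quantity + 0.5))
    return OVERLAY_DOUBLET if rounded <= 2 else OVERLAY_LARGER


def render_overlay(
    m: Micrograph,
    nuclei: Sequence["NucleusRecord"],
    mhc: Sequence["MhcRegion"],
    size_classes: "CalibrationModel | None" = None,
) -> np.ndarray:
    """Rasterize the analysis of one colony as an RGB image for visual QC.

    MHC+ cytoplasm is painted red; DAPI+ regions are painted on top, colored
    by calibrated size class (blue = single nucleus, green = doublet-scale,
    yellow = larger clump); background stays black.
    """
    out = np.zeros((m.height, m.width, 3), dtype=np.uint8)
    for region in mhc:
        coords = region.region.coords
        if coords.size and (
            coords[:, 0].max() >= m.height or coords[:, 1].max() >= m.width
        ):
            raise ConsistencyError("MHC region extends beyond the micrograph")
        out[coords[:, 0], coords[:, 1]] = OVERLAY_MHC
    for record in nuclei:
        coords = record.region.coords
        if coords.size and (
            coords[:, 0].max() >= m.height or coords[:, 1].max() >= m.width
        ):
            raise ConsistencyError("nucleus region extends beyond the micrograph")
        out[coords[:, 0], coords[:, 1]] = _size_class_color(record)
    return out


def _metrics_row(metrics: "ColonyMetrics") -> list[str]:
    return [
        metrics.image_id,
        repr(float(metrics.total_nuclei)),
        repr(float(metrics.stain_negative_nuclei)),
        repr(float(metrics.mhc_positive_nuclei)),
        repr(float(metrics.df)),
        repr(float(metrics.ui)),
        str(metrics.mono_count),
        str(metrics.bi_count),
        str(metrics.multi_count),
    ]


def append_results_csv(path: str | os.PathLike, metrics: "ColonyMetrics") -> None:
    """Append one colony's metrics to the batch results CSV.

    Creates the file with a header row on first use; on subsequent calls the
    existing header is checked and a mismatch refuses the append rather than
    silently producing a ragged file.
    """
    path = Path(path)
    header = ",".join(RESULTS_COLUMNS)
    if path.exists() and path.stat().st_size > 0:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            existing = fh.readline().strip()
        if existing != header:
            raise CsvFormatError(
                f"{path} has header {existing!r}, expected {header!r}"
            )
        mode = "a"
    else:
        mode = "w"
    with open(path, mode, encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        if mode == "w":
            writer.writerow(RESULTS_COLUMNS)
        writer.writerow(_metrics_row(metrics))


def read_results_csv(path: str | os.PathLike):
    """Read a results CSV back into a pandas DataFrame (full float precision)."""
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")
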