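"""Dataset-wide nuclear-size calibration.

Connected DAPI+ regions vary widely in size: a narrow low-area peak of bona
fide single nuclei is followed by a broader peak of doublets/triplets and a
long tail of larger clumps of overlapping nuclei. The calibration pools the
areas of every DAPI+ region across *all* images of a batch into one
histogram, identifies the first peak (the single-nucleus mode), and takes
the mean area within that peak as the size of one nucleus.

Nuclear quantities are then assigned per region: regions whose area falls
inside the first-peak bounds count as exactly 1 nucleus; every other region
— smaller debris as well as larger clumps — is counted as its area divided
by the mean single-nucleus area. The quotient is kept fractional; rounding
happens only later, when fibers are classified as mono/bi/multinucleated.

The primary mode is user-selected peak bounds (chosen by inspecting the
histogram); an automatic first-peak finder is provided for unattended runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .segmentation import LabeledRegion

logger = logging.getLogger("myocfc")


class CalibrationError(ValueError):
    """Raised when no usable single-nucleus population can be identified."""


class CalibrationSource(Enum):
    USER_BOUNDS = "user_bounds"
    AUTO = "auto"


@dataclass(frozen=True)
class AreaHistogram:
    """Histogram of DAPI+ region areas pooled across an image ensemble."""

    bin_edges: np.ndarray  # length n_bins + 1, increasing
    counts: np.ndarray  # length n_bins, non-negative ints
    total_regions: int

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        if int(self.counts.sum()) != self.total_regions:
            raise ValueError("counts must sum to total_regions")


@dataclass(frozen=True)
class CalibrationModel:
    """First-peak bounds and the mean single-nucleus area they enclose."""

    first_peak_lower: float
    first_peak_upper: float
    mean_single_area: float
    n_singles: int
    source: CalibrationSource

    def __post_init__(self) -> None:
        if not 0 < self.first_peak_lower <= self.first_peak_upper:
            raise ValueError("require 0 < first_peak_lower <= first_peak_upper")
        if not (
            self.first_peak_lower <= self.mean_single_area <= self.first_peak_upper
        ):
            raise ValueError("mean_single_area must lie within the peak bounds")
        if self.n_singles < 1:
            raise ValueError("n_singles must be >= 1")


@dataclass
class NucleusRecord:
    """One DAPI+ region with its calibrated nuclear quantity.

    ``nuclear_quantity`` is exactly 1 for in-peak regions and the fractional
    area ratio otherwise. ``assigned_mhc_label`` is filled in by the MHC
    mapping stage (None = stain-negative).
    """

    region: LabeledRegion
    nuclear_quantity: float
    in_first_peak: bool
    assigned_mhc_label: Optional[int] = None


def _region_areas(regions: Iterable[LabeledRegion | int | float]) -> np.ndarray:
    areas = [
        float(r.area_px) if isinstance(r, LabeledRegion) else float(r)
        for r in regions
    ]
    return np.asarray(areas, dtype=np.float64)


def build_area_histogram(
    regions: Sequence[LabeledRegion | int | float], bin_width: int = 10
) -> AreaHistogram:
    """Bin the pooled region areas of the whole dataset.

    Calibration is explicitly dataset-wide: ``regions`` should contain every
    DAPI+ region from every image of the batch, not one image's worth.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    areas = _region_areas(regions)
    if areas.size == 0:
        raise CalibrationError("no DAPI+ regions found")
    lo = np.floor(areas.min() / bin_width) * bin_width
    hi = np.floor(areas.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width, dtype=np.float64)
    counts, _ = np.histogram(areas, bins=edges)
    return AreaHistogram(
        bin_edges=edges, counts=counts.astype(np.int64), total_regions=int(areas.size)
    )


def _auto_peak_bounds(hist: AreaHistogram) -> tuple[float, float]:
    """Locate the first peak of the smoothed histogram.

    Counts are smoothed with a 5-bin moving average — wide enough to ride
    over the spikes that quantized region areas put into narrow bins — then
    the first local maximum scanning upward from small areas is taken as the
    single-nucleus mode, and the peak is extended outward to the nearest
    enclosing local minima (or the histogram ends).
    """
    counts = hist.counts.astype(np.float64)
    if len(counts) == 1:
        logger.warning(
            "degenerate single-bin area histogram; peak bounds set to the bin span"
        )
        return float(hist.bin_edges[0]), float(hist.bin_edges[1])
    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    peak = len(smooth) - 1
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i + 1 < len(smooth) else -np.inf
        if smooth[i] > left and smooth[i] >= right:
            peak = i
            break
    lo = peak
    while lo > 0 and smooth[lo - 1] <= smooth[lo]:
        lo -= 1
    hi = peak
    while hi + 1 < len(smooth) and smooth[hi + 1] <= smooth[hi]:
        hi += 1
    return float(hist.bin_edges[lo]), float(hist.bin_edges[hi + 1])


def fit_calibration(
    hist: AreaHistogram,
    user_bounds: Optional[tuple[float, float]] = None,
    raw_areas: Optional[Sequence[float]] = None,
) -> CalibrationModel:
    """Fit the single-nucleus size model from the pooled area ensemble.

    With ``user_bounds`` the given (lower, upper) limits are used exactly —
    ideally the sizes of the smallest and largest single nucleus, chosen by
    the user from the histogram. Without them the first peak is located
    automatically. ``mean_single_area`` is the arithmetic mean of the raw
    areas inside the bounds (inclusive); if raw areas are not supplied, bin
    midpoints weighted by counts are used as a fallback.
    """
    if user_bounds is not None:
        lower, upper = float(user_bounds[0]), float(user_bounds[1])
        if lower > upper:
            raise ValueError(f"peak bounds out of order: ({lower}, {upper})")
        source = CalibrationSource.USER_BOUNDS
    else:
        lower, upper = _auto_peak_bounds(hist)
        source = CalibrationSource.AUTO

    if raw_areas is not None and len(raw_areas) > 0:
        areas = np.asarray(raw_areas, dtype=np.float64)
        inside = areas[(areas >= lower) & (areas <= upper)]
        if inside.size == 0:
            raise CalibrationError(
                f"no region areas fall inside the first-peak bounds "
                f"({lower}, {upper})"
            )
        mean_single = float(inside.mean())
        n_singles = int(inside.size)
    else:
        mids = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        sel = (mids >= lower) & (mids <= upper)
        weights = hist.counts[sel]
        if weights.sum() == 0:
            raise CalibrationError(
                f"no histogram mass inside the first-peak bounds ({lower}, {upper})"
            )
        mean_single = float(np.average(mids[sel], weights=weights))
        n_singles = int(weights.sum())
    # the mean of inside-areas is within the bounds by construction; clip
    # guards only against float round-off at the edges
    mean_single = float(np.clip(mean_single, lower, upper))
    return CalibrationModel(
        first_peak_lower=lower,
        first_peak_upper=upper,
        mean_single_area=mean_single,
        n_singles=n_singles,
        source=source,
    )


def assign_nuclear_quantities(
    regions: Sequence[LabeledRegion],
    model: CalibrationModel,
    min_area: int = 0,
) -> List[NucleusRecord]:
    """Assign each DAPI+ region its probabilistic nuclear quantity.

    In-peak regions get quantity exactly 1. Every out-of-peak region —
    whether smaller (debris fragments) or larger (overlapping clumps) — gets
    its area divided by the mean single-nucleus area, unrounded. Regions
    with area below ``min_area`` are discarded outright (optional debris
    filter, off by default).
    """
    if model.mean_single_area <= 0:
        raise ValueError("mean_single_area must be positive")
    records: List[NucleusRecord] = []
    for region in regions:
        if region.area_px < min_area:
            continue
        in_peak = model.first_peak_lower <= region.area_px <= model.first_peak_upper
        quantity = 1.0 if in_peak else region.area_px / model.mean_single_area
        records.append(
            NucleusRecord(
                region=region, nuclear_quantity=quantity, in_first_peak=in_peak
            )
        )
    return records


def histogram_to_csv(hist: AreaHistogram, path) -> None:
    """Write the area histogram as CSV (bin_lower, bin_upper, count)."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_lower", "bin_upper", "count"])
        for i, count in enumerate(hist.counts):
            writer.writerow(
                [repr(float(hist.bin_edges[i])), repr(float(hist.bin_edges[i + 1])), int(count)]
            )


def plot_histogram(
    hist: AreaHistogram, path, model: Optional[CalibrationModel] = None
) -> None:
    """Render the area histogram as a PNG for the bound-selection workflow."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.counts, width=widths, align="edge",
           color="steelblue", edgecolor="white")
    if model is not None:
        ax.axvspan(model.first_peak_lower, model.first_peak_upper,
                   color="orange", alpha=0.25, label="first peak")
        ax.axvline(model.mean_single_area, color="red", lw=1,
                   label="mean single-nucleus area")
        ax.legend()
    ax.set_xlabel("DAPI+ region area (px)")
    ax.set_ylabel("count")
    ax.set_title("DAPI+ region size distribution (dataset-wide)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
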