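"""MHC+ region detection and nucleus-to-cytoplasm mapping.

The red channel (sarcomeric myosin heavy chain, detected via an Alexa Fluor
555 secondary) is segmented with the same open/threshold/label pipeline as
the nuclear channel, with its own radius and threshold — dim MHC stains are
handled by lowering the red-channel threshold.

A nucleus belongs to an MHC+ cytoplasm iff the *centroid* of its DAPI+
region falls inside the MHC+ area: the geometric center decides, even when
the DAPI+ area only partially overlaps the cytoplasm. Per MHC+ region the
assigned nuclear quantities are summed (unrounded) into the probabilistic
estimate of its nucleus count, and each region is classified as anucleate,
mono-, bi- or multinucleated (more than two nuclei — a definitive fusion
product, since binucleated cells could merely be dividing).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Sequence, Tuple

import numpy as np

from .image_io import Channel, ChannelPlane, ConsistencyError
from .calibration import NucleusRecord
from .segmentation import LabeledRegion, SegmentationParams, segment_channel


class FiberClass(Enum):
    ANUCLEATE = "anucleate"
    MONO = "mono"
    BI = "bi"
    MULTI = "multi"


@dataclass
class MhcRegion:
    """One MHC+ cytoplasmic region with its estimated nucleus content."""

    region: LabeledRegion
    nuclei_total: float
    member_nucleus_labels: List[int]
    fiber_class: FiberClass


def detect_mhc_regions(
    plane: ChannelPlane, params: SegmentationParams
) -> List[LabeledRegion]:
    """Segment MHC+ areas from the red channel.

    Same pipeline as nuclear segmentation (open, threshold, label) with the
    red channel's independent R and T.
    """
    if plane.channel is not Channel.MHC_RED:
        raise ValueError(f"expected the MHC_RED plane, got {plane.channel}")
    return segment_channel(plane, params)


def _round_half_up(x: float) -> int:
    """Round to nearest integer, exact halves toward the larger value."""
    return int(np.floor(x + 0.5))


def classify_fiber(nuclei_total: float) -> FiberClass:
    """Mono/bi/multinucleated classification of an MHC+ region.

    The fractional nucleus estimate is rounded half-up first; more than two
    nuclei means a definitive fusion product (MULTI).
    """
    n = _round_half_up(nuclei_total)
    if n <= 0:
        return FiberClass.ANUCLEATE
    if n == 1:
        return FiberClass.MONO
    if n == 2:
        return FiberClass.BI
    return FiberClass.MULTI


def assign_nuclei_to_mhc(
    nuclei: Sequence[NucleusRecord],
    mhc_regions: Sequence[LabeledRegion],
    mhc_label_image: np.ndarray,
) -> Tuple[List[NucleusRecord], List[MhcRegion]]:
    """Map nuclear centroids onto the MHC label grid and total per region.

    Each nucleus whose centroid (rounded to the nearest pixel, half toward
    the larger index) lands on a labeled MHC pixel is assigned that label;
    centroids on background stay unassigned (stain-negative). Every MHC
    region gets the sum of its members' nuclear quantities and a fiber
    class; a region with no centroids is ANUCLEATE.

    Assignment is a pure label lookup, so it is independent of the order in
    which nuclei or regions are enumerated.
    """
    mhc_label_image = np.asarray(mhc_label_image)
    if mhc_label_image.ndim != 2:
        raise ConsistencyError("MHC label image must be 2D")
    h, w = mhc_label_image.shape
    for nucleus in nuclei:
        coords = nucleus.region.coords
        if coords.size and (coords[:, 0].max() >= h or coords[:, 1].max() >= w):
            raise ConsistencyError(
                "nucleus coordinates exceed the MHC label image dimensions"
            )

    totals: dict[int, float] = {r.label: 0.0 for r in mhc_regions}
    members: dict[int, List[int]] = {r.label: [] for r in mhc_regions}
    for nucleus in nuclei:
        row = _round_half_up(nucleus.region.centroid[0])
        col = _round_half_up(nucleus.region.centroid[1])
        row = min(max(row, 0), h - 1)
        col = min(max(col, 0), w - 1)
        label = int(mhc_label_image[row, col])
        if label > 0:
            nucleus.assigned_mhc_label = label
            totals[label] += nucleus.nuclear_quantity
            members[label].append(nucleus.region.label)
        else:
            nucleus.assigned_mhc_label = None

    out: List[MhcRegion] = []
    for region in mhc_regions:
        total = totals[region.label]
        out.append(
            MhcRegion(
                region=region,
                nuclei_total=total,
                member_nucleus_labels=members[region.label],
                fiber_class=classify_fiber(total),
            )
        )
    return list(nuclei), out
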