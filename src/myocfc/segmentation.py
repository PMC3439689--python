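"""Channel segmentation: opening, thresholding, connected components.

One channel plane becomes a list of labeled foreground regions in three
steps, run in this order:

1. grayscale morphological opening with a flat disk of radius ``R``
   (suppresses background noise and features narrower than the disk);
2. strict value thresholding at ``T`` (foreground iff intensity > T);
3. 8-connected component labeling with per-region area, centroid and a
   traced outer boundary.

The disk structuring element is the exact Euclidean disk (all offsets with
distance <= R from the center), not a decomposed approximation. Regions
touching the image border are retained; interior holes do not count toward
a region's area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from skimage import measure, morphology

from .image_io import Channel, ChannelPlane


@dataclass(frozen=True)
class SegmentationParams:
    """Per-channel segmentation settings (set independently per stain)."""

    radius_R: int
    threshold_T: float
    channel: Channel

    def __post_init__(self) -> None:
        if self.radius_R < 0:
            raise ValueError(f"radius_R must be >= 0, got {self.radius_R}")
        if not 0.0 <= self.threshold_T <= 1.0:
            raise ValueError(
                f"threshold_T must lie in [0, 1], got {self.threshold_T}"
            )


# Clockwise Moore neighborhood starting north, for boundary tracing.
_MOORE = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


def _trace_boundary(coords: np.ndarray) -> np.ndarray:
    """Moore-neighbor trace of a region's outer boundary.

    Returns ordered (row, col) member pixels along the outer perimeter,
    starting from the topmost-leftmost pixel and proceeding clockwise.
    """
    rmin = int(coords[:, 0].min())
    cmin = int(coords[:, 1].min())
    local = coords - (rmin, cmin)
    h = int(local[:, 0].max()) + 1
    w = int(local[:, 1].max()) + 1
    mask = np.zeros((h + 2, w + 2), dtype=bool)  # 1-px pad: no bounds checks
    mask[local[:, 0] + 1, local[:, 1] + 1] = True

    rs, cs = np.nonzero(mask)
    start = (int(rs[0]), int(cs[0]))  # first in raster order -> west is bg
    if len(rs) == 1:
        return np.array([[start[0] - 1 + rmin, start[1] - 1 + cmin]])

    boundary = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    for _ in range(8 * len(rs) + 8):  # safety bound; trace always terminates
        d = (backtrack[0] - cur[0], backtrack[1] - cur[1])
        i = _MOORE.index(d)
        nxt = None
        for k in range(1, 9):
            j = (i + k) % 8
            cand = (cur[0] + _MOORE[j][0], cur[1] + _MOORE[j][1])
            if mask[cand]:
                nxt = cand
                backtrack = (
                    cur[0] + _MOORE[(i + k - 1) % 8][0],
                    cur[1] + _MOORE[(i + k - 1) % 8][1],
                )
                break
        if nxt is None:
            break  # isolated pixel (unreachable: handled above)
        move = (cur, nxt)
        if cur == start:
            if first_move is None:
                first_move = move
            elif move == first_move:
                break  # closed the loop with the same entry move
        if nxt != start:
            boundary.append(nxt)
        cur = nxt
    pts = np.asarray(boundary, dtype=np.int64)
    # de-duplicate revisits (a 1-px spur is walked twice) but keep order
    _, first_idx = np.unique(pts, axis=0, return_index=True)
    keep = np.zeros(len(pts), dtype=bool)
    keep[np.sort(first_idx)] = True
    pts = pts[keep]
    return pts + (rmin - 1, cmin - 1)


@dataclass
class LabeledRegion:
    """One 8-connected foreground component.

    ``centroid`` is the unweighted mean of member pixel (row, col)
    coordinates. ``boundary`` is the Moore-traced outer perimeter, computed
    lazily on first access.
    """

    label: int
    area_px: int
    centroid: tuple[float, float]
    coords: np.ndarray
    _boundary: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def boundary(self) -> np.ndarray:
        if self._boundary is None:
            self._boundary = _trace_boundary(self.coords)
        return self._boundary


def remove_background(plane: ChannelPlane, radius_R: int) -> ChannelPlane:
    """Grayscale morphological opening with a flat Euclidean disk of radius R.

    Erosion followed by dilation: bright features narrower than the disk are
    suppressed while larger structures keep their intensity. R = 0 is the
    identity. Output intensities stay within [0, 1].
    """
    if radius_R < 0:
        raise ValueError(f"radius_R must be >= 0, got {radius_R}")
    if radius_R == 0:
        return ChannelPlane(plane.channel, plane.pixels.copy(), plane.source_image_id)
    footprint = morphology.disk(radius_R)  # Euclidean disk: ||offset|| <= R
    opened = morphology.opening(plane.pixels, footprint=footprint)
    return ChannelPlane(plane.channel, opened, plane.source_image_id)


def threshold_plane(plane: ChannelPlane, threshold_T: float) -> np.ndarray:
    """Binary foreground mask: pixel is foreground iff intensity > T (strict).

    T = 0 marks every strictly positive pixel; T = 1 yields an empty mask.
    """
    if not 0.0 <= threshold_T <= 1.0:
        raise ValueError(f"threshold_T must lie in [0, 1], got {threshold_T}")
    return plane.pixels > threshold_T


def label_regions(mask: np.ndarray) -> List[LabeledRegion]:
    """Label all 8-connected foreground components of a binary mask.

    Labels run 1..K with no gaps, in raster order of first encounter.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    mask = mask.astype(bool)
    lbl = measure.label(mask, connectivity=2)
    n = int(lbl.max())
    if n == 0:
        return []
    flat = lbl.ravel()
    idx = np.flatnonzero(flat)
    vals = flat[idx]
    order = np.argsort(vals, kind="stable")
    idx = idx[order]
    vals = vals[order]
    rows, cols = np.unravel_index(idx, mask.shape)
    counts = np.bincount(vals, minlength=n + 1)[1:]
    starts = np.concatenate(([0], np.cumsum(counts)))
    regions: List[LabeledRegion] = []
    for k in range(n):
        sl = slice(starts[k], starts[k + 1])
        r = rows[sl]
        c = cols[sl]
        regions.append(
            LabeledRegion(
                label=k + 1,
                area_px=int(counts[k]),
                centroid=(float(r.mean()), float(c.mean())),
                coords=np.column_stack((r, c)).astype(np.int64),
            )
        )
    return regions


def segment_channel(
    plane: ChannelPlane, params: SegmentationParams
) -> List[LabeledRegion]:
    """Full per-channel pipeline: open (grayscale), threshold, label."""
    if params.channel is not plane.channel:
        raise ValueError(
            f"params are for {params.channel}, plane is {plane.channel}"
        )
    opened = remove_background(plane, params.radius_R)
    mask = threshold_plane(opened, params.threshold_T)
    return label_regions(mask)


def regions_to_label_image(
    regions: List[LabeledRegion], shape: tuple[int, int]
) -> np.ndarray:
    """Paint labeled regions back into a dense label grid (0 = background)."""
    out = np.zeros(shape, dtype=np.int32)
    for region in regions:
        out[region.coords[:, 0], region.coords[:, 1]] = region.label
    return out
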