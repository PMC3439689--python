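"""Independent brute-force oracles used by the test suite.

These deliberately avoid scikit-image and the package's own code paths:
labeling is a hand-written BFS flood fill, the opening reference applies
erosion/dilation directly from their min/max definitions, and confidence
intervals come from the closed-form t formula.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

_NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_regions(mask: np.ndarray) -> list[dict]:
    """8-connected components by BFS; returns area and centroid per region.

    Regions are reported in raster order of their first (topmost-leftmost)
    pixel, matching a raster-scan labeling.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    regions = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            pixels = []
            while queue:
                r, c = queue.popleft()
                pixels.append((r, c))
                for dr, dc in _NEIGHBORS_8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            regions.append(
                {
                    "area": len(pixels),
                    "centroid": (sum(rows) / len(rows), sum(cols) / len(cols)),
                    "pixels": frozenset(pixels),
                }
            )
    return regions


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Exact Euclidean disk: all offsets with distance <= radius."""
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def reference_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening straight from the definitions.

    Erosion: minimum over the structuring element (border handled by
    padding with +inf so out-of-image samples never win the min); dilation:
    maximum over the reflected element (padding with -inf). Matches the
    flat-structuring-element convention of the fast implementation.
    """
    offsets = disk_offsets(radius)
    h, w = image.shape
    pad = radius
    padded = np.pad(image.astype(np.float64), pad, constant_values=np.inf)
    eroded = np.full((h, w), np.inf)
    for dr, dc in offsets:
        eroded = np.minimum(
            eroded, padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w]
        )
    padded = np.pad(eroded, pad, constant_values=-np.inf)
    dilated = np.full((h, w), -np.inf)
    for dr, dc in offsets:
        dilated = np.maximum(
            dilated, padded[pad - dr : pad - dr + h, pad - dc : pad - dc + w]
        )
    return dilated


def t_interval(values, t_crit: float) -> tuple[float, float]:
    """Closed-form two-sided CI: mean +/- t_crit * s / sqrt(n)."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    hw = t_crit * math.sqrt(var) / math.sqrt(n)
    return mean - hw, mean + hw


def metrics_from_truth_table(nuclei_rows, mhc_counts) -> tuple[float, float]:
    """Recompute D_f and U_i straight from a generator truth table."""
    total = len(nuclei_rows)
    if total == 0:
        return 0.0, 0.0
    inside = sum(1 for n in nuclei_rows if n["in_mhc"])
    fused = sum(
        1 for n in nuclei_rows if n["in_mhc"] and mhc_counts[n["mhc_id"]] > 2
    )
    return inside / total, fused / total
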