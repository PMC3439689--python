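"""Synthetic colony micrographs with exported ground truth.

Emulates the structures the analysis has to cope with: disk-like nuclei with
a unimodal single-nucleus size distribution, doublet/multiplet clusters of
overlapping nuclei that merge into larger DAPI+ regions, contiguous MHC+
cytoplasm polygons enclosing subsets of nuclei, additive Gaussian background
noise and sub-nuclear bright specks (debris). Every generated image comes
with a complete ground-truth table (per-nucleus positions and cluster
structure, per-MHC-region true nucleus counts, true D_f / U_i), so every
pipeline stage can be tested without real micrographs.

Cluster members are spaced 1.35-1.6 mean radii apart: close enough that
their thresholded disks always merge into one DAPI+ region (centers are
well under one diameter apart), far enough that a merged k-nucleus region
keeps an area close to k single areas, as real moderately-overlapping
nuclei clumps do.

Rendering is deterministic under a fixed seed, and intensities are
quantized to the 8-bit grid so that writing to PNG and reading back is
lossless.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.draw import polygon as draw_polygon

from .image_io import Micrograph, write_micrograph

_MAX_TURN = math.radians(30)  # chain turn limit: keeps overlaps pairwise


class GenerationError(RuntimeError):
    """Raised when a colony cannot be packed into the requested image."""


@dataclass(frozen=True)
class SyntheticColonySpec:
    """Generative parameters for one synthetic colony image.

    Defaults describe a moderately dense colony on a 384x384 field: ~20
    isolated nuclei, a handful of doublets and small multiplets, two MHC+
    cytoplasm regions capturing about half the nuclei, mild sensor noise
    and a few sub-nuclear debris specks.
    """

    seed: int = 0
    height: int = 384
    width: int = 384
    n_singles: int = 20
    n_doublets: int = 5
    n_multiplets: int = 2
    multiplet_size_min: int = 3
    multiplet_size_max: int = 4
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 0.5
    n_mhc_regions: int = 2
    mhc_region_radius: float = 70.0
    fraction_nuclei_in_mhc: float = 0.5
    nucleus_intensity: float = 0.8
    mhc_intensity: float = 0.7
    background_noise_sd: float = 0.02
    speck_count: int = 5
    # member spacing within a cluster, in units of the mean member radius;
    # the default produces clearly merged regions with moderate overlap,
    # (1.7, 1.9) approximates overlap-clean doublets whose area ~ 2 singles
    cluster_spacing: Tuple[float, float] = (1.35, 1.6)
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("n_singles", "n_doublets", "n_multiplets", "speck_count",
                     "n_mhc_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_nuclei_in_mhc <= 1.0:
            raise ValueError("fraction_nuclei_in_mhc must lie in [0, 1]")
        if self.nucleus_radius_mean <= 1.0:
            raise ValueError("nucleus_radius_mean must exceed 1 px")
        if not 2 <= self.multiplet_size_min <= self.multiplet_size_max:
            raise ValueError("need 2 <= multiplet_size_min <= multiplet_size_max")
        lo, hi = self.cluster_spacing
        if not 0.5 <= lo <= hi < 2.0:
            raise ValueError(
                "cluster_spacing must satisfy 0.5 <= lo <= hi < 2.0 "
                "(members must stay close enough to merge)"
            )

    @property
    def resolved_image_id(self) -> str:
        return self.image_id or f"synthetic_{self.seed:05d}"

    @property
    def total_nuclei(self) -> int:
        # multiplet sizes are drawn at generation time; this is the minimum
        return self.n_singles + 2 * self.n_doublets


@dataclass
class GroundTruth:
    """Complete generative truth for one synthetic colony."""

    image_id: str
    # per-nucleus: nucleus_id, row, col, radius, cluster_id, in_mhc, mhc_id
    nuclei: List[dict]
    # per-cluster: cluster_id -> (member count, mhc_id or None)
    clusters: dict
    # per-MHC-region: mhc_id -> true contained-nucleus count
    mhc_counts: dict
    mhc_masks: List[np.ndarray]
    total_nuclei: int
    df_true: float
    ui_true: float


def _cluster_offsets(
    rng: np.random.Generator,
    radii: np.ndarray,
    spacing_range: Tuple[float, float],
) -> np.ndarray:
    """Member-center offsets for one cluster, chained with bounded turns."""
    k = len(radii)
    offsets = np.zeros((k, 2))
    heading = rng.uniform(0.0, 2.0 * math.pi)
    for i in range(1, k):
        spacing = rng.uniform(*spacing_range) * 0.5 * (radii[i - 1] + radii[i])
        if i > 1:
            heading += rng.uniform(-_MAX_TURN, _MAX_TURN)
        offsets[i] = offsets[i - 1] + spacing * np.array(
            [math.sin(heading), math.cos(heading)]
        )
    return offsets - offsets.mean(axis=0)


def _random_blob(
    rng: np.random.Generator, center: Tuple[float, float], radius: float
) -> Polygon:
    """A convex-ish irregular polygon around ``center`` (row, col)."""
    n_vertices = int(rng.integers(8, 13))
    angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, n_vertices))
    radii = radius * rng.uniform(0.7, 1.0, n_vertices)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return Polygon(np.column_stack([cols, rows]))  # shapely is (x, y)


def _place_mhc_polygons(
    rng: np.random.Generator, spec: SyntheticColonySpec
) -> List[Polygon]:
    polygons: List[Polygon] = []
    for _ in range(spec.n_mhc_regions):
        placed = False
        for _ in range(300):
            radius = spec.mhc_region_radius * rng.uniform(0.8, 1.2)
            margin = radius + 4
            if 2 * margin >= min(spec.height, spec.width):
                break
            center = (
                rng.uniform(margin, spec.height - margin),
                rng.uniform(margin, spec.width - margin),
            )
            candidate = _random_blob(rng, center, radius)
            if all(candidate.distance(p) > 8.0 for p in polygons):
                polygons.append(candidate)
                placed = True
                break
        if not placed:
            raise GenerationError(
                "could not place the requested MHC+ regions in the image"
            )
    return polygons


def _soft_disk_paint(
    canvas: np.ndarray, row: float, col: float, radius: float, intensity: float
) -> None:
    """Union-paint a flat disk with a soft 1-px linear edge."""
    h, w = canvas.shape
    r0 = max(int(math.floor(row - radius - 2)), 0)
    r1 = min(int(math.ceil(row + radius + 2)) + 1, h)
    c0 = max(int(math.floor(col - radius - 2)), 0)
    c1 = min(int(math.ceil(col + radius + 2)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dist = np.hypot(rr - row, cc - col)
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = intensity * coverage
    canvas[r0:r1, c0:c1] = np.maximum(canvas[r0:r1, c0:c1], patch)


def generate_colony(spec: SyntheticColonySpec) -> Tuple[Micrograph, GroundTruth]:
    """Render one synthetic colony and its ground truth.

    Nuclei are flat-intensity blue disks with a soft 1-px edge; clusters
    merge by union-of-disks, so a merged region's area is below the sum of
    its members' areas, as in real clumps. MHC+ cytoplasm is rendered as
    filled red polygons placed so that approximately
    ``fraction_nuclei_in_mhc`` of the nuclei have their centers inside
    (clusters are placed whole, so the achieved fraction — recorded in the
    truth table — can differ slightly from the request). Isolated nuclei are
    separated by more than two maximal radii; clusters never touch other
    clusters. Raises :class:`GenerationError` when the requested content
    cannot be packed after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    image_id = spec.resolved_image_id

    # ----- cluster inventory --------------------------------------------
    sizes = (
        [1] * spec.n_singles
        + [2] * spec.n_doublets
        + [
            int(rng.integers(spec.multiplet_size_min, spec.multiplet_size_max + 1))
            for _ in range(spec.n_multiplets)
        ]
    )
    order = rng.permutation(len(sizes))
    sizes = [sizes[i] for i in order]
    total_nuclei = sum(sizes)

    radii = [
        np.clip(
            rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd, size),
            2.0,
            spec.nucleus_radius_mean + 4.0 * spec.nucleus_radius_sd + 1.0,
        )
        for size in sizes
    ]
    offsets = [_cluster_offsets(rng, r, spec.cluster_spacing) for r in radii]
    bounding = [
        float(np.max(np.hypot(off[:, 0], off[:, 1]) + r))
        for off, r in zip(offsets, radii)
    ]

    # ----- MHC polygons and membership ----------------------------------
    polygons = _place_mhc_polygons(rng, spec) if spec.n_mhc_regions else []
    target_inside = round(spec.fraction_nuclei_in_mhc * total_nuclei)
    in_mhc: List[bool] = []
    running = 0
    for size in sizes:
        if polygons and running < target_inside:
            in_mhc.append(True)
            running += size
        else:
            in_mhc.append(False)

    # ----- placement (rejection sampling) -------------------------------
    max_radius = max((float(np.max(r)) for r in radii), default=0.0)
    centers_by_idx: dict[int, Tuple[float, float]] = {}
    mhc_by_idx: dict[int, Optional[int]] = {}
    inner = [p.buffer(-4.0) for p in polygons]
    areas = np.array([max(p.area, 1e-9) for p in inner]) if inner else None

    # big clusters first (in-MHC before free-field): packs far more reliably
    placement_order = sorted(
        range(len(sizes)), key=lambda i: (not in_mhc[i], -bounding[i])
    )
    for idx in placement_order:
        size = sizes[idx]
        bound = bounding[idx]
        centers = list(centers_by_idx.values())
        occupied_bounds = [bounding[j] for j in centers_by_idx]
        placed = False
        for _ in range(2000):
            if in_mhc[idx]:
                poly_id = int(rng.choice(len(inner), p=areas / areas.sum()))
                target = inner[poly_id]
                if target.is_empty:
                    continue
                minx, miny, maxx, maxy = target.bounds
                col = rng.uniform(minx, maxx)
                row = rng.uniform(miny, maxy)
                member_pts = [
                    Point(col + off[1], row + off[0]) for off in offsets[idx]
                ]
                if not all(target.contains(pt) for pt in member_pts):
                    continue
            else:
                poly_id = None
                margin = bound + 2.0
                if 2 * margin >= min(spec.height, spec.width):
                    break
                row = rng.uniform(margin, spec.height - margin)
                col = rng.uniform(margin, spec.width - margin)
                member_pts = [
                    Point(col + off[1], row + off[0]) for off in offsets[idx]
                ]
                if any(
                    p.distance(pt) < 4.0 or p.contains(pt)
                    for p in polygons
                    for pt in member_pts
                ):
                    continue
            if any(
                math.hypot(row - r0, col - c0)
                < max(bound + other + 4.0, 2.0 * max_radius)
                for (r0, c0), other in zip(centers, occupied_bounds)
            ):
                continue
            if not (
                bound + 1 <= row <= spec.height - bound - 1
                and bound + 1 <= col <= spec.width - bound - 1
            ):
                continue
            centers_by_idx[idx] = (row, col)
            mhc_by_idx[idx] = poly_id
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place cluster {idx} (size {size}) after bounded retries; "
                "reduce the nucleus count or enlarge the image"
            )
    centers = [centers_by_idx[i] for i in range(len(sizes))]
    mhc_of_cluster = [mhc_by_idx[i] for i in range(len(sizes))]

    # ----- truth table ---------------------------------------------------
    # nucleus centers snap to integer pixels: equal-radius nuclei then share
    # identical rasterizations, which the exact-count contracts rely on
    nuclei_rows: List[dict] = []
    clusters: dict = {}
    mhc_counts = {i: 0 for i in range(len(polygons))}
    nucleus_id = 0
    for idx, size in enumerate(sizes):
        row0, col0 = centers[idx]
        poly_id = mhc_of_cluster[idx]
        clusters[idx] = {"size": size, "mhc_id": poly_id}
        if poly_id is not None:
            mhc_counts[poly_id] += size
        for m in range(size):
            r = int(round(row0 + offsets[idx][m][0]))
            c = int(round(col0 + offsets[idx][m][1]))
            nuclei_rows.append(
                {
                    "nucleus_id": nucleus_id,
                    "image_id": image_id,
                    "row": r,
                    "col": c,
                    "radius": float(radii[idx][m]),
                    "cluster_id": idx,
                    "in_mhc": poly_id is not None,
                    "mhc_id": poly_id if poly_id is not None else -1,
                }
            )
            nucleus_id += 1

    inside_total = sum(1 for n in nuclei_rows if n["in_mhc"])
    fused_total = sum(
        1
        for n in nuclei_rows
        if n["in_mhc"] and mhc_counts[n["mhc_id"]] > 2
    )
    df_true = inside_total / total_nuclei if total_nuclei else 0.0
    ui_true = fused_total / total_nuclei if total_nuclei else 0.0

    # ----- rendering ------------------------------------------------------
    blue = np.zeros((spec.height, spec.width))
    red = np.zeros((spec.height, spec.width))
    green = np.zeros((spec.height, spec.width))

    mhc_masks: List[np.ndarray] = []
    for poly in polygons:
        xs, ys = poly.exterior.coords.xy
        rr, cc = draw_polygon(np.array(ys), np.array(xs), shape=red.shape)
        mask = np.zeros_like(red, dtype=bool)
        mask[rr, cc] = True
        mhc_masks.append(mask)
        red[mask] = spec.mhc_intensity

    for n in nuclei_rows:
        _soft_disk_paint(blue, n["row"], n["col"], n["radius"], spec.nucleus_intensity)

    # sub-nuclear debris specks, kept clear of nuclei clusters
    for _ in range(spec.speck_count):
        for _ in range(100):
            r = rng.uniform(2, spec.height - 3)
            c = rng.uniform(2, spec.width - 3)
            if all(
                math.hypot(r - r0, c - c0) > bounding[j] + 5.0
                for j, (r0, c0) in enumerate(centers)
            ):
                _soft_disk_paint(blue, r, c, rng.uniform(0.6, 1.2), 0.9)
                break

    if spec.background_noise_sd > 0:
        for channel in (red, green, blue):
            channel += rng.normal(0.0, spec.background_noise_sd, channel.shape)

    def _quantize(x: np.ndarray) -> np.ndarray:
        return np.round(np.clip(x, 0.0, 1.0) * 255.0) / 255.0

    micrograph = Micrograph(
        image_id=image_id,
        red=_quantize(red),
        green=_quantize(green),
        blue=_quantize(blue),
    )
    truth = GroundTruth(
        image_id=image_id,
        nuclei=nuclei_rows,
        clusters=clusters,
        mhc_counts=mhc_counts,
        mhc_masks=mhc_masks,
        total_nuclei=total_nuclei,
        df_true=df_true,
        ui_true=ui_true,
    )
    return micrograph, truth


TRUTH_COLUMNS = (
    "nucleus_id",
    "image_id",
    "row",
    "col",
    "radius",
    "cluster_id",
    "in_mhc",
    "mhc_id",
)


def generate_batch(
    specs: Sequence[SyntheticColonySpec], out_dir: str | os.PathLike
) -> List[GroundTruth]:
    """Render a batch of colonies to ``out_dir`` with a pooled truth CSV.

    Writes one PNG per spec plus ``truth.csv`` (one row per nucleus across
    all images). Returns the per-image ground truths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths: List[GroundTruth] = []
    with open(out_dir / "truth.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_COLUMNS)
        for spec in specs:
            micrograph, truth = generate_colony(spec)
            write_micrograph(micrograph, out_dir / f"{truth.image_id}.png")
            for n in truth.nuclei:
                writer.writerow([n[c] for c in TRUTH_COLUMNS])
            truths.append(truth)
    return truths


def truth_summary(truth: GroundTruth) -> dict:
    """Per-image truth totals in the shape the metrics stage reports."""
    return {
        "image_id": truth.image_id,
        "total_nuclei": truth.total_nuclei,
        "df_true": truth.df_true,
        "ui_true": truth.ui_true,
        "multi_region_ids": [
            mhc_id for mhc_id, count in truth.mhc_counts.items() if count > 2
        ],
    }
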