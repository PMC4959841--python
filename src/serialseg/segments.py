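"""2D candidate segments: extraction, measurement, filtering, artifact pruning.

A segment is one 8-connected foreground component on one section —
hypothesized to be the cross-section of a labeled process. Geometry follows
the moment-equivalent-ellipse convention: the major axis is 4 times the
square root of the largest eigenvalue of the pixel-coordinate covariance
(no discrete-pixel +1/12 correction). Filtering keeps segments with
3 px < area < 130,000 px and major axis < 900 px (all bounds strict);
irregularly large segments sandwiched between much smaller linked
neighbors on both adjacent sides are flagged as imaging artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .contrast import SectionImage


@dataclass(frozen=True)
class FilterParams:
    """Geometric bounds on kept segments (all strict) plus the pruning ratio."""

    min_area_px: int = 3
    max_area_px: int = 130_000
    max_major_axis_px: float = 900.0
    prune_area_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_area_px < self.max_area_px:
            raise ValueError(
                f"need 0 <= min_area_px < max_area_px, got {self.min_area_px}, {self.max_area_px}"
            )
        if self.max_major_axis_px <= 0:
            raise ValueError(f"max_major_axis_px must be > 0, got {self.max_major_axis_px}")
        if self.prune_area_ratio <= 1:
            raise ValueError(f"prune_area_ratio must be > 1, got {self.prune_area_ratio}")


@dataclass
class SegmentRecord:
    """One 2D candidate segment and its measured geometry.

    ``label`` is unique across the whole volume once assigned by the store
    (0 = not yet assigned). ``bbox`` is half-open 0-based
    (y_min, x_min, y_max, x_max); ``centroid`` uses the 0-based
    pixel-center convention. ``coords`` holds the component's (y, x) pixel
    coordinates so masks can be rebuilt for overlap tests and label-stack
    export.
    """

    label: int
    z_index: int
    area_px: int
    centroid: tuple[float, float]
    major_axis_px: float
    bbox: tuple[int, int, int, int]
    mean_intensity: float
    pruned_flag: bool = False
    prune_reason: str = ""
    coords: np.ndarray | None = field(default=None, repr=False)

    def mask_rle(self) -> str:
        """Run-length encoding of the mask over the bbox, 'start:length,...' in
        row-major flat bbox-local indices."""
        if self.coords is None:
            return ""
        y0, x0, y1, x1 = self.bbox
        width = x1 - x0
        flat = np.sort((self.coords[:, 0] - y0) * width + (self.coords[:, 1] - x0))
        runs = []
        start = prev = int(flat[0])
        for v in flat[1:]:
            v = int(v)
            if v == prev + 1:
                prev = v
                continue
            runs.append(f"{start}:{prev - start + 1}")
            start = prev = v
        runs.append(f"{start}:{prev - start + 1}")
        return ",".join(runs)

    @staticmethod
    def coords_from_rle(rle: str, bbox: tuple[int, int, int, int]) -> np.ndarray:
        y0, x0, y1, x1 = bbox
        width = x1 - x0
        flat: list[int] = []
        if rle:
            for run in rle.split(","):
                start, length = (int(v) for v in run.split(":"))
                flat.extend(range(start, start + length))
        arr = np.asarray(flat, dtype=np.int64)
        return np.column_stack([arr // width + y0, arr % width + x0]).astype(np.int64)


def extract_segments(mask: np.ndarray, section: SectionImage) -> list[SegmentRecord]:
    """Decompose a binary foreground mask into measured candidate segments.

    One record per 8-connected component; properties come from the
    component's pixels (area, sub-pixel centroid, covariance-eigenvalue
    major axis, half-open bbox, mean original intensity). Labels are left
    unassigned (0) until the store numbers the whole volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != section.pixels.shape:
        raise ValueError(f"mask shape {mask.shape} != section shape {section.pixels.shape}")
    if not mask.any():
        return []
    labeled = cc_label(mask, connectivity=2)
    records = []
    for rp in regionprops(labeled, intensity_image=section.pixels):
        records.append(
            SegmentRecord(
                label=0,
                z_index=section.z_index,
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                major_axis_px=float(rp.axis_major_length),
                bbox=tuple(int(v) for v in rp.bbox),
                mean_intensity=float(rp.intensity_mean),
                coords=np.asarray(rp.coords, dtype=np.int64),
            )
        )
    return records


def filter_segments(segments: list[SegmentRecord], params: FilterParams = FilterParams()) -> list[SegmentRecord]:
    """Keep segments with min_area < area < max_area and major axis < the bound.

    All comparisons are strict; order is preserved and the operation is
    idempotent.
    """
    return [
        s
        for s in segments
        if params.min_area_px < s.area_px < params.max_area_px
        and s.major_axis_px < params.max_major_axis_px
    ]


def prune_artifacts(
    segments: list[SegmentRecord],
    neighbor_areas: dict[int, tuple[list[int], list[int]]],
    prune_area_ratio: float = 10.0,
) -> list[SegmentRecord]:
    """Flag irregularly large segments that interrupt a process's progression.

    ``neighbor_areas`` maps a segment's label to the areas of its
    candidate-linked segments on sections above and below (screening-mode
    neighborhood search). A segment is flagged when it has neighbors on
    *both* sides and its area exceeds ``prune_area_ratio`` times the median
    neighbor area. Flagged segments are excluded from linking but never
    deleted.
    """
    out = []
    for s in segments:
        above, below = neighbor_areas.get(s.label, ([], []))
        if above and below:
            med = median(list(above) + list(below))
            if med > 0 and s.area_px > prune_area_ratio * med:
                out.append(replace(s, pruned_flag=True, prune_reason="area_ratio"))
                continue
        out.append(s)
    return out
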