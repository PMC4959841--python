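"""Durable, queryable table of labeled segments (the pipeline's database role).

Backed by an on-disk CSV (rows, fixed column order) plus a JSON sidecar
(volume geometry, section list including gaps, parameter snapshot, row
count for integrity). Centroid neighborhoods are computed in physical nm
coordinates: with anisotropic voxels (tens of nm in-plane vs tens to
hundreds of nm between sections) pixel-space distances would be
meaningless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segments import SegmentRecord

_COLUMNS = [
    "label",
    "z_index",
    "area_px",
    "centroid_y",
    "centroid_x",
    "major_axis_px",
    "bbox",
    "mean_intensity",
    "pruned_flag",
    "reason",
    "rle",
]


@dataclass
class SegmentTable:
    """All labeled segments of one volume plus its metadata.

    ``volume_meta`` carries ``voxel`` (x_nm, y_nm, z_nm), ``sections`` (the
    z-indices present, gaps preserved) and ``params`` (the parameter
    snapshot that produced the rows).
    """

    segments: list[SegmentRecord] = field(default_factory=list)
    volume_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        if len(labels) != len(set(labels)):
            raise ValueError("segment labels must be unique within a table")
        self._by_label = {s.label: s for s in self.segments}

    def __len__(self) -> int:
        return len(self.segments)

    def get(self, label: int) -> SegmentRecord:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown segment label {label}") from None

    @property
    def voxel(self) -> tuple[float, float, float]:
        return tuple(self.volume_meta.get("voxel", (20.0, 20.0, 30.0)))


def assign_labels(
    segments: list[SegmentRecord], volume_meta: dict | None = None
) -> SegmentTable:
    """Number segments 1..N in (z_index, discovery order) and build a table.

    Deterministic for identical input; discovery order within a section is
    the order the extractor emitted (raster order of the components).
    """
    ordered = sorted(enumerate(segments), key=lambda t: (t[1].z_index, t[0]))
    relabeled = []
    for new_label, (_, seg) in enumerate(ordered, start=1):
        seg.label = new_label
        relabeled.append(seg)
    meta = dict(volume_meta or {})
    meta.setdefault("voxel", (20.0, 20.0, 30.0))
    meta.setdefault("sections", sorted({s.z_index for s in relabeled}))
    meta.setdefault("params", {})
    return SegmentTable(segments=relabeled, volume_meta=meta)


def _to_frame(table: SegmentTable) -> pd.DataFrame:
    rows = []
    for s in table.segments:
        rows.append(
            {
                "label": s.label,
                "z_index": s.z_index,
                "area_px": s.area_px,
                "centroid_y": s.centroid[0],
                "centroid_x": s.centroid[1],
                "major_axis_px": s.major_axis_px,
                "bbox": ";".join(str(v) for v in s.bbox),
                "mean_intensity": s.mean_intensity,
                "pruned_flag": s.pruned_flag,
                "reason": s.prune_reason,
                "rle": s.mask_rle(),
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def persist_table(table: SegmentTable, path: str | Path) -> None:
    """Write the rows CSV and its JSON metadata sidecar (lossless round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = _to_frame(table)
    df.to_csv(path, index=False)  # default shortest-repr floats round-trip exactly
    meta = dict(table.volume_meta)
    meta["n_rows"] = len(df)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_table(path: str | Path) -> SegmentTable:
    """Load a persisted table; refuses truncated or meta-less files."""
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    if not path.exists() or not meta_path.exists():
        raise FileNotFoundError(f"segment table or its metadata missing at {path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(
        path,
        dtype={"reason": str, "rle": str},
        keep_default_na=False,
        na_values=[],
        float_precision="round_trip",
    )
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"unexpected columns in {path}: {list(df.columns)}")
    n_expected = meta.pop("n_rows", None)
    if n_expected is not None and len(df) != n_expected:
        raise ValueError(
            f"truncated segment table: expected {n_expected} rows, found {len(df)}"
        )
    segments = []
    for row in df.itertuples(index=False):
        bbox = tuple(int(v) for v in str(row.bbox).split(";"))
        rle = str(row.rle)
        coords = SegmentRecord.coords_from_rle(rle, bbox) if rle else None
        segments.append(
            SegmentRecord(
                label=int(row.label),
                z_index=int(row.z_index),
                area_px=int(row.area_px),
                centroid=(float(row.centroid_y), float(row.centroid_x)),
                major_axis_px=float(row.major_axis_px),
                bbox=bbox,
                mean_intensity=float(row.mean_intensity),
                pruned_flag=bool(row.pruned_flag) if not isinstance(row.pruned_flag, str) else row.pruned_flag == "True",
                prune_reason=str(row.reason),
                coords=coords,
            )
        )
    if "voxel" in meta:
        meta["voxel"] = tuple(meta["voxel"])
    return SegmentTable(segments=segments, volume_meta=meta)


def export_segments_csv(table: SegmentTable, path: str | Path) -> None:
    """CSV export in the fixed interchange column order (no mask column)."""
    df = _to_frame(table).drop(columns=["rle"])
    df.to_csv(path, index=False)


def query_neighborhood(
    table: SegmentTable,
    segment: SegmentRecord | int,
    radius_nm: float,
    max_gap_sections: int,
    two_sided: bool = False,
) -> list[SegmentRecord]:
    """Candidate segments near a query segment on nearby sections.

    Returns segments whose z-offset from the query lies in
    ``[1, max_gap_sections]`` (also ``[-max_gap_sections, -1]`` in
    two-sided screening mode) and whose centroid is within ``radius_nm``
    in-plane (x/y physical distance).
    """
    seg = table.get(segment) if isinstance(segment, (int, np.integer)) else table.get(segment.label)
    x_nm, y_nm, _ = table.voxel
    qy, qx = seg.centroid
    out = []
    for other in table.segments:
        dz = other.z_index - seg.z_index
        if not (1 <= dz <= max_gap_sections or (two_sided and 1 <= -dz <= max_gap_sections)):
            continue
        d = math.hypot((other.centroid[0] - qy) * y_nm, (other.centroid[1] - qx) * x_nm)
        if d <= radius_nm:
            out.append(other)
    return out
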