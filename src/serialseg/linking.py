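"""Graph-based linking of 2D segments into 3D reconstructed processes.

For each (non-pruned) segment, candidate partners are sought on the
following ``max_gap_sections`` sections within an in-plane physical radius;
edges go to the k nearest centroids (k = 2, supporting one continuation
plus one branch). The in-plane metric deliberately excludes z: section
spacing (30-270 nm) would otherwise swamp in-plane proximity. Connected
components of the resulting graph, after a same-section overlap consistency
merge, are the reconstructed 3D processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .store import SegmentTable

LinkGraph = nx.Graph


@dataclass(frozen=True)
class LinkParams:
    """k-NN linking parameters.

    ``radius_nm`` bounds the candidate neighborhood in-plane;
    ``max_gap_sections`` lets links jump missing or undetected sections;
    ``max_link_distance_nm`` (defaults to the radius) caps accepted edge
    lengths.
    """

    k: int = 2
    radius_nm: float = 2000.0
    max_gap_sections: int = 3
    max_link_distance_nm: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.radius_nm <= 0:
            raise ValueError(f"radius_nm must be > 0, got {self.radius_nm}")
        if self.max_gap_sections < 1:
            raise ValueError(f"max_gap_sections must be >= 1, got {self.max_gap_sections}")

    @property
    def link_cap_nm(self) -> float:
        return self.radius_nm if self.max_link_distance_nm is None else self.max_link_distance_nm


@dataclass
class Reconstruction:
    """Partition of non-pruned segments into numbered 3D processes.

    Component ids are numbered by descending total 2D area (ties: smallest
    member label). ``summary`` has one row per component: segment count,
    z-extent, total area.
    """

    components: dict[int, list[int]]
    summary: pd.DataFrame
    table: SegmentTable = field(repr=False, default=None)

    def component_of(self) -> dict[int, int]:
        """Map segment label -> component id."""
        return {lbl: cid for cid, members in self.components.items() for lbl in members}


def _candidates_by_offset(table: SegmentTable, max_gap: int):
    """Index segments by z for gap-aware candidate lookup (non-pruned only)."""
    by_z: dict[int, list] = {}
    for s in table.segments:
        if not s.pruned_flag:
            by_z.setdefault(s.z_index, []).append(s)
    return by_z


def build_link_graph(
    table: SegmentTable,
    params: LinkParams = LinkParams(),
    max_gap: int | None = None,
    _min_gap: int = 1,
) -> LinkGraph:
    """Link each segment to its k nearest upward candidates.

    Candidates are pooled over z-offsets 1..max_gap_sections within
    ``radius_nm`` (in-plane nm); the k of minimum centroid distance are
    linked, ties broken toward the smaller label; edges farther than the
    link cap are dropped. Undirected, deduplicated; isolated segments keep
    a node with no edges.
    """
    gap_limit = params.max_gap_sections if max_gap is None else max_gap
    x_nm, y_nm, _ = table.voxel
    by_z = _candidates_by_offset(table, gap_limit)
    g = nx.Graph()
    cap = params.link_cap_nm
    for s in table.segments:
        if s.pruned_flag:
            continue
        g.add_node(s.label)
        found: list[tuple[float, int, int]] = []  # (distance, label, z_gap)
        for dz in range(_min_gap, gap_limit + 1):
            for other in by_z.get(s.z_index + dz, ()):
                dy = (other.centroid[0] - s.centroid[0]) * y_nm
                dx = (other.centroid[1] - s.centroid[1]) * x_nm
                d = float(np.hypot(dy, dx))
                if d <= params.radius_nm:
                    found.append((d, other.label, dz))
        found.sort(key=lambda t: (t[0], t[1]))
        for d, lbl, dz in found[: params.k]:
            if d <= cap:
                g.add_edge(s.label, lbl, distance_nm=d, z_gap=dz)
    return g


def bridge_gaps(graph: LinkGraph, table: SegmentTable, params: LinkParams = LinkParams()) -> LinkGraph:
    """Add gap-jumping edges (z-gap >= 2) missing from an existing graph.

    Runs the same pooled k-NN candidate search as :func:`build_link_graph`
    over the full gap range and inserts only the resulting edges whose
    z-gap is at least 2. With no gaps in the data the graph is returned
    unchanged.
    """
    full = build_link_graph(table, params)
    out = graph.copy()
    for a, b, attrs in full.edges(data=True):
        if attrs["z_gap"] >= 2 and not out.has_edge(a, b):
            out.add_edge(a, b, **attrs)
    return out


def _overlap_px(a, b) -> int:
    if a.coords is None or b.coords is None:
        return 0
    ay0, ax0, ay1, ax1 = a.bbox
    by0, bx0, by1, bx1 = b.bbox
    if ay1 <= by0 or by1 <= ay0 or ax1 <= bx0 or bx1 <= ax0:
        return 0
    sa = {(int(y), int(x)) for y, x in a.coords}
    return sum((int(y), int(x)) in sa for y, x in b.coords)


def merge_components(graph: LinkGraph, table: SegmentTable) -> Reconstruction:
    """Merge linked segments into numbered 3D processes.

    Components are the connected components of the link graph (every
    non-pruned segment belongs to exactly one). A consistency pass then
    merges any two components holding same-section segments that overlap
    in-plane by >= 50% of the smaller segment's area — duplicate detections
    of one physical process.
    """
    g = graph.copy()
    for s in table.segments:
        if not s.pruned_flag:
            g.add_node(s.label)

    comp_sets = [set(c) for c in nx.connected_components(g)]
    comp_of = {lbl: i for i, c in enumerate(comp_sets) for lbl in c}

    # consistency pass: same-section >= 50% overlap merges components
    parent = list(range(len(comp_sets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_z: dict[int, list] = {}
    for s in table.segments:
        if not s.pruned_flag:
            by_z.setdefault(s.z_index, []).append(s)
    for segs in by_z.values():
        for i, a in enumerate(segs):
            for b in segs[i + 1 :]:
                ra, rb = find(comp_of[a.label]), find(comp_of[b.label])
                if ra == rb:
                    continue
                ov = _overlap_px(a, b)
                if ov and ov >= 0.5 * min(a.area_px, b.area_px):
                    parent[max(ra, rb)] = min(ra, rb)

    merged: dict[int, set[int]] = {}
    for i, c in enumerate(comp_sets):
        merged.setdefault(find(i), set()).update(c)

    # deterministic numbering: descending total area, ties by smallest label
    def sort_key(members: set[int]):
        total = sum(table.get(lbl).area_px for lbl in members)
        return (-total, min(members))

    ordered = sorted(merged.values(), key=sort_key)
    components = {cid: sorted(members) for cid, members in enumerate(ordered, start=1)}

    rows = []
    for cid, members in components.items():
        zs = [table.get(lbl).z_index for lbl in members]
        rows.append(
            {
                "component": cid,
                "n_segments": len(members),
                "z_min": min(zs),
                "z_max": max(zs),
                "total_area_px": sum(table.get(lbl).area_px for lbl in members),
            }
        )
    summary = pd.DataFrame(rows, columns=["component", "n_segments", "z_min", "z_max", "total_area_px"])
    return Reconstruction(components=components, summary=summary, table=table)


def label_stack(recon: Reconstruction, shape: tuple[int, int], z_indices: list[int]) -> np.ndarray:
    """Per-section image stack where each pixel carries its component id."""
    comp_of = recon.component_of()
    z_pos = {z: i for i, z in enumerate(z_indices)}
    out = np.zeros((len(z_indices), *shape), dtype=np.uint32)
    for lbl, cid in comp_of.items():
        s = recon.table.get(lbl)
        if s.coords is not None and s.z_index in z_pos:
            out[z_pos[s.z_index], s.coords[:, 0], s.coords[:, 1]] = cid
    return out


def export_reconstruction(recon: Reconstruction, out_dir: str | Path) -> None:
    """Write component label stack (TIFF), per-component summary CSV and
    per-component centroid chains (z, y, x in nm) for 3D rendering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = recon.table.volume_meta
    z_indices = sorted(meta.get("sections", sorted({s.z_index for s in recon.table.segments})))
    shape = tuple(meta.get("shape", (0, 0)))
    if shape == (0, 0):
        ymax = max((s.bbox[2] for s in recon.table.segments), default=1)
        xmax = max((s.bbox[3] for s in recon.table.segments), default=1)
        shape = (ymax, xmax)
    if z_indices:
        tifffile.imwrite(out / "components.tif", label_stack(recon, shape, z_indices))
    else:
        tifffile.imwrite(out / "components.tif", np.zeros((1, *shape), dtype=np.uint32))
    recon.summary.to_csv(out / "summary.csv", index=False)

    x_nm, y_nm, z_nm = recon.table.voxel
    rows = []
    for cid, members in recon.components.items():
        for lbl in sorted(members, key=lambda l: recon.table.get(l).z_index):
            s = recon.table.get(lbl)
            rows.append(
                {
                    "component": cid,
                    "z_nm": s.z_index * z_nm,
                    "y_nm": s.centroid[0] * y_nm,
                    "x_nm": s.centroid[1] * x_nm,
                }
            )
    pd.DataFrame(rows, columns=["component", "z_nm", "y_nm", "x_nm"]).to_csv(
        out / "centroid_chains.csv", index=False
    )
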