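"""End-to-end orchestration: sections -> segments -> table -> reconstruction.

Each stage is a pure function of its inputs and parameters; the per-section
thresholds actually applied (tau and modulated tau') are returned so runs
can be logged and audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

from .contrast import (
    SectionImage,
    ThresholdParams,
    binarize,
    cluster_threshold,
    equalize_histogram,
    modulate_threshold,
)
from .linking import LinkParams, Reconstruction, build_link_graph, merge_components
from .segments import FilterParams, SegmentRecord, extract_segments, filter_segments, prune_artifacts
from .store import SegmentTable, assign_labels, query_neighborhood

logger = logging.getLogger("serialseg")


def segment_section(
    section: SectionImage,
    tparams: ThresholdParams = ThresholdParams(),
    fparams: FilterParams = FilterParams(),
    equalize: bool = True,
) -> tuple[list[SegmentRecord], float, float]:
    """Threshold and segment one section; returns (kept segments, tau, tau')."""
    work = equalize_histogram(section, n_bins=tparams.n_bins) if equalize else section
    try:
        tau = cluster_threshold(work, tparams)
    except ValueError:
        # degenerate histogram (blank section): conservative fallback
        tau = tparams.cutoff
    tau_prime = modulate_threshold(tau, tparams)
    mask = binarize(work, tau_prime)
    segs = filter_segments(extract_segments(mask, section), fparams)
    logger.debug("section z=%d: tau=%.5f tau'=%.5f kept=%d", section.z_index, tau, tau_prime, len(segs))
    return segs, tau, tau_prime


def segment_stack(
    sections: list[SectionImage],
    tparams: ThresholdParams = ThresholdParams(),
    fparams: FilterParams = FilterParams(),
    equalize: bool = True,
    volume_meta: dict | None = None,
) -> tuple[SegmentTable, dict[int, tuple[float, float]]]:
    """Segment every section and assemble the labeled volume table."""
    all_segs: list[SegmentRecord] = []
    tau_log: dict[int, tuple[float, float]] = {}
    for sec in sections:
        segs, tau, tau_prime = segment_section(sec, tparams, fparams, equalize)
        tau_log[sec.z_index] = (tau, tau_prime)
        all_segs.extend(segs)
    meta = dict(volume_meta or {})
    if sections:
        meta.setdefault("voxel", (*sections[0].pixel_pitch, sections[0].section_spacing_nm))
        meta.setdefault("shape", tuple(sections[0].pixels.shape))
    meta.setdefault("sections", sorted(s.z_index for s in sections))
    meta.setdefault(
        "params",
        {"threshold": asdict(tparams), "filter": asdict(fparams), "equalize": equalize},
    )
    table = assign_labels(all_segs, meta)
    return table, tau_log


def prune_table(table: SegmentTable, fparams: FilterParams, lparams: LinkParams) -> SegmentTable:
    """Flag irregularly large artifacts using two-sided candidate screening."""
    neighbor_areas: dict[int, tuple[list[int], list[int]]] = {}
    for s in table.segments:
        cands = query_neighborhood(
            table, s, lparams.radius_nm, lparams.max_gap_sections, two_sided=True
        )
        above = [c.area_px for c in cands if c.z_index > s.z_index]
        below = [c.area_px for c in cands if c.z_index < s.z_index]
        neighbor_areas[s.label] = (above, below)
    pruned = prune_artifacts(table.segments, neighbor_areas, fparams.prune_area_ratio)
    return SegmentTable(segments=pruned, volume_meta=table.volume_meta)


def reconstruct(
    table: SegmentTable, lparams: LinkParams = LinkParams()
) -> tuple[Reconstruction, "build_link_graph"]:
    """Link the table's segments and merge into 3D components."""
    graph = build_link_graph(table, lparams)
    recon = merge_components(graph, table)
    return recon, graph


def run_chain(
    sections: list[SectionImage],
    tparams: ThresholdParams = ThresholdParams(),
    fparams: FilterParams = FilterParams(),
    lparams: LinkParams = LinkParams(),
    equalize: bool = True,
    prune: bool = True,
) -> tuple[SegmentTable, Reconstruction, dict[int, tuple[float, float]]]:
    """Full 2D-segmentation + 3D-reconstruction chain on a section stack."""
    table, tau_log = segment_stack(sections, tparams, fparams, equalize)
    if prune:
        table = prune_table(table, fparams, lparams)
    recon, _ = reconstruct(table, lparams)
    return table, recon, tau_log


def write_provenance(out_dir: str | Path, stage: str, params: dict, inputs: list[str | Path], seed=None) -> Path:
    """Record a stage's parameter snapshot, input checksums and code version."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    record = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": params,
        "input_sha256": checksums,
    }
    path = out / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
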