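"""Evaluation against ground truth and overview-to-high-resolution ROI proposal.

Recall is the fraction of ground-truth 2D segments recovered by the
automatic segmentation (a truth segment counts as recovered when a single
predicted segment covers at least half of its area, by default). ROI
proposal turns a low-resolution overview reconstruction into padded
physical boxes for targeted re-imaging, quantified by the imaging-time
reduction factor total_volume / roi_volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .linking import Reconstruction
from .segments import SegmentRecord


@dataclass
class MatchResult:
    """Outcome of matching predicted segments to ground-truth segments."""

    n_truth: int
    n_matched: int
    recall: float
    missed: list[dict]
    mean_missed_bbox: tuple[float, float]  # (height_px, width_px)
    n_predicted: int = 0
    precision: float = float("nan")


def _truth_segments(mask: np.ndarray):
    """Per-section truth segments: connected components of each process id."""
    for pid in np.unique(mask):
        if pid == 0:
            continue
        cc = cc_label(mask == pid, connectivity=2)
        for k in range(1, cc.max() + 1):
            ys, xs = np.nonzero(cc == k)
            yield pid, ys, xs


def match_segments(
    predicted: list[SegmentRecord],
    truth_masks: dict[int, np.ndarray],
    min_overlap: float = 0.5,
) -> MatchResult:
    """Match ground-truth segments against predicted ones, section by section.

    ``truth_masks`` maps z-index -> integer label mask (0 = background,
    otherwise process id). A truth segment is matched when some single
    predicted segment on its section overlaps >= ``min_overlap`` of the
    truth segment's area. Also reports precision (predicted segments whose
    majority pixel is labeled in truth), which plays no role in matching.
    """
    if not truth_masks or all((m > 0).sum() == 0 for m in truth_masks.values()):
        raise ValueError("ground truth contains no labeled segments")

    pred_by_z: dict[int, list[SegmentRecord]] = {}
    for s in predicted:
        if not s.pruned_flag:
            pred_by_z.setdefault(s.z_index, []).append(s)

    n_truth = n_matched = 0
    missed: list[dict] = []
    pred_hit: dict[int, bool] = {id(s): False for segs in pred_by_z.values() for s in segs}

    for z, mask in truth_masks.items():
        pred_img = np.zeros(mask.shape, dtype=np.int64)
        segs = pred_by_z.get(z, [])
        for i, s in enumerate(segs, start=1):
            if s.coords is not None:
                pred_img[s.coords[:, 0], s.coords[:, 1]] = i
        for pid, ys, xs in _truth_segments(mask):
            n_truth += 1
            area = ys.size
            under = pred_img[ys, xs]
            under = under[under > 0]
            best = np.bincount(under).max() if under.size else 0
            if best >= min_overlap * area:
                n_matched += 1
                if under.size:
                    for i in np.unique(under):
                        pred_hit[id(segs[i - 1])] = True
            else:
                missed.append(
                    {
                        "z": z,
                        "process_id": int(pid),
                        "bbox_height_px": int(ys.max() - ys.min() + 1),
                        "bbox_width_px": int(xs.max() - xs.min() + 1),
                        "area_px": int(area),
                    }
                )
        # mark predicted segments overlapping any truth at all (for precision)
        for i, s in enumerate(segs, start=1):
            if s.coords is not None:
                t = mask[s.coords[:, 0], s.coords[:, 1]]
                if (t > 0).sum() >= min_overlap * s.area_px:
                    pred_hit[id(s)] = True

    if n_truth == 0:
        raise ValueError("ground truth contains no labeled segments")
    n_predicted = sum(len(v) for v in pred_by_z.values())
    precision = (
        sum(pred_hit.values()) / n_predicted if n_predicted else float("nan")
    )
    if missed:
        mh = float(np.mean([m["bbox_height_px"] for m in missed]))
        mw = float(np.mean([m["bbox_width_px"] for m in missed]))
    else:
        mh = mw = 0.0
    return MatchResult(
        n_truth=n_truth,
        n_matched=n_matched,
        recall=n_matched / n_truth,
        missed=missed,
        mean_missed_bbox=(mh, mw),
        n_predicted=n_predicted,
        precision=precision,
    )


@dataclass
class RoiProposal:
    """Padded 3D physical boxes proposed for high-resolution re-imaging.

    Component-derived boxes are (z_min_section, z_max_section_exclusive,
    y0_nm, y1_nm, x0_nm, x1_nm); explicit user boxes are fully in nm
    (z0_nm, z1_nm, y0_nm, y1_nm, x0_nm, x1_nm). Volumes are in cubic
    micrometers; ``reduction_factor``
    is the overview volume divided by the proposed ROI volume — the factor
    by which targeted re-imaging shrinks acquisition time relative to
    imaging everything at high resolution.
    """

    boxes: list[tuple[int, int, float, float, float, float]]
    total_volume_um3: float
    roi_volume_um3: float
    reduction_factor: float


def _box_volume_um3(box, z_nm: float) -> float:
    z0, z1, y0, y1, x0, x1 = box
    return (z1 - z0) * z_nm * (y1 - y0) * (x1 - x0) / 1e9


def propose_roi(
    recon: Reconstruction | None,
    margin_nm: float = 0.0,
    selector="all",
    volume_bounds_nm: tuple[float, float, float] | None = None,
) -> RoiProposal:
    """Propose re-imaging boxes from an overview reconstruction.

    ``selector`` is ``"all"`` (every component), a list of component ids,
    or ``{"box": (z0, z1, y0_nm, y1_nm, x0_nm, x1_nm)}`` for an explicit
    physical box (then ``recon`` may be None if ``volume_bounds_nm`` gives
    the overview extent as (z_extent_nm, y_extent_nm, x_extent_nm)).
    """
    if isinstance(selector, dict) and "box" in selector:
        boxes_raw = [tuple(selector["box"])]
        if volume_bounds_nm is not None:
            z_ext, y_ext, x_ext = volume_bounds_nm
            total = z_ext * y_ext * x_ext / 1e9
            roi = sum((b[1] - b[0]) * (b[3] - b[2]) * (b[5] - b[4]) / 1e9 for b in boxes_raw)
            if roi <= 0:
                raise ValueError("explicit ROI box has zero volume")
            return RoiProposal(
                boxes=boxes_raw,
                total_volume_um3=total,
                roi_volume_um3=roi,
                reduction_factor=total / roi,
            )
        if recon is None:
            raise ValueError("explicit box needs volume_bounds_nm or a reconstruction")

    if recon is None or not recon.components:
        raise ValueError("empty selection: no reconstruction components to propose from")

    table = recon.table
    x_nm, y_nm, z_nm = table.voxel
    meta = table.volume_meta
    sections = sorted(meta.get("sections", sorted({s.z_index for s in table.segments})))
    n_z = sections[-1] - sections[0] + 1
    shape = meta.get("shape")
    if shape is None:
        shape = (
            max(s.bbox[2] for s in table.segments),
            max(s.bbox[3] for s in table.segments),
        )
    h, w = shape
    total = n_z * z_nm * h * y_nm * w * x_nm / 1e9

    if selector == "all":
        ids = list(recon.components)
    else:
        ids = list(selector)
        unknown = [c for c in ids if c not in recon.components]
        if unknown:
            raise ValueError(f"unknown component ids: {unknown}")
    if not ids:
        raise ValueError("empty selection")

    boxes = []
    for cid in ids:
        members = [table.get(lbl) for lbl in recon.components[cid]]
        z0 = min(s.z_index for s in members)
        z1 = max(s.z_index for s in members) + 1
        y0 = max(min(s.bbox[0] for s in members) * y_nm - margin_nm, 0.0)
        y1 = min(max(s.bbox[2] for s in members) * y_nm + margin_nm, h * y_nm)
        x0 = max(min(s.bbox[1] for s in members) * x_nm - margin_nm, 0.0)
        x1 = min(max(s.bbox[3] for s in members) * x_nm + margin_nm, w * x_nm)
        boxes.append((z0, z1, y0, y1, x0, x1))

    roi = sum(_box_volume_um3(b, z_nm) for b in boxes)
    if roi <= 0:
        raise ValueError("proposed ROI has zero volume")
    return RoiProposal(
        boxes=boxes,
        total_volume_um3=total,
        roi_volume_um3=roi,
        reduction_factor=total / roi,
    )


def density_report(
    recon: Reconstruction, truth_masks: dict[int, np.ndarray] | None = None
) -> dict:
    """Per-component and per-volume statistics of a reconstruction.

    Always reports component count, z-extents and labeled-voxel fraction.
    With ground truth, adds split errors (extra components per truth
    process) and merge errors (extra truth processes per component), where
    a segment's truth assignment is its majority-overlap process id.
    """
    table = recon.table
    report: dict = {
        "n_components": len(recon.components),
        "component_z_extents": {
            int(r.component): (int(r.z_min), int(r.z_max)) for r in recon.summary.itertuples()
        },
    }
    meta = table.volume_meta
    shape = meta.get("shape")
    sections = meta.get("sections", sorted({s.z_index for s in table.segments}))
    if shape is not None and sections:
        total_px = len(sections) * shape[0] * shape[1]
        labeled = sum(s.area_px for s in table.segments if not s.pruned_flag)
        report["labeled_voxel_fraction"] = labeled / total_px
    if truth_masks is None:
        return report

    comp_of = recon.component_of()
    truth_of_comp: dict[int, set[int]] = {cid: set() for cid in recon.components}
    comps_of_truth: dict[int, set[int]] = {}
    for s in table.segments:
        if s.pruned_flag or s.label not in comp_of or s.coords is None:
            continue
        mask = truth_masks.get(s.z_index)
        if mask is None:
            continue
        under = mask[s.coords[:, 0], s.coords[:, 1]]
        under = under[under > 0]
        if under.size == 0:
            continue
        tid = int(np.bincount(under).argmax())
        cid = comp_of[s.label]
        truth_of_comp[cid].add(tid)
        comps_of_truth.setdefault(tid, set()).add(cid)

    report["split_errors"] = sum(max(0, len(v) - 1) for v in comps_of_truth.values())
    report["merge_errors"] = sum(max(0, len(v) - 1) for v in truth_of_comp.values())
    report["n_truth_processes_detected"] = len(comps_of_truth)
    return report
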