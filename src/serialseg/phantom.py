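"""Synthetic serial-section phantom volumes with known tubular ground truth.

The generator emulates the statistical regime of overview-resolution EM of
peroxidase(DAB)-labeled tissue: sparse, very dark tubular processes
(dendrites/axons) embedded in a brighter, smoothly textured neuropil
background, with per-pixel shot-like noise, small per-section alignment
jitter, optional missing sections and optional large dark non-neuronal
distractors (erythrocytes, staining artifacts). Geometry is anisotropic:
x/y pixel pitch in the tens of nm, section spacing ~30 nm and upward.

Centerlines are bounded-curvature 3D meanders (a smoothed random walk with
capped lateral amplitude), so tubes stay mutually separated and never
double back within one section. Output is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .contrast import SectionImage, cnr

_MAX_WANDER_PX = 12.0  # cap on centerline lateral meander amplitude
_MIN_TUBE_SEPARATION_PX = 96.0  # min pairwise start separation; with the
# wander cap this keeps tube centerlines > 72 px apart everywhere — beyond
# the default 2000 nm linking radius at the 30 nm/px overview pitch, which
# is what "mutually well-separated" processes means to the linker


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic volume.

    Intensities are on [0, 1] with *low = dark = electron-dense*; the
    stained (labeled) mean must therefore lie below the background mean.
    ``(mean, sd)`` pairs give per-pixel intensity statistics, except
    ``tube_radius_px`` and ``distractor_radius_px`` where the sd spreads
    radii across objects. ``dropout_sections`` removes those images from the
    returned stack but keeps z-indexing (a gap, not a renumbering),
    mirroring sparse overview acquisition such as imaging every 10th
    section.
    """

    n_sections: int = 100
    section_shape: tuple[int, int] = (512, 512)
    voxel: tuple[float, float, float] = (30.0, 30.0, 30.0)  # x, y, z in nm (overview pitch)
    n_processes: int = 10
    tube_radius_px: tuple[float, float] = (6.0, 0.5)
    stained_intensity: tuple[float, float] = (0.15, 0.02)
    background_intensity: tuple[float, float] = (0.65, 0.02)
    background_texture_scale: float = 24.0
    noise_sd: float = 0.015
    n_distractors: int = 0
    distractor_radius_px: tuple[float, float] = (210.0, 5.0)
    dropout_sections: tuple[int, ...] = ()
    jitter_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError(f"n_sections must be >= 1, got {self.n_sections}")
        if len(self.section_shape) != 2 or min(self.section_shape) < 1:
            raise ValueError(f"section_shape must be a positive (height, width), got {self.section_shape}")
        if min(self.voxel) <= 0:
            raise ValueError(f"voxel pitches must be positive, got {self.voxel}")
        for name in ("n_processes", "n_distractors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("tube_radius_px", "stained_intensity", "background_intensity", "distractor_radius_px"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0, got {sd}")
            if name.endswith("intensity") and not 0.0 <= mean <= 1.0:
                raise ValueError(f"{name} mean must be in [0, 1], got {mean}")
        if self.stained_intensity[0] >= self.background_intensity[0]:
            raise ValueError(
                "stained_intensity mean must be below background_intensity mean "
                "(electron-dense label is dark)"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.jitter_px < 0:
            raise ValueError(f"jitter_px must be >= 0, got {self.jitter_px}")
        bad = [z for z in self.dropout_sections if not 0 <= z < self.n_sections]
        if bad:
            raise ValueError(f"dropout_sections out of range: {bad}")


@dataclass
class PhantomGroundTruth:
    """Per-section true label masks plus per-process identities.

    ``label_stack[z]`` holds 0 for background and the process id (1-based)
    for labeled pixels, for every physical section including dropped ones.
    ``process_table`` lists centerline points (one row per process per
    section: id, z, y_px, x_px); ``voxel_counts`` maps id -> total labeled
    pixels across the stack.
    """

    label_stack: np.ndarray
    process_table: pd.DataFrame
    voxel_counts: dict[int, int] = field(default_factory=dict)


def _sample_starts(rng: np.random.Generator, spec: PhantomSpec, margin: float) -> np.ndarray:
    h, w = spec.section_shape
    if spec.n_processes == 0:
        return np.empty((0, 2))
    lo = margin
    hi_y, hi_x = h - margin, w - margin
    if hi_y <= lo or hi_x <= lo:
        raise ValueError("section_shape too small for the requested tube geometry")
    starts: list[np.ndarray] = []
    for _ in range(20000):
        p = rng.uniform([lo, lo], [hi_y, hi_x])
        if all(np.hypot(*(p - q)) >= _MIN_TUBE_SEPARATION_PX for q in starts):
            starts.append(p)
            if len(starts) == spec.n_processes:
                return np.array(starts)
    raise RuntimeError(
        f"could not place {spec.n_processes} mutually separated tubes in "
        f"{spec.section_shape}; reduce n_processes or enlarge the volume"
    )


def _centerline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smoothed, amplitude-capped 2D meander of length n (offsets from start)."""
    steps = rng.normal(0.0, 1.0, size=(n, 2))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    if n > 1:
        # pin both ends so the net drift stays bounded
        t = np.linspace(0.0, 1.0, n)[:, None]
        walk = walk - t * walk[-1]
        walk = gaussian_filter1d(walk, sigma=3.0, axis=0, mode="nearest")
    amp = float(np.abs(walk).max())
    target = rng.uniform(0.3, 1.0) * _MAX_WANDER_PX
    if amp > 0:
        walk *= target / amp
    return walk


def generate_phantom(spec: PhantomSpec) -> tuple[list[SectionImage], PhantomGroundTruth]:
    """Render the phantom volume described by ``spec``.

    Returns the present sections (dropout sections omitted, z-indices kept)
    and the ground truth over all physical sections. Identical spec (which
    includes the seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.section_shape
    n = spec.n_sections
    r_mean, r_sd = spec.tube_radius_px
    margin = _MAX_WANDER_PX + max(r_mean + 3 * r_sd, 1.0) + spec.jitter_px + 4.0

    starts = _sample_starts(rng, spec, margin)
    radii = np.clip(rng.normal(r_mean, r_sd, size=spec.n_processes), 1.0, None)
    lines = np.array([_centerline(rng, n) for _ in range(spec.n_processes)]).reshape(
        spec.n_processes, n, 2
    )
    lines += starts[:, None, :]

    jitter = (
        rng.uniform(-spec.jitter_px, spec.jitter_px, size=(n, 2))
        if spec.jitter_px > 0
        else np.zeros((n, 2))
    )
    lines += jitter[None, :, :]

    # distractors: (z, y, x, radius), rendered darker than the label
    d_mean, d_sd = spec.distractor_radius_px
    distractors = []
    for _ in range(spec.n_distractors):
        dr = max(float(rng.normal(d_mean, d_sd)), 1.0)
        # keep the blob fully inside the section so its rendered area is
        # not clipped below what the radius implies
        dy = rng.uniform(dr, h - dr) if 2 * dr < h else h / 2.0
        dx = rng.uniform(dr, w - dr) if 2 * dr < w else w / 2.0
        distractors.append((int(rng.integers(0, n)), dy, dx, dr))

    yy, xx = np.mgrid[0:h, 0:w]
    label_stack = np.zeros((n, h, w), dtype=np.int32)
    sections: list[SectionImage] = []
    bg_mean, bg_sd = spec.background_intensity
    st_mean, st_sd = spec.stained_intensity
    dropout = set(spec.dropout_sections)

    for z in range(n):
        texture = rng.normal(0.0, 1.0, size=(h, w))
        if spec.background_texture_scale > 0 and bg_sd > 0:
            texture = gaussian_filter(texture, sigma=spec.background_texture_scale, mode="reflect")
            s = texture.std()
            texture = texture / s * bg_sd if s > 0 else texture
        else:
            texture = texture * bg_sd
        img = bg_mean + texture

        for pid in range(spec.n_processes):
            cy, cx = lines[pid, z]
            r = radii[pid]
            inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if inside.any():
                img[inside] = st_mean + (rng.normal(0.0, st_sd, size=int(inside.sum())) if st_sd > 0 else 0.0)
                label_stack[z][inside] = pid + 1

        for dz, dy, dx, dr in distractors:
            if dz == z:
                inside = (yy - dy) ** 2 + (xx - dx) ** 2 <= dr**2
                img[inside] = max(st_mean * 0.7, 0.0)

        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
        img = np.clip(img, 0.0, 1.0)

        if z not in dropout:
            sections.append(
                SectionImage(
                    z_index=z,
                    pixels=img,
                    pixel_pitch=(spec.voxel[0], spec.voxel[1]),
                    section_spacing_nm=spec.voxel[2],
                )
            )

    rows = [
        {"id": pid + 1, "z": z, "y_px": float(lines[pid, z, 0]), "x_px": float(lines[pid, z, 1])}
        for pid in range(spec.n_processes)
        for z in range(n)
    ]
    table = pd.DataFrame(rows, columns=["id", "z", "y_px", "x_px"])
    counts = {
        pid + 1: int((label_stack == pid + 1).sum()) for pid in range(spec.n_processes)
    }
    truth = PhantomGroundTruth(label_stack=label_stack, process_table=table, voxel_counts=counts)
    return sections, truth


def phantom_cnr(sections: list[SectionImage], truth: PhantomGroundTruth) -> float:
    """Contrast-to-noise ratio of the rendered volume.

    Computed as (mu_bg - mu_stained)/sqrt(sigma_bg^2 + sigma_stained^2) over
    the true stained vs background pixel populations of the present
    sections; positive when the label is darker than the neuropil.
    """
    stained, background = [], []
    for sec in sections:
        mask = truth.label_stack[sec.z_index] > 0
        stained.append(sec.pixels[mask])
        background.append(sec.pixels[~mask])
    stained = np.concatenate(stained) if stained else np.empty(0)
    background = np.concatenate(background) if background else np.empty(0)
    if stained.size == 0 or background.size == 0:
        raise ValueError("phantom_cnr requires at least one stained and one background pixel")
    return cnr(stained, background)


def distractor_demo_spec(**overrides) -> PhantomSpec:
    """Preset with oversized dark distractor blobs.

    Distractor radii (~210 px) put their areas above the 130,000 px upper
    area bound of the default segment filter, so the geometric filter's
    efficacy against large non-neuronal objects is directly testable.
    """
    kw = dict(n_sections=12, n_processes=2, n_distractors=3, seed=7)
    kw.update(overrides)
    return PhantomSpec(**kw)


def write_phantom(sections: list[SectionImage], truth: PhantomGroundTruth, out_dir: str | Path) -> None:
    """Write images.tif (8-bit, rounded), labels.tif, process_table.csv, meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.rint(s.pixels * 255).astype(np.uint8) for s in sections])
    tifffile.imwrite(out / "images.tif", stack)
    tifffile.imwrite(out / "labels.tif", truth.label_stack.astype(np.int32))
    truth.process_table.to_csv(out / "process_table.csv", index=False)
    counts = pd.Series(truth.voxel_counts, name="voxel_count")
    counts.rename_axis("id").to_csv(out / "voxel_counts.csv")
    meta = {
        "z_indices": [s.z_index for s in sections],
        "pixel_pitch": list(sections[0].pixel_pitch) if sections else [20.0, 20.0],
        "section_spacing_nm": sections[0].section_spacing_nm if sections else 30.0,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def read_phantom(in_dir: str | Path) -> tuple[list[SectionImage], PhantomGroundTruth | None]:
    """Read a phantom (or any compatible stack) written by :func:`write_phantom`."""
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    stack = tifffile.imread(src / "images.tif")
    if stack.ndim == 2:
        stack = stack[None]
    sections = [
        SectionImage(
            z_index=int(z),
            pixels=stack[i].astype(float) / 255.0,
            pixel_pitch=tuple(meta["pixel_pitch"]),
            section_spacing_nm=float(meta["section_spacing_nm"]),
        )
        for i, z in enumerate(meta["z_indices"])
    ]
    truth = None
    if (src / "labels.tif").exists():
        labels = tifffile.imread(src / "labels.tif")
        table = pd.read_csv(src / "process_table.csv")
        counts_df = pd.read_csv(src / "voxel_counts.csv")
        counts = dict(zip(counts_df["id"].astype(int), counts_df["voxel_count"].astype(int)))
        truth = PhantomGroundTruth(label_stack=labels, process_table=table, voxel_counts=counts)
    return sections, truth
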