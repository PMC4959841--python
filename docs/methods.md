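# Methods

## Imaging model and assumptions

`serialseg` targets aligned serial-section EM stacks in which a genetically
encoded peroxidase label renders a sparse subset of neuronal processes
strongly electron-dense. The working assumptions are:

- intensities are grayscale on [0, 1] after normalization, with the label
  *darker* than the surrounding neuropil (DAB/osmium polarity; the package
  fixes this polarity throughout — foreground is a closed lower set);
- sections are already registered (alignment is upstream of this package);
- voxels are anisotropic: x/y pitch in the tens of nm, section spacing
  30 nm and upward (10× that when only every 10th section is imaged);
- labeled processes are locally tube-like and continue smoothly from
  section to section, so centroid proximity is a valid linking cue;
- the label is sparse enough that two distinct processes rarely touch
  in-plane.

## Thresholding

The global per-section threshold is the Otsu criterion evaluated at the
interior edges of a 256-bin histogram on [0, 1]: maximize
ω₀ω₁(μ₀ − μ₁)². Ties break toward the *lowest* maximizing edge, which is
conservative (smaller dark foreground) and deterministic; on a sparse dark
class the between-class variance is constant across the empty gap between
modes, so the tie rule pins τ to the top of the stained mode. A constant
image has no two-class split and raises; the pipeline falls back to the
modulation cutoff for blank sections.

The modulation rule τ′ = 0.82 τ (τ < 0.6, strict) else 0.86 τ shifts the
threshold into the label's contrast-enhanced range. Both factors are ≤ 1,
so modulation only tightens the foreground criterion; when Otsu locks onto
an internal split of the background mode, the modulation pushes τ′ into
the background's lower tail, suppressing background pixels to sparse
speckle that the minimum-area filter removes. The boundary τ = 0.6 takes
the high factor (strict `<` as published); pixels exactly at τ′ are
foreground. Cutoff, both factors and the bin count are configurable
(`threshold.*`).

Histogram equalization (the cross-slice normalization step) is implemented
as the image's own 256-bin CDF mapping and is governed by the `equalize`
config flag, default on. It exists to remove acquisition drift between
real slices. For synthetic phantoms it should be off: exact equalization
maps any intensity distribution to uniform on [0, 1], which drives the
two-class threshold to ≈ 0.5 regardless of content and makes the modulated
threshold select a fixed ~41 % darkest-pixel quantile — appropriate only
when the dark class is itself a large intensity mode, never in a sparse
phantom whose sections are intensity-consistent by construction. All
phantom-based tests and the acceptance script therefore run
`equalize: false`.

## Segment geometry conventions

Segments are 8-connected (thin diagonal neurites must not fragment).
Centroids use the 0-based pixel-center convention; bounding boxes are
half-open. The major axis is 4·√(largest eigenvalue of the pixel-coordinate
covariance) — the moment-equivalent ellipse, without the +1/12
discrete-pixel correction — and the 900 px filter bound is interpreted in
this convention. The filters (3 px < area < 130,000 px, major axis
< 900 px) are strict at every bound.

Artifact pruning concretizes "irregularly large objects interrupting a
process's progression" as: a segment is flagged when it has
candidate-linked neighbors on *both* adjacent sides (two-sided screening
query over the linking radius and gap range) and its area exceeds 10×
(configurable, `filter.prune_area_ratio`) the median neighbor area.
Flagged segments are excluded from linking but kept in the store with a
reason code for audit.

## Linking and merging

Candidates for each segment are pooled over z-offsets 1..`max_gap_sections`
(default 3) within `radius_nm` (default 2000 nm, several dendrite
diameters); the k = 2 of minimum *in-plane* physical distance are linked
(distance ties break toward the smaller label). z is excluded from the
metric deliberately: at 30-270 nm section spacing a z term would swamp
in-plane proximity. One pooled k across all offsets (rather than k per
section) matches a single-k nearest-neighbor search and leaves room for a
branching process (one continuation + one branch). The search runs upward
only; edges are undirected, so the graph is the same set a bidirectional
search would deduplicate to, minus the k-budget spent on reverse queries.

Reconstructions are connected components of the link graph, followed by a
consistency pass: two components holding same-section segments that
overlap in-plane by ≥ 50 % of the smaller area are merged (duplicate
detections of one physical object). Component numbering is deterministic:
descending total 2D area, ties by smallest member label.

A known consequence of the k-NN rule: a segment with fewer than k
same-process candidates in range (stack ends, process terminations) will
link its next-nearest neighbor if one sits inside `radius_nm`, fusing two
processes. Processes separated by more than the radius are immune; this is
why the phantom's default geometry keeps tube centerlines beyond the
radius (below).

## Phantom generator

The generator emulates overview-resolution stacks of sparse dark tubes in
textured neuropil. What it reproduces: contrast polarity and scale,
smooth (bounded-curvature) 3D trajectories, anisotropic voxels, per-pixel
noise, smooth background texture, per-section alignment jitter, missing
sections (dropout keeps z-indexing: a gap, not a renumbering), and
optional large dark distractor blobs that are *not* recorded as processes.
What it does not reproduce: membranes, organelles, section-thickness
variation, staining gradients, charging or focus artifacts — so passing
tests demonstrate the pipeline's logic and its behavior in the intended
contrast regime, not performance on real tissue.

Defaults (all configurable through `phantom.*`): 100 sections of 512×512
at 30 nm/px and 30 nm spacing (the overview-imaging regime), 10 tubes of
radius 6 ± 0.5 px (≈ 360 nm diameter, mid-range for dendrites), stained
intensity 0.15 ± 0.02, background 0.65 ± 0.02 with texture correlation
length 24 px, extra white noise sd 0.015, jitter ± 2 px, no distractors.
Two constraints drove the geometry:

- tube centerlines stay mutually separated beyond the 2000 nm linking
  radius (start separation ≥ 96 px, meander amplitude capped at 12 px), so
  "well-separated" holds in the sense the linker needs;
- the stained class carries enough histogram weight that the Otsu gap
  maximum dominates any internal background split on every section, making
  the threshold branch deterministic across sections and seeds.

Centerlines are smoothed, end-pinned random walks scaled to a bounded
lateral amplitude; radii are per-process; jitter shifts each section's
content and is reflected in the ground truth, so truth masks remain
geometrically consistent with the rendered images. Intensities are
generated on [0, 1]; the 8-bit TIFF export quantizes by rounding. The
distractor preset draws blobs of radius ≈ 210 px, whose area exceeds the
130,000 px filter bound, so filter efficacy against large non-neuronal
objects is directly testable. Output is a pure function of the spec
(which includes the seed).

## Evaluation

Recall is per-truth-segment: each connected component of each process's
per-section mask counts once, and is recovered when a *single* predicted
segment covers ≥ `eval.min_overlap` (default 0.5) of its area. Missed
segments are summarized by mean bounding-box height × width. Precision
(predicted segments whose pixels are ≥ 50 % truth-labeled) is reported for
information only. Split errors count extra components per truth process;
merge errors count extra truth processes per component, with each segment
assigned to its majority-overlap process.

ROI proposal pads selected components' bounding boxes by `eval.roi_margin_nm`
(default 500 nm), clips to the volume, and reports
V_total / V_roi — the factor by which targeted re-imaging reduces
acquisition relative to imaging the whole overview volume at high
resolution. Volumes are computed in nm³ and reported in µm³, so the factor
is unit-consistent by construction.

## Numerical and problem-size choices

- All stages are deterministic given (inputs, config, seed); per-section
  work (thresholding, component extraction) is independent across sections
  and operates one section at a time, so memory stays proportional to one
  section plus the segment table.
- The acceptance script and end-to-end tests use the default phantom
  (5 seeds × 100 sections of 512×512 plus one dropout variant), about a
  minute of single-CPU work, which is ample to exercise every stage at the
  generator's stated conditions.
- Degenerate inputs: blank sections fall back to the modulation cutoff;
  empty masks yield empty segment lists; empty reconstructions export
  valid empty artifacts; zero-variance CNR with distinct means returns
  signed infinity by contract.

## Known limitations

- No splitting of touching processes (no watershed/boundary evidence); two
  labeled processes in contact in-plane will merge.
- The pruning rule is a concrete stand-in for an informally specified
  artifact-rejection step; its ratio is a free parameter.
- Recall measured on phantoms is an upper bound on real-data performance:
  the phantom's contrast (CNR ≈ 14) is cleaner than real DAB-stained
  tissue, and none of the failure modes of real EM (staining gradients,
  fold/debris artifacts, alignment error beyond small jitter) are
  simulated beyond the distractor blobs.
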