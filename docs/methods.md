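# Methods

This note documents the models, parameters and design decisions behind
`osteoatlas`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The problem being modelled

Osteocytes inhabit lacunae in mineralized bone and communicate through
dendritic processes in canaliculi. A standard morphological surrogate for
cell health in block-face imagery is the number of visible processes: cells
showing three or more are read as viable, fewer as pyknotic (condensed /
fragmenting nuclei). Multibeam SEM makes region-scale maps of these cells
possible — one stage position (mFOV) is imaged simultaneously by an array
of beams (61 on the prototype generation used for the default accounting),
each beam yielding one tile — but real maps run to 10^5–10^7 tiles and are
not publicly deposited. The package therefore treats the *workflow* as the
object of study and supplies its own imaging model with exact ground truth.

## Phantom model (`phantom`)

Grey-level conventions follow backscatter contrast of a carbon-coated PMMA
block face: light resin background (200 on the 8-bit scale), dark somata
(60), darker nucleus (25), thin dark processes (60). A ghost lacuna — a
resin-filled cavity with no cellular content — renders as a smooth fill
(150) with a darker rim (100), no nucleus and no processes; its only
distinguishing feature is the *absence of interior texture*, which is what
the classifier's `ghost_suspect` flag keys on.

Parameters and defaults (`PhantomSpec`):

| parameter | default | meaning |
|---|---|---|
| `n_cells` | 200 | lacunae per panorama (benchmark size) |
| `viable_fraction` | 600/650 ≈ 0.923 | P(viable) among non-ghosts; mirrors a 600 living / 50 pyknotic annotation corpus |
| `ghost_fraction` | 0.05 | P(ghost) per lacuna |
| `soma_axes_px` | 20 × 12 | full ellipse axes at native scale |
| `process_length_px` | 40 | radial ray length beyond the soma |
| `noise_sd` | 8 | additive Gaussian grey-level noise |
| `background_level` | 200 | resin grey level |

No size or intensity statistics exist for the real imagery at 12 nm/px, so
these are plausible placeholders chosen once, not calibrated values; the
92% benchmark below is a *surrogate* statement about this synthetic model,
not about bone.

Process counts are drawn conditioned on status — viable uniform on {3..8},
pyknotic uniform on {0..2} — so the ground truth satisfies the
classification rule by construction. Ray angles are rejection-sampled with
a minimum separation of 20°. Cell centres are uniform over the admissible
interior with a hard-core minimum spacing of twice the soma major axis
(40 px); exceeding packing capacity raises an explicit error. Overlap of
*processes* between neighbouring cells is allowed and intended — it is the
main realistic nuisance the classifier must tolerate. Rendering composites
patches by pixelwise minimum (dark features win), then adds one noise field
over the whole panorama; all draws come from a single seeded generator, so
output is byte-reproducible.

Ground-truth boxes are fixed 96 px squares for every cell regardless of how
many rays happen to be rendered. The box represents the nominal whole-cell
footprint (soma + processes ≈ 100 px; trimmed to 96 so that two cells at
the minimum spacing cannot exceed the 0.5 NMS IoU even with a few pixels of
localization error). Using one nominal size for all cells keeps IoU
matching consistent between 0-ray and 8-ray cells.

What the phantom does **not** model: electron-optics artifacts, stage
drift, illumination gradients, blood vessels and bone-lining cells (an
optional `distractors` flag adds large faint ellipses for stress tests),
canaliculi as *connected* inter-cell channels (rays are local), and any 3-D
structure. Passing tests therefore demonstrate the pipeline's correctness
and its behaviour under this noise model — not detector performance on real
mSEM data.

## Geometry and stitching (`geometry`)

Accounting is exact integer arithmetic: tiles = mFOVs × beams/mFOV, and
storage = pixels × bytes/px with 1 Mpx = 10^6 px, 1 TB = 10^12 bytes at
1 byte/px greyscale. The hexagonal beam layout (1 centre + rings of
6/12/18/24 = 61) is provided as a geometry helper in ring order; phantom
tile coverage itself uses a rectangular stride grid (stride = tile −
overlap, last row/column shifted inward), because complete coverage and an
exact stitch round trip are what downstream stages consume.

Stitching copies each tile at its recorded coordinate — no registration,
no resampling. In overlaps the later-indexed tile wins (a mean-blend option
exists); since phantom overlaps are copies, partition→stitch is
pixel-identical, which the suite asserts on 20 random phantoms. A missing
tile file is a hard error naming the tile; duplicated origins only warn.

`downscale_for_detection` computes `scale = min(1, target/native)` with
`target = 200 px` per cell, area-averages, and records the composite pixel
size `pixel_size_nm / scale`. Upsampling is never performed. At the phantom
defaults the native cell is already ~100 px, so the benchmark runs at
native scale.

## Detection (`detect`)

The detector keeps the standard single-shot contract — resize onto a
448 × 448 letterboxed canvas, divide into an S × S grid (S = 7), at most
one candidate per grid cell, five predictions (X, Y, W, H, p) per box,
greedy NMS, confidence floor 0.5 — while the scoring backend is a
deterministic matched filter: normalized cross-correlation against a bank
of elliptical soma templates (six orientations at 30° steps; scales
configurable). NCC is contrast- and offset-invariant, which is realistic in
an uncalibrated-grey-level setting and means ghost lacunae *are* detected —
as in the original workflow, where they were a known confounder; they are
handled downstream, not hidden.

Confidence is a fixed, documented map of the NCC score: p = clip((score −
0.2) / 0.7, 0, 1). NMS suppresses first (descending p, ties broken by
(X, Y); suppression at IoU > 0.5) and applies the p > 0.5 floor afterwards
— for any input that matters the two orders agree, and suppress-first gives
the simpler invariant. The floor is strict, as is the separate 0.7 display
floor used only for pin rendering.

Large panoramas are processed by `detect_panorama`: the response map is
computed once over the full image (NCC normalization is local to the
template footprint, so this equals per-window responses away from borders),
the grid-candidate rule is applied in overlapping 448 px windows (stride
224 — the half-stride shifts grid boundaries so two nearby cells sharing a
grid cell in one window are split in another), and one global NMS pass
removes duplicates.

Training-set plumbing exists for pluggable learned backends: `augment`
expands annotations over a deterministic transform grid and returns
*parameter records* (images materialize on demand), so million-example
grids cost metadata only. The default grid is 30 rotations (12° steps) ×
53 scales (1% steps, 0.74–1.26) × 1 contrast × 1 translation = 1,590
transforms; 629 annotations × 1,590 = 1,000,110 examples. The 53-point
axis is placed on scale because the grid size factorizes as 30 × 53 and 53
is prime — contrast and translation variation are available by supplying
non-default lists. `split` partitions **by source annotation**
(round(0.75 · n) sources to training), so no test example is a transform of
a training example; this leakage guard is a deliberate strengthening over
splitting the augmented pool directly.

`evaluate` matches detections to ground truth one-to-one, greedily by
descending IoU with a 0.5 floor. Accuracy is defined as *joint* detection +
classification: matched non-ghost cells whose predicted class equals the
true status, divided by the non-ghost truth count. Ghosts are excluded from
that denominator; a detection matched to a ghost counts against precision
unless ghost-tolerant mode is on. This metric definition is the package's
own — the original 92% figure was reported without one, so the benchmark
treats 92% as a target under this stated metric on synthetic data only.

## Classification (`classify`)

Each detection is cropped at 1.5× its box. Segmentation thresholds at
median − max(4·σ̂, 5) grey levels, with σ̂ the MAD-based noise estimate of
the patch — a small-foreground-fraction regime where histogram-split
thresholds (e.g. Otsu) latch onto the background noise mode instead of the
cells. The mask is closed with a 1 px element and reduced to the connected
component containing (or nearest) the patch centre; empty or sub-30 px
foreground flags the record unsegmentable rather than forcing a call.

Process counting: the soma is isolated by a 3 px-radius opening (which
erases the thin rays), the mask is skeletonized, and distinct skeleton
crossings of an annulus centred on the soma blob are counted, merging
crossings within 15° of arc. The annulus radius is 1.2× the *mask*
equivalent radius (√(area/π)): because the mask area grows with the number
and length of processes, the annulus automatically moves outward to where
adjacent rays (≥ 20° apart) have separated from the merged wedge they form
near the soma boundary — at the soma-only radius, 20°-spaced rays of
2–3 px width physically overlap and cannot be resolved. A crossing must
also have skeleton support beyond the annulus (+2 px), which rejects
boundary spurs. Centring on the soma blob rather than the whole-mask
centroid keeps the count local when a neighbour's process wanders into the
crop. The noise-free sweep test recovers 0–8 rays exactly across random
orientations and angle sets.

The viability call is the pure threshold **n ≥ 3 → viable** (exactly 3 is
viable, resolving the tie in favour of the "three or more" reading; the
boundary is asserted in tests). Records whose eroded soma interior variance
falls below 150 grey² are flagged `ghost_suspect` — the erosion (4 px)
must shed the lacuna rim, otherwise rim/fill contrast masquerades as
texture. Flagged records keep their nominal status but are excluded from
pin display. No biological validity is claimed for any of this: process
count is a surrogate that the source literature itself reports as flawed.

## Connectome (`connectome`)

Canaliculi are not imaged, so edges are a documented stand-in: link two
cells when their centres are within 60 µm, then prune each node to its 12
nearest neighbours with *mutual* pruning (an edge survives only if both
endpoints keep it); distance ties break on node id, making the graph
deterministic.

Information transfer is operationalized as global efficiency with
hop-count distances, E = mean over ordered pairs of 1/d(i,j), 1/∞ = 0
(µm-weighted paths behind a flag). Node-removal curves evaluate efficiency
over the **original** pair count N₀(N₀−1): efficiency over remaining pairs
can *rise* when a peripheral node is deleted, whereas the original-pair
normalization is provably non-increasing under node removal — that is the
testable choice, and the suite asserts it for every strategy. Curves are
normalized by the intact-graph value (transfer starts at 1, ends at 0);
replicate mean and standard deviation are reported. Strategies: uniformly
random order; pyknotic-first (random within each status group, reducing
exactly to random when no pyknotic cells exist); degree-targeted
(descending *initial* degree, ties by id — degrees are not recomputed
during removal). `compare_strategies` reports the area under each curve and
whether the expected ordering (targeted ≤ random) held; it is reported, not
asserted, because small graphs can violate it by chance.

No numeric curve from the source imagery is used as a target: the original
stochastic network model's parameters and y-axis quantity are not
recoverable, so the module's claims are structural (monotonicity,
determinism, brute-force agreement on ≤ 8-node graphs).

## Atlas export (`atlas_export`)

The panorama at native resolution is the deepest zoom level;
max_zoom = ceil(log₂(max_dim / 256)). Each coarser level is a 2× block
mean (odd edges padded with background), so level z−1 dimensions are
ceil(level-z/2) and level 0 always fits one 256 px tile; tiles are written
as `tiles/{z}/{x}/{y}.png` in a flat XYZ scheme with y increasing downward
— the specimen plane is flat, so no map projection is used. Pins are
normalized by the native panorama dimensions (centre = (0.5, 0.5)) and
exported as GeoJSON plus a CSV mirror; the transforms are exact inverses up
to float quantization (≤ 0.5 px asserted). The display filter is strictly
p > 0.7 and never shows unsegmentable or ghost-suspect records. A stub
`index.html` is emitted for convenience and is not part of the tested
surface.

## Problem sizes and numerical conventions

The default benchmark (200 cells, 4 mFOV × 4 beams, 512 px tiles, 32 px
overlap → a 1952 px panorama) is the package's chosen desk scale: large
enough for ~15 ghost lacunae and realistic process overlap between
neighbours, small enough that the full pipeline runs in seconds. All
coordinates are 0-based pixels, origin top-left, x rightward, y downward,
half-open pixel intervals; physical coordinates are pixels ×
pixel_size_nm (12 nm default). Seeds below 2³¹ drive every random draw
through `numpy.random.default_rng`.

## Known limitations

- Phantom appearance parameters are uncalibrated placeholders; the
  benchmark accuracy says nothing about real mSEM imagery.
- The table-driven storage model (1 byte/px) reproduces only the
  first-generation size at rounding precision; later-generation pixel
  totals imply unstated overlap fractions and are not independently
  recomputable, so only tile counts are used as cross-checks.
- 2-D block-face process counts undercount true 3-D dendrites; no
  correction is attempted.
- The NCC backend assumes roughly elliptical dark somata; it is a contract
  stand-in, not a competitor to a trained convolutional detector.
- Streaming block-wise stitching keeps memory proportional to the output
  panorama; terabyte-scale mosaics are out of scope by design.
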