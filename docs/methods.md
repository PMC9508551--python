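# Methods

## The processing model

`plateseg` treats a bulk microCT scan of stacked microtiter plates as three
greyscale populations: air (near 0), the plate/mount material (intermediate),
and the specimens (high). Two physical effects complicate a clean three-level
picture: partial-volume averaging, which smears a "halo" of intermediate
values around every material boundary, and scanner noise. The segmentation
model is therefore intensity-only and intentionally simple — quantise,
bracket, then rely on 3D connectivity and a size filter to separate real
specimens from residual mount fragments. It assumes the mount was chosen to
be less dense than the specimens; it makes no attempt at multiphase
segmentation or at specimens overlapping the mount in density.

### Quantisation (cel-shading)

`X_new = X − (X mod C)` maps every intensity onto the floor of its bin of
width `C`. It is idempotent, never increases a value, and yields
`⌊levels/C⌋` usable grey bins on an image of `levels` levels (the count
conventionally quoted; direct enumeration over 0..255 gives one more, the
zero bin — `grey_level_count` exposes both conventions). Quantisation is
applied *before* thresholding and is optional (`cel_base=0` disables it).
Note the rounding is always downward; voxels just below a bin edge drop into
the lower bin, which can erode one voxel from specimen margins — the export
margin (below) compensates.

### Bracketing

Foreground is `T_lower ≤ X ≤ T_upper`, both cuts applied together. The
upper cut exists for dense inclusions and bright artefacts; with
`T_upper = 255` it reduces to an ordinary lower threshold. Thresholds are
inclusive. When both thresholds are multiples of the cel-shading base and
the bracket is aligned to bin edges, bracketing commutes with quantisation.

### Blobbing

Connected components of the binary mask under 6/18/26-connectivity
(default 26, so diagonally touching fragments of one specimen stay
together). Components below `min_blob_size` voxels — counted at the working
(downsampled) resolution — are discarded. Blob ids are assigned in raster
order of each component's first voxel, making exports reproducible
run-to-run. An exhaustive BFS flood fill serves as the test oracle.

## Plate detection and labelling

A z-slice is "occupied" iff its foreground pixel count is at least
`min_blob_size`; maximal runs of occupied slices are plates, and the plate
centre is the median slice of the run (a half-integer for even runs; it is
only used for ordering, never as an index). This exploits the guaranteed
empty gaps between stacked plates and is exactly reproducible by a 1D
run-length computation, which is how it is property-tested.

Label grids come from one header-less CSV per plate, cells mirroring the
physical wells; blank cells mark empty wells, and duplicate IDs within one
CSV are rejected (they would collide as filenames). Cell (r, c) starts at
`((c+0.5)·pitch_x, (r+0.5)·pitch_y)` and the user transform is applied in
the fixed order flips (about the grid centre) → rotation (about the grid
centre) → translation. The corner IDs after flips are logged so a human can
catch a mirrored scan; no automatic mirror correction is attempted.

Matching direction: each blob is matched to its nearest non-empty cell
centre in the plate plane (2D; grids are planar per plate), with per-cell
multiplicity allowed. This single rule realises both special cases: an empty
cell can never be matched, and a doubled well (two specimens in one well)
yields two assignments suffixed `_1`/`_2` by ascending distance. Blobs
farther than `max_match_distance` from every cell (default
`0.75·min(pitch)`) — and all blobs when no CSV is given — receive sequential
`specimen_NNNN` labels rather than being dropped: data is never silently
lost. Equidistant cells tie-break row-major-first; a blob whose centroid
falls in a gap between plates is attached to the nearest plate by centre
distance. Cross-plate label collisions are resolved by a `.2` suffix as a
final uniqueness guard.

## Export and meshing

Segmentation runs on the stride-downsampled template (output voxel
`(i,j,k)` = input `(i·f, j·f, k·f)`, dims floored; block-mean averaging is
available behind a flag but the template is only a guide, so the fast stride
is the default). Exports go back to the original files: the blob bounding
box is multiplied by the factor, grown by a margin (default 2 full-resolution
voxels, so blurred halos survive the crop) and clamped; the blob's
working-resolution mask is upscaled by nearest-neighbour block replication.
Three stacks per specimen: raw crop (8-bit; deeper inputs are min–max
rescaled), `{0,255}` mask, and processed (raw voxels inside the mask, zero
outside — so `processed = raw × mask/255` holds identically). Filenames are
rooted at the assigned label, ASCII-sanitised (anything outside
`[A-Za-z0-9._-]` becomes `_`), and a manifest CSV records label, cell, bbox
and voxel size per specimen.

Meshes are extracted from the blob's binary mask (not the greyscale crop)
with marching cubes at iso-level 0.5, after one-voxel zero padding so
border-touching specimens still close. No smoothing, decimation or repair is
performed. Vertices are re-centred on their centroid and scaled by
`voxel_size_um / 1000` to millimetres. PLY output is binary little-endian by
default (ASCII behind a flag), float32 vertices, uint32 face indices, with
the label, voxel size and units carried as header comments; the writer is
deliberately minimal and is cross-checked against an independent reader
(trimesh) in the tests. Hollow point clouds keep only boundary voxels —
per-slice 2D boundary retention by default (internal surfaces and voids are
preserved), with a full-3D morphological boundary behind `method="3d"`; the
brute-force surface-voxel oracle checks the 3D variant. Boundary retention
is morphological (foreground minus its erosion) rather than a gradient edge
detector, because the contract is "keep exactly the boundary voxels".

## The synthetic phantom

The generator emulates the structural features the pipeline depends on:
mount-grey slabs stacked in z with empty gaps; cylindrical well cavities on
a regular pitch (well radius 0.35·pitch, a 2-slice mount floor); occupied
wells holding random ellipsoids (axis ratios in [0.5, 1]) of specimen grey;
Gaussian blur (the partial-volume halo) followed by additive Gaussian noise
clipped to [0, 255]. Defaults: 2 plates of 4×6 wells (a 24-well plate),
pitch 16 voxels, specimen radii 3–5 voxels, grey levels 0/31/114
(air/mount/specimen — the three-peak histogram of a real bulk scan),
blur σ 0.7 voxel, noise σ 2 grey levels, 8-slice gaps, 14-slice plates,
48 µm voxels. Specimens are centred in their wells by default (a `jitter`
knob displaces them for irregularity tests). A `doubled_well` mode puts two
fixed-radius spheres in the first occupied well — pushed apart so the blur
halo cannot bridge them at the working threshold — and empties the last, to
exercise the suffixed/absent labelling paths.

What the phantom does **not** model: ring artefacts, beam hardening, cupping,
drift, polychromatic spectra, realistic bone micro-structure, or specimens
touching each other or the well walls. Tests passing on phantoms therefore
demonstrate the correctness of the pipeline's logic (segmentation,
detection, matching, export geometry), not robustness to every real-scan
pathology; on real data the thresholds and the grid transform remain the
user's responsibility.

## Numerical and design choices

- Indexing is 0-based `(z, y, x)` everywhere; z is the stacking axis.
- `.info` sidecar dialect: UTF-8 `key=value` lines, mandatory
  `voxel_size_um`, optional `dims=z,y,x`, `bit_depth`, `slice_order`,
  `downsample_factor`; unknown keys tolerated so vendor files can be pointed
  at directly. A missing voxel size raises a recoverable "metadata absent"
  error so callers can supply one and regenerate the file.
- TIFF slices are ordered by numeric-aware filename sort unless an explicit
  `slice_order` is given. Raw input is voxel-major, x fastest; its byte size
  must equal `prod(dims) × bytes/voxel` exactly.
- The stated bit depths 8/16/32 are read as unsigned integers; float TIFF
  input is accepted and min–max rescaled by `to_8bit` (8-bit input passes
  through untouched; constant input maps to 0).
- Mesh watertightness (every edge shared by exactly two faces) holds for
  specimen-like (blob) masks; voxel soup with diagonal self-contacts can
  produce non-manifold edges, which is outside the intended input class.
- Problem sizes in tests and the acceptance script (phantoms of ~50×80×110
  voxels, 16³/12³ oracle masks, radius-10 spheres) were chosen as the
  smallest sizes at which every behaviour of interest — multi-plate
  detection, 48-specimen recovery, sub-5% sphere-volume agreement — is
  expressed; everything scales to full scans linearly in voxel count.

## Known limitations

- Intensity-bracket segmentation cannot separate specimens overlapping the
  mount in density; no adaptive (Otsu) or learned thresholding is provided.
- Grid placement is manual (transform in the config); there is no automatic
  grid-to-plate registration.
- Mask upscaling is block replication; `ExportJob.rethreshold` optionally
  re-applies the greyscale bracket to the full-resolution crop within the
  blob's support for sharper edges, at the cost of reading intensities twice.
- No 16-bit export, STL output, or mesh smoothing.
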