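# plateseg

Segment, label and export individual specimens from bulk microCT scans of
stacked microtiter plates.

Bulk scanning places tens to hundreds of small specimens (bone fragments,
teeth, seeds) in the wells of standard microtiter plates, stacks the plates
vertically and digitises the whole stack in one scan. That makes acquisition
fast, but leaves the downstream bottleneck: splitting one enormous volume
into per-specimen datasets *without losing the externally assigned specimen
IDs* (museum accession numbers, lab codes). `plateseg` automates that step,
headlessly: it segments the scan, detects the plates, matches each specimen
to its well in a CSV spreadsheet that mirrors the plate layout, and exports
each specimen as full-resolution 8-bit TIFF stacks plus a real-unit PLY
surface mesh — all named by its original ID.

## Method

Scans arrive as a headerless `.raw` volume or a folder of single-slice
TIFFs, with a plain-text `.info` sidecar carrying the voxel size. The volume
is stride-downsampled on import into a working template. Segmentation is
deliberately simple and fast:

1. **Cel-shading** (optional): each voxel intensity X is quantised to
   `X_new = X − (X mod C)` for a base value C, collapsing similar greyscales
   into bins. An 8-bit image (255 levels) with base 10 has 25 grey bins,
   which makes threshold choice straightforward and suppresses noise.
2. **Greyscale bracketing**: a voxel is foreground iff
   `T_lower ≤ X ≤ T_upper`, excluding both the low-density mounting material
   below the bracket and any dense artefacts above it.
3. **3D blobbing**: connected components (26-connectivity by default) of the
   foreground mask become candidate specimens; components smaller than a
   minimum voxel count (residual mount fragments) are discarded.

Plates are found as maximal runs of z-slices whose foreground pixel count
reaches the minimum blob size; the gaps between runs are the empty spaces
between stacked plates. Each plate has a CSV grid of specimen IDs matching
its well layout. The grid is placed over the scan by a user transform
(flip → rotate → translate, with per-axis well pitch), corner IDs are logged
so a mirrored scan is caught by eye, and each blob is assigned the label of
its nearest non-empty cell centre (Euclidean distance in the plate plane).
Doubled wells yield suffixed labels (`…_1`, `…_2`); blobs far from any cell,
or whole plates without a CSV, fall back to sequential numeric labels so no
data is dropped.

Finally each specimen's bounding box is scaled back to the original
full-resolution data and exported in three modes (raw crop, binary mask,
masked "processed" crop), and its mask is meshed with marching cubes
(iso-level 0.5, one-voxel padding, no smoothing), re-centred on the origin,
scaled from voxels to millimetres using the scan voxel size, and written as
PLY.

A fully synthetic phantom generator (`plateseg.phantom`) renders stacked
plates with known specimen placements, the three-peak air/mount/specimen
histogram structure of real scans (grey levels 0/31/114 by default),
partial-volume blur and additive noise — so the entire pipeline is testable
end-to-end without any scan data.

## Worked example

Generate a synthetic two-plate scan (2 × 4×6 wells, fully occupied), then
run the whole pipeline on it at downsample factor 2:

```sh
plateseg phantom --out scan --seed 1
cat > run.yaml <<EOF
input: scan/slices
kind: tiff_folder
out_dir: exports
downsample_factor: 2
segmentation: {t_lower: 52, t_upper: 255, min_blob_size: 1}
plates:
  - {csv: scan/plate_1.csv, transform: {translate: [3, 3], pitch: [8, 8]}}
  - {csv: scan/plate_2.csv, transform: {translate: [3, 3], pitch: [8, 8]}}
EOF
plateseg run --config run.yaml
```

which prints (abridged):

```
INFO working volume: dims=(26, 38, 54) (factor 2)
INFO segmentation: 48 blobs, 2 plate spans
INFO plate 0: slices 6..10, centre 8.0
INFO plate 1: slices 18..20, centre 19.0
INFO plate 0 corner labels (after flips): ('P1-A01', 'P1-A06', 'P1-D01', 'P1-D06')
INFO blob 1 -> P1-A03 (plate 0, cell (0, 2), distance 0.00)
...
INFO exported 48 specimens
exported 48 specimens to exports
```

All 48 specimens were found, split into the two plates, and matched to their
spreadsheet IDs (the logged distances are blob-centroid to well-centre, in
working-resolution voxels). `exports/` then holds one folder per specimen —

```
exports/P1-A01/raw/P1-A01_raw_0000.tif ...   # full-resolution crop
exports/P1-A01/mask/...                       # {0,255} binary mask stack
exports/P1-A01/processed/...                  # crop zeroed outside the mask
exports/P1-A01/P1-A01.ply                     # surface mesh, mm units
exports/manifest.csv                          # label, cell, bbox, voxel size per row
```

The same stages are available piecewise (`plateseg segment`, `label`,
`export`, `mesh`, `split-plates`) and as library functions.

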