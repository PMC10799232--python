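# cycleproc

Preprocessing for cyclic multiplexed fluorescence acquisitions: from raw
per-cycle folders of single-plane 16-bit TIFF tiles to corrected, registered,
stitched mosaics, segmented nuclei and per-cell measurement tables
(CSV, FCS 3.1, ImageJ ROI zip).

The processing chain, in canonical order:

| step            | what it does |
|-----------------|--------------|
| `deconvolve`    | Richardson–Lucy deconvolution of each Z-stack (Gaussian widefield PSF from wavelength / NA / voxel size; 10 iterations by default) |
| `edf`           | extended depth of field: per-pixel in-focus slice selection (variance-of-Laplacian focus measure) |
| `shading`       | per-channel shading profiles from the first/last anchor cycles — median across positions divided by its σ=64 Gaussian blur — linearly interpolated per cycle, then divided out |
| `background`    | blank-cycle autofluorescence (σ=10 blur) linearly interpolated across cycles and subtracted |
| `register`      | translation-only inter-cycle registration by phase correlation on the nuclear channel; common-frame crop by the greatest translation |
| `clip_negatives`| negatives → 0, then minimum positive value subtracted from the positive pixels |
| `stitch`        | neighbour offsets from overlap strips, maximum-quality spanning tree, one uint16 mosaic per (cycle, channel) with feathered blending |
| `segment`       | nuclei from the reference-cycle nuclear mosaic (classical watershed segmenter; pluggable seam for e.g. StarDist) |
| `overlay`       | RGB outline overlay of the segmentation |
| `measure`       | per-cell centroid, shape descriptors and per-(cycle, channel) mean intensities |
| `export`        | analysis-ready output tree with checksum manifest |

A synthetic-acquisition simulator (`cycleproc.synthetic_acquisition`)
generates phantom tissue with known ground truth — vignetting, cycle-drifting
autofluorescence, stage drift, Z defocus, noise — written in the exact raw
layout, and backs most of the test suite.

## CLI

```sh
# write a synthetic acquisition (raw layout + ground-truth sidecar)
cycleproc simulate --out /tmp/acq --seed 1 --n-nuclei 30

# check a raw directory against its Experiment.json
cycleproc validate /tmp/acq

# run the pipeline (any subset of steps; stages resume from work_dir)
cycleproc run --config config.yaml --steps edf,shading,background,register,clip_negatives,stitch,segment,measure,export
```

Minimal `config.yaml`:

```yaml
input_dir: /tmp/acq
work_dir: /tmp/work
output_dir: /tmp/out
```

## Raw input layout

One folder per cycle (`cyc01`, `cyc02`, …) of single-plane TIFFs named
`<experiment>-position{P}_Z{ZZ}_CH{C}.tif`, plus `Experiment.json` (grid
rows/columns, overlap fraction, snake order, wavelengths, voxel size,
numerical aperture, …) and `channelNames.txt` (one reporter per line,
cycle-major; the literal `Blank` marks a channel acquired without reporter —
the first and last cycles are blank anchors used for shading and
autofluorescence estimation).

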