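# adipometry

Calibrated adipocyte counting and sizing for H&E-style micrographs, plus
colour-separation area quantification for histology and fluorescent images.

The pipeline: load a raster image (TIFF/PNG/JPEG/BMP), resolve a
micron-per-pixel calibration (metadata tag, manual line, or explicit value),
condition the image (haze removal, median denoising, Otsu or manual
thresholding, border-line thickening), trace the external contour of every
8-connected foreground object with collinear chain compression, measure
pixel and physical areas, and filter reversibly by size range, frame
contact, or manual point clicks. Results export to CSV/xlsx; two methods'
binned results can be compared by Pearson correlation and percent
differences. A synthetic-tissue generator with exact ground truth backs the
test suite — no external data is needed.

## CLI

```sh
# generate a synthetic 50-cell mosaic with ground truth
adipometry synth --kind voronoi --seed 2 --cells 50 --out scratch/

# count and size cells (calibration from TIFF metadata here)
adipometry count scratch/voronoi_2.tif --exclude-border \
    --min-area 250 --max-area 2000 --bins 10,251,501,1001,2001,3001,4001,6001 \
    --out scratch/run1

# manual corrections: toggle the object at pixel (row,col), or hand-edit the
# exported mask in any paint program and feed it back
adipometry count img.tif --mpp 0.881 --toggle 120,84 --out out/
adipometry count img.tif --mpp 0.881 --edited-mask corrected.png --out out/

# colour-range area fraction and fluorescent channel splitting
adipometry colorsep img.tif --range 140:160,65:85,50:70 --mpp 0.881 --out out/
adipometry channels fluor.tif --select rb --out out/

# compare two methods' bin tables
adipometry compare out/bins.csv other/bins.csv --out out/
```

Calibration sources, in precedence order: `--mpp <float>`,
`--cal-line <px> <um>` (length of a drawn line and its true length), or
image metadata (TIFF resolution tags; unitless resolutions are read as
pixels per micron, and description text such as `microns per pixel: 0.5` is
also recognised).

## Layout

- `src/adipometry/io_calibration.py` — image I/O, MPP calibration, sessions
- `src/adipometry/preprocess.py` — dehaze/denoise/threshold/thicken, mask edit round trip
- `src/adipometry/segmentation.py` — external contour tracing, chain compression, cell populations
- `src/adipometry/filters.py` — size/border/manual exclusion (reversible)
- `src/adipometry/color_separation.py` — RGB-range masks, channel splitting, area fractions
- `src/adipometry/stats_report.py` — totals, histograms, method comparison, CSV/xlsx export
- `src/adipometry/fixtures.py` — deterministic synthetic tissue with ground truth
- `src/adipometry/cli.py` — `count`, `colorsep`, `channels`, `compare`, `synth`
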