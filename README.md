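# goldx

Detection and texture-matched erasure of gold fiducial markers in
cryo-electron-tomography tilt series.

Gold nanoparticles (5–15 nm) are added to cryo-ET samples as tracking
fiducials for tilt-series alignment. Their electron density is orders of
magnitude above the biology around them, and because tomograms are
reconstructed from an incomplete ±60° projection set, every bead seeds
non-local missing-wedge streaks that can bury nearby structures of
interest. Masking beads with uniform disks trades one artifact for another:
the sharp texture border of the disk streaks too.

`goldx` removes the beads in the 2D tilt images, before reconstruction:

1. **Detect** each bead with a *reduced template* — a point-set template
   with a dark inner disk, a thin bright outer ring at the defocus-halo
   radius, and an excluded gap annulus between them that absorbs
   bead-to-bead size variation. The score at position *p* is the locally
   normalized contrast

   *score(p) = (mean over ring − mean over disk) / s(p)*,

   thresholded at mean + 5 SD of the score map, eroded with a small disk to
   kill spurious single-pixel peaks. The only required inputs are the pixel
   size (Å/px) and the mean bead diameter (nm).
2. **Segment** each bead's exact shape by marker-based watershed of the
   intensity landscape (dark beads are basins), seeded by the detected
   peaks. A single marker on a cluster of touching beads floods the whole
   aggregate. The step takes no user parameters.
3. **Dilate** each mask with a disk so the bright defocus halo is covered.
4. **Replace** every masked pixel from a flat background square of the same
   tilt image (flattest of 50 random candidates by RMS deviation), drawing
   per-bead a random dihedral transform (mirror/90° rotations) and window,
   affinely rescaled to the mean and RMS of the pixels immediately
   surrounding the mask. No constant fill, no synthetic texture, no border:
   pixels outside the masks are bit-identical to the input.

The tool is for cryo-ET practitioners who align with gold fiducials and
want clean tomograms — in particular for data where beads sit on or next to
the structures being studied. It is tracking-free and
workflow-agnostic: any aligned (or raw) MRC tilt stack works.

## Worked example

Simulate a 9-tilt series (−60°…+60°) with 12 beads of known position,
erase them, and verify that nothing is left to detect:

```
goldx simulate --out stack.mrc --truth-csv truth.csv --seed 7 \
    --n-beads 12 --shape 512,512 --n-tilts 9 --tilt-min -60 --tilt-max 60
goldx erase --in stack.mrc --out cleaned.mrc \
    --pixel-size 4.59 --bead-nm 10 --seed 7 --report report.json
goldx detect --in cleaned.mrc --pixel-size 4.59 --bead-nm 10 \
    --out-markers residual.csv
```

The erase step logs one line per tilt:

```
INFO goldx: tilt 0: 12 markers
INFO goldx: tilt 1: 12 markers
...
INFO goldx: tilt 8: 12 markers
```

meaning all 12 beads were found on every tilt (at 4.59 Å/px a 10 nm bead is
a 21.8 px disk; the template's inner radius is 10.9 px). `report.json`
records, per tilt, the marker count, the chosen background square (origin,
side, RMS deviation) and any warnings; `residual.csv` comes back with a
header and zero rows — the cleaned stack contains nothing the detector
still considers a bead. Everything outside the dilated masks is
bit-identical to the input stack.

The same run on real data is just the `erase` line with your own stack. For
difficult data, tune on two images first (`--tilts 0,max`), inspect the
overlay PNG from `goldx detect` and the constant-fill preview
(`--preview-value 0`), then adjust `--threshold-sd`, `--scale` or
`--dilate-radius`; defaults are designed to need no tuning on well-behaved
series. All flags can also be given in a YAML file via `--config`
(flag > config > default), and `--seed` makes runs bit-reproducible.

## Library API

```python
from goldx import GoldXParams, process_stack, read_tilt_series

series = read_tilt_series("aligned_stack.mrc")
params = GoldXParams(pixel_size_angstrom=4.59, bead_diameter_nm=10.0, seed=7)
cleaned, markers, report = process_stack(series, params)
```

`detect_image`, `watershed_masks`, `dilate_masks`, `select_background`,
`random_patch`, `scale_patch` and `replace_fiducial` expose the individual
stages; `goldx.synth` generates synthetic tilt series with ground truth.
See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

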