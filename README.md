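# vitrophen

Side-view phenotyping of tissue-cultured grasses from RGB photographs.
The package isolates plant tissue from a blue imaging background with a
dual-colourspace pipeline, measures shape traits from the resulting binary
mask, and scores verdancy versus chlorosis with a CIELAB-based 0–100
greenness index. A synthetic scene generator with exact ground truth makes
the whole method testable without any study imagery.

## Method overview

1. **Crop** the working region (default 2800 × 2600 px, centred).
2. **Y branch** — convert to CMYK, binarise the yellow channel at
   threshold 45 (foreground above), then a 5 × 5 morphological closing
   followed by a 3 × 3 cruciform opening.
3. **a\* branch** — convert to CIELAB (D65/2°), encode a\* as offset-128
   8-bit, binarise at threshold 124 keeping the green side (≤ 124,
   equivalent to binarise-then-invert), then remove components
   smaller than 50 px.
4. **Fuse** the two masks with a logical OR and zero the background.
5. **Traits** — pixel area, convex hull area (pixel-count convention),
   outer-boundary perimeter (axial step 1, diagonal √2), solidity
   (area / hull area), and the foreground split above/below the medium row.
6. **Greenness** — over foreground pixels with a\* < 0 and b\* > 0, form
   ā = |mean a\*| and b̄ = mean b\*, take θ = arctan(ā/b̄)·180/π and map it
   linearly to [0, 100] with θ = 0° → 0 and θ = 90° → 100.

## Command line

```sh
# generate a synthetic 6-treatment × 3-day experiment (18 PNGs + truth.csv)
vitrophen synth --seed 4 --out scenes/

# batch-analyse a directory into traits.csv and summary.csv
vitrophen run --input scenes/ --manifest scenes/truth.csv \
    --config config.json --out results/

# summarise an existing traits table by (treatment, day)
vitrophen summarize results/traits.csv --out results/summary.csv
```

The segmentation config is a JSON or YAML mapping of
`SegmentationConfig` fields (`crop_width`, `crop_height`, `crop_anchor`,
`y_threshold`, `a_threshold`, `close_kernel`, `fill_min_size`,
`medium_row`). For synthetic scenes set the crop to the canvas size, e.g.
`{"crop_width": 480, "crop_height": 360, "medium_row": 300}`.
Image metadata comes from a manifest CSV (an `image` column plus
`treatment`, `plant_id`, `day` and optionally a per-image `medium_row`)
or, failing that, from filenames shaped `<treatment>_<plantid>_day<D>`.

## Python API

```python
from vitrophen import SceneSpec, SegmentationConfig, generate_scene
from vitrophen import segment_plant, greenness_index
from vitrophen import morpho

img, truth = generate_scene(SceneSpec(seed=7, chlorosis=0.25))
cfg = SegmentationConfig(crop_width=480, crop_height=360, medium_row=300)
mask, masked = segment_plant(img, cfg)
traits = morpho.compute_traits(mask, medium_row=300)
green = greenness_index(masked, mask)
```

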