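# organotrack

Pixel-level organoid detection, single-organoid identification, frame-to-frame
tracking and morphometric analysis for brightfield and phase-contrast
microscopy.

Organoids — 3-D multicellular structures grown from primary or stem cells —
are powerful *ex vivo* disease models, but extracting per-organoid counts,
sizes, shapes and death signals from time-lapse microscopy is laborious.
`organotrack` automates the full chain:

1. **Detection.** A compact u-net maps a grayscale image to a per-pixel
   organoid probability map `p(x, y) ∈ [0, 1]`. Channel widths are reduced to
   8 first-layer filters, keeping the network under 500,000 trainable
   parameters (the classic 64-filter layout exceeds 30 million) — a ≥98%
   reduction that limits overfitting on small annotated datasets. Hidden
   activations are ELU, the output is a 1×1 sigmoid convolution, dropout
   (12.5%) follows every convolution during training. The network is
   implemented in pure NumPy, including backpropagation and the Adam
   optimiser, so training and inference run anywhere NumPy does.
2. **Identification.** Because training masks carry a 2-pixel boundary
   between organoids in contact, the network is slightly less confident along
   contact lines. A Canny-style detector (Sobel gradient → Gaussian blur,
   σ = 2 → hysteresis threshold 0.05/0.005) finds those low-confidence
   contours; subtracting them from the thresholded (0.5) detection mask
   leaves one seed per organoid, and a watershed transform on the inverted
   probability map grows each seed back to its full contour. Objects under
   200 px or touching the border are discarded, yielding a labeled image
   (id k > 0 per organoid instance).
3. **Tracking.** Detections in consecutive frames are matched by the
   Hungarian (Munkres) algorithm on a cost matrix whose entries are
   1 / (shared pixels), padded with pseudo-assignment rows/columns so
   organoids can appear and disappear.
4. **Measurement.** Per organoid and frame: area, perimeter, centroid,
   circularity `4πA/P²`, solidity `A/A_hull`, eccentricity of the
   moment-equivalent ellipse, fluorescence density (signal per unit area),
   fold change vs. the initial timepoint, per-track normalisation to the
   timepoint of first detection, Cohen's *d* effect sizes, coefficients of
   variation, and 4-parameter-logistic dose-response fits
   `y = bottom + (top − bottom) / (1 + (dose/EC50)^hill)` for EC50 estimation.
5. **Evaluation.** Intersection-over-union (IOU), Lin's concordance
   correlation coefficient (with logit transform for metrics bounded in
   (0, 1)), Bland–Altman bias/limits of agreement, and per-frame tracking
   accuracy.

A synthetic-fixture module (`organotrack.synth`) generates organoid-like
scenes with exact ground truth — instance labels, probability maps with
reduced-confidence contact valleys, drifting/growing time-lapses with known
tracks, and dose-response tables with known EC50 — so the entire pipeline is
testable end-to-end without real microscopy data.

## Worked example

Generate a 6-frame synthetic time-lapse (4 organoids, 3% radial growth per
frame, 2 px drift), run the identification → tracking → measurement pipeline
on its probability maps, and inspect the measurement table:

```python
import pathlib
import pandas as pd
import organotrack as ot
from organotrack import io as oio
from organotrack.pipeline import RunConfig, run_pipeline

scene = ot.FixtureSpec(image_size=384, n_organoids=4, radius_range=(14, 22), seed=3)
ts = ot.TimelapseSpec(n_frames=6, drift_per_frame=2.0, growth_rate=0.03, seed=3)
tl = ot.make_timelapse(ts, scene)

src = pathlib.Path("example_probs"); src.mkdir(exist_ok=True)
for i, p in enumerate(tl.probs):
    oio.write_probability(src / f"frame{i}.tif", p)

run_pipeline(RunConfig(input_path="example_probs", output_dir="example_out",
                       inputs_are_probabilities=True))
m = pd.read_csv("example_out/measurements.csv")
print(m[["frame", "label", "track_id", "area_px2", "circularity",
         "solidity", "eccentricity"]].head(8).to_string(index=False))
```

```
 frame  label  track_id  area_px2  circularity  solidity  eccentricity
     0      1         1    1171.0     0.906669  0.969371      0.551928
     0      2         2     984.0     0.911573  0.973294      0.576642
     0      3         3     887.0     0.842037  0.972588      0.815659
     0      4         4     788.0     0.914059  0.972840      0.530316
     1      1         1    1243.0     0.916229  0.977201      0.555612
     1      2         2    1045.0     0.926487  0.980300      0.584718
     1      3         3     949.0     0.826438  0.967380      0.817185
     1      4         4     839.0     0.902516  0.968822      0.518025
```

All four organoids are identified in every frame and keep a stable
`track_id`. The per-organoid shape metrics behave as constructed: the
elongated organoid (track 3) shows the highest eccentricity (~0.82) and the
lowest circularity. Track 1's area fold-change across the six frames is

```
[1.0, 1.061, 1.13, 1.195, 1.265, 1.344]
```

i.e. ~6% area growth per frame, matching the generator's 3% radial growth
((1.03)² ≈ 1.061). `example_out/` also contains per-frame labeled TIFFs,
colored overlay PNGs, `tracks.csv` and a `manifest.json` recording every
parameter of the run.

The same pipeline is available from the shell:

```sh
organotrack synth --out scenes --n-scenes 1 --n-organoids 6 --seed 1
organotrack identify --input scenes/scene000_prob.tif --out-dir labels
organotrack track --input labels --out-csv tracks.csv
organotrack run --input scenes --out-dir out --probabilities
```

Training a detector on your own (or synthetic) image/mask pairs:

```sh
organotrack train --images imgs/ --masks masks/ --val-fraction 0.2 \
    --augment-n 2000 --seed 0 --out-weights model.npz
organotrack predict --weights model.npz --input new_images/ --out-dir probs
```

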