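# dendrocam

Monocular image + laser-range measurement of tree **diameter at breast
height (DBH)** — the software core of a handheld photogrammetric
dendrometer, for forest-inventory researchers and instrument builders.

One RGB photograph of a trunk and one horizontal range reading `D` (mm)
are enough: a lightweight separable-convolution attention U-net
segments the trunk, the pixel span `N` between the two trunk edges is
read off the transverse measurement line, and pinhole geometry inverts
it to a diameter.  With normalized focal length `f_x = f/µ` (focal
length over pixel pitch, in pixel units), the trunk semidiameter is

```
R = D·N / (2·f_x − N),      DBH = 2R
```

The package contains:

* `dendrocam.geometry` — the exact forward/inverse projection model and
  camera intrinsics handling;
* `dendrocam.nn` — a U-net-like trunk segmenter built entirely from
  depthwise-separable 3×3 convolutions (1312 weights per 32→32 block
  instead of 9216) with a spatial attention module at the bottleneck,
  plus analytic receptive-field and parameter/cost calculators;
  implemented directly on numpy with hand-written backprop, Adam, and
  seeded determinism;
* `dendrocam.edges` — centre-prior edge extraction on the measurement
  row, with the device-style manual "refine" override;
* `dendrocam.scenes` — a ground-truthed synthetic scene generator
  (procedural bark, background clutter, sun spots) plus canned suites:
  a training pool, a 180-scene standard-cylinder accuracy benchmark
  (6 diameters × 3 ranges × 10 replicates), and a viewing-frame sweep;
* `dendrocam.metrics` — absRE, aveRE, BIAS, relBIAS, RMSE, relRMSE and
  the correlation / t-test / regression agreement protocol;
* `dendrocam.records` + a `dendrocam` CLI — the instrument's
  timestamp-named record files and `measure / simulate / train /
  evaluate / benchmark` subcommands.

## Worked example

```python
import dendrocam as dc

cam = dc.CameraIntrinsics(focal_length_mm=16.0, pixel_size_um=3.7)
print("f_x =", round(cam.fx, 4), "px")

# render a 150 mm trunk at 2.5 m, recover its diameter from the mask
scene = dc.generate_scene(dc.SceneSpec(
    true_diameter_mm=150.0, distance_mm=2500.0, intrinsics=cam,
    image_size=(128, 1024), bark_style="mottled", seed=7))
pair = dc.extract_edges(scene.mask)
print("detected span:", pair.pixel_span, "px  (true", round(scene.true_span, 2), "px)")
est = dc.diameter_from_span(dc.TrunkObservation(2500.0, pair.pixel_span), cam)
print("DBH estimate:", round(est.diameter_mm, 2), "mm")
```

prints

```
f_x = 4324.3243 px
detected span: 252 px  (true 251.9 px)
DBH estimate: 150.06 mm
```

`f_x` is the focal length expressed in pixels (16 mm / 3.7 µm); the
rendered trunk projects to 251.9 px and rasterises to 252 whole pixels,
and inverting the projection recovers the 150 mm diameter to within the
half-pixel quantization floor (0.04 % here).  On the full 180-scene
cylinder benchmark this quantization-limited pipeline shows a mean
absolute relative error of ≈0.14 %; a network trained for 12 epochs on
100 synthetic scenes reaches the same level on clean cylinder scenes
and >99 % held-out pixel accuracy (see `tests/test_acceptance.py` for
the exact protocols).

From the shell:

```sh
dendrocam simulate --n 5 --out scenes/ --seed 1
dendrocam train --n 100 --epochs 12 --out model.npz
dendrocam measure scenes/scene_0000.png --distance 2287 --model model.npz
dendrocam benchmark --model model.npz
dendrocam evaluate field_pairs.csv        # your own measured/reference CSV
```

## Limitations

Intrinsics must be pre-calibrated (no distortion model); breast-height
positioning of the measurement line is the operator's responsibility;
the synthetic scenes validate pipeline conventions and segmentation of
rendered bark, not field performance — feed real campaign data through
`dendrocam evaluate`.  See `docs/methods.md` for the full model
description and design rationale.
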