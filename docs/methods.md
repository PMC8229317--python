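# Methods

`dendrocam` re-creates, in software, a handheld photogrammetric
dendrometer: one RGB photograph of a tree trunk plus one horizontal
laser-range reading yield the diameter at breast height (DBH).  This
note records the model, the design choices that were genuinely open,
the synthetic-data conditions the package is tested under, and what
those tests do and do not demonstrate.

## Imaging model

A thin-lens pinhole camera at horizontal distance `D` (mm) from the
*front surface* of a trunk of semidiameter `R` (mm) projects the trunk
half-width onto the sensor as

    L / f = R / (R + D),

with `f` the focal length.  The projection covers `N = 2L/µ` pixels
(`µ` = pixel pitch), and with the normalized focal length `f_x = f/µ`
the inversion is

    R = D·N / (2·f_x − N),        DBH = 2R.

Conventions that the equations do not fix by themselves:

* **Range origin.** `D` is the distance to the trunk surface at the
  ranging point, so `R + D` is the distance to the trunk axis.  This is
  the only reading under which the projection equation is consistent
  with a surface-targeting rangefinder.  The rangefinder origin and the
  optical centre are assumed co-located; any baseline between them is
  the caller's responsibility to fold into `D`.
* **Units.** All lengths are carried in mm internally; pixel pitch is
  accepted in µm and converted once at the boundary.
* **Real-valued spans.** `N` is real-valued throughout the geometry
  core; quantization to whole pixels happens only in edge extraction.
  This keeps `span_from_diameter` and `diameter_from_span` exactly
  mutually inverse (round-trip closure is tested to 1e-9 relative over
  `R ∈ [10, 500] mm`, `D ∈ [0.5, 4] m`).
* **Degeneracy.** `N ≥ 2·f_x` is geometrically impossible (the trunk
  would fill or overfill the field) and raises rather than returning a
  negative diameter.

The reference optics used in examples and benchmarks are a 16 mm lens
over a 3.7 µm-pitch sensor, `f_x = 16000/3.7 ≈ 4324.32` px.
`CameraIntrinsics.scaled(k)` models k-fold pixel binning (`f_x/k`),
which is how small training frames are kept geometrically honest.

## Trunk segmentation network

The segmenter is a U-net-style encoder/decoder in which **every**
convolution is depthwise-separable (one 3×3 spatial filter per channel
followed by a 1×1 pointwise mix).  The parameter/cost accounting
implemented in `nn.accounting` is the usual one: a standard convolution
(kernel `D_k`, `M` in-channels, `N_out` out-channels) costs
`D_k²·M·N_out` weights, the separable substitute `D_k²·M + M·N_out` —
for the 3×3, 32→32 blocks used here, 9216 versus 1312 — and the cost
ratio is `1/N_out + 1/D_k²`.  The receptive-field recursion
`l_k = l_{k−1} + (f_k − 1)·Π s_i` is validated against an
impulse-response oracle; note that for stride > kernel the footprint
has holes, and the recursion gives the extent, not the count.

Architecture specifics and the choices behind them:

* **Channel schedule**: constant 32 channels in and out of every block
  by default (the compression setting; equal in/out channel counts are
  also cache-friendly).  Classic per-level doubling is available via
  `double_channels=True`; the parameter audit covers both.
* **Attention**: a spatial attention module — channel-wise max- and
  average-pooling concatenated into a 2-channel descriptor, one 7×7
  convolution, sigmoid — applied after the third pooling stage (the
  bottleneck of the default 3-level net; placement configurable).  It
  exploits the operating convention that the target trunk is centred.
* **Decoder**: nearest-neighbour 2× up-sampling followed by a separable
  up-convolution, concatenation with the matching encoder map, then two
  separable 3×3 convolutions with ReLU.  Resize-then-convolve was
  chosen over transposed convolution to avoid checkerboard artefacts.
* **Padding**: 'same' zero padding everywhere, so the output probability
  map is pixel-aligned with the input and no crop bookkeeping is needed.
* **Biases**: convolutions are bias-free, which makes the parameter
  audit exactly the sum of the separable-block formulas; the only two
  bias terms are the attention convolution and the final 1×1 classifier.
  Inputs are centred (x − 0.5), so intensity thresholds remain
  representable without per-layer biases.
* **Output convention**: trunk probability from a final 1×1 convolution
  + sigmoid; label 1 iff probability ≥ 0.5 (ties to trunk).

The network is implemented directly on numpy (forward and backward)
with shift-and-add spatial convolutions and matmul channel mixing; this
keeps the package dependency-light and the arithmetic transparent, and
at the small sizes involved it is memory-bandwidth-bound rather than
compute-bound.  Training uses pixel-wise binary cross-entropy on logits
and Adam (default 2e-3 in the CLI; the acceptance protocol uses 5e-3),
batch size 8.  Every stochastic element — weight init, shuffling —
takes an explicit seed (default 0), and identical seeds reproduce loss
histories exactly on a given platform.  The network is fully
convolutional: trained at 128×128 it is applied unchanged to any frame
divisible by 8, which is how models trained on small frames evaluate
wide benchmark strips.

## Edge extraction

The measured span is taken on a single row (the transverse mark line;
default the vertical centre of the frame — positioning the line at
1.3 m breast height is the operator's job).  Among maximal runs of
trunk pixels on that row, the run containing the centre column wins;
otherwise the run whose nearest endpoint is closest to the centre
(ties: wider run, then leftmost).  The span is the inclusive count
`N = right − left + 1`, i.e. the number of trunk pixels; the synthetic
renderer uses the identical convention, so the two conventions cannot
drift apart unnoticed (the equidistant/tie rules are checked against a
brute-force run enumerator).  Manual refine mode replaces either edge
column and re-validates, swapping crossed edges with a warning.
Multi-row averaging is deliberately absent by default — the instrument
being modelled measures one line.

## Synthetic scenes: what they emulate, and what they do not

No field photographs are distributable, so all image data are rendered.
The trunk is a vertical band of procedurally textured bark (uniform /
striped / mottled / shaggy; seeded value noise) on a plain, cluttered
(hazy background trunks) or foliage background, with optional sun-spot
blotches straddling a trunk edge — a known failure mode of trunk
segmentation — and a global illumination gain.  Geometry is exact: the
band's real-valued width comes from the forward projection, its
rasterised width is `round(true_span)` (hard edges by default, so
oracle tests are exact; an anti-aliased mode exists), and scenes whose
span does not fit the frame raise rather than clip.  Perspective
curvature of the silhouette is ignored: the imaging model itself is a
single-width model at the measurement row.  Everything is deterministic
given the spec seed; replicate/per-scene seeds are derived by a fixed
affine rule.

Default study conditions:

* **Training pool** (`generate_dataset`): 128×128 frames with 8×-binned
  reference optics (`f_x ≈ 540.5`), diameters 60–400 mm, trunk
  occupying 10–90 % of the frame width, all bark/background styles,
  sun spots with probability 0.3, illumination gain 0.7–1.2.  The
  training protocol mirrors a 200-picture campaign split half/half into
  train and test.
* **Cylinder benchmark** (`cylinder_benchmark`): six reference
  diameters {50, 100, 150, 200, 250, 300} mm, each imaged ten times at
  {2, 2.5, 3} m — 180 scenes.  Replicates jitter texture and
  illumination, never geometry.  Scenes are rendered at the full sensor
  pitch as a 128×1024 strip around the measurement line, so the
  thinnest cylinder at 3 m still spans ~71 px and pixel quantization
  contributes < 1 % relative error.  Rangefinder noise (≈3 % on real
  time-of-flight modules) can be injected multiplicatively but is off
  by default: the suite isolates the imaging pipeline.
* **Viewing-frame sweep** (`viewing_frame_sweep`): solves the range so
  the trunk occupies each requested fraction of the frame, for the
  framing-versus-error analysis (binned by `frame_error_curve`).

Because scene geometry is exact by construction, passing the oracle
closure (ground-truth mask → edges → inversion recovers the diameter to
within half-pixel quantization) validates the *pipeline conventions*,
not segmentation.  The trained-network benchmark validates segmentation
on rendered bark only: real bark, lens distortion, motion blur, true
rangefinder noise, and breast-height localisation error are outside
what these tests can show.  Field-campaign accuracy must come from
user-supplied paired measurements via `PairedMeasurements.from_csv`.

## Accuracy statistics

Population (divide-by-n) conventions exactly as the formulas are
printed: absRE, aveRE, BIAS, relBIAS, RMSE, relRMSE — so
`RMSE² = BIAS² + Var(x − x_ref)` holds identically, and all relative
metrics are invariant under common rescaling.  The agreement protocol
reports the two-tailed Pearson correlation, the **independent-samples**
two-sided t-test between the measured and reference series — kept as
the default for fidelity to instrument-evaluation practice even though
the data are paired; the paired p-value is reported alongside — and the
OLS regression of measured on reference.  "Fraction below a threshold"
summaries use strict `<`.  Degenerate inputs (constant series, n = 1)
return NaN for the protocol entries instead of raising.  Implementation
follows the printed operation order (`|x−r|/r·100` etc.), so statistics
recomputed from a CSV reproduce hand calculations bit-for-bit.

## Records

Each saved measurement is a `<timestamp>.txt` / `<timestamp>.jpg` pair
under `data/record/` and `data/images/`, named `YYYY-MM-DD-HH-MM-SS` to
one-second precision.  Only the naming scheme follows the instrument
convention; the text layout (one `key=value` per line: `dbh_mm`,
`distance_mm`, `lon`, `lat`, GPS fields empty when absent) is this
package's own dialect.  Colliding timestamps get `_1`, `_2`, …
suffixes rather than overwriting.

## Problem sizes and numerical notes

The shipped protocols — 100 training scenes at 128×128 for ≤ 20 epochs,
a 180-scene benchmark strip at 128×1024 — were sized for a single-CPU
workstation run in minutes; they are configuration, not limits.
Float32 arithmetic throughout the network; float64 in geometry and
metrics.  Max-pool gradient routes to every maximal element of a window
(ties have measure zero on continuous activations).  BCE is computed in
the numerically stable softplus form.  Known limitations: no lens
distortion model (intrinsics are assumed pre-calibrated), no automatic
breast-height localisation, single-trunk scenes only, and bias-free
convolutions trade a little optimisation flexibility for an exact
parameter audit.
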