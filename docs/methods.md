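# Methods

`sdstrack` implements surface depth-sensing (SDS) tracking of the laryngeal
prominence for radiotherapy motion assessment: an RGBD camera films the
anterior neck while the patient swallows; a small convolutional regressor
("pose-estimation model") predicts the pixel position of the prominence in
every frame; the pinhole camera model converts predictions plus the measured
depth into millimetre coordinates; per-axis motion ranges summarise the
excursion; and a paired analysis quantifies how planning-target-volume (PTV)
margins change when physicians see the tracking data.

## Coordinate conventions

Pixels are 0-based, x rightward, y downward, sub-pixel coordinates allowed.
Camera-frame axes follow the pixel conventions (X right, Y down, Z along the
optical axis, all in mm).  Back-projection of a pixel (x, y) with depth D is

    X = (x − cx)·D/fx,  Y = (y − cy)·D/fy,  Z = D,

with fx, fy the focal lengths in pixels and (cx, cy) the principal point.
Lens distortion is assumed negligible or corrected upstream; the library
deliberately has no distortion model — undistort first if needed.

The anatomical mapping assumes a supine patient facing the camera:
LR = X, CC = −Y (image-up is cranial), AP = −(Z − resting median depth)
(toward the camera is anterior).  The resting depth is the per-recording
median of the tracked Z, which is robust because the larynx rests for most
of a recording.  The mapping is configurable for other rigs.

## Preprocessing

Frames are normalised *per section*, not globally: a fixed region of
interest (ROI) around the resting prominence defines the statistics window
for the entire sequence.  Per channel (R, G, B, depth independently) the
mean μ and population SD σ over valid ROI pixels are computed, values are
clipped to μ ± k·σ and rescaled affinely to [0, 1].  k defaults to 2 (a
standard robust-contrast choice; exposed in the config).  Depth readings of
0 mean "no sensor return" and are excluded from the statistics.  A
zero-variance channel maps to constant 0.5.  The normalised ROI is resized
bilinearly to the square network input and stacked R, G, B, depth; the
crop+resize transform is invertible and is stored with every model so
predictions map back to full-frame pixels exactly.

A model-free diagnostic (`blob_preview`) tracks the centroid of the
lowest-depth blob in the normalised ROI; it gives a sanity trajectory and a
preview motion distance but is not the primary tracker.

## Pose-estimation model

Three ConvBlocks (3×3 stride-1 'same' convolution → ReLU → 2×2 max pool),
a flatten, and two fully connected layers (hidden width 128, ReLU) with two
outputs interpreted as normalised crop coordinates in [0, 1].  The channel
widths (16, 32, 64), kernel size and FC width are implementation choices
exposed in `ModelConfig`; at the 64 px input used in the desk-scale
experiments the network has ~0.53 M parameters.

Training: L1 loss in normalised coordinates, Adam (β1 = 0.9, β2 = 0.99),
learning rate 1e-3, mini-batches of 4, and minimum-validation-loss
checkpoint selection.  Weight initialisation and data shuffling derive from
one seed, so fits are bit-reproducible.  The layers are a small NumPy
library with explicit backprop (im2col convolutions; the input gradient is
computed as a convolution with spatially flipped kernels, so no scatter-add
appears in the hot path).  Analytic gradients are pinned against central
finite differences in the test suite to ~1e-10.

At tracking time the depth for back-projection is sampled at the rounded
predicted pixel; if that reading is invalid the nearest valid pixel within
a 3 px radius is used, and frames with no valid depth nearby are flagged
and excluded from trajectories.

## Motion statistics

Per recording, the motion range of each anatomical axis is the
max-minus-min of that coordinate over the trajectory, and the spatial
displacement is the Euclidean norm of the three ranges — this definition
reproduces every published per-patient displacement from its axis triple
(e.g. √(1.6² + 16.4² + 10.5²) = 19.54 → 19.5).  Cohort summaries use the
sample SD (n − 1), which reproduces the published cohort row (population SD
does not).  No temporal smoothing is applied by default because ranges are
extremum statistics and smoothing changes them; an optional odd-window
median filter exists behind a flag.  A displacement-vs-time exceedance
curve is provided as a diagnostic for margin selection short of the
extremum; no reference values exist for it.

## Margin analysis

Observers set per-axis PTV margins per patient twice — without and with the
tracking data.  Determinations are paired per (patient, observer); the
analysis reports per-axis means ± sample SD under both conditions, the mean
paired difference, the percent change (difference ÷ without-condition mean,
rounded to integer — this convention reproduces the published −18%, 235%,
45%), and a two-sided paired t-test t = mean(d)/(sd(d)/√n) with n − 1
degrees of freedom.  Zero-variance differences leave t undefined and are
reported as such rather than raising from the comparison.  The t-test is
cross-checked against an exhaustive sign-flip permutation distribution in
the tests.

## Synthetic data generator

The generator emulates the recording protocol so the whole pipeline is
testable without patient data.  It does **not** attempt photorealism.

* **Kinematics** — rest, then per swallow a raised-cosine pulse (C1,
  compact support) moving the prominence cranially by `amp_cc`, anteriorly
  by `amp_ap`, with a ±`amp_lr`/2 lateral wobble (one half-cycle each way),
  returning to rest.  Pulse amplitude equals the axis range of the
  noise-free trajectory by construction.  Three consecutive swallows by
  default (swallow 1.5 s, rest 3.0 s); amplitudes default to the published
  cohort means (LR 1.6, CC 21.4, AP 6.4 mm).  Gaussian per-frame jitter
  (default SD 0.2 mm) models physiological tremor.
* **Scene** — a vertical cylinder (radius 60 mm, standoff 400 mm) stands in
  for the neck; the prominence is a Gaussian bump (height 6 mm, footprint
  σ 8 mm at 256 px, 6 mm at the tighter 128 px framing) whose apex depth
  equals the trajectory Z exactly.  Sensor noise is i.i.d. Gaussian per
  pixel (default SD 0.2 mm); depth is stored in 0.1 mm units.  Color is a
  shading of the depth gradient so the bump is visible in RGB.
* **Cameras** — defaults 256×256 px, 30 fps, fx = fy = 300 px.  The
  desk-scale ("reduced") camera is 128×128 with fx = fy = 600: a tightly
  framed quarter-area sensor keeping the pixel pitch at 0.67 mm so the
  small lateral excursion remains resolvable while the full cranio-caudal
  travel stays in frame.
* **Datasets** — 7 subjects split 5 train / 2 validation, mirroring the
  clinical video split.  Per-subject amplitudes can be drawn from the
  cohort mean ± SD (truncated at 0); the desk-scale recovery experiment
  instead fixes all subjects at the cohort means, which are the conditions
  its scores refer to.  All randomness flows from one master seed through
  named, recorded sub-seeds; identical seeds give byte-identical datasets.

A crude mandible stand-in exists as an option (`occlude_top_px` replaces
the top image band with a near plane, hiding the cranial extreme of the
excursion); it defaults off and no reference values exist for occluded
scenes.

What the generator omits by default — mandible occlusion of cranial motion,
respiratory baseline drift, specular/IR artefacts, non-Gaussian depth
noise, appearance variability between patients — bounds what synthetic
results can show: passing recovery tests demonstrates that the
implementation tracks and measures correctly under the modelled physics,
not that the clinical accuracy of the original measurements is reproduced.

## Desk-scale recovery experiment

`sdstrack.pipeline.run_synthetic_experiment` generates the reduced dataset
(~300 frames per sequence: 10 s at 30 fps with rest shortened to 1.2 s),
trains for up to 20 epochs, tracks the two validation sequences, and scores

* the mean pixel error of predictions against ground-truth labels, and
* the per-axis recovered motion range against the range of the *realised*
  ground-truth trajectory (jitter included).  Ranges are extremum
  statistics, so even a perfect tracker inflates past the bare amplitude
  parameter under jitter; comparing realised ranges measures tracking
  fidelity rather than generator arithmetic.

The fixed crop is 64×64, shifted cranially (y0 = 16) so the prominence
stays inside it throughout the excursion.  Problem sizes (128 px frames,
300-frame sequences, 20 epochs) were chosen so the experiment trains
comfortably on a single CPU core in a few minutes.

## Numerical and degenerate-input choices

* Population SD for image normalisation (descriptive statistic); sample SD
  for cohort/repeat statistics (estimator; reproduces the published SDs).
* Depth 0 is invalid everywhere: excluded from statistics, triggers the
  nearest-valid fallback at sampling, flags predictions when unresolvable.
* Back-projecting depth 0 yields the degenerate origin point, which callers
  treat as invalid rather than raising inside vectorised loops.
* Zero-variance paired differences: `paired_t` raises
  ("degenerate differences"), while the margin comparison catches this and
  reports t/p as undefined.
* Bilinear resize uses the half-pixel-centre convention; the same
  convention defines the crop transform, making map-back exact.
* Max pooling breaks ties by first occurrence (argmax); with float inputs
  ties are measure-zero.

## Known limitations

* The CNN is trained per dataset; no pretrained weights ship with the
  package (training is minutes on CPU at desk scale).
* The tracker assumes one prominence-like blob in the ROI; it has no
  occlusion handling, matching the generator's omission of the mandible.
* Motion ranges are sensitive to single-frame outliers by definition;
  the optional median filter and the exceedance curve are the provided
  mitigations, both off by default.
* The paired t-test assumes approximately normal differences; with 21
  pairs this is conventional but untestable at that n, hence the
  permutation cross-check in the suite.
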