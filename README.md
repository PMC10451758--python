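# sdstrack — surface depth-sensing tracking of laryngeal motion

Swallowing moves the larynx by centimetres within a second, which makes it
one of the hardest organs to target in radiotherapy: IMRT margins drawn
without motion information can miss most of the cranio-caudal excursion.
`sdstrack` implements the surface depth-sensing (SDS) approach to this
problem for physicists and engineers working on surface-guided
radiotherapy: a commodity RGBD camera films the anterior neck, a small
convolutional pose-estimation network regresses the pixel position of the
laryngeal prominence in every frame, and the pinhole camera model turns
predictions into millimetre motion measurements that can inform
individualised PTV margins.

The package covers the full chain:

* **rgbd_io** — an inspectable on-disk dialect for RGBD sequences (paired
  8-bit color / 16-bit depth PNGs + YAML sidecar), point-label CSVs, and a
  CVAT points-XML importer;
* **geometry** — pinhole back-projection
  `X = (x − cx)·D/fx, Y = (y − cy)·D/fy, Z = D` and its inverse;
* **preprocess** — ROI-wise section normalisation (clip to μ ± kσ, rescale
  to [0, 1]) and fused H×W×4 RGBD model inputs with invertible crop
  transforms;
* **pose** — the three-ConvBlock regression CNN with the L1/Adam training
  protocol and minimum-validation-loss selection (statsmodels-style:
  `PoseEstimationModel(...).fit()` → `PoseEstimationResults` with
  `summary()` and `track_sequence()`), implemented on a small NumPy layer
  library with verified analytic gradients;
* **metrics** — anatomical axis mapping, per-axis motion ranges, spatial
  displacement (Euclidean norm of the three ranges), cohort and
  repeat-measurement statistics;
* **margins** — paired PTV-margin comparison with/without tracking data
  (`PairedMarginModel.from_dataframe(df).fit().summary()`), including the
  paired t-test;
* **synthetic** — a seeded generator of neck-like RGBD swallow videos with
  exact ground-truth labels, so everything above is testable end to end
  without patient data;
* **cli** — `sdstrack simulate | train | track | metrics | margins`.

## Worked example

Motion statistics from per-recording axis ranges (here the seven clinical
measurements, mm):

```python
import numpy as np
from sdstrack.metrics import Trajectory3D, motion_summary, summaries_to_frame

rows = [(2.0, 16.0, 3.0), (1.7, 29.9, 5.6), (2.5, 24.6, 3.9),
        (1.6, 16.4, 10.5), (1.3, 17.5, 5.5), (0.1, 23.2, 4.6),
        (2.0, 22.5, 11.5)]
summaries = [motion_summary(Trajectory3D(times=np.array([0.0, 1.0]),
                                         points=np.array([[0, 0, 0], row]),
                                         source_id=str(i + 1)))
             for i, row in enumerate(rows)]
print(summaries_to_frame(summaries).to_string(index=False))
```

```
  subject   LR (mm)    CC (mm)   AP (mm) Distance (mm)
        1       2.0       16.0       3.0          16.4
        ...
        7       2.0       22.5      11.5          25.3
Mean ± SD 1.6 ± 0.8 21.4 ± 5.1 6.4 ± 3.3    22.7 ± 4.9
```

Each `Distance` is the Euclidean norm of that recording's three axis
ranges; the cohort row is mean ± sample SD.  A swallow moves the larynx
~21 mm cranio-caudally on average — far beyond typical 3–10 mm PTV margins.

Paired margin comparison (two physician determinations per patient and
observer, without → with tracking data):

```python
from sdstrack.margins import MarginRecord, compare_margins

records = []
for i in range(2):
    records.append(MarginRecord(f"p{i}", "obs", "without_sds", lr=3.9, cc=4.8, ap=4.0))
    records.append(MarginRecord(f"p{i}", "obs", "with_sds",    lr=3.2, cc=16.1, ap=5.8))
print(compare_margins(records).summary())
```

```
Paired PTV-margin comparison (with vs without depth-sensing data)
==================================================================
paired (patient, observer) determinations: 2
                            LR              CC              AP
Without (mm)       3.9 ± 0.0       4.8 ± 0.0       4.0 ± 0.0
With (mm)          3.2 ± 0.0      16.1 ± 0.0       5.8 ± 0.0
Difference        -0.7 ± 0.0      11.3 ± 0.0       1.8 ± 0.0
Change (%)                -18%            235%             45%
p value              undefined       undefined       undefined
```

Seeing the tracking data, physicians widened the cranio-caudal margin by
235% and the anterior-posterior margin by 45% while slightly shrinking the
lateral one.  (p is undefined here because these illustrative pairs have
zero-variance differences; with real per-pair data the paired t-test is
reported.)

End-to-end on synthetic data:

```bash
sdstrack simulate --seed 1 --out ds/            # 7 RGBD sequences + labels
sdstrack train --dataset ds --seed 1 --out model/
sdstrack track --checkpoint model/checkpoint.npz --roi model/roi.json \
               --sequence ds/subj06 --out tracked/
```

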