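# octlayers

Automated intra-retinal layer segmentation for 2-D OCT B-scans, with
calibrated layer-thickness profiling and the reliability statistics
(ICC, coefficient of repeatability, Bland–Altman limits of agreement)
used to judge repeated thickness measurements.

Quantifying the thickness of individual retinal layers — not just the
total retina or the nerve fiber layer that commercial software reports —
matters for glaucoma, macular degeneration and several neurological
disorders. `octlayers` is aimed at researchers who need (a) a
transparent, reproducible implementation of graph-based boundary
tracking on their own B-scans, and (b) the statistical machinery to
show that the resulting thicknesses are repeatable across scans,
examiners and instruments.

## Method in brief

A B-scan `I(r, c)` (rows = depth, row 0 at the vitreous side) is median-
and Gaussian-filtered, then turned into per-polarity node-cost images

    cost(r, c) = 1 − normalize( max(±∂I/∂r, 0) )

so the strongest dark-to-bright (or bright-to-dark) edge costs ≈ 0.
A boundary is the row sequence `r(c)` minimizing

    Σ_c cost(r(c), c) + λ Σ_c |r(c) − r(c−1)|,   |r(c) − r(c−1)| ≤ max_jump,

found exactly by dynamic programming inside a per-column search band.
Nine boundaries (ILM, NFL/GCL, IPL/INL, INL/OPL, OPL/ONL, ELM, IS/OS,
OS/RPE, RPE/choroid) are detected sequentially: ILM and RPE/choroid
first (peak-onset and brightest-pixel initializations, then banded
refinement), the rest inside the bands between already-found enclosing
boundaries. Segmentation errors in low-reflectivity regions are fixed
semi-automatically by re-running the search forced through anchor
points (`correct_boundary`).

Layer thicknesses are boundary-row differences times the axial µm/pixel
calibration; reliability of repeated measurements is summarized per
layer by the two-way-ANOVA intraclass correlation ICC(3,1) (ICC(2,1)
optional), the coefficient of repeatability 100·SD(d)/mean, limits of
agreement mean(d) ± 1.96·SD(d), and a paired t-test.

Since no clinical images are bundled, `octlayers.phantom` generates
macular B-scans with exactly known boundaries — foveal pit, layer-
specific reflectivity, instrument axial PSF (3 µm/1365×2048 `uhr` and
5 µm/640×960 `rtvue100` presets over an 8 mm scan), multiplicative
speckle and repositioning jitter — so the whole chain is testable end
to end. See `docs/methods.md` for the model details and its limits.

## Worked example

```python
import numpy as np
from octlayers import *

cfg = get_config("uhr")                       # 3 µm PSF, 1365x2048, 8 mm
truth = make_truth(cfg, seed=7)               # ground-truth boundaries
img = render_bscan(truth, cfg, noise=0.15, seed=7)   # speckled B-scan

bounds = segment_boundaries(img, SegmentationParams.defaults_for(img, cfg))
mae = np.abs(bounds.trace_array() - truth.trace_array()).mean(axis=1)
for name, m in zip(BOUNDARY_NAMES, mae):
    print(f"{name:12s} MAE {m:.2f} px")

profile = layer_profiles(bounds)
fovea = locate_fovea(profile.data["Total"].to_numpy())
print(mean_central(profile, fovea, window_mm=6.0).to_string(index=False))
```

prints

```
ILM          MAE 0.36 px
NFL/GCL      MAE 0.52 px
IPL/INL      MAE 0.42 px
INL/OPL      MAE 0.45 px
OPL/ONL      MAE 0.43 px
ELM          MAE 0.38 px
IS/OS        MAE 0.43 px
OS/RPE       MAE 0.91 px
RPE/choroid  MAE 0.43 px
  layer    mean_um     sd_um  n_columns  window_mm
   RNFL  19.779702  4.625393       1537        6.0
GCL+IPL  57.752394 13.325395       1537        6.0
    INL  27.694343  6.474388       1537        6.0
    OPL  17.062766  3.901125       1537        6.0
    ONL  61.125688  0.575770       1537        6.0
     IS  27.979071  0.572431       1537        6.0
     OS  31.883485  1.072166       1537        6.0
    RPE  29.051533  0.974739       1537        6.0
  Total 272.328982 28.229837       1537        6.0
```

Every boundary is recovered to sub-pixel accuracy under 15% speckle
contrast; the per-layer means are averages over the central 6 mm around
the detected fovea, so the pit pulls the inner-layer means below their
peripheral values (e.g. RNFL 19.8 µm vs 23 µm peripherally) while the
outer complex (ONL through RPE) is pit-independent and nearly constant.

The same chain is available from the shell:

```
octlayers phantom --config uhr --seed 7 --noise 0.15 --out scan/
octlayers segment scan/image.tiff --config uhr --out bounds.csv
octlayers thickness bounds.csv --window-mm 6 --out thickness.csv
octlayers reliability table.csv --design repeatability --out report.csv
octlayers demo --config rtvue100 --out demo/        # full chain
```

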