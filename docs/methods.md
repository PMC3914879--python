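# Methods

## Problem and scope

`octlayers` segments nine boundaries of the macular retina in a single
2-D OCT B-scan — ILM, NFL/GCL, IPL/INL, INL/OPL, OPL/ONL, ELM, IS/OS,
OS/RPE and RPE/choroid — converts them into calibrated thickness
profiles of the eight enclosed layers plus the total retina, and
provides the reliability statistics used to judge repeated thickness
measurements (ICC, coefficient of repeatability, Bland–Altman limits of
agreement, paired t). Because no clinical images ship with the package,
a synthetic phantom generator produces macular B-scans with exactly
known boundaries for two instrument configurations: an
ultra-high-resolution research device (3 µm axial PSF, 1365×2048 grid)
and a commercial device (5 µm, 640×960), both spanning an 8 mm scan.

## Segmentation model

Each boundary is one row per column. A boundary is extracted as the
minimum-cost path through a node-weighted graph: node cost is one minus
the min-max-normalized, half-wave-rectified vertical intensity
derivative of the appropriate sign, so the strongest rising
(dark-to-bright) or falling (bright-to-dark) edge costs ~0 and
featureless tissue costs ~1. The path must stay within a per-column
search band and may move at most `max_jump` rows between adjacent
columns; it is found exactly by dynamic programming in
O(depth × width × (2·max_jump+1)). Ties are resolved to the
lexicographically smallest path (left to right, smaller rows first), so
results are bit-reproducible; an exhaustive enumerator with the same
objective and tie rule acts as an independent oracle in the tests.

The nine boundaries are found sequentially. The ILM is initialized per
A-scan at the half-rise point of the first intensity peak whose
prominence exceeds 30% of the column's dynamic range (the "first highly
reflective increase" entering the retina); the RPE/choroid boundary is
initialized at the brightest pixel below the ILM (the RPE is the most
hyper-reflective band). Both initializations are laterally median-
filtered, lightly smoothed and slope-clamped to `max_jump` — a
robustification against speckle-outlier columns that would otherwise
make the banded search infeasible — then refined by a shortest-path
search within ±18 µm (ILM) and ±32 µm (RPE; the brightest pixel can sit
a full RPE thickness above the choroid interface). The remaining seven
boundaries are detected in the order IS/OS, OS/RPE, ELM, OPL/ONL,
NFL/GCL, IPL/INL, INL/OPL — strong edges before faint ones — each within
the band between its nearest already-found enclosing boundaries.

Numerical details that matter:

- **Guard gap.** Enclosing bands are shrunk by `ceil(3σ_PSF)+1` pixels
  rather than a single pixel: a blurred strong edge (e.g. the ILM's)
  leaks gradient over ±3σ, and a 1 px guard would let a faint-boundary
  search latch onto that tail.
- **Step penalty.** The pipeline adds 0.05 cost units per pixel of
  vertical jump. The DP is exact with or without it; its role is to make
  the path straight across featureless stretches, where a pure
  lexicographic tie-break would dive toward the band edge. The library
  default for `shortest_path` itself is 0.
- **Foveal degeneracy.** Where the guarded gap between enclosing
  boundaries collapses, the band contracts to the midpoint curve (always
  included, and as smooth as the enclosing traces, so a connected path
  always exists); boundaries may coincide, giving zero layer thickness.
- **Ordering.** The anatomical ordering is enforced by clipping each
  new boundary to its enclosing pair and a final cumulative-maximum
  pass; every returned `BoundarySet` satisfies it exactly.
- Paths are integer-valued; an optional three-point parabolic sub-pixel
  refinement (`parabolic_refine`) is available but off by default.

## Semi-automated correction

Real scans contain regions of very low reflectivity where any
gradient-driven tracker fails. `correct_boundary` re-runs the
constrained search for one named boundary with its band collapsed to
caller-supplied anchor rows at the anchor columns, returning the
constrained optimum through all anchors; neighbouring boundaries are
re-clipped if the correction violates the ordering. This replaces an
interactive GUI with a programmatic API. The bundled failure fixture
erases the OPL/ONL contrast over a 120-column window (collapsing INL,
OPL and ONL to one reflectivity), which reliably makes the tracker lock
onto the IPL/INL interface ~50 µm away; a single anchor at the true row
restores sub-pixel accuracy in the window because the competing edge is
unreachable from the anchor under the jump limit and the step penalty
keeps the informationless stretch straight.

## Phantom

Ground truth is built top-down from a smooth outer (RPE/choroid)
surface: parabolic curvature (25 µm sag) plus a seeded band-limited
undulation (3 µm, three random-phase cosines). Peripheral layer
thicknesses default to RNFL 23, GCL+IPL 67, INL 32, OPL 20, ONL 61,
IS 28, OS 32, RPE 29 µm (total 292 µm, typical of healthy adults). A
Gaussian foveal pit (FWHM 1.3 mm) multiplies the RNFL-through-OPL
thicknesses by `1 − 0.6·exp(−x²/2σ²)`; the outer complex is
pit-independent. The 0.6 depth fraction (inner layers retain 40% at the
pit centre) is a deliberate simplification: it keeps the ILM visible to
the first-peak initializer at the fovea and bounds the pit slope below
the jump limit on both grids, at the cost of not reproducing the
complete inner-layer disappearance of a real fovea.

Rendering assigns each pixel the reflectivity of the layer containing
its centre (palette: vitreous 0.02, RNFL 0.85, GCL+IPL 0.55, INL 0.30,
OPL 0.50, ONL 0.12, IS 0.35, OS 0.80, RPE 0.95, choroid 0.30 — chosen
so that within each detection band the target boundary carries the
strongest gradient of its polarity, mirroring the contrast pattern of
real macular OCT), convolves axially with a Gaussian PSF of the
instrument's FWHM, multiplies by i.i.d. unit-mean gamma speckle
(contrast = SD/mean; the standard fully-developed-speckle
approximation) and clips to [0, 1]. The axial calibration converts the
1.48 mm air scan depth with a tissue refractive index of 1.38
(configurable; only the air calibration is a measured quantity).
Repeated acquisitions draw an independent global axial shift per repeat
(repositioning jitter) plus fresh speckle; layer thickness is a
boundary difference and hence shift-invariant.

What the phantom does *not* model: vessels and their shadows, motion
artifacts within a B-scan, lateral PSF, depth-dependent signal decay,
curvature of the pit floor, pathology. Passing the phantom suite
therefore demonstrates correctness of the algorithmic chain under the
stated image model, not clinical-grade performance on real scans.

## Thickness

Thickness per layer per column is the boundary-row difference times the
axial µm/pixel; `Total` telescopes exactly to the sum of the eight
layers. The fovea is located as the argmin of the moving-average-
smoothed total-thickness profile within the central 50% of columns
(ties to the smaller column), and summary statistics are the mean and
n−1 SD over a ±3 mm window (6 mm central scan length) around it,
clipped to the scan with a logged warning if necessary.

## Reliability statistics

`icc` computes the single-measure two-way-ANOVA ICC. The default is the
consistency form ICC(3,1) = (MSR−MSE)/(MSR+(k−1)·MSE); the
absolute-agreement form ICC(2,1) is available behind `form="agreement"`
since study reports often do not say which was used. An all-constant
matrix returns NaN with a warning. `cor_percent` is
100·SD(t1−t2)/mean(pooled values); `bland_altman` returns the mean
difference and mean ± 1.96·SD limits (the midpoint identity is asserted
on every call); `paired_t` raises on zero-variance differences. No
multiplicity correction is applied (one statistic per layer × meridian,
as reported). `reliability_report` assembles these per layer × meridian
for three designs: repeatability (examiner 1, repeat 1 vs 2),
reproducibility (examiner 1 vs examiner 2, first repeats), agreement
(instrument A vs B, each the mean of examiner-1's repeats).

`simulate_study` generates the measurement tables for these designs
from phantom anatomy: each subject's geometry is scaled by
N(1, 0.05) — giving a between-subject total-thickness SD of ~15 µm, the
spread seen across healthy adults — true per-layer central means are
computed from the exact truth boundaries, and every acquisition reads
each quantity (eight layers and Total independently) with N(0, 1 µm)
noise, emulating boundary-localisation error between repeated scans.
Under this model the total-retina ICC is 15²/(15²+1²) = 225/226 ≈
0.9956, while a ~20 µm layer with the same absolute read noise is
necessarily less reliable — the qualitative pattern expected of layer
thickness reliability studies (near-perfect for the total retina, worse
for thin or faint layers). The simulation is deliberately at the
measurement level; the image-level pipeline is exercised separately by
the phantom recovery, speckle-robustness and correction checks.

## Problem sizes and tolerances

Acceptance-level checks run the full-size grids (1365×2048 and 640×960):
noise-free recovery on both presets (boundary MAE ≤ 1 px; central layer
means within one axial pixel of truth), 20 speckled scans per preset at
contrast 0.15 (ILM/IS-OS/RPE-choroid MAE ≤ 2 px, ordering never
violated), and the resolution-ordering comparison in micrometres (the
finer instrument wins). DP optimality is verified against exhaustive
enumeration on 200+ random instances up to 5×6 with arbitrary band
shapes and jumps 1–2, requiring exact path identity. ICC recovery runs
500 replicates of the n=20, k=2 generating model with tolerance 0.002
on the mean (the estimator's finite-sample bias, ~5·10⁻⁴, exceeds the
Monte-Carlo SE of the mean, so an SE-level tolerance would be
unattainable). The whole suite runs in about a minute on one CPU.
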