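# Methods

This note documents the models, conventions and numerical choices behind
`cemqa`, and what its synthetic tests do and do not demonstrate about real
CEM systems.

## Phantom model and coordinates

The phantom is an idealized CIRS Model 022-style stack: 55 mm total
thickness, a 10-mm target plate of 50/50 gland/adipose material carrying
two mirrored five-plug sets (iodine surface densities 0.2, 0.5, 1.0,
2.0 mg/cm² plus one 100%-glandular plug per set), a 25-mm contrast plate
split into a 100%-adipose and a 100%-glandular half, and two 10-mm adipose
plates. Plates are ideal slabs; rounded edges and compression-paddle
deformation are not modelled.

The exact plug coordinates of the physical phantom are not public. The
default layout places each set as a cross centered in its half: four iodine
plugs (10 mm diameter) at the cardinal points, 15 mm from the set center,
glandular plug at the center. The 15-mm offset is chosen so that every
plug's background ring (up to 1.6× the plug radius) clears its neighbours,
the contrast-plate boundary and the field edge within the default
100 × 80 mm field; a tighter cross would let a neighbouring plug leak into
the ring and bias both MPV_bkg and SD_bkg. All geometry is overridable and
serializable as YAML, so real images with a different layout remain
analyzable.

Coordinates: phantom frame in mm, origin at the chest-wall-side top-left, x
along the chest wall; pixels are 0-based (row, col), row ↔ y, col ↔ x, with
`mm = origin + index × spacing` (pixel (0,0) centered at the origin). One
explicit convention prevents silent flips between simulation and analysis.
The default frame is 1000 × 800 px at 0.1 mm pitch, matching the coarsest
detector pixel pitch among the emulated systems.

## Synthetic acquisition model

Each energy channel (LE below, HE above the iodine k-edge) is described by
an energy-lumped profile rather than a spectral simulation — the analysis
only measures per-plug contrast and noise, so lumped coefficients
calibrated to a measured CNR table carry all the information the metrics
use. The noiseless signal is

```
mean(x, y) = B_e                              adipose half
           × t_e                              if (x, y) in the glandular half
           × exp(−α_e σ)                      inside an iodine plug (σ in mg/cm²)
           × p_e                              inside a 100%-glandular plug
```

with background mean `B_e` (arbitrary linear detector units, default
10000 LE / 4000 HE), tissue step `t_e ∈ (0, 1]`, effective iodine
attenuation `α_e` (cm²/mg), and glandular-plug step `p_e`. Per-pixel noise
is Gaussian with `variance = a_e · mean + b_e` (quantum plus electronic;
Gaussian is an excellent Poisson approximation at mammographic signal
levels). Plug edges are rendered with area-weighted partial-pixel coverage
(4 × 4 subsampling of boundary pixels) so ROI statistics are not biased by
aliasing. Scatter, detector blur, heel effect and grid are omitted: none of
them is measured by the pipeline's metrics. Identical
(phantom, profile, frame, seed) inputs reproduce images bit for bit.

Note `α_HE < α_LE` is *not* imposed: HE spectra sit just above the k-edge,
so per-mg contrast ordering is system-dependent and left to calibration.

**Glandular plug step.** The 100%-glandular plug is 10 mm of pure gland
replacing 50/50 plate material — 5 mm of excess gland measured against the
25-mm contrast plate that defines the tissue step. Its lumped step is
therefore tied to the tissue step as `p_e = t_e^0.2`. Because the plug is
the same material as the glandular half, a tissue-nulling recombination
cancels it to first order, which is exactly the behaviour the physical
phantom is designed to exhibit (visible on LE, "invisible" on DES).

**Calibration.** `calibrate_profile_to_cnr` matches a profile to a measured
CNR table. Under quantum-dominated noise the adipose-half analytic CNR is
`K (1 − e^{−α σ})` with `K = B/√(aB + b)`, so the anchor (2.0 mg/cm²
adipose) fixes one combination of (α, K) exactly; α is then chosen by least
squares over the remaining densities subject to that constraint, and the
quantum coefficient `a` is re-solved from the anchor (`b` is kept; default
0 — pixel-level noise data for the real systems are not available, so the
(a, b) split is degenerate and the quantum-only choice is the simplest
consistent one). When the glandular-half anchor is present, the tissue step
is solved the same way (for pure quantum noise this reduces to
`t = (CNR_gland/CNR_adip)²`). Per-plug residual mismatches are attached to
the returned profile; an unattainable target (e.g. a non-concave CNR shape)
degrades gracefully to the best least-squares α with a warning, never a
failure. Calibrated profiles are descriptive: they reproduce measured CNR,
not absolute pixel values, spectra or AEC behaviour.

## DES recombination

Vendors' recombination algorithms are proprietary, so the package
implements the literature-standard weighted log subtraction

```
DES = ln(max(I_HE, ε)) − w · ln(max(I_LE, ε)) + offset,   ε = 1e−6 × max(I)
```

with `w` estimated per study (robust to per-acquisition gain drift) as the
ratio of the glandular/adipose mean-log steps of HE and LE, measured on
auto-placed plug-free rectangular patches, one per half. On noiseless input
this nulls the tissue step exactly (`w = ln t_HE / ln t_LE`); a vanishing
LE log step yields `w = 0` with a degenerate flag instead of a blow-up.
Vendor DES images bypass this module and are treated as opaque inputs to
the ROI metrics — their unknown log/linear scaling is irrelevant because
CNR is invariant under affine intensity maps.

## ROI metrics

ROI sizes are not published for the reference measurements, so they are
configurable factors of the plug radius, defaulting to ROI = 0.6×,
ring = 1.2–1.6× — margins against edge blur and localization error.
Membership is by pixel-center inclusion with no partial weighting, and
SD_bkg is the population SD; both conventions are pinned so a brute-force
per-pixel loop reproduces the statistics exactly, which the tests assert.

Plug centers are refined by maximizing the absolute disk-minus-annulus
contrast over a ±2 mm window at pixel resolution (FFT convolution with a
plug-sized disk and a 1.05–1.35× annulus — tighter than the measurement
ring so the search region fits the image for edge-most plugs). If the
refinement hits the window edge, or the best contrast is consistent with
zero (≤ 1e−9 of the local signal scale, e.g. invisible plugs), a warning is
emitted and the nominal center is used. Refinement is deliberately disabled
for the residual-CNR targets: a well-cancelled glandular plug is invisible
by design, so only the nominal center is meaningful there.

`cnr()` raises on SD = 0 rather than returning infinity; study-level tables
keep the ROI statistics and record NaN in that (noiseless-input) case so
that noiseless cancellation and linearity analyses remain possible.

The DES linearity QC fits ordinary least squares of the signed signal
difference (MPV_target − MPV_bkg) against iodine density and reports slope,
intercept and R² (defined as 0 for a flat response); at least three
densities are required.

## Dosimetry

`MGD = K · g · c · s`: incident air kerma `K` from the tube output (µGy/mAs
at the source-to-support reference distance), mAs, and an inverse-square
correction to the breast top surface; `g` converts kerma to MGD for a
50%-glandular breast as a function of HVL and thickness; `c` corrects to
the actual glandularity (1 at 50%, the phantom's target-plate value, which
is the default); `s` corrects for the anode/filter spectrum, including the
high-energy Cu/Ti beams. Interpolation is bi-/trilinear on the grids;
queries outside the grid by at most one step extrapolate and are flagged,
anything further raises. The dose-limit check against the EU 2.64-mGy
value for a 55-mm breast is inclusive (≤).

The bundled factor grids are **synthetic representative surfaces** (clearly
labelled in the file names and headers): smooth functions with the
published factors' qualitative structure (g increasing in HVL, decreasing
in thickness; c = 1 at 50% glandularity; per-combination s). They exercise
and validate the interpolation/dose machinery; for absolute dosimetry,
replace them with transcriptions of published tables in the same CSV
schema (the files carry a provenance header line for exactly this reason).
Reports that reproduce the bundled reference study consume its printed
per-image MGDs directly — those values cannot be recomputed from first
principles because the source does not give HVL, output or air kerma.

## Aggregation and reporting

Repeatability follows the reference convention: mean over repeats with the
maximum half-dispersion `(max − min)/2` as the error estimator. Ratio
tables divide reference mean CNRs by comparator mean CNRs per
(image kind, half, density) cell; the mean ratio is the arithmetic mean of
the full-precision cell ratios, and a half-away-from-zero one-decimal
"printed view" is emitted alongside — both are reported because the source
tables' own mean rows mix rounded and unrounded arithmetic. Cells of the
bundled tables that are typographically inconsistent at source are
transcribed verbatim, flagged `suspect`, and excluded from derived
summaries; recomputed quantities that differ from the printed presentation
(e.g. a total of 2.52 vs a printed 2.53 from unrounded source data) are
flagged, never corrected. Reports are deterministic: identical inputs give
byte-identical CSV/JSON.

## Problem sizes and what the tests show

The test suite and the acceptance script run entirely on synthetic data at
desk scale: 1000 × 800 px images, 25 seeded replicates for recovery checks
(the replicate-mean measured CNR must sit within three standard errors of
the analytic truth per plug), and three calibrated profiles × three repeats
for the end-to-end comparison. Passing shows that the measurement chain is
unbiased and self-consistent under the stated image model and that the
table arithmetic reproduces the bundled published values; it does not show
that any real system's scatter, blur or recombination artifacts are
modelled — they deliberately are not. Real-image paths (DICOM exposure
parsing, vendor-DES analysis) are exercised on synthetic stand-ins.

## Known limitations

* Energy-lumped model: no spectra, no beam hardening inside the phantom.
* Gaussian noise without spatial correlation; no detector MTF/NPS.
* Synthetic dose-factor grids (see above) — relative dose behaviour is
  exact, absolute values are representative only.
* The tissue-nulling weight assumes the two halves are each locally
  uniform in the patch regions; strongly non-uniform real acquisitions
  (heel effect) would need flat-fielding first.
* No observer-model detectability (d′, NPWE) — CNR only.
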