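# Methods

This note records the models behind `sarjdose`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate about real film dosimetry.

## Film calibration model

Radiochromic film darkens with dose; a flatbed scan's mean red-channel
pixel value (16-bit scale, 0–65535) decreases monotonically with absorbed
dose. Calibration fits **dose as a polynomial of pixel value** (order 3
or 4), although film work is usually *plotted* the other way around. The
two views carry identical information for a monotone relation; fitting in
the evaluation direction avoids a numerical inversion on every conversion.
An automatic order selector minimises leave-one-out RMS error when the
caller does not fix the order.

Guards:

- **Monotonicity** of the fitted polynomial is verified on a 1000-point
  grid over the calibrated pixel span; a non-monotone fit raises — it
  signals an unusable calibration, and under point noise an order-4 fit
  occasionally goes non-monotone at the flat high-dose shoulder, in which
  case analysis code falls back to order 3.
- **Extrapolation** beyond the calibrated pixel span (± a configurable 1 %
  guard band) raises rather than clipping: film saturates outside its
  dynamic range (RTQA2 0.02–8 Gy, EBT-XD 0.1–60 Gy) and the polynomial is
  meaningless there. In-span evaluations landing outside the calibrated
  dose range are clipped with a warning.
- A 0 Gy (unexposed-base) calibration point is always admissible even for
  film whose dynamic range starts above zero.

The standard calibration grid is
{0, 0.1, 0.5, 1, 2.5, 3, 3.5, 4, 5, 6, 7, 10, 12, 15, 17, 20, 22, 24, 30,
33} Gy; individual experiments use the subset covering their working range
(e.g. 0–7 Gy for a 5 Gy prescription on RTQA2-range film), which also keeps
low-dose interpolation accurate where leakage doses (tens of mGy) are read.

**Measurement ordering.** Doses are measured by converting the ROI-*mean*
pixel value, never by averaging per-pixel doses. The dose-of-pixel mapping
is nonlinear, so averaging converted pixels carries a convexity bias (about
+10 % at 2 Gy under 1 % grain in the synthetic model), and per-pixel
span-masking in near-unexposed regions truncates the noise distribution
asymmetrically. ROI-mean-first is also how film is read in practice.

**Error propagation.** Pixel noise maps to dose error through the inverse
response slope, σ_D = σ_p·|dD/dp|. The relative dose error per unit
relative pixel error is strongly dose-dependent — roughly 17:1 at 1 Gy
and 1.5:1 at 33 Gy for the default response shape — so low-dose accuracy
claims must be stated against this propagated scale, not a flat
percentage. Tests bound recovery errors by the propagated 3σ where that
exceeds the 2.5 % film-variability scale.

## Image handling

Scans are 48-bit RGB TIFF (or PNG) at known dpi; only the red channel is
dosimetric. Coordinates are (row, col), 0-based, row 0 at the top;
physical scale is mm/px = 25.4/dpi (0.04233 mm at 600 dpi). 8-bit inputs
are accepted and rescaled ×257 with a warning. Dose maps mask — never
clip — pixels outside the calibrated span, so shielded-region statistics
are not silently biased. Profiles taken from dose maps can average a band
of rows/columns (default test usage: 50 px ≈ 2.1 mm), the digital analogue
of reading a film strip across its width; this suppresses grain noise that
would otherwise bias the outward crossing search on the penumbra tails.

## Profile metrics

Profiles are normalised to percent of the plateau mean. The default
plateau is all samples ≥ 98 % of the 98th percentile (a robust top that
excludes the penumbra shoulder); noisy profiles should pass an explicit
plateau window to avoid threshold-selection bias. Level crossings (50 %
edges, 80/20 penumbra bounds) are found by walking outward from the
plateau core (≥ 90 %) and linearly interpolating the first bracketing
sample pair — robust to plateau noise. An edge that never crosses a level
reports per-edge failure (NaN + warning) without invalidating the other
edge.

For an error-function edge of scale σ the exact 80–20 width is
2√2·erfinv(0.6)·σ ≈ 1.6832 σ. A leakage pedestal f shifts the crossing
levels to w = (level − f)/(1 − f), widening the true width by ≈ 1 % at
f = 0.008; the field generator returns the exact pedestal-aware value as
ground truth.

Margin offsets are signed: **positive = exposure edge on the tumour side
of the margin** (stated in every report header); the tumour side is read
off the local dose gradient. Uniformity across restraints reports both
SEM % and maximum absolute deviation % — related but different summaries
that are never conflated.

Flatness uses the central 80 % of the 50 %-edge field width by default
(configurable); note that for a 10 mm aperture with ~1.2 mm edge σ this
window reaches into the penumbra shoulder, so single-beam flatness numbers
are dominated by edge rolloff, not plateau ripple.

## Jig physics

All closed form. n HVLs transmit 2<sup>−n</sup>; the lead HVL at this beam
quality is 0.7 mm, derived from the design statement that 2.1 mm of lead is
three HVLs (the value is not otherwise printed). The restraint shielding
plus the 3.0 mm roof gives 5.1 mm ≈ 7.3 HVLs, quoted as seven (0.8 %
leakage). Dose rate scales as the inverse square of source distance
(37 cm reference). Depth dose is a single effective exponential,
μ_eff = 0.0207 /mm by default so the entry-to-midline drop across a 7 mm
tumour is 7 % — the centre of the 5–10 % band expected for kilovoltage
beams in soft tissue; no buildup or scatter kernel is modelled.
Parallel-opposed midline prescriptions set each entry dose to
(D/2)·e^(+μ_eff·t/2); the summed profile of the two antisymmetric
exponentials is flatter than either single beam at every interior point.
The 15°/195° angles are labels; the only angular dependence modelled is the
measured ~7 % lower dose rate of the 195° field, handled as a configured
rate ratio (default 0.93) that lengthens beam-on time.

Shielded-site doses beyond narrow-beam transmission are represented by a
single additive `scatter_fraction` (default 0): measured shielded doses in
broad-beam geometry exceed the 2<sup>−n</sup> prediction because of
scatter, which an analytical model cannot resolve; the parameter makes the
gap explicit instead of hiding it.

## Treatment statistics

Tumour volume is the calliper formula V = W²·L/2 (mm³). Growth summaries
include an animal only through its event day, so later group means
describe surviving animals. Survival uses the product-limit (Kaplan–Meier)
estimator via `lifelines`; humane-endpoint euthanasia is an event, study
close (day 35) is censoring. The rank-sum test enumerates all
C(n_a+n_b, n_a) group assignments of the pooled data and reports the exact
two-sided permutation p-value for the U statistic (pair counts, ties a
half); enumeration is restricted to ≤ 20 total observations, far above the
n = 6 + 6 design. Per-day application to volumes is supported and labelled
as such (the alternative — testing a summary like AUC — is a caller
decision).

## Synthetic-data generators

Every generator returns its ground truth with the data; recovery tests
compare estimate to generator truth, never to published measurements. One
explicit seed per call; fixed seed ⇒ bit-identical output.

**Film response.** The ground truth is a strictly decreasing quartic
dose(pixel) on the span [15 500, 60 000] counts (0 Gy at 60 000, 33 Gy near
16 300), frozen from a constrained fit to an exponential-saturation film
curve; the scan response pixel(dose) is its numerical inverse via a dense
lookup table. Parameterising the truth in the direction the analysis fits
makes the polynomial calibration model well specified, so recovery error
reflects noise rather than a baked-in approximation mismatch. Noise:
a 2.5 % per-sheet (batch) multiplicative offset between experiments — the
scale of observed inter-batch film variability — plus 0.5 % per-point
grain on calibration points (which are ROI means) and 1 % per-pixel grain
when rendering images. Per-experiment calibration uses film from the same
sheet as the measurement, so the batch offset is common mode and cancels;
this is why batch noise of 2.5 % yields median dose-recovery errors near
1 %, not 2.5 %.

**Beam field.** Separable product of erf windows on a leakage pedestal:
dose = P·(f + (1−f)·w(x)·w(y)), defaults 10 mm aperture, σ = 1.188 mm
(so the pure-edge 80–20 width is the design ~2 mm), plateau 5 Gy,
f = 0.008 (seven HVLs), margin at the left field edge. σ = 0 gives an
ideal step field.

**Phantom exposure.** Six film sites: dorsal/midline/ventral through the
7 mm wax tumour (depths 0, t/2, t per beam, reversed for the opposed
beam) and head/body/rear behind the full shield stack. Per-restraint dose
jitter has a geometric component (5 %) anticorrelated between opposed
beams — a positioning offset that boosts one tangent attenuates the
other — plus independent per-beam noise (2 %). This reproduces the
qualitative uniformity hierarchy: single-beam spreads on the ~10 % scale,
summed-dose spreads well inside 5 %.

**Tumour growth.** Exponential growth from V₀ = 256 mm³ (an 8 × 8 mm
tumour at day 8 post-injection) at 0.25 /day (±15 % between animals); each
radiation fraction (days 8, 9, 10) removes 85 % of the volume; regrowth
resumes at the native rate 3 days after the last fraction, producing
regression followed by recurrence. Measurements every 2 days with 8 %
calliper noise; the humane endpoint is the first measurement ≥ 1000 mm³,
study close at day 35. Under these defaults controls reach endpoint around
days 14–18 while treated animals regress by three orders of magnitude and
recur without reaching endpoint within the study window.

## What the synthetic tests do and do not show

The generators emulate the *structure* of film dosimetry — monotone
saturating response, batch/grain noise hierarchy, erf penumbrae, leakage
pedestals, exponential depth dose — with parameters at the documented
working point. Passing tests therefore demonstrate that the analysis chain
is unbiased and accurate **under this model**: they validate the
estimators, not the physics of any particular scanner or film lot. Real
film adds effects deliberately out of scope: darkening kinetics between
exposure and scan (fixed 24 h here, stored as metadata), lateral scanner
response and colour management, multichannel dosimetry, energy-spectrum
and backscatter effects, and broad-beam scatter beyond the single additive
fraction. Published measured values that depend on those effects (e.g. a
specific 4.6 % SEM across restraints or 0.46 % mean shielded dose) are
design anchors for generator defaults, not quantities this package claims
to reproduce from first principles.

## Numerical choices and problem sizes

- Calibration fits: `numpy.polyfit`; residual reported as RMS relative
  dose error over non-zero points.
- Inverse response table: 20 001 points over the pixel span
  (interpolation error ≪ 1 count).
- Field rasters: 600 dpi grids, 25–30 mm extents (≈ 600–710 px square) —
  the native film-scan resolution at a size that keeps the full test suite
  and the acceptance script each within a few seconds.
- Round-trip ROI areas are sized from the grain-noise budget: 160 px
  calibration pieces and three 160 px shielded ROIs put the leakage
  standard error near 0.02 percentage points, ~5σ inside the 0.1-point
  acceptance band; the plateau uses the standard 50 px ROI.
- Monte-Carlo style checks use 200 replicates (calibration unbiasedness,
  treatment-effect reliability), enough for standard-error bounds an order
  of magnitude below the tested tolerances.
- Exact rank-sum enumeration covers all C(8,4)+C(8,3) splits in the
  cross-check against the classical exact distribution.

## Known limitations

- The analytical shield model is narrow-beam; real shielded-site doses
  include scatter the model only represents through `scatter_fraction`.
- The depth-dose exponential has no buildup region; at kilovoltage
  energies and millimetre depths this is a small effect but it is a model
  choice, not a measurement.
- Penumbra estimation assumes a monotone edge after band averaging; very
  low signal-to-noise single-row profiles can still trip the outward
  crossing search.
- The exact rank-sum test is O(C(n, n_a)) and intentionally refuses more
  than 20 observations; use a normal-approximation test beyond that.
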