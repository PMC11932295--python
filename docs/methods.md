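# Methods

## The measurement model

The assay is ratiometric. A cadmium-sensitive firefly luciferase emits
green light whose spectrum red-shifts as cadmium binds, so the
green-to-red intensity ratio of a reaction well, photographed by an RGB
camera in a dark box, decreases with the well's cadmium concentration.
Working with a ratio of channels — equivalently with sum-normalized
chromatic coordinates r = R/(R+G+B), g = G/(R+G+B) — makes the readout
invariant to exposure, gain and overall lighting, which is what lets a
consumer camera serve as the detector. Over the working range
(0.1–2 mM) the ratio is taken to be linear in concentration; linearity is
an assumption of the calibration model, checked per plate by the fit's
R² and enforced in sign (a non-negative slope aborts the run as an assay
failure rather than producing numbers).

## Pipeline stages and their parameters

**Detection.** The RGB frame collapses to a per-pixel channel maximum:
unlike a luminance weighting, the max scores a pure-green and a
pure-orange well equally, so dim high-cadmium wells are not penalized.
Binarization is Otsu's threshold by default (`--threshold fixed:T` for a
fixed value), followed by a morphological opening (disk radius 1,
removes specks), a matching closing and hole filling. The closing/fill
step regularizes the component boundary: at the rim of a dim well the
pixel noise straddles the threshold, and the resulting ragged outline can
inflate the polygonal perimeter enough to push circularity
(4πA/P²) below the acceptance filter even though the well itself is
perfectly round. Components are kept when area ≥ 100 px² and circularity
≥ 0.6 (both CLI-tunable); circularity values marginally above 1 — a
discretization artifact of the polygonal perimeter — are clamped to 1.

**Grid assignment.** Detections sorted by y split into rows wherever the
y-gap exceeds half the median detection diameter; rows map top→bottom to
layout rows and, within a row, left→right to the occupied columns. This
tolerates the few degrees of rotation a plate can have in a fixed dark
box (verified to 3° in the tests) and deliberately avoids fitting a
homography — the plate is photographed face-on, and a wrong homography
fails silently where the gap rule fails loudly.

**Color.** Each well's color is the per-channel *median* (robust to
residual glare and dust) over a core disk shrunk to 0.7 of the detected
radius (avoiding the rim gradient), excluding pixels saturated in any
channel. If more than 50% of the core is saturated the well is rejected
with advice to lower the exposure — a saturated ratio is biased toward 1
and must not be reported. Background is the per-channel median of an
annulus at 1.2–1.5× the well radius, excluding pixels of any other
detected well; no dark-frame capture is assumed.

**Calibration and inversion.** Ordinary least squares of ratio on
concentration over the control (0 mM, anchoring the pure-green intercept)
and the eight standards (0.1, 0.25, 0.5, 0.6, 0.8, 1.0, 1.5, 2 mM);
replicate standards enter individually. Unknowns are quantified by
inverse prediction with the classical delta-method standard error, which
is smallest at the mean calibration ratio and grows symmetrically away
from it. Estimates outside [min, max] standard concentration are flagged
`below_range`/`above_range` but still reported — clamping would hide
assay failure. The linear OLS form is this package's design choice: the
original mobile application's concentration model is proprietary, and a
straight line is the minimal model consistent with the assay's stated
linearity; the fitting interface is a single function so alternatives
(e.g. weighted or piecewise fits) can be swapped in.

**Units.** ppm (mg/L) = mM × molar mass, default basis CdSO₄
(208.47 g/mol), which maps the 0.1–2 mM working range to roughly
20–400 ppm; elemental Cd (112.41 g/mol) is selectable. For field samples
enriched by evaporation, dividing by the known concentration factor
recovers the original concentration (reported in µM), e.g. a 20 µM sample
enriched 100× lands at the 2 mM top of the calibration range.

## The synthetic plate generator

The generator emulates the dark-box photographs the assay produces:
a near-black background (floor 5 counts), disk-shaped wells (radius
18 px, pitch 60 px, flat core to 0.8 r with a cosine falloff to the rim,
≤1 px center jitter), a calibration row of control + standards and a row
of samples (defaults 0.5, 1.0, 1.5 mM). Ground truth is defined in ratio
space, ρ(C) = 2.0 − 0.75·C, and the per-well noiseless RGB is
(E, E·ρ(C), 0.1·E) at exposure E = 90 counts, so the peak green is ~180
counts (≈0.7 of 8-bit full scale — never saturated by default). The
spectral mode instead mixes two Gaussian emission peaks (nominal 550 nm
green and 610 nm red-shifted, σ = 30 nm — configurable, since the real
enzyme's spectra are not bundled) and solves the mixing fraction so the
camera-integrated G/R (Gaussian sensitivities at 460/540/610 nm) equals
the same ρ(C); both modes therefore satisfy the linearity exactly, making
calibration recovery a sharp end-to-end test. Noise is the standard CCD
pair — Poisson shot noise (gain 1 count/photon-equivalent) plus Gaussian
read noise (σ = 2 counts) — quantized to the bit depth; every random
draw comes from one generator seeded by the spec, so identical spec +
seed gives a bit-identical image.

What the generator does *not* model: optical blur/PSF, lens distortion or
perspective, JPEG artifacts, Bayer demosaicing, white-balance processing,
well-to-well chemistry variation, and the luminescence decay over the
minutes of the reaction. Passing tests on synthetic plates therefore
demonstrate that the *computational* pipeline is correct and unbiased
under realistic counting noise — not that the wet assay achieves any
particular accuracy on real water samples.

## Numerical choices and degenerate inputs

- Otsu on a constant image has no separable classes and raises instead of
  returning an arbitrary threshold.
- Median over ~400 integer-valued core pixels has a resolution of one
  count; at the default 8-bit exposure this contributes up to ~0.01 to
  the ratio. The exposure-invariance check (same scene at 0.5× and 1×
  exposure agreeing within 1e-3 mM) is run on 16-bit renders at high
  exposure, where quantization is negligible and the property is actually
  measurable.
- A zero red channel makes the ratio undefined: the well is flagged
  invalid, the (valid) chromatic coordinates are still attached to the
  error.
- Per-well failures (saturation, undefined ratio) never abort a run; only
  calibration failure does, because nothing downstream is meaningful
  without the line.
- Grid-assignment ties in y are broken by x, then by detection order;
  assignment is validated as a bijection onto the occupied layout cells.

## Problem sizes

Default plates are 560×144 px with 12 wells — small enough that a full
render + analysis takes well under a second, and the ten-plate
recovery-accuracy run (30 sample wells) completes in seconds. The
Monte-Carlo checks (median concentration under noise, OLS sampling
distribution) use 1000 seeded replicates each.

## Known limitations

- The linear OLS calibration is a stand-in for the original proprietary
  concentration model; on real plates with curvature at the range ends a
  4PL-style fit would be the next step (out of scope here).
- No limit-of-detection/quantification estimation beyond the range flags.
- Mercury cross-sensitivity of the enzyme is not modeled; on samples
  containing mercury the reported "cadmium" is an aggregate response.
- The grid inference assumes a face-on photograph; strong perspective or
  >~5° rotation requires re-shooting rather than correction.
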