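# Methods

## Measurement model

The device couples the abdominal surrogate (the *central piece*, resting
between umbilicus and xiphoid at longitudinal coordinate `Z0`) to pivot
points on the body-frame sidewalls (`Zp`) through rigid 470 mm bars,
each carrying a 2 mm copper wire.  An axial slice at longitudinal
coordinate `Z` intersects both wires; when the central piece moves
vertically by `A0`, the wire cross-sections in that slice move by

    Az = A0 · (Z − Zp) / (Z0 − Zp),

a pure lever ratio.  The measurement inverts this relation.  Rod
rotation about the pivot is approximated as vertical translation at the
slice: for displacements ≤ 10 mm over lever arms of hundreds of mm the
angular correction is ≪ 0.1 mm, far below the pixel size.

Image coordinates put the origin at the upper-left corner with y
increasing toward the patient table, so exhale — the surrogate closest
to the table — corresponds to each wire's *maximal* image y over the
cine sequence.  Per frame the exhale-referenced wire displacement is the
two-wire average

    Az(t) = ((y1max − y1(t)) + (y2max − y2(t))) / 2 · s,

with `s` the pixel spacing; averaging the wires suppresses uncorrelated
centroid noise by √2 and cancels any common vertical registration
offset.  Each wire is referenced to its own maximum.  The series is
scaled pointwise by the lever ratio (a single multiplicative constant
per slice, so scaling before or after fitting is mathematically
identical; scaling first makes traces from different slices directly
comparable and averageable), then fitted to

    y(t) = y0 + A · sin(2π (t − tc) / T).

With a 16 s capture of a 6 s cycle (≥ 2 full periods) the observed
maximum is a reliable exhale reference; shorter captures trigger a
warning.  Because the sampling grid rarely lands on the true extremes,
the *fitted* amplitude A — not the raw peak-to-peak — is the estimator
of the preset amplitude.

## Fitting

Bounded trust-region least squares over (y0, A, tc, T) with
A ∈ [0, 50] mm and T ∈ [2, 20] s (physiological breathing range; the
period bound suppresses period-doubling local minima on 20-point
captures).  Initialisation: y0 = mean, A = half peak-to-peak, T from the
maximum of a Lomb–Scargle periodogram over a 600-point period grid
(valid for irregular timestamps — the cine interval is only nominally
0.8 s), tc from a linear sin/cos fit at fixed T.  If the first start
does not converge or leaves adjusted R² < 0.9, three further starts
shifted by quarter periods in tc run in fixed order and the lowest SSE
wins — deterministic by construction.  The result is canonicalised to
A ≥ 0, tc ∈ [0, T).

Parameter uncertainties come from the residual-based covariance
`(JᵀJ)⁻¹ · SSE/(n−4)`; the headline `sd_amplitude` / `sd_period` are
these standard errors, with the plain residual SD reported alongside
(the two readings of "SD extracted from the residuals" differ and both
are provided).  Adjusted R² uses the n−4 denominator.  Degenerate
inputs: a trace whose peak-to-peak range is below twice the noise floor
(default 0.05 mm) returns a zero-amplitude result with NaN period
instead of a spurious fit; a perfectly constant trace fitted by itself
defines adjusted R² = 1.

## Synthetic studies

The simulator emulates a 10-slice scanner's cine protocol: slabs of
8 × 3 mm slices acquired sequentially (zero inter-slab gap by default,
configurable), 20 frames per slice at 0.8 s over 16 s, 768 × 768 matrix
over a 500 mm FOV (0.651 mm/px).  The scene is a soft-tissue ellipse
(40 HU) with two lung ellipses (−700 HU) over air (−1000 HU); the wires
are anti-aliased 2 mm discs at 3000 HU rendered by area-weighted pixel
coverage (16×16 sub-pixel sampling; rendered-centroid fidelity < 0.1 px,
verified against a brute-force intensity centroid).  Copper saturates
clinical HU scales, so any value far above tissue works; the numbers are
fixed for reproducibility.  Gaussian noise (default SD 20 HU) is added
per frame from a seeded generator — identical seeds reproduce a study
bit for bit.

Each frame is an instantaneous sample at its nominal timestamp; the
0.5 s exposure's motion blur is off by default (an optional flag
averages 5 sub-samples across the exposure window) because the analysis
treats each image as one time point.  Optional uniform timing jitter
models the "nominally 0.8 s" interval.  An optional spherical target
(1 or 3 cm) with independent motion can be placed in the lung for
end-to-end sorting demonstrations; the signal pipeline never uses it.

The shark-fin surrogate is not published analytically by phantom
vendors; the implemented stand-in is

    y(t) = y0 + A · (2·|sin(π (t − tc)/T)|⁴ − 1),

T-periodic with half peak-to-peak exactly A, a sharp inhale peak and a
prolonged exhale dwell (~37 % of the cycle above baseline).  It is a
single swappable function (`resp4d.motion`), and the exponent is
configurable.

What the simulator does *not* model — and therefore what passing tests
do not show about real data: CT reconstruction physics (sinograms, beam
hardening, metal/motion artefacts), couch and frame hardware in the
image, mechanical play and friction of a physical device, irregular
patient breathing (variable period/amplitude, hysteresis between
surrogate and target).  Simulated errors are dominated by detection
noise alone, so end-to-end discrepancies land well inside the
sub-millimetre envelope a physical bench shows.

## Detection

Fixed 1500 HU threshold (midway between tissue and wire — a
deterministic replacement for interactive windowing), 8-connected
component labelling, area filter (3–200 px), the two largest surviving
components taken as the wires and ordered left/right by x.  If a third
component reaches 90 % of the second's area the frame raises an
ambiguity error rather than guessing.  The sub-pixel centroid weights
each pixel by max(HU − 0 HU, 0) over the component dilated by 2 px: the
dilation recovers the partial-coverage rim pixels below the detection
threshold, without which the centroid quantises too coarsely for the
0.4 mm amplitude budget (the wire spans only ~3 px).  Measured fidelity:
< 0.03 px noiseless, < 0.3 px at 20 HU noise.

Tracking links per-frame detections by x-order (the wires sit on
opposite sides of the patient and cannot cross) with a
nearest-neighbour continuity guard (default 50 px max jump).  Failed or
discontinuous frames are flagged invalid and excluded downstream; a
track with < 50 % valid frames is rejected as unusable (configurable).

## Phase sorting

phase(t) = ((t − tc)/T) mod 1 from the fitted sine, with phase 0 at the
upward zero-crossing (tc is the model's natural anchor; a flag
re-references to peak inhale for the clinical convention).  Velocity
sign follows the model derivative.  Phase bins are uniform deciles by
default; amplitude bins are equal-width over [0, max displacement] on
the *measured* trace (so irregular breathing degrades gracefully), and
amplitude+velocity splits each amplitude bin by sign.  The
representative frame per (bin, slice) is the one closest to the bin
centre (circular distance for phase), earliest time breaking ties —
deterministic.  Empty cells are reported, never interpolated: a 16 s
cine covers only ~2⅔ cycles and fabricating slices would be silent data
invention.  Bin count and representative rule are this package's
choices; no standard exists.

## Default geometry

Central piece at Z0 = 580 mm (the stereotactic phantom-centre
coordinate of the reference setup), pivot at Zp = 110 mm (one 470 mm
bar length away), evaluation slice 200 mm from the central piece (lever
ratio ≈ 0.574) — the most distal, hence hardest, plane: the wire
excursion there is the smallest, so signal recovered there implies
recovery everywhere closer.  Z0 and Zp are free configuration values;
only their differences enter the model.

## Problem sizes in the validation sweep

The validation sweep (`resp4d.experiments`, also run by
`scripts/acceptance.py`) uses one evaluation slice per study, 20 frames
each, amplitudes {1, 2, 3, 6, 10} mm × 10 seeds — 50 end-to-end studies,
1000 rendered and detected frames — with the starting phase drawn
uniformly per seed, as successive bench acquisitions would have.  These
sizes give stable worst-case statistics while keeping a full run under a
minute on one CPU.

## Known limitations

- The lever model assumes the frame and scanner longitudinal axes are
  aligned (the frame's alignment procedure); no stereotactic-to-DICOM
  registration is performed.
- Points of the bars also move slightly longitudinally during breathing;
  this second-order effect is neither quantified nor corrected here.
- Only regular (stationary-parameter) waveforms are generated; the
  fitting and amplitude-binning paths accept irregular traces but are
  validated only on regular ones.
- Prospective gating is out of scope by design: the signal exists only
  after the images do.
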