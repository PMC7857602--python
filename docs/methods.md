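# Methods

## The gradient model

The DV pSmad5 gradient is represented as a monotone non-increasing curve
G(θ) over θ ∈ [0°, 180°] (0° ventral-most, 180° dorsal-most, the two
lateral halves folded together). G is a cubic Hermite spline through a
small set of anchors (angle, value, derivative); every segment must satisfy
the Fritsch–Carlson box condition — both endpoint derivatives between zero
and three times the secant slope — which is sufficient for segment
monotonicity (at the extreme corner d₀ = d₁ = 3s the derivative is
3s(2t−1)² ≥ 0).

The **canonical wild-type profile** is built from its slope-magnitude
profile rather than from hand-placed values: |G′(θ)| is piecewise linear
and pinned to the measured boundary readouts — 60 A.U. (of a 100 A.U.
ventral maximum) at slope 1.4 A.U./degree at the *sizzled* boundary (75°),
25 A.U. at 0.76 for *foxi1*, 7 A.U. at 0.35 for *bambia* — and the *foxi1*
and *bambia* boundary angles follow by integration: shedding 35 A.U.
between the sizzled and foxi1 boundaries at a slope interpolating
1.4 → 0.76 takes 35/1.08 ≈ 32.4°, so the foxi1 boundary sits at ≈107.4°;
shedding 18 A.U. at 0.76 → 0.35 puts the bambia boundary at ≈139.8°.
With a linear slope profile the intensity curve is piecewise quadratic,
which the Hermite segments reproduce exactly, so anchor values, anchor
derivatives and analytic threshold crossings are all exact by
construction. Deriving the boundary spacing from the printed level/slope
pairs (instead of fixing the angles a priori) is what makes the slope
profile *smooth* through each boundary; a gradient whose printed slopes
were narrow local minima of |G′| would make local slope readout ill-posed
under any finite-window smoother. The ventral approach rises from a flat
pole through a knee at 45° to a gentle peak at 65°, solved so the total
ventral drop is exactly 40 A.U. and the slope arrives at 75° without a
kink; the dorsal tail decays to ≈1.1 A.U. with zero slope at the dorsal
pole (both poles are symmetry points of the folded axis).

The **chordin-mutant profile** keeps the same maximum but expands
laterally: anchors at 100° and 125° pin the laterally shifted 60 A.U. and
25 A.U. crossings, and two free anchor values (at 50° and 148°) are solved
by bisection so that the window-mean |G′| over 25–75° is exactly half the
wild-type value and over 125–155° exactly twice it (for a monotone curve
the window-mean slope magnitude is the net drop divided by the window
width, so both constraints are solved analytically, without quadrature).
Interior derivatives come from the shape-preserving PCHIP rule, which
satisfies the box condition by construction. The **bmp7-mutant profile**
is flat at 1 A.U.

## Synthetic data

`sample_embryo` draws nuclei uniformly on a spherical cap (radius 350 μm,
cap extent 120° from the animal pole, 4,000 nuclei — plausible for an early
gastrula; none of these is a published value and all are configurable).
pSmad5 is G at the nucleus's true DV angle plus additive Gaussian noise
(σ = 5 A.U.) clipped at zero; FISH channels are 100 A.U. times the readout
model's activation indicator plus the same noise. Activation is evaluated
on the noiseless signal: the cell responds to its actual signaling state,
and the noise models measurement error only. Gene truths: activation
thresholds 60 (*sizzled*), 25 (*foxi1*), 7 (*bambia*, *ved*) A.U.;
transcription-onset delays 10 / 20 / 30 / 10 minutes.

Dissociated-cell assays draw per-cell pSmad5 from dose-calibrated
truncated normals — 20 ng/ml → N(75, 15²), 5 ng/ml → N(20, 8²), dose 0 →
N(1, 1²) — chosen so the high dose recapitulates the endogenous ventral
high (most cells above the 60 A.U. threshold) and the low dose sits
between the 7 and 60 A.U. thresholds for nearly all cells; no per-dose
distribution is published. Pulse experiments are deterministic rule
applications (level and duration against per-gene parameters); the slope
readout is undefined for spatially uniform exposure and is rejected.

What the generator does *not* emulate: cell movement and division,
nonspherical embryo shape, spatially correlated or intensity-dependent
noise, optical attenuation with depth, and transcription dynamics beyond a
fixed onset delay. Passing recovery tests therefore demonstrates that the
measurement pipeline is unbiased under idealized geometry and noise — not
that it would be unbiased on real confocal data.

## Measurement pipeline

- **Sphere fit**: algebraic least squares (Coope's linearization); needs
  ≥4 non-coplanar points.
- **Orientation**: the ventral pole is the intensity-weighted mean radial
  direction of the top pSmad5 decile, projected orthogonal to the animal
  axis. A resultant-length concentration below 0.3 (azimuthally incoherent
  bright nuclei, e.g. a flat bmp7-mutant gradient) flags the embryo as
  unorientable. Registration between embryos is a rigid pole-frame
  alignment; nonrigid point-set registration is unnecessary for
  rigid-geometry synthetic clouds and is out of scope.
- **Band profiles**: mean channel intensity in a 40-μm-wide band of cells
  (a ring at AV position 80 for DV profiles; the ventral–animal–dorsal
  meridian for AV profiles), binned at 1°. Empty bins propagate as
  missing, never as zero. The 1° default (rather than a coarser bin)
  halves the partial-bin bias of boundary interpolation, which matters at
  steep boundaries.
- **Smoothing and slopes**: robust locally weighted regression (lowess)
  of the binned means, span 0.15, 2 robustifying iterations; the slope
  magnitude is the centered finite difference of the smoothed curve. Two
  numerical guards: (1) robustifying iterations are skipped when a
  second-difference noise estimate is negligible, because bisquare weights
  computed from curvature residuals on noiseless input arbitrarily zero
  out high-curvature points; (2) the span was chosen by validating the
  estimator against the analytic |G′| on noiseless profiles and across
  simulation seeds — 0.15 of a 180° profile (≈±13.5°) is the best
  bias/variance compromise for features tens of degrees wide; wider spans
  visibly inflate window-slope ratios where the curve is convex.
- **Boundary calls**: boundaries are detected on the *unsmoothed* binned
  expression profile — walking from the profile maximum outward to the
  first bin below 10% of maximum and interpolating linearly. A hard
  expression front is a step; any symmetric smoother displaces a step's
  10%-of-max crossing systematically outward (robust lowess at span 0.2:
  +2–9°), while binned means keep the detector within one bin of the
  analytic crossing. pSmad5 level and slope at the boundary are
  interpolated from the smoothed pSmad5 profile; percent-of-max uses the
  same embryo's profile maximum.
- **Heat maps and clusters**: 8 AV rows × 16 DV columns over the full
  circumference, folded into 8×8 by averaging bilaterally symmetric
  column pairs, normalized to the maximum bin; the DV profile is the
  column sum. A gene is expressed in a DV bin if its profile exceeds
  0.5 A.U.; clusters follow the dorsal-most expressed bin (≤4 → 1, 5 → 2,
  6–7 → 3, otherwise — bin 8, empty, or dorsally enriched — 4).

## Model discrimination

`compare_genotypes` runs, per gene, Welch two-sample t-tests on
per-embryo boundary levels and slopes across genotypes and computes the
relative cohort-mean deviation ρ = |m_wt − m_mut| / m_wt for both
readouts. A model is *supported* when its readout deviation is ≤ 0.15 for
every gene — the cutoff is this package's quantification of "similar" and
is configurable and reported in every verdict; the t-tests remain the
primary statistics. The slope model additionally fails the positional
uniqueness check when a boundary's slope value occurs at ≥2 distinct
angular loci of the same profile (a non-monotone |G′| cannot encode unique
position). `duration_test` rejects a duration code when every gene is on
after a pulse far shorter than the endogenous ~4-hour exposure (default
≤30 min) and checks that expression order follows onset delays rather than
domain size. `concentration_test` supports the threshold model when
expressing fractions (strictly >10% of a reference maximum pooled across
doses — pooling keeps the rule meaningful in conditions where no cell
expresses) match the fractions above each predicted threshold within 0.05
at both doses, and the highest-threshold gene stays off at the low dose.

## Problem sizes and determinism

Recovery suites use 20 embryos per genotype (seeds 1–20 wild-type,
101–120 chordin-mutant) at the default 4,000 nuclei — the full double
cohort quantifies in about a second. All randomness flows through
`numpy.random.default_rng` seeded per embryo; a fixed seed reproduces
tables bit-for-bit.

## Known limitations

- The AV-axis profile of a purely azimuthal synthetic gradient collapses
  to a ventral-high/dorsal-low step across the animal pole; AV boundary
  analysis is implemented but exercised less than the DV path.
- Lowess leaves a small curvature bias: window-mean slope ratios between
  genotypes carry ≈+5% where one profile is strongly convex inside the
  window.
- The bambia boundary of the canonical wild-type profile (≈139.8°) lies
  dorsal of the 70–110° region usually quoted for target-gene patterning;
  it is the angle implied by integrating the printed level/slope readouts
  and matches the broad bambia domains seen in predicted expression maps.
- The 0.15 support cutoff for ρ and the 0.3 orientation-concentration
  cutoff are pragmatic constants, not estimated quantities; both are
  parameters of their functions.
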