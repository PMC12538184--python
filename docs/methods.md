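# Methods

`mcdt` re-implements a sensorized motor-and-cognitive dual-task (MCDT)
analysis pipeline: wearable-IMU recordings of five motor exercises —
forefinger tapping (FTAP), thumb-forefinger tapping (THFF), toe tapping
with heel pinned (TTHP), heel tapping with toe pinned (HTTP), and a 10 m
walk (GAIT) — each performed alone (CL0) and while counting backwards by
1, 3 and 7 (CL1–CL3), are reduced to kinematic features, cognitively
weighted dual-task costs, one pooled index per exercise, and
leave-one-out-validated logistic classification of three diagnostic
groups: cognitively healthy older adults (OA), subjective cognitive
impairment (SCI) and mild cognitive impairment (MCI). Because the
underlying clinical recordings are not public, a seeded synthetic cohort
generator is a first-class part of the package and defines the conditions
under which everything is tested.

## Signal model and preprocessing

A trial is a 100 Hz six-channel stream (tri-axial accelerometer, m/s²;
tri-axial gyroscope, deg/s). Tapping trials comprise 3 s of rest followed
by 15 s of self-paced movement; gait trials are 3 s standing, a 10 m
walk, and 3 s standing. All channels pass through a fourth-order low-pass
Butterworth filter — 5 Hz for tapping, 3 Hz for gait, reflecting the
slower frequency content of walking. Filtering is applied
forward-backward (zero phase): event *times* drive every downstream
feature, and a causal pass would lag them by tens of milliseconds.

The channel carrying the movement is the angular velocity orthogonal to
the movement plane (gyro y) for all four tapping tasks; gait is analysed
in the sagittal plane (acc x, acc z, gyro y).

## Segmentation

**Tapping.** Each tap is a biphasic gyro-y pattern — positive opening
lobe, negative closing lobe — delimited by three characteristic times:
action start, maximum amplitude (the opening-to-closing zero crossing),
and action end. The detector thresholds |gyro y| at
max(10 deg/s, 5 × still-phase noise SD, 0.10 × the 95th percentile of
|gyro y| over the movement window), merges super-threshold regions
separated by less than 50 ms, discards regions shorter than 50 ms or
touching the window boundaries, and reads the three times off each
region. The amplitude-relative term is needed because the 5 Hz filter
smears large tap pulses into the inter-tap dwell; without it the dwell
never falls below a fixed floor and adjacent taps merge. All constants
live in `TapDetectorSettings`.

**Gait.** Each stride carries four characteristic times: the foot starts
to move, toe-off, heel strike, and foot flat. Mid-swing is a positive
peak of the filtered gyro y; toe-off is the last negative minimum before
it and heel strike the first negative minimum after it (standard
shank/foot gyro event logic). The stillness tests — walking back from
toe-off to find movement onset, and forward from heel strike to find
foot flat (|gyro y| < 10 deg/s sustained for ≥ 50 ms) — read the *raw*
channel: the 3 Hz filter's impulse-response tail keeps the filtered
signal above the stillness band for another 50–70 ms after the foot is
genuinely flat, which would bias stance time. Swing is
[toe-off, heel strike]; stance is the complement within the stride;
fewer than two detected strides yields no gait record, with a warning.

## Feature extraction

Eight parameters per tapping trial: tap count; excursion (mean per-cycle
peak angle, deg) and its SD; opening and closing velocity (per-cycle peak
|gyro y| in each phase, deg/s) and their SDs; and IAV, the time integral
of the still-phase-corrected acceleration magnitude (m/s), an energy
proxy. Thirteen for gait: gait time (first movement onset to last foot
flat), stride count, velocity (10 m / gait time), stride length
(10 m / stride count), stride/swing/stance times with SDs, relative
stance (mean stance fraction), and swing excursion with SD. Across the
four tapping tasks and gait that is 8×4 + 13 = 45 parameters per
cognitive load, 180 feature columns for a complete 4-condition protocol.

Angles come from trapezoidal integration of the angular rate at the
native 10 ms sample spacing. Over a full tap cycle the integrated angle
is linearly detrended so the cycle-end angle returns to the cycle-start
angle — the zero-velocity-update principle, which removes slow gyro bias
without modelling it. Two numerical choices matter here:

- *Integration uses the raw channel; detection uses the filtered one.*
  Integration is itself a smoothing operation, and the low-pass filter's
  ring tails otherwise leak 2–4% of a pulse's area into its neighbours,
  biasing recovered excursions by more than a degree.
- *Integration supports extend to the inter-tap dwell midpoints*, not
  just the detection-threshold crossings, so sub-threshold lobe tails are
  counted. The dwell is where the digit genuinely rests, so it is the
  natural anchor for the per-cycle detrend.

IAV subtracts the still-phase mean acceleration vector before taking the
magnitude; without this, gravity dominates the integral.

## The weighted dual-task cost

For feature f, exercise Ex, load k and participant j the standard cost is

    DTC = 100 · (f(Ex, CLk, sj) − f(Ex, CL0, sj)) / f(Ex, CL0, sj),   k ∈ {1,2,3}

Its blind spot: a participant who silently stops counting keeps their
motor output near baseline and scores a deceptively normal DTC ≈ 0%. The
weighted variant multiplies the dual-task feature by an engagement weight
before costing it:

    DTC* = 100 · (Zc · f(Ex, CLk, sj) − f(Ex, CL0, sj)) / f(Ex, CL0, sj)

where Zc(Ex, CLk) is the participant's correct-response count Nc,
z-scored across the analysed sample and affinely rescaled so the sample
minimum maps to 0.01 (never exactly zero) and the maximum to 1. Since
z-scoring is affine, the composition equals a direct min-max rescale —
asserted to 1e-12 in the tests. With Zc = 1 the weighted cost reduces to
the standard one; with Zc = 0.01 it approaches −99% regardless of motor
output. Degenerate cases (a single participant, or zero spread in Nc)
map every weight to 1 with a warning: without spread there is no
evidence of differential engagement, and 1 reproduces the unweighted
cost. Zero or near-zero baselines (|f_ST| < 1e-9) leave the cost missing
rather than raising: cohort runs proceed past degenerate trials.

## Pooled indices

Each exercise's candidate pool is all (feature, CL1–3) weighted-cost
columns — 24 for a tapping task, 39 for gait; pooling across the three
dual-task loads maximises the information available to the composite
(a per-load pool is a config switch). Redundancy screening deletes
iteratively:

1. count each column's partners with |Spearman rho| ≥ 0.4 (absolute
   value: anti-correlated columns are equally redundant) and delete the
   column with the most;
2. on a tie, delete the tied column with the smaller |Cohen's d| on the
   MCI-vs-OA contrast (the primary diagnostic contrast);
3. on a residual tie, a fixed priority list of feature names decides
   (plain magnitude features outrank speeds, which outrank variability).

The loop stops when no pair reaches the threshold; if more than six
uncorrelated columns remain, the six with the largest |d| are kept.
Every deletion is logged in a machine-readable trace, making the
otherwise under-determined selection auditable.

Survivors are oriented so higher always means better functioning, then
min-max normalised to [0, 1] across participants and averaged per
participant (missing-aware). The default orientation is +1 for every
weighted-cost column: the weighting algebra drives DTC* strongly
negative under low engagement for *any* nonnegative feature — exactly
the limit case that motivates the starred cost — so lower weighted cost
uniformly signals worse dual-task functioning. (For pooling *unweighted*
costs the map must be overridden: variability and time features then
flip sign.) A zero-spread component contributes a constant 0.5.

## Classification

Per exercise and problem — binary MCI vs OA, and ternary OA/SCI/MCI — a
logistic model on (pooled index, age, FAB score). The ternary model is a
single multinomial logit rather than one-vs-rest. Predictors are
standardised inside each training fold, and a small L2 ridge (1e-6 on
standardised predictors) keeps coefficients finite under the
quasi-separation that 43-subject training folds invite. Validation is
leave-one-out; equal predicted probabilities break ties toward the fixed
class order (OA, SCI, MCI), deterministically. Metrics: sensitivity,
specificity and accuracy for two classes (MCI positive); per-class and
support-weighted recall, precision, F1 and overall accuracy for three.
Weighted recall equals overall accuracy by construction — kept as a
cross-check, not a redundancy. Reports round to integer percent; raw
floats are retained in the JSON artifacts.

## Cohort statistics

Sex-by-group and education-by-group use Pearson chi-square without
continuity correction — the uncorrected statistic reproduces the
published statistics for cohorts of this shape exactly, the corrected one
does not. Age and FAB use tie-corrected Kruskal-Wallis (df = K − 1),
with two-sided Mann-Whitney post hoc tests (exact p below 20 per group
without ties, normal approximation otherwise) at a Bonferroni-corrected
critical p of 0.05/3 ≈ .02. Summary tables report median (IQR) with
linear-interpolation quartiles.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes —
not biomechanics. Demographics: 10 OA / 17 SCI / 17 MCI; ages normal
around medians 63/72/73 years (SDs matched to the reported IQRs); FAB
means 16.8/15.0/13.2 (OA > SCI > MCI); MMSE truncated at 24, the
exclusion threshold; sex and education probabilities follow the reported
group breakdowns.

Tapping waveforms are trains of biphasic raised-cosine (sin²) pulses:
opening and closing lobes sized so the trapezoidal integral over each
lobe equals the configured excursion *exactly* on the sample grid, with
a dwell occupying 30% of each cycle, a 0.25 s reaction delay, per-tap
log-normal jitter on period and amplitude, Gaussian gyro noise
(SD 2 deg/s) and a linear bias drift (0.2 deg/s per s). Baseline tap
rates 2.2/2.0/1.8 Hz and excursions 45/40/34 deg for OA/SCI/MCI;
dual-task interference multiplies rate and excursion by group- and
load-specific factors constrained to MCI ≤ SCI ≤ OA at every load
(e.g. rate factors at CL3: 0.87/0.79/0.68). These magnitudes are free
parameters of the simulation — no per-group kinematic distributions are
published to calibrate against — chosen once at plausible values for
older adults and documented in `CohortConfig`.

Gait strides are three raised-cosine lobes (toe-off negative, mid-swing
positive, heel-strike negative) separated by short near-zero gaps, with
stance occupying 0.60 of the stride; the gaps exist because butting the
lobes together lets the 3 Hz filter's crosstalk displace the detected
minima by 2–4 samples. Stride times 1.10/1.20/1.30 s and lengths
1.25/1.15/1.05 m per group, scaled by the same interference factors;
strides tile the 10 m walkway.

Correct-response counts are censored Poisson draws of a group-by-load
rate (OA 14/9/6, SCI 13/8/5, MCI 11/6/3 over the 15 s window, capped at
20) — decreasing in load and ordered across groups.

What the generator does *not* emulate: sensor orientation drift beyond a
linear bias, dropouts, tremor, hesitations, double-taps, turning at the
end of the walkway, or any correlation between motor and cognitive noise
within a participant. Passing tests therefore demonstrate that the
pipeline recovers known structure from signals of this class — exact tap
counts and excursions in the noiseless limit, interference orderings and
above-baseline classification under noise — not that clinical effect
sizes are reproduced. The published classification accuracies depend on
the unreleased 44-participant dataset and are out of reach by design;
the one quantitative bridge to the paper's numbers is the demographic
chi-square statistics, recomputed from the printed contingency tables.

## Problem sizes

Default analyses run the full 44-participant, 5-exercise, 4-load
protocol (880 trials, ~10 s end to end). The repeated-seed robustness
check in the acceptance tests runs 20 independent cohorts on a single
exercise; examples and pipeline tests use reduced cohorts where cohort
size is irrelevant to the property under test.

## Known limitations

- Tap counts under default noise are exact for ~85% of trials and within
  ±2 otherwise (region splits/merges near the threshold) — realistic for
  threshold detectors, but a caution against treating single-trial
  counts as ground truth.
- The recovered stance fraction carries a ~0.01 bias from single-sample
  event quantisation at 100 Hz.
- The screening step's outcome depends on the sample's correlation
  structure; with 44 participants the selected component set varies
  across seeds. The deletion trace is the intended audit tool.
- `wo`/`wc` use per-cycle *peak* angular speed (the conventional tapping
  metric); a phase-mean alternative is a config flag away but not the
  default.
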