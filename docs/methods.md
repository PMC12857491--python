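# Methods

## Signal model and conventions

A trial is one muscle site (vastus lateralis or triceps brachii) in one
ambient condition (normoxia or normobaric hypoxia) during a 3-min all-out
cycling test. Time is expressed in seconds relative to the start of the
effort, so the test spans [0, 180] and a full record spans [−30, 210]
(30 s of seated baseline, the effort, 30 s of recovery). This makes "the
last 45 s of the effort" the fixed interval [135, 180] for every trial,
independent of recording length.

SmO₂ is a percentage on an arbitrarily scaled 0–100 axis ("a.u. of %SmO₂").
Values of exactly 0 or 100 are accepted — continuous-wave oximeters do
saturate — but logged as suspect, because a window clipped flat at the floor
or ceiling can look spuriously stable.

## Signal conditioning

1. **Moving average, 5 s, trailing.** The Moxy firmware smooths in real time,
   so the default is causal: the output at time t averages all samples in
   (t − width, t]. Support shortens at the left edge (mean over whatever is
   available). A centered variant exists for sensitivity analyses. A
   double-smoothing guard skips this step when the trace is flagged as
   already device-smoothed, which is the default for both loaded and
   synthetic data; `force_smooth` overrides it.
2. **Resampling to 1 Hz.** Linear interpolation onto the integer-second grid
   [⌈t₀⌉, ⌊t_end⌋]. No extrapolation outside the sampled range is ever
   performed — fabricating values of a bounded physiological signal is worse
   than a shorter grid. A gap between consecutive samples larger than
   `max_gap_s` (default 4 s, i.e. two missed 2-s samples) aborts with the
   gap's location rather than interpolating across a dropout. Linear is the
   only interpolant offered; piecewise-linear is the conservative choice for
   a heavily smoothed, slowly varying signal, and the config validates the
   choice explicitly so alternatives could be added without silent changes.
3. **Window extraction** is inclusive on integer seconds: [a, b] carries
   b − a + 1 samples, so the 45-s search region holds 46 values and each
   30-s window holds 31. Stated prominently because off-by-one conventions
   here directly change detection counts.

## Plateau criteria

`PlateauCriterion` has four axes: mode (absolute a.u. / relative %),
threshold T > 0, window length (default 30 s), and stability metric.

* **Anchored (default).** Every sample's change from the window's first
  value must lie in [−T, +T]. This reading matches how the thresholds are
  phrased as changes within a band ("−5 to +5"), and the relative mode's
  reference — the window's own first value, not the trial baseline — matches
  the observation that 5 % of a ~20 a.u. plateau is only ~1 a.u.
* **Range (alternative).** max − min ≤ T across the window. Range-stability
  at T implies anchored-stability at T; anchored-stability at T implies
  range-stability at 2T. Provided as configuration so published counts can
  arbitrate the convention when the original dataset is available.

Bounds are inclusive: a worst deviation of exactly T counts as stable
(benefit of the doubt; also keeps the criterion's decision a closed set, so
boundary fixtures are deterministic). Candidate windows start on integer
seconds from 135 to 150; the earliest stable window wins and its signed
worst-case deviation is reported. When no window is stable the
least-unstable window's deviation is reported with no window start.

The battery A5/A10/R5/R10 is fixed by id for interoperability with the
summary tables and CLI. Threshold monotonicity (every A5 positive is an A10
positive) is a structural invariant and is property-tested.

## Agreement analytics

Fleiss' kappa for binary categories is computed through
`statsmodels.stats.inter_rater` (category aggregation + kappa); the test
suite checks it against an independently hand-coded category-count formula
on random matrices. When every rating in a matrix falls into a single
category, chance agreement is exactly 1 and kappa is 0/0: the package
returns an explicit undefined marker (and the band "undefined") rather than
1.0 or an exception, since raw agreement is perfect but the chance-corrected
statistic is indeterminate. No kappa confidence intervals or significance
tests are produced.

Interpretation bands are the Landis–Koch labels with right-closed
intervals: < 0 poor, [0, 0.20] slight, (0.20, 0.40] fair, (0.40, 0.60]
moderate, (0.60, 0.80] substantial, (0.80, 1] almost perfect. Boundary
values take the lower band's label.

Visual-assessment consensus is "at least 3 of 4 raters" (configurable
`min_agree`); a 2–2 split is negative. Method-vs-method comparison is plain
percent agreement on aligned trial vectors, reported pairwise in a symmetric
matrix with 100 on the diagonal.

## Synthetic generator

The noise-free backbone is

    v(t) = baseline                                        t < onset
    v(t) = plateau + (baseline − plateau)·e^{−(t−onset)/τ_drop}
           + drift·max(0, t − 135)                          onset ≤ t ≤ 180
    v(t) = baseline + (v(180) − baseline)·e^{−(t−180)/τ_reoxy}   t > 180

with defaults: baseline 65 a.u. (cohort draws from 60–75 a.u., the typical
pre-test range), plateau level drawn from the end-test means reported for
trained athletes — 20.1–22.1 a.u. for females, 10.6–11.6 a.u. for males,
mixed 1:2 to mirror a 10 F / 20 M cohort — τ_drop 15 s (desaturation is
essentially complete within the first minute, as group kinetics show),
τ_reoxy 20 s, sensor noise SD 1.0 a.u., sampling every 2 s over [−30, 210].

Plateau-breaking trials get a late linear drift of −0.3 a.u./s confined to
[135, 180]: every 30-s anchored change is then −9 a.u. — decisively outside
±5 yet inside ±10 — without altering the early kinetics. Confining drift to
the analysis region means one parameter flips the label and nothing else.
A drifting trial whose plateau level is low can run into the 0 % floor and
is clipped there; the floor-contact advisory in the logs is expected for
such trials.

Ground-truth labels are computed by running the detector itself on the
noise-free backbone under a labeling criterion (default A5, anchored). This
deliberately separates criterion behaviour from noise sensitivity: in the
noiseless limit detection must equal the label *by construction*, so any
noisy-cohort misclassification measures noise robustness alone. Noise is
independent Gaussian per sample before clipping to [0, 100]; an AR(1)
switch with matched marginal SD exists for robustness studies, since the
device's true noise spectrum is unpublished.

Cohorts place floor(n·fraction + 0.5) true-plateau trials per group,
shuffled, across the 2 × 2 muscle × condition design, and can be written to
disk in the same CSV + manifest format the IO layer consumes.

### What the generator does and does not emulate

It reproduces the morphology, amplitude ranges, sampling and noise scale of
real end-test records, which is what the detector is sensitive to. It does
not model oxygen transport, total-haemoglobin dynamics, pacing strategies,
movement-artifact statistics of real cycling, or rater behaviour. Passing
synthetic-recovery tests therefore demonstrates the pipeline's correctness
and noise robustness under this signal model — not the physiological
validity of any particular criterion on real athletes, which requires the
original study dataset (see below).

## Validation and problem sizes

The suite validates every stage against independent oracles: brute-force
windowed means, hand-coded two-point interpolation, exhaustive per-sample
window scans, the Fleiss category-count formula, and closed-form mean/SD.
Synthetic recovery uses noise-free cohorts (exact agreement required),
a 200-trial cohort at noise SD 1.0 a.u. (≥ 95 % accuracy required), and 50
noise-free drift trials (A5 negative and A10 positive on all). These sizes
give stable estimates while keeping the whole suite in seconds.

Reproduction of the published per-group plateau counts runs only when the
original 120-trial dataset (distributed as journal Supporting Information,
not redistributable here) is placed at `data/supplementary/manifest.csv`;
the corresponding test otherwise fails with that explanation rather than
silently skipping. The published kappa values likewise require the raw
per-rater annotations; only their band labels are checked unconditionally.

## Known limitations

* The anchored-vs-range reading of "stability" and the inclusiveness of the
  bounds are conventions the original analysis does not pin down; both are
  configurable, defaults documented above.
* The detector is specified for 3-min all-out tests only; the plateau
  definition is not validated for ramp or step protocols, and no
  breakpoint/sigmoid fitting is attempted.
* Relative-mode criteria are undefined when a window's anchor is 0 (percent
  change from zero); the detector raises rather than guessing.
* Percentages in summaries are full-precision floats; published tables that
  truncate repeating decimals (29/30 → 96.66) should be compared on counts.
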