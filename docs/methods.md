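# Methods

## Scope

`pdkin` implements a complete analysis for separating the TD and PIGD motor
subtypes of Parkinson's disease from full-body marker kinematics: subtype
scoring from MDS-UPDRS items, preprocessing and windowing of 11-marker
trajectories, statistical/temporal-frequency and spatiotemporal gait
features, leakage-aware repeated cross-validation of three classifier
families, and feature-relevance analyses. Because clinical recordings of
this kind are not publicly distributable, a synthetic-cohort generator is a
first-class, tested component: it defines the study conditions under which
the pipeline is validated.

## Subtype scoring

Tremor score = mean of items 2.10, 3.15, 3.16, 3.17, 3.18; gait score =
mean of items 2.12, 2.13, 3.10, 3.11, 3.12; each item an integer 0–4.
Ratio = tremor/gait; PIGD iff ratio ≤ 0.90, TD iff ratio ≥ 1.15, otherwise
Indeterminate, with both thresholds inclusive. Conventions this package
fixes where the rule is silent: a zero gait score with nonzero tremor maps
to ratio +∞ and TD (zero gait burden is maximally tremor-dominant); both
scores zero is Indeterminate with the ratio recorded as NaN. Raters who
score body-part sub-items can pre-aggregate them with
`subtyping.aggregate_subitems` (plain mean); whether sub-items should be
averaged before item averaging is a rater-convention question the package
does not decide beyond documenting this helper.

## Synthetic cohort

Each virtual participant carries generative parameters (stride frequency
and length, step width, arm swing, tremor amplitude/frequency, freeze
rate/duration/band frequency, stride-to-stride CV, sensor noise, height).
Marker trajectories are the sum of:

* a sacral path — forward speed = stride length × stride-phase rate, so
  displacement per stride equals the stride length exactly; heading handles
  the 360°-turn (stepping in place) and TUG (stand 2 s → walk out → 180°
  turn → walk back → 180° turn) scripts;
* anthropometric offsets scaled by height, rotated by the heading;
* sinusoidal gait oscillations driven by a common stride phase with
  multiplicative stride-time and stride-length noise (piecewise-linear,
  ~one-stride correlation, CV as parameterized). The anterior heel
  waveform is phase-warped so the stance fraction is 0.60: left heel
  strike at integer phase, left toe-off at phase 0.60, right side offset
  by half a cycle (initial double support 10%, single support 40%);
* phenotype oscillations — TD: resting tremor at 4–6 Hz on both wrists
  (mediolateral + vertical) and at half amplitude on thigh/shank markers
  (resting tremor involves the legs; this is also what makes a
  thigh+shank-only marker set carry the discriminative signal); PIGD
  freezers: episodes during which the stride-phase rate collapses to 3% of
  normal (forward displacement < 20% of the walking median) while a
  3–8 Hz trembling rides on shank/heel channels. Episode starts follow a
  Poisson draw at the phenotype's rate over walking time (≥ 1 forced on
  walks longer than 15 s for freezers), non-overlapping, with 0.25-s
  activity ramps;
* white Gaussian sensor noise (0.15 cm SD).

Ground truth exposes event times (phase crossings during active stepping),
freeze intervals, sagittal joint-angle series computed from the noiseless
geometry, and the generative stride length/cadence/support fractions.

Defaults (TD stride ≈ N(118, 14) cm vs PIGD ≈ N(104, 14) cm, tremor
amplitude U(1.5, 3) cm, freeze rate U(2, 5)/min, PIGD stride CV twice the
TD value) were chosen once for clinical plausibility: stride distributions
deliberately **overlap** between subtypes — the literature disagrees on
whether spatiotemporal gait separates TD from PIGD — so the reliable
discriminators are spectral. Tremor and freeze amplitudes in marker units
are free parameters of the emulation, not estimates of any clinical
dataset; passing tests therefore demonstrate pipeline correctness and the
qualitative feature-family orderings under these conditions, not clinical
effect sizes. UPDRS synthesis maps tremor amplitude to tremor items and
freeze rate + stride shortfall to gait items with a final adjustment that
guarantees label consistency at zero rater noise; noise jitters items ±1
with the given probability.

## Preprocessing

Order: linear gap filling (interior interpolation, edge extrapolation from
the two nearest observed samples) → hip-centering (subtract the sacral
position per frame) → per-channel Z-normalization over the session
(population SD; zero-variance channels map to zeros) → segmentation into
4-s windows with 1 s of *shared signal* between consecutive windows (hop
3 s; the phrasing "1-s overlap" is read literally, the hop is
configurable). Recordings shorter than one window yield a single
whole-recording fallback window, since straight-walk trials average 4.75 s
and are often shorter than 4 s. Whether Z-normalization precedes
hip-centering is not observable in the features (hip-centering is a
per-frame translation); the fixed order above is the package's convention.
No smoothing or filtering is applied.

## Kinematic features

Per channel and window: mean, minimum, maximum, population variance;
freezing index (3–8 Hz over 0.5–3 Hz band power, locomotor power floored
at a relative 1e-12 epsilon); spectral centroid and dominant frequency
within 0.5–12 Hz (DC and sensor-noise bands excluded; zero-power bands
return 0; dominant-frequency ties break to the lower bin); mean absolute
detail coefficient of a 4-level symmetric-padded db4 DWT pooled across
levels (the dyadic detail bands cover ≈ 3.75–60 Hz at 120 frames/s).
Spectra are single-taper **symmetric**-Hann periodograms of the
mean-removed window — symmetric rather than periodic so spectral
magnitudes are exactly invariant to time reversal; at 4 s this gives
0.25 Hz bins, the maximal resolution the window admits, which is why
Welch averaging is not used. Band edges, the search band and the wavelet
family/level are configurable; "mean of wavelet coefficients" is
implemented as the absolute pooled mean (a signed mean of detail
coefficients is ≈ 0 for any near-stationary signal and carries no
information). Whether spectral features see Z-normalized or raw-amplitude
channels follows from the preprocessing order above (normalized); the
freezing index and the frequency locations are amplitude-invariant either
way. Feature-table Z-standardization is *not* part of extraction: it is a
training step fitted on training folds only.

## Gait features

Events are detected from the heel anterior position relative to the sacrum:
strikes at local maxima, toe-offs at local minima, extrema below 10% of the
channel's excursion rejected, minimum peak spacing set by the channel's
dominant stride frequency. Events are gated to frames where the smoothed
sacral horizontal speed exceeds 25 cm/s, which excludes standing, freezing
episodes and turning-in-place strides; turning sessions therefore
(intentionally) raise insufficient-gait. These operations take the raw
gap-filled recording: detection hip-centers internally, while stride/step
lengths and forward velocity need world-frame paths, which hip-centering
would zero out and Z-scoring would destroy.

Definitions: step length = anterior distance between contralateral heel
positions at successive strikes; stride length = between successive
ipsilateral strikes; cadence = 60 × valid steps / summed valid step
intervals (step intervals spanning gated-out segments are dropped — on a
gap-free walk this equals steps over the strike-bounded span); forward
velocity = sacral anterior displacement over the strike-bounded span;
support/swing/initial-double/single-support percentages from strike and
toe-off phase fractions per cycle, cycles longer than 1.8× the median
dropped; step width = mean mediolateral distance between heels at paired
strikes. "Initial double support" is the interval from the ipsilateral
strike to the next contralateral toe-off. Knee and ankle angles are
sagittal-plane segment-vector proxies (Sacral→Thigh vs Thigh→Shank;
Thigh→Shank vs Shank→Heel) because the 11-marker set has no joint markers;
0° means collinear segments. Height normalization divides length
parameters by the participant's height, imputing the 180 cm population
mean when unknown.

## Cross-validation

The 50/20/30 train/validation/test fractions do not form a literal k-fold
rotation, so each (repeat, fold) draws an independent partition from a
deterministic child seed (`SeedSequence(seed, repeat, fold)`, reduced below
2³¹); "5-fold × 50 repeats" = 250 independent evaluations, summarized by
the mean F1 and its Wilson 95% interval at N = 250 (closed form, no
continuity correction). User-independent splits partition participants,
stratified by label; a class with fewer participants than `n_folds` is
refused. User-dependent splits partition windows within participants and
then remove from validation/test any window that shares frames with, or
neighbors (|Δ window index| = 1), a training window of the same session;
with the default 4 s/3 s geometry the two conditions coincide.
Hyperparameters (RF: trees 100–500, depth, features-per-split; SVM:
C ∈ 10^[−2,3], γ ∈ 10^[−4,1]; MLP: 1–2 layers of {32, 64, 128}) are drawn
25 times, scored by validation F1 on the first split, and the winning
configuration is reused across all repeats — a single nested search rather
than per-fold searches, which also keeps the 250 evaluations comparable.
The MLP uses early stopping only when the training set can spare a
meaningful internal validation split (n ≥ 200); below that it trains to
tolerance, because the restored best-validation iterate is unreliable when
ranked on a handful of samples. Binary F1 takes PIGD as the positive class
(the majority clinical target; configurable). No class rebalancing is
applied. FOG filtering ("FOG excluded") keeps only participants whose item
3.11 is 0.

## Feature analysis

MDI importance is the accumulated Gini impurity decrease per feature,
averaged over trees and normalized to sum to one (scikit-learn's
`feature_importances_`; an independent tree-walking oracle verifies it in
the tests). Feature–score correlations are Pearson r over windows, matching
how features enter the classifier; window samples overlap in time and are
not independent, which the output records as a caveat, and a
participant-mean mode is offered. Restricted-set reruns accept explicit
feature lists (top-k of a ranking) or marker lists (all 8 features × 3 axes
per marker) and otherwise reproduce the unrestricted experiment exactly
under equal seeds; top-k selections should use mean ranks across repeats.

## Problem sizes and determinism

The standard evaluation cohort is 40 participants (balanced TD/PIGD, half
of PIGD freezing), one 40-s TUG session per participant for window features
(13 windows each) and two 10-s straight walks for gait features; gait
recovery uses a 20-participant cohort at 10-s walks; the permutation null
runs 10 repeats × 5 folds and the ordering experiments 3 repeats × 5 folds
with a fixed 300-tree forest. These reduced session lengths and repeat
counts are the package's chosen problem sizes: they give stable statistics
for the properties being checked while keeping any run on one CPU in the
minutes range. All randomness flows from explicit seeds through
`SeedSequence`-derived child seeds; identical inputs reproduce outputs
bit-for-bit.

## Known limitations

* The kinematic model is a phase-driven sinusoid sum, not a biomechanical
  simulation: joint angles are segment-vector proxies, there are no
  kinematic constraints, no medication ON/OFF dynamics, and no pathological
  asymmetries beyond the modeled ones.
* Synthetic class separation is by construction stronger than clinical
  reality; absolute F1 values on the benchmark say nothing about clinical
  performance, only the orderings and the pipeline's correctness are
  meaningful.
* TRC/CSV I/O covers the common tab-delimited mocap dialects; binary C3D
  is out of scope.
* The linear mixed-effects demographic-bias analysis sometimes paired with
  this design is out of scope (standard regression available elsewhere).
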