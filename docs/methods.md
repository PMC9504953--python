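# Methods

## Signal model

Four load cells, one under each bed leg, measure vertical force at 50 Hz
(configurable).  The channels are named by position: LH/RH under the head
end (left/right as seen from above, lying on one's back), LF/RF under the
foot end.  Forces are treated as those of the occupant-bed *system*: the
empty-bed load (tare) is **not** subtracted by default.  The CoM equations
are scale-dependent through the total force, so mean-CoM features differ
between the tared and untared conventions; `apply_tare` is provided for
workflows that prefer occupant-only forces, but the default matches the
system definition, and all scale-free features (ratios, angles, normalised
rms) are identical either way.

The planar centre of mass follows from moment balance about the bed centre:

    CoM_x = (w/2)(LH + LF − RH − RF)/Σ,   CoM_y = (l/2)(LH + RH − LF − RF)/Σ

with Σ the summed force, w the lateral and l the longitudinal sensor
spacing.  `compute_com` refuses recordings whose total force drops to ≤ 1 N
(configurable) — a near-empty bed makes the quotient meaningless.

## Filters

The filter parameters are implementation choices, exposed in `FilterSpec`:

| parameter | default | rationale |
|---|---|---|
| respiratory filter | Chebyshev II low-pass, stop edge 1.0 Hz, 40 dB, order 8 | adult resting breathing sits at 0.15–0.5 Hz; 1 Hz stop edge keeps the full band with a flat passband while rejecting cardiac/motion energy |
| cardiac filter | equiripple FIR band-pass 0.8–2.5 Hz, 60 dB stop, ≤ 1 dB pass ripple, 0.3 Hz transitions | resting heart rate 48–150 bpm; FIR symmetry gives exact linear phase |
| rms normalisation | per-window 97th percentile | see below |

Both filters are applied forward–backward (`filtfilt`, odd-symmetric edge
padding of 3× the filter length), so the effective response is the squared
magnitude and the phase is exactly zero — breath and beat landmark times are
preserved, which the extrema-based angle feature depends on.  The FIR tap
count comes from the Kaiser estimate with a 20 % margin, forced odd
(type I); the design targets a pass-band deviation of 0.5 % — tighter than
the 1 dB budget — so that even the squared response stays within a few
tenths of a percent of unity.  Tests verify the achieved response rather
than assuming it.  Zero-phase filtering needs more samples than the padding
length, which for the default FIR (~727 taps) means recordings shorter than
about 44 s cannot be filtered; one analysis window (45 s) is exactly the
practical minimum.

Because a low-pass retains DC, the respiratory rms features are computed on
the mean-removed signal within each window; otherwise the static posture
offset would dominate the rms.

## Breaths and the respiratory-axis angle

Breath landmarks are zero crossings of the first difference of the filtered
respiratory signal: + → − sign changes mark maxima (end of exhalation),
− → + minima (end of inhalation).  Detection runs on whichever component
(x or y) has the larger variance; under the generative model both oscillate
in phase along the respiratory axis, so their extrema coincide, and the
larger component is the better-conditioned detector near axis angles of 0°
or 90°.  A constant signal yields no landmarks (not an error).

For every maximum and the following minimum the angle is
`arctan(|Δy/Δx|) ∈ [0°, 90°]` of the CoM displacement between the two
landmarks — i.e. the inhalation stroke only.  Residual in-band noise
produces spurious tiny "breaths" between real ones whose angles are
essentially uniform; a breath whose displacement magnitude is below 25 % of
the 90th percentile of all breath displacements is therefore discarded.
With noiseless input nothing is discarded and the per-window angle is exact
to well under 0.1°; the threshold matters only when sensor noise leaks into
the respiratory band.

Per window, `CoM_resp_ANG` is the mean of the angles of all breath pairs
that lie fully inside the window and `stdCoM_resp_ANG` their standard
deviation (0 for a single breath; both missing, and the row flagged, for a
window without any breath pair).

## Window features

Windows are half-open `[t, t + 45 s)`, anchored at the recording start and
advanced by 15 s; a recording of T seconds yields ⌊(T − 45)/15⌋ + 1 windows
of 2250 samples at 50 Hz.  The twelve features per window: mean and
standard deviation of CoM_x and CoM_y and the y/x quotients of each; the
respiratory-angle mean and standard deviation; the rms of the mean-removed
respiratory x and y components, each divided by the 97th percentile of its
absolute values within the same window (the per-window reading keeps the
feature free of cross-window state; a global-percentile and an unnormalised
variant are selectable), and their quotient; and the rms of the
cardiac-band signal.  Any zero ratio denominator or breathless window
yields a missing value and flags the row; flagged rows are excluded from
classification.

## Simulator

The generator emulates exactly the statistical structure the features
assume, with defaults chosen as typical resting adult physiology:

* body weight 700 N; posture-dependent static CoM offsets
  (LEFT (+0.07, 0.18) m, SUPINE (0, 0.20) m, RIGHT (−0.07, 0.18) m —
  lateral sign encodes the side, the longitudinal offset reflects the torso
  lying head-of-centre);
* a sinusoidal respiratory CoM excursion, amplitude 1.5 mm at 0.25 Hz
  (15 breaths/min), along a posture-dependent axis (80° supine, 20°/35°
  side-lying);
* a cardiac force sinusoid, 0.5 N peak at 1.17 Hz (~70 bpm), carried by the
  head-end channels and balanced with the opposite sign on the foot-end
  channels: the beat is an internal force redistribution, so the summed
  vertical force stays exactly body weight + tare at every sample;
* white Gaussian noise per channel, 0.5 N sd.

Forces are laid out by the bilinear corner distribution
`LH = W(½ + x/w)(½ + y/l)` etc., the exact right-inverse of the CoM
equations, so ground truth is recoverable by construction.  Posture changes
cross-fade linearly over 2 s (a moving average of the offset step trace),
and a window's ground-truth label is its majority-time posture.

Cohorts draw profiles from uniform ranges (weight 450–900 N, side offsets
±(0.02–0.12) m, supine offset ±0.04 m, respiratory angles 45–80° supine and
5–45° side-lying, breathing 0.18–0.32 Hz, noise 0.3–1 N).  The side/supine
offset ranges and the angle ranges deliberately overlap *across subjects*:
a cross-subject classifier then generalises imperfectly (c = 0 accuracy well
below ceiling) and per-subject calibration genuinely helps, which is the
phenomenon the incremental-learning protocol measures.  Within one subject
the postures remain separable.

What the simulator does **not** model: mattress and frame dynamics,
posture-dependent breathing-waveform shape, movement artefacts other than
the cross-fade, drifting sensor baselines, or partial bed exits.  Passing
tests therefore demonstrate the correctness of the pipeline's mechanics and
its behaviour under the assumed signal structure — not field performance on
real sleepers.

## Evaluation protocol

One LOPO fold per participant.  Within each fold the held-out windows are
split 30:70 (class-stratified, seeded) into a calibration pool and a fixed
test set; the split is a function of the seed alone, so the test set is
identical across incremental levels and results at different c are directly
comparable.  The increment at level c is a stratified c/0.30 fraction of
the pool; increments are nested across levels.  Models are refit from
scratch on train ∪ increment (the "incremental" aspect is the data, not
warm-started weights — refitting is the conservative choice and keeps all
eight families on equal footing).  A chronological-prefix split mode is a
natural alternative (a home deployment would collect calibration data
first) and can be added via the split function; the default is random
stratified.

Reported metrics: accuracy and F1 per fold with the pooled 3×3 confusion
matrix.  F1 is macro-averaged by default (unweighted over the three
postures, the standard choice under class imbalance), configurable to
weighted.  The MLPs are scikit-learn `MLPClassifier`s with the
fully-connected widths 12→64→100→3 ("OG") and 12→12→6→4→3 ("SIMPLE"), ReLU,
softmax/cross-entropy, early stopping on a 10 % validation split, behind a
standard scaler; scikit-learn's MLP has no dropout or batch-normalisation
layers, so those regularisers are omitted — at this feature dimensionality
early stopping provides the equivalent safeguard.  Remaining
hyperparameters follow the library defaults and are recorded in the run
manifest.

Model comparison at a chosen c: Shapiro–Wilk per model and Levene across
models (assumption checks, reported not enforced), Friedman rank test
across models paired by participant, then pairwise Wilcoxon signed-rank
tests on the top three models by mean with the Bonferroni threshold
α/(number of pairs) — 0.05/3 ≈ 0.017 — reported next to raw p-values.
Degenerate inputs (no variance anywhere) produce an explicit "no variation"
report rather than a statistic.  Note the exact two-sided signed-rank test
cannot reach p < 0.017 with fewer than eight paired subjects.

## Rater agreement

Fleiss's kappa with the standard closed form; the per-category variant
κ_j = 1 − Σ_i x_ij(r − x_ij) / (n r (r−1) p_j (1−p_j)) isolates agreement on
one posture.  Windows with missing rater labels are excluded listwise
(the statistic requires a constant rater count).  κ is undefined when
chance agreement is 1 (all ratings in a single category) and κ_j when a
category is never or always used; both are reported as missing, never as a
number.  Interpretation bands: < 0.20 poor, 0.21–0.40 fair, 0.41–0.60
moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect; values in the
non-contiguous gaps between band edges are assigned to the band above.

## Numerical and design notes

* Consensus ground truth is the strict plurality across raters; a window
  with a full three-way tie is marked UNRESOLVED and excluded downstream —
  inventing ground truth for it would contaminate both training and kappa.
* Ratio features use the convention y-quantity / x-quantity throughout.
* Adding a constant force to all four channels rescales the CoM by
  Σ/(Σ + 4c): mean and std features rescale by exactly that factor, while
  angles, ratios, normalised rms and the cardiac rms are scale-free; the
  test suite asserts the exact rescaling rather than a false invariance.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); derived seeds stay below
  2³¹ for library compatibility.  Identical seeds give bit-identical
  simulations and evaluation results.
* Default experiment scale: nine simulated subjects at 30 minutes each
  (~118 windows per subject), which puts per-fold test sets near 80 windows
  and keeps a full two-model, four-level evaluation under a minute on one
  CPU; longer nights only narrow the error bars.

## Known limitations

* The MLPs omit dropout/batch-norm (see above) and, like all eight
  families, use library-default hyperparameters — no tuning is attempted.
* The breath detector assumes a single dominant respiratory axis; paradoxical
  or highly irregular breathing would scatter the angle feature.
* Fleiss's kappa assumes raters are interchangeable; rater-specific bias is
  not modelled.
* The simulator's noise is white; real load-cell noise has 1/f components
  that would pass the respiratory filter more readily.
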