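# Methods

## The measurement

`ictalsync` quantifies brain synchronization across the ictal phases of
cyclic electrographic seizures recorded on a reduced 8-electrode 10–20
scalp montage (Fp1, Fp2, C3, C4, T3, T4, O1, O2; monopolar signals used as
stored, nominally 256 Hz).

The synchrony measure is the **low-frequency imaginary coherence
(LF-iCOH)**. For channels x and y, coherency is the normalized
cross-spectrum

    C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f)),

a complex number with |C_xy| ≤ 1. Volume conduction — the passive spread
of a single cortical generator to several scalp electrodes — produces
*instantaneous* (zero-lag) correlation, which lands entirely in the real
part of C_xy. Discarding the real part and retaining |Im C_xy(f)| leaves a
measure blind to that leakage and sensitive only to time-lagged
interaction. A band value is the mean of |Im C_xy| over the frequency bins
inside the band; the LF value is the arithmetic mean of the delta-band
(1–4 Hz) and theta-band (4–8 Hz) values, ranging from 0 (no lagged
correlation) to 1 (perfect lagged synchronization).

Choices the measure definition leaves open, and what this package does:

- **Rectification.** The band aggregate uses the absolute imaginary part
  per bin. A signed average could not span the stated 0–1 range and would
  let opposite-lag bins cancel.
- **Bin assignment.** delta = bins with 1.0 ≤ f < 4.0, theta = 4.0 ≤ f ≤
  8.0: a disjoint cover of [1, 8] Hz with the shared 4 Hz bin counted once
  (in theta).
- **Spectral estimator.** Welch averaging with 2-s Hann segments, 50%
  overlap, per-segment mean removal: 0.5 Hz resolution (resolving the 1 Hz
  band edge) and 9 segments per 10-s analysis window. With a single
  segment |coherency| ≡ 1 identically, so at least two segments are
  enforced. All estimator settings are configurable (`SpectralParams`).
- **No additional filtering.** Clinical acquisition already band-passes
  0.5–70 Hz with a mains notch; synthetic data is generated in-band.

Because Welch averaging is finite, |Im C| is biased away from zero even
for independent signals (about 0.18 for 9 segments). `icoh_null_quantile`
calibrates this "no correlation" level by seeded Monte Carlo over
independent Gaussian pairs; detection claims are made relative to it.

## Phase windowing and reduction

Each selected seizure contributes four 10-s windows anchored on its
onset (O) and termination (T) markers: pre-ictal [O−10, O), onset
[O, O+10), termination [T−10, T), post-ictal [T, T+10). Inter-ictal
markers (≥ 5 min from any seizure) contribute the two windows flanking
them. Windows are half-open in samples; a marker falling between samples
resolves to the nearest earlier sample. Windows extending outside the
recording are dropped with a warning, and seizures missing any of their
four windows are omitted.

Per window, an 8×8 connectivity matrix holds LF-iCOH for all 28 unordered
channel pairs (diagonal 0 by convention). The inter-ictal baseline Z_ic is
the elementwise mean over all inter-ictal windows of the recording, and
every ictal-phase matrix Z_n is adjusted entrywise as

    (Z_n − Z_ic) / Z_ic,

so 0 means "at the inter-ictal level" and positive values mean
hypersynchronization. The estimator's noise floor keeps Z_ic entries
strictly positive; an entry below 1e−6 raises an explicit error rather
than dividing by it. Because every phase of a pair is divided by the same
baseline entry, baseline estimation noise rescales all four phases of a
location together and cancels from within-location phase contrasts.

Adjusted matrices reduce to:

- **regional averages** — the mean over five designated electrode pairs
  per region (anterior, centrotemporal, posterior, left, right). The
  five-pair assignment is configuration, not inference; the default
  anchors each region on its own electrodes and uses only
  within-hemisphere pairs for left/right. It is logged with every run and
  should not be mistaken for a canonical map.
- **electrode totals** — the row sum of the 7 off-diagonal entries, the
  total adjusted synchrony of one electrode.

Both reductions consume adjusted entries by default (a raw mode exists
for descriptive displays).

## Inference

The long-format synchrony table (one value per seizure × phase × location)
is modeled with a linear mixed-effects model of the possibly transformed
value on phase × location, REML-estimated, with a random intercept per
seizure (single recording) or per patient plus a seizure-within-patient
variance component (pooled cohorts).

- **Term tests.** Factors use sum-to-zero coding and each fixed term is
  tested by the Wald chi-square b′V⁻¹b on its coefficient block. For the
  balanced designs this pipeline produces, this block test coincides with
  a Type II analysis-of-deviance table. Inference is large-sample
  (infinite-df) Wald: with hundreds of windows per fit,
  small-sample degrees-of-freedom corrections (Kenward–Roger,
  Satterthwaite) are second-order, and omitting them keeps the test a
  closed-form matrix computation.
- **Post-hoc contrasts.** Within every location, the termination phase is
  contrasted against each other phase (3 contrasts). Multiplicity is
  handled per location family with Dunnett's method against the
  termination reference: the adjusted p of contrast k is
  P(max_j |Z_j| ≥ |t_k|) under the joint normal law of the family's Wald
  statistics, evaluated by equicoordinate multivariate-normal integration
  (quasi-Monte-Carlo, seeded; reproducible given the seed and accurate to
  ~1e−5; adjusted p is additionally clipped to be ≥ the unadjusted p).
- **Calls.** A location shows *terminal hypersynchronization* when
  termination exceeds all three other phases with positive contrast sign
  and adjusted p < 0.05 (the default "all" rule). Whether one significant
  elevation should suffice is genuinely open; the "any" rule is a config
  option and the CLI reports both.
- **Transforms.** "identity", "log" (log(1+v), well defined because
  adjusted values are bounded below by −1) and "sqrt" (√(1+v)) are
  available; "auto" keeps identity unless its residual skewness exceeds 1,
  then tries log, then sqrt. Both transforms are monotone increasing, so
  contrast signs are preserved. The choice is recorded on the fit.

## The synthetic cohort generator

No public recordings of this kind exist, so validation runs on synthetic
cohorts whose ground truth is known exactly. The generator emulates the
statistical structure the analysis relies on — not the biophysics:

- **Cyclic seizures.** Onsets recur at Gaussian inter-onset intervals
  (default 380 ± 30 s ≈ 9/h, above the > 3/h cyclic definition);
  truncated-normal durations (default 118 ± 34 s, floored at 21 s so the
  > 20 s selection filter never bites on defaults). An optional
  two-component interval mixture imitates clustering. 11-min lead-in and
  lead-out segments carry inter-ictal markers, as does the midpoint of any
  inter-seizure gap ≥ 610 s.
- **Ictal rhythm.** A cosine whose frequency falls linearly from 6 to
  2 Hz over the seizure, with 2-s raised-cosine onset/offset ramps,
  amplitude 0.7× the background RMS. (Narrowband, so it still dominates
  its own spectral bins; nonconvulsive discharges are not high-voltage.)
- **Lagged coupling.** For each configured pair, the common rhythm is
  injected into both members, the second delayed by an integer-sample lag
  (default 62.5 ms, a quarter period at the 4 Hz band center, maximizing
  |Im C|) and scaled by a gain (default 0.5, keeping pair LF-iCOH
  mid-range with headroom above the null floor and below saturation).
- **Terminal boost.** During the final 10 s of each seizure the injection
  gain of every coupled pair is multiplied — on both members — by
  `terminal_boost`. Boosting only the delayed copy was rejected: inflating
  one channel's auto-power suppresses the finite-sample |Im C| bias on its
  noise-only pairs, depressing that electrode's total at termination — an
  estimator artifact masquerading as the effect under study.
- **Volume conduction.** The 8-channel source array is left-multiplied by
  a near-identity mixing matrix (default 0.05 off-diagonals). This is the
  adversarial ingredient: it creates exactly the zero-lag leakage the
  imaginary part must reject.
- **Background.** Independent per-channel 1/f Gaussian noise, shaped in
  the frequency domain.

What the generator does **not** emulate — hence what passing tests do not
show about clinical data: movement and electrode artifacts, sedation
effects, non-stereotyped or multifocal seizures, realistic head-volume
conduction (a full-rank lead field rather than a near-identity mixture),
non-stationary background, and reference-electrode effects.

## Calibration studies and problem sizes

Two replicated studies exercise the full chain
(`ictalsync.calibration`): a **null study** (no coupling anywhere, so all
four phases are exchangeable) checking that the per-location-family
Dunnett familywise error rate sits at the nominal α = 0.05 and that the
stricter all-contrasts call rate stays below it; and a **power study**
(one C3–C4 coupled pair, terminal boost 3, 60 seizures per cohort)
checking that both coupled electrodes are called and occipital electrodes
are not.

Replicated cohorts are deliberately scaled down: 64 Hz sampling (the
analysis bands end at 8 Hz), ~30 s seizures on a ~60 s cycle, inter-ictal
baseline windows from the lead-in/lead-out segments. This preserves every
structural element the detector uses (9 Welch segments per window, four
phases per seizure, baseline adjustment, mixed-model design) at a fraction
of the cost; 200 null and 100 effect cohorts complete in minutes on one
CPU. Because calls within one cohort share windows and electrode pairs,
rates are assessed against the binomial band computed at the number of
*cohorts*, the independent replication unit.

A note on the interaction term: on null cohorts its Wald test is
conservative (rejection rate below nominal) because region and electrode
values within a seizure-phase share electrode pairs and noise, a residual
correlation the location factor does not model. The familywise error of
the per-location Dunnett families — the quantity the procedure actually
calibrates — sits at the nominal level.

## Numerical and I/O details

- EDF reading goes through `mne`; channel matching is case-insensitive
  and strips clinical decorations ("EEG Fp1-Ref" → Fp1). Writing uses a
  minimal 16-bit EDF encoder (1-s records, physical dimension µV) whose
  output round-trips through the `mne` reader to within one quantization
  step.
- Marker files are plain CSV (`kind,time_s,label`), times in seconds from
  recording start; onset/termination rows pair in file order; a per-seizure
  "exclude" label supports manual artifact/multifocal exclusions, which are
  not automated.
- Seizure selection retains durations strictly > 20 s, warns (rather than
  fails) below 51 seizures, and drops inter-ictal markers within 300 s of
  a retained seizure boundary. Selection is idempotent.
- All simulation and Monte-Carlo code draws from `numpy` Generators seeded
  explicitly; fixed seeds reproduce cohorts bit-exactly.
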