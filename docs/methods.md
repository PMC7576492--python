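# Methods

This note documents the models, numerical choices and known limitations of
`emgforce`.  It covers the pre-processing pipeline, the two channel-selection
families, the fast-orthogonal-search (FOS) force model, the evaluation
protocol, and the synthetic data generator that supplies the test
conditions.

## Signal model and pre-processing

Input trials hold three 8-channel monopolar linear-array EMG recordings
(one array per elbow flexor: biceps brachii long head, short head,
brachioradialis) at 2048 Hz, plus the wrist force at 1000 Hz, for an
isometric contraction at a fixed elbow angle (60/90/120°) and forearm
posture (neutral/supinated).  The force profile visits three constant
plateaus at 20, 35 and 50 % of maximum voluntary contraction (MVC), 5 s
each, in random order.

Processing steps, in order:

1. **Differential derivation.**  Channel *i* of each array becomes
   `monopolar[i+1] − monopolar[i]` (8 → 7 channels per muscle), rejecting
   common-mode interference.
2. **Band-pass 10–500 Hz, 4th-order Butterworth.**  Applied
   forward–backward (`sosfiltfilt`): the analysis is offline, so zero
   phase is preferable; the effective magnitude response is the square of
   the single-pass filter (8th-order roll-off).
3. **Linear envelope.**  Full-wave rectification followed by a 300-sample
   (~147 ms) *centered* moving average.  Whether a causal or centered
   window is used is an open choice for offline analysis; centered avoids
   a group delay against the force channel.  Edge samples average over the
   truncated window; envelopes are consumed only inside plateau segments,
   which never touch the edges.
4. **MVC normalization.**  Each channel's envelope is divided by its mean
   over the 50 %MVC plateau(s) of the *training* trial.  The same
   reference is reused for the test trials of the condition, mirroring the
   subject-specific calibration a deployed system would perform once.
5. **Force alignment.**  The 1000 Hz force is up-sampled to 2048 Hz by
   linear interpolation (original sample values preserved exactly).
6. **Plateau extraction.**  The centered 3 s of each 5 s plateau is
   extracted.  The localization rule is not standardized; we use a
   sliding-window (0.5 s) standard deviation below 2 % of the local mean
   (with a floor at 5 % of the trace maximum) to mark flat regions,
   require each flat run to contain the 3 s window and a mean above 10 %
   of the trace maximum, and assign nominal levels by scaling the largest
   plateau mean to the largest level.  The assignment must consume every
   nominal level exactly once, otherwise a segmentation error is raised.
   With threshold-based detection "centered" holds to within a fraction
   of the window when ramp slopes are asymmetric.

All downstream computations (selection scores, model fitting, %NMSE) use
the concatenated plateau samples — 3 × 6144 = 18 432 observations per
trial.

## Channel selection

Scores are computed per muscle and trial on the band-passed *differential
EMG* (not the envelopes — smoothing would inflate the correlations), over
the concatenated plateaus.

**Power-correlation ratio.**  `PCR_c = PSD̄_c / m_c` with

- `PSD̄_c`: total 10–500 Hz band power from a Welch estimate (Hann window,
  1024-sample segments, 50 % overlap, trapezoidal band integration),
  normalized by the per-muscle maximum.  How a PSD function is reduced to
  one number per channel is an implementation choice; total band power is
  the natural scalar summary.
- `m_c`: mean absolute Pearson correlation of channel *c* with the other
  six channels of the muscle.

A channel whose mean |r| is zero (to rounding) has no redundancy at all
and receives `PCR = +inf`, ranking first.  PCR is invariant to a common
positive gain on all channels of a muscle and strictly increasing in a
single channel's gain while that channel's power stays below the
per-muscle maximum (the normalized power saturates at 1 on the maximal
channel).

**PCA selection.**  PCA is run on mean-centered, *unstandardized* data
(covariance PCA): amplitude differences between channels are informative
and must not be scaled away.  Time-domain selection decomposes the
envelope time courses per muscle; frequency-domain selection decomposes
the FFT magnitude spectra (10–500 Hz bins, phase discarded) of all 21
channels jointly and then ranks within each muscle.  With `n_pcs > 1` the
rank score is the variance-weighted vote
`score_c = Σ_i evf_i · |loading_{i,c}|`; the weighting is configurable in
principle (an unweighted Borda count is the obvious alternative) but the
variance-weighted form is the default because it degrades gracefully to
the single-PC rule as PC1 dominates.  Loading signs are arbitrary, so
absolute values are used; exact score ties break to the lower channel
index.  Rankings are computed once per trial, so the selected sets for
k and k+1 are nested by construction.

## FOS force model

The candidate pool for active envelope channels {LE_i} and trial angle θ
contains: the constant, θ, each LE_i, sin θ·LE_i, cos θ·LE_i,
sin θ·LE_i·LE_j and cos θ·LE_i·LE_j for cross-muscle pairs, and four
nonlinear transforms per channel — LE², a saturating square
min(LE², s) with s = 4, √LE, and a logistic sigmoid
1/(1+exp(−(LE−1)/0.25)).  The sigmoid center sits at 1 because envelopes
are normalized to 1 at 50 %MVC; the saturating square clips at twice the
reference amplitude.  These parametric forms are reconstructions — the
analytic forms used with the original hardware pools are not public — and
are configurable via `BasisConfig`.  The pool size follows the closed
form N = 2 + 7C + 2P (C channels, P cross-muscle pairs).  An intercept is
always included since measured force has an offset.  Trigonometric
factors are evaluated exactly in degrees; at θ = 90° the cosine families
vanish identically and are omitted rather than kept as rounding-noise
columns.

Fitting is greedy orthogonal least squares.  The implementation keeps
inner-product recursions only: for every remaining candidate the
residualized correlation `g_c = ⟨p_c, y⟩ − Σ_j ⟨p_c, q_j⟩⟨q_j, y⟩` and
orthogonalized energy `e_c = ‖p_c‖² − Σ_j ⟨p_c, q_j⟩²` are updated from a
single matrix–vector product per step, so each step is
O(n_samples · n_candidates).  The candidate maximizing `g²/e` (the MSE
reduction) is added; exact ties break to the lowest candidate index.  A
candidate is skipped once `e_c < 1e-10 · ‖p_c‖²` (collinearity guard; the
basis families are deliberately redundant within a constant-angle trial,
e.g. sin θ·LE ∝ LE, and the guard is what resolves that).  The chosen
column is orthonormalized against the selected set with one
re-orthogonalization pass for numerical stability.  The loop stops at 9
terms (the stopping rule established for this basis in prior work on the
same rig), earlier if no candidate retains independent energy, or when
the best MSE reduction falls below `min_q_frac · mean(y²)` (default 0).
Coefficients in the original basis are recovered by back-substitution
through the triangular Gram–Schmidt factor; tests verify exact agreement
(terms and coefficients, 1e-8) with a brute-force greedy oracle that
refits ordinary least squares for every candidate at every step.

## Evaluation protocol

For each (subject, angle, posture) condition the first trial trains
everything — normalization references, channel selection, FOS model — and
the next two trials are scored.  `%NMSE = 100·Σ(F_meas−F_est)²/ΣF_meas²`
is computed over the concatenated plateau segments of each test trial and
averaged over the two.  Condition-level aggregates report mean ±
standard error (sample SD across subjects / √n).  Grand means average the
condition means; with a balanced design this equals the overall mean.
Both per-trial and per-condition granularities are exposed, since
averaging order (across force levels vs across trials) is a reporting
choice.  Significance helpers (one-way ANOVA across methods with the
all-channel runs as reference group, pairwise Welch t-tests with a
Bonferroni-adjusted threshold) delegate to scipy and are reporting
conveniences only.

## Synthetic data generator

The generator emulates the acquisition protocol at full scale: 2048 Hz
EMG / 1000 Hz force, 20 s trials (0.5 s rests, 1 s ramps, three 5 s
plateaus at 20/35/50 %MVC in seeded-random order), subject-specific MVC
(250 ± 25 N), measured-force noise of 0.3 N.

Per muscle, each monopolar channel carries a band-limited (10–500 Hz,
8th-order zero-phase Butterworth — steeper than the analysis filter so
that generated content stays inside the nominal band) Gaussian carrier
mixed from one shared and one private unit-variance latent source with a
unit-norm mixing row, amplitude-modulated by the envelope law
`A(t) = α·f + β·f²` (f = force as MVC fraction; defaults α = 1,
β = 0.25, a mild physiological nonlinearity) and scaled by the channel
gain.  The shared-source weight alternates in sign along the array;
without the alternation, neighbor differencing would cancel the shared
component exactly and no redundancy would survive at the differential
level.

Planted structure: monopolar channels 0..n_informative (default 3) form
the informative zone (gain 1.0, shared fraction 0.1, additive noise SD
0.025), so differential channels {0, 1, 2} are the planted informative
set; the remaining channels form the redundant zone (gain 0.5, shared
fraction 0.9, noise SD 0.12 — noise SDs are relative to the unit-variance
carrier, whose modulated amplitude is ≈0.2–0.6 on the plateaus — and a
per-trial lognormal gain jitter of 20 %).  The jitter emulates
electrode-contact instability, the dominant artifact of flexible HD
arrays, and is what makes the redundant channels actively harmful to a
model trained on one trial and tested on another.

All randomness flows from a single seed through named substreams (profile
order, carriers, noise, force noise, subject MVC, gain jitter), so a spec
plus a trial key reproduces a trial bit-for-bit.

**What the generator does not model:** motor-unit recruitment and firing
statistics, volume conduction, fatigue, force-tracking errors, or
inter-channel propagation delay.  The carrier is amplitude-modulated
noise, so passing tests demonstrate that the pipeline's amplitude- and
correlation-based machinery behaves correctly under controlled
conditions — not that the specific error magnitudes transfer to human
recordings.  In particular, the planted redundancy/instability contrast
is engineered to be recoverable; on real arrays the informative subset is
subject-specific and the margin between selection methods is smaller.

## Numerical choices and degenerate inputs

- Zero-variance channels make Pearson correlation undefined and raise an
  error rather than returning NaN; a muscle whose every channel has zero
  band power is rejected as degenerate.
- Identically-zero envelope channels are dropped from the candidate pool
  with a warning (the pool invariant forbids all-zero columns).
- Plateau extraction raises a segmentation error when it cannot find
  exactly one flat run per nominal level.
- Sliding-window statistics, envelopes and the FOS recursions are
  cumulative-sum based; energies are clipped at zero to absorb rounding.
- Problem sizes used by the shipped tests and the acceptance script
  (single-subject cohorts, 50-seed repetitions, 12-condition protocol
  comparisons) were chosen to exercise the full pipeline at the protocol's
  native sampling rates while keeping a complete run in the minutes
  range on one CPU.
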