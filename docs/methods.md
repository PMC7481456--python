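# Methods

`lagte` quantifies directed, time-scale-resolved coupling between two
stationary processes — in its motivating application, the beat-indexed
heart-period series (RR) and respiration amplitude series (RESP) of
sleeping neonates — with a lagged version of transfer entropy (TE)
estimated by non-uniform embedding and nearest-neighbor statistics.  This
note records the model, the estimation choices, the calibration of the
selection and significance procedures, what the synthetic generators do
and do not emulate, and the known limitations.

## Transfer entropy with non-uniform embedding

For processes X (source) and Y (target), TE is the information the past
of X carries about the present of Y beyond Y's own past,

    TE_{X->Y} = H(y_n | y_past) − H(y_n | x_past, y_past),

in nats.  Rather than a fixed (Takens) delay vector, the conditioning set
is assembled greedily from the pooled candidate set
Ω = {X_{n−1},…,X_{n−L}, Y_{n−1},…,Y_{n−L}} with L = `l_max` = 10: each
round proposes the candidate with the largest estimated conditional
mutual information (CMI) gain given the already-selected set, a
permutation gate decides whether that gain is distinguishable from
chance, and the first failure stops selection.  The resulting ordered
vector V_k = [V_k^X, V_k^Y] enters the conditioning-vector form

    TE_{X->Y} = H(y_n, V_k^Y) − H(V_k^Y) − H(y_n, V_k) + H(V_k).

An embedding with no source-side candidate yields TE = 0 exactly.

## Lag semantics

The lag τ (0…`tau_max` = 15) always shifts the Y-labelled (driven)
series back in time, and both directional TEs are evaluated on the
shifted pair:

- **X→Y**: the target sample becomes y_{n−τ} while the source past stays
  anchored at x_{n−1..n−L}.  Source candidates therefore span relative
  delays 1−τ … L−τ around the target — deliberately including
  instantaneous and slightly anticipatory terms — and a designed coupling
  at delay d drops out of the candidate span once τ + d > L.
- **Y→X**: the target stays at x_n and the source past is deferred to
  y_{n−τ−1..n−τ−L}, so the source information set never overlaps the
  target's future.

Applying the X→Y rule symmetrically to Y→X would let source samples
overlap the target's future; when the reverse pathway is strong this
"finds" the target inside the source's future samples and produces large
spurious reverse TE.  The y-shift convention avoids that artifact and is
the construction under which the validation system below reproduces its
designed asymmetry.  At τ = 0 both conventions coincide with standard TE.
Usable rows after truncation are N − τ − L for every τ; analyses require
at least 50 of them.

## Estimator

All information quantities are nearest-neighbor estimates under the
max-coordinate (Chebyshev) metric with k = 10 neighbors.  Plain
differential entropy uses the Kozachenko–Leonenko form.  CMI — and TE,
which is the CMI I(y_n; V_k^X | V_k^Y) — is an entropy combination whose
four terms share the k-th-neighbor radius of the joint space, reducing to
the digamma neighbor-count form

    I(t; S | C) = ψ(k) − ⟨ψ(n_tC + 1) + ψ(n_SC + 1) − ψ(n_C + 1)⟩,

the conditional analogue of the Kraskov–Stögbauer–Grassberger estimator.
Sharing the radius makes the dimension-dependent biases of the four
entropy terms cancel; on 300-sample segments this is the difference
between usable and unusable estimates (a naive sum of four independent
entropy estimates carries per-term biases of order 0.1 nat in the
dimensions reached by the embedding).  Computed with the shared radius,
the four-term decomposition and the direct count form agree to floating
precision, which the test suite asserts at 1e−9.

Numerics: ties in the Chebyshev distances (repeated values in short,
quantized series) are broken by a deterministic jitter of amplitude
1e−10 × the per-column SD, drawn from a named substream of the run seed
and applied once per design matrix so that every term sees identical
coordinates.  Raw CMI/TE estimates may be slightly negative (estimator
noise); reported values are clipped at zero, with the raw value retained
alongside.  Degenerate (constant) coordinates raise an error naming the
offending column.

Short designs (≤ 2000 rows) are evaluated by dense kernels that keep
row-sorted pairwise distance matrices of the current conditioning set and
evaluate each one-column augmentation with an early-terminating walk;
longer series use a cKDTree.  Candidate *selection* — a model-choice
step — runs on at most 2000 evenly strided rows, while the TE value
itself is always computed from every row; at the study's native N = 300
this policy changes nothing.

## Selection gate and its calibration

The gate tests the proposed (maximal) candidate against `n_shuffles` =
100 random permutations of its own column at level α = 0.05.  Because
the proposal is the best of the remaining candidates, comparing it
against the 95th percentile of a single candidate's permutation null
would accept a spurious candidate in roughly 1 − 0.95^20 ≈ 64 % of null
rounds.  The default gate ("max-corrected") therefore tests at a
Šidák-adjusted per-candidate level (1 − α)^(1/C), with the family C
taken as the remaining candidates of the winner's *own process* — the
scientific question being whether that process informs the target, at
level α per process.  Under the null each process family is then
admitted at rate α, so the embedding stays empty with probability
(1 − α)² ≈ 0.9025 and a spurious source candidate appears at rate ≈ α —
jointly the calibration that makes the downstream surrogate test land at
its nominal level.  The extreme quantile of the permutation null cannot
be read off 100 draws directly, so it is evaluated from a moment fit —
mean and SD with a Cornish–Fisher adjustment for the mild right skew of
permutation CMI nulls — and the Gaussian multiplier itself is solved
numerically to account for the sampling noise of moments estimated from
100 draws.  An accepted candidate must additionally have positive gain.
Measured over 200 white-noise pairs (N = 300): 86.5 % empty embeddings
and a 7 % source-acceptance rate, about two points liberal of the design
values and inside their exact binomial bands (asserted in the suite).
The uncorrected empirical-percentile gate of the toolbox lineage remains
available as `gate="per-candidate"`; it selects far more liberally,
which inflates embeddings under the null.

One visible consequence of the calibrated gate: couplings near the
detection floor (the validation system's 0.07 reverse coupling at
N = 300) are accepted in only a few percent of replicates, so the
source-side candidate histogram of the reverse direction is flat rather
than concentrated on delay 1.

## Surrogate significance

Significance of one TE value is assessed against 100 time-shift
surrogates: the source series is circularly shifted by an integer drawn
uniformly from [1, `max_shift` = 20] (forward shifts; the direction is
immaterial for a circular shift destroying alignment), and TE is
recomputed on each shifted pair **with the observed conditioning
vector**.  A value is significant when it strictly exceeds the empirical
95th percentile (96th order statistic, no interpolation) of the
surrogate distribution.

Selection is deliberately not re-run inside the surrogates.  A circular
shift of the source merely relabels the candidate delays — delay j of
the shifted source is delay j + shift of the original — so a re-run
greedy selection rediscovers the very alignment that produced the
observed value whenever the selected delay plus shift stays within the
candidate span, and the surrogate then *ties* the observed statistic
instead of nulling it (measured: surrogate thresholds exactly equal to
the observed TE, with dozens of duplicated values).  With the fixed
observed embedding, a shift turns the selected candidate into a
genuinely null alignment and the surrogate distribution is the proper
reference.  The observed value is the gate-passed maximum over
candidates while the surrogate values are single fixed-candidate draws;
at the process-level gate calibration above, the acceptance rate (≈ α)
and the conditional rejection rate combine to a false-positive rate at
the nominal level: 13 significant calls over 200 independent white-noise
pairs, inside the exact binomial 95 % band around 0.05 (asserted in the
suite), with full power (30/30) on coupled-AR replicates.

## Validation system

The coupled autoregressive pair

    X_n = a1 X_{n−1} + a2 X_{n−2} + 0.07 Y_{n−1} + U_n
    Y_n = C1 X_{n−1} + C2 X_{n−2} + C3 X_{n−5} + V_n

with unit-variance white noises realizes a lasting, strong X→Y drive
(delays 1, 2, 5) and a weak, transient Y→X feedback.  X is an AR(2)
oscillator with complex poles at normalized frequency f = 0.1
cycles/sample and modulus ρ = 0.95 (a1 = 2ρcos2πf ≈ 1.5371,
a2 = −ρ² = −0.9025).  C1 = C2 = C3 = 0.5 — values strong enough that the
designed asymmetry dominates estimator noise at N = 300; the stated
frequency is read as cycles/sample, the convention of unit-sampled AR
simulations.  Stationarity is enforced by checking the spectral radius of
the joint companion matrix before generation, and a 1000-sample burn-in
is discarded.  The replicated study (100 realizations per the study
design, N = 300, lags 0–15, embedding re-selected per direction and lag)
shows: TE_X→Y stable near 0.68 nats for τ = 0–5, a step down when the
delay-5 coupling leaves the candidate span (τ = 6), further decline as
delay 2 and delay 1 leave (τ = 9, 10), and near-zero values beyond;
TE_Y→X flat and far lower at every lag.  The one-way lag ANOVA on
TE_X→Y is the headline quantity recomputed by `scripts/acceptance.py`.

With ρ = 0.95 the oscillator is strongly autocorrelated, so the unique
information of the delay-2 coupling given delay 1 is small; adjacent
mid-range lags (6, 7, 8) therefore differ only marginally and not every
pairwise Bonferroni contrast among lags 6–10 reaches significance in
every run.  The step structure across the designed delay groups is the
robust signature and is what the suite asserts quantitatively.

## Synthetic cardiorespiratory records

No public neonatal recordings accompany the motivating study, so the
package ships a synthetic generator that emulates the signal properties
the preprocessing chain depends on: R-peak times with mean RR 0.45 s
(inside the 0.3–0.667 s acceptance band), beat-to-beat respiratory sinus
arrhythmia (RR_n = mean + gain × respiration at the beat + slow AR(1)
noise), a 200 Hz respiration belt waveform with amplitude drift,
alternating quiet/active sleep bouts with state-dependent breathing rate
(0.75 / 1.0 Hz), a gestational-age-graded RSA gain (LPT < ET < FT), and
injected artifacts (doubled "missed-beat" intervals, short ectopic-like
intervals) whose beat indices are returned as ground truth.  Clean beats
are clamped so that consecutive changes stay below 4.5 %, guaranteeing
that the artifact filter's rejected set equals the injected set exactly —
the round-trip property the tests rely on.  The generator does **not**
emulate real ECG morphology, R-peak detection error, apnea or periodic
breathing, movement artifacts in the belt signal, or non-stationary state
transitions; passing tests demonstrate the correctness of the
preprocessing rules and pipeline plumbing, not clinical validity on real
recordings.

## Preprocessing rules

RR(n) is the interval between R peaks n and n+1.  The respiration
waveform is band-pass filtered 0.05–3.5 Hz (4th-order Butterworth applied
forward-backward, so zero phase) and linearly interpolated at each R-peak
onset, giving RESP(n) on the beat time base (linear interpolation is
adequate because the belt signal is heavily oversampled relative to its
band).  Artifact rules: RR outside 0.3–0.667 s, or changing more than
10 % against the previous *accepted* beat (so one outlier does not
cascade); breathing cycles — successive rising zero crossings of the
filtered waveform — outside 0.5–2.5 s or changing more than 40 % against
the previous accepted cycle, with all beats inside a rejected cycle
rejected.  The cycle reading interprets the second-series thresholds,
which are stated in seconds, as cycle durations; amplitude units could
not satisfy them.  Non-overlapping 300-beat windows are tiled
earliest-first within each sleep-state bout; a window with more than 5 %
rejected samples is discarded whole (no editing or imputation), and each
kept window is z-normalized per channel with the population (divide-by-n)
SD.  Breathing rate is the dominant Welch-spectrum peak in 0.2–2.0 Hz,
requiring at least 60 s of signal and a peak at least five times the
median in-band power.

## Statistical designs

The validation ANOVA is a one-way fixed-effects ANOVA of TE against the
16-level lag factor, with Bonferroni-adjusted pairwise lag contrasts
(pooled-variance t tests; the family is all 120 pairs within one
direction).  The cohort-style model is an OLS ANCOVA of TE on categorical
lag, categorical gestational-age group and their interaction, with sex,
mode of delivery and hours of life as covariates, Type-II sums of
squares, and Bonferroni-adjusted pairwise group contrasts from
covariate-adjusted two-group refits.  Repeated segments per infant are
treated as independent units, mirroring the study design; no clustering
correction is applied, which is a documented limitation.  Sobel mediation
fits M ~ IV, DV ~ IV, DV ~ IV + M by OLS and reports
z = ab / √(b²se_a² + a²se_b²) and the proportion mediated (c − c′)/c.
A synthetic-cohort generator with injectable group shifts (in units of
residual SD) provides the parameter-recovery surface for these designs.

## Problem sizes in the shipped runs

The replicated validation study uses 100 replicates × 16 lags × 2
directions; the type-I calibration uses 200 white-noise pairs with 100
surrogates each (evaluated only where the observed embedding has a
source candidate — a pair without one has TE = 0 and all its surrogate
values are identically zero, so it cannot be significant); the
estimator-oracle checks run at n = 10,000; a handful of unit tests use
scaled-down replicate counts (6–20) of the same constructions.

## Known limitations

- The gate's extreme-quantile moment fit assumes the permutation null is
  well summarized by mean, SD and skewness; calibration was verified
  empirically at N = 300, k = 10, and may drift for very short segments
  or very small k.
- TE magnitudes from k-NN estimates at N = 300 carry finite-sample bias;
  the validation study interprets profiles and contrasts, not absolute
  nats.
- Time-shift surrogates share the candidate span with the embedding, so
  they cannot be combined with per-surrogate re-selection (the shift is
  undone by delay relabeling); the fixed-embedding surrogate distribution
  is the appropriate null but inherits the observed conditioning vector.
- The X→Y lag construction intentionally admits instantaneous and
  anticipatory source terms; users comparing with strictly causal lagged
  TE variants should note the convention.
- Breathing-cycle artifact detection assumes a reasonably sinusoidal belt
  signal; heavily distorted waveforms may produce spurious zero-crossing
  cycles.
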