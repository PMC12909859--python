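# Methods

`dyadsync` reimplements, as a tested pipeline, a dual-EEG analysis of
mother–infant brain-to-brain synchrony across a smartphone-adapted
Still-Face Paradigm (SFP): five contiguous conditions — free play (FP1),
still-face with maternal smartphone absorption (SF1), free play (FP2),
still-face (SF2), reunion (RU) — of 120 s each, recorded at 512 Hz on two
interconnected BioSemi-style systems. Because raw dual-EEG of this kind is
not publicly shareable, the package pairs the analysis chain with a
synthetic dyad generator whose cross-brain coupling is known by
construction, so every stage is verifiable end to end.

## The synchrony estimator

For each 2-s hyper-epoch (a time-locked segment of both members' EEG), each
frequency band b, and each cross-brain channel pair (mother channel j,
infant channel k), the instantaneous phase difference series is

    Δφ_i = φ_j^M(t_i) − φ_k^I(t_i),   i = 1…N,

with phases from the analytic signal (Hilbert transform) of the band-passed
data and N the number of samples in the epoch. The weighted Phase Lag Index
of the epoch is

    wPLI = | (1/N) Σ_i |Im e^{iΔφ_i}| · sign(Im e^{iΔφ_i}) |
           ─────────────────────────────────────────────────
                     (1/N) Σ_i |Im e^{iΔφ_i}|
         = | Σ_i sin Δφ_i | / Σ_i |sin Δφ_i|  ∈ [0, 1].

The numerator inside the absolute value is signed, so the printed ratio
alone would live in [−1, 1]; the outer absolute value restores the
conventional [0, 1] range (1 = one member consistently leads or lags, 0 =
no consistent lead/lag). When every Δφ_i is exactly 0 (mod π) the
denominator vanishes and the estimator returns 0 — zero-lag coupling, the
signature of volume conduction, is invisible by design. The Phase Locking
Value, PLV = |(1/N) Σ e^{iΔφ_i}|, is computed alongside for comparison; it
is sensitive to zero-lag coupling and requires a *stable* offset, not just
a consistent lead/lag direction.

The "N" of the estimator is interpreted as time samples within one epoch
(per-epoch wPLI), with epochs then trial-averaged; a pooled alternative
(all retained samples of a condition in one estimate) can be obtained by
concatenating epochs, but the per-epoch reading is the only one consistent
with validating and excluding individual epochs.

Infant developmental bands are used: theta 3–5 Hz and alpha 6–9 Hz.

## Preprocessing

* Zero-phase (forward–backward) order-4 Butterworth band-pass 1–30 Hz plus
  a zero-phase 50 Hz notch (Q = 30). Zero-phase filtering is essential in
  hyperscanning: any asymmetric group delay would shift one member's phases
  against the other's.
* Bad channels (≤ 10% of a member's montage) are replaced by the mean of
  their immediate montage neighbours; beyond the cap the dyad should be
  excluded. Spherical splines are deliberately out of scope at 12 channels.
* Each condition block is cut into 2-s hyper-epochs with 50% overlap
  (119 per 120-s block); epoch start times are half-open [start, start+2 s)
  from block onset. 2 s keeps ≥ 3 cycles of the lowest frequency (3 Hz).
* Artifact screening is a peak-to-peak amplitude criterion per epoch —
  defaults 100 µV (mother) and 200 µV (infant), an epoch is dropped when
  either member exceeds its threshold on any analysis channel. The source
  study rejected artifacts without stating its criteria; amplitude
  screening is the minimal defensible stand-in, and the generator's
  movement-artifact bursts exercise it the way infant data does.
* Analysis is restricted to 12 channels per person in a fixed canonical
  order: F3, F4, F7, F8, C3, C4, T7, T8, P3, P4, P7, P8.

One numerical point discovered during development: a narrow low-frequency
band-pass (order-4 Butterworth at 3–5 Hz) has an impulse response longer
than a 2-s epoch and cannot settle on an isolated segment — even with
generous reflect padding the mid-epoch phase error reaches ~0.3 rad and the
wPLI of a perfectly coupled pair drops far below 1. The band-pass and
Hilbert transform therefore run once per continuous 2-min condition block
and the phase series is sliced into epochs afterwards. A per-epoch fallback
(with ~3-cycle reflect padding) exists for hand-built epoch sets.

## Surrogate validation

Each observed pair-epoch value is compared with 200 surrogate values in
which the mother's phase series is replaced so that the cross-brain
relation is destroyed while each marginal phase distribution is preserved.
The observed value is retained iff it strictly exceeds at least
⌈0.95 · 200⌉ surrogates (ties count against retention); excluded
pair-epochs do not enter the trial averages. Exclusion granularity is
per pair-epoch by default; a whole-epoch policy (drop the epoch when fewer
than half its pairs validate) is available. Because every epoch carries the
same 144 pairs, the pooled retention fraction, the mean of per-epoch
retention rates and the mean of per-pair retention rates coincide; the
pooled number is reported.

Two shuffling schemes are implemented, and the choice matters more than it
looks:

* `time_shuffle` (default): uniform permutation of the time index of the
  mother's phase series within the epoch — the classic phase-shuffling
  recipe. For band-limited phases this null is **anti-conservative**: the
  permutation whitens a smooth phase trajectory, the surrogate wPLI
  distribution collapses toward zero, and most epochs of band-limited data
  beat it even when the members are independent (~90% measured at
  512 Hz/2-s epochs). On genuinely coupled data it retains nearly
  everything, which is also why the validation step barely moves the trial
  averages. It is exactly calibrated only for serially independent phase
  samples.
* `epoch_shuffle`: the mother's phases are taken from another epoch of the
  same condition (donors > 2 epochs away, clearing the 50% overlap and the
  coherence time of genuine band-limited coupling; donor draws are
  stratified so each donor appears ⌊S/D⌋–⌈S/D⌉ times — plain resampling
  noise in the quantile only ever inflates retention). This preserves the
  phase autocorrelation and is calibrated: measured null retention is
  5.5–6% against the exchangeable expectation of 11/201 ≈ 5.5% at the 5%
  level. Use it whenever calibration is the point.

The trade-off is intrinsic: with 2-s epochs a band-limited phase series has
only ~2·bandwidth·T ≈ 8 effective samples, so a *calibrated* test has
essentially no power against weak coupling at the single pair-epoch level —
it retains only the upper tail and would bias trial averages upward. The
anti-conservative time-shuffle null, by contrast, certifies nearly all
epochs (reproducing the ">95% retained" behaviour reported for this kind of
data) and leaves averages essentially unbiased. The default follows the
field's procedure; the calibrated method exists for null-calibration work,
and both are exercised by the tests.

PLV systematically under-validates relative to wPLI when the cross-brain
lead-lag offset wanders within an epoch without reversing direction: wPLI
only needs the sign of sin Δφ to be consistent, PLV needs the offset itself
to be stable. The generator can produce this regime (`lag_wobble_amp`), and
the validation comparison then excludes ~3–9× more epochs under PLV than
under wPLI — the mechanism offered here for the empirical observation that
PLV fails surrogate validation on most real epochs while wPLI passes.

## Aggregation and statistics

Retained pair-epoch values are averaged per (dyad, condition, band) into a
12×12 trial-averaged matrix; its grand mean is the scalar **global wPLI** —
one value per dyad × 5 conditions × 2 bands.

The inferential chain mirrors standard nonparametric repeated-measures
practice:

1. outlier screening per condition column (|value − mean| > 3 SD;
   configurable, `none` to disable). Removal makes that dyad's band row
   incomplete: Friedman then drops the dyad listwise (or imputes the
   column mean, `missing="impute"`), the pairwise tests drop it only for
   affected pairs.
2. exploratory covariate screens: Welch two-sample t between mother–son and
   mother–daughter dyads (unequal variances, Welch–Satterthwaite df) and
   Pearson correlation with infant age, per (band, condition).
3. Friedman χ² over the five conditions per band (df = 4). A rank test
   admits no covariates; covariate influence is addressed by the screens
   above and the parametric sensitivity check below.
4. pairwise Wilcoxon signed-rank tests over all 10 condition pairs,
   two-sided, Benjamini–Hochberg FDR within the 10-test family per band.
   W is the smaller signed-rank sum. Small samples (n ≤ 14 nonzero
   differences) use full enumeration of the signed-rank distribution
   (exact even with tied ranks); n ≤ 25 without ties uses the standard
   exact distribution; otherwise the normal approximation with continuity
   correction. The convention is recorded on each result row.
5. a thin repeated-measures ANCOVA sensitivity wrapper: OLS on the long
   table with dyad fixed effects, the condition factor and condition×age,
   condition×sex interactions; the reported F is the within-subject
   condition effect with the classic RM-ANCOVA error structure.

### Topography

Electrodes are grouped into five regions per head — frontal {F7, F8},
central-parietal {C3, C4}, occipital {P7, P8}, left temporal {T7}, right
temporal {T8}; F3, F4, P3, P4 are unassigned by default, following the
five-region scheme this analysis replicates (the map is configurable). Per
dyad, pair matrices are averaged over the combined still-face conditions
(SF1, SF2) and over the combined FP1, FP2, RU conditions — unweighted over
condition means first, then over electrode pairs — and each of the 5×5
inter-brain region pairs is tested with a one-sided paired t-test
(SF < FP/RU). The 25 tests × 2 bands form one 50-test BH-FDR family by
default (`per_band` optional). All-zero differences give t = 0, one-sided
p = 0.5; zero-variance nonzero differences are reported as degenerate with
p of 0 or 1 by sign.

## The synthetic dyad generator

Each member's background EEG is independent 1/f^α noise (α = 1 by default,
periodogram slope verified within ±0.3), scaled to 8 µV RMS (mother) and
15 µV RMS (infant). Within each condition block and band, a shared
narrow-band oscillator — the analytic signal of band-passed white noise —
is mixed into the designated channels of both members:

    x = √(1 − Σ_b κ_b²) · noise + Σ_b κ_b · g · ρ_b · A · Re(z_b e^{iδ})   (mother)
    y = √(1 − Σ_b κ_b²) · noise + Σ_b κ_b · g · ρ_b · A · Re(z_b)          (infant)

with κ the coupling strength in [0, 1], g = 1.5 the oscillator gain, ρ_b
the in-band RMS fraction of the 1/f background (computed from the
generator's own discrete spectrum), A the member's amplitude scale, and δ
the cross-brain phase offset (π/4 by default; δ ≡ 0 mod π is rejected
whenever κ > 0 because zero-lag coupling is invisible to wPLI). κ = 1
yields a pure oscillator and per-epoch wPLI = 1. Optional offset dynamics:
a Brownian drift (`lag_drift`) and a bounded sinusoidal wobble
(`lag_wobble_amp`, `lag_wobble_hz`) for the PLV comparison regime.

Defaults mirror the study conditions: 33 dyads, 512 Hz, 12 channels per
person, five 120-s blocks, infant age ~ N(9.29, 1.38²) months clipped to
the observed 5.7–12.2 range, sex ratio 18F:15M. Coupling baselines were
calibrated once, during generator design, so that the simulated global wPLI
magnitudes land where the study reports them (theta ≈ 0.41, alpha ≈ 0.36 at
2-s epochs; the baseline sits close to the estimator's small-sample floor,
which is exactly where the empirical values live): κ = 0.30 in both bands
during FP/RU, dropping by 0.15 to κ = 0.15 during SF1 and SF2 — the
built-in still-face effect. A per-dyad, per-band κ offset ~ N(0, 0.05),
constant across conditions, emulates between-dyad heterogeneity (and
matches the reported between-dyad SDs of 0.02–0.03). Movement artifacts are
Hann-windowed 1–3 Hz bursts of 400 µV on the infant's channels at
2 bursts/min.

What the generator does **not** emulate: volume conduction within a head,
realistic cross-channel covariance, non-stationary background spectra,
stereotyped ocular/cardiac artifacts, or behaviour-locked coupling
dynamics. Passing recovery tests therefore shows the *pipeline* recovers
known coupling structure under realistic noise and amplitudes — not that
the biological effect itself is re-demonstrated.

## Verification, problem sizes, determinism

Every stage is tested against independent oracles: the vectorized wPLI/PLV
kernels against naive per-sample loops (≤ 1e−12 on random series), Friedman
against hand rank sums, Wilcoxon against full sign-pattern enumeration,
BH-FDR against a brute-force step-up on random p-vectors, Welch's df
against the closed form, the paired t against its closed form.

Simulation-based checks run at reduced problem sizes chosen to keep the
whole suite in minutes on one CPU while preserving the quantities under
test: surrogate calibration at 256 Hz on a 60-s block (8 496 pair-epochs,
200 surrogates); coupling monotonicity on 180-s single-condition runs at
128 Hz (Spearman ρ = 1.0 over the κ grid, 10 seeds); still-face recovery on
33-dyad cohorts with 12-s blocks at 128 Hz, 50 effect repeats and 50 null
repeats (effect recovered — Friedman and the SF1<FP1, SF<RU post hocs at
FDR < .05 — in ≥ 90% of repeats; null cohorts reject within binomial bounds
of the 5% level). Epoch counts scale with block length (11 per 12-s block
vs 119 per 120-s block); per-epoch estimator behaviour is unchanged because
epoch length, bands and overlap stay at their defaults.

All randomness flows from explicit seeds: the generator uses
`seed + dyad_index`, the connectivity stage `seed + 100000 + dyad_index`
(recorded in the run manifest), and pipeline runs are byte-identical under
a fixed seed.

## Known limitations

* The surrogate-validation dilemma described above is a property of the
  method, not of this implementation: per-pair-epoch validation of weak
  band-limited coupling cannot be simultaneously calibrated and
  high-retention.
* Neighbour-mean interpolation is crude below ~32 channels and is capped at
  10% of the montage for a reason.
* The RM-ANCOVA wrapper assumes sphericity (no Greenhouse–Geisser
  correction); it is a sensitivity check, not the primary inference.
* EDF output quantizes to 16 bits over the recording's amplitude range;
  round trips are exact only to that resolution.
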