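# Methods

This note documents the models, parameter choices and numerical conventions
behind `bciloop`, and what the synthetic benchmark does and does not say
about real EEG.

## Synthetic EEG model

Each channel carries three independent Gaussian components, all produced by
causal streaming filters so that the same generator serves offline runs and
the sample-by-sample closed-loop race driver:

1. **Background**: white noise shaped by a 257-tap FIR filter whose squared
   magnitude follows 1/f^γ above 1 Hz (γ = 1 by default), scaled to a
   12 µV RMS. A 2 µV RMS white floor is added. The FIR realization was
   chosen over exact frequency-domain synthesis because it streams causally
   with persistent filter state; its response is known exactly on the
   analysis grid, which the calibration below exploits.
2. **SMR component** (effect channels only; default C3, Cz, C4 — the hand
   and foot motor representations): white noise through an order-4
   Butterworth band-pass over the effect band (default β, 22–32 Hz), with
   input variance depending on the mental class. Both-feet imagery gets the
   larger β variance (an ERS at the effect channels), both-hands the
   smaller, rest the geometric middle. This realizes class-dependent *band
   power*, matching the band-power feature assumption, rather than adding
   deterministic sinusoids.
3. **EOG**: 3 µV RMS low-passed noise on four sensors; artifacts (blink,
   horizontal saccade, muscle burst) are parametric templates injected on
   demand — Hann bumps of 0.3–0.4 s for the ocular events (energy
   concentrated below ~10 Hz by construction) and a 0.5 s broadband noise
   burst for muscle. Only their detectability matters; no attempt is made
   at realistic EMG spectra.

### Effect-size calibration

`effect_size` is the target Fisher score FS = |μ₁−μ₂|/√(s₁²+s₂²) of the
log band-power feature at an effect channel, averaged over the 2 Hz bins
inside the effect band. For a class power ratio r per bin, the log-feature
mean shift is ln r and the within-class spread of ln(bin power) is an
approximately constant σ_ln set by the Welch estimator's degrees of
freedom, so FS ≈ ln r / (√2·σ_ln) per bin. The per-bin expected powers of
all three components are computed from the actual filter responses, and the
symmetric log-variance offset δ (feet = v·e^δ, hands = v·e^−δ) is solved
numerically (Brent) so the band-averaged predicted FS equals the request.
σ_ln = 0.636 was measured once by Monte Carlo on the generator at null
effect with the standard windowing (1 s windows, 0.5 s Hann sub-segments at
50% overlap) and is frozen in `synth.LOG_BINPOWER_STD`. Measured scores
land within ~5% of the request at 300 s per class; the documented tolerance
is ±20%, dominated at small samples by the positive finite-sample bias of
FS under heavily overlapping windows (~0.1 at 300 s/class, the null floor).

The rest-state SMR power equals the background band power by default
(`smr_rest_ratio = 1`), putting intentional non-control genuinely between
the two active classes.

Amplitudes are conventional (tens of µV): no raw-amplitude statistics were
available to match, and all downstream quantities are scale-invariant.

### Seeds

All randomness flows from `numpy.random.SeedSequence`. A campaign derives
per-run seeds as `SeedSequence([master, index])`, so runs are independent
and reproducible; a run splits its seed into EEG and EOG streams. Identical
configuration ⇒ bit-identical recordings.

## Feature pipeline

- **Laplacian**: out[c] = in[c] − mean(neighbors), with orthogonal nearest
  neighbors on the FC/C/CP × {3,1,z,2,4} grid (e.g. Cz ↔ {FCz, CPz, C1,
  C2}); the exact neighbor weighting of the original montage is not
  published, so the map is an editable argument. Channels without
  neighbors (the 16th channel, Fz) pass through.
- **Welch band power**: 2 Hz resolution from 0.5 s periodic-Hann
  sub-segments at 50% overlap averaged within each 1 s window, windows
  sliding every 62.5 ms; verified bin-for-bin against `scipy.signal.welch`.
  A band labeled f Hz is the bin centered at f; a region [lo, hi] includes
  centers lo..hi inclusively, so β 22–32 Hz has six bins and the medial β
  region 3 × 6 = 18 cells. Features are log₁₀ power by default (standard
  for SMR work and friendlier to the Gaussian classifier; raw power is a
  flag). Window counts follow ⌊(T−1)/0.0625⌋+1 exactly.
- **Fisher score**: sample (n−1) variances throughout. Degenerate inputs:
  zero spread with equal means → 0; with distinct means → +inf with a
  warning.
- **CVA ranking**: for two classes the canonical direction reduces to the
  Fisher discriminant w = Sw⁻¹Δμ; Sw is shrunk toward its scaled identity
  ((1−λ)Sw + λ(tr Sw/d)I, λ = 0.05, automatically increased on
  ill-conditioned inputs and flagged). Per-feature discriminant power is
  |wᵢ|·√(Sw)ᵢᵢ, which matches the per-feature Fisher ordering when features
  are uncorrelated; ties break toward the lower feature index.

## Decoder

One diagonal Gaussian per class over the selected features, uniform priors,
closed-form fit; an optional full-batch gradient-descent refinement of the
cross-entropy is provided but off by default because the closed form is
reproducible and sufficient on this data. Evidence accumulation per 62.5 ms
step: reject if max p < ρ, else I′ = αI + (1−α)p; emit class c when
I′_c ≥ θ_c outside refractory and artifact gates, then reset I to uniform.
From uniform with constant accepted p = (1,0), Iₙ = 1 − ½αⁿ, so α = 0.96
and θ = 0.9 decide exactly at step 40 (2.5 s) — the analytic oracle used in
tests. Module defaults are α = 0.96, ρ = 0.55, θ = 0.9.

During refractory the evidence keeps integrating but emission is
suppressed, and I is reset again when the refractory elapses, so each
command starts an unbiased trial; a freeze-state variant is available as a
flag. Simultaneous threshold crossings resolve to the larger integrated
probability, ties by class order. Rejected samples freeze the state rather
than leaking it toward uniform — the text describing the scheme does not
exclude either reading, and freezing keeps rejection and integration
orthogonal.

### Campaign operating point

The accumulation parameters are explicitly operating-point choices that
were tuned per pilot in the original system. The campaign pipeline runs a
stricter rejection ρ = 0.8 with a faster integrator α = 0.9 (θ = 0.9,
refractory 1 s): at synthetic effect sizes the accepted-posterior mean
under the permissive defaults sits below θ, so no commands would ever be
emitted; with strict rejection, only confident samples integrate, giving
seconds-scale decisions during imagery while rest mostly rejects —
intentional non-control emerges from the statistics rather than a rest
class. The pipeline also selects 12 features (top CVA ranks) and uses a 3 s
paradigm-4 pair window, compatible with the ≥1 s refractory between the
two constituent commands.

## Artifact gating

EOG_h = EOG1 − EOG3, EOG_v = EOG2 − (EOG1+EOG3)/2, and the sensor average
(taken over the three active sensors; the fourth is the recording
reference) are band-passed 1–10 Hz with a causal order-2 Butterworth from
zero initial state — online operation forbids zero-phase filtering, so a
brief settling transient at stream start is expected and the frame tests
tolerate one frame of edge effect. A 62.5 ms frame decides 1 if any
rectified sample on any monitored channel exceeds the common threshold
(default 25 µV — the original threshold is configurable and unpublished).
Onsets fire on 0→1 frame transitions; the gate lifts a configurable
timeout (default 1 s) after the latest onset, later onsets extending the
block, so gated intervals are merged half-open [onset, offset) windows
during which the decoder may not emit.

## Control paradigms

1. three imagery classes mapped directly to spin/jump/slide;
2. two classes to spin/jump, slide unsupported;
3. two classes to spin/jump, slide after a configurable idle period —
   the idle timer re-arms after every decision *and* every emitted slide
   (otherwise a long idle could slide only once, which cannot serve yellow
   pads at arbitrary positions);
4. two classes to spin/jump, slide when two consecutive commands of
   different types arrive within the pair window — the constituent
   commands are forwarded as they occur and the slide is emitted at the
   second command's time (the game's overriding rule makes the final state
   "slide"); the pair window resets once consumed. Whether the original
   implementation withheld the constituents until the window elapsed is
   not documented; forwarding matches the description of commands being
   sent as produced.

Idle windows for INC metrics are half-open [t, t+Δ); boundary decisions
belong to the later window.

## Race mechanics

Mechanics are parameterized directly in time-to-cross per regime (boost /
base / penalty) rather than virtual meters and speeds: the printed
crossing-time bounds then hold exactly and simultaneously for every pad
type, which no single global "slow speed" could achieve. Progress through a
pad accrues at 1/t_regime fractions per second; a correct command boosts
until the pad ends or a wrong command overrides; any wrong command (or any
command on a white pad) starts a 4 s penalty whose timer resets on further
errors and which ends at expiry (resuming base), at an overriding correct
command, or at the next pad entry; regimes always reset to base at pad
boundaries. Closed forms for single-switch crossings (t = s + (1−s/t_A)·t_B
etc.) serve as randomized oracles. The 240 s competition cap is recorded as
a validity flag, never a clamp. Command latency is zero: bounds are defined
by idealized delivery. The track's "500 virtual meters" is cosmetic and not
modeled.

## Evaluation

Per-command accuracy is the percentage of pads of that color on which the
matching command was delivered while on the pad — delivery, not net speed,
so a wrong-then-right pad still counts. Overall accuracy is the arithmetic
mean of exactly the three per-command rates; the white-pad true-negative
rate (crossing without any command) is reported separately and never folds
into the overall mean. All six white-type pads (four middle whites plus
start and end) enter the TNR. Under paradigm 4, the synthesized slide is
the delivered command on yellow pads; its constituent spin/jump still incur
their in-game penalties but are not double-counted as accuracy errors.

Trends are Pearson correlations with two-sided p from the exact t
transform (n−2 df). First-versus-last-k-session contrasts (k = 4) pool runs
per session and use the two-sided Wilcoxon rank-sum test — exact null
distribution for tie-free pooled samples up to 25, otherwise the normal
approximation with midrank tie correction. The campaign summary
discriminancy `disc_smr_beta` averages the medial and lateral β aggregates.

## Campaign pipeline and problem sizes

Each campaign run: a 80 s offline recording (ten 4 s trials per class,
alternating), feature extraction, per-run classifier retraining (the
original system recalibrated rarely, but per-run retraining keeps synthetic
runs self-contained and is itself a defensible calibration policy), a
region discriminancy snapshot, then one closed-loop race on a fresh random
track. The simulated pilot performs the imagery matching the current pad,
rests on whites and after a successful boost, and alternates the two
classes on yellow pads under paradigm 4. The default campaign is 20 runs
with effect sizes ramping 0.1 → 0.6, two runs per session; these sizes keep
a full campaign under ~30 s on one core while leaving the trend statistics
well-powered. Races are hard-capped at 340 s of simulated time (above the
327 s physical bound) before coasting to the finish.

## What the synthetic benchmark shows — and does not

Passing tests demonstrate that the decoding chain, accumulation policy,
gating, paradigms, race mechanics and statistics behave exactly as
specified, and that the end-to-end system converts a programmed increase in
SMR separability into the expected learning signature (rising discriminancy
and accuracy, falling race times, negative discriminancy–race-time
coupling). They do not certify performance on real EEG: the generator's
components are Gaussian and stationary within a trial, artifacts are
stylized, there is no non-stationarity across a session, no μ-band
modulation, no cross-channel source mixing beyond the Laplacian's reach,
and the two pilots' published numbers (their race times, accuracies and
correlation coefficients) reflect human learning and are out of scope.
Known further limitations: the closed-loop driver supports the two-class
paradigms only, and CVA beyond two classes is not implemented.
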