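# Methods

This note documents the models, conventions and numerical choices behind the
package, in the order data flows through the pipeline.

## Level conventions and acoustic geometry

All levels are decibels re an arbitrary digital reference: a waveform of RMS
amplitude 1.0 is defined to be 60 dB. No microphone calibration is modelled,
and none is needed — every analysis in the pipeline (SNR, effective
amplitude, IVAD, threshold contrasts) consumes only dB *differences*, which
are invariant to the reference. Pulsed signals are calibrated by **peak RMS**
(the maximum 5 ms sliding RMS over the pulse plateau), continuous maskers by
**long-term RMS** over the whole burst, mirroring how tone pips and noise are
calibrated in practice.

The geometry helpers use a speed of sound of 344 m/s (air, ~21 °C). For the
fly's 500 µm ear separation this gives a best-case acoustic ITD of
500 µm / 344 m s⁻¹ = 1.45 µs, and a 5 kHz carrier has a wavelength of
6.88 cm — both orders of magnitude away from what classical binaural cues
would require, which is the premise for the mechanically coupled ear model.

## Stimuli

The target signal emulates a synthetic field-cricket trill: a 5 kHz tone
gated into 10 ms pulses with 1 ms linear on/off ramps, repeated at
50 pulses/s (50% duty cycle); a 40 ms variant carries exactly two pulses.
Ramp shape is linear (only the 1 ms duration is physiologically
constrained). Maskers are stationary Gaussian noise band-limited to
2–7 kHz by spectral shaping: white noise is transformed with an rFFT,
out-of-band bins are zeroed with 200 Hz raised-cosine transitions, and the
result is inverse-transformed. This construction guarantees ≥ 40 dB
out-of-band rejection for every seed (property-tested over random seeds) and
makes "coherent" maskers trivially exact: two sources sharing a noise seed
share a waveform sample-for-sample. The amplitude distribution of the
masker is Gaussian; the band edges were chosen at the nominal 2 and 7 kHz.

Scene timing follows the standard trial: 5 s acquisition, masker (4 s) onset
at 0.5 s, signal (2 s trill) onset at 1.5 s, so the signal is embedded
symmetrically — it begins 1 s after masker onset and ends 1 s before masker
offset. Default sample rate is 44100 Hz, matching common DAQ hardware.

## Generative ear model

The mechanically coupled ears are modelled *phenomenologically* at the level
the downstream analyses need: a directionality curve mapping source azimuth
θ to the interaural vibration amplitude difference,

IVAD(θ) = IVAD_max · (2 / (1 + e^(−θ/σ)) − 1) = IVAD_max · tanh(θ / 2σ),

antisymmetric, monotone, saturating at ±IVAD_max. Defaults IVAD_max = 10 dB,
σ = 30° give ~9.05 dB at ±90°, in the range reported for tympanal
directionality in this species; the true curve was never published
numerically, so the parametric sigmoid is a stand-in and an azimuth↔IVAD
table can be imported in its place. Only the interaural *difference* is
physiologically constrained; the per-ear split is the symmetric choice
G_R = +IVAD/2, G_L = −IVAD/2 dB, which is invisible to every analysis
(all use differences). Mechanical ITDs and frequency-dependent
directionality are deliberately not modelled: the direction-prediction
analysis this package implements uses amplitude differences only.

Each ear's trace is the gain-weighted sum of all source waveforms plus an
independent Gaussian measurement-noise floor, default 36 dB (40 dB below the
standard 76 dB stimulus) — a laser-vibrometry-like instrument floor that also
serves as the "quiet" reference for effective-amplitude measurements in
masker-free scenes.

### Afferent model

Auditory afferents are onset-phasic: Type I marks each suprathreshold
envelope onset with one spike, Type II with a short burst, both followed by
a ~4 ms refractory dead time. The envelope is full-wave rectification
followed by a 1 ms sliding RMS. Detection is *adaptive*: the threshold at
time t is the larger of a static floor (3× the quiet-epoch envelope RMS, the
same 3σ rule used for impulse detection in recordings) and 1.8× a trailing
200 ms average of the envelope (lagged 10 ms so a pulse does not raise its
own floor). The ratio 1.8 was chosen so that sustained masker noise elicits
only occasional spikes (~2 s⁻¹ from envelope fluctuations, matching the
qualitative physiology of phasic units in noise) while a pulse ≥ 3.5 dB
above the running floor triggers reliably. This single knob reproduces the
masking logic: a louder floor in the masker-ipsilateral ear silences pulse
onsets there first, producing the better-ear (masker-contralateral)
advantage. Type III (tonic) afferents are not simulated.

## Vibrometry analysis

Sliding RMS uses a centred window with shrink-to-valid edges (constants map
to constants; no zero-padding bias). The **effective amplitude** of an ear is
20·log₁₀(RMS_signal-window / RMS_floor-window) per signal repetition,
averaged arithmetically in dB across repetitions. Window schedules:

* repeated-pulse protocol (vibrometry, 400 ms period): 30 ms windows at each
  pulse onset, floor windows 200 ms later in the inter-pulse interval;
* continuous 2 s trill: pulse-length (10 ms) windows at each pulse onset,
  skipping the first and last 100 ms of the trill, with floor windows tiling
  the 1 s masker-alone epoch immediately before signal onset back-to-back
  (using the full epoch minimizes the variance of the floor estimate, which
  otherwise dominates the IVAD error near curve saturation).

The effective IVAD is the contralateral-minus-ipsilateral effective
amplitude (equivalently right-minus-left in the signed frame). The
IVAD-vs-azimuth calibration is fitted with a 4-parameter logistic
y = y₀ + a/(1 + e^(−(x−x₀)/s)) by derivative-free Nelder–Mead least squares:
≥ 5 starts (both orientations, additive scale-aware perturbations — a
multiplicative jitter would freeze a coordinate whose start is zero, such as
a centred inflection), one restart from each incumbent to re-inflate
collapsed simplices, RSS tolerance 1e−8, best-RSS winner. Predicted incident
direction is the numerical inverse of the fitted curve by bisection;
measurements beyond the fitted range clamp to the endpoints with a warning.
Measurements average three sweeps per condition, matching the vibrometry
protocol of three sweeps per SNR; with the defaults this recovers source
azimuths in {−90…+90}° to within 3° in ≥ 90% of seeded runs, the hard cases
being ±90° where the sigmoid saturates and dθ/dIVAD ≈ 33°/dB amplifies
floor-estimate noise.

## Signal detection (nerve) analysis

Impulse detection on voltage traces thresholds at RMS + 3·SD of a ≥ 100 ms
unstimulated epoch with a 1 ms dead time. Per-sweep responses are impulse
counts in a fixed 40 ms window (window RMS is available as an alternative
measure; both are tested). Detectability is the standard separation

d_a = (μ_{n+s} − μ_n) / √((σ²_{n+s} + σ²_n)/2),

the pooled (sum) form, which is defined for equal variances and consistent
with d_a's purpose of tolerating *unequal* ones. A variance-difference form
(√((σ²_{n+s} − σ²_n)/2)) is retained behind `form="printed"`; it returns NaN
with a flag when its radicand is non-positive. Masked threshold is the level
at which a monotone logistic fitted to (level, d_a) crosses d_a = 1.0, found
by bisection on the fitted curve; the swept level axis is parameterized
(signal level swept ⇒ rising curve, masker level swept ⇒ falling curve), and
the simulated nerve experiment sweeps masker level over a range wide enough
(±18 dB SNR) that both ears' crossings fall inside it. Fully separated
constant count distributions (infinite d_a) are capped at ±10 for fitting.
With the default ear model the masker-contralateral ear's threshold exceeds
the ipsilateral ear's by ~6–9 dB of masker level — the better-ear effect in
sign and order of magnitude; the absolute values depend on afferent
parameters that are not published, and are reported as what the configured
model yields.

## Kinematics

Velocities are v = pixel-increment × calibration × f_s with steering from x
(right-positive) and forward from y; display smoothing is a centred 50 ms
moving average, but **latency detection runs on the unsmoothed velocity**
(a centred window would shift the detected onset half a window early).
Response onset is the first post-stimulus sample where forward velocity
exceeds 3× its pre-stimulus SD (with a 0.05 cm/s absolute floor for
perfectly quiescent baselines) sustained for ≥ 20 ms; this criterion is the
package's construction and recovers injected latencies within ±5 ms.
Trajectories are cumulative sums of calibrated increments; total distance is
the sum of per-sample step lengths; a trial is a valid response when total
translation exceeds 1 cm. Angular heading is atan2(net_x, net_y) of the
displacement from response onset to either the temporal midpoint between
response onset and signal offset (**mid-response heading**, the default) or
the end of the trial (`heading_mode="whole"`). Trials recorded under
mirror-image speaker layouts are pooled by negating left-masker headings;
per-fly means are taken before cross-fly statistics. Defaults: 2160 Hz,
0.0028 cm/px calibration (supplied constant; video calibration is out of
scope).

## Staircase

Descending staircase from 76 dB in 3 dB steps to the first non-response,
then a single probe half a step (1.5 dB) above it. The probe defines one
bound; the other is the nearest bracketing tested level (last response /
first non-response) — the only assignment that guarantees LB < UB from
observed trials. Threshold = 10·log₁₀((10^{UB/10} + 10^{LB/10})/2), a
power-domain average that always lies in (LB, UB) and at or above the dB
midpoint (Jensen). No re-testing after the probe. For a deterministic
observer the estimate brackets the true threshold within one step; for a
logistic observer steep relative to the step, the mean estimate over seeded
runs is within one step of the 50% point.

## Circular statistics

* **Watson U²** (two-sample) on pooled circular ranks, ties by mid-ranks.
  Asymptotic p from the limiting Watson distribution, computed by the
  alternating exponential series for U² ≥ 0.12 and the Jacobi-theta
  transformed series below (the alternating form diverges at small U²);
  both agree to < 1e−3 at the crossover. The asymptotic tail (p ≲ 0.25) is
  accurate down to n = 6+6; mid-range p at such small N is coarse, so an
  exact/Monte-Carlo permutation option is provided and recommended there.
* **Watson–Williams F** with the standard correction 1 + 3/(8κ̂), κ̂ from the
  Best–Fisher approximation. A high-concentration test by construction: it
  warns (and still returns) when the weighted mean resultant length falls
  below 0.7. Under a concentrated von Mises null it holds the 5% level;
  under uniform data it does not (no correct implementation would), which is
  what the warning is for.
* **Hotelling pair-sample**: per-subject difference of unit vectors,
  Hotelling T² of the bivariate mean against zero,
  F = (n−2)/(2(n−1))·T² on (2, n−2) df. Singular covariance (zero
  within-sample spread) short-circuits to p = 1 (zero mean) or p = 0
  (nonzero mean).
* **Harrison–Kanji two-factor ANOVA**: squared-resultant decomposition into
  main effects, interaction and residual. For κ̂ > 2, F-ratios on
  (df_effect, n − pq) df. For lower concentration, a chi-square
  approximation with inflation factor 2/(1 − ρ²), ρ = I₁(κ̂)/I₀(κ̂), on
  **2×df** degrees of freedom — both components of each mean vector
  fluctuate, and with doubled df the branch is calibrated (measured type-I
  0.046–0.061) from κ ≈ 1 down to the uniform limit, where it reduces to the
  classical Rayleigh-type decomposition; with single df it over-rejects
  (0.13–0.22). Repeated measures are treated as independent groups.
* Descriptives: circular mean/resultant; circular SEM as
  1/√(n·R̄·κ̂) radians (the large-κ standard error of a von Mises mean
  direction) — the convention used for "mean ± SEM" of headings.

## Simulated experiments

The experiment layer wires everything together with study-scale defaults:
13 simulated flies, 3 repeats per condition, separations {6°, 90°}, SNRs
{−6, 0, +6} dB, masker 76 dB. A behavioural trial renders the scene,
measures the effective IVAD, inverts the directionality curve into a
commanded heading (toward the ear with the larger effective amplitude), adds
von Mises-like heading noise (SD 5°, the scale of reported heading SEMs),
synthesizes a treadmill walk (latency ~56 ± 8 ms, forward speed rising
~2.3 → 4.7 cm/s over −6 → +6 dB SNR) and re-analyzes it with the kinematics
chain — so every reported heading has passed through the full
measurement path. The staircase experiment uses a closed-form observer
derived from the same ear model (better-ear effective amplitude against a
criterion of 3 dB softened by a 0.5 dB logistic); with the default
directional masker gains this observer *does* show a better-ear release for
the 90° separation — the pipeline reports whatever the configured model
yields and makes no claim that the simulation must reproduce an empirical
null that depends on unpublished physiology.

Problem sizes in the test suite and acceptance script are desk-scale
choices: 20 seeded runs per angle for direction recovery, 27 trials per
symmetry condition, 20 sweeps per nerve level, 2000 simulations per type-I
calibration.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the real measurements — pulse
timing, band-limited masking, direction-dependent per-ear gains, phasic
spiking, treadmill streams — with Gaussian noise everywhere and a
hand-chosen directionality curve. Passing tests therefore demonstrate that
the analysis chain is correct and self-consistent (round-trip parameter
recovery, calibrated test sizes, correct orderings), not that the simulation
reproduces the animal's published numbers: empirical thresholds, headings
and IVADs depend on tympanal and afferent parameters that were never
published numerically and are exposed here as configuration. Known
limitations: no mechanical ITDs or frequency-dependent directionality, no
coupled-oscillator biophysics of the intertympanal bridge, no free-field
acoustics (speaker transfer functions, echoes), no closed-loop treadmill
physics, and afferent adaptation reduced to a single trailing-baseline rule.
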