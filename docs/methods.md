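# Methods

voltscope re-implements, as one tested pipeline, the analysis stack used to
characterise a positive-going genetically encoded voltage indicator (GEVI):
from raw fluorescence movies and photon-count traces to spike detection,
ground-truth evaluation against electrophysiology, screening metrics,
biophysical fits, functional tuning, multimodal phase analysis, and spatial
rate maps. Because public datasets for this kind of experiment are scarce,
the package ships a first-class synthetic-data module whose ground truth
makes every downstream stage verifiable.

## Forward model of the indicator

The generator composes four physical stages.

**Steady state.** ΔF/F at holding potential `v` follows a logistic sigmoid

    dff(v) = L / (1 + exp(-k (v - x0))) + b

with the default parameters `L = 7.063`, `k = 0.02023` /mV, `x0 = -10` mV,
and `b` chosen so that `dff(-70 mV) = 0`. These were obtained once by least
squares so the anchored curve passes through the indicator's measured
steady-state responses from a −70 mV rest: ΔF/F = 0.874 at −40 mV and 2.27
at 0 mV. They are a test fixture that reproduces the measured response
range, not a re-measurement of the protein.

**Kinetics.** The fluorescence state relaxes toward the instantaneous
sigmoid target with direction-dependent time constants: a single 2.8-ms
on-component (depolarising) and two off-components of 2.4 and 9.1 ms with
equal weights. On/off component lists are zipped into independent kinetic
tracks (singleton lists broadcast); each track applies the *exact*
exponential update per simulation step, `F <- s + (F - s) exp(-dt/tau)`,
rather than forward Euler, so the one-component limit equals the analytic
RC charge/discharge to 1e-6 and tests can assert against the closed form.
No mixing rule between multi-component on and off lists of different
lengths exists in the literature for arbitrary waveforms; such models are
rejected rather than silently averaged.

**Photon emission.** Per-frame counts are Poisson with mean
`flux · dt · (1 + ΔF/F) · bleach(t)`, where `bleach` is an optional
multi-exponential decay. Frame edges are computed in fractional sample
units so a non-integer ratio between simulation rate and frame rate (e.g.
10 kHz → 7142.9 Hz) introduces no cumulative timing drift — an earlier
integer-binned version drifted several milliseconds per minute, enough to
break frame-window spike matching.

**Scenes and populations.** Movies are rendered from disk-shaped cells with
per-pixel Poisson noise, a uniform neuropil background, and an injected
per-frame rigid shift table recorded in the ground truth. Population
generators emulate three acquisition designs: orientation-tuned responses
to interleaved drifting gratings (0.5-s blank + 0.5-s motion, von Mises
tuning on orientation), a slow 0.1–1 Hz neuromodulator oscillation whose
phase gates 2–10 Hz voltage-band amplitude with an injected lag, and
open-field foraging (80 × 80 cm, correlated random walk with reflective
walls) driving a wall- or centre-tuned inhomogeneous-Poisson spike train.

**Voltage protocols.** `steps` reproduces the clamp protocol (1-s steps at
90…−120 mV from a −70 mV hold); `spike_train` injects AP waveforms of
100 mV amplitude and 2 ms FWHM (Gaussian shape); `burst_on_up_state` rides
spikes on a ~24 mV sustained depolarisation; `spontaneous` combines
Poisson spikes (hard 10-ms refractory, via thinning) with
Ornstein–Uhlenbeck subthreshold noise (tau = 50 ms, sigma configurable).
The OU parameters are placeholders: in-vivo subthreshold spectral content
is not specified by any measurement we reproduce, and tests treat them as
free conditions, not claims.

## Preprocessing

Background is the integer-binned histogram mode of the first frame
(Freedman–Diaconis bins for non-integer data), excluding pixels that
saturate anywhere in the movie. Motion correction is rigid and two-step:
integer shifts against the global mean template by FFT phase correlation
(template re-averaged and re-estimated up to three passes, because
uncorrected motion blurs the first template), then subpixel refinement
against a local rolling-window template. Shifts are reported relative to
the first frame, since a template defines them only up to a constant.
Recordings whose mean shift exceeds 10 μm are flagged for exclusion.

Pixel selection ranks foreground pixels by Pearson correlation with the
mask-mean template and keeps the rank prefix whose summed trace maximises
the screening SNR, defined here as (peak − baseline mean)/baseline SD with
the first 100 ms as baseline; the source protocol does not define this SNR,
so the definition is a package choice, and ties resolve to the largest
prefix (extra pixels that do not hurt SNR contribute photons). FOVs with
fewer than 300 selected pixels are rejected.

Photobleach fitting tries 1–3 exponential components plus an offset and
selects the order by goodness of fit (R², RMSE, MAE) subject to the
local-minimum rule on both BIC and AIC (an order qualifies when its
criterion is below both neighbours, single neighbour at the ends);
correction divides by the fit normalised to 1 at t = 0. The slow-bleach
tail is quantified separately as the log10–log10 slope of the 1-Hz-lowpass,
140×-downsampled trace for t ≥ 60 s. ΔF/F baselines implement four
conventions: rolling 5th percentile (30-s windows), fixed-window mean,
blank-period mean (0.3–0.5 s), and subtract-and-divide by a 0.1-Hz lowpass.

## Screening metrics

Per FOV: relative brightness `B` (mean of the first 20 green frames over
the red reference), response amplitude `R = max ΔF/F0 − SD(Fpre/F0)` (F0 =
first 100 ms, Fpre = 100 ms before the pulse), photostability `P`
(trapezoid AUC of the normalised trace divided by the ideal non-bleaching
AUC). Compound metrics: `DI = R·B^e` and `DB = R·(B·P)^e`. The printed
formulas for DI/DB lost their exponent formatting in transit; the default
`e = 1/2` follows the convention of the parent screening methodology and
`e = 1` is selectable. Wells aggregate FOVs by pixel-count weighting.

## Biophysical fits

Step-response kinetics use the piecewise model
`F(t) = Σ k_i exp((t−t0) λ_i) + c` for `t > t0` (flat at `Σ k_i + c`
before), with `λ_i = −1/τ_i` and component fractions `|k_i|/Σ|k_j|`.
The fit is solved by variable projection — for any candidate `(t0, τ)` the
amplitudes and plateau are linear — with a noise-robust integral
initialiser (the area under the decay equals amplitude × Σ w_i τ_i) and a
smoothed-derivative onset estimate. Components slower than 0.2 s are
flagged as photobleaching and excluded from the reported kinetics.
Residuals are weighted uniformly. Parameter-recovery conditions follow the
step protocol: three replicate steps are averaged before fitting; at
per-replicate SNR 20 the averaged fit recovers 2.4/9.1-ms equal-weight
components within 15 % (taus) and ±10 % (fractions) in ≥ 95 of 100 seeded
runs. Single-replicate fits are unbiased but have ~11 % SD on the fast tau
— an intrinsic identifiability limit at that noise level, not an optimiser
artefact.

F–V curves fit the logistic sigmoid and then translate the curve so
F(−70 mV) = 0; anchoring is idempotent. Spike metrics take amplitude as
peak minus the pre-onset baseline level (onset = last pre-peak sample
within 10 % of the peak elevation), FWHM from half-maximum crossings on a
20-kHz linear interpolation, and tau-off from a single-exponential fit
from the peak to the return within 10 % of baseline. The downsampling
analysis upsamples the peak-normalised waveform to 1 MHz and resamples at
25–7000 Hz over 20 temporal phases, reporting mean and CV of the sampled
peak; a phase grid that misses the waveform records a peak of 0.

## Spike detection

**Adaptive KDE threshold.** After a 20-Hz zero-phase high-pass, first-pass
local maxima (strict, ≥ 2-sample separation) feed a Gaussian KDE (Scott
bandwidth) of peak amplitudes. The noise distribution is the KDE reflected
about the median; on a 512-point grid spanning the amplitude range the
score `g(x) = Fmax(x)^p − Fnoise(x)^p` (tail integrals, stringency
p = 0.1) is maximised, ties to the smallest x. The tail integrals use the
exact closed form (mean of normal survival functions): numerical
quadrature underflows to zero in the far tail, and since `0^p` erases the
noise-tail penalty the quadrature argmax is systematically biased to high
thresholds. Events are peaks above `threshold × scale`.

**Delayed-differential (kHz) detector.** A 40-Hz second-order Butterworth
high-pass, then contrast = (2-ms trailing mean − 3-ms trailing mean
delayed by 1 ms) × positive part of the 250-Hz high-passed trace, z-scored
and thresholded at 20 SD; supra-threshold runs merge within 3 ms (about
one optical spike width, far below the 10-ms spacing of 100-Hz bursts).
Onsets are the local peak of the 3-ms regression slope on a 10-kHz
interpolation. Two implementation choices matter and are deliberate:
(1) both filters are zero-phase — causal variants phase-distort the
~2.6-ms optical spike enough that the 20-SD threshold cannot reach
criterion recall at spike SNR 8; (2) the z-scale is
`max(negative-half estimate, 8-sigma-clipped SD)`. Noise products are
nearly symmetric about zero while spikes are strictly positive, so the
negative half estimates the noise scale without spike inflation; the
clipped term equals the plain SD on spike-free traces and captures the
mild positive skew of the clip-multiplied noise. With these choices the
20-SD threshold sits between the 60-s noise tail (~20 SD) and isolated
spikes (~45 SD) at SNR 8 — measured recall 0.98–1.0 and precision
0.99–1.0. The corollary is an honest false-positive floor: on pure-noise
records the extreme tail occasionally (about one seed in six) produces one
or two single-sample crossings per minute.

**Sliding-SD detector.** Detrend with a 3rd-order 15-Hz zero-phase
Butterworth high-pass, then accept peaks above 3.5× the 1-s sliding SD.
The false-positive rate is estimated by inverting the trace and re-running
the identical analysis (inverted/upright event-count ratio).

Post-processing: singlet isolation (bilateral 50- or 100-ms gaps),
spike-triggered averages with two per-event baseline rules (pre-window
mean, or last-20-frames-minus-final-5 convention), three SNR conventions
(pre-peak-window SD; shot noise = sqrt(mean photon count); dynamic
spike-free noise = 2× SD of downward deviations from a ±1-s local mean
over ±5 s), rolling spike rate (1-min window, 250-ms steps, normalised to
the first minute), and subthreshold fluctuation (0.1–50 Hz bandpass,
speed < 1 cm/s; low state = 1st percentile, high state = median at spike
onsets). The detectability index is defined here as
`d' = ΔF/F_spike × sqrt(photons collected over the optical-spike FWHM)` —
a package definition of shot-noise-limited discriminability (the exact
formula used in prior work is not restated by the protocols we
re-implement); it scales as sqrt(flux) and linearly in amplitude, which is
what the tests assert.

## Ground-truth evaluation

Electrophysiological spike times are mapped to imaging frame centers
(frame `i` stamped at `(i+0.5)/rate`). Regions with inter-spike intervals
below 100 ms (doublets/bursts) are excluded from evaluation on both sides:
burst spikes leave the truth set, and detections within the cutoff of a
burst spike are discarded rather than counted as false positives. Matching
is greedy earliest-first and one-to-one within the same or two subsequent
frames; on instances up to 200 spikes it attains the optimum of a
maximum-cardinality assignment oracle. Zero-division conventions:
precision = 1 when nothing is detected; recall = 0 when truth exists with
no matches; F1 = 0 when P + R = 0. PR curves sweep the adaptive-threshold
scale over 0.1–2.2; for cohorts, TP/FP/FN counts are summed across
recordings per scale before computing pooled metrics, and the population
scale maximises pooled F1. Subthreshold correspondence low-passes both
traces at 50 Hz, interpolates fluorescence to the electrophysiology clock,
bins into a 150 × 150 probability histogram, and reports the linear
regression slope in ΔF/F per mV.

## Functional mapping

Direction regressors evaluate
`R(t) = (1 − e^{−max(0,t−t_on)/τ}) − (1 − e^{−max(0,t−t_off)/τ})` with
τ = 0.7 s at frame centers, one column per direction summed over trials.
Movies are normalised by subtract-and-divide 0.1-Hz detrending, then
per-pixel mean-centering and root-sum-of-squares scaling, in that order.
Coefficients come from OLS against the regressor matrix (which reduces to
the stated matrix product for orthogonal designs; rank-deficient designs
are rejected) and project onto `e^{2iθ}/sqrt(N/2)`: phase → preferred
orientation (mod π; the basis identifies opposite directions), magnitude →
tuning strength, rendered as HSV. Visual responsiveness uses one-tailed
Welch t-tests per direction (variance equality is not assumed) at the
Bonferroni level 0.05/8. The voltage–neuromodulator analysis bandpasses
voltage 2–10 Hz (zero-phase Hamming FIR, order ≈ 3× the longest period in
band, applied by forward–backward FFT convolution for tractable tap
counts), takes the Hilbert amplitude, filters it 0.1–1 Hz, and bins it by
the Hilbert phase of the 0.1–1-Hz-filtered modulator into 65 bins over
(−π, π], smoothed with a circular 3-bin rolling mean (empty bins are
NaN-flagged and excluded). Cross-correlations run on 0.1–2-Hz bandpassed,
z-scored traces with the peak lag restricted to a 3-s window centered on
zero. Behavioural epoch selection keeps pupil cycles with ≥ 1-s dilations
followed by constrictions faster than 0.2 mm/s, drops epochs with ≥ 25 %
NaN samples, and excludes epochs overlapping running periods (> 1 cm/s
sustained ≥ 1 s) padded by ±3 s, with reason codes in the audit trail.

## Spatial analysis

Speed is the per-frame Euclidean step of the tracked scope divided by the
frame interval, smoothed with a 0.5-s moving average after dropping points
with likelihood ≤ 0.7 (linearly interpolated); head direction is 90°
counter-clockwise from the left-ear → right-ear vector. Rate maps use
2.5-cm bins, exclude samples below 2.5 cm/s, count a bin as visited at
≥ 0.1 s occupancy, and smooth with a 3-cm Gaussian via normalised
convolution so unvisited bins do not bleed in. Firing fields are
4-connected regions of ≥ 9 bins at ≥ 30 % of the session peak, detected on
the smoothed map (configurable). The border score is `(c − d)/(c + d)`
with `c` the maximum fraction of visited wall-edge bins touched by a field
over the four walls and `d` the rate-weighted mean field distance to the
nearest wall normalised by half the arena extent — the canonical
definition, bounded in [−1, 1], rotation-invariant. Significance uses a
circular time-shift null (uniform shift in [30 s, T − 30 s], 200
repetitions); a cell is border-tuned when its score exceeds the null's
95th percentile *and* 0.5.

## What the synthetic data do and do not show

The generators reproduce the statistical structures the analyses assume —
Poisson shot noise, sigmoid + two-time-constant kinetics, grating-locked
tuning, slow-oscillation phase coupling, border-biased firing — with
matched sizes (60-s kHz traces, 32 × 32-pixel tuning movies, 400-s
foraging sessions, 20-seed shuffle cohorts) chosen to exercise each method
at realistic SNR. They omit non-rigid motion, optical PSF blur and depth
scattering, detector electronics noise beyond Poisson, correlated neuropil
dynamics, and behavioural nonstationarity. Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the
stated model, not performance on any particular animal dataset.

## Numerical choices and limitations

- Seeds thread explicitly through every stochastic call; fixed seeds give
  bitwise-identical outputs.
- Zero-phase (forward–backward) filtering wherever a zero-phase filter is
  stated, and in the kHz detector (rationale above); causal elsewhere.
- The KDE threshold grid is 512 points over [min, max] peak amplitude;
  argmax ties resolve to the smallest amplitude.
- Kinetics fits bound taus in [2 samples, 10× the post-onset span] and the
  onset within ±50 samples of the derivative estimate.
- The rolling-percentile ΔF/F baseline lags a decaying trend by up to
  ~half a window; with 30-s windows this stays within 2 % for bleach time
  constants of 20 min or slower.
- `match_spikes` assumes the detector reports optical spikes at (or after)
  the corresponding truth time once mapped to frames; onset-convention
  trains should be converted to peak times before frame-window matching.
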