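"""Stimulus-locked functional analysis.

Direction regressors for drifting-grating trials, pixelwise orientation
tuning via complex projection of regression coefficients, tuning curves,
visual-responsiveness tests, peristimulus time histograms, and the
voltage-neuromodulator phase-binning and cross-correlation analyses.

The orientation basis ``exp(2 i theta)`` identifies opposite motion
directions by construction, so preferred orientations are reported modulo
pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .types import Movie, SpikeTrain, Trace

__all__ = [
    "DirectionRegressors",
    "TuningMap",
    "PhaseBinProfile",
    "build_regressors",
    "normalize_movie",
    "pixelwise_tuning",
    "tuning_curve",
    "visual_responsiveness",
    "psth",
    "bandpass_fir",
    "phase_bin_lowfreq",
    "crosscorr_lag",
    "select_behavior_epochs",
]


@dataclass
class DirectionRegressors:
    matrix: np.ndarray          # (n_frames, n_directions)
    directions_deg: np.ndarray
    tau_s: float
    schedule: np.ndarray        # (n_trials, 3): onset, offset, direction


def build_regressors(schedule: np.ndarray, frame_times: np.ndarray,
                     tau_s: float = 0.7) -> DirectionRegressors:
    """Evaluate the trial response regressor at frame centers.

    For each unique direction the regressor is

        R(t) = (1 - exp(-max(0, t - t_on)/tau))
             - (1 - exp(-max(0, t - t_off)/tau))

    summed over that direction's trials.  R rises towards 1 during the trial
    and relaxes back to 0 after offset; tau defaults to 0.7 s.
    """
    sched = np.asarray(schedule, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    dirs = np.unique(sched[:, 2])
    mat = np.zeros((t.size, dirs.size))
    for onset, offset, d in sched:
        j = int(np.flatnonzero(dirs == d)[0])
        rise = 1.0 - np.exp(-np.maximum(0.0, t - onset) / tau_s)
        fall = 1.0 - np.exp(-np.maximum(0.0, t - offset) / tau_s)
        mat[:, j] += rise - fall
    return DirectionRegressors(mat, dirs, tau_s, sched)


@dataclass
class TuningMap:
    complex_map: np.ndarray     # per-pixel complex projection
    coefficients: np.ndarray    # per-pixel regression coefficients

    @property
    def phase(self) -> np.ndarray:
        """Preferred orientation in radians, in [0, pi)."""
        return np.mod(np.angle(self.complex_map) / 2.0, np.pi)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_map)

    @property
    def preferred_deg(self) -> np.ndarray:
        return np.rad2deg(self.phase)

    def hsv(self) -> np.ndarray:
        """HSV rendering: hue = orientation, saturation & value = amplitude
        scaled to its maximum."""
        amp = self.amplitude
        scale = amp / amp.max() if amp.max() > 0 else amp
        return np.stack([self.phase / np.pi, scale, scale], axis=-1)


def normalize_movie(movie: Movie, detrend_hz: float = 0.1) -> np.ndarray:
    """The two-stage pixel normalisation used before tuning regression:
    detrend by subtracting and dividing a 0.1 Hz low-pass copy, then center
    each pixel on its mean and divide by its root-sum-of-squares."""
    flat = movie.data.reshape(movie.n_frames, -1).astype(float)
    if detrend_hz < movie.frame_rate / 2:
        sos = sps.butter(2, detrend_hz, btype="low", fs=movie.frame_rate,
                         output="sos")
        low = sps.sosfiltfilt(sos, flat, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            flat = np.where(low != 0, (flat - low) / low, 0.0)
    flat = flat - flat.mean(axis=0)
    rss = np.sqrt((flat ** 2).sum(axis=0))
    rss[rss == 0] = 1.0
    return (flat / rss).reshape(movie.shape)


def pixelwise_tuning(movie_normalized: np.ndarray,
                     regressors: DirectionRegressors) -> TuningMap:
    """Per-pixel orientation tuning by complex projection.

    Regression coefficients (OLS against the direction regressor matrix,
    which reduces to the matrix product for orthogonal designs) are
    projected onto ``exp(2 i theta_j) / sqrt(N/2)``; the phase of the result
    is the preferred orientation, the magnitude the tuning strength.
    """
    data = np.asarray(movie_normalized, dtype=float)
    n_frames = data.shape[0]
    flat = data.reshape(n_frames, -1)
    X = regressors.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("regressor matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    theta = np.deg2rad(regressors.directions_deg)
    basis = np.exp(2j * theta) / np.sqrt(theta.size / 2.0)
    cplx = (basis[:, None] * coef).sum(axis=0)
    shape = data.shape[1:]
    return TuningMap(cplx.reshape(shape), coef.T.reshape(shape + (theta.size,)))


def tuning_curve(dff: Trace, schedule: np.ndarray):
    """Mean ΔF/F per direction with SEM across trials.

    Returns ``(directions_deg, mean, sem, n_trials)``; directions with no
    trials are flagged by n_trials = 0 and NaN statistics.
    """
    sched = np.asarray(schedule, dtype=float)
    t = dff.times
    dirs = np.unique(sched[:, 2])
    mean = np.full(dirs.size, np.nan)
    sem = np.full(dirs.size, np.nan)
    n = np.zeros(dirs.size, dtype=int)
    for j, d in enumerate(dirs):
        trials = sched[sched[:, 2] == d]
        vals = []
        for onset, offset, _ in trials:
            sel = (t >= onset) & (t < offset)
            if sel.any():
                vals.append(dff.data[sel].mean())
        if vals:
            v = np.asarray(vals)
            mean[j] = v.mean()
            sem[j] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            n[j] = v.size
    return dirs, mean, sem, n


def visual_responsiveness(per_trial_stim, per_trial_blank,
                          alpha: float = 0.05):
    """Visual-responsiveness verdict from per-direction trial statistics.

    ``per_trial_stim`` maps direction -> array of per-trial responses during
    stimulation; ``per_trial_blank`` is the matched blank-period array (or a
    single pooled array).  A one-tailed Welch t-test (stim > blank) is run
    per direction; the cell is VR iff any direction's p-value is below
    ``alpha / n_directions`` (Bonferroni).  Returns ``(verdict, p_values)``.
    """
    dirs = sorted(per_trial_stim)
    n_dir = len(dirs)
    pvals = {}
    for d in dirs:
        stim = np.asarray(per_trial_stim[d], dtype=float)
        blank = np.asarray(per_trial_blank[d] if isinstance(per_trial_blank, dict)
                           else per_trial_blank, dtype=float)
        if stim.size < 2 or blank.size < 2:
            raise ValueError("at least 2 trials per direction required")
        res = stats.ttest_ind(stim, blank, equal_var=False,
                              alternative="greater")
        pvals[d] = float(res.pvalue)
    thresh = alpha / n_dir
    return any(p < thresh for p in pvals.values()), pvals


def psth(trains, align_times_s, window_s: tuple = (-0.5, 1.0),
         bin_ms: float = 10.0):
    """Peristimulus time histogram in spikes/s.

    ``trains`` is a list of spike-time arrays (one per trial source); each is
    aligned to each alignment time.  Returns ``(bin_centers_s, rate_hz)``.
    The histogram integrates to (total aligned spike count) / n_alignments.
    """
    bw = bin_ms / 1000.0
    edges = np.arange(window_s[0], window_s[1] + bw / 2, bw)
    counts = np.zeros(edges.size - 1)
    n_align = 0
    for t0 in np.asarray(align_times_s, dtype=float):
        n_align += 1
        for tr in trains:
            rel = np.asarray(tr, dtype=float) - t0
            counts += np.histogram(rel, bins=edges)[0]
    if n_align == 0:
        raise ValueError("no alignment times")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (n_align * bw)


def bandpass_fir(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float,
                 order: int | None = None) -> np.ndarray:
    """Zero-phase Hamming-window FIR bandpass.

    The filter order defaults to 3x the longest period in the band (in
    samples, forced odd) so the slowest component fits in the kernel.
    """
    if order is None:
        order = int(3 * fs / lo_hz) | 1
    order = min(order, ((x.size - 2) // 3) | 1)
    taps = sps.firwin(order, [lo_hz, hi_hz], pass_zero=False, fs=fs,
                      window="hamming")
    # zero-phase via forward-backward FFT convolution with reflect padding
    # (an FIR of thousands of taps makes direct filtfilt prohibitively slow)
    pad = min(x.size - 1, 3 * order)
    ext = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    fwd = sps.fftconvolve(ext, taps, mode="same")
    bwd = sps.fftconvolve(fwd[::-1], taps, mode="same")[::-1]
    return bwd[pad:pad + x.size]


@dataclass
class PhaseBinProfile:
    bin_centers: np.ndarray      # 65 centers over (-pi, pi)
    mean: np.ndarray
    sem: np.ndarray
    smoothed: bool = True
    n_per_bin: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


def phase_bin_lowfreq(voltage_dff: Trace, modulator_dff: Trace,
                      epochs=None, n_bins: int = 65,
                      voltage_band=(2.0, 10.0), slow_band=(0.1, 1.0),
                      smooth_bins: int = 3) -> PhaseBinProfile:
    """Bin voltage-band amplitude by the phase of a slow neuromodulator.

    The voltage trace is band-passed 2-10 Hz (zero-phase Hamming FIR), its
    Hilbert amplitude low-frequency filtered to 0.1-1 Hz; the modulator is
    filtered 0.1-1 Hz and its Hilbert phase computed.  Samples inside the
    analysis epochs are binned into ``n_bins`` phase bins over (-pi, pi);
    bin means are smoothed with a 3-bin rolling average (NaN bins excluded).
    """
    fs = voltage_dff.rate
    v = bandpass_fir(voltage_dff.data, fs, *voltage_band)
    amp = np.abs(sps.hilbert(v))
    amp = bandpass_fir(amp, fs, *slow_band)
    m = bandpass_fir(modulator_dff.data, fs, *slow_band)
    phase = np.angle(sps.hilbert(m))
    mask = np.zeros(voltage_dff.n, dtype=bool)
    if epochs is None:
        mask[:] = True
    else:
        t = voltage_dff.times
        for a, b in epochs:
            mask |= (t >= a) & (t <= b)
    if not mask.any():
        raise ValueError("empty analysis epochs")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(phase[mask], edges) - 1, 0, n_bins - 1)
    vals = amp[mask]
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    n_per = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        n_per[b] = sel.sum()
        if n_per[b]:
            mean[b] = vals[sel].mean()
            sem[b] = (vals[sel].std(ddof=1) / np.sqrt(n_per[b])
                      if n_per[b] > 1 else 0.0)
    if smooth_bins > 1:
        sm = np.full(n_bins, np.nan)
        half = smooth_bins // 2
        for b in range(n_bins):
            idx = [(b + k) % n_bins for k in range(-half, half + 1)]
            valsb = mean[idx]
            good = ~np.isnan(valsb)
            if good.any():
                sm[b] = valsb[good].mean()
        mean = sm
    return PhaseBinProfile(centers, mean, sem, smooth_bins > 1, n_per)


def crosscorr_lag(x_dff: Trace, y_dff: Trace, band_hz=(0.1, 2.0),
                  max_lag_s: float = 3.0):
    """Normalized cross-correlation between two co-sampled traces with the
    peak lag restricted to a window centered on zero.

    Both traces are band-passed (0.1-2 Hz), z-scored, and cross-correlated;
    positive lag means y follows x.  Returns ``(lags_s, corr, peak_lag_s)``.
    """
    if x_dff.n != y_dff.n or x_dff.rate != y_dff.rate:
        raise ValueError("traces must be co-sampled and equal length")
    fs = x_dff.rate
    if band_hz is not None:
        x = bandpass_fir(x_dff.data, fs, *band_hz)
        y = bandpass_fir(y_dff.data, fs, *band_hz)
    else:
        x, y = x_dff.data, y_dff.data
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    corr = sps.correlate(y, x, mode="full") / x.size
    lags = sps.correlation_lags(y.size, x.size, mode="full") / fs
    win = np.abs(lags) <= max_lag_s / 2
    peak = lags[win][int(np.argmax(corr[win]))]
    return lags, corr, float(peak)


def select_behavior_epochs(pupil: Trace, running_speed: Trace,
                           min_dilation_s: float = 1.0,
                           constriction_speed_mm_s: float = 0.2,
                           nan_fraction_max: float = 0.25,
                           run_speed_cm_s: float = 1.0,
                           run_min_s: float = 1.0,
                           run_margin_s: float = 3.0):
    """Select quiet-wakefulness pupil epochs for phase analyses.

    A candidate epoch is one pupil cycle: a dilation lasting at least
    ``min_dilation_s`` followed by a constriction faster than
    ``constriction_speed_mm_s``.  Epochs are excluded (with a reason code)
    when >= 25 % of their pupil samples are NaN or when they overlap a
    running period (speed > 1 cm/s for >= 1 s) padded by ±3 s.

    Returns ``(epochs, audit)`` where each epoch is ``(start_s, end_s)`` and
    the audit lists ``(start_s, end_s, reason)`` for rejected candidates.
    """
    t = pupil.times
    d = pupil.data
    fs = pupil.rate
    filled = d.copy()
    nanmask = np.isnan(filled)
    if nanmask.all():
        raise ValueError("pupil trace is all NaN")
    filled[nanmask] = np.interp(t[nanmask], t[~nanmask], d[~nanmask])
    # smooth lightly so derivative sign is stable
    w = max(1, int(round(0.25 * fs)))
    kernel = np.ones(w) / w
    smooth = np.convolve(filled, kernel, mode="same")
    vel = np.gradient(smooth, t)      # mm/s

    dilating = vel > 0
    # decompose into maximal runs of constant dilation state
    change = np.flatnonzero(np.diff(dilating.astype(int)))
    bounds = np.concatenate([[0], change + 1, [t.size]])
    runs = [(int(bounds[i]), int(bounds[i + 1]), bool(dilating[bounds[i]]))
            for i in range(bounds.size - 1)]
    # candidate epoch: a long-enough dilation run + its constriction run
    candidates = []
    for k in range(len(runs) - 1):
        s, e, is_dil = runs[k]
        if not is_dil:
            continue
        if (t[e - 1] - t[s]) < min_dilation_s:
            continue
        cs, ce, _ = runs[k + 1]
        con_speed = np.abs(vel[cs:ce]).max() if ce > cs else 0.0
        if con_speed <= constriction_speed_mm_s:
            continue
        candidates.append((float(t[s]), float(t[ce - 1])))

    # running periods
    rs = running_speed
    fast = rs.data > run_speed_cm_s
    run_periods = []
    edges_r = np.diff(fast.astype(int))
    r_starts = list(np.flatnonzero(edges_r == 1) + 1)
    r_ends = list(np.flatnonzero(edges_r == -1) + 1)
    if fast.size and fast[0]:
        r_starts.insert(0, 0)
    if fast.size and fast[-1]:
        r_ends.append(fast.size)
    for a, b in zip(r_starts, r_ends):
        if (b - a) / rs.rate >= run_min_s:
            run_periods.append((rs.times[a] - run_margin_s,
                                rs.times[b - 1] + run_margin_s))

    epochs, audit = [], []
    for a, b in candidates:
        sel = (t >= a) & (t <= b)
        if np.isnan(d[sel]).mean() >= nan_fraction_max:
            audit.append((a, b, "nan_fraction"))
            continue
        if any(not (b < ra or a > rb) for ra, rb in run_periods):
            audit.append((a, b, "running"))
            continue
        epochs.append((a, b))
    return epochs, audit
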