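"""Indicator biophysics: step-response kinetics, the F-V sigmoid, optical
spike-waveform metrics, and the frame-rate downsampling analysis.

Step responses are fitted with piecewise exponential models

    F(t) = sum_i k_i * exp((t - t0) * lambda_i) + c   for t > t0
    F(t) = sum_i k_i + c                              for t <= t0

where lambda_i = -1/tau_i and the k_i are signed component amplitudes; the
reported component fraction of tau_i is |k_i| / sum_j |k_j|.  Components
slower than ``slow_tau_s`` are flagged as photobleaching and excluded from
the kinetics report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .types import Trace

__all__ = [
    "ExpKineticsFit",
    "SigmoidFVFit",
    "SpikeMetrics",
    "fit_step_kinetics",
    "fit_fv_sigmoid",
    "spike_metrics",
    "downsampling_analysis",
]


@dataclass
class ExpKineticsFit:
    order: int
    k: np.ndarray            # component amplitudes (signed)
    lam: np.ndarray          # rate terms, lambda_i = -1/tau_i
    c: float                 # plateau
    t0: float                # event onset
    fractions: np.ndarray    # |k_i| / sum|k_j| over reported components
    slow_flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    stats: dict = field(default_factory=dict)

    @property
    def taus_s(self) -> np.ndarray:
        return -1.0 / self.lam

    def reported_taus_s(self) -> np.ndarray:
        """Time constants with slow photobleach components excluded."""
        return self.taus_s[~self.slow_flagged]


def _step_model(t, t0, c, *kl):
    n = len(kl) // 2
    ks = np.array(kl[:n])
    lams = np.array(kl[n:])
    out = np.full_like(t, c + ks.sum())
    post = t > t0
    dt = t[post] - t0
    out[post] = c + sum(k * np.exp(dt * lam) for k, lam in zip(ks, lams))
    return out


def fit_step_kinetics(trace: Trace, order: int = 1, t0_guess: float | None = None,
                      slow_tau_s: float = 0.2) -> ExpKineticsFit:
    """Nonlinear least squares of a 1-3 component step-response model.

    Initial tau guesses come from a log-linear regression on the decay tail;
    residuals are weighted uniformly.  ``slow_tau_s`` marks components slower
    than this as photobleaching, which are excluded from reported fractions.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    t, y = trace.times, trace.data
    if t.size < 10 * (2 * order + 2):
        raise ValueError("trace too short for the requested model order")
    if t0_guess is None:
        # largest absolute derivative of a ~1-ms-smoothed copy marks the
        # event onset (the raw derivative is noise-dominated)
        from scipy.ndimage import uniform_filter1d

        w = max(1, int(round(0.001 * trace.rate)))
        ys = uniform_filter1d(y, w, mode="nearest")
        d = np.abs(ys[w:] - ys[:-w])
        t0_guess = t[int(np.argmax(d)) + w // 2]
    if not (t[0] <= t0_guess <= t[-1]):
        raise ValueError("t0 outside the fitted crop")
    plateau = y[t > t0_guess + 0.6 * (t[-1] - t0_guess)].mean()
    step_amp = y[t <= t0_guess].mean() - plateau
    if abs(step_amp) < 1e-12:
        # degenerate flat input: amplitude terms ~ 0
        return ExpKineticsFit(order, np.zeros(order),
                              np.full(order, -1.0), float(y.mean()),
                              float(t0_guess), np.full(order, 1.0 / order),
                              np.zeros(order, bool), {"r2": 1.0})

    # Variable projection: for fixed (t0, taus) the amplitudes and plateau
    # are linear, so only the time constants are optimised nonlinearly.
    def design(t0, taus):
        cols = [np.where(t > t0, np.exp(-np.maximum(t - t0, 0.0) / tau), 1.0)
                for tau in taus]
        cols.append(np.ones_like(t))
        return np.column_stack(cols)

    def solve_linear(t0, taus):
        A = design(t0, taus)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return coef, float(resid @ resid)

    # integral initialisation: for y - c = sum k_i exp(-dt/tau_i) the area
    # over the decay equals step_amp * sum(w_i tau_i), a noise-robust scale
    dt = t[1] - t[0]
    span = t[-1] - t0_guess
    post = t > t0_guess
    area = np.trapezoid(y[post] - plateau, t[post])
    tau_eff = np.clip(abs(area / step_amp), 2 * dt, span)
    if order == 1:
        starts = [[tau_eff], [tau_eff / 3]]
    elif order == 2:
        starts = [[tau_eff / 3, 3 * tau_eff], [tau_eff / 6, 1.5 * tau_eff]]
    else:
        starts = [[tau_eff / 6, tau_eff, min(span, 6 * tau_eff)],
                  [tau_eff / 3, 2 * tau_eff, min(span, 10 * tau_eff)]]

    def objective(params):
        t0 = params[0]
        taus = np.exp(params[1:])
        A = design(t0, taus)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return y - A @ coef

    t0_lo = max(t[0], t0_guess - 50 * dt)
    t0_hi = min(t[-1], t0_guess + 50 * dt)
    best = None
    for taus0 in starts:
        taus0 = np.clip(taus0, 2 * dt, 10 * span)
        p0 = np.concatenate([[np.clip(t0_guess, t0_lo, t0_hi)], np.log(taus0)])
        lo = np.concatenate([[t0_lo], np.full(order, np.log(2 * dt))])
        hi = np.concatenate([[t0_hi], np.full(order, np.log(10 * span))])
        try:
            res = optimize.least_squares(objective, p0, bounds=(lo, hi),
                                         max_nfev=200)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("kinetics fit failed to converge")
    t0_fit = float(best.x[0])
    taus_fit = np.exp(best.x[1:])
    coef, _ = solve_linear(t0_fit, taus_fit)
    k = np.asarray(coef[:order])
    c = float(coef[order])
    lam = -1.0 / taus_fit
    srt = np.argsort(-1.0 / lam)  # sort by tau ascending
    k, lam = k[srt], lam[srt]
    taus = -1.0 / lam
    slow = taus > slow_tau_s
    rep = np.abs(k[~slow])
    fractions = np.zeros(order)
    if rep.sum() > 0:
        fractions[~slow] = np.abs(k[~slow]) / rep.sum()
    resid = y - design(t0_fit, taus_fit) @ coef
    tss = ((y - y.mean()) ** 2).sum()
    st = {"r2": 1.0 - (resid ** 2).sum() / tss if tss > 0 else 1.0,
          "rmse": float(np.sqrt((resid ** 2).mean()))}
    return ExpKineticsFit(order, k, lam, float(c), float(t0_fit),
                          fractions, slow, st)


@dataclass
class SigmoidFVFit:
    L: float
    k_slope: float
    x0: float
    b: float          # offset after anchoring so that F(-70 mV) = 0

    def evaluate(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        return self.L / (1.0 + np.exp(-self.k_slope * (v - self.x0))) + self.b

    def anchored(self, v_anchor: float = -70.0) -> "SigmoidFVFit":
        shift = self.evaluate(v_anchor)
        return SigmoidFVFit(self.L, self.k_slope, self.x0, self.b - shift)


def _sigmoid(v, L, k, x0, b):
    return L / (1.0 + np.exp(-k * (v - x0))) + b


def fit_fv_sigmoid(points, anchor_mV: float = -70.0) -> SigmoidFVFit:
    """Fit steady-state (mV, ΔF/F) points to the logistic sigmoid
    F(x) = L / (1 + exp(-k (x - x0))) + b, then translate the curve so that
    F(anchor) = 0.

    Requires >= 5 voltage levels.  A degenerate flat input returns L ~ 0 with
    the anchored curve identically zero.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("at least 5 voltage levels required")
    v, f = pts[:, 0], pts[:, 1]
    span = f.max() - f.min()
    if span < 1e-12:
        return SigmoidFVFit(0.0, 0.0, float(v.mean()), 0.0)
    p0 = [span * 1.5, 4.0 / (v.max() - v.min()), float(v.mean()), f.min()]
    try:
        popt, _ = optimize.curve_fit(_sigmoid, v, f, p0=p0, maxfev=40000)
    except RuntimeError as e:
        raise RuntimeError(f"sigmoid fit failed: {e}") from e
    fit = SigmoidFVFit(*popt)
    if not np.isfinite(fit.evaluate(v)).all():
        raise RuntimeError("sigmoid fit diverged")
    return fit.anchored(anchor_mV)


@dataclass
class SpikeMetrics:
    amplitude: float        # ΔF/F from onset to peak
    fwhm_ms: float          # width at half maximum (nan if undefined)
    tau_off_ms: float       # exponential time constant of repolarisation
    flags: tuple = ()


def _interp_to(trace: Trace, rate: float):
    t = trace.times
    ti = np.arange(t[0], t[-1], 1.0 / rate)
    return ti, np.interp(ti, t, trace.data)


def spike_metrics(sta: Trace, interp_rate: float = 20_000.0,
                  onset_index: int | None = None) -> SpikeMetrics:
    """Amplitude, FWHM, and repolarisation tau of an average spike waveform.

    Amplitude is peak minus onset value, measured on the native samples.
    FWHM is measured on a 20 kHz linear interpolation via half-maximum
    crossings.  tau_off comes from a single-exponential fit to the
    repolarisation segment, from the peak to the return within 10 % of
    baseline.
    """
    y = sta.data
    peak_i = int(np.argmax(y))
    if onset_index is None:
        # onset: last pre-peak sample at or below 10% of the peak elevation
        base0 = y[: max(1, peak_i // 4)].mean() if peak_i >= 4 else y[0]
        thresh = base0 + 0.1 * (y[peak_i] - base0)
        pre = np.flatnonzero(y[:peak_i] <= thresh)
        onset_index = int(pre[-1]) if pre.size else 0
    # the onset point's level is the pre-spike baseline: the mean of the
    # samples up to the onset (robust to the onset landing a few samples up
    # the rise); amplitude is peak minus that level
    base = float(y[: onset_index + 1].mean()) if onset_index > 0 else float(y[0])
    amplitude = float(y[peak_i] - base)
    flags = []

    # FWHM at half maximum above the pre-spike baseline, on a dense
    # interpolation
    ti, yi = _interp_to(sta, interp_rate)
    pk = int(np.argmax(yi))
    half = base + 0.5 * (y[peak_i] - base)
    above = yi >= half
    fwhm_ms = np.nan
    left = np.flatnonzero(~above[:pk])
    right = np.flatnonzero(~above[pk:])
    if left.size and right.size:
        fwhm_ms = (ti[pk + right[0]] - ti[left[-1]]) * 1000.0
    else:
        flags.append("fwhm_undefined")

    # tau_off from peak to return within 10% of baseline
    ret_level = base + 0.1 * (y[peak_i] - base)
    post = y[peak_i:]
    below = np.flatnonzero(post <= ret_level)
    end = peak_i + (int(below[0]) + 1 if below.size else post.size)
    seg_t = sta.times[peak_i:end] - sta.times[peak_i]
    seg_y = y[peak_i:end] - base
    tau_off_ms = np.nan
    if seg_t.size >= 4 and np.all(seg_y > 0):
        try:
            popt, _ = optimize.curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau), seg_t, seg_y,
                p0=[seg_y[0], max(seg_t[-1] / 2, 1e-5)], maxfev=20000)
            tau_off_ms = float(popt[1] * 1000.0)
        except RuntimeError:
            flags.append("tau_off_fit_failed")
    else:
        flags.append("tau_off_undefined")
    return SpikeMetrics(amplitude, fwhm_ms, tau_off_ms, tuple(flags))


def downsampling_analysis(waveform: Trace, rates=None, n_phases: int = 20,
                          upsample_rate: float = 1_000_000.0):
    """Effect of frame rate on measured peak amplitude of a spike waveform.

    The peak-normalised waveform is upsampled (linear interpolation) to
    ``upsample_rate`` and resampled at each target rate with ``n_phases``
    temporal offsets.  Returns a dict: rate -> (mean normalised peak, CV
    across phases).
    """
    if rates is None:
        rates = [25, 50, 100, 200, 400, 800, 1600, 3500, 7000]
    y = waveform.data / waveform.data.max()
    t = waveform.times
    tu = np.arange(t[0], t[-1], 1.0 / upsample_rate)
    yu = np.interp(tu, t, y)
    out = {}
    for rate in rates:
        if rate > upsample_rate:
            raise ValueError("target rate exceeds the upsample rate")
        stride = int(round(upsample_rate / rate))
        # a phase whose sample grid misses the waveform entirely records a
        # peak of 0 (baseline): the spike fell between samples
        peaks = np.array([
            yu[ph * stride // n_phases::stride].max()
            if yu[ph * stride // n_phases::stride].size else 0.0
            for ph in range(n_phases)])
        mean = float(peaks.mean())
        cv = float(peaks.std() / mean) if mean > 0 else np.nan
        out[rate] = (mean, cv)
    return out
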