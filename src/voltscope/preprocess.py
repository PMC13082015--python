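"""Movie- and trace-level conditioning.

Background estimation from the first-frame intensity histogram mode,
two-step (global then local template) phase-correlation motion correction,
correlation-ranked pixel selection, multi-exponential photobleach fitting
with information-criterion model selection, the several ΔF/F baseline
conventions used across acquisition modalities, the power-law tail of slow
bleaching, and the quadratic illumination-power correction for excitation
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, stats
from skimage.registration import phase_cross_correlation

from .types import Movie, Trace

__all__ = [
    "estimate_background",
    "motion_correct",
    "select_pixels",
    "BleachFit",
    "fit_bleach",
    "compute_dff",
    "bleach_power_law",
    "power_correct",
    "PixelSelection",
]

MOTION_EXCLUSION_UM = 10.0


def _histogram_mode(values: np.ndarray, integer_data: bool | None = None) -> float:
    """Mode of an intensity histogram.

    Integer-valued data (photon counts) are binned at unit width; otherwise
    Freedman-Diaconis bins are used.  Ties resolve to the smallest bin.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no pixels available for background estimation")
    if integer_data is None:
        integer_data = np.allclose(v, np.round(v))
    if integer_data:
        lo, hi = int(v.min()), int(v.max())
        counts = np.bincount((v - lo).astype(int))
        return float(lo + int(np.argmax(counts)))
    iqr = stats.iqr(v)
    if iqr == 0:
        return float(np.median(v))
    width = 2 * iqr / v.size ** (1 / 3)
    bins = max(1, int(np.ceil((v.max() - v.min()) / width)))
    counts, edges = np.histogram(v, bins=bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def estimate_background(movie: Movie) -> float:
    """Background intensity: histogram mode of the first frame, excluding
    pixels that saturate at any point in the movie."""
    sat = np.any(movie.data >= movie.saturation_value, axis=0)
    first = movie.data[0][~sat]
    if first.size == 0:
        raise ValueError("all pixels saturated")
    return _histogram_mode(first)


def _phase_shift(template: np.ndarray, frame: np.ndarray,
                 upsample: int = 1) -> np.ndarray:
    if template.std() == 0 or frame.std() == 0:
        return np.zeros(2)
    shift, _, _ = phase_cross_correlation(template, frame,
                                          upsample_factor=upsample,
                                          normalization=None)
    return np.asarray(shift, dtype=float)


def motion_correct(movie: Movie, local_window_s: float = 10.0,
                   upsample: int = 10, um_per_px: float = 1.0):
    """Two-step rigid motion correction.

    Step 1 estimates integer shifts of each frame against the global mean
    template by phase correlation; step 2 refines against a local rolling
    template (window ``local_window_s``) with subpixel precision.  Frames are
    shifted by the negated estimate.  Returns ``(corrected Movie, info)``
    where ``info`` holds the per-frame ``(dy, dx)`` shift table, the mean
    shift magnitude, an exclusion flag for mean motion above 10 μm, and a
    degenerate-input warning for constant movies.
    """
    if movie.n_frames < 2:
        raise ValueError("motion correction requires >= 2 frames")
    data = movie.data
    degenerate = bool(np.all(data.std(axis=0) == 0)) or data[0].std() == 0

    # _phase_shift returns the correction to apply to the frame; the frame's
    # displacement (the quantity reported) is its negation.  The global
    # template is re-averaged after each pass because uncorrected motion
    # blurs it; iteration stops when the integer shifts settle.
    coarse_corr = np.zeros((movie.n_frames, 2))
    corrected = data
    for _ in range(3):
        template = corrected.mean(axis=0)
        step = np.array([np.round(_phase_shift(template, f))
                         for f in corrected])
        if not np.any(step):
            break
        coarse_corr = coarse_corr + step
        corrected = np.array([
            ndimage.shift(f, s, order=1, mode="nearest") if np.any(s) else f
            for f, s in zip(data, coarse_corr)
        ])

    half = max(1, int(round(local_window_s * movie.frame_rate / 2)))
    fine_corr = np.zeros_like(coarse_corr)
    if not degenerate:
        for i in range(movie.n_frames):
            lo, hi = max(0, i - half), min(movie.n_frames, i + half + 1)
            local = corrected[lo:hi].mean(axis=0)
            fine_corr[i] = _phase_shift(local, corrected[i], upsample=upsample)
        corrected = np.array([
            ndimage.shift(f, s, order=1, mode="nearest") if np.any(s) else f
            for f, s in zip(corrected, fine_corr)
        ])
    shifts = -(coarse_corr + fine_corr)
    # the template only defines shifts up to a constant; report displacement
    # relative to the first frame and re-align the movie accordingly
    ref = shifts[0].copy()
    shifts = shifts - ref
    if np.any(ref):
        corrected = np.array([
            ndimage.shift(f, -ref, order=1, mode="nearest")
            for f in corrected
        ])
    mean_mag = float(np.hypot(shifts[:, 0], shifts[:, 1]).mean())
    info = {
        "shifts": shifts,
        "mean_shift_px": mean_mag,
        "mean_shift_um": mean_mag * um_per_px,
        "excluded": mean_mag * um_per_px > MOTION_EXCLUSION_UM,
        "degenerate": degenerate,
    }
    return Movie(corrected, movie.frame_rate, movie.saturation_value), info


@dataclass
class PixelSelection:
    """Correlation-ranked pixel subset with its prefix-SNR audit trail."""

    ranked_indices: np.ndarray       # flat pixel indices, best-correlated first
    snr_curve: np.ndarray            # summed-trace SNR for each prefix length
    chosen: np.ndarray               # selected flat pixel indices
    min_pixels: int
    accepted: bool


def _prefix_snr(summed: np.ndarray, frame_rate: float) -> float:
    """Screening SNR of a summed trace: (peak - baseline mean) / baseline SD,
    baseline = first 100 ms."""
    nb = max(2, int(round(0.1 * frame_rate)))
    base = summed[:nb]
    sd = base.std()
    if sd == 0:
        return np.inf if summed.max() > base.mean() else 0.0
    return float((summed.max() - base.mean()) / sd)


def select_pixels(movie: Movie, mask: np.ndarray,
                  min_pixels: int = 300) -> PixelSelection:
    """Correlation-based pixel selection for screening FOVs.

    The template is the mean trace over the foreground mask; pixels are
    ranked by Pearson correlation with it, and the prefix (in rank order)
    whose summed trace maximises the screening SNR is chosen.  Selections
    smaller than ``min_pixels`` mark the FOV as rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty foreground mask")
    flat = movie.data.reshape(movie.n_frames, -1)
    idx = np.flatnonzero(mask.ravel())
    traces = flat[:, idx]
    template = traces.mean(axis=1)
    if template.std() == 0:
        raise ValueError("zero-variance template")
    tc = template - template.mean()
    pc = traces - traces.mean(axis=0)
    denom = np.sqrt((pc ** 2).sum(axis=0)) * np.sqrt((tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (pc * tc[:, None]).sum(axis=0) / denom, -np.inf)
    order = np.argsort(-r, kind="stable")
    ranked = idx[order]
    csum = np.cumsum(traces[:, order], axis=1)
    snr = np.array([_prefix_snr(csum[:, k], movie.frame_rate)
                    for k in range(ranked.size)])
    # ties (within float tolerance) resolve to the largest prefix: when
    # additional pixels do not hurt the summed-trace SNR, keep their photons
    smax = snr.max()
    tol = 1e-9 * max(abs(smax), 1.0)
    best = int(np.flatnonzero(snr >= smax - tol)[-1])
    chosen = ranked[: best + 1]
    return PixelSelection(ranked, snr, chosen, min_pixels,
                          accepted=chosen.size >= min_pixels)


# ---------------------------------------------------------------------------
# photobleach fitting


@dataclass
class BleachFit:
    model_order: int
    amplitudes: np.ndarray
    taus_s: np.ndarray
    offset: float
    stats: dict = field(default_factory=dict)

    def evaluate(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus_s):
            out += a * np.exp(-t / tau)
        return out

    def correction(self, trace: Trace) -> Trace:
        """Divide by the fit normalised to 1 at t = 0."""
        fit = self.evaluate(trace.times)
        f0 = self.evaluate(np.array([0.0]))[0]
        return trace.copy_with(trace.data / (fit / f0))


def _multi_exp(t, *params):
    n = (len(params) - 1) // 2
    out = np.full_like(t, params[-1])
    for i in range(n):
        out += params[2 * i] * np.exp(-t / params[2 * i + 1])
    return out


def _fit_order(t, y, order):
    span = max(t[-1] - t[0], 1e-9)
    amp0 = (y[0] - y[-1]) / order
    p0, lo, hi = [], [], []
    for i in range(order):
        tau0 = span / (3.0 ** (order - i))
        p0 += [amp0, tau0]
        lo += [-np.inf, 1e-6 * span]
        hi += [np.inf, 100 * span]
    p0.append(y[-1])
    lo.append(-np.inf)
    hi.append(np.inf)
    popt, _ = optimize.curve_fit(_multi_exp, t, y, p0=p0, bounds=(lo, hi),
                                 maxfev=20000)
    resid = y - _multi_exp(t, *popt)
    n, k = y.size, len(popt)
    rss = float((resid ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    st = {
        "r2": 1.0 - rss / tss if tss > 0 else 1.0,
        "rmse": np.sqrt(rss / n),
        "mae": float(np.abs(resid).mean()),
        "bic": n * np.log(max(rss / n, 1e-300)) + k * np.log(n),
        "aic": n * np.log(max(rss / n, 1e-300)) + 2 * k,
    }
    amps = np.array([popt[2 * i] for i in range(order)])
    taus = np.array([popt[2 * i + 1] for i in range(order)])
    srt = np.argsort(taus)
    return amps[srt], taus[srt], float(popt[-1]), st


def _is_local_min(values, i):
    """Criterion local-minimum rule: lower than both neighbours (single
    neighbour at the ends)."""
    left_ok = i == 0 or values[i] < values[i - 1]
    right_ok = i == len(values) - 1 or values[i] < values[i + 1]
    return left_ok and right_ok


def fit_bleach(trace: Trace, exclude_intervals=()) -> BleachFit:
    """Fit 1-3 component exponential decays to a fluorescence trace and pick
    the best order.

    Samples inside ``exclude_intervals`` (list of ``(start_s, end_s)``, e.g.
    stimulation epochs) are removed before fitting.  Candidate orders are
    ranked by goodness of fit (highest R², lowest RMSE and MAE) and must sit
    at a local minimum of both BIC and AIC across orders; if no candidate
    satisfies the criterion rule, the BIC-minimising order is used.
    """
    t, y = trace.times, trace.data
    keep = np.ones(t.size, dtype=bool)
    for a, b in exclude_intervals:
        keep &= ~((t >= a) & (t <= b))
    t, y = t[keep], y[keep]
    fits, failures = {}, []
    for order in (1, 2, 3):
        if t.size < 10 * (2 * order + 1):
            continue
        try:
            fits[order] = _fit_order(t, y, order)
        except RuntimeError as e:  # non-convergence
            failures.append((order, str(e)))
    if not fits:
        raise RuntimeError(f"no bleach model converged: {failures}")
    orders = sorted(fits)
    bic = [fits[o][3]["bic"] for o in orders]
    aic = [fits[o][3]["aic"] for o in orders]
    admissible = [o for i, o in enumerate(orders)
                  if _is_local_min(bic, i) and _is_local_min(aic, i)]
    pool = admissible or [orders[int(np.argmin(bic))]]
    best = max(pool, key=lambda o: (fits[o][3]["r2"], -fits[o][3]["rmse"],
                                    -fits[o][3]["mae"]))
    amps, taus, c, st = fits[best]
    st = dict(st, admissible_orders=admissible,
              bic_by_order=dict(zip(orders, bic)),
              aic_by_order=dict(zip(orders, aic)))
    return BleachFit(best, amps, taus, c, st)


# ---------------------------------------------------------------------------
# ΔF/F baselines


def compute_dff(trace: Trace, method: str = "rolling_p5", **params) -> Trace:
    """ΔF/F = (F - F0)/F0 with a method-specific baseline F0.

    method = "rolling_p5"   bottom 5th percentile over rolling windows
                            (``window_s``, default 30 s)
    method = "mean"         mean over ``(start_s, end_s)`` or the whole trace
    method = "blank_window" mean over a fixed window (``start_s``, ``end_s``;
                            default 0.3-0.5 s), the blank-period convention
    method = "lowpass_divide"
                            subtract and divide by a low-pass filtered copy
                            (``cutoff_hz``, default 0.1 Hz)
    """
    f = trace.data
    t = trace.times
    if method == "rolling_p5":
        window_s = float(params.get("window_s", 30.0))
        w = max(1, int(round(window_s * trace.rate)))
        half = w // 2
        # percentile over a centred rolling window, edge-clamped
        f0 = np.empty_like(f)
        for i in range(f.size):
            lo, hi = max(0, i - half), min(f.size, i + half + 1)
            f0[i] = np.percentile(f[lo:hi], 5)
    elif method == "mean":
        a = float(params.get("start_s", t[0]))
        b = float(params.get("end_s", t[-1]))
        sel = (t >= a) & (t <= b)
        f0 = np.full_like(f, f[sel].mean())
    elif method == "blank_window":
        a = float(params.get("start_s", 0.3))
        b = float(params.get("end_s", 0.5))
        sel = (t >= a) & (t <= b)
        if not sel.any():
            raise ValueError("blank window outside trace")
        f0 = np.full_like(f, f[sel].mean())
    elif method == "lowpass_divide":
        cutoff = float(params.get("cutoff_hz", 0.1))
        sos = signal.butter(2, cutoff, btype="low", fs=trace.rate, output="sos")
        f0 = signal.sosfiltfilt(sos, f)
    else:
        raise ValueError(f"unknown dff method {method!r}")
    if np.any(f0 <= 0):
        raise ValueError("F0 <= 0: baseline undefined")
    return trace.copy_with((f - f0) / f0, units="dff")


def bleach_power_law(trace: Trace, t_start_s: float = 60.0,
                     lowpass_hz: float = 1.0, downsample: int = 140) -> float:
    """Slope of the slow photobleaching tail on log10-log10 axes.

    The trace is low-pass filtered at 1 Hz, downsampled 140x, restricted to
    t >= ``t_start_s``, and fitted with a line in (log10 t, log10 F).
    """
    if trace.duration <= t_start_s:
        raise ValueError("trace shorter than t_start_s")
    f = trace.data
    if lowpass_hz < trace.rate / 2:
        sos = signal.butter(2, lowpass_hz, btype="low", fs=trace.rate, output="sos")
        f = signal.sosfiltfilt(sos, f)
    f = f[::downsample]
    t = trace.times[::downsample]
    sel = t >= t_start_s
    t, f = t[sel], f[sel]
    if np.any(f <= 0):
        raise ValueError("non-positive values after conditioning")
    res = stats.linregress(np.log10(t), np.log10(f))
    return float(res.slope)


def power_correct(values: np.ndarray, powers: np.ndarray,
                  p_ref: float | None = None, normalize: bool = True) -> np.ndarray:
    """Correct a per-wavelength spectrum for illumination-power jitter,
    assuming fluorescence scales with the square of excitation power.

    corrected = value * (P_ref / P)^2, then normalised to its maximum.
    """
    values = np.asarray(values, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if np.any(powers <= 0):
        raise ValueError("powers must be positive")
    if p_ref is None:
        p_ref = powers[0]
    out = values * (p_ref / powers) ** 2
    if normalize and np.max(np.abs(out)) > 0:
        out = out / out.max()
    return out
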