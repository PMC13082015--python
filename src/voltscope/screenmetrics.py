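"""High-throughput screening scoreboard.

Per-FOV metrics for indicator ranking: relative brightness B against a
co-expressed red reference protein, field-stimulation response amplitude R,
photostability AUC fraction P, and the compound detectability index (DI) and
detectability budget (DB).  FOV records aggregate to wells by pixel-count
weighting.

The printed DI/DB formulas lost their formatting in transit; both the
square-root-brightness convention (default, DI = R*sqrt(B)) and the linear
convention (DI = R*B) are supported via ``brightness_exponent``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Trace

__all__ = [
    "ScreenRecord",
    "relative_brightness",
    "response_amplitude",
    "photostability_auc",
    "detectability",
    "aggregate_well",
]


@dataclass
class ScreenRecord:
    B: float = np.nan          # relative brightness (GEVI / reference)
    R: float = np.nan          # peak response amplitude
    P: float = np.nan          # photostability AUC fraction in (0, 1]
    DI: float = np.nan
    DB: float = np.nan
    n_pixels: int = 0
    flags: tuple = ()

    @property
    def fov_area_weight(self) -> float:
        return float(self.n_pixels)


def relative_brightness(green: Trace, red: Trace, n_frames: int = 20) -> float:
    """B = mean of the first ``n_frames`` green-channel frames over the same
    mean in the red (reference) channel.  Both traces must be
    background-corrected."""
    if green.n < n_frames or red.n < n_frames:
        raise ValueError(f"traces must contain at least {n_frames} frames")
    red_mean = red.data[:n_frames].mean()
    if red_mean <= 0:
        raise ValueError("reference-channel mean must be positive")
    return float(green.data[:n_frames].mean() / red_mean)


def response_amplitude(dff_corrected: Trace, pulse_time_s: float,
                       response_window_s: float = 0.25,
                       baseline_s: float = 0.1) -> float:
    """Peak stimulation response R = max ΔF/F0 in the response window minus
    the SD of the F0-normalised pre-pulse baseline.

    F0 is the mean of the first 100 ms of the bleach-corrected trace; Fpre is
    the 100 ms immediately preceding the pulse.  The SD subtraction accounts
    for baseline fluctuations (a noiseless step from F0=1 to F=1.5 scores
    R = 0.5).
    """
    t = dff_corrected.times
    f = dff_corrected.data
    nb = max(2, int(round(baseline_s * dff_corrected.rate)))
    f0 = f[:nb].mean()
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    norm = f / f0 - 1.0
    pre = (t >= pulse_time_s - baseline_s) & (t < pulse_time_s)
    resp = (t >= pulse_time_s) & (t <= pulse_time_s + response_window_s)
    if not resp.any() or not pre.any():
        raise IndexError("pulse window outside trace")
    return float(norm[resp].max() - norm[pre].std())


def photostability_auc(f_norm: Trace) -> float:
    """P = trapezoid AUC of the normalised fluorescence-vs-time trace divided
    by the AUC of an ideal non-bleaching indicator (a line at y = 1) over the
    same duration.  The input must be normalised to 1 at t = 0."""
    if abs(f_norm.data[0] - 1.0) > 1e-6:
        raise ValueError("trace must be normalised to 1 at t=0")
    t = f_norm.times
    auc = np.trapezoid(f_norm.data, t)
    return float(auc / (t[-1] - t[0]))


def detectability(record: ScreenRecord,
                  brightness_exponent: float = 0.5) -> tuple:
    """Compound screening metrics from B, R, P.

    DI = R * B**e and DB = R * (B*P)**e with e = ``brightness_exponent``
    (default 1/2).  DB replaces the initial brightness with the bleach-
    averaged brightness B*P, since P is the normalised bleaching AUC.
    """
    if record.B < 0:
        raise ValueError("negative brightness")
    e = brightness_exponent
    di = record.R * record.B ** e
    db = record.R * (record.B * record.P) ** e
    return float(di), float(db)


def aggregate_well(fov_records, brightness_exponent: float = 0.5) -> ScreenRecord:
    """Pixel-count-weighted mean of all metrics across the surviving FOVs of
    a well.  Rejected FOVs (n_pixels below threshold) should be filtered out
    by the caller; an empty list flags the well with no score."""
    records = [r for r in fov_records if r.n_pixels > 0]
    if not records:
        return ScreenRecord(flags=("all_fovs_rejected",))
    w = np.array([r.fov_area_weight for r in records])
    w = w / w.sum()
    agg = ScreenRecord(
        B=float(np.dot(w, [r.B for r in records])),
        R=float(np.dot(w, [r.R for r in records])),
        P=float(np.dot(w, [r.P for r in records])),
        n_pixels=int(sum(r.n_pixels for r in records)),
    )
    agg.DI, agg.DB = detectability(agg, brightness_exponent)
    return agg
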