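"""Ground-truth evaluation of optical spike detection.

Electrophysiological spike times (10 kHz class) are mapped to imaging frame
centers; a detected optical spike matches a truth spike if it falls in the
same or one of the two subsequent frames.  Matching is greedy earliest-first
and one-to-one.  Precision-recall curves sweep the adaptive-threshold scale
factor over 0.1-2.2, reporting per-recording and pooled best scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detect import AdaptiveConfig, detect_adaptive_kde
from .types import SpikeTrain, Trace

__all__ = [
    "MatchResult",
    "PRCurve",
    "map_to_frames",
    "exclude_bursts",
    "match_spikes",
    "pr_curve",
    "prf1",
    "subthreshold_correspondence",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list                  # (truth_time_s, optical_time_s)
    tolerance_frames: int = 2
    flags: tuple = ()

    @property
    def precision(self) -> float:
        return 1.0 if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return np.nan
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(r) or p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


def prf1(tp: int, fp: int, fn: int) -> tuple:
    """Precision, recall, F1 with the zero-division conventions: precision=1
    when nothing was detected, recall=0 when truth exists but none matched,
    F1=0 when P+R=0."""
    p = 1.0 if tp + fp == 0 else tp / (tp + fp)
    r = np.nan if tp + fn == 0 else tp / (tp + fn)
    f1 = 0.0 if (np.isnan(r) or p + r == 0) else 2 * p * r / (p + r)
    return p, r, f1


def map_to_frames(times_s: np.ndarray, frame_rate: float) -> np.ndarray:
    """Map event times to the index of the nearest imaging frame center."""
    t = np.asarray(times_s, dtype=float)
    return np.round(t * frame_rate - 0.5).astype(int)


def exclude_bursts(truth_times_s: np.ndarray, isi_cutoff_s: float = 0.1):
    """Split truth spikes into singlets and burst-region spikes.

    Any spike within ``isi_cutoff_s`` of a neighbour belongs to a burst
    region (doublets included) and is excluded from evaluation.
    """
    t = np.sort(np.asarray(truth_times_s, dtype=float))
    if t.size == 0:
        return t, t
    near_prev = np.concatenate([[False], np.diff(t) < isi_cutoff_s])
    near_next = np.concatenate([np.diff(t) < isi_cutoff_s, [False]])
    burst = near_prev | near_next
    return t[~burst], t[burst]


def match_spikes(truth_times_s: np.ndarray, optical: SpikeTrain,
                 frame_rate: float, tolerance_frames: int = 2,
                 isi_cutoff_s: float = 0.1) -> MatchResult:
    """Match ground-truth spikes to detected optical spikes.

    Truth times are singlet-filtered (burst regions excluded), mapped to
    frame centers, and matched greedily earliest-first: each truth spike
    takes the earliest unused optical spike in the same or the following
    ``tolerance_frames`` frames.  Detections inside the excluded burst
    regions (± the ISI cutoff around burst spikes) are removed from
    evaluation entirely, so real burst spikes do not count as false
    positives.  TP+FN equals the number of evaluated truth singlets; each
    spike is used at most once.
    """
    singlets, burst = exclude_bursts(truth_times_s, isi_cutoff_s)
    flags = ()
    if singlets.size == 0:
        flags = ("empty_truth",)
    opt_times = np.asarray(optical.times_s, float)
    if burst.size and opt_times.size:
        near_burst = np.min(np.abs(opt_times[:, None] - burst[None, :]),
                            axis=1) <= isi_cutoff_s
        opt_times = opt_times[~near_burst]
    tf = map_to_frames(singlets, frame_rate)
    of = map_to_frames(opt_times, frame_rate)
    used = np.zeros(of.size, dtype=bool)
    pairs = []
    tp = 0
    for i, f in enumerate(tf):
        cand = np.flatnonzero((~used) & (of >= f) & (of <= f + tolerance_frames))
        if cand.size:
            j = cand[0]
            used[j] = True
            tp += 1
            pairs.append((float(singlets[i]), float(opt_times[j])))
    fn = tf.size - tp
    fp = int((~used).sum())
    return MatchResult(tp, fp, fn, pairs, tolerance_frames, flags)


@dataclass
class PRCurve:
    scales: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    best_scale: float
    counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    degenerate: bool = False


def pr_curve(truth_times_s, trace: Trace, frame_rate: float | None = None,
             scales=None, cfg: AdaptiveConfig | None = None,
             tolerance_frames: int = 2) -> PRCurve:
    """Precision-recall curve over adaptive-threshold scale factors.

    ``truth_times_s`` may be a single array (one recording) or a list of
    arrays paired with a list of traces, in which case TP/FP/FN counts are
    summed across recordings at each scale before computing the metrics (the
    multi-recording pooling rule).  The best scale maximises the (pooled) F1.
    """
    if scales is None:
        scales = np.round(np.arange(0.1, 2.2001, 0.1), 10)
    scales = np.asarray(scales, dtype=float)
    cfg = cfg or AdaptiveConfig()
    single = not isinstance(trace, (list, tuple))
    traces = [trace] if single else list(trace)
    truths = [truth_times_s] if single else list(truth_times_s)
    fr = frame_rate or traces[0].rate

    counts = np.zeros((scales.size, 3), dtype=int)
    for tr, tt in zip(traces, truths):
        for si, s in enumerate(scales):
            c = AdaptiveConfig(hp_hz=cfg.hp_hz, p=cfg.p, scale=float(s),
                               grid_points=cfg.grid_points,
                               min_peaks=cfg.min_peaks,
                               min_separation=cfg.min_separation)
            train = detect_adaptive_kde(tr, c)
            m = match_spikes(tt, train, fr, tolerance_frames)
            counts[si] += (m.tp, m.fp, m.fn)
    prf = np.array([prf1(*row) for row in counts])
    f1 = prf[:, 2]
    degenerate = bool(np.all(counts[:, 0] + counts[:, 1] == 0))
    best = float(scales[int(np.argmax(f1))])
    return PRCurve(scales, prf[:, 0], prf[:, 1], f1, best, counts, degenerate)


def subthreshold_correspondence(ephys: Trace, dff: Trace, bins: int = 150,
                                lowpass_hz: float = 50.0):
    """Joint statistics of subthreshold voltage and fluorescence.

    Both traces are low-pass filtered at 50 Hz; the fluorescence trace is
    linearly interpolated onto the electrophysiology time base.  Returns the
    (bins x bins) joint histogram normalised to a probability distribution,
    the bin edges, and the linear-regression slope in ΔF/F per mV.
    """
    from scipy import signal as sps

    if np.std(ephys.data) == 0:
        raise ValueError("constant voltage: slope undefined")

    def lp(tr: Trace):
        if lowpass_hz >= tr.rate / 2:
            return tr.data
        sos = sps.butter(2, lowpass_hz, btype="low", fs=tr.rate, output="sos")
        return sps.sosfiltfilt(sos, tr.data)

    v = lp(ephys)
    f = np.interp(ephys.times, dff.times, lp(dff))
    hist, xe, ye = np.histogram2d(v, f, bins=bins)
    hist = hist / hist.sum()
    slope = stats.linregress(v, f).slope
    return hist, (xe, ye), float(slope)
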