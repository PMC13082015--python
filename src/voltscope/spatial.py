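"""Freely-moving spatial analyses.

Kinematics from tracked points (speed from the tracked scope position,
head direction from the ear vector), occupancy-normalised firing-rate maps,
the border score, and circular-shift shuffle significance testing.

Conventions: 2.5 cm square bins, Gaussian smoothing with a 3 cm standard
deviation, bins visited for >= 0.1 s, samples at running speed below
2.5 cm/s excluded from map construction.  Border fields are contiguous
regions of >= 9 bins with rates >= 30 % of the session peak (on the
smoothed map); the score is (c - d) / (c + d) with c the maximum
single-wall coverage and d the rate-weighted mean field distance to the
nearest wall, normalised by half the arena extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import Trace

__all__ = [
    "BehaviorTrack",
    "RateMap",
    "BorderResult",
    "compute_kinematics",
    "rate_map",
    "border_score",
    "shuffle_test",
]


@dataclass
class BehaviorTrack:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray            # cm/s, 0.5-s smoothed
    head_direction_deg: np.ndarray | None = None
    rate: float = 30.0


@dataclass
class RateMap:
    rate: np.ndarray             # Hz, smoothed; NaN on unvisited bins
    rate_raw: np.ndarray         # Hz, unsmoothed
    occupancy_s: np.ndarray
    spike_counts: np.ndarray
    visited: np.ndarray
    bin_size_cm: float
    arena_cm: float


@dataclass
class BorderResult:
    score: float
    field_labels: np.ndarray
    n_fields: int
    wall_coverage: np.ndarray    # per wall (left, right, bottom, top)
    mean_firing_distance: float  # normalised to half arena extent
    flags: tuple = ()
    shuffle_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))


def compute_kinematics(t, positions: dict, likelihoods: dict | None = None,
                       target_rate: float | None = None,
                       likelihood_min: float = 0.7,
                       smooth_s: float = 0.5) -> BehaviorTrack:
    """Speed and heading from tracked body points.

    ``positions`` maps point name -> (n, 2) array in cm; the point named
    ``"scope"`` (or the first point) provides the position for speed.  Points
    with likelihood <= 0.7 are dropped and linearly interpolated; the track
    is optionally upsampled to ``target_rate`` by linear interpolation.
    Speed is the per-frame Euclidean step over the inter-frame interval,
    smoothed with a 0.5-s moving average.  If both ears are tracked, head
    direction is 90° counterclockwise from the left-ear -> right-ear vector.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("at least 2 frames required")

    def clean(name):
        p = np.asarray(positions[name], dtype=float).copy()
        if likelihoods and name in likelihoods:
            bad = np.asarray(likelihoods[name]) <= likelihood_min
            p[bad] = np.nan
        for d in range(2):
            col = p[:, d]
            nans = np.isnan(col)
            if nans.all():
                raise ValueError(f"no valid samples for point {name!r}")
            col[nans] = np.interp(t[nans], t[~nans], col[~nans])
        return p

    key = "scope" if "scope" in positions else next(iter(positions))
    pos = clean(key)
    if target_rate is not None:
        tn = np.arange(t[0], t[-1], 1.0 / target_rate)
        pos = np.column_stack([np.interp(tn, t, pos[:, d]) for d in range(2)])
        t_out = tn
    else:
        t_out = t
    dt = np.diff(t_out)
    step = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    speed = np.concatenate([[0.0], step / dt])
    rate = 1.0 / np.median(dt)
    w = max(1, int(round(smooth_s * rate)))
    speed = np.convolve(speed, np.ones(w) / w, mode="same")

    hd = None
    if "left_ear" in positions and "right_ear" in positions:
        le, re = clean("left_ear"), clean("right_ear")
        if target_rate is not None:
            le = np.column_stack([np.interp(t_out, t, le[:, d]) for d in range(2)])
            re = np.column_stack([np.interp(t_out, t, re[:, d]) for d in range(2)])
        v = re - le
        hd = np.rad2deg(np.arctan2(v[:, 1], v[:, 0])) + 90.0
        hd = np.mod(hd, 360.0)
    return BehaviorTrack(t_out, pos[:, 0], pos[:, 1], speed, hd, rate)


def rate_map(track: BehaviorTrack, spike_times_s: np.ndarray,
             arena_cm: float = 80.0, bin_cm: float = 2.5,
             smooth_cm: float = 3.0, min_occupancy_s: float = 0.1,
             speed_min_cm_s: float = 2.5) -> RateMap:
    """Occupancy-normalised firing-rate map.

    Samples below the running-speed threshold are excluded; spikes are
    assigned the interpolated animal position at their time.  The raw map is
    spikes/occupancy on visited bins (>= 0.1 s); the smoothed map applies a
    Gaussian of ``smooth_cm`` SD with unvisited bins masked (NaN).
    """
    n_bins = int(np.ceil(arena_cm / bin_cm))
    moving = track.speed >= speed_min_cm_s
    if not moving.any():
        raise ValueError("no samples above the speed threshold")
    dt = 1.0 / track.rate

    def binned(xs, ys):
        bx = np.clip((xs / bin_cm).astype(int), 0, n_bins - 1)
        by = np.clip((ys / bin_cm).astype(int), 0, n_bins - 1)
        return by, bx

    by, bx = binned(track.x[moving], track.y[moving])
    occ = np.zeros((n_bins, n_bins))
    np.add.at(occ, (by, bx), dt)
    if not (occ > 0).any():
        raise ValueError("zero occupancy everywhere")

    st = np.asarray(spike_times_s, dtype=float)
    sx = np.interp(st, track.t, track.x)
    sy = np.interp(st, track.t, track.y)
    ssp = np.interp(st, track.t, track.speed)
    sel = ssp >= speed_min_cm_s
    sby, sbx = binned(sx[sel], sy[sel])
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (sby, sbx), 1.0)

    visited = occ >= min_occupancy_s
    raw = np.full((n_bins, n_bins), np.nan)
    raw[visited] = counts[visited] / occ[visited]

    sigma_bins = smooth_cm / bin_cm
    filled = np.where(visited, raw, 0.0)
    weight = visited.astype(float)
    sm_num = ndimage.gaussian_filter(filled, sigma_bins)
    sm_den = ndimage.gaussian_filter(weight, sigma_bins)
    smooth = np.full_like(raw, np.nan)
    ok = visited & (sm_den > 0)
    smooth[ok] = sm_num[ok] / sm_den[ok]
    return RateMap(smooth, raw, occ, counts, visited, bin_cm, arena_cm)


def _detect_fields(rate: np.ndarray, visited: np.ndarray,
                   peak_fraction: float = 0.3, min_bins: int = 9):
    peak = np.nanmax(rate)
    if not np.isfinite(peak) or peak <= 0:
        return np.zeros_like(visited, dtype=int), 0
    mask = visited & (np.nan_to_num(rate) >= peak_fraction * peak)
    labels, n = ndimage.label(mask,
                              structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    out = np.zeros_like(labels)
    nf = 0
    for lb in range(1, n + 1):
        if (labels == lb).sum() >= min_bins:
            nf += 1
            out[labels == lb] = nf
    return out, nf


def border_score(rmap: RateMap, peak_fraction: float = 0.3,
                 min_field_bins: int = 9) -> BorderResult:
    """Border score of a rate map.

    Firing fields are 4-connected regions of >= ``min_field_bins`` bins at
    >= 30 % of the session peak (smoothed map).  For each wall the coverage
    is the fraction of valid (visited) wall-edge bins touched by a field;
    c = max coverage over the four walls.  d = rate-weighted mean distance
    of field bins to the nearest wall, normalised by half the arena extent.
    Score = (c - d) / (c + d), in [-1, 1].
    """
    labels, nf = _detect_fields(rmap.rate, rmap.visited,
                                peak_fraction, min_field_bins)
    if nf == 0:
        return BorderResult(np.nan, labels, 0, np.zeros(4), np.nan,
                            flags=("no_field",))
    n = rmap.rate.shape[0]
    infield = labels > 0
    walls = {
        "left": (slice(None), 0), "right": (slice(None), n - 1),
        "bottom": (0, slice(None)), "top": (n - 1, slice(None)),
    }
    cov = []
    for sl in walls.values():
        valid = rmap.visited[sl]
        if valid.sum() == 0:
            cov.append(0.0)
        else:
            cov.append(float((infield[sl] & valid).sum() / valid.sum()))
    c_max = max(cov)
    yy, xx = np.indices(rmap.rate.shape)
    # distance of a bin center to the nearest wall, in bins
    dist = np.minimum.reduce([yy, xx, n - 1 - yy, n - 1 - xx]) + 0.5
    w = np.nan_to_num(rmap.rate) * infield
    d_mean = float((dist * w).sum() / w.sum())
    d_norm = d_mean / (n / 2.0)
    score = (c_max - d_norm) / (c_max + d_norm) if (c_max + d_norm) > 0 else np.nan
    return BorderResult(float(score), labels, nf, np.asarray(cov), d_norm)


def shuffle_test(track: BehaviorTrack, spike_times_s: np.ndarray, score_fn,
                 n_shuffles: int = 200, margin_s: float = 30.0,
                 percentile: float = 95.0, score_floor: float | None = 0.5,
                 seed: int = 0):
    """Circular-shift shuffle significance test for spatial tuning.

    The spike sequence is circularly time-shifted along the trajectory by a
    random interval in [margin, T - margin], ``n_shuffles`` times; the
    observed score is compared with the null distribution's 95th percentile.
    For border tuning the verdict additionally requires the observed score
    above ``score_floor`` (0.5); pass ``score_floor=None`` to disable.

    Returns ``(observed, null_scores, verdict)``.
    """
    T = float(track.t[-1] - track.t[0])
    if T <= 2 * margin_s:
        raise ValueError("session too short for the shuffle margins")
    rng = np.random.default_rng(seed)
    st = np.asarray(spike_times_s, dtype=float)
    observed = score_fn(track, st)
    null = np.empty(n_shuffles)
    t0 = track.t[0]
    for i in range(n_shuffles):
        shift = rng.uniform(margin_s, T - margin_s)
        assert margin_s <= shift <= T - margin_s
        shifted = t0 + np.mod(st - t0 + shift, T)
        null[i] = score_fn(track, np.sort(shifted))
    thresh = np.nanpercentile(null, percentile)
    verdict = bool(np.isfinite(observed) and observed > thresh)
    if score_floor is not None:
        verdict = verdict and observed > score_floor
    return float(observed), null, verdict
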