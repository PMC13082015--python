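"""Synthetic GEVI data generation with exact ground truth.

Every downstream stage of the pipeline (spike detection, kinetics fitting,
tuning maps, rate maps) is exercised on data from this module, so each
generator records the parameters it injected.  The physical chain is

    membrane voltage  ->  steady-state ΔF/F (logistic sigmoid)
                      ->  kinetic relaxation (direction-dependent taus)
                      ->  photon emission (Poisson at the frame rate,
                          multiplied by a multi-exponential bleach curve)
                      ->  optional movie rendering with motion and neuropil.

Kinetic relaxation uses the exact exponential update per simulation step
(not forward Euler), so a single-component model reproduces the analytic RC
charge/discharge to machine precision.
"""

from __future__ import annotations

import numpy as np

from .types import GEVIModel, GroundTruth, Movie, SceneSpec, Trace, VoltageSim

__all__ = [
    "default_force1s_model",
    "spike_waveform",
    "simulate_voltage",
    "voltage_to_dff",
    "emit_photons",
    "render_movie",
    "simulate_population",
]

REST_MV = -70.0
#: 1-s step levels of the voltage-clamp F-V protocol, in mV.
STEP_LEVELS_MV = (90, 70, 50, 30, 20, 0, -20, -40, -60, -80, -100, -120)

# Logistic sigmoid anchored by least squares to the indicator's steady-state
# responses from a -70 mV rest (ΔF/F 0.874 at -40 mV, 2.27 at 0 mV) with
# dff(-70) pinned to 0.  A fixture for testing, not a re-measurement.
_SIGMOID_L = 7.0631371
_SIGMOID_K = 0.020231
_SIGMOID_X0 = -10.0
_SIGMOID_B = -1.6175909194675964


def default_force1s_model(flux: float = 100_000.0, bleach=()) -> GEVIModel:
    """A FORCE1s-like forward model: anchored sigmoid, 2.8-ms on kinetics,
    2.4/9.1-ms equally weighted off kinetics."""
    return GEVIModel(
        L=_SIGMOID_L, k_slope=_SIGMOID_K, x0=_SIGMOID_X0, b=_SIGMOID_B,
        tau_on_ms=((2.8, 1.0),),
        tau_off_ms=((2.4, 0.5), (9.1, 0.5)),
        baseline_flux_photons_per_s=flux,
        bleach=tuple(bleach),
    )


def spike_waveform(sim_rate: float, amplitude_mv: float = 100.0,
                   fwhm_ms: float = 2.0, window_ms: float = 12.0) -> np.ndarray:
    """An action-potential-like transient: Gaussian rise/decay with the
    requested amplitude and full width at half maximum.

    Returns the additive voltage waveform (mV, peak at the centre sample).
    """
    sigma_s = (fwhm_ms / 1000.0) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(round(window_ms / 2000.0 * sim_rate))
    t = np.arange(-half, half + 1) / sim_rate
    return amplitude_mv * np.exp(-0.5 * (t / sigma_s) ** 2)


def _add_spikes(v: np.ndarray, spike_times: np.ndarray, sim_rate: float,
                amplitude_mv: float, fwhm_ms: float) -> None:
    wav = spike_waveform(sim_rate, amplitude_mv, fwhm_ms)
    half = wav.size // 2
    for ts in spike_times:
        i = int(round(ts * sim_rate))
        lo, hi = i - half, i + half + 1
        wlo = max(0, -lo)
        whi = wav.size - max(0, hi - v.size)
        v[max(0, lo):min(v.size, hi)] += wav[wlo:whi]


def _poisson_times_thinned(rate_hz: float, duration_s: float,
                           refractory_s: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike times with a hard refractory gap."""
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if t >= duration_s:
            break
        if not times or t - times[-1] >= refractory_s:
            times.append(t)
    return np.asarray(times)


def _ou_process(n: int, dt: float, tau_s: float, sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck noise with stationary SD ``sigma`` via the exact
    discrete update."""
    x = np.empty(n)
    a = np.exp(-dt / tau_s)
    sd_step = sigma * np.sqrt(1.0 - a * a)
    x[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, sd_step, size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def simulate_voltage(protocol: str, sim_rate: float = 10_000.0, seed: int = 0,
                     **kw) -> VoltageSim:
    """Simulate a membrane-potential trace under one of four protocols.

    Parameters
    ----------
    protocol : {"steps", "spike_train", "burst_on_up_state", "spontaneous"}
        * ``steps`` — hold at −70 mV with 1-s steps at the clamp levels
          (90 … −120 mV), 1 s at rest between steps, 4-s initial hold.
        * ``spike_train`` — AP waveforms (default 100 mV amplitude, 2 ms
          FWHM) at ``spike_times_s`` or ``(n_spikes, rate_hz)``.
        * ``burst_on_up_state`` — a sustained ~24 mV subthreshold
          depolarisation carrying a burst of spikes.
        * ``spontaneous`` — Poisson spikes (``rate_hz``) riding on
          Ornstein-Uhlenbeck subthreshold noise (``ou_tau_s``, ``ou_sigma_mv``).
    sim_rate : Hz, must be >= 2000.
    seed : RNG seed for the stochastic protocols.

    Returns a :class:`VoltageSim` with exact ground-truth spike times.
    """
    if sim_rate < 2000:
        raise ValueError("sim_rate must be >= 2 kHz to resolve AP waveforms")
    rng = np.random.default_rng(seed)
    amplitude = float(kw.get("amplitude_mv", 100.0))
    fwhm = float(kw.get("fwhm_ms", 2.0))

    if protocol == "steps":
        hold_s = float(kw.get("hold_s", 4.0))
        step_s = float(kw.get("step_s", 1.0))
        gap_s = float(kw.get("gap_s", 1.0))
        levels = kw.get("levels_mv", STEP_LEVELS_MV)
        segs = [np.full(int(hold_s * sim_rate), REST_MV)]
        for lv in levels:
            segs.append(np.full(int(step_s * sim_rate), float(lv)))
            segs.append(np.full(int(gap_s * sim_rate), REST_MV))
        v = np.concatenate(segs)
        spike_times = np.empty(0)
        up = []
    elif protocol == "spike_train":
        duration = float(kw.get("duration_s", 0.0))
        if "spike_times_s" in kw:
            spike_times = np.sort(np.asarray(kw["spike_times_s"], dtype=float))
        else:
            n_spk = int(kw.get("n_spikes", 5))
            rate = float(kw.get("rate_hz", 2.0))
            t0 = float(kw.get("first_spike_s", 0.5))
            spike_times = t0 + np.arange(n_spk) / rate
        if duration <= 0:
            duration = (spike_times[-1] + 0.5) if spike_times.size else 1.0
        v = np.full(int(duration * sim_rate), REST_MV)
        _add_spikes(v, spike_times, sim_rate, amplitude, fwhm)
        up = []
    elif protocol == "burst_on_up_state":
        duration = float(kw.get("duration_s", 3.0))
        up_start = float(kw.get("up_start_s", 1.0))
        up_dur = float(kw.get("up_duration_s", 1.0))
        up_mv = float(kw.get("up_mv", 24.0))
        n_spk = int(kw.get("n_spikes", 4))
        burst_rate = float(kw.get("burst_rate_hz", 100.0))
        v = np.full(int(duration * sim_rate), REST_MV)
        i0, i1 = int(up_start * sim_rate), int((up_start + up_dur) * sim_rate)
        ramp = int(0.02 * sim_rate)  # 20-ms edges so the plateau is not a step
        env = np.zeros(v.size)
        env[i0:i1] = 1.0
        if ramp > 1:
            k = np.ones(ramp) / ramp
            env = np.convolve(env, k, mode="same")
        v += up_mv * env
        spike_times = up_start + 0.2 + np.arange(n_spk) / burst_rate
        # spikes ride on the plateau: 60-90 mV from the depolarised level
        _add_spikes(v, spike_times, sim_rate,
                    float(kw.get("burst_spike_mv", 76.0)), 1.8)
        up = [(up_start, up_start + up_dur)]
    elif protocol == "spontaneous":
        duration = float(kw.get("duration_s", 60.0))
        rate = float(kw.get("rate_hz", 5.0))
        refr = float(kw.get("refractory_s", 0.01))
        spike_times = _poisson_times_thinned(rate, duration, refr, rng)
        n = int(duration * sim_rate)
        v = np.full(n, REST_MV)
        v += _ou_process(n, 1.0 / sim_rate, float(kw.get("ou_tau_s", 0.05)),
                         float(kw.get("ou_sigma_mv", 3.0)), rng)
        _add_spikes(v, spike_times, sim_rate, amplitude, fwhm)
        up = []
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    t = np.arange(v.size) / sim_rate
    return VoltageSim(t, v, spike_times, up, sim_rate)


def _kinetic_tracks(model: GEVIModel):
    """Zip on/off component lists into (tau_on, tau_off, weight) tracks.

    Singleton lists broadcast across the other direction's components;
    weights come from the multi-component side.  Unequal multi-component
    lengths have no stated mixing rule and are rejected.
    """
    on, off = list(model.tau_on_ms), list(model.tau_off_ms)
    if len(on) == len(off):
        return [(on[i][0], off[i][0], off[i][1]) for i in range(len(on))]
    if len(on) == 1:
        return [(on[0][0], t, w) for t, w in off]
    if len(off) == 1:
        return [(t, off[0][0], w) for t, w in on]
    raise ValueError("on/off component lists of unequal length > 1 are ambiguous")


def voltage_to_dff(v: VoltageSim, model: GEVIModel) -> Trace:
    """Convert a voltage trace to ΔF/F through the indicator forward model.

    The steady-state target is the sigmoid evaluated at each sample; each
    kinetic track relaxes toward it with the exact exponential update, using
    tau_on when the target is above the current state (depolarising /
    brightening direction) and tau_off otherwise.  The output is the
    weight-summed track state, initialised at steady state.
    """
    target = model.sigmoid(v.v_mV)
    dt = 1.0 / v.sim_rate
    tracks = _kinetic_tracks(model)
    out = np.zeros(target.size)
    for tau_on, tau_off, w in tracks:
        a_on = np.exp(-dt / (tau_on / 1000.0))
        a_off = np.exp(-dt / (tau_off / 1000.0))
        f = np.empty(target.size)
        f[0] = target[0]
        state = f[0]
        for i in range(1, target.size):
            s = target[i]
            a = a_on if s > state else a_off
            state = s + (state - s) * a
            f[i] = state
        out += w * f
    return Trace(out, v.sim_rate, units="dff", provenance="voltage_to_dff")


def emit_photons(dff: Trace, model: GEVIModel, frame_rate: float,
                 seed: int = 0) -> Trace:
    """Integrate a ΔF/F trace into Poisson photon counts per imaging frame.

    The expected count of frame ``i`` is ``flux * dt * mean(1 + dff) *
    bleach(t_i)`` over the frame's samples.  Negative expected rates (ΔF/F
    below −1) are a physical model error.
    """
    if frame_rate > dff.rate + 1e-9:
        raise ValueError("frame_rate must not exceed the dff sampling rate")
    rel = 1.0 + dff.data
    if np.any(rel < 0):
        raise ValueError("1 + dff < 0: negative photon rate is unphysical")
    # frame edges in sample units keep the nominal frame rate exact even when
    # the rate ratio is not an integer (frames then span 22/23 samples etc.)
    ratio = dff.rate / frame_rate
    n_frames = int(np.floor(dff.n / ratio))
    edges = np.floor(np.arange(n_frames + 1) * ratio).astype(int)
    csum = np.cumsum(np.insert(rel, 0, 0.0))
    widths = np.diff(edges)
    rel_mean = (csum[edges[1:]] - csum[edges[:-1]]) / np.maximum(widths, 1)
    t = (np.arange(n_frames) + 0.5) / frame_rate
    mu = (model.baseline_flux_photons_per_s / frame_rate) * rel_mean \
        * model.bleach_curve(t)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu).astype(float)
    return Trace(counts, frame_rate, units="photons", provenance="emit_photons")


def _disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def render_movie(scene: SceneSpec, dff_traces: np.ndarray,
                 model: GEVIModel | None = None, frame_rate: float = 440.0,
                 noise: bool = True):
    """Render a synthetic movie from per-cell ΔF/F traces.

    Parameters
    ----------
    scene : cell layout, neuropil gain, per-frame (dy, dx) motion, seed.
    dff_traces : (n_cells, n_frames) ΔF/F of each cell.
    model : supplies the baseline photon flux; default FORCE1s-like model.
    noise : if True, per-pixel Poisson noise is applied.

    Returns ``(Movie, masks, GroundTruth)``; masks are the *unshifted* cell
    footprints and the injected shift table is recorded in the ground truth.
    """
    model = model or default_force1s_model()
    dff_traces = np.atleast_2d(np.asarray(dff_traces, dtype=float))
    n_cells, n_frames = dff_traces.shape
    if n_cells != len(scene.cell_centers):
        raise ValueError("one dff trace per cell required")
    shifts = (np.zeros((n_frames, 2)) if scene.motion is None
              else np.asarray(scene.motion, dtype=float))
    if shifts.shape != (n_frames, 2):
        raise ValueError("motion table must be (n_frames, 2)")

    per_px = model.baseline_flux_photons_per_s / frame_rate / 100.0
    masks = [_disk_mask(scene.shape, c, r)
             for c, r in zip(scene.cell_centers, scene.cell_radii)]
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((n_frames,) + tuple(scene.shape))
    neuropil = scene.neuropil_gain * per_px
    for f in range(n_frames):
        img = np.full(scene.shape, neuropil, dtype=float)
        dy, dx = shifts[f]
        for c, (center, r) in enumerate(zip(scene.cell_centers, scene.cell_radii)):
            m = _disk_mask(scene.shape, (center[0] + dy, center[1] + dx), r)
            img[m] += per_px * (1.0 + dff_traces[c, f])
        frames[f] = rng.poisson(img) if noise else img
    movie = Movie(frames, frame_rate)
    truth = GroundTruth(shifts=shifts, dff_traces=dff_traces,
                        params={"flux_per_pixel": per_px,
                                "neuropil_gain": scene.neuropil_gain})
    return movie, masks, truth


# ---------------------------------------------------------------------------
# population-level generators


def _grating_schedule(n_directions: int, n_trials: int, blank_s: float = 0.5,
                      stim_s: float = 0.5, rng=None):
    """Interleaved drifting-grating schedule: per-trial (onset, offset,
    direction_deg) with a blank before each presentation."""
    dirs = np.arange(n_directions) * (360.0 / n_directions)
    order = np.tile(dirs, n_trials)
    if rng is not None:
        rng.shuffle(order)
    onsets = blank_s + np.arange(order.size) * (blank_s + stim_s)
    return np.column_stack([onsets, onsets + stim_s, order])


def simulate_population(kind: str, params: dict | None = None, seed: int = 0):
    """Generate a population-level dataset with known functional structure.

    kind = "grating_tuned"
        Orientation-tuned ΔF/F responses to an interleaved drifting-grating
        schedule (0.5-s blank + 0.5-s motion per trial).  Tuning follows a
        von Mises profile on orientation (period π) with concentration
        ``kappa``.  Returns ``(dff (n_cells, n_frames), schedule,
        GroundTruth)`` where the truth records each cell's preferred
        orientation in degrees.

    kind = "ach_coupled"
        A slow (0.1-1 Hz) neuromodulator oscillation whose phase gates the
        amplitude of 2-10 Hz voltage-band activity with an injected phase
        lag.  Returns ``(voltage Trace, modulator Trace, GroundTruth)``.

    kind = "arena_border"
        An open-field random-foraging trajectory in an 80x80 cm arena and an
        inhomogeneous-Poisson spike train from a wall-tuned (or central)
        firing-rate field.  Returns ``(track dict, spike_times, GroundTruth)``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "grating_tuned":
        n_dir = int(p.get("n_directions", 8))
        n_tr = int(p.get("n_trials", 10))
        fr = float(p.get("frame_rate", 115.0))
        kappa = float(p.get("kappa", 2.0))
        n_cells = int(p.get("n_cells", 8))
        amp = float(p.get("amplitude", 1.0))
        noise_sd = float(p.get("noise_sd", 0.1))
        tau = float(p.get("tau_s", 0.7))
        sched = _grating_schedule(n_dir, n_tr,
                                  float(p.get("blank_s", 0.5)),
                                  float(p.get("stim_s", 0.5)),
                                  rng if p.get("shuffle", True) else None)
        duration = sched[-1, 1] + 0.5
        n_frames = int(duration * fr)
        t = (np.arange(n_frames) + 0.5) / fr
        prefs = p.get("preferred_deg")
        if prefs is None:
            prefs = rng.uniform(0, 180, size=n_cells)
        prefs = np.asarray(prefs, dtype=float)
        n_cells = prefs.size
        dff = rng.normal(0.0, noise_sd, size=(n_cells, n_frames))
        pref_rad = np.deg2rad(prefs)
        for onset, offset, d in sched:
            resp = np.clip(1.0 - np.exp(-np.maximum(0.0, t - onset) / tau)
                           - (1.0 - np.exp(-np.maximum(0.0, t - offset) / tau)),
                           0.0, None)
            theta = np.deg2rad(d)
            if np.isinf(kappa):
                gains = np.isclose((d - prefs) % 180.0, 0.0).astype(float)
            else:
                gains = np.exp(kappa * (np.cos(2 * (theta - pref_rad)) - 1.0))
            dff += amp * gains[:, None] * resp[None, :]
        truth = GroundTruth(params={"preferred_deg": prefs, "kappa": kappa,
                                    "frame_rate": fr, "amplitude": amp})
        return dff, sched, truth

    if kind == "ach_coupled":
        fr = float(p.get("frame_rate", 395.0))
        duration = float(p.get("duration_s", 120.0))
        f_slow = float(p.get("slow_hz", 0.3))
        f_fast = float(p.get("fast_hz", 5.0))
        lag_rad = float(p.get("lag_rad", 0.0))
        depth = float(p.get("depth", 0.8))
        noise_sd = float(p.get("noise_sd", 0.0))
        n = int(duration * fr)
        t = (np.arange(n) + 0.5) / fr
        mod_phase = 2 * np.pi * f_slow * t
        modulator = np.cos(mod_phase)
        envelope = 1.0 + depth * np.cos(mod_phase - lag_rad)
        voltage = envelope * np.sin(2 * np.pi * f_fast * t)
        if noise_sd > 0:
            voltage = voltage + rng.normal(0, noise_sd, n)
            modulator = modulator + rng.normal(0, noise_sd, n)
        truth = GroundTruth(params={"lag_rad": lag_rad, "slow_hz": f_slow,
                                    "fast_hz": f_fast, "depth": depth,
                                    "frame_rate": fr})
        return (Trace(voltage, fr, units="dff", provenance="ach_coupled.voltage"),
                Trace(modulator, fr, units="dff", provenance="ach_coupled.modulator"),
                truth)

    if kind == "arena_border":
        size = float(p.get("arena_cm", 80.0))
        duration = float(p.get("duration_s", 600.0))
        fs = float(p.get("track_rate", 30.0))
        speed_cm_s = float(p.get("speed_cm_s", 12.0))
        field = p.get("field", "wall")  # "wall" or "center"
        peak_hz = float(p.get("peak_rate_hz", 8.0))
        base_hz = float(p.get("base_rate_hz", 0.3))
        width_cm = float(p.get("field_width_cm", 8.0))
        n = int(duration * fs)
        # correlated random walk with reflective walls
        heading = rng.uniform(0, 2 * np.pi)
        xy = np.empty((n, 2))
        xy[0] = rng.uniform(0.2 * size, 0.8 * size, 2)
        step = speed_cm_s / fs
        for i in range(1, n):
            heading += rng.normal(0, 0.4)
            nxt = xy[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
            for d in range(2):
                if nxt[d] < 0:
                    nxt[d] = -nxt[d]
                    heading += np.pi / 2
                elif nxt[d] > size:
                    nxt[d] = 2 * size - nxt[d]
                    heading += np.pi / 2
            xy[i] = nxt
        t = np.arange(n) / fs
        dist_wall = np.minimum.reduce([xy[:, 0], xy[:, 1],
                                       size - xy[:, 0], size - xy[:, 1]])
        if field == "wall":
            rate = base_hz + peak_hz * np.exp(-dist_wall / width_cm)
        else:
            d_center = np.hypot(xy[:, 0] - size / 2, xy[:, 1] - size / 2)
            rate = base_hz + peak_hz * np.exp(-0.5 * (d_center / width_cm) ** 2)
        # inhomogeneous Poisson by per-sample thinning
        spikes = t[rng.random(n) < rate / fs]
        track = {"t": t, "x": xy[:, 0], "y": xy[:, 1],
                 "likelihood": np.ones(n), "rate": fs, "arena_cm": size}
        truth = GroundTruth(spike_times_s=spikes,
                            params={"field": field, "peak_rate_hz": peak_hz,
                                    "width_cm": width_cm, "arena_cm": size,
                                    "rate_map_rate": rate})
        return track, spikes, truth

    raise ValueError(f"unknown population kind {kind!r}")
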