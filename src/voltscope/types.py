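"""Core containers shared across the voltscope pipeline.

Lightweight dataclasses wrap the numerical payloads (numpy arrays) together
with the metadata the analyses depend on: sampling rates, unit flags, and the
configuration that produced a result.  Traces are 1-D, movies are
frames x rows x cols.  Frame timestamps follow the frame-center convention:
frame ``i`` at rate ``fr`` covers ``[i/fr, (i+1)/fr)`` and is stamped
``(i + 0.5) / fr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Trace",
    "Movie",
    "SpikeTrain",
    "VoltageSim",
    "GEVIModel",
    "SceneSpec",
    "GroundTruth",
    "frame_centers",
]


def frame_centers(n_frames: int, frame_rate: float) -> np.ndarray:
    """Timestamps (s) of frame centers for ``n_frames`` at ``frame_rate`` Hz."""
    return (np.arange(n_frames) + 0.5) / float(frame_rate)


@dataclass
class Trace:
    """A 1-D sampled signal with its rate and a units flag.

    ``units`` is one of ``"photons"`` (integer photon counts), ``"arb"``
    (uncalibrated intensity) or ``"dff"`` (fractional fluorescence change).
    """

    data: np.ndarray
    rate: float
    units: str = "arb"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Trace data must be 1-D")
        if self.rate <= 0:
            raise ValueError("Trace rate must be positive")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return frame_centers(self.n, self.rate)

    def copy_with(self, data: np.ndarray, units: str | None = None) -> "Trace":
        return Trace(np.asarray(data, dtype=float), self.rate,
                     self.units if units is None else units, self.provenance)


@dataclass
class Movie:
    """An imaging stack (frames x rows x cols) with frame-rate metadata."""

    data: np.ndarray
    frame_rate: float
    saturation_value: float = np.inf

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("Movie requires a non-empty frames x rows x cols stack")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        return frame_centers(self.n_frames, self.frame_rate)


@dataclass
class SpikeTrain:
    """Detected events: sample indices and times plus per-event scores.

    ``times_s`` follow the frame-center convention of the trace the detector
    ran on.  ``config`` records the detector settings that produced the train.
    """

    indices: np.ndarray
    times_s: np.ndarray
    amplitudes: np.ndarray
    detector: str = ""
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("SpikeTrain times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times_s.size

    def __len__(self) -> int:
        return self.n


@dataclass
class VoltageSim:
    """Simulated membrane potential with exact ground-truth spike times."""

    time_s: np.ndarray
    v_mV: np.ndarray
    spike_times_s: np.ndarray
    up_state_intervals: list = field(default_factory=list)
    sim_rate: float = 10_000.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if not np.all(np.isfinite(self.v_mV)):
            raise ValueError("v_mV must be finite")
        if self.spike_times_s.size > 1 and not np.all(np.diff(self.spike_times_s) > 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class GEVIModel:
    """Forward model of an indicator: steady-state F-V sigmoid, kinetics,
    photon flux, and photobleaching.

    The sigmoid is ``dff(v) = L / (1 + exp(-k (v - x0))) + b`` in ΔF/F units
    against membrane potential in mV.  ``tau_on_ms``/``tau_off_ms`` are lists
    of ``(tau_ms, weight)`` with weights summing to 1 per direction; "on" is
    the depolarising (brightening, for a positive-going indicator) direction.
    ``bleach`` is a list of ``(amplitude, tau_s)`` exponential decay terms; an
    empty list means no bleaching.
    """

    L: float
    k_slope: float
    x0: float
    b: float
    tau_on_ms: Sequence[tuple] = ((2.8, 1.0),)
    tau_off_ms: Sequence[tuple] = ((2.4, 0.5), (9.1, 0.5))
    baseline_flux_photons_per_s: float = 100_000.0
    bleach: Sequence[tuple] = ()

    def __post_init__(self) -> None:
        for comps, name in ((self.tau_on_ms, "tau_on_ms"), (self.tau_off_ms, "tau_off_ms")):
            w = sum(c[1] for c in comps)
            if not np.isclose(w, 1.0):
                raise ValueError(f"{name} weights must sum to 1 (got {w})")
            if any(c[0] <= 0 for c in comps):
                raise ValueError(f"{name} time constants must be positive")
        if self.baseline_flux_photons_per_s < 0:
            raise ValueError("flux must be non-negative")
        if any(t <= 0 for _, t in self.bleach):
            raise ValueError("bleach time constants must be positive")

    def sigmoid(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        return self.L / (1.0 + np.exp(-self.k_slope * (v - self.x0))) + self.b

    def sigmoid_slope(self, v_mV):
        """d(ΔF/F)/dV at ``v_mV`` (per mV)."""
        s = 1.0 / (1.0 + np.exp(-self.k_slope * (np.asarray(v_mV, float) - self.x0)))
        return self.L * self.k_slope * s * (1.0 - s)

    def bleach_curve(self, t_s):
        t = np.asarray(t_s, dtype=float)
        if not self.bleach:
            return np.ones_like(t)
        out = np.zeros_like(t)
        for a, tau in self.bleach:
            out += a * np.exp(-t / tau)
        return out


@dataclass
class SceneSpec:
    """Layout of a synthetic movie: cells, neuropil, and injected motion."""

    shape: tuple
    cell_centers: Sequence[tuple]
    cell_radii: Sequence[float]
    neuropil_gain: float = 0.0
    motion: np.ndarray | None = None  # (n_frames, 2) of (dy, dx) shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
        max_shift = 0.0 if self.motion is None else float(np.abs(self.motion).max())
        for (cy, cx), r in zip(self.cell_centers, self.cell_radii):
            if (cy - r - max_shift < 0 or cx - r - max_shift < 0
                    or cy + r + max_shift > self.shape[0] - 1
                    or cx + r + max_shift > self.shape[1] - 1):
                raise ValueError("cell overlaps frame edge after maximal shift")


@dataclass
class GroundTruth:
    """Everything a downstream parameter-recovery test needs, recorded at
    generation time so nothing has to be re-simulated."""

    spike_times_s: np.ndarray | None = None
    voltage: VoltageSim | None = None
    shifts: np.ndarray | None = None
    dff_traces: np.ndarray | None = None
    params: dict = field(default_factory=dict)
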