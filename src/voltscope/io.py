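"""File I/O for the pipeline's standard formats.

Movies travel as multipage TIFF; traces and ground truth as HDF5 with a
fixed group layout (``/trace`` with a ``rate`` attribute,
``/truth/spike_times``, ``/truth/shifts``); spike trains and schedules as
CSV; scene specs as YAML.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import GroundTruth, Movie, SceneSpec, SpikeTrain, Trace

__all__ = [
    "read_movie_tiff", "write_movie_tiff",
    "read_trace_h5", "write_trace_h5",
    "read_spiketrain_csv", "write_spiketrain_csv",
    "read_schedule_csv", "read_scene_yaml",
]


def write_movie_tiff(path, movie: Movie) -> None:
    tifffile.imwrite(path, movie.data.astype(np.float32),
                     metadata={"frame_rate": movie.frame_rate})


def read_movie_tiff(path, frame_rate: float | None = None) -> Movie:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if frame_rate is None:
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            frame_rate = float(meta.get("frame_rate", 0) or 0)
    if not frame_rate:
        raise ValueError("frame_rate not found in TIFF metadata; pass it explicitly")
    return Movie(data.astype(float), frame_rate)


def write_trace_h5(path, trace: Trace, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trace", data=trace.data)
        d.attrs["rate"] = trace.rate
        d.attrs["units"] = trace.units
        if truth is not None:
            g = f.create_group("truth")
            if truth.spike_times_s is not None:
                g.create_dataset("spike_times", data=truth.spike_times_s)
            if truth.shifts is not None:
                g.create_dataset("shifts", data=truth.shifts)


def read_trace_h5(path):
    with h5py.File(path, "r") as f:
        d = f["trace"]
        trace = Trace(d[...], float(d.attrs["rate"]),
                      str(d.attrs.get("units", "arb")))
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruth(
                spike_times_s=g["spike_times"][...] if "spike_times" in g else None,
                shifts=g["shifts"][...] if "shifts" in g else None)
    return trace, truth


def write_spiketrain_csv(path, train: SpikeTrain) -> None:
    df = pd.DataFrame({"time_s": train.times_s, "index": train.indices,
                       "amplitude": train.amplitudes})
    with open(path, "w") as f:
        f.write(f"# detector={train.detector} config={train.config}\n")
        df.to_csv(f, index=False)


def read_spiketrain_csv(path) -> SpikeTrain:
    df = pd.read_csv(path, comment="#")
    return SpikeTrain(df["index"].to_numpy(), df["time_s"].to_numpy(),
                      df["amplitude"].to_numpy())


def read_schedule_csv(path) -> np.ndarray:
    """Stimulus schedule CSV with columns onset_s, offset_s, direction_deg."""
    df = pd.read_csv(path)
    return df[["onset_s", "offset_s", "direction_deg"]].to_numpy(float)


def read_scene_yaml(path) -> SceneSpec:
    with open(path) as f:
        d = yaml.safe_load(f)
    return SceneSpec(
        shape=tuple(d["shape"]),
        cell_centers=[tuple(c) for c in d["cell_centers"]],
        cell_radii=list(d["cell_radii"]),
        neuropil_gain=float(d.get("neuropil_gain", 0.0)),
        motion=np.asarray(d["motion"], float) if d.get("motion") else None,
        seed=int(d.get("seed", 0)),
    )
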