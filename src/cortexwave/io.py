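"""File I/O: HDF5/CSV traces, TIFF movies, CSV stimulus logs and event
tables, JSON ground truth, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import SimConfig
from .geometry import FieldGeometry
from .photometry import EventList, PhotometryTrace
from .synthgen import GroundTruth, StimulusTrain
from .widefield import Movie

PathLike = Union[str, Path]

__all__ = [
    "write_trace_h5", "read_trace_h5",
    "write_trace_csv", "read_trace_csv",
    "write_movie_tiff", "read_movie_tiff",
    "write_stimuli_csv", "read_stimuli_csv",
    "write_events_csv", "read_events_csv",
    "write_ground_truth_json", "read_ground_truth_json",
    "geometry_to_dict", "geometry_from_dict",
]


# -- traces ------------------------------------------------------------

def write_trace_h5(path: PathLike, trace: PhotometryTrace) -> None:
    """Write a trace with datasets /signal and /fs plus site/state attrs."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("signal", data=trace.samples)
        fh.create_dataset("fs", data=float(trace.fs_hz))
        ds.attrs["site"] = trace.site
        ds.attrs["state"] = trace.state_label
        ds.attrs["kind"] = trace.kind


def read_trace_h5(path: PathLike) -> PhotometryTrace:
    with h5py.File(path, "r") as fh:
        ds = fh["signal"]
        return PhotometryTrace(
            samples=ds[()], fs_hz=float(fh["fs"][()]),
            site=str(ds.attrs.get("site", "")),
            state_label=str(ds.attrs.get("state", "unknown")),
            kind=str(ds.attrs.get("kind", "calcium")))


def write_trace_csv(path: PathLike, trace: PhotometryTrace) -> None:
    """CSV fallback: columns time_s, signal (site/state not preserved)."""
    pd.DataFrame({"time_s": trace.times(), "signal": trace.samples}
                 ).to_csv(path, index=False)


def read_trace_csv(path: PathLike, site: str = "",
                   state_label: str = "unknown") -> PhotometryTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return PhotometryTrace(samples=df["signal"].to_numpy(), fs_hz=fs,
                           site=site, state_label=state_label)


# -- movies ------------------------------------------------------------

def write_movie_tiff(path: PathLike, movie: Movie) -> None:
    """Multi-page TIFF; frame rate and pixel pitch stored as metadata."""
    tifffile.imwrite(
        path, movie.frames.astype(np.float32),
        metadata={"frame_rate_hz": movie.frame_rate_hz,
                  "pixel_pitch_mm": movie.geometry.pixel_pitch_mm})


def read_movie_tiff(path: PathLike, frame_rate_hz: Optional[float] = None,
                    geometry: Optional[FieldGeometry] = None) -> Movie:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    rate = frame_rate_hz or float(meta.get("frame_rate_hz", 0) or 0)
    if rate <= 0:
        raise ValueError("frame rate not in metadata; pass frame_rate_hz")
    if geometry is None:
        pitch = float(meta.get("pixel_pitch_mm", 0) or 0)
        if pitch <= 0:
            raise ValueError("pixel pitch not in metadata; pass geometry")
        geometry = FieldGeometry(fov_ap_mm=frames.shape[1] * pitch,
                                 fov_ml_mm=frames.shape[2] * pitch,
                                 pixel_pitch_mm=pitch, sites={})
    return Movie(frames=frames, frame_rate_hz=rate, geometry=geometry)


# -- stimuli and events ------------------------------------------------

def write_stimuli_csv(path: PathLike, stimuli: StimulusTrain) -> None:
    pd.DataFrame({"onset_s": stimuli.onsets_s,
                  "modality": stimuli.modality,
                  "pulse_ms": stimuli.pulse_ms}).to_csv(path, index=False)


def read_stimuli_csv(path: PathLike) -> StimulusTrain:
    df = pd.read_csv(path)
    return StimulusTrain(onsets_s=df["onset_s"].to_numpy(),
                         modality=str(df["modality"].iloc[0]),
                         pulse_ms=float(df["pulse_ms"].iloc[0])
                         if "pulse_ms" in df else 10.0)


def write_events_csv(path: PathLike, events: EventList) -> None:
    events.to_frame().to_csv(path, index=False)


def read_events_csv(path: PathLike) -> EventList:
    return EventList.from_frame(pd.read_csv(path))


# -- ground truth ------------------------------------------------------

def geometry_to_dict(geom: FieldGeometry) -> dict:
    return {"fov_ap_mm": geom.fov_ap_mm, "fov_ml_mm": geom.fov_ml_mm,
            "pixel_pitch_mm": geom.pixel_pitch_mm,
            "sites": {k: list(v) for k, v in geom.sites.items()}}


def geometry_from_dict(d: dict) -> FieldGeometry:
    return FieldGeometry(fov_ap_mm=d["fov_ap_mm"], fov_ml_mm=d["fov_ml_mm"],
                         pixel_pitch_mm=d["pixel_pitch_mm"],
                         sites={k: tuple(v) for k, v in d["sites"].items()})


def write_ground_truth_json(path: PathLike, gt: GroundTruth) -> None:
    payload = {"config": gt.config.to_dict(),
               "geometry": geometry_to_dict(gt.geometry),
               "ground_truth": gt.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth_json(path: PathLike) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    config = SimConfig.from_dict(payload["config"])
    geometry = geometry_from_dict(payload["geometry"])
    return GroundTruth.from_dict(payload["ground_truth"], config, geometry)
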