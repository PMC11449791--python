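"""The Recording container and its HDF5 / CSV serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["Recording", "read_recording", "write_recording"]


@dataclass
class Recording:
    """A continuous LFP trace with an optional aligned velocity trace.

    ``samples`` are in volts as acquired or z-units after normalization;
    ``velocity`` (cm/s) has its own sampling rate ``fs_vel_hz``. ``meta``
    carries subject/group/stage tags and a provenance log of processing
    steps applied.
    """

    samples: np.ndarray
    fs_hz: float
    velocity: np.ndarray | None = None
    fs_vel_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)
            if self.fs_vel_hz is None or self.fs_vel_hz <= 0:
                raise ValueError("velocity requires a positive fs_vel_hz")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz

    def replace(self, **kw) -> "Recording":
        d = dict(
            samples=self.samples, fs_hz=self.fs_hz, velocity=self.velocity,
            fs_vel_hz=self.fs_vel_hz, meta=dict(self.meta),
        )
        d.update(kw)
        return Recording(**d)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write HDF5 (datasets /lfp, /velocity) or CSV (time,lfp[,velocity])."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("lfp", data=rec.samples.astype(np.float32))
            f.attrs["fs_lfp_hz"] = rec.fs_hz
            if rec.velocity is not None:
                f.create_dataset("velocity", data=rec.velocity.astype(np.float32))
                f.attrs["fs_vel_hz"] = rec.fs_vel_hz
            for k in ("subject", "group", "stage"):
                if k in rec.meta:
                    f.attrs[k] = str(rec.meta[k])
    elif path.suffix.lower() == ".csv":
        cols = {"time": rec.time_s, "lfp": rec.samples}
        if rec.velocity is not None:
            # CSV is a flat table: velocity is interpolated to the LFP base
            t_vel = np.arange(rec.velocity.size) / rec.fs_vel_hz
            cols["velocity"] = np.interp(rec.time_s, t_vel, rec.velocity)
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            samples = f["lfp"][...].astype(float)
            fs = float(f.attrs["fs_lfp_hz"])
            vel = None
            fs_vel = None
            if "velocity" in f:
                vel = f["velocity"][...].astype(float)
                fs_vel = float(f.attrs.get("fs_vel_hz", fs))
            meta = {
                k: f.attrs[k]
                for k in ("subject", "group", "stage")
                if k in f.attrs
            }
        return Recording(samples, fs, vel, fs_vel, meta)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        t = df["time"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        vel = df["velocity"].to_numpy() if "velocity" in df else None
        return Recording(
            df["lfp"].to_numpy(), fs, vel, fs if vel is not None else None
        )
    raise ValueError(f"unsupported recording format: {path.suffix}")
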