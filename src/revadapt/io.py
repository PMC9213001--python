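"""Persistence helpers: WAV waveforms, HDF5 cochleagrams/kernels, CSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .cochlea import Cochleagram
from .ridge import Kernel
from .room import ImpulseResponse, RTProfile


def save_wav(path: str | Path, samples: np.ndarray, sample_rate: float) -> None:
    """Write a mono float32 PCM WAV file."""
    wavfile.write(path, int(round(sample_rate)), np.asarray(samples, dtype=np.float32))


def load_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float64 mono (integer PCM is rescaled to +-1)."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def save_impulse_response(path: str | Path, ir: ImpulseResponse) -> None:
    save_wav(path, ir.samples, ir.sample_rate)


def load_impulse_response(path: str | Path) -> ImpulseResponse:
    samples, rate = load_wav(path)
    return ImpulseResponse(sample_rate=rate, samples=samples)


def save_cochleagram(path: str | Path, coch: Cochleagram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=coch.values)
        f.create_dataset("channel_centers_hz", data=coch.channel_centers)
        f.attrs["bin_ms"] = coch.bin_duration * 1000.0
        f.attrs["floor_db"] = coch.floor_db


def load_cochleagram(path: str | Path) -> Cochleagram:
    with h5py.File(path, "r") as f:
        return Cochleagram(
            values=f["values"][()],
            channel_centers=f["channel_centers_hz"][()],
            bin_duration=float(f.attrs["bin_ms"]) / 1000.0,
            floor_db=float(f.attrs["floor_db"]),
        )


def save_kernels(path: str | Path, kernels: list[Kernel]) -> None:
    """One HDF5 group per kernel: weights, bias, ridge strength, target."""
    with h5py.File(path, "w") as f:
        for i, k in enumerate(kernels):
            g = f.create_group(f"kernel_{i:04d}")
            g.create_dataset("weights", data=k.weights)
            g.attrs["bias"] = k.bias
            g.attrs["lambda"] = k.lam
            g.attrs["target_id"] = str(k.target_id)
            if k.channel_centers is not None:
                g.create_dataset("channel_centers_hz", data=k.channel_centers)


def load_kernels(path: str | Path) -> list[Kernel]:
    kernels = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            centers = (
                g["channel_centers_hz"][()] if "channel_centers_hz" in g else None
            )
            kernels.append(
                Kernel(
                    weights=g["weights"][()],
                    bias=float(g.attrs["bias"]),
                    lam=float(g.attrs["lambda"]),
                    target_id=g.attrs["target_id"],
                    channel_centers=centers,
                )
            )
    return kernels


def rt_profile_frame(profile: RTProfile) -> pd.DataFrame:
    """RT profile as a table (band_center_hz, rt60_s, rt10_s)."""
    return pd.DataFrame(
        {
            "band_center_hz": profile.band_centers,
            "rt60_s": profile.rt60,
            "rt10_s": profile.rt10,
        }
    )


def save_rt_profile(path: str | Path, profile: RTProfile) -> None:
    rt_profile_frame(profile).to_csv(path, index=False)
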