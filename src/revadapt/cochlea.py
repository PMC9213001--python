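"""Log-power ("log-pow") cochleagram.

A waveform is converted to a time-frequency representation that stands in
for the output of the cochlea: short-time Fourier power (Hann windows),
pooled into log-spaced overlapping triangular frequency bands, converted to
dB with a hard floor.  Defaults follow the configuration used for cortical
encoding models: 20 ms windows, 10 ms hop, 30 channels from 400 Hz to
19 kHz, floor at -94 dB.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window


@dataclass(frozen=True)
class CochlearConfig:
    """Parameters of the cochleagram transform.

    window_ms/hop_ms set the STFT frame length and spacing (hop equals the
    output bin duration).  n_channels triangular bands are centred on a
    geometric grid from f_min to f_max.  Power below floor_db is clipped.
    """

    window_ms: float = 20.0
    hop_ms: float = 10.0
    n_channels: int = 30
    f_min: float = 400.0
    f_max: float = 19000.0
    floor_db: float = -94.0
    window_shape: str = "hann"

    def __post_init__(self) -> None:
        if self.hop_ms > self.window_ms:
            raise ValueError("hop_ms must not exceed window_ms")
        if not (self.f_min < self.f_max):
            raise ValueError("f_min must be < f_max")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")

    @property
    def channel_centers(self) -> np.ndarray:
        """Geometrically spaced band centre frequencies in Hz."""
        return np.geomspace(self.f_min, self.f_max, self.n_channels)


@dataclass
class Cochleagram:
    """channels x time matrix of band power in dB (floored)."""

    values: np.ndarray  # (n_channels, n_bins)
    channel_centers: np.ndarray  # Hz, strictly increasing
    bin_duration: float  # seconds
    floor_db: float = -94.0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin centre times in seconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_duration


@lru_cache(maxsize=16)
def _band_weights(
    sample_rate: float,
    n_fft: int,
    n_channels: int,
    f_min: float,
    f_max: float,
) -> np.ndarray:
    """Triangular band weights on the log-frequency axis.

    Channel i has unit weight at centre c_i, falling linearly (in log f) to
    zero at the neighbouring centres; the outermost triangles extend one
    geometric step beyond f_min/f_max.  Within [f_min, f_max] the triangles
    sum to one, so broadband power is conserved by the pooling.
    """
    centers = np.geomspace(f_min, f_max, n_channels)
    step = np.log(centers[1]) - np.log(centers[0])
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    w = np.zeros((n_channels, freqs.size))
    pos = freqs > 0
    logf = np.log(freqs[pos])
    for i, c in enumerate(centers):
        w[i, pos] = np.clip(1.0 - np.abs(logf - np.log(c)) / step, 0.0, None)
    return w


def cochleagram(
    sound: np.ndarray, sample_rate: float, cfg: CochlearConfig | None = None
) -> Cochleagram:
    """Compute the log-power cochleagram of a mono waveform.

    The number of time bins is floor((N - window) / hop) + 1; only full
    frames are used.  Band power is 10*log10 of triangularly pooled STFT
    power, clipped at cfg.floor_db.

    Raises ValueError if the sample rate cannot represent f_max (Nyquist)
    or the sound is shorter than one analysis window.
    """
    cfg = cfg or CochlearConfig()
    sound = np.asarray(sound, dtype=float)
    if sound.ndim != 1:
        raise ValueError("sound must be a 1-D mono waveform")
    if sample_rate < 2.0 * cfg.f_max:
        raise ValueError(
            f"sample rate {sample_rate} Hz cannot represent f_max={cfg.f_max} Hz"
        )
    win = int(round(cfg.window_ms * 1e-3 * sample_rate))
    hop = int(round(cfg.hop_ms * 1e-3 * sample_rate))
    if sound.size < win:
        raise ValueError("sound shorter than one analysis window")

    frames = sliding_window_view(sound, win)[::hop]
    taper = get_window(cfg.window_shape, win, fftbins=True)
    spec = np.fft.rfft(frames * taper, axis=1)
    power = spec.real**2 + spec.imag**2

    weights = _band_weights(
        float(sample_rate), win, cfg.n_channels, float(cfg.f_min), float(cfg.f_max)
    )
    band_power = power @ weights.T  # (n_bins, n_channels)
    floor_power = 10.0 ** (cfg.floor_db / 10.0)
    values = 10.0 * np.log10(np.maximum(band_power, floor_power)).T
    return Cochleagram(
        values=values,
        channel_centers=cfg.channel_centers,
        bin_duration=hop / sample_rate,
        floor_db=cfg.floor_db,
    )
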