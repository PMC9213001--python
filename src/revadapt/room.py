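"""Shoebox-room acoustics by the image-source method.

Rooms are cuboids with frequency-dependent surface absorption.  The
impulse response at a receiver is built by enumerating mirror-image
sources on the reflection lattice: each image is attenuated by 1/distance,
and per frequency band by the product of the surface reflection
coefficients sqrt(1 - alpha) accumulated along its reflection history.
Band-limited components are recombined through a zero-phase filterbank
whose masks form a partition of unity, so a frequency-flat room reduces
exactly to the broadband image sum.  Optional air absorption attenuates
each band by a fixed dB-per-metre rate over the propagation distance.

Reverberation time is measured the way auditory experiments measure it:
the impulse response is passed through the cochlear model and a straight
line is fitted to each band's decaying dB power; RT60 (RT10) is the time
for that line to fall by 60 (10) dB, and a room's headline RT is the
median over bands.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.signal import fftconvolve

from .cochlea import CochlearConfig, cochleagram

_SURFACES = ("x0", "x1", "y0", "y1", "z0", "z1")


def _load_materials() -> dict:
    text = (
        importlib.resources.files("revadapt").joinpath("data/materials.yaml")
    ).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class RoomSpec:
    """A cuboid room with per-surface, per-band energy absorption.

    dimensions: (length, width, height) in metres.
    band_centers_hz: strictly increasing band centre frequencies.
    absorption: (6, n_bands) energy absorption coefficients in [0, 1],
        surfaces ordered x0, x1, y0, y1, z0, z1 (a (n_bands,) vector is
        broadcast to all six surfaces).
    air_db_per_m: optional per-band air attenuation in dB per metre.
    """

    dimensions: tuple[float, float, float]
    band_centers_hz: np.ndarray
    absorption: np.ndarray
    speed_of_sound: float = 343.0
    air_db_per_m: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        dims = np.asarray(self.dimensions, dtype=float)
        if dims.shape != (3,) or np.any(dims <= 0):
            raise ValueError("dimensions must be three positive lengths")
        bands = np.asarray(self.band_centers_hz, dtype=float)
        if bands.ndim != 1 or np.any(np.diff(bands) <= 0):
            raise ValueError("band frequencies must be strictly increasing")
        a = np.broadcast_to(
            np.asarray(self.absorption, dtype=float), (6, bands.size)
        ).copy()
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("absorption coefficients must lie in [0, 1]")
        object.__setattr__(self, "dimensions", tuple(float(d) for d in dims))
        object.__setattr__(self, "band_centers_hz", bands)
        object.__setattr__(self, "absorption", a)
        if self.air_db_per_m is not None:
            air = np.asarray(self.air_db_per_m, dtype=float)
            if air.shape != bands.shape or np.any(air < 0):
                raise ValueError("air_db_per_m must be non-negative, one per band")
            object.__setattr__(self, "air_db_per_m", air)


@dataclass(frozen=True)
class Geometry:
    """Source and receiver positions (metres, room coordinates)."""

    source_position: tuple[float, float, float]
    receiver_position: tuple[float, float, float]

    def validate(self, room: RoomSpec) -> None:
        for label, p in (
            ("source", self.source_position),
            ("receiver", self.receiver_position),
        ):
            p = np.asarray(p, dtype=float)
            if p.shape != (3,):
                raise ValueError(f"{label} position must be a 3-vector")
            if np.any(p <= 0) or np.any(p >= np.asarray(room.dimensions)):
                raise ValueError(f"{label} position must lie strictly inside the room")
        if np.allclose(self.source_position, self.receiver_position):
            raise ValueError("source and receiver coincide")

    @property
    def distance(self) -> float:
        return float(
            np.linalg.norm(
                np.asarray(self.source_position) - np.asarray(self.receiver_position)
            )
        )


@dataclass
class ImpulseResponse:
    """Pressure impulse response at the receiver."""

    sample_rate: float
    samples: np.ndarray
    truncated: bool = False  # True if the tail was cut before full decay

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class RTProfile:
    """Per-band reverberation times derived from one fitted decay slope.

    rt60 and rt10 come from the same line fit (rt60 = 6 * rt10 exactly);
    bands whose power did not decay are NaN and excluded from the medians.
    """

    band_centers: np.ndarray
    rt60: np.ndarray
    rt10: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.rt60)

    @property
    def median_rt60(self) -> float:
        return float(np.nanmedian(self.rt60))

    @property
    def median_rt10(self) -> float:
        return float(np.nanmedian(self.rt10))


def _axis_images(length: float, src: float, rcv: float, max_dist: float):
    """Image offsets and per-wall reflection counts along one axis.

    Returns (delta, q_lo, q_hi): delta[i] is the axial distance component
    image_coord - receiver; q_lo/q_hi count reflections off the wall at 0
    and at `length`.
    """
    n_max = int(np.ceil(max_dist / (2.0 * length))) + 1
    ns = np.arange(-n_max, n_max + 1)
    # even images: 2nL + s, |n| reflections off each wall
    d_even = 2.0 * ns * length + src - rcv
    q_lo_e = np.abs(ns)
    q_hi_e = np.abs(ns)
    # odd images: 2nL - s; n >= 1: (n-1, n); n <= 0: (|n|+1, |n|)
    d_odd = 2.0 * ns * length - src - rcv
    q_lo_o = np.where(ns >= 1, ns - 1, np.abs(ns) + 1)
    q_hi_o = np.where(ns >= 1, ns, np.abs(ns))
    delta = np.concatenate([d_even, d_odd])
    q_lo = np.concatenate([q_lo_e, q_lo_o])
    q_hi = np.concatenate([q_hi_e, q_hi_o])
    keep = np.abs(delta) <= max_dist
    return delta[keep], q_lo[keep], q_hi[keep]


def _recombination_masks(band_centers: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Zero-phase filterbank masks (partition of unity on log frequency)."""
    nb = band_centers.size
    masks = np.zeros((nb, freqs.size))
    logc = np.log(band_centers)
    pos = freqs > 0
    logf = np.log(freqs[pos])
    for b in range(nb):
        m = np.zeros(pos.sum())
        if b == 0:
            m[logf <= logc[0]] = 1.0
        else:
            lo, hi = logc[b - 1], logc[b]
            seg = (logf > lo) & (logf <= hi)
            m[seg] = (logf[seg] - lo) / (hi - lo)
        if b == nb - 1:
            m[logf > logc[-1]] = 1.0
        else:
            lo, hi = logc[b], logc[b + 1]
            seg = (logf > lo) & (logf <= hi)
            m[seg] = (hi - logf[seg]) / (hi - lo)
        masks[b, pos] = m
    masks[0, ~pos] = 1.0  # DC goes with the lowest band
    return masks


def simulate_rir(
    room: RoomSpec,
    geom: Geometry,
    sample_rate: float = 48828.0,
    duration: float = 0.5,
    highpass_hz: float | None = 100.0,
) -> ImpulseResponse:
    """Simulate the room impulse response by the image-source method.

    Images are enumerated out to a radius of speed_of_sound * duration;
    fractional-sample arrival delays are rounded to the nearest sample.
    Per-band image sums are recombined through a zero-phase filterbank.
    With absorption 1 on every surface only the direct path survives.

    The sampled image sum is all-positive and accumulates a nonphysical
    quasi-DC pedestal; a gentle zero-phase high-pass (cosine roll-off up
    to highpass_hz) removes it, as is standard for image-method
    simulators.  Pass highpass_hz=None for the raw image sum.
    """
    geom.validate(room)
    if duration <= geom.distance / room.speed_of_sound:
        raise ValueError("duration shorter than the direct-path delay")
    c = room.speed_of_sound
    n_samples = int(round(duration * sample_rate))
    max_dist = c * duration
    refl = np.sqrt(np.clip(1.0 - room.absorption, 0.0, 1.0))  # (6, nb) amplitude

    axes = []
    for ax in range(3):
        delta, q_lo, q_hi = _axis_images(
            room.dimensions[ax],
            geom.source_position[ax],
            geom.receiver_position[ax],
            max_dist,
        )
        # per-band amplitude factor contributed by this axis, per image
        fac = (
            refl[2 * ax][:, None] ** q_lo[None, :]
            * refl[2 * ax + 1][:, None] ** q_hi[None, :]
        )  # (nb, n_images_axis)
        axes.append((delta, fac))

    dx, fx = axes[0]
    dy, fy = axes[1]
    dz, fz = axes[2]
    nb = room.band_centers_hz.size

    d2_yz = dy[:, None] ** 2 + dz[None, :] ** 2  # (ny, nz)
    fac_yz = fy[:, :, None] * fz[:, None, :]  # (nb, ny, nz)

    ir_bands = np.zeros((nb, n_samples))
    max_d2 = max_dist**2
    for i in range(dx.size):
        d2 = dx[i] ** 2 + d2_yz
        mask = d2 <= max_d2
        if not mask.any():
            continue
        d = np.sqrt(d2[mask])
        np.maximum(d, 1e-6, out=d)
        t_idx = np.rint(d / c * sample_rate).astype(np.intp)
        inside = t_idx < n_samples
        if not inside.all():
            d = d[inside]
            t_idx = t_idx[inside]
        inv_d = 1.0 / d
        for b in range(nb):
            w = fac_yz[b][mask]
            if not inside.all():
                w = w[inside]
            w = w * (fx[b, i] * inv_d)
            ir_bands[b] += np.bincount(t_idx, weights=w, minlength=n_samples)

    # air absorption: attenuate by distance, using delay as a distance proxy
    if room.air_db_per_m is not None:
        dist_of_t = np.arange(n_samples) * (c / sample_rate)
        ir_bands *= 10.0 ** (
            -room.air_db_per_m[:, None] * dist_of_t[None, :] / 20.0
        )

    flat_surfaces = np.allclose(room.absorption, room.absorption[:, :1])
    flat_air = room.air_db_per_m is None or np.allclose(
        room.air_db_per_m, room.air_db_per_m[0]
    )
    flat = nb == 1 or (flat_surfaces and flat_air)

    nfft = next_fast_len(n_samples)
    freqs = rfftfreq(nfft, d=1.0 / sample_rate)
    if flat:
        # frequency-flat room: every band component is identical
        spectrum = rfft(ir_bands[0], nfft)
    else:
        masks = _recombination_masks(room.band_centers_hz, freqs)
        spectrum = np.zeros(freqs.size, dtype=complex)
        for b in range(nb):
            spectrum += rfft(ir_bands[b], nfft) * masks[b]
    if highpass_hz is not None and highpass_hz > 0:
        hp = np.ones(freqs.size)
        ramp = (freqs > 0) & (freqs < highpass_hz)
        hp[freqs <= 0] = 0.0
        hp[ramp] = 0.5 - 0.5 * np.cos(np.pi * freqs[ramp] / highpass_hz)
        spectrum *= hp
    elif flat:
        return ImpulseResponse(sample_rate=sample_rate, samples=ir_bands[0])
    ir = irfft(spectrum, nfft)[:n_samples]

    return ImpulseResponse(sample_rate=sample_rate, samples=ir)


def convolve_stimulus(
    sound: np.ndarray, sample_rate: float, ir: ImpulseResponse
) -> np.ndarray:
    """Linear convolution of a stimulus with a room impulse response.

    Output length is len(sound) + len(ir) - 1; no clipping or
    normalisation is applied.  Sample rates must match.
    """
    if sample_rate != ir.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: stimulus {sample_rate}, IR {ir.sample_rate}"
        )
    sound = np.asarray(sound, dtype=float)
    return fftconvolve(sound, ir.samples, mode="full")


def measure_rt(
    ir: ImpulseResponse, coch_cfg: CochlearConfig | None = None
) -> RTProfile:
    """Measure per-band RT60/RT10 from the impulse response's cochleagram.

    For each band, a least-squares line is fitted to the dB power from the
    band's peak bin to the last bin strictly above floor + 1 dB; RT is the
    time for the fitted line to decay by 60 (10) dB.  Bands with a
    non-negative slope are invalid (NaN).  If no band reaches the floor
    before the end of the impulse response the profile is flagged
    truncated (the slope is then estimated from the available decay).
    """
    cfg = coch_cfg or CochlearConfig()
    coch = cochleagram(ir.samples, ir.sample_rate, cfg)
    nb = coch.n_channels
    rt60 = np.full(nb, np.nan)
    hit_floor = np.zeros(nb, dtype=bool)
    dt = coch.bin_duration
    threshold = cfg.floor_db + 1.0
    for b in range(nb):
        p = coch.values[b]
        peak = int(np.argmax(p))
        above = np.nonzero(p > threshold)[0]
        above = above[above >= peak]
        if above.size == 0:
            continue
        last = int(above[-1])
        hit_floor[b] = last < coch.n_bins - 1
        if last - peak + 1 < 3:
            continue
        t = np.arange(peak, last + 1) * dt
        slope = np.polyfit(t, p[peak : last + 1], 1)[0]
        if slope < 0:
            rt60[b] = 60.0 / abs(slope)
    truncated = not hit_floor.any()
    return RTProfile(
        band_centers=coch.channel_centers,
        rt60=rt60,
        rt10=rt60 / 6.0,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Presets for the study rooms


def _stone_room(scale: float, name: str, air: bool = True) -> tuple[RoomSpec, Geometry]:
    mat = _load_materials()
    bands = np.asarray(mat["band_centers_hz"], dtype=float)
    stone = np.asarray(mat["materials"]["stone"]["absorption"], dtype=float)
    air_tab = np.asarray(mat["air"]["db_per_m"], dtype=float) if air else None
    dims = (3.0 * scale, 0.3 * scale, 0.3 * scale)
    room = RoomSpec(
        dimensions=dims,
        band_centers_hz=bands,
        absorption=stone,
        air_db_per_m=air_tab,
        name=name,
    )
    # receiver 1/4 along the length, mid-width, 0.15 m above the floor;
    # source 1.5 m straight ahead at the same height
    rcv = (dims[0] / 4.0, dims[1] / 2.0, 0.15)
    src = (dims[0] / 4.0 + 1.5, dims[1] / 2.0, 0.15)
    return room, Geometry(source_position=src, receiver_position=rcv)


# Default impulse-response durations for the presets: roughly half the
# room's reverberation time, enough decay for a stable line fit while
# keeping the image enumeration tractable.
PRESET_IR_DURATION = {"small": 0.4, "medium": 0.8, "large": 1.3, "anechoic": 0.05}


def room_preset(name: str) -> tuple[RoomSpec, Geometry]:
    """Named study rooms: 'small' (3 x 0.3 x 0.3 m, stone), 'medium'
    (x2.5), 'large' (x5), and 'anechoic' (fully absorbing surfaces)."""
    scales = {"small": 1.0, "medium": 2.5, "large": 5.0}
    if name in scales:
        return _stone_room(scales[name], name)
    if name == "anechoic":
        mat = _load_materials()
        bands = np.asarray(mat["band_centers_hz"], dtype=float)
        room = RoomSpec(
            dimensions=(15.0, 1.5, 1.5),
            band_centers_hz=bands,
            absorption=np.ones_like(bands),
            name="anechoic",
        )
        rcv = (15.0 / 4.0, 0.75, 0.15)
        src = (15.0 / 4.0 + 1.5, 0.75, 0.15)
        return room, Geometry(source_position=src, receiver_position=rcv)
    raise KeyError(f"unknown room preset {name!r}")


def simulate_preset(
    name: str, sample_rate: float = 48828.0, duration: float | None = None
) -> tuple[RoomSpec, Geometry, ImpulseResponse]:
    """Simulate one of the named study rooms with its default duration."""
    rm, geom = room_preset(name)
    dur = duration if duration is not None else PRESET_IR_DURATION[name]
    ir = simulate_rir(rm, geom, sample_rate, dur)
    return rm, geom, ir
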