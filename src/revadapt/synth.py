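"""Synthetic stimuli and ground-truth neuron populations.

This module stands in for everything the original experiment supplied
from outside: a corpus of natural-sound-like snippets assembled into
blocks, reverberant renderings of those blocks, anechoic noise probes
embedded late in each block, room-switching stimuli, and populations of
model neurons whose spectrotemporal tuning either does ("adaptive") or
does not ("static") change with the reverberation condition.  Because
every quantity is planted, each stage of the analysis pipeline can be
checked against a known answer.

Snippets are 2 s of amplitude-modulated 1/f noise, harmonic stacks,
click trains or band-passed textures - matching the coarse spectrotemporal
statistics of natural sounds (spectral tilt, modulation from a few Hz to
tens of Hz, impulsive events) without attempting perceptual realism.  All
generators are bit-reproducible under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .cochlea import Cochleagram
from .neurons import SigmoidParams, sigmoid
from .ridge import Kernel
from .room import ImpulseResponse, convolve_stimulus

# ---------------------------------------------------------------------------
# Corpus


@dataclass(frozen=True)
class CorpusConfig:
    """Corpus of ramped snippets concatenated into fixed-length blocks."""

    n_snippets: int = 40
    snippet_duration: float = 2.0
    ramp: float = 0.25
    block_duration: float = 40.0
    sample_rate: float = 48828.0
    band: tuple[float, float] | None = (200.0, 20000.0)
    rms: float = 0.05
    snippet_kinds: tuple[str, ...] = ("am_noise", "harmonic", "clicks", "texture")
    seed: int = 0

    def __post_init__(self) -> None:
        per_block = self.block_duration / self.snippet_duration
        if abs(per_block - round(per_block)) > 1e-9:
            raise ValueError("block_duration must be a multiple of snippet_duration")
        if self.n_snippets % round(per_block):
            raise ValueError("n_snippets must fill whole blocks")

    @property
    def snippets_per_block(self) -> int:
        return int(round(self.block_duration / self.snippet_duration))

    @property
    def n_blocks(self) -> int:
        return self.n_snippets // self.snippets_per_block


@dataclass
class Corpus:
    """Generated snippets and their concatenation into blocks."""

    snippets: list[np.ndarray]
    blocks: list[np.ndarray]
    snippet_kind: list[str]
    config: CorpusConfig


def _spectral_tilt(x: np.ndarray, gamma: float, fs: float) -> np.ndarray:
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = (f[nz] / 1000.0) ** (-gamma / 2.0)
    shaping[~nz] = 0.0
    return np.fft.irfft(spec * shaping, x.size)


def _am_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    # natural modulation spectra are low-pass but extend to tens of Hz
    f_mod = np.exp(rng.uniform(np.log(2.0), np.log(64.0)))
    phase = rng.uniform(0, 2 * np.pi)
    depth = rng.uniform(0.5, 0.95)
    t = np.arange(n) / fs
    return 1.0 - depth * 0.5 * (1.0 + np.sin(2 * np.pi * f_mod * t + phase))


def _snippet_am_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    x = _spectral_tilt(rng.standard_normal(n), rng.uniform(0.5, 1.5), fs)
    return x * _am_envelope(n, fs, rng)


def _snippet_harmonic(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    f0 = np.exp(rng.uniform(np.log(100.0), np.log(800.0)))
    t = np.arange(n) / fs
    vibrato = 1.0 + 0.01 * np.sin(2 * np.pi * rng.uniform(3, 7) * t)
    n_harm = int(min(30, np.floor(0.45 * fs / f0)))
    x = np.zeros(n)
    for k in range(1, n_harm + 1):
        x += np.sin(2 * np.pi * k * f0 * np.cumsum(vibrato) / fs + rng.uniform(0, 2 * np.pi)) / k
    return x * _am_envelope(n, fs, rng)


def _snippet_clicks(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    # impulsive events (footsteps, cracking branches): up to ~80 per second
    rate = rng.uniform(8.0, 80.0)
    duration = n / fs
    n_clicks = max(1, rng.poisson(rate * duration))
    onsets = np.sort(rng.uniform(0, duration, n_clicks))
    pulse_len = max(int(2e-3 * fs), 8)
    pulse = np.hanning(pulse_len) * _spectral_tilt(
        rng.standard_normal(pulse_len), 0.3, fs
    )
    x = np.zeros(n + pulse_len)
    for on in onsets:
        i = int(on * fs)
        x[i : i + pulse_len] += pulse * rng.uniform(0.5, 1.0)
    return x[:n]


def _snippet_texture(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    f_lo = np.exp(rng.uniform(np.log(300.0), np.log(min(6000.0, 0.2 * fs))))
    width = rng.uniform(1.0, 2.0)  # octaves
    f_hi = min(f_lo * 2**width, 0.45 * fs)
    sos = butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    # slow stochastic envelope
    env = sosfilt(butter(2, 8.0, fs=fs, output="sos"), rng.standard_normal(n))
    env = np.abs(env)
    env /= max(env.max(), 1e-12)
    return x * (0.25 + 0.75 * env)


_SNIPPET_MAKERS = {
    "am_noise": _snippet_am_noise,
    "harmonic": _snippet_harmonic,
    "clicks": _snippet_clicks,
    "texture": _snippet_texture,
}


def generate_corpus(cfg: CorpusConfig | None = None) -> Corpus:
    """Generate ramped snippets and concatenate them into blocks.

    Each snippet gets a cosine onset/offset ramp, is normalised to the
    configured RMS, and blocks are optionally band-pass filtered
    (8th-order Butterworth) to the corpus band.
    """
    cfg = cfg or CorpusConfig()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.snippet_duration * fs))
    n_ramp = int(round(cfg.ramp * fs))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))

    snippets, kinds = [], []
    for i in range(cfg.n_snippets):
        kind = cfg.snippet_kinds[int(rng.integers(len(cfg.snippet_kinds)))]
        x = _SNIPPET_MAKERS[kind](n, fs, rng)
        x = x - x.mean()
        x *= cfg.rms / max(np.sqrt(np.mean(x**2)), 1e-12)
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
        snippets.append(x)
        kinds.append(kind)

    blocks = []
    per_block = cfg.snippets_per_block
    for b in range(cfg.n_blocks):
        block = np.concatenate(snippets[b * per_block : (b + 1) * per_block])
        if cfg.band is not None:
            hi = min(cfg.band[1], 0.45 * fs)
            sos = butter(8, [cfg.band[0], hi], btype="bandpass", fs=fs, output="sos")
            block = sosfilt(sos, block)
        blocks.append(block)
    return Corpus(snippets=snippets, blocks=blocks, snippet_kind=kinds, config=cfg)


def render_rooms(
    blocks: list[np.ndarray],
    irs: dict[str, ImpulseResponse],
    sample_rate: float,
) -> dict[str, list[np.ndarray]]:
    """Convolve each block with each room's impulse response.

    Outputs are truncated to the block length so every room shares one
    time axis; the direct-path delay is identical across rooms (same
    source-receiver distance), so renders are aligned to a common onset.
    """
    out: dict[str, list[np.ndarray]] = {}
    for label, ir in irs.items():
        rendered = []
        for block in blocks:
            y = convolve_stimulus(block, sample_rate, ir)
            rendered.append(y[: block.size])
        out[label] = rendered
    return out


# ---------------------------------------------------------------------------
# Noise probes


@dataclass(frozen=True)
class ProbeSpec:
    """An unreverberated broadband noise burst late in each block."""

    duration: float = 0.5
    window: tuple[float, float] = (36.0, 39.5)  # onset range, seconds
    repeats_with_probe: int = 7
    n_repeats: int = 10
    level: float = 1.0  # probe RMS relative to block RMS

    def __post_init__(self) -> None:
        if self.window[0] + 0 > self.window[1]:
            raise ValueError("empty probe onset window")
        if self.repeats_with_probe > self.n_repeats:
            raise ValueError("more probed repeats than repeats")


@dataclass
class ProbeLog:
    """Probe waveform plus per-(block, repeat) onsets (None = no probe)."""

    probe: np.ndarray
    onsets: dict[tuple[int, int], float | None]
    spec: ProbeSpec

    def probed_repeats(self, block: int) -> list[int]:
        return [
            r
            for (b, r), on in self.onsets.items()
            if b == block and on is not None
        ]


def make_probe_log(
    n_blocks: int,
    block_duration: float,
    spec: ProbeSpec,
    sample_rate: float,
    seed: int = 0,
) -> ProbeLog:
    """Draw probe onsets: uniform within the window, independent across
    blocks and repeats; exactly repeats_with_probe of n_repeats repeats
    carry a probe.  One fixed broadband burst is shared by all probes."""
    if spec.window[1] + spec.duration > block_duration:
        raise ValueError("probe would extend past the end of the block")
    rng = np.random.default_rng(seed)
    n_probe = int(round(spec.duration * sample_rate))
    ramp_n = max(int(0.005 * sample_rate), 2)
    probe = rng.standard_normal(n_probe)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    probe[:ramp_n] *= ramp
    probe[-ramp_n:] *= ramp[::-1]
    onsets: dict[tuple[int, int], float | None] = {}
    for b in range(n_blocks):
        probed = rng.choice(spec.n_repeats, size=spec.repeats_with_probe, replace=False)
        for r in range(spec.n_repeats):
            if r in probed:
                onsets[(b, r)] = float(rng.uniform(*spec.window))
            else:
                onsets[(b, r)] = None
    return ProbeLog(probe=probe, onsets=onsets, spec=spec)


def apply_probe(
    block_wave: np.ndarray,
    log: ProbeLog,
    block: int,
    repeat: int,
    sample_rate: float,
) -> np.ndarray:
    """Add the (unreverberated) probe into one repeat of a rendered block.

    The probe is added after room rendering, so it carries no
    reverberation; its amplitude is level x the block RMS.  Repeats
    without a probe return the block unchanged.
    """
    onset = log.onsets[(block, repeat)]
    if onset is None:
        return block_wave
    out = block_wave.copy()
    i = int(round(onset * sample_rate))
    scale = log.spec.level * np.sqrt(np.mean(block_wave**2)) / np.sqrt(
        np.mean(log.probe**2)
    )
    out[i : i + log.probe.size] += scale * log.probe[: max(out.size - i, 0)]
    return out


# ---------------------------------------------------------------------------
# Switching stimuli


@dataclass(frozen=True)
class SwitchingSpec:
    """Stimuli alternating room every epoch, each epoch split in two
    periods (S1/S2 in the small room, L1/L2 in the large room)."""

    epoch: float = 8.0
    period: float = 4.0
    n_stimuli: int = 8
    stimulus_duration: float = 40.0
    crossfade: float = 0.010
    overlap: float = 0.005

    def __post_init__(self) -> None:
        if self.period * 2 != self.epoch:
            raise ValueError("an epoch is exactly two periods")
        if self.stimulus_duration % self.epoch:
            raise ValueError("stimulus must hold whole epochs")

    @property
    def epochs_per_stimulus(self) -> int:
        return int(self.stimulus_duration / self.epoch)


@dataclass
class SwitchingStimuli:
    waveforms: list[np.ndarray]
    annotations: list[list[dict]]  # per stimulus: {label, period, start, end}
    spec: SwitchingSpec


def build_switching(
    blocks_small: list[np.ndarray],
    blocks_large: list[np.ndarray],
    spec: SwitchingSpec,
    sample_rate: float,
    seed: int = 0,
) -> SwitchingStimuli:
    """Cut the rendered blocks of both rooms into period-length snippets,
    duplicate and independently shuffle each set, and splice them into
    alternating-room stimuli with cosine crossfades.

    The first-period sets (S1, L1) and second-period sets (S2, L2)
    contain the same snippet multisets in different orders; half the
    stimuli start with the large room.
    """
    rng = np.random.default_rng(seed)
    n_per = int(round(spec.period * sample_rate))

    def cut(blocks: list[np.ndarray]) -> list[np.ndarray]:
        joined = np.concatenate(blocks)
        n_snips = joined.size // n_per
        return [joined[i * n_per : (i + 1) * n_per] for i in range(n_snips)]

    snips_s = cut(blocks_small)
    snips_l = cut(blocks_large)
    n_epochs_total = spec.n_stimuli * spec.epochs_per_stimulus
    if len(snips_s) * 2 < n_epochs_total or len(snips_l) * 2 < n_epochs_total:
        raise ValueError("not enough source material for the switching set")

    order = {
        "S1": rng.permutation(len(snips_s)),
        "S2": rng.permutation(len(snips_s)),
        "L1": rng.permutation(len(snips_l)),
        "L2": rng.permutation(len(snips_l)),
    }
    pointers = {k: 0 for k in order}

    n_fade = int(round(spec.crossfade * sample_rate))
    n_ov = int(round(spec.overlap * sample_rate))
    fade_in = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))

    stimuli, annotations = [], []
    for s in range(spec.n_stimuli):
        start_large = s < spec.n_stimuli // 2
        labels: list[str] = []
        for e in range(spec.epochs_per_stimulus):
            large = start_large if e % 2 == 0 else not start_large
            labels += ["L1", "L2"] if large else ["S1", "S2"]
        pieces = []
        ann = []
        pos = 0
        for k, label in enumerate(labels):
            src = snips_l if label.startswith("L") else snips_s
            idx = order[label][pointers[label]]
            pointers[label] += 1
            piece = src[idx].copy()
            piece[:n_fade] *= fade_in
            piece[-n_fade:] *= fade_in[::-1]
            start = 0 if k == 0 else pos - n_ov
            ann.append(
                {
                    "label": label,
                    "period": k,
                    "start": start / sample_rate,
                    "end": (start + n_per) / sample_rate,
                    "snippet": int(idx),
                }
            )
            pieces.append((start, piece))
            pos = start + n_per
        wave = np.zeros(pos)
        for start, piece in pieces:
            wave[start : start + n_per] += piece
        stimuli.append(wave)
        annotations.append(ann)
    return SwitchingStimuli(waveforms=stimuli, annotations=annotations, spec=spec)


# ---------------------------------------------------------------------------
# Ground-truth neurons


@dataclass(frozen=True)
class PopulationConfig:
    """Distributions from which ground-truth neurons are drawn.

    Each neuron's STRF is a Gaussian in log-frequency (channel index)
    times a difference of Gaussians in time: an early excitatory lobe and
    a delayed inhibitory lobe.  Lobes are kept temporally separated so
    the planted inhibition delay maps directly onto the inhibitory centre
    of mass.  Sigmoid parameters act on the z-scored linear drive; slopes
    are gentle (rho2 of order the drive SD) so the static nonlinearity
    introduces only mild stimulus-statistics artefacts.
    """

    n_freq: int = 30
    h_max: int = 20
    tau_ms: float = 10.0
    bf_channel_range: tuple[int, int] = (4, 26)
    exc_latency_ms: tuple[float, float] = (10.0, 25.0)
    exc_width_ms: tuple[float, float] = (4.0, 7.0)
    inh_delay_after_exc_ms: tuple[float, float] = (25.0, 40.0)
    inh_width_ms: tuple[float, float] = (10.0, 16.0)
    inh_gain: tuple[float, float] = (0.8, 1.2)
    spectral_width_ch: tuple[float, float] = (1.2, 2.2)
    rho1: tuple[float, float] = (2.0, 4.0)  # spikes/bin output range
    rho2: tuple[float, float] = (1.2, 2.0)  # slope scale, drive-SD units
    rho3: tuple[float, float] = (0.4, 1.2)  # threshold, drive-SD units
    rho4: tuple[float, float] = (0.02, 0.10)  # baseline spikes/bin


@dataclass
class GroundTruthNeuron:
    """A planted neuron with (possibly) room-dependent inhibition delay.

    adaptation_shift is the inhibition delay added per unit increase of
    the room's reverberation rank (rooms ordered by median RT60); 0 makes
    the neuron static.  The sigmoid operates on the z-scored linear
    drive, with the z-scoring frozen against a fixed reference stimulus
    so the neuron itself has no adaptive component.
    """

    unit_id: int
    bf_channel: int
    exc_latency: float  # ms
    exc_width: float
    inh_delay: float  # ms, room rank 0
    inh_width: float
    inh_gain: float
    spectral_width: float  # channels
    adaptation_shift: float  # ms per unit room rank
    nonlinearity: SigmoidParams
    config: PopulationConfig

    def kernel(self, room_rank: float = 0.0, channel_centers: np.ndarray | None = None) -> Kernel:
        """Ground-truth STRF for a room of the given reverberation rank."""
        cfg = self.config
        t = (np.arange(cfg.h_max) + 0.5) * cfg.tau_ms
        f = np.arange(cfg.n_freq)
        t_inh = self.inh_delay + self.adaptation_shift * room_rank
        temporal = np.exp(-0.5 * ((t - self.exc_latency) / self.exc_width) ** 2)
        temporal -= self.inh_gain * np.exp(-0.5 * ((t - t_inh) / self.inh_width) ** 2)
        spectral = np.exp(-0.5 * ((f - self.bf_channel) / self.spectral_width) ** 2)
        return Kernel(
            weights=np.outer(spectral, temporal),
            bias=0.0,
            target_id=self.unit_id,
            channel_centers=channel_centers,
        )


def generate_population(
    n_units: int,
    adaptation_shift_ms: float,
    cfg: PopulationConfig | None = None,
    seed: int = 0,
    adaptive_fraction: float = 1.0,
) -> list[GroundTruthNeuron]:
    """Draw a population of ground-truth neurons.

    The first round(adaptive_fraction * n_units) units receive the given
    adaptation shift; the rest are static.  All tuning parameters are
    drawn independently per unit from the configured ranges.
    """
    cfg = cfg or PopulationConfig()
    rng = np.random.default_rng(seed)
    n_adaptive = int(round(adaptive_fraction * n_units))
    units = []
    for i in range(n_units):
        exc_lat = rng.uniform(*cfg.exc_latency_ms)
        units.append(
            GroundTruthNeuron(
                unit_id=i,
                bf_channel=int(rng.integers(*cfg.bf_channel_range)),
                exc_latency=exc_lat,
                exc_width=rng.uniform(*cfg.exc_width_ms),
                inh_delay=exc_lat + rng.uniform(*cfg.inh_delay_after_exc_ms),
                inh_width=rng.uniform(*cfg.inh_width_ms),
                inh_gain=rng.uniform(*cfg.inh_gain),
                spectral_width=rng.uniform(*cfg.spectral_width_ch),
                adaptation_shift=adaptation_shift_ms if i < n_adaptive else 0.0,
                nonlinearity=SigmoidParams(
                    rho1=rng.uniform(*cfg.rho1),
                    rho2=rng.uniform(*cfg.rho2),
                    rho3=rng.uniform(*cfg.rho3),
                    rho4=rng.uniform(*cfg.rho4),
                ),
                config=cfg,
            )
        )
    return units


def simulate_population(
    neurons: list[GroundTruthNeuron],
    design_by_room: dict[str, np.ndarray],
    room_ranks: dict[str, float],
    n_trials: int = 10,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Poisson trial counts of every neuron in every room.

    design_by_room maps room label to the lagged cochleagram design
    matrix (T x P).  Each neuron's drive is z-scored against the pooled
    rooms using its rank-0 kernel (a fixed, condition-independent
    normalisation), passed through its sigmoid, and sampled n_trials
    times.  Returns room -> counts array (n_units, n_trials, T).
    """
    rooms = list(design_by_room)
    X_all = np.vstack([design_by_room[r] for r in rooms])
    W0 = np.stack([nrn.kernel(0.0).weights.ravel() for nrn in neurons], axis=1)
    drive_ref = X_all @ W0  # (T_all, n_units)
    mu = drive_ref.mean(axis=0)
    sd = drive_ref.std(axis=0)
    sd[sd == 0] = 1.0

    root = np.random.SeedSequence(seed)
    room_seeds = root.spawn(len(rooms))
    out: dict[str, np.ndarray] = {}
    for ri, r in enumerate(rooms):
        X = design_by_room[r]
        Wr = np.stack(
            [nrn.kernel(room_ranks[r]).weights.ravel() for nrn in neurons], axis=1
        )
        z = (X @ Wr - mu) / sd  # (T, n_units)
        counts = np.empty((len(neurons), n_trials, X.shape[0]), dtype=np.int64)
        unit_seeds = room_seeds[ri].spawn(len(neurons))
        for i, nrn in enumerate(neurons):
            rate = np.clip(sigmoid(z[:, i], nrn.nonlinearity), 0.0, None)
            rng = np.random.default_rng(unit_seeds[i])
            counts[i] = rng.poisson(rate, size=(n_trials, rate.size))
        out[r] = counts
    return out


def embed_probes(
    n_blocks: int,
    block_duration: float,
    sample_rate: float,
    spec: ProbeSpec | None = None,
    seed: int = 0,
) -> ProbeLog:
    """Draw the probe schedule for a rendered stimulus set (see
    make_probe_log); realise individual repeats with apply_probe."""
    return make_probe_log(
        n_blocks, block_duration, spec or ProbeSpec(), sample_rate, seed
    )
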