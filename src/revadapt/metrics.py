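"""Temporal-structure metrics for kernels and STRFs.

A kernel's excitatory and inhibitory structure is summarised by rectifying
its weights, averaging over frequency to get per-lag profiles v+ and v-,
and reducing each profile to a centre of mass (COM) and a peak time (PT).
Lag h (0-based) covers the window [h*tau, (h+1)*tau) and is assigned its
bin centre (h + 0.5) * tau, so with tau = 10 ms and 20 lags both metrics
live in [5, 195] ms.  Peak times are read off a band-limited (Fourier)
interpolation of the profile to defeat the 10 ms quantisation.

Undefined metrics (an all-zero rectified profile, a kernel with no
positive weight) are returned as NaN and excluded pairwise from
population statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample

from .ridge import Kernel

TAU_MS = 10.0  # time-bin duration in ms


@dataclass
class TemporalProfile:
    """Frequency-averaged rectified weight profiles per lag."""

    v_plus: np.ndarray  # >= 0, mean positive part per lag
    v_minus: np.ndarray  # <= 0, mean negative part per lag
    tau_ms: float = TAU_MS

    @property
    def h_max(self) -> int:
        return self.v_plus.size

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return (np.arange(self.h_max) + 0.5) * self.tau_ms


@dataclass
class RFMetrics:
    """Scalar temporal/spectral metrics of one kernel (NaN = undefined)."""

    com_plus: float
    com_minus: float
    pt_plus: float
    pt_minus: float
    best_frequency: float


def temporal_profiles(kernel: Kernel | np.ndarray, tau_ms: float = TAU_MS) -> TemporalProfile:
    """Rectified frequency-mean profiles: v+[h] = mean_f max(w[f,h], 0),
    v-[h] = mean_f min(w[f,h], 0)."""
    w = kernel.weights if isinstance(kernel, Kernel) else np.asarray(kernel)
    return TemporalProfile(
        v_plus=np.maximum(w, 0.0).mean(axis=0),
        v_minus=np.minimum(w, 0.0).mean(axis=0),
        tau_ms=tau_ms,
    )


def center_of_mass(profile: TemporalProfile, sign: str) -> float:
    """Weighted mean of lag-bin centres, weights |v+| or |v-|.

    Returns NaN when the selected profile is identically zero.
    """
    v = _select(profile, sign)
    w = np.abs(v)
    total = w.sum()
    if total == 0:
        return float("nan")
    return float((profile.bin_centers_ms * w).sum() / total)


def peak_time(
    profile: TemporalProfile, sign: str, interp_factor: int = 100
) -> float:
    """Time of the profile's extremum after Fourier interpolation.

    The profile is band-limited resampled by interp_factor; PT+ is the
    time of the maximum of v+, PT- the time of the minimum of v-.  The
    search is restricted to times up to the last bin centre so the metric
    stays within [tau/2, tau*(h_max - 0.5)]; exact ties resolve to the
    earliest time.  NaN for an identically zero profile.
    """
    v = _select(profile, sign)
    if np.all(v == 0):
        return float("nan")
    n = v.size
    fine = resample(v, n * interp_factor)
    times = (np.arange(n * interp_factor) / interp_factor + 0.5) * profile.tau_ms
    limit = (n - 0.5) * profile.tau_ms
    keep = times <= limit
    fine, times = fine[keep], times[keep]
    idx = int(np.argmax(fine)) if sign == "+" else int(np.argmin(fine))
    return float(times[idx])


def best_frequency(kernel: Kernel) -> float:
    """Centre frequency of the channel holding the largest kernel weight.

    Ties resolve to the lowest-frequency channel.  NaN if the kernel has
    no positive weight (no excitatory field to assign a frequency to).
    """
    w = kernel.weights
    if kernel.channel_centers is None:
        raise ValueError("kernel carries no channel centre frequencies")
    if w.max() <= 0:
        return float("nan")
    f_idx = int(np.unravel_index(int(np.argmax(w)), w.shape)[0])
    return float(kernel.channel_centers[f_idx])


def rf_metrics(kernel: Kernel, tau_ms: float = TAU_MS) -> RFMetrics:
    """All temporal/spectral metrics of one kernel.

    Best frequency is NaN when the kernel carries no channel-centre grid.
    """
    prof = temporal_profiles(kernel, tau_ms)
    bf = (
        best_frequency(kernel)
        if kernel.channel_centers is not None
        else float("nan")
    )
    return RFMetrics(
        com_plus=center_of_mass(prof, "+"),
        com_minus=center_of_mass(prof, "-"),
        pt_plus=peak_time(prof, "+"),
        pt_minus=peak_time(prof, "-"),
        best_frequency=bf,
    )


def psth_com(
    psth: np.ndarray, tau_ms: float = TAU_MS, window_ms: tuple[float, float] = (0.0, 100.0)
) -> float:
    """Centre of mass of a firing-rate profile within a post-onset window.

    psth holds non-negative rates per tau_ms bin, bin 0 starting at the
    alignment time; only bins whose centres fall inside window_ms
    contribute.  NaN if the windowed rate is all zero.
    """
    psth = np.asarray(psth, dtype=float)
    if np.any(psth < 0):
        raise ValueError("rates must be non-negative")
    centers = (np.arange(psth.size) + 0.5) * tau_ms
    keep = (centers > window_ms[0]) & (centers < window_ms[1])
    if not keep.any():
        raise ValueError("window contains no bins")
    w = psth[keep]
    if w.sum() == 0:
        return float("nan")
    return float((centers[keep] * w).sum() / w.sum())


def _select(profile: TemporalProfile, sign: str) -> np.ndarray:
    if sign == "+":
        return profile.v_plus
    if sign == "-":
        return profile.v_minus
    raise ValueError("sign must be '+' or '-'")
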