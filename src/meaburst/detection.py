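"""Spike, burst and network-burst detection.

Three stages, each with the parameter set conventional for dissociated
cortical cultures on MEAs:

* spike detection on raw traces with a differential (peak-to-peak) threshold
  of 8x the noise SD, a 2 ms spike lifetime and a 1 ms refractory period;
* burst detection on spike trains with the string method (>= 5 spikes, all
  inter-spike intervals <= 100 ms);
* network-burst detection by chaining per-electrode burst events whose gaps
  fall below a self-adaptive inter-burst-event-interval threshold, keeping
  chains that span >= 20% of the recording electrodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

DEFAULT_THRESHOLD_FACTOR = 8.0
DEFAULT_LIFETIME_S = 2e-3
DEFAULT_REFRACTORY_S = 1e-3
DEFAULT_MIN_SPIKES = 5
DEFAULT_MAX_ISI_S = 0.1
DEFAULT_MIN_NB_FRACTION = 0.20
IBEI_FALLBACK_S = 0.1
IBEI_CAP_S = 1.0


@dataclass(frozen=True)
class Burst:
    """A run of >=5 spikes on one electrode with all ISIs <= 100 ms."""

    electrode: str
    start: float  # s, first spike
    end: float  # s, last spike
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1e3


@dataclass(frozen=True)
class NetworkBurst:
    """A chained group of bursts spanning >=20% of recording electrodes."""

    nb_id: int
    start: float
    end: float
    participating_electrodes: frozenset[str]
    fraction_active: float


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD of a raw trace (µV): median(|x|)/0.6745.

    The median-absolute-deviation estimator ignores the sparse large
    excursions produced by spikes, which inflate the plain SD.  A constant
    trace yields 0 with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    sd = float(np.median(np.abs(trace)) / 0.6745)
    if sd == 0.0:
        warnings.warn("constant trace: noise SD is 0", stacklevel=2)
    return sd


def detect_spikes_ptsd(
    trace: np.ndarray,
    sampling_rate: float,
    threshold: float | None = None,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    lifetime: float = DEFAULT_LIFETIME_S,
    refractory: float = DEFAULT_REFRACTORY_S,
) -> np.ndarray:
    """Differential-threshold spike detection with precise timing.

    Scans the local extrema of the trace; a pair of consecutive opposite
    extrema within one spike lifetime whose peak-to-peak excursion reaches
    the differential threshold (``threshold_factor`` x noise SD unless an
    absolute ``threshold`` in µV is given) marks a spike, timed at the
    absolutely larger extremum.  Detections closer than the refractory
    period are merged (first kept).  Returns sorted spike times in seconds.
    """
    if lifetime <= 0 or refractory <= 0:
        raise ValueError("lifetime and refractory must be positive")
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        return np.empty(0)
    if threshold is None:
        threshold = threshold_factor * estimate_noise_sd(trace)
    if threshold <= 0:
        return np.empty(0)

    maxima, _ = signal.find_peaks(trace)
    minima, _ = signal.find_peaks(-trace)
    ext = np.sort(np.concatenate([maxima, minima]))
    if ext.size < 2:
        return np.empty(0)
    vals = trace[ext]
    max_lag = int(round(lifetime * sampling_rate))
    candidates: list[int] = []
    for i in range(ext.size - 1):
        j = i + 1
        if ext[j] - ext[i] > max_lag:
            continue
        if abs(vals[j] - vals[i]) < threshold:
            continue
        spike_idx = ext[i] if abs(vals[i]) >= abs(vals[j]) else ext[j]
        candidates.append(int(spike_idx))
    if not candidates:
        return np.empty(0)
    candidates = sorted(set(candidates))
    ref_samples = refractory * sampling_rate
    kept = [candidates[0]]
    for idx in candidates[1:]:
        if idx - kept[-1] >= ref_samples:
            kept.append(idx)
    return np.asarray(kept, dtype=float) / sampling_rate


def detect_bursts_string(
    train: np.ndarray,
    electrode: str = "",
    min_spikes: int = DEFAULT_MIN_SPIKES,
    max_isi: float = DEFAULT_MAX_ISI_S,
) -> list[Burst]:
    """String-method burst detection on one sorted spike train.

    Maximal runs of consecutive spikes whose inter-spike intervals are all
    <= ``max_isi`` become bursts when they contain >= ``min_spikes`` spikes;
    burst start/end are the first/last spike of the run.
    """
    train = np.asarray(train, dtype=float)
    bursts: list[Burst] = []
    if train.size < min_spikes:
        return bursts
    gaps = np.flatnonzero(np.diff(train) > max_isi)
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [train.size - 1]])
    for s, e in zip(starts, ends):
        n = int(e - s + 1)
        if n >= min_spikes:
            bursts.append(Burst(electrode, float(train[s]), float(train[e]), n))
    return bursts


def compute_ibei_threshold(bursts: list[Burst]) -> tuple[float, bool]:
    """Self-adaptive merge threshold from the network-wide IBeI histogram.

    Pools burst-event onsets across electrodes, histograms the log10
    inter-burst-event intervals, and places the threshold at the density
    valley between the two largest modes (within-NB vs between-NB gaps),
    capped at 1 s.  A unimodal histogram falls back to 100 ms.  Returns
    ``(threshold_s, is_fallback)``.  Requires >= 2 burst events.
    """
    if len(bursts) < 2:
        raise ValueError("need at least 2 burst events for a threshold")
    onsets = np.sort(np.array([b.start for b in bursts]))
    ibei = np.diff(onsets)
    ibei = ibei[ibei > 0]
    if ibei.size < 2:
        return IBEI_FALLBACK_S, True
    log_ibei = np.log10(ibei)
    nbins = max(10, min(100, ibei.size // 2))
    hist, edges = np.histogram(log_ibei, bins=nbins)
    smooth = gaussian_filter1d(hist.astype(float), sigma=1.0)
    # zero-pad so modes in the first/last bin still count as peaks
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = signal.find_peaks(padded, prominence=smooth.max() * 0.1)
    peaks -= 1
    if peaks.size < 2:
        return IBEI_FALLBACK_S, True
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    # a genuine bimodal histogram dips well below its smaller mode
    if smooth[valley] > 0.5 * min(smooth[lo], smooth[hi]):
        return IBEI_FALLBACK_S, True
    centers = (edges[:-1] + edges[1:]) / 2
    threshold = float(10.0 ** centers[valley])
    return min(threshold, IBEI_CAP_S), False


def detect_network_bursts(
    bursts: list[Burst],
    n_recording_electrodes: int,
    min_fraction: float = DEFAULT_MIN_NB_FRACTION,
    threshold: float | None = None,
) -> list[NetworkBurst]:
    """Chain burst events into network bursts.

    Burst events sorted by onset are chained while the gap between an
    event's onset and the running chain end is <= the IBeI threshold
    (self-adaptive unless given).  Chains involving >= ``min_fraction`` of
    the ``n_recording_electrodes`` become network bursts spanning the
    min start to max end of their member bursts.
    """
    if not bursts or n_recording_electrodes <= 0:
        return []
    if threshold is None:
        if len(bursts) < 2:
            return []
        threshold, _ = compute_ibei_threshold(bursts)
    events = sorted(bursts, key=lambda b: (b.start, b.end, b.electrode))
    chains: list[list[Burst]] = [[events[0]]]
    chain_end = events[0].end
    for b in events[1:]:
        if b.start - chain_end <= threshold:
            chains[-1].append(b)
            chain_end = max(chain_end, b.end)
        else:
            chains.append([b])
            chain_end = b.end
    nbs: list[NetworkBurst] = []
    for chain in chains:
        electrodes = frozenset(b.electrode for b in chain)
        fraction = len(electrodes) / n_recording_electrodes
        if fraction >= min_fraction:
            nbs.append(
                NetworkBurst(
                    nb_id=len(nbs),
                    start=min(b.start for b in chain),
                    end=max(b.end for b in chain),
                    participating_electrodes=electrodes,
                    fraction_active=fraction,
                )
            )
    return nbs


def detect_all_bursts(
    trains: dict[str, np.ndarray],
    min_spikes: int = DEFAULT_MIN_SPIKES,
    max_isi: float = DEFAULT_MAX_ISI_S,
) -> dict[str, list[Burst]]:
    """String-method bursts for every electrode of a recording."""
    return {
        e: detect_bursts_string(t, electrode=e, min_spikes=min_spikes, max_isi=max_isi)
        for e, t in trains.items()
    }
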