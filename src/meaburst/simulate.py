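"""Synthetic MEA recordings with pacemaker-driven network bursts.

The generator emulates the dynamics of dissociated cortical cultures on a
60-electrode array: sparse background spiking on every electrode, rhythmic
network bursts (NBs) recurring a few tens of times per minute, a hierarchy
of initiator clusters that start most NBs, ordered recruitment of the
remaining clusters with a tunable preference for edge-adjacent ("circular")
propagation on the 2x2 cluster grid, and occasional verbatim repetition of
the previous activation sequence.  Every recording comes with a ground-truth
log (NB times, initiators, sequences, per-cluster activation times) so that
detection and sequence-extraction stages can be scored by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .dose_response import hill_curve
from .io import RawTraceSet, RecordingMetadata, SpikeTrainSet
from .layout import CLUSTERS, ClusterLayout


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the network-burst generator.

    Defaults describe a 20-min recording of an active modular culture:
    0.5 spikes/s background per electrode, 30 NBs/min, a dominant-initiator
    hierarchy, 100 ms lag between consecutive cluster activations and a
    strong preference for grid-adjacent propagation.
    """

    seed: int = 0
    duration: float = 1200.0  # s
    n_electrodes_per_cluster: int = 13
    background_rate: float = 0.5  # spikes/s per electrode, Poisson
    nb_rate: float = 30.0  # network bursts per minute
    initiator_probs: tuple[float, float, float, float] = (0.45, 0.30, 0.15, 0.10)
    inter_cluster_delay: float = 0.1  # s between consecutive cluster activations
    circular_bias: float = 0.75  # P(next cluster is unvisited grid-adjacent)
    within_burst_rate: float = 60.0  # spikes/s per electrode during a burst
    burst_len: float = 0.3  # s of elevated firing per cluster
    recruit_probs: float = 0.85  # P(each non-initiator cluster joins an NB)
    repeat_run_prob: float = 0.15  # P(next NB repeats the previous sequence)
    min_isi: float = 2e-3  # s; closer events are unresolvable on one electrode

    def __post_init__(self) -> None:
        p = np.asarray(self.initiator_probs, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("initiator_probs must be a 4-vector of probabilities summing to 1")
        for name in ("background_rate", "nb_rate", "within_burst_rate", "burst_len",
                     "inter_cluster_delay", "duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("circular_bias", "recruit_probs", "repeat_run_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthNB:
    """Logged truth for one simulated network burst."""

    nb_id: int
    t_start: float  # onset of the first cluster's firing
    t_end: float  # offset of the last cluster's firing
    initiator: str
    sequence: tuple[str, ...]  # recruited clusters in activation order
    cluster_peak_times: dict[str, float]  # expected IFR peak per recruited cluster


MIN_NB_GAP_S = 0.2  # silent gap between the end of one NB and the next onset


def _nb_interval_mean(params: SimulationParams) -> float:
    """Mean exponential waiting time on top of the dead time.

    The renewal process (interval = event span + gap + Exponential) keeps
    the realized NB rate at ``nb_rate``: plain thinning of a Poisson stream
    would deflate it.  Sized against the full-recruitment event span.
    """
    if params.nb_rate <= 0:
        raise ValueError("nb_rate must be positive to place network bursts")
    span_max = 3 * params.inter_cluster_delay + params.burst_len
    exp_mean = 60.0 / params.nb_rate - (span_max + MIN_NB_GAP_S)
    if exp_mean <= 0:
        raise ValueError("nb_rate too high for the non-overlap constraint")
    return exp_mean


def _draw_order(
    initiator: str,
    layout: ClusterLayout,
    circular_bias: float,
    rng: np.random.Generator,
) -> list[str]:
    """Activation order over all four clusters, built stepwise.

    At each step the next cluster is, with probability ``circular_bias``, a
    uniform draw among *unvisited grid-adjacent* clusters (when any exist),
    otherwise a uniform draw among all unvisited clusters.  ``circular_bias=0``
    therefore makes all 6 orders from a given initiator equiprobable, and
    ``circular_bias=1`` forces a circular walk.
    """
    order = [initiator]
    unvisited = [c for c in CLUSTERS if c != initiator]
    while unvisited:
        adj = [c for c in unvisited if layout.is_adjacent(order[-1], c)]
        if adj and rng.random() < circular_bias:
            pool = adj
        else:
            pool = unvisited
        nxt = pool[rng.integers(len(pool))]
        order.append(nxt)
        unvisited.remove(nxt)
    return order


# inverse CDF of the raised-cosine (Hann) density on [0, 1], tabulated once
_HANN_GRID = np.linspace(0.0, 1.0, 2049)
_HANN_CDF = _HANN_GRID - np.sin(2 * np.pi * _HANN_GRID) / (2 * np.pi)


def _hann_times(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n points on [0,1] from the raised-cosine density 1 - cos(2*pi*u)."""
    return np.interp(rng.random(n), _HANN_CDF, _HANN_GRID)


def simulate_recording(
    params: SimulationParams, layout: ClusterLayout
) -> tuple[SpikeTrainSet, list[GroundTruthNB]]:
    """Simulate spike trains plus the ground-truth NB log.

    Within-burst firing of each recruited cluster is an inhomogeneous Poisson
    process with a raised-cosine rate profile of mean ``within_burst_rate``
    over ``burst_len``, lagged by ``inter_cluster_delay`` per activation rank;
    the profile peaks at lag + burst_len/2, which is the logged expected
    cluster IFR peak time.  Interstitial electrodes carry background spiking
    only.  Same seed, same params => bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    meta = RecordingMetadata(duration=params.duration, assembly_type="4N")
    spikes: dict[str, list[np.ndarray]] = {e: [] for e in layout.electrode_ids}

    # background Poisson spiking on every electrode (incl. interstitial)
    if params.background_rate > 0:
        for e in layout.electrode_ids:
            n = rng.poisson(params.background_rate * params.duration)
            spikes[e].append(rng.uniform(0.0, params.duration, n))

    members = {c: layout.members(c)[: params.n_electrodes_per_cluster] for c in CLUSTERS}
    truth: list[GroundTruthNB] = []
    prev_sequence: tuple[str, ...] | None = None
    exp_mean = _nb_interval_mean(params) if params.nb_rate > 0 else None
    span_max = 3 * params.inter_cluster_delay + params.burst_len
    t0 = rng.exponential(exp_mean) if exp_mean is not None else np.inf
    k = 0
    while t0 + span_max < params.duration:
        if prev_sequence is not None and rng.random() < params.repeat_run_prob:
            sequence = prev_sequence
        else:
            initiator = CLUSTERS[int(rng.choice(4, p=np.asarray(params.initiator_probs)))]
            order = _draw_order(initiator, layout, params.circular_bias, rng)
            sequence = tuple(
                c for i, c in enumerate(order)
                if i == 0 or rng.random() < params.recruit_probs
            )
        peak_times: dict[str, float] = {}
        for rank, c in enumerate(sequence):
            lag = t0 + rank * params.inter_cluster_delay
            peak_times[c] = lag + params.burst_len / 2
            for e in members[c]:
                n = rng.poisson(params.within_burst_rate * params.burst_len)
                times = lag + params.burst_len * _hann_times(n, rng)
                spikes[e].append(times)
        t_end = t0 + (len(sequence) - 1) * params.inter_cluster_delay + params.burst_len
        truth.append(
            GroundTruthNB(k, float(t0), float(t_end), sequence[0], sequence, peak_times)
        )
        prev_sequence = sequence
        t0 = t_end + MIN_NB_GAP_S + rng.exponential(exp_mean)
        k += 1

    trains: dict[str, np.ndarray] = {}
    for e, chunks in spikes.items():
        if chunks:
            t = np.unique(np.concatenate(chunks))
            t = np.clip(t, 0.0, params.duration - 1e-9)
            trains[e] = _enforce_min_isi(t, params.min_isi)
        else:
            trains[e] = np.empty(0)
    return SpikeTrainSet(meta, trains), truth


def _enforce_min_isi(times: np.ndarray, min_isi: float) -> np.ndarray:
    """Greedily drop events closer than min_isi to their kept predecessor.

    Without spike sorting an electrode cannot resolve two events within the
    detector's dead time; the ground truth honours the same floor so that
    detection recall is well defined.
    """
    if times.size < 2 or min_isi <= 0:
        return times
    kept = [times[0]]
    for x in times[1:]:
        if x - kept[-1] >= min_isi:
            kept.append(x)
    return np.asarray(kept)


def default_spike_template(
    amplitude_uv: float, sampling_rate: float = 10_000.0
) -> np.ndarray:
    """Stereotyped biphasic extracellular spike waveform.

    Derivative-of-Gaussian shape, ~1.2 ms long, scaled so its peak-to-peak
    amplitude equals ``amplitude_uv``.
    """
    n = max(int(round(1.2e-3 * sampling_rate)), 5)
    t = np.linspace(-3, 3, n)
    wave = -t * np.exp(-(t**2) / 2)
    wave[t < 0] *= 0.6  # smaller leading lobe, as in extracellular waveforms
    return wave / np.ptp(wave) * amplitude_uv


def simulate_raw_traces(
    spikes: SpikeTrainSet,
    noise_sd: float,
    spike_template: np.ndarray | None = None,
    seed: int = 0,
) -> RawTraceSet:
    """Gaussian noise plus a stereotyped waveform inserted at each spike time.

    Overlapping templates are summed.  With ``noise_sd=0`` the traces are the
    clean superposition of templates, which a spike detector must recover
    exactly (noiseless limit).
    """
    rng = np.random.default_rng(seed)
    fs = spikes.metadata.sampling_rate
    n_samples = int(round(spikes.metadata.duration * fs))
    if spike_template is None:
        spike_template = default_spike_template(10.0 * max(noise_sd, 1.0), fs)
    template = np.asarray(spike_template, dtype=float)
    half = int(np.argmax(np.abs(template)))  # dominant extremum sits on the spike sample
    traces: dict[str, np.ndarray] = {}
    for e, train in spikes.trains.items():
        trace = (
            rng.normal(0.0, noise_sd, n_samples)
            if noise_sd > 0
            else np.zeros(n_samples)
        )
        for t in train:
            # align the template's extremum with the spike sample
            center = int(round(t * fs))
            lo = center - half
            hi = lo + template.size
            tlo, thi = max(lo, 0), min(hi, n_samples)
            trace[tlo:thi] += template[tlo - lo : template.size - (hi - thi)]
        traces[e] = trace
    return RawTraceSet(spikes.metadata, traces)


@dataclass(frozen=True)
class HillSimParams:
    """Ground truth for a synthetic dose–response experiment."""

    ic50: float = 15.0  # µM
    hc: float = 1.0
    mfr_max: float = 1.0  # normalized rate at zero dose
    mfr_min: float = 0.0  # normalized rate at saturating dose
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0)  # µM
    noise_sd: float = 0.0  # additive Gaussian noise on the normalized rate

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if not self.mfr_max >= self.mfr_min >= 0:
            raise ValueError("require mfr_max >= mfr_min >= 0")


def simulate_dose_response(
    p: HillSimParams, seed: int = 0
) -> list[tuple[float, float]]:
    """Normalized-MFR points drawn from the Hill curve plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    out = []
    for c in p.concentrations:
        v = float(hill_curve(c, p.mfr_max, p.mfr_min, p.hc, p.ic50))
        if p.noise_sd > 0:
            v += rng.normal(0.0, p.noise_sd)
        out.append((float(c), v))
    return out
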