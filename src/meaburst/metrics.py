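"""Firing/bursting statistics and IFR-based cluster activation sequences.

The instantaneous firing rate (IFR) of an electrode is its spike count in a
sliding 100 ms window, realised as a Gaussian kernel of that width; cluster
IFRs average the member electrodes that pass the 0.1 spikes/s activity
filter.  Within each network burst (NB) a cluster's activation time is the
time its IFR peaks inside the NB window,

    t_start(i,k) = argmax_t IFR_i(t),   t in [t_start(k), t_end(k)]

and the clusters ordered by these activation times form the NB's
*activation sequence*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .detection import Burst, NetworkBurst
from .layout import CLUSTERS, ClusterLayout
from .sequences import ActivationSequence

ACTIVE_MFR_THRESHOLD = 0.1  # spikes/s; quieter electrodes are discarded
IFR_WINDOW_S = 0.1  # Delta-t of the smoothing window
IFR_GRID_STEP_S = 0.01


def filter_active(
    trains: Mapping[str, np.ndarray], duration: float,
    threshold: float = ACTIVE_MFR_THRESHOLD,
) -> set[str]:
    """Electrodes whose mean firing rate reaches ``threshold`` spikes/s."""
    return {e for e, t in trains.items() if t.size / duration >= threshold}


@dataclass
class MetricsTable:
    """Per-electrode and per-recording firing/bursting statistics.

    ``per_electrode`` columns: mfr (spikes/s), mbr (bursts/min), bd_ms (mean
    burst duration), ibi_s (mean inter-burst interval, burst start to next
    burst start), sd_ibi_s, cv_ibi.  ``recording`` keys: nb_per_min, nbd_ms,
    inbi_s (list), mean_inbi_s, n_active_electrodes, duration_s.
    """

    per_electrode: pd.DataFrame
    recording: dict
    ibi_lists: dict[str, np.ndarray] = field(default_factory=dict)


def compute_metrics(
    trains: Mapping[str, np.ndarray],
    bursts: Mapping[str, list[Burst]],
    nbs: Sequence[NetworkBurst],
    duration: float,
) -> MetricsTable:
    rows = {}
    ibi_lists: dict[str, np.ndarray] = {}
    for e, train in trains.items():
        el_bursts = bursts.get(e, [])
        mfr = train.size / duration
        mbr = len(el_bursts) / duration * 60.0
        bd_ms = float(np.mean([b.duration_ms for b in el_bursts])) if el_bursts else np.nan
        starts = np.array([b.start for b in el_bursts])
        ibi = np.diff(np.sort(starts)) if starts.size >= 2 else np.empty(0)
        ibi_lists[e] = ibi
        mean_ibi = float(np.mean(ibi)) if ibi.size else np.nan
        sd_ibi = float(np.std(ibi, ddof=1)) if ibi.size >= 2 else np.nan
        cv_ibi = sd_ibi / mean_ibi if ibi.size >= 2 and mean_ibi > 0 else np.nan
        rows[e] = dict(mfr=mfr, mbr=mbr, bd_ms=bd_ms, ibi_s=mean_ibi,
                       sd_ibi_s=sd_ibi, cv_ibi=cv_ibi)
    per_electrode = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    nb_starts = np.array([nb.start for nb in nbs])
    inbi = np.diff(np.sort(nb_starts)) if nb_starts.size >= 2 else np.empty(0)
    recording = {
        "nb_per_min": len(nbs) / duration * 60.0,
        "nbd_ms": float(np.mean([(nb.end - nb.start) * 1e3 for nb in nbs])) if nbs else np.nan,
        "inbi_s": [float(x) for x in inbi],
        "mean_inbi_s": float(np.mean(inbi)) if inbi.size else np.nan,
        "n_active_electrodes": len(filter_active(trains, duration)),
        "duration_s": float(duration),
    }
    return MetricsTable(per_electrode, recording, ibi_lists)


@dataclass(frozen=True)
class IFRSeries:
    """Smoothed firing rate on a uniform time grid (spikes/s)."""

    times: np.ndarray  # grid centers, s
    rates: np.ndarray
    step: float  # s
    scope: str = "electrode"

    def window(self, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        mask = (self.times >= start) & (self.times <= end)
        return self.times[mask], self.rates[mask]


def compute_ifr(
    train: np.ndarray,
    duration: float,
    window: float = IFR_WINDOW_S,
    step: float = IFR_GRID_STEP_S,
) -> IFRSeries:
    """Gaussian-smoothed instantaneous firing rate of one spike train.

    Spikes are binned at ``step`` resolution and smoothed with a Gaussian of
    sigma = window/2 (so +-sigma spans the 100 ms window); the result is
    scaled to spikes/s and conserves total spike count (reflected edges).
    """
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    n_bins = max(int(round(duration / step)), 1)
    edges = np.arange(n_bins + 1) * step
    counts, _ = np.histogram(np.asarray(train, dtype=float), bins=edges)
    sigma_bins = (window / 2) / step
    rates = gaussian_filter1d(counts.astype(float), sigma=sigma_bins, mode="reflect")
    rates /= step
    centers = (edges[:-1] + edges[1:]) / 2
    return IFRSeries(centers, rates, step)


def cluster_ifr(
    trains: Mapping[str, np.ndarray],
    layout: ClusterLayout,
    cluster: str,
    duration: float,
    active: set[str] | None = None,
    window: float = IFR_WINDOW_S,
    step: float = IFR_GRID_STEP_S,
) -> IFRSeries | None:
    """Cluster IFR: the average IFR of the cluster's active member electrodes.

    Interstitial electrodes never contribute.  Returns ``None`` when the
    cluster has no active member (the cluster then cannot be recruited).
    """
    if active is None:
        active = filter_active(trains, duration)
    members = [e for e in layout.members(cluster) if e in active]
    if not members:
        return None
    series = [compute_ifr(trains[e], duration, window, step) for e in members]
    rates = np.mean([s.rates for s in series], axis=0)
    return IFRSeries(series[0].times, rates, step, scope=f"cluster:{cluster}")


@dataclass(frozen=True)
class ClusterActivation:
    nb_id: int
    cluster: str
    t_start: float | None  # s; None when not recruited
    peak_ifr: float
    recruited: bool
    tie: bool = False  # argmax was not unique; earliest grid time reported


def recruitment(
    bursts: Mapping[str, list[Burst]],
    layout: ClusterLayout,
    nb: NetworkBurst,
    active: set[str],
) -> dict[str, bool]:
    """A cluster joins an NB iff one of its active electrodes bursts in it."""
    out = {}
    for c in CLUSTERS:
        out[c] = any(
            b.start <= nb.end and b.end >= nb.start
            for e in layout.members(c)
            if e in active
            for b in bursts.get(e, [])
        )
    return out


def activation_times(
    cluster_ifrs: Mapping[str, IFRSeries | None],
    nb: NetworkBurst,
    recruited: Mapping[str, bool],
) -> list[ClusterActivation]:
    """Per-cluster activation time: argmax of the cluster IFR inside the NB.

    Ties at the maximum are broken to the earliest grid time and flagged.
    Raises ``ValueError`` if the NB window contains no grid point.
    """
    out: list[ClusterActivation] = []
    for c in CLUSTERS:
        series = cluster_ifrs.get(c)
        if series is None or not recruited.get(c, False):
            out.append(ClusterActivation(nb.nb_id, c, None, 0.0, False))
            continue
        times, rates = series.window(nb.start, nb.end)
        if times.size == 0:
            raise ValueError(f"NB window [{nb.start}, {nb.end}] contains no IFR grid point")
        peak = float(rates.max())
        at_peak = times[rates == peak]
        out.append(
            ClusterActivation(nb.nb_id, c, float(at_peak[0]), peak, True, tie=at_peak.size > 1)
        )
    return out


def extract_sequence(activations: Sequence[ClusterActivation]) -> ActivationSequence:
    """Order the recruited clusters by activation time into a sequence."""
    recruited = [a for a in activations if a.recruited]
    if not recruited:
        raise ValueError("no recruited cluster: no sequence to extract")
    recruited.sort(key=lambda a: (a.t_start, a.cluster))
    nb_id = recruited[0].nb_id
    return ActivationSequence(tuple(a.cluster for a in recruited), nb_index=nb_id)


def extract_all_sequences(
    trains: Mapping[str, np.ndarray],
    bursts: Mapping[str, list[Burst]],
    nbs: Sequence[NetworkBurst],
    layout: ClusterLayout,
    duration: float,
    window: float = IFR_WINDOW_S,
    step: float = IFR_GRID_STEP_S,
) -> list[ActivationSequence]:
    """Convenience pipeline stage: cluster IFRs -> activations -> sequences."""
    active = filter_active(trains, duration)
    ifrs = {
        c: cluster_ifr(trains, layout, c, duration, active, window, step)
        for c in CLUSTERS
    }
    sequences: list[ActivationSequence] = []
    for nb in nbs:
        rec = recruitment(bursts, layout, nb, active)
        if not any(rec.values()):
            continue
        acts = activation_times(ifrs, nb, rec)
        sequences.append(extract_sequence(acts))
    return sequences
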