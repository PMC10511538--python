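"""Hill-equation dose–response analysis of firing-rate inhibition.

During a drug-delivery protocol the culture is recorded once per
concentration phase; the first two minutes of each phase are discarded
(mechanical/diffusion transients) and the mean firing rate (MFR) is computed
on the remaining 8-min window, averaged over the electrodes that were active
during the basal (pre-drug) recording, and normalised to the basal value.
The concentration dependence of the normalised MFR is fitted with the
four-parameter Hill curve

    MFR_norm(c) = top + (bottom - top) / (1 + 10^(HC * (log10(IC50) - log10(c))))

where ``top``/``bottom`` are the high/low asymptotes, ``HC`` the Hill
coefficient (slope) and ``IC50`` the half-maximal inhibitory concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .io import SpikeTrainSet

PHASE_DISCARD_S = 120.0  # first 2 min of every phase dropped
PHASE_ANALYSIS_S = 480.0  # 8-min analysis window per phase
ACTIVE_MFR_THRESHOLD = 0.1  # spikes/s


def hill_curve(
    conc: np.ndarray | float,
    top: float,
    bottom: float,
    hc: float,
    ic50: float,
) -> np.ndarray | float:
    """Four-parameter Hill (log-logistic) inhibition curve."""
    conc = np.asarray(conc, dtype=float)
    return top + (bottom - top) / (1.0 + 10.0 ** (hc * (np.log10(ic50) - np.log10(conc))))


@dataclass(frozen=True)
class HillFit:
    mfr_norm_max: float
    mfr_norm_min: float
    hc: float
    ic50: float  # µM
    rss: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.mfr_norm_max < self.mfr_norm_min:
            raise ValueError("max asymptote below min asymptote")

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        return hill_curve(conc, self.mfr_norm_max, self.mfr_norm_min, self.hc, self.ic50)


class HillFitError(RuntimeError):
    """Fit failed to converge or the data carry no transition."""


def phase_analysis_window(phase_duration: float) -> tuple[float, float]:
    """Analysis window of a concentration phase: skip 2 min, analyse 8 min."""
    if phase_duration <= PHASE_DISCARD_S:
        raise ValueError("phase shorter than the discarded transient")
    end = min(phase_duration, PHASE_DISCARD_S + PHASE_ANALYSIS_S)
    return PHASE_DISCARD_S, end


def _mean_mfr(spikes: SpikeTrainSet, electrodes: Iterable[str]) -> float:
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("no electrodes to average over")
    dur = spikes.metadata.duration
    rates = [spikes.trains.get(e, np.empty(0)).size / dur for e in electrodes]
    return float(np.mean(rates))


def normalize_mfr(
    phases: Sequence[tuple[float, SpikeTrainSet]],
    basal: SpikeTrainSet,
    apply_window: bool = True,
) -> list[tuple[float, float]]:
    """Normalised MFR per concentration phase.

    ``phases`` is a list of (concentration_uM, phase recording).  The basal
    recording defines both the active-electrode set (MFR >= 0.1 spikes/s)
    and the normalisation reference; each phase MFR is computed on its 8-min
    analysis window when ``apply_window`` is set and the recording is long
    enough.
    """
    basal_active = [
        e
        for e, t in basal.trains.items()
        if t.size / basal.metadata.duration >= ACTIVE_MFR_THRESHOLD
    ]
    if not basal_active:
        raise ValueError("no active electrodes in the basal recording")
    basal_mfr = _mean_mfr(basal, basal_active)
    if basal_mfr <= 0:
        raise ValueError("basal MFR must be positive for normalisation")
    points: list[tuple[float, float]] = []
    for conc, rec in phases:
        if apply_window and rec.metadata.duration > PHASE_DISCARD_S + 1.0:
            lo, hi = phase_analysis_window(rec.metadata.duration)
            rec = rec.subset_window(lo, hi)
        points.append((float(conc), _mean_mfr(rec, basal_active) / basal_mfr))
    return points


def fit_hill(points: Sequence[tuple[float, float]]) -> HillFit:
    """Least-squares Hill fit in log-concentration space.

    Zero-concentration (basal) points are used for normalisation upstream and
    are excluded here.  IC50 is parameterised as log10(IC50) so the fit
    cannot produce a non-positive concentration.
    """
    pts = [(c, v) for c, v in points if c > 0]
    if len(pts) < 4:
        raise HillFitError("need at least 4 positive-concentration points")
    conc = np.array([c for c, _ in pts], dtype=float)
    y = np.array([v for _, v in pts], dtype=float)
    if np.ptp(y) < 1e-12:
        raise HillFitError("constant response: no transition to fit")

    def model(logc: np.ndarray, top: float, bottom: float, hc: float, logic50: float):
        return top + (bottom - top) / (1.0 + 10.0 ** (hc * (logic50 - logc)))

    p0 = [float(y.max()), float(y.min()), 1.0, float(np.mean(np.log10(conc)))]
    try:
        popt, _ = optimize.curve_fit(model, np.log10(conc), y, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        raise HillFitError(f"Hill fit did not converge: {exc}") from exc
    top, bottom, hc, logic50 = popt
    if top < bottom:  # curve_fit may swap asymptotes with negative slope
        top, bottom, hc = bottom, top, -hc
    resid = y - model(np.log10(conc), top, bottom, hc, logic50)
    return HillFit(float(top), float(bottom), float(hc), float(10.0 ** logic50), float(resid @ resid))


def ivb_effect_report(
    basal: SpikeTrainSet,
    drug: SpikeTrainSet,
    washout: SpikeTrainSet,
    bursts_by_phase: dict[str, dict[str, list]] | None = None,
) -> dict:
    """Paired basal / drug / washout comparison of per-electrode firing.

    Per-electrode MFR across the three phases is compared with the
    Kruskal–Wallis test (plus basal-vs-drug and basal-vs-washout
    Mann–Whitney post-hocs with Bonferroni correction).  Burst-level metrics
    are included when per-phase bursts are supplied.
    """
    phases = {"basal": basal, "drug": drug, "washout": washout}
    mfr = {
        name: np.array(
            [t.size / rec.metadata.duration for t in rec.trains.values()]
        )
        for name, rec in phases.items()
    }
    report: dict = {"n_electrodes": {k: int(v.size) for k, v in mfr.items()}}
    stat, p = stats.kruskal(mfr["basal"], mfr["drug"], mfr["washout"])
    report["mfr"] = {
        "median": {k: float(np.median(v)) for k, v in mfr.items()},
        "kruskal_stat": float(stat),
        "kruskal_p": float(p),
    }
    posthoc = {}
    for other in ("drug", "washout"):
        u, pu = stats.mannwhitneyu(mfr["basal"], mfr[other], alternative="two-sided")
        posthoc[f"basal_vs_{other}"] = {
            "u": float(u),
            "p_bonferroni": float(min(1.0, 2 * pu)),
        }
    report["mfr"]["posthoc"] = posthoc

    if bursts_by_phase is not None:
        mbr = {}
        for name, rec in phases.items():
            per_el = bursts_by_phase.get(name, {})
            counts = [len(per_el.get(e, [])) for e in rec.trains]
            mbr[name] = np.array(counts) / rec.metadata.duration * 60.0
        stat, p = stats.kruskal(mbr["basal"], mbr["drug"], mbr["washout"])
        report["mbr"] = {
            "median": {k: float(np.median(v)) for k, v in mbr.items()},
            "kruskal_stat": float(stat),
            "kruskal_p": float(p),
        }
    return report
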