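"""End-to-end orchestration: detection -> metrics -> sequences -> statistics."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import detection, metrics, sequences
from .io import SpikeTrainSet
from .layout import ClusterLayout


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis parameters, defaulting to the standard MEA settings.

    Spike detection: differential threshold 8x noise SD, 2 ms lifetime,
    1 ms refractory.  Bursts: >=5 spikes, ISI <= 100 ms.  Network bursts:
    >=20% of recording electrodes, self-adaptive chaining threshold.
    Activity filter 0.1 spikes/s; IFR window 100 ms on a 10 ms grid.
    """

    threshold_factor: float = 8.0
    lifetime_s: float = 2e-3
    refractory_s: float = 1e-3
    min_spikes: int = 5
    max_isi_s: float = 0.1
    nb_min_fraction: float = 0.20
    active_threshold: float = 0.1  # spikes/s
    ifr_window_s: float = 0.1
    ifr_step_s: float = 0.01
    mc_seed: int = 0
    mc_n: int = 10_000

    def __post_init__(self) -> None:
        positive = (
            "threshold_factor", "lifetime_s", "refractory_s", "max_isi_s",
            "nb_min_fraction", "ifr_window_s", "ifr_step_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 1 or self.mc_n < 1:
            raise ValueError("min_spikes and mc_n must be >= 1")
        if self.active_threshold < 0:
            raise ValueError("active_threshold must be >= 0")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(
    spikes: SpikeTrainSet,
    layout: ClusterLayout,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run detection, metrics, sequence extraction and sequence statistics.

    Returns a JSON-serialisable report; when ``out_dir`` is given the report
    and intermediate TSVs are written there.  Deterministic for a fixed
    config (Monte Carlo draws use ``config.mc_seed``).
    """
    config = config or AnalysisConfig()
    duration = spikes.metadata.duration
    report: dict = {
        "config": dataclasses.asdict(config),
        "metadata": dataclasses.asdict(spikes.metadata),
    }
    try:
        bursts = detection.detect_all_bursts(
            spikes.trains, min_spikes=config.min_spikes, max_isi=config.max_isi_s
        )
        all_bursts = [b for bl in bursts.values() for b in bl]
        active = metrics.filter_active(spikes.trains, duration, config.active_threshold)
        nbs = detection.detect_network_bursts(
            [b for b in all_bursts if b.electrode in active],
            n_recording_electrodes=len(active),
            min_fraction=config.nb_min_fraction,
        ) if len(all_bursts) >= 2 and active else []
    except Exception as exc:
        raise StageError(f"detection: {exc}") from exc

    try:
        table = metrics.compute_metrics(spikes.trains, bursts, nbs, duration)
        report["metrics"] = {
            "per_electrode_median": {
                k: float(v) for k, v in table.per_electrode.median().items()
            },
            "recording": table.recording,
            "n_bursts": len(all_bursts),
            "n_network_bursts": len(nbs),
        }
    except Exception as exc:
        raise StageError(f"metrics: {exc}") from exc

    try:
        seqs = metrics.extract_all_sequences(
            spikes.trains, bursts, nbs, layout, duration,
            window=config.ifr_window_s, step=config.ifr_step_s,
        )
        report["sequences"] = {
            "n_sequences": len(seqs),
            "length_histogram": {
                str(k): int(sum(1 for s in seqs if len(s) == k)) for k in (1, 2, 3, 4)
            },
        }
    except Exception as exc:
        raise StageError(f"sequences: {exc}") from exc

    try:
        report["stats"] = sequence_stats_report(seqs, layout, config) if seqs else None
    except Exception as exc:
        raise StageError(f"stats: {exc}") from exc

    if out_dir is not None:
        _write_outputs(Path(out_dir), report, bursts, nbs, seqs)
    return report


def sequence_stats_report(
    seqs: list[sequences.ActivationSequence],
    layout: ClusterLayout,
    config: AnalysisConfig,
) -> dict:
    """Path, initiator, diversity and repeated-series statistics of one run."""
    n_cp, n_long = sequences.count_circular(seqs, layout)
    initiators = sequences.initiator_classes(seqs)
    diversity = sequences.sequence_diversity(seqs)
    null = sequences.monte_carlo_sequences(
        [len(s) for s in seqs], seed=config.mc_seed
    )
    null_diversity = sequences.sequence_diversity(null)
    series = sequences.find_series(seqs)
    return {
        "paths": {
            "n_sequences_len3plus": n_long,
            "observed_cp": n_cp,
            "expected_cp": sequences.expected_circular(n_long),
        },
        "initiators": {
            "class_frequencies": list(initiators.class_frequencies),
            "class_clusters": list(initiators.class_clusters),
            "tie": initiators.tie,
        },
        "diversity": {
            "H": diversity.h,
            "E": diversity.e,
            "n_types": diversity.n_types,
            "E_expected": null_diversity.e,
        },
        "series": {
            str(length): {
                "occurrences": int(row["occurrences"]),
                "weight": float(row["weight"]),
            }
            for length, row in series.table.iterrows()
        },
    }


def _write_outputs(out_dir: Path, report: dict, bursts, nbs, seqs) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "bursts.tsv").open("w") as fh:
        fh.write("electrode_id\tstart_s\tend_s\tn_spikes\n")
        for e in sorted(bursts):
            for b in bursts[e]:
                fh.write(f"{e}\t{b.start:.6f}\t{b.end:.6f}\t{b.n_spikes}\n")
    with (out_dir / "network_bursts.tsv").open("w") as fh:
        fh.write("nb_id\tstart_s\tend_s\tn_electrodes\tfraction\n")
        for nb in nbs:
            fh.write(
                f"{nb.nb_id}\t{nb.start:.6f}\t{nb.end:.6f}"
                f"\t{len(nb.participating_electrodes)}\t{nb.fraction_active:.4f}\n"
            )
    with (out_dir / "sequences.tsv").open("w") as fh:
        fh.write("nb_id\tsequence\tn_clusters\n")
        for s in seqs:
            fh.write(f"{s.nb_index}\t{'>'.join(s.clusters)}\t{len(s)}\n")
    (out_dir / "report.json").write_text(report_json(report))


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a pipeline report."""
    return json.dumps(report, indent=1, sort_keys=True, allow_nan=True)
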