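"""Spike-train containers and the plain-text exchange format.

A recording is exchanged as a UTF-8 TSV with header
``electrode_id<TAB>spike_time_s`` (one spike per row) plus a sidecar JSON
(same path with ``.json`` appended) holding ``sampling_rate_hz``,
``duration_s``, ``assembly_type``, ``phase_label`` and the electrode→cluster
``layout`` map.  Raw voltage traces use one little-endian float32 binary file
per electrode next to the same sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .layout import ClusterLayout


@dataclass(frozen=True)
class RecordingMetadata:
    sampling_rate: float = 10_000.0  # Hz
    duration: float = 1200.0  # s; 20-min standard session
    assembly_type: str = "4N"  # {1N, 4N}
    phase_label: str = "spontaneous"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times (seconds from recording start)."""

    metadata: RecordingMetadata
    trains: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for e, t in self.trains.items():
            arr = np.asarray(t, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"train for {e} must be 1-D")
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"train for {e} is not strictly increasing")
            if arr.size and (arr[0] < 0 or arr[-1] > self.metadata.duration):
                raise ValueError(
                    f"train for {e} has times outside [0, {self.metadata.duration}]"
                )
            clean[e] = arr
        self.trains = clean

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def subset_window(self, start: float, end: float) -> "SpikeTrainSet":
        """Spikes in [start, end), re-referenced to ``start``."""
        meta = RecordingMetadata(
            self.metadata.sampling_rate,
            end - start,
            self.metadata.assembly_type,
            self.metadata.phase_label,
        )
        trains = {
            e: t[(t >= start) & (t < end)] - start for e, t in self.trains.items()
        }
        return SpikeTrainSet(meta, trains)


@dataclass
class RawTraceSet:
    """Per-electrode sampled voltage (µV) at metadata.sampling_rate."""

    metadata: RecordingMetadata
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {t.size for t in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must have equal length")


class SpikeTrainParseError(ValueError):
    """Malformed row / invariant violation in the exchange format."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_spike_trains(
    spikes: SpikeTrainSet, path: str | Path, layout: ClusterLayout | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("electrode_id\tspike_time_s\n")
        for e in sorted(spikes.trains):
            for t in spikes.trains[e]:
                fh.write(f"{e}\t{t:.9f}\n")
    sidecar = {
        "sampling_rate_hz": spikes.metadata.sampling_rate,
        "duration_s": spikes.metadata.duration,
        "assembly_type": spikes.metadata.assembly_type,
        "phase_label": spikes.metadata.phase_label,
        "layout": dict(layout.cluster_of) if layout is not None else None,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_spike_trains(path: str | Path) -> tuple[SpikeTrainSet, ClusterLayout | None]:
    """Read the exchange format; returns the set and the sidecar layout (if any)."""
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    meta = RecordingMetadata(
        sampling_rate=float(sidecar["sampling_rate_hz"]),
        duration=float(sidecar["duration_s"]),
        assembly_type=str(sidecar["assembly_type"]),
        phase_label=str(sidecar.get("phase_label", "")),
    )
    layout_map: Mapping[str, str] | None = sidecar.get("layout")
    trains: dict[str, list[float]] = {}
    if layout_map:
        trains = {e: [] for e in layout_map}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["electrode_id", "spike_time_s"]:
            raise SpikeTrainParseError(f"{path}:1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SpikeTrainParseError(f"{path}:{lineno}: expected 2 fields")
            e, t_raw = parts
            try:
                t = float(t_raw)
            except ValueError as exc:
                raise SpikeTrainParseError(
                    f"{path}:{lineno}: bad spike time {t_raw!r}"
                ) from exc
            if layout_map is not None and e not in layout_map:
                raise SpikeTrainParseError(
                    f"{path}:{lineno}: unknown electrode {e!r}"
                )
            if t < 0 or t > meta.duration:
                raise SpikeTrainParseError(
                    f"{path}:{lineno}: time {t} outside [0, {meta.duration}]"
                )
            bucket = trains.setdefault(e, [])
            if bucket and t <= bucket[-1]:
                raise SpikeTrainParseError(
                    f"{path}:{lineno}: times for {e} not strictly increasing"
                )
            bucket.append(t)
    spike_set = SpikeTrainSet(meta, {e: np.asarray(t) for e, t in trains.items()})
    layout = None
    if layout_map:
        layout = ClusterLayout(tuple(sorted(layout_map)), dict(layout_map))
    return spike_set, layout


def write_raw_traces(raw: RawTraceSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for e, trace in raw.traces.items():
        np.asarray(trace, dtype="<f4").tofile(directory / f"{e}.f32")
    sidecar = {
        "sampling_rate_hz": raw.metadata.sampling_rate,
        "duration_s": raw.metadata.duration,
        "assembly_type": raw.metadata.assembly_type,
        "phase_label": raw.metadata.phase_label,
        "electrodes": sorted(raw.traces),
    }
    (directory / "traces.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_raw_traces(directory: str | Path) -> RawTraceSet:
    directory = Path(directory)
    sidecar = json.loads((directory / "traces.json").read_text())
    meta = RecordingMetadata(
        sampling_rate=float(sidecar["sampling_rate_hz"]),
        duration=float(sidecar["duration_s"]),
        assembly_type=str(sidecar["assembly_type"]),
        phase_label=str(sidecar.get("phase_label", "")),
    )
    traces = {
        e: np.fromfile(directory / f"{e}.f32", dtype="<f4").astype(float)
        for e in sidecar["electrodes"]
    }
    return RawTraceSet(meta, traces)
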