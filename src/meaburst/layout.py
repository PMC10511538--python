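"""Electrode/cluster geometry for 4-cluster (4N) and single (1N) MEA assemblies.

The modular assemblies place four neuronal sub-populations at the corners of
a 1.8 mm x 1.4 mm rectangle on a 60-electrode array; each corner cluster
covers 13 electrodes and 7 further electrodes sit in the gaps between
clusters.  Uniform (1N) control networks are analysed with the same topology
by carving "virtual clusters" of 13 electrodes out of the homogeneous layout.

Cluster labels are fixed on the 2x2 grid as A=(0,0), B=(0,1), C=(1,1),
D=(1,0) so that the cyclic order A->B->C->D walks the edges of the square;
two clusters are *adjacent* when their grid positions differ in exactly one
coordinate (diagonal pairs A-C and B-D are not adjacent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

CLUSTERS = ("A", "B", "C", "D")
INTERSTITIAL = "interstitial"

#: canonical grid positions: A->B->C->D is the circular (edge) walk
GRID_POSITION = {"A": (0, 0), "B": (0, 1), "C": (1, 1), "D": (1, 0)}

ELECTRODES_PER_CLUSTER = 13
N_INTERSTITIAL = 7


def _grid_adjacency() -> dict[str, frozenset[str]]:
    adj: dict[str, frozenset[str]] = {}
    for a, pa in GRID_POSITION.items():
        adj[a] = frozenset(
            b
            for b, pb in GRID_POSITION.items()
            if b != a and (pa[0] == pb[0]) != (pa[1] == pb[1])
        )
    return adj


@dataclass(frozen=True)
class ClusterLayout:
    """Map from electrodes to the four clusters (or the interstitial gap)."""

    electrode_ids: tuple[str, ...]
    cluster_of: Mapping[str, str]
    grid_position: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(GRID_POSITION)
    )
    adjacency: Mapping[str, frozenset[str]] = field(default_factory=_grid_adjacency)
    positions: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        clusters = {c for c in self.cluster_of.values() if c != INTERSTITIAL}
        if clusters != set(CLUSTERS):
            raise ValueError(f"expected clusters {CLUSTERS}, got {sorted(clusters)}")
        missing = set(self.electrode_ids) - set(self.cluster_of)
        if missing:
            raise ValueError(f"electrodes without cluster assignment: {sorted(missing)}")

    def members(self, cluster: str) -> tuple[str, ...]:
        """Electrodes belonging to ``cluster`` (in electrode_ids order)."""
        return tuple(e for e in self.electrode_ids if self.cluster_of[e] == cluster)

    @property
    def clustered_electrodes(self) -> tuple[str, ...]:
        return tuple(e for e in self.electrode_ids if self.cluster_of[e] != INTERSTITIAL)

    def is_adjacent(self, a: str, b: str) -> bool:
        return b in self.adjacency[a]

    def is_diagonal_step(self, a: str, b: str) -> bool:
        return a != b and b not in self.adjacency[a]


def _cluster_footprint(x0: float, y0: float, pitch: float) -> list[tuple[float, float]]:
    # 13 sites: a 4x4 patch minus the three corners pointing away from the
    # array centre; schematic stand-in for the real corner-cluster footprint.
    sites = [(x0 + i * pitch, y0 + j * pitch) for i in range(4) for j in range(4)]
    sites_sorted = sorted(sites, key=lambda p: ((p[0] - x0 - 1.5 * pitch) ** 2 + (p[1] - y0 - 1.5 * pitch) ** 2))
    return sites_sorted[:13]


def build_4q_layout() -> ClusterLayout:
    """Layout of the four-cluster (4N) assembly.

    Returns a :class:`ClusterLayout` with 4 clusters x 13 electrodes plus 7
    interstitial electrodes (59 active-area electrodes in total; the 60th MEA
    contact is the reference and carries no signal).  Electrode coordinates
    are schematic (micrometres), spanning the 1.8 mm x 1.4 mm active area.
    """
    width, height = 1800.0, 1400.0
    pitch = 100.0
    corner_origin = {
        "A": (0.0, 0.0),
        "B": (width - 3 * pitch, 0.0),
        "C": (width - 3 * pitch, height - 3 * pitch),
        "D": (0.0, height - 3 * pitch),
    }
    # grid rows of the 2x2 arrangement: row 0 = bottom (A, B), row 1 = top (D, C)
    electrode_ids: list[str] = []
    cluster_of: dict[str, str] = {}
    positions: dict[str, tuple[float, float]] = {}
    for c in CLUSTERS:
        x0, y0 = corner_origin[c]
        for k, (x, y) in enumerate(sorted(_cluster_footprint(x0, y0, pitch)), start=1):
            eid = f"{c}{k:02d}"
            electrode_ids.append(eid)
            cluster_of[eid] = c
            positions[eid] = (x, y)
    # 7 interstitial electrodes along the cross arms between the clusters
    cx, cy = width / 2, height / 2
    inter_sites = [
        (cx, cy),
        (cx - 450, cy), (cx + 450, cy),
        (cx, cy - 350), (cx, cy + 350),
        (cx - 450, cy - 350), (cx + 450, cy + 350),
    ]
    for k, (x, y) in enumerate(inter_sites, start=1):
        eid = f"I{k:02d}"
        electrode_ids.append(eid)
        cluster_of[eid] = INTERSTITIAL
        positions[eid] = (x, y)
    return ClusterLayout(tuple(electrode_ids), cluster_of, positions=positions)


def build_virtual_layout(
    electrode_positions: Mapping[str, tuple[float, float]],
) -> ClusterLayout:
    """Carve four 13-electrode "virtual clusters" out of a uniform layout.

    Control (1N) cultures grow over the whole active area; to compare their
    activation sequences with the modular assemblies, electrodes are grouped
    into four virtual clusters mirroring the 4N footprint.  Electrodes are
    split into spatial quadrants around the layout centroid and, within each
    quadrant, the 13 electrodes nearest the quadrant's outer corner form the
    virtual cluster; any leftover electrodes are left interstitial.

    Raises ``ValueError`` if fewer than 52 electrodes are available or a
    quadrant holds fewer than 13 electrodes.
    """
    if len(electrode_positions) < 4 * ELECTRODES_PER_CLUSTER:
        raise ValueError(
            f"need at least {4 * ELECTRODES_PER_CLUSTER} electrodes for virtual "
            f"clusters, got {len(electrode_positions)}"
        )
    ids = sorted(electrode_positions)
    xs = [electrode_positions[e][0] for e in ids]
    ys = [electrode_positions[e][1] for e in ids]
    cx, cy = sum(xs) / len(xs), sum(ys) / len(ys)
    xmin, xmax, ymin, ymax = min(xs), max(xs), min(ys), max(ys)
    # quadrant -> cluster label matching the canonical grid (row = y, col = x)
    corner = {
        "A": (xmin, ymin),
        "B": (xmax, ymin),
        "C": (xmax, ymax),
        "D": (xmin, ymax),
    }
    quadrant_of = {
        e: ("B" if electrode_positions[e][0] >= cx else "A")
        if electrode_positions[e][1] < cy
        else ("C" if electrode_positions[e][0] >= cx else "D")
        for e in ids
    }
    cluster_of: dict[str, str] = {e: INTERSTITIAL for e in ids}
    for c in CLUSTERS:
        members = [e for e in ids if quadrant_of[e] == c]
        if len(members) < ELECTRODES_PER_CLUSTER:
            raise ValueError(
                f"quadrant {c} holds only {len(members)} electrodes; "
                f"{ELECTRODES_PER_CLUSTER} required"
            )
        gx, gy = corner[c]
        members.sort(
            key=lambda e: (
                (electrode_positions[e][0] - gx) ** 2
                + (electrode_positions[e][1] - gy) ** 2,
                e,
            )
        )
        for e in members[:ELECTRODES_PER_CLUSTER]:
            cluster_of[e] = c
    return ClusterLayout(tuple(ids), cluster_of, positions=dict(electrode_positions))
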