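"""Aromatic ring geometry, interaction band persistence, and cluster events.

An aromatic–aromatic interaction is present when the ring-centroid distance
lies in the closed 4.5–7.0 Å band typical of aromatic pairs in proteins.
Clusters are connected components (size ≥ 3 by default) of the
presence graph.  A nearest-ring-atom metric is available as an alternative
to centroids for minimal-distance-style traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_model import Structure, Trajectory
from .kinematics import TimeSeries

__all__ = [
    "RING_ATOMS",
    "DEFAULT_BAND",
    "AromaticCluster",
    "aromatic_residues",
    "ring_centroid",
    "pair_distance_series",
    "persistence_percentage",
    "detect_aromatic_clusters",
    "cluster_formation_events",
]

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

DEFAULT_BAND = (4.5, 7.0)


class RingGeometryError(ValueError):
    """An aromatic residue is missing one of its named ring atoms."""


def aromatic_residues(
    topology: Structure, include_his: bool = False
) -> dict[int, list[int]]:
    """residue_index -> ring atom indices for every aromatic residue.

    Histidine is only conditionally aromatic here and excluded by default.
    """
    wanted = {"PHE", "TYR", "TRP"} | ({"HIS"} if include_his else set())
    by_res: dict[int, dict[str, int]] = {}
    names: dict[int, str] = {}
    for i, atom in enumerate(topology.atoms):
        rn = atom.residue_name.upper()
        if rn in wanted:
            names[atom.residue_index] = rn
            by_res.setdefault(atom.residue_index, {})[atom.name] = i
    out: dict[int, list[int]] = {}
    for res, atom_map in by_res.items():
        ring = RING_ATOMS[names[res]]
        missing = [a for a in ring if a not in atom_map]
        if missing:
            raise RingGeometryError(
                f"residue {res} ({names[res]}) missing ring atom(s) {missing}"
            )
        out[res] = [atom_map[a] for a in ring]
    return out


def ring_centroid(
    topology: Structure, residue_index: int, frame: np.ndarray,
    include_his: bool = False,
) -> np.ndarray:
    """Unweighted mean of the residue's ring heavy-atom coordinates."""
    rings = aromatic_residues(topology, include_his=include_his)
    if residue_index not in rings:
        raise RingGeometryError(f"residue {residue_index} is not aromatic")
    return np.asarray(frame, dtype=float)[rings[residue_index]].mean(axis=0)


def _centroids_per_frame(
    traj: Trajectory, rings: dict[int, list[int]]
) -> dict[int, np.ndarray]:
    return {
        res: traj.coords[:, idx, :].mean(axis=1) for res, idx in rings.items()
    }


def _pair_series(
    traj: Trajectory, res_a: int, res_b: int, stride: int, metric: str,
    include_his: bool,
) -> tuple[np.ndarray, np.ndarray]:
    rings = aromatic_residues(traj.topology, include_his=include_his)
    for r in (res_a, res_b):
        if r not in rings:
            raise RingGeometryError(f"residue {r} is not aromatic")
    times, frames = traj.sampled(stride)
    ia, ib = rings[res_a], rings[res_b]
    if metric == "centroid":
        ca = frames[:, ia, :].mean(axis=1)
        cb = frames[:, ib, :].mean(axis=1)
        d = np.linalg.norm(ca - cb, axis=1)
    elif metric == "min_atom":
        diff = frames[:, ia, None, :] - frames[:, None, ib, :]
        d = np.sqrt(np.sum(diff**2, axis=-1)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return times, d


def pair_distance_series(
    traj: Trajectory,
    res_a: int,
    res_b: int,
    stride: int = 1,
    metric: str = "centroid",
    include_his: bool = False,
) -> TimeSeries:
    """Ring–ring distance per sampled frame (Å); symmetric in arguments.

    ``metric="centroid"`` (default) is the band criterion's native metric;
    ``metric="min_atom"`` gives the nearest-ring-atom distance used for
    minimal-distance-style traces.
    """
    times, d = _pair_series(traj, res_a, res_b, stride, metric, include_his)
    return TimeSeries(times, d, unit="Å", name=f"d({res_a},{res_b})")


def persistence_percentage(
    traj: Trajectory,
    res_a: int,
    res_b: int,
    stride: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    metric: str = "centroid",
    include_his: bool = False,
) -> float:
    """Percent of sampled frames with the pair inside the interaction band."""
    _, d = _pair_series(traj, res_a, res_b, stride, metric, include_his)
    if d.size == 0:
        raise ValueError("no sampled frames")
    lo, hi = band
    return 100.0 * float(np.mean((d >= lo) & (d <= hi)))


@dataclass
class AromaticCluster:
    members: frozenset
    onset_ns: float | None = None


def _components(
    centroids: dict[int, np.ndarray], band: tuple[float, float], min_size: int
) -> list[frozenset]:
    lo, hi = band
    g = nx.Graph()
    g.add_nodes_from(centroids)
    residues = sorted(centroids)
    for i, a in enumerate(residues):
        for b in residues[i + 1 :]:
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            if lo <= d <= hi:
                g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def detect_aromatic_clusters(
    frame: np.ndarray,
    topology: Structure,
    min_size: int = 3,
    band: tuple[float, float] = DEFAULT_BAND,
    include_his: bool = False,
) -> list[AromaticCluster]:
    """Connected components of the in-band interaction graph for one frame.

    Components of size ≥ ``min_size`` are reported, largest first then by
    lowest residue index.  Membership is transitive: A–B and B–C in band
    joins A and C even if they are far apart.
    """
    rings = aromatic_residues(topology, include_his=include_his)
    frame = np.asarray(frame, dtype=float)
    centroids = {res: frame[idx].mean(axis=0) for res, idx in rings.items()}
    return [AromaticCluster(c) for c in _components(centroids, band, min_size)]


def cluster_formation_events(
    traj: Trajectory,
    reference_frame: int = 0,
    stride: int = 1,
    persistence: int = 5,
    min_size: int = 3,
    band: tuple[float, float] = DEFAULT_BAND,
    include_his: bool = False,
) -> list[AromaticCluster]:
    """Newly formed aromatic clusters that persist.

    A member set absent at the reference frame that appears as a connected
    component for at least ``persistence`` consecutive sampled frames is
    reported with onset = the first frame of that run.
    """
    rings = aromatic_residues(traj.topology, include_his=include_his)
    times, frames = traj.sampled(stride)
    ref = np.asarray(traj.frame(reference_frame), dtype=float)
    ref_centroids = {res: ref[idx].mean(axis=0) for res, idx in rings.items()}
    native = set(_components(ref_centroids, band, min_size))

    per_frame: list[set[frozenset]] = []
    for frame in frames:
        centroids = {res: frame[idx].mean(axis=0) for res, idx in rings.items()}
        per_frame.append(set(_components(centroids, band, min_size)))

    candidates = set().union(*per_frame) - native if per_frame else set()
    events = []
    for members in candidates:
        run = 0
        onset = None
        for k, comps in enumerate(per_frame):
            if members in comps:
                run += 1
                if run >= persistence:
                    onset = k - persistence + 1
                    break
            else:
                run = 0
        if onset is not None:
            events.append(AromaticCluster(members, onset_ns=float(times[onset])))
    events.sort(key=lambda e: (e.onset_ns, min(e.members)))
    return events
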