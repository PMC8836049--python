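"""Residue contacts, native-contact fraction Q, ensemble and subtractive maps.

A contact between residues i and j exists when any heavy atom of i lies
within the cutoff (default 6.5 Å, closed boundary) of any heavy atom of j.
Q(t) is the number of contacts present at time t divided by the number in the
frame-0 reference; because the numerator counts *all* contacts at t (not only
native pairs), Q can exceed 1 when non-native contacts form.  A strict-native
mode restricts the numerator to the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_model import Region, RegionMap, Structure, Trajectory
from .kinematics import TimeSeries

__all__ = [
    "ContactSet",
    "ContactFractionSeries",
    "ContactMap",
    "contact_set",
    "contact_set_bruteforce",
    "contact_fraction_series",
    "ensemble_contact_map",
    "subtractive_map",
    "region_pair_contact_summary",
]


@dataclass(frozen=True)
class ContactSet:
    """Canonical (i < j) residue-index pairs found within the cutoff."""

    pairs: frozenset
    cutoff: float
    min_separation: int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContactFractionSeries:
    series: TimeSeries
    reference: ContactSet
    region: tuple[int, int] | None = None


@dataclass
class ContactMap:
    """Symmetric residue × residue contact frequency over sampled frames."""

    frequencies: np.ndarray
    n_frames: int
    reference_indicator: np.ndarray
    author_numbers: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.frequencies.shape[0]


def _heavy_arrays(topology: Structure) -> tuple[np.ndarray, np.ndarray]:
    mask = topology.heavy_mask
    if not mask.any():
        raise ValueError("structure has no heavy atoms")
    return np.nonzero(mask)[0], topology.residue_index[mask]


def contact_set(
    frame: np.ndarray,
    topology: Structure,
    cutoff: float = 6.5,
    min_separation: int = 1,
) -> ContactSet:
    """Heavy-atom residue contacts of one frame (KD-tree accelerated).

    The boundary is closed: an atom pair exactly at the cutoff counts.  A
    residue pair is reported once however many atom pairs qualify;
    ``min_separation`` is the minimum |i - j| (default 1, i.e. all i ≠ j).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    heavy_idx, res_of = _heavy_arrays(topology)
    coords = np.asarray(frame, dtype=float)[heavy_idx]
    tree = cKDTree(coords)
    pairs = set()
    for a, b in tree.query_pairs(r=cutoff):
        ri, rj = int(res_of[a]), int(res_of[b])
        if ri == rj:
            continue
        if abs(ri - rj) < min_separation:
            continue
        pairs.add((min(ri, rj), max(ri, rj)))
    return ContactSet(frozenset(pairs), cutoff, min_separation)


def contact_set_bruteforce(
    frame: np.ndarray,
    topology: Structure,
    cutoff: float = 6.5,
    min_separation: int = 1,
) -> ContactSet:
    """All-pairs reference implementation of :func:`contact_set`.

    Quadratic in heavy atoms; kept as the definitional oracle the accelerated
    path must agree with exactly.
    """
    heavy_idx, res_of = _heavy_arrays(topology)
    coords = np.asarray(frame, dtype=float)[heavy_idx]
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    within = d2 <= cutoff * cutoff
    pairs = set()
    ai, aj = np.nonzero(within)
    for a, b in zip(ai, aj):
        if a >= b:
            continue
        ri, rj = int(res_of[a]), int(res_of[b])
        if ri == rj or abs(ri - rj) < min_separation:
            continue
        pairs.add((min(ri, rj), max(ri, rj)))
    return ContactSet(frozenset(pairs), cutoff, min_separation)


def _author_numbers(topology: Structure) -> np.ndarray:
    """author residue number per internal residue index (1-based)."""
    out = np.zeros(topology.n_residues + 1, dtype=int)
    for idx, _, _, author in topology.residues():
        out[idx] = author
    return out


def _region_bounds(region, regions: RegionMap | None) -> tuple[int, int]:
    if isinstance(region, str):
        if regions is None:
            raise ValueError("region name given but no RegionMap supplied")
        region = regions.resolve(region)
    if isinstance(region, Region):
        return region.start, region.end
    lo, hi = region
    return int(lo), int(hi)


def _pair_in_region(pairs, authors: np.ndarray, lo: int, hi: int):
    return {
        (i, j)
        for i, j in pairs
        if lo <= authors[i] <= hi or lo <= authors[j] <= hi
    }


def contact_fraction_series(
    traj: Trajectory,
    stride: int = 1,
    region=None,
    cutoff: float = 6.5,
    min_separation: int = 1,
    regions: RegionMap | None = None,
    strict_native: bool = False,
) -> ContactFractionSeries:
    """Q(t): contacts at time t over contacts in the frame-0 reference.

    ``region`` (author-numbered bounds, a Region, or a region name) restricts
    both numerator and denominator to pairs with at least one member residue
    inside the region — the "contacts of a region with its neighbours"
    reading.  ``strict_native=True`` intersects the numerator with the
    reference so Q stays within [0, 1].
    """
    top = traj.topology
    authors = _author_numbers(top)
    ref = contact_set(traj.frame(0), top, cutoff, min_separation)
    ref_pairs = set(ref.pairs)
    bounds = None
    if region is not None:
        bounds = _region_bounds(region, regions)
        ref_pairs = _pair_in_region(ref_pairs, authors, *bounds)
    if not ref_pairs:
        raise ValueError("reference contact set is empty: Q undefined")
    denom = len(ref_pairs)
    times, frames = traj.sampled(stride)
    values = np.empty(len(frames))
    for k, frame in enumerate(frames):
        cur = set(contact_set(frame, top, cutoff, min_separation).pairs)
        if bounds is not None:
            cur = _pair_in_region(cur, authors, *bounds)
        if strict_native:
            cur &= ref_pairs
        values[k] = len(cur) / denom
    return ContactFractionSeries(
        series=TimeSeries(times, values, unit="", name="Q"),
        reference=ContactSet(frozenset(ref_pairs), cutoff, min_separation),
        region=bounds,
    )


def detect_q_drop(
    qs: ContactFractionSeries,
    factor: float = 0.8,
    baseline_frames: int = 10,
    persistence: int = 3,
) -> float | None:
    """Onset time (ns) of a sustained contact-fraction drop, or None.

    The baseline is the median Q over the first ``baseline_frames`` sampled
    frames; the onset is the first sampled time at which Q falls below
    ``factor`` × baseline and stays below for ``persistence`` consecutive
    frames.
    """
    v = qs.series.values
    baseline = float(np.median(v[:baseline_frames]))
    below = v < factor * baseline
    run = 0
    for k, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= persistence:
            return float(qs.series.times_ns[k - persistence + 1])
    return None


def ensemble_contact_map(
    traj: Trajectory,
    stride: int = 1,
    cutoff: float = 6.5,
    min_separation: int = 1,
) -> ContactMap:
    """Fraction of sampled frames in which each residue pair is in contact."""
    top = traj.topology
    n = top.n_residues
    counts = np.zeros((n, n))
    _, frames = traj.sampled(stride)
    if len(frames) == 0:
        raise ValueError("no sampled frames")
    for frame in frames:
        for i, j in contact_set(frame, top, cutoff, min_separation).pairs:
            counts[i - 1, j - 1] += 1
            counts[j - 1, i - 1] += 1
    freq = counts / len(frames)
    ref = np.zeros((n, n))
    for i, j in contact_set(traj.frame(0), top, cutoff, min_separation).pairs:
        ref[i - 1, j - 1] = 1.0
        ref[j - 1, i - 1] = 1.0
    return ContactMap(
        frequencies=freq,
        n_frames=len(frames),
        reference_indicator=ref,
        author_numbers=_author_numbers(top)[1:],
    )


def subtractive_map(
    map_a: ContactMap, map_b: ContactMap, mode: str = "raw"
) -> np.ndarray:
    """Signed difference map between two ensembles.

    ``raw``: A − B on the ensemble frequencies.  ``loss``: per-trajectory
    change maps (frequency minus own frame-0 indicator) are subtracted, so the
    two ensembles' different reference structures are each accounted for.
    Negative entries mark frequency (or contact retention) that is lower in A:
    with A the urea-like ensemble's loss map, redder/negative means greater
    loss in A.  Antisymmetric under operand swap.
    """
    if map_a.frequencies.shape != map_b.frequencies.shape:
        raise ValueError("contact maps have different dimensions")
    if mode == "raw":
        return map_a.frequencies - map_b.frequencies
    if mode == "loss":
        loss_a = map_a.frequencies - map_a.reference_indicator
        loss_b = map_b.frequencies - map_b.reference_indicator
        return loss_a - loss_b
    raise ValueError(f"unknown mode {mode!r}")


def region_pair_contact_summary(
    cmap: ContactMap,
    region_a,
    region_b,
    regions: RegionMap | None = None,
    matrix: np.ndarray | None = None,
) -> float:
    """Mean contact frequency over the region_a × region_b block.

    Diagonal entries are excluded.  ``matrix`` lets the same block summary be
    taken over a subtractive map instead of the ensemble frequencies.
    """
    lo_a, hi_a = _region_bounds(region_a, regions)
    lo_b, hi_b = _region_bounds(region_b, regions)
    authors = cmap.author_numbers
    ia = np.nonzero((authors >= lo_a) & (authors <= hi_a))[0]
    ib = np.nonzero((authors >= lo_b) & (authors <= hi_b))[0]
    src = cmap.frequencies if matrix is None else matrix
    total = 0.0
    count = 0
    for i in ia:
        for j in ib:
            if i == j:
                continue
            total += src[i, j]
            count += 1
    if count == 0:
        raise ValueError("empty region block")
    return total / count
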