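"""Kabsch–Sander hydrogen bonds, DSSP-style labels and unfolding events.

The backbone N–H···O=C hydrogen bond is scored with the electrostatic model

    E = 0.42 · 0.20 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

and called a bond when E < −0.5 kcal/mol.  Amide hydrogens are reconstructed
1.0 Å from N, anti-parallel to the preceding residue's C=O vector, so files
without hydrogens work.  Assignment covers the n-turn (G/H/I), bridge/ladder
(B/E) and turn (T) patterns with priority H > E > G > I > B > T > C; solvent
accessibility and bend flags of full DSSP are out of scope.

Unfolding events are per-region drops of rolling β-content (E+B labels) below
a threshold that persist, ordered by onset time — the trajectory's headline
"which strand detached when" output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import MAINCHAIN_ATOMS, Region, RegionMap, Structure, Trajectory

__all__ = [
    "HBOND_Q1Q2F",
    "HBOND_ENERGY_CUTOFF",
    "GeometryError",
    "SSMatrix",
    "UnfoldingEvent",
    "ks_hbond_energy",
    "assign_secondary_structure",
    "ss_timeseries",
    "region_beta_percentage",
    "detect_unfolding_events",
]

#: 0.42 e · 0.20 e · 332 kcal·Å/(mol·e²) — the Kabsch–Sander prefactor.
HBOND_Q1Q2F = 27.888
HBOND_ENERGY_CUTOFF = -0.5
_ENERGY_FLOOR = -9.9  # clamp, as in reference implementations
_CHAIN_BREAK_CA = 4.5  # Å; larger CA(i)-CA(i+1) gaps split the chain


class GeometryError(ValueError):
    """Missing or unusable mainchain geometry."""


def ks_hbond_energy(donor: dict, acceptor: dict) -> float:
    """Kabsch–Sander energy (kcal/mol) of one putative N–H···O=C bond.

    ``donor`` needs ``N`` and either ``H`` or the preceding residue's
    ``C_prev``/``O_prev`` for hydrogen reconstruction; ``acceptor`` needs
    ``C`` and ``O``.  A proline donor has no amide hydrogen and scores 0
    (never bonded).  Raises :class:`GeometryError` for missing atoms and
    ``ValueError`` for clashing (< 0.5 Å) geometry.
    """
    if donor.get("resname", "").upper() == "PRO":
        return 0.0
    try:
        n = np.asarray(donor["N"], dtype=float)
        c = np.asarray(acceptor["C"], dtype=float)
        o = np.asarray(acceptor["O"], dtype=float)
    except KeyError as exc:
        raise GeometryError(f"missing mainchain atom {exc}") from None
    if "H" in donor:
        h = np.asarray(donor["H"], dtype=float)
    elif "C_prev" in donor and "O_prev" in donor:
        h = reconstruct_amide_h(
            n, np.asarray(donor["C_prev"], float), np.asarray(donor["O_prev"], float)
        )
    else:
        raise GeometryError("donor needs H or preceding C/O for reconstruction")
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        raise ValueError("clashing geometry: interatomic distance < 0.5 Å")
    return float(HBOND_Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def reconstruct_amide_h(n: np.ndarray, c_prev: np.ndarray, o_prev: np.ndarray) -> np.ndarray:
    """Place the amide H 1.0 Å from N, anti-parallel to the previous C=O."""
    v = c_prev - o_prev
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise GeometryError("degenerate C=O vector for H reconstruction")
    return n + v / norm


def _mainchain_table(frame: np.ndarray, topology: Structure):
    """Per-residue N/CA/C/O coordinates, presence mask and residue names."""
    n_res = topology.n_residues
    coords = {name: np.full((n_res, 3), np.nan) for name in MAINCHAIN_ATOMS}
    resnames = [""] * n_res
    frame = np.asarray(frame, dtype=float)
    for i, atom in enumerate(topology.atoms):
        r = atom.residue_index - 1
        resnames[r] = atom.residue_name
        if atom.name in coords and np.isnan(coords[atom.name][r]).any():
            coords[atom.name][r] = frame[i]
    complete = np.ones(n_res, dtype=bool)
    for name in MAINCHAIN_ATOMS:
        complete &= ~np.isnan(coords[name]).any(axis=1)
    return coords, complete, resnames


def _segment_ids(ca: np.ndarray, complete: np.ndarray) -> np.ndarray:
    """Contiguous-segment id per residue; breaks at CA gaps or missing atoms."""
    n = ca.shape[0]
    seg = np.zeros(n, dtype=int)
    current = 0
    for i in range(1, n):
        broken = (
            not complete[i]
            or not complete[i - 1]
            or np.linalg.norm(ca[i] - ca[i - 1]) > _CHAIN_BREAK_CA
        )
        if broken:
            current += 1
        seg[i] = current
    return seg


def _hbond_matrix(frame: np.ndarray, topology: Structure):
    """Boolean donor × acceptor H-bond matrix (and segment ids)."""
    coords, complete, resnames = _mainchain_table(frame, topology)
    n_res = topology.n_residues
    ca = coords["CA"]
    seg = _segment_ids(ca, complete)

    h = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        if (
            complete[i]
            and complete[i - 1]
            and seg[i] == seg[i - 1]
            and resnames[i].upper() != "PRO"
        ):
            h[i] = reconstruct_amide_h(coords["N"][i], coords["C"][i - 1], coords["O"][i - 1])
    has_h = ~np.isnan(h).any(axis=1)

    donors = np.nonzero(has_h & complete)[0]
    acceptors = np.nonzero(complete)[0]
    hb = np.zeros((n_res, n_res), dtype=bool)
    if donors.size == 0 or acceptors.size == 0:
        return hb, seg, complete

    dN = coords["N"][donors]
    dH = h[donors]
    aC = coords["C"][acceptors]
    aO = coords["O"][acceptors]

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with np.errstate(divide="ignore"):
        e = HBOND_Q1Q2F * (
            1.0 / dist(dN, aO) + 1.0 / dist(dH, aC) - 1.0 / dist(dH, aO) - 1.0 / dist(dN, aC)
        )
    e = np.maximum(e, _ENERGY_FLOOR)
    sep = np.abs(donors[:, None] - acceptors[None, :])
    bonded = (e < HBOND_ENERGY_CUTOFF) & (sep >= 2)
    for di, d in enumerate(donors):
        for aj in np.nonzero(bonded[di])[0]:
            hb[d, acceptors[aj]] = True
    return hb, seg, complete


def assign_secondary_structure(frame: np.ndarray, topology: Structure) -> np.ndarray:
    """Single-character secondary-structure label per residue for one frame."""
    n_res = topology.n_residues
    labels = np.full(n_res, "C", dtype="<U1")
    if n_res < 3:
        import warnings

        warnings.warn("chain shorter than 3 residues: all coil")
        return labels
    hb, seg, complete = _hbond_matrix(frame, topology)

    # Hbond(a_CO, b_NH) in the classic notation is hb[b, a] here.
    def co_accepts(i: int, j: int) -> bool:
        """CO of residue i accepts the NH of residue j."""
        return bool(hb[j, i]) if 0 <= i < n_res and 0 <= j < n_res else False

    turns = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if seg[i] == seg[i + n] and co_accepts(i, i + n):
                turns[n][i] = True

    helix = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, n_res - n):
            if turns[n][i - 1] and turns[n][i]:
                helix[n][i : i + n] = True

    para = np.zeros((n_res, n_res), dtype=bool)
    anti = np.zeros((n_res, n_res), dtype=bool)
    for i in range(n_res):
        for j in range(i + 3, n_res):
            if not (complete[i] and complete[j]):
                continue
            if (co_accepts(i - 1, j) and co_accepts(j, i + 1)) or (
                co_accepts(j - 1, i) and co_accepts(i, j + 1)
            ):
                para[i, j] = para[j, i] = True
            if (co_accepts(i, j) and co_accepts(j, i)) or (
                co_accepts(i - 1, j + 1) and co_accepts(j - 1, i + 1)
            ):
                anti[i, j] = anti[j, i] = True

    bridge = para | anti
    bridged = bridge.any(axis=1)
    in_ladder = np.zeros(n_res, dtype=bool)
    for i in range(n_res):
        for j in np.nonzero(bridge[i])[0]:
            for di in (-1, 1):
                ii = i + di
                if 0 <= ii < n_res and seg[ii] == seg[i]:
                    for dj in (-1, 1):
                        jj = j + dj
                        if 0 <= jj < n_res and bridge[ii, jj]:
                            in_ladder[i] = True

    is_turn = np.zeros(n_res, dtype=bool)
    for n in (3, 4, 5):
        for i in np.nonzero(turns[n])[0]:
            is_turn[i + 1 : i + n] = True

    for i in range(n_res):
        if helix[4][i]:
            labels[i] = "H"
        elif in_ladder[i]:
            labels[i] = "E"
        elif helix[3][i]:
            labels[i] = "G"
        elif helix[5][i]:
            labels[i] = "I"
        elif bridged[i]:
            labels[i] = "B"
        elif is_turn[i]:
            labels[i] = "T"
    return labels


@dataclass
class SSMatrix:
    """Residue × sampled-frame label matrix with the sampled times."""

    labels: np.ndarray
    times_ns: np.ndarray
    author_numbers: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.labels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[1]


def ss_timeseries(traj: Trajectory, stride: int = 1) -> SSMatrix:
    """Secondary-structure labels for every sampled frame."""
    times, frames = traj.sampled(stride)
    top = traj.topology
    labels = np.empty((top.n_residues, len(frames)), dtype="<U1")
    for k, frame in enumerate(frames):
        labels[:, k] = assign_secondary_structure(frame, top)
    authors = np.zeros(top.n_residues, dtype=int)
    for idx, _, _, author in top.residues():
        authors[idx - 1] = author
    return SSMatrix(labels=labels, times_ns=times, author_numbers=authors)


def _region_rows(ssm: SSMatrix, region, regions: RegionMap | None) -> np.ndarray:
    if isinstance(region, str):
        if regions is None:
            raise ValueError("region name given but no RegionMap supplied")
        region = regions.resolve(region)
    if isinstance(region, Region):
        lo, hi = region.start, region.end
    else:
        lo, hi = region
    rows = np.nonzero((ssm.author_numbers >= lo) & (ssm.author_numbers <= hi))[0]
    if rows.size == 0:
        raise ValueError(f"region {lo}-{hi} matches no residues")
    return rows


def region_beta_percentage(
    ssm: SSMatrix,
    region,
    time_window: tuple[float, float] | None = None,
    regions: RegionMap | None = None,
) -> float:
    """Percent of E/B labels in the region × time-window block."""
    rows = _region_rows(ssm, region, regions)
    if time_window is None:
        cols = np.arange(ssm.n_frames)
    else:
        t0, t1 = time_window
        cols = np.nonzero((ssm.times_ns >= t0) & (ssm.times_ns <= t1))[0]
    if cols.size == 0:
        raise ValueError("empty time window")
    block = ssm.labels[np.ix_(rows, cols)]
    return 100.0 * float(np.isin(block, ("E", "B")).mean())


@dataclass
class UnfoldingEvent:
    region: str
    onset_ns: float
    kind: str  # beta_loss | melt
    beta_before_pct: float
    beta_after_pct: float


def _rolling_beta(ssm: SSMatrix, rows: np.ndarray, window: int) -> np.ndarray:
    beta = np.isin(ssm.labels[rows], ("E", "B")).mean(axis=0) * 100.0
    if window <= 1:
        return beta
    half = window // 2
    padded = np.pad(beta, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: beta.size]


def detect_unfolding_events(
    ssm: SSMatrix,
    regions: RegionMap,
    threshold: float = 50.0,
    persistence: int = 5,
    window: int = 5,
) -> list[UnfoldingEvent]:
    """Ordered β-loss events: rolling β-content below threshold, persisting.

    For each region, the onset is the first sampled time at which the
    centered rolling (``window`` frames) β-content drops below ``threshold``
    and stays below for at least ``persistence`` consecutive sampled frames.
    A region whose final β-content ends under 10% while another event region
    lies within 10 residues is flagged ``melt`` instead of ``beta_loss``.
    Events are sorted by onset.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    candidates: list[tuple[str, int, np.ndarray, tuple[int, int]]] = []
    for name in regions:
        rows = _region_rows(ssm, name, regions)
        beta = _rolling_beta(ssm, rows, window)
        below = beta < threshold
        onset = None
        run = 0
        for k, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= persistence:
                onset = k - persistence + 1
                break
        if onset is None:
            continue
        if not below[0] or onset > 0:  # ignore regions that start unfolded
            region = regions[name]
            candidates.append((name, onset, beta, (region.start, region.end)))

    events: list[UnfoldingEvent] = []
    for name, onset, beta, bounds in candidates:
        before = float(beta[:onset].mean()) if onset > 0 else float(beta[0])
        after = float(beta[onset:].mean())
        final = float(beta[-1])
        kind = "beta_loss"
        if final < 10.0:
            for other, _, _, ob in candidates:
                if other == name:
                    continue
                if min(abs(ob[0] - bounds[1]), abs(bounds[0] - ob[1])) <= 10 or (
                    ob[0] <= bounds[1] and bounds[0] <= ob[1]
                ):
                    kind = "melt"
                    break
        events.append(
            UnfoldingEvent(
                region=name,
                onset_ns=float(ssm.times_ns[onset]),
                kind=kind,
                beta_before_pct=before,
                beta_after_pct=after,
            )
        )
    events.sort(key=lambda e: e.onset_ns)
    return events
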