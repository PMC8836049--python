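"""Idealized structures and scripted trajectories with known ground truth.

Every analysis stage in this package is validated against trajectories whose
"events" are scripted here: strand detachments with known onset frames,
rigid interdomain rotations with a known twist/closure mix, aromatic-cluster
formation at a known time, and isotropic Gaussian coordinate noise with a
stated σ and seed.  The geometry is an idealized two-domain antiparallel
β-sandwich — the acceptance surface is parameter recovery, not structural
realism.

Strand geometry is built by internal-coordinate chain construction (NeRF)
at canonical β dihedrals; each added strand is placed rigidly by a
least-squares fit to the canonical antiparallel inter-strand N···O hydrogen
bond distances, so the sheets register as β by Kabsch–Sander criteria.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .io_model import MAINCHAIN_ATOMS, Atom, RegionMap, Structure, Trajectory
from .aromatics import RING_ATOMS

__all__ = [
    "DetachmentEvent",
    "RotationEvent",
    "ClusterEvent",
    "UnfoldingScript",
    "GroundTruth",
    "build_chain",
    "build_helix",
    "build_strand",
    "build_antiparallel_sheet",
    "build_toy_two_domain",
    "build_composition_stand_in",
    "simulate_trajectory",
    "ion_pair_count",
    "preset",
]

# canonical mainchain geometry (Å / degrees)
_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.8


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement: position of atom d given chain a-b-c and internals."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(dihedral) * np.sin(angle),
            bond * np.sin(dihedral) * np.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(phi_psi: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Mainchain N/CA/C/O coordinates for a peptide at given (φ, ψ) angles.

    ω is fixed at 180°; the carbonyl O is placed trans to the next N.
    Returns arrays of shape (n_res, 3) keyed by atom name.
    """
    n_res = len(phi_psi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_NCA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_NCAC)
    C[0] = CA[0] + _B_CAC * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_CN, _A_CACN, psi_prev)
            CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_NCA, _A_CNCA, 180.0)
            C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CAC, _A_NCAC, phi)
        psi_prev = psi
    for i in range(n_res):
        if i + 1 < n_res:
            O[i] = _place_atom(N[i + 1], CA[i], C[i], _B_CO, _A_CACO, 180.0)
        else:
            O[i] = _place_atom(N[i], CA[i], C[i], _B_CO, _A_CACO, phi_psi[i][1] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def build_helix(n_res: int = 12) -> dict[str, np.ndarray]:
    """Ideal α-helix mainchain (φ = −57°, ψ = −47°)."""
    return build_chain([(-57.0, -47.0)] * n_res)


def build_strand(n_res: int = 6) -> dict[str, np.ndarray]:
    """Ideal extended β-strand mainchain (φ = −139°, ψ = 135°)."""
    return build_chain([(-139.0, 135.0)] * n_res)


def _stack(chain: dict[str, np.ndarray]) -> np.ndarray:
    """(n_res, 4, 3) in N, CA, C, O order."""
    return np.stack([chain[a] for a in MAINCHAIN_ATOMS], axis=1)


def _transform(coords: np.ndarray, rotvec: np.ndarray, trans: np.ndarray) -> np.ndarray:
    R = Rotation.from_rotvec(rotvec).as_matrix()
    center = coords.reshape(-1, 3).mean(axis=0)
    return (coords - center) @ R.T + center + trans


def _pair_residuals(params, fixed, mobile, pairs, direction):
    """N···O distance residuals for the antiparallel H-bond register."""
    moved = _transform(mobile, params[:3], params[3:])
    res = []
    for k, j in pairs:
        # narrow pair: NH(fixed k) ... OC(mobile j) and NH(mobile j) ... OC(fixed k)
        res.append(np.linalg.norm(fixed[k, 0] - moved[j, 3]) - 2.9)
        res.append(np.linalg.norm(moved[j, 0] - fixed[k, 3]) - 2.9)
    # keep the sheet flat: CA-CA of paired residues near 5.0 Å
    for k in range(fixed.shape[0]):
        j = direction(k)
        if 0 <= j < mobile.shape[0]:
            res.append(0.3 * (np.linalg.norm(fixed[k, 1] - moved[j, 1]) - 5.0))
    return np.array(res)


def build_antiparallel_sheet(
    n_strands: int, strand_length: int
) -> list[dict[str, np.ndarray]]:
    """n identical strands placed in antiparallel register.

    Strand s+1 is strand s rotated half a turn in the sheet plane and
    refined by least squares so the canonical narrow-pair N···O ≈ 2.9 Å
    hydrogen bonds of an antiparallel ladder are met.
    """
    if strand_length < 4:
        raise ValueError("strand_length must be >= 4")
    if n_strands < 1:
        raise ValueError("need at least one strand")
    base = _stack(build_strand(strand_length))
    strands = [base]
    L = strand_length
    for s in range(1, n_strands):
        prev = strands[-1]
        # initial guess: half-turn about z through the centroid, offset in y
        guess = _transform(prev, np.array([0.0, 0.0, np.pi]), np.array([0.0, 4.85, 0.0]))
        # antiparallel register: residue k of prev pairs with L-1-k of next
        pairs = [(k, L - 1 - k) for k in range(0, L, 2) if 0 <= L - 1 - k < L]
        sol = least_squares(
            _pair_residuals,
            x0=np.zeros(6),
            args=(prev, guess, pairs, lambda k: L - 1 - k),
            xtol=1e-12,
            ftol=1e-12,
        )
        strands.append(_transform(guess, sol.x[:3], sol.x[3:]))
    return [
        {name: s[:, i, :] for i, name in enumerate(MAINCHAIN_ATOMS)} for s in strands
    ]


# planar ring templates (local 2D coordinates, Å); atom order = RING_ATOMS
_HEX = 1.39 * np.array(
    [[np.cos(a), np.sin(a)] for a in np.radians(np.arange(0, 360, 60))]
)
_RING_TEMPLATES = {
    "PHE": _HEX,
    "TYR": _HEX,
    "TRP": np.array(
        [
            [0.00, 0.00], [0.77, 1.10], [1.35, -0.25], [2.13, 0.80], [2.26, -0.59],
            [0.95, -1.90], [3.25, -1.77], [1.50, -3.10], [2.86, -2.95],
        ]
    ),
    "HIS": 1.16 * np.array(
        [[np.cos(a), np.sin(a)] for a in np.radians(np.arange(90, 450, 72))]
    ),
}


def _ring_coords(resname: str, ca, n, c) -> np.ndarray:
    """Idealized planar ring attached on the side-chain side of CA."""
    u = 2.0 * ca - n - c
    u = u / np.linalg.norm(u)
    axis = c - n
    axis = axis / np.linalg.norm(axis)
    v = np.cross(axis, u)
    v = v / np.linalg.norm(v)
    center = ca + 2.4 * u
    template = _RING_TEMPLATES[resname]
    template = template - template.mean(axis=0)
    return center + template[:, 0, None] * u + template[:, 1, None] * v


def build_toy_two_domain(
    n_strands_per_domain: int = 4,
    strand_length: int = 6,
    aromatic_positions: dict[int, str] | None = None,
    domain_gap: float = 8.0,
) -> tuple[Structure, RegionMap]:
    """Idealized two-domain β-sandwich with named strand/domain regions.

    Residues are numbered sequentially (author = internal index).  Designated
    residues in ``aromatic_positions`` (index -> PHE/TYR/TRP/HIS) get an
    idealized planar ring in addition to their mainchain.  The emitted
    :class:`RegionMap` names every strand (``domain1_strand1`` ...) exactly
    once plus both domains.
    """
    aromatic_positions = aromatic_positions or {}
    sheet = build_antiparallel_sheet(n_strands_per_domain, strand_length)
    per_domain = n_strands_per_domain * strand_length

    # second domain: same sheet shifted along the strand axis by extent + gap
    all_ca = np.concatenate([s["CA"] for s in sheet])
    extent = all_ca[:, 0].max() - all_ca[:, 0].min()
    shift = np.array([extent + domain_gap, 0.0, 0.0])

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    regions = RegionMap()
    serial = 0
    res_index = 0
    for dom in (1, 2):
        offset = shift * (dom - 1)
        for s_i, strand in enumerate(sheet, start=1):
            start_res = res_index + 1
            for r in range(strand_length):
                res_index += 1
                resname = aromatic_positions.get(res_index, "ALA").upper()
                if resname not in RING_ATOMS and resname != "ALA":
                    raise ValueError(f"unsupported residue name {resname!r}")
                mc = {a: strand[a][r] + offset for a in MAINCHAIN_ATOMS}
                for name in MAINCHAIN_ATOMS:
                    serial += 1
                    atoms.append(
                        Atom(serial, name, name[0], res_index, resname, "A", res_index)
                    )
                    coords.append(mc[name])
                if resname in RING_ATOMS:
                    ring = _ring_coords(resname, mc["CA"], mc["N"], mc["C"])
                    for rname, pos in zip(RING_ATOMS[resname], ring):
                        serial += 1
                        atoms.append(
                            Atom(serial, rname, rname[0], res_index, resname, "A", res_index)
                        )
                        coords.append(pos)
            regions.add(
                f"domain{dom}_strand{s_i}", start_res, res_index, f"β-strand {s_i}"
            )
        regions.add(
            f"domain{dom}",
            per_domain * (dom - 1) + 1,
            per_domain * dom,
            f"domain {dom}",
        )
    structure = Structure(atoms, [np.array(coords)])
    return structure, regions


# 3-letter codes used to fill the non-aromatic remainder of the stand-in
_FILLER = ("ALA", "GLY", "SER", "LEU", "VAL", "THR", "ASP", "GLU", "ARG", "LYS",
           "ASN", "GLN", "ILE", "PRO", "MET", "CYS", "HIS")


def build_composition_stand_in() -> Structure:
    """Synthetic CA-only stand-in for the mature 173-residue lens-crystallin chain.

    This is a *synthetic* fixture, not a deposited structure: it reproduces
    the documented chain composition — 173 residues with 14 tyrosines, 4
    tryptophans and 6 phenylalanines — with filler residues elsewhere, so the
    parse → composition pipeline can be exercised offline.  Coordinates trace
    an arbitrary smooth spiral.
    """
    n_res = 173
    resnames = []
    aromatic = ["TYR"] * 14 + ["TRP"] * 4 + ["PHE"] * 6
    spacing = n_res // len(aromatic)
    positions = {1 + k * spacing: aromatic[k] for k in range(len(aromatic))}
    for i in range(1, n_res + 1):
        resnames.append(positions.get(i, _FILLER[i % len(_FILLER)]))
    atoms = []
    coords = []
    for i, rn in enumerate(resnames, start=1):
        atoms.append(Atom(i, "CA", "C", i, rn, "A", i))
        theta = 0.6 * i
        coords.append((8.0 * np.cos(theta), 8.0 * np.sin(theta), 1.5 * i))
    return Structure(atoms, [np.array(coords)])


# ---------------------------------------------------------------------------
# Scripted trajectories
# ---------------------------------------------------------------------------

@dataclass
class DetachmentEvent:
    region: str
    onset_frame: int
    displacement: tuple[float, float, float]
    ramp_frames: int = 5


@dataclass
class RotationEvent:
    moving_region: str
    fixed_region: str
    total_angle_deg: float
    twist_fraction: float
    axis: tuple[float, float, float] | None = None


@dataclass
class ClusterEvent:
    members: tuple[int, ...]
    onset_frame: int
    target_distance: float = 5.5


@dataclass
class UnfoldingScript:
    """Deterministic recipe for a synthetic trajectory."""

    seed: int = 0
    n_frames: int = 100
    dt_ns: float = 0.25
    noise_sigma: float = 0.15
    detachments: list[DetachmentEvent] = field(default_factory=list)
    rotations: list[RotationEvent] = field(default_factory=list)
    cluster_events: list[ClusterEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for ev in self.detachments + self.cluster_events:
            if not 0 <= ev.onset_frame < self.n_frames:
                raise ValueError(f"onset frame {ev.onset_frame} outside trajectory")
        for ev in self.rotations:
            if not 0.0 <= ev.twist_fraction <= 1.0:
                raise ValueError("twist fraction must be in [0, 1]")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "UnfoldingScript":
        from pathlib import Path

        raw_str = str(text_or_path)
        if raw_str.lstrip().startswith("{"):
            text = raw_str
        else:
            text = Path(raw_str).read_text()
        raw = json.loads(text)
        return cls(
            seed=raw.get("seed", 0),
            n_frames=raw.get("n_frames", 100),
            dt_ns=raw.get("dt_ns", 0.25),
            noise_sigma=raw.get("noise_sigma", 0.15),
            detachments=[DetachmentEvent(**d) for d in raw.get("detachments", [])],
            rotations=[RotationEvent(**d) for d in raw.get("rotations", [])],
            cluster_events=[
                ClusterEvent(members=tuple(d.pop("members")), **d)
                for d in raw.get("cluster_events", [])
            ],
        )


@dataclass
class GroundTruth:
    """True event parameters implied by an :class:`UnfoldingScript`."""

    detachment_onsets: list[dict]
    rotation: list[dict]
    cluster_onsets: list[dict]
    noise_sigma: float
    dt_ns: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_json_default)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _region_atoms(structure: Structure, regions: RegionMap, name: str) -> np.ndarray:
    region = regions.resolve(name)
    return np.array(
        [
            i
            for i, a in enumerate(structure.atoms)
            if region.start <= a.author_residue_number <= region.end
        ],
        dtype=int,
    )


def _perpendicular(d: np.ndarray) -> np.ndarray:
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(trial, d)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(d, trial)
    return p / np.linalg.norm(p)


def _simplex(k: int, edge: float) -> np.ndarray:
    """k points in 3-D with all pairwise distances equal to ``edge`` (k ≤ 4)."""
    if k == 2:
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    elif k == 3:
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    elif k == 4:
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(8)
    else:
        raise ValueError("equidistant cluster scripting supports 2-4 members")
    pts = pts * edge
    return pts - pts.mean(axis=0)


def simulate_trajectory(
    structure: Structure,
    script: UnfoldingScript,
    regions: RegionMap,
) -> tuple[Trajectory, GroundTruth]:
    """Render a script into frames: rotations + ramped detachments + noise.

    Deterministic given (structure, script, seed).  Raises if a rotation and
    a detachment claim the same atoms, since the scripted ground truth would
    then be ill-defined.
    """
    base = structure.coords(0)
    n_atoms = structure.n_atoms
    nf = script.n_frames
    rng = np.random.default_rng(script.seed)

    det_atoms = [( _region_atoms(structure, regions, d.region), d) for d in script.detachments]
    rot_specs = []
    for ev in script.rotations:
        mov = _region_atoms(structure, regions, ev.moving_region)
        fix = _region_atoms(structure, regions, ev.fixed_region)
        for idx, _ in det_atoms:
            if np.intersect1d(idx, mov).size:
                raise ValueError(
                    "script error: detachment and rotation target the same atoms"
                )
        c_mov = base[mov].mean(axis=0)
        c_fix = base[fix].mean(axis=0)
        d = c_mov - c_fix
        d = d / np.linalg.norm(d)
        if ev.axis is not None:
            axis = np.asarray(ev.axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
        else:
            p = _perpendicular(d)
            axis = np.sqrt(ev.twist_fraction) * d + np.sqrt(1.0 - ev.twist_fraction) * p
            axis = axis / np.linalg.norm(axis)
        rot_specs.append((mov, c_mov, axis, d, ev))

    cluster_specs = []
    from .aromatics import aromatic_residues

    rings = aromatic_residues(structure, include_his=True) if script.cluster_events else {}
    for ev in script.cluster_events:
        members = tuple(ev.members)
        for r in members:
            if r not in rings:
                raise ValueError(f"cluster member {r} is not an aromatic residue")
        centroids = {r: base[rings[r]].mean(axis=0) for r in members}
        center = np.mean([centroids[r] for r in members], axis=0)
        targets = _simplex(len(members), ev.target_distance) + center
        shifts = {
            r: targets[k] - centroids[r] for k, r in enumerate(sorted(members))
        }
        side_atoms = {
            r: np.array(
                [
                    i
                    for i, a in enumerate(structure.atoms)
                    if a.residue_index == r and a.name not in MAINCHAIN_ATOMS
                ],
                dtype=int,
            )
            for r in members
        }
        cluster_specs.append((side_atoms, shifts, ev))

    frames = np.empty((nf, n_atoms, 3))
    rotation_truth_angles = [np.zeros(nf) for _ in rot_specs]
    for k in range(nf):
        frame = base.copy()
        for ri, (mov, c_mov, axis, d, ev) in enumerate(rot_specs):
            angle = ev.total_angle_deg * (k / (nf - 1)) if nf > 1 else 0.0
            rotation_truth_angles[ri][k] = angle
            R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
            frame[mov] = (frame[mov] - c_mov) @ R.T + c_mov
        for idx, ev in det_atoms:
            if k >= ev.onset_frame:
                f = min(1.0, (k - ev.onset_frame + 1) / max(1, ev.ramp_frames))
                frame[idx] = frame[idx] + f * np.asarray(ev.displacement)
        for side_atoms, shifts, ev in cluster_specs:
            if k >= ev.onset_frame:
                for r, idx in side_atoms.items():
                    frame[idx] = frame[idx] + shifts[r]
        if script.noise_sigma > 0:
            frame = frame + rng.normal(0.0, script.noise_sigma, size=frame.shape)
        frames[k] = frame

    times = np.arange(nf) * script.dt_ns
    traj = Trajectory(structure, times, frames)
    truth = GroundTruth(
        detachment_onsets=[
            {
                "region": ev.region,
                "onset_frame": ev.onset_frame,
                "onset_ns": ev.onset_frame * script.dt_ns,
            }
            for _, ev in det_atoms
        ],
        rotation=[
            {
                "moving_region": ev.moving_region,
                "axis": axis,
                "interdomain_vector": d,
                "percent_twist": 100.0 * float(np.dot(axis, d) ** 2),
                "total_angle_deg": ev.total_angle_deg,
                "per_frame_angle_deg": angles,
            }
            for (mov, c, axis, d, ev), angles in zip(rot_specs, rotation_truth_angles)
        ],
        cluster_onsets=[
            {
                "members": list(ev.members),
                "onset_frame": ev.onset_frame,
                "onset_ns": ev.onset_frame * script.dt_ns,
            }
            for _, _, ev in cluster_specs
        ],
        noise_sigma=script.noise_sigma,
        dt_ns=script.dt_ns,
    )
    return traj, truth


def ion_pair_count(concentration_mM: float, box_edge_nm: float) -> int:
    """Ions of one species needed for a salt concentration in a cubic box.

    round(c · N_A · V) with c in mol/L and V = edge³ in litres
    (1 nm³ = 1e-24 L).
    """
    if concentration_mM < 0 or box_edge_nm <= 0:
        raise ValueError("concentration must be >= 0 and edge > 0")
    volume_l = (box_edge_nm**3) * 1e-24
    return int(round(concentration_mM * 1e-3 * Avogadro * volume_l))


# ---------------------------------------------------------------------------
# Presets exercising the published region vocabulary on the toy fold
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0):
    """Named study presets: (structure, regions, script).

    ``gdnhcl_like``: three sequential strand detachments (the motif-2-β3 →
    motif-1-β3 → motif-2-β2 order) plus a closure-dominated interdomain
    rotation.  ``urea_like``: one detachment, a twist-dominated rotation and
    a late four-ring aromatic-cluster formation.  ``static``: empty script.
    Published region names are aliased onto the toy strands so configuration
    files can use the field vocabulary.
    """
    aromatics = {9: "TYR", 21: "TYR", 23: "TYR", 27: "TRP"}
    structure, regions = build_toy_two_domain(6, 6, aromatic_positions=aromatics)
    # aliases chosen so no scripted strand is a sheet neighbour of another
    # scripted strand: each region's contact/β loss is caused only by its own
    # detachment (strands 1-6 per domain; s6 first, far edge s1, inner s3)
    for alias, target in (
        ("motif2_beta3", "domain1_strand6"),
        ("motif1_beta3", "domain1_strand1"),
        ("motif2_beta2", "domain1_strand3"),
    ):
        r = regions[target]
        regions.add(alias, r.start, r.end, f"alias of {target}")
    # strands 4-5 of domain 1 never move in any preset script: a rigid
    # anchor for interdomain-motion analysis once other strands detach
    regions.add("domain1_core", regions["domain1_strand4"].start,
                regions["domain1_strand5"].end, "rigid core strands s4-s5")

    if name == "static":
        script = UnfoldingScript(seed=seed, n_frames=40, noise_sigma=0.0)
    elif name == "gdnhcl_like":
        script = UnfoldingScript(
            seed=seed,
            n_frames=100,
            dt_ns=0.25,
            noise_sigma=0.15,
            detachments=[
                DetachmentEvent("motif2_beta3", 15, (0.0, 18.0, 6.0), 5),
                DetachmentEvent("motif1_beta3", 45, (0.0, -16.0, 8.0), 5),
                DetachmentEvent("motif2_beta2", 75, (0.0, 6.0, 20.0), 5),
            ],
            rotations=[RotationEvent("domain2", "domain1_core", 12.0, twist_fraction=0.1)],
        )
    elif name == "urea_like":
        script = UnfoldingScript(
            seed=seed,
            n_frames=100,
            dt_ns=0.25,
            noise_sigma=0.15,
            detachments=[DetachmentEvent("motif2_beta3", 25, (0.0, 18.0, 6.0), 5)],
            rotations=[RotationEvent("domain2", "domain1_core", 12.0, twist_fraction=0.9)],
            cluster_events=[ClusterEvent((9, 21, 23, 27), 55, 5.5)],
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return structure, regions, script
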