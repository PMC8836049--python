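"""Rigid-body superposition, fluctuation measures, essential-dynamics PCA and
two-domain closure/twist decomposition.

The closure/twist split follows a simplified screw-axis picture: after the
fixed domain is superposed, the moving domain's optimal rotation has a unit
axis **n**; with **d** the unit interdomain (centroid-to-centroid) vector of
the reference, the twist share is 100·(n·d)² and the closure share the
complement, so the two always sum to 100.  Rotation about the interdomain
axis is a pure twist; rotation about any perpendicular axis is a pure
closure/opening motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io_model import AtomSelection, Region, RegionMap, Structure, Trajectory, select_atoms

__all__ = [
    "TimeSeries",
    "SuperpositionResult",
    "EigenModel",
    "RotationDescriptor",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "pca_essential",
    "project_frames",
    "domain_rotation",
    "motion_fraction",
]


@dataclass
class TimeSeries:
    """A unit-tagged scalar series over strictly increasing times (ns)."""

    times_ns: np.ndarray
    values: np.ndarray
    unit: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ns.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times_ns.size > 1 and np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation and the attained RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _selection_indices(
    selection: AtomSelection | np.ndarray | None, n_atoms: int
) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    if isinstance(selection, AtomSelection):
        return selection.indices
    return np.asarray(selection, dtype=int)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: AtomSelection | np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The rotation is proper (det = +1, Kabsch solution); the RMSD is computed
    over the selection after applying the transform.  Raises for fewer than
    three selected atoms or a collinear selection, where the rotation is not
    determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _selection_indices(selection, mobile.shape[0])
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    mob = mobile[idx]
    ref = reference[idx]
    if mob.shape != ref.shape:
        raise ValueError("selection shapes differ between mobile and reference")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection: rotation ill-conditioned")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: AtomSelection | np.ndarray | None = None,
    fit: bool = True,
) -> TimeSeries:
    """Per-frame RMSD (Å) over the selection, against a reference frame.

    With ``fit=True`` (default) each frame is least-squares superposed onto
    the reference on the selection first, so rigid-body motion does not
    register; ``fit=False`` evaluates the raw coordinate deviation.
    """
    idx = _selection_indices(selection, traj.topology.n_atoms)
    if idx.size == 0:
        raise ValueError("empty selection")
    ref = traj.frame(reference_frame)
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        if fit:
            values[i] = kabsch_superpose(traj.frame(i), ref, idx).rmsd
        else:
            diff = traj.frame(i)[idx] - ref[idx]
            values[i] = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return TimeSeries(traj.times_ns, values, unit="Å", name="rmsd")


def _align_frames(coords: np.ndarray, reference: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        sup = kabsch_superpose(coords[i], reference, idx)
        out[i] = sup.apply(coords[i])
    return out


def rmsf_per_residue(
    traj: Trajectory,
    selection: AtomSelection | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (Å) about the time-averaged structure.

    Two-pass alignment: frames are first superposed onto frame 0 on the
    selection, averaged, then re-superposed onto that average before the
    fluctuations are measured.  The residue value is the mean RMSF of the
    residue's selected (by default mainchain) atoms.  Returns
    ``(residue_indices, rmsf)``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = traj.topology
    if selection is None:
        selection = select_atoms(top, "mainchain")
    idx = _selection_indices(selection, top.n_atoms)
    aligned = _align_frames(traj.coords, traj.frame(0), idx)
    mean1 = aligned.mean(axis=0)
    aligned = _align_frames(aligned, mean1, idx)
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    res_of = top.residue_index[idx]
    residues = np.unique(res_of)
    values = np.array([per_atom[idx][res_of == r].mean() for r in residues])
    return residues, values


@dataclass
class EigenModel:
    """Essential-dynamics PCA model over a fixed atom selection.

    Eigenvalues are in Å², sorted descending; eigenvector columns are
    orthonormal in the 3m-dimensional flattened coordinate space of the m
    selected atoms.  ``reference`` keeps the frame-0 selection coordinates so
    projections realign new frames identically.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    selection: np.ndarray
    reference: np.ndarray = field(repr=False, default=None)


def pca_essential(
    traj: Trajectory,
    selection: AtomSelection | np.ndarray | None = None,
) -> EigenModel:
    """Diagonalise the coordinate covariance of the (aligned) trajectory.

    Frames are superposed to frame 0 on the selection first, which removes
    rigid-body modes; eigenpairs are sorted by eigenvalue descending and each
    eigenvector's sign is fixed so its first component of magnitude > 1e-12
    is positive.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    top = traj.topology
    if selection is None:
        selection = select_atoms(top, "mainchain")
    idx = _selection_indices(selection, top.n_atoms)
    aligned = _align_frames(traj.coords, traj.frame(0), idx)
    X = aligned[:, idx, :].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        col = evecs[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            evecs[:, j] = -col
    return EigenModel(
        mean=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        selection=idx,
        reference=traj.frame(0)[idx].copy(),
    )


def project_frames(traj: Trajectory, model: EigenModel, k: int = 2) -> np.ndarray:
    """Project frames onto the top-k essential modes -> (n_frames, k)."""
    if k > model.eigenvectors.shape[1]:
        raise ValueError(f"k={k} exceeds available modes {model.eigenvectors.shape[1]}")
    idx = model.selection
    proj = np.empty((traj.n_frames, k))
    for i in range(traj.n_frames):
        sup = kabsch_superpose(traj.frame(i)[idx], model.reference)
        x = sup.apply(traj.frame(i)[idx]).reshape(-1) - model.mean
        proj[i] = x @ model.eigenvectors[:, :k]
    return proj


@dataclass
class RotationDescriptor:
    """Interdomain rotation split into closure and twist components."""

    axis: np.ndarray
    angle_deg: float
    hinge_point: np.ndarray
    percent_closure: float
    percent_twist: float

    @property
    def label(self) -> str:
        return "closure" if self.percent_closure >= 50.0 else "twist"


def _region_mainchain(
    top: Structure, region: Region | tuple[int, int], regions: RegionMap | None
) -> np.ndarray:
    if isinstance(region, str):
        if regions is None:
            raise ValueError("region name given but no RegionMap supplied")
        region = regions.resolve(region)
    if isinstance(region, Region):
        bounds = (region.start, region.end)
    else:
        bounds = region
    sel = select_atoms(top, bounds).intersect(select_atoms(top, "mainchain"))
    return sel.indices, bounds


def domain_rotation(
    frame: np.ndarray,
    reference: np.ndarray,
    topology: Structure,
    fixed_domain: Region | str | tuple[int, int],
    moving_domain: Region | str | tuple[int, int],
    regions: RegionMap | None = None,
) -> RotationDescriptor:
    """Rotation of ``moving_domain`` relative to ``fixed_domain``.

    The frame is first superposed onto the reference on the fixed domain's
    mainchain; the Kabsch rotation of the moving domain then gives the screw
    axis and angle.  The hinge point is the projection of the moving domain's
    reference centroid onto the screw axis.
    """
    fixed_idx, fb = _region_mainchain(topology, fixed_domain, regions)
    moving_idx, mb = _region_mainchain(topology, moving_domain, regions)
    if max(fb[0], mb[0]) <= min(fb[1], mb[1]):
        raise ValueError(f"domains overlap: {fb} vs {mb}")
    if len(fixed_idx) < 9 or len(moving_idx) < 9:
        raise ValueError("each domain needs at least 3 residues of mainchain atoms")

    sup = kabsch_superpose(frame, reference, fixed_idx)
    aligned = sup.apply(frame)

    ref_mov = reference[moving_idx]
    frm_mov = aligned[moving_idx]
    sup_mov = kabsch_superpose(ref_mov, frm_mov)
    R = sup_mov.rotation
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))

    c_fixed = reference[fixed_idx].mean(axis=0)
    c_mov = ref_mov.mean(axis=0)
    d = c_mov - c_fixed
    d = d / np.linalg.norm(d)

    if angle > 1e-12:
        n = rotvec / np.linalg.norm(rotvec)
    else:
        n = np.array([0.0, 0.0, 1.0])
    pct_twist = float(100.0 * np.dot(n, d) ** 2)
    pct_closure = 100.0 - pct_twist

    # screw-axis point: solve (I - R) p = t_perp, then slide to the centroid
    t = frm_mov.mean(axis=0) - R @ c_mov
    t_perp = t - np.dot(t, n) * n
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    hinge = p + np.dot(c_mov - p, n) * n
    return RotationDescriptor(
        axis=n,
        angle_deg=angle,
        hinge_point=hinge,
        percent_closure=pct_closure,
        percent_twist=pct_twist,
    )


def motion_fraction(
    traj: Trajectory,
    fixed_domain,
    moving_domain,
    stride: int = 1,
    angle_floor: float = 1.0,
    regions: RegionMap | None = None,
) -> dict:
    """Closure/twist time-share of the interdomain motion versus frame 0.

    Frames with rotation angle below ``angle_floor`` degrees carry no net
    rotation and are excluded from the fractions (their count is reported).
    Returned fractions are percentages of the counted frames and sum to 100;
    both are NaN (with a warning) when every frame is below the floor.
    """
    times, frames = traj.sampled(stride)
    ref = traj.frame(0)
    records = []
    n_closure = n_twist = n_excluded = 0
    for t, frame in zip(times, frames):
        desc = domain_rotation(frame, ref, traj.topology, fixed_domain, moving_domain, regions)
        if desc.angle_deg < angle_floor:
            n_excluded += 1
            records.append((t, desc.angle_deg, desc.percent_closure, "none"))
            continue
        if desc.label == "closure":
            n_closure += 1
        else:
            n_twist += 1
        records.append((t, desc.angle_deg, desc.percent_closure, desc.label))
    counted = n_closure + n_twist
    if counted == 0:
        warnings.warn("all frames below angle floor: motion fractions undefined")
        frac_c = frac_t = float("nan")
    else:
        frac_c = 100.0 * n_closure / counted
        frac_t = 100.0 * n_twist / counted
    return {
        "fraction_closure": frac_c,
        "fraction_twist": frac_t,
        "n_counted": counted,
        "n_excluded": n_excluded,
        "per_frame": records,
    }
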