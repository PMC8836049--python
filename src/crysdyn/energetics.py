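"""Potential-energy bookkeeping with a pluggable scorer.

The breakdown mirrors the classical force-field partition

    E_pot     = E_valence + E_nonbond
    E_valence = E_str + E_bend + E_tor + E_inv
    E_nonbond = E_van + E_elec + E_hbond

and ΔE between two trajectory endpoints is the exact difference of the two
breakdowns' E_pot.  The built-in toy scorer implements harmonic bond stretch
(E_str = k·(r−r0)², declared convention, not ½k), 12-6 Lennard–Jones and
uniform-dielectric Coulomb terms; the remaining terms are recorded as zero
and flagged, so the bookkeeping contract can be exercised without a full
force-field parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import Structure, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "EnergyDelta",
    "ToyParameters",
    "toy_energy",
    "potential_energy_delta",
]

#: kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637

_TERMS = ("E_str", "E_bend", "E_tor", "E_inv", "E_van", "E_elec", "E_hbond")
_VALENCE = ("E_str", "E_bend", "E_tor", "E_inv")
_NONBOND = ("E_van", "E_elec", "E_hbond")


@dataclass
class EnergyBreakdown:
    """Term-wise potential energy (kcal/mol) satisfying the sum identities."""

    E_str: float = 0.0
    E_bend: float = 0.0
    E_tor: float = 0.0
    E_inv: float = 0.0
    E_van: float = 0.0
    E_elec: float = 0.0
    E_hbond: float = 0.0
    unimplemented: tuple[str, ...] = ()

    @property
    def E_valence(self) -> float:
        return self.E_str + self.E_bend + self.E_tor + self.E_inv

    @property
    def E_nonbond(self) -> float:
        return self.E_van + self.E_elec + self.E_hbond

    @property
    def E_pot(self) -> float:
        return self.E_valence + self.E_nonbond

    def as_dict(self) -> dict[str, float]:
        d = {t: getattr(self, t) for t in _TERMS}
        d.update(E_valence=self.E_valence, E_nonbond=self.E_nonbond, E_pot=self.E_pot)
        return d


@dataclass
class EnergyDelta:
    delta_E: float
    t_start_ns: float
    t_end_ns: float
    breakdown_start: EnergyBreakdown
    breakdown_end: EnergyBreakdown

    def term_deltas(self) -> dict[str, float]:
        a = self.breakdown_start.as_dict()
        b = self.breakdown_end.as_dict()
        return {k: b[k] - a[k] for k in a}


@dataclass
class ToyParameters:
    """Parameters for the built-in scorer.

    ``lj``: atom index -> (epsilon kcal/mol, sigma Å); ``charges``: atom
    index -> e; ``bonds``: (i, j, r0 Å, k kcal/mol/Å²) with E = k·(r−r0)².
    Bonded pairs are excluded from the nonbonded terms.  ``dielectric`` is
    the uniform relative permittivity of the Coulomb term.
    """

    lj: dict[int, tuple[float, float]] = field(default_factory=dict)
    charges: dict[int, float] = field(default_factory=dict)
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    dielectric: float = 1.0


def toy_energy(
    frame: np.ndarray, topology: Structure, parameters: ToyParameters
) -> EnergyBreakdown:
    """Score one frame with the toy force field.

    Every atom must have LJ parameters and a charge; a missing entry raises a
    parameterization error.  Terms the scorer does not implement (bend,
    torsion, inversion, explicit H-bond) are zero and listed in
    ``unimplemented``.
    """
    coords = np.asarray(frame, dtype=float)
    n = topology.n_atoms
    for i in range(n):
        if i not in parameters.lj or i not in parameters.charges:
            raise KeyError(f"missing LJ/charge parameters for atom index {i}")

    bonded = set()
    e_str = 0.0
    for i, j, r0, k in parameters.bonds:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e_str += k * (r - r0) ** 2
        bonded.add((min(i, j), max(i, j)))

    e_van = 0.0
    e_elec = 0.0
    for i in range(n):
        eps_i, sig_i = parameters.lj[i]
        qi = parameters.charges[i]
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            eps = np.sqrt(eps_i * parameters.lj[j][0])
            sig = 0.5 * (sig_i + parameters.lj[j][1])
            if eps > 0:
                sr6 = (sig / r) ** 6
                e_van += 4.0 * eps * (sr6 * sr6 - sr6)
            qj = parameters.charges[j]
            if qi != 0 and qj != 0:
                e_elec += COULOMB_CONSTANT * qi * qj / (parameters.dielectric * r)

    return EnergyBreakdown(
        E_str=e_str,
        E_van=e_van,
        E_elec=e_elec,
        unimplemented=("E_bend", "E_tor", "E_inv", "E_hbond"),
    )


def potential_energy_delta(
    traj: Trajectory,
    scorer,
    t_start_ns: float,
    t_end_ns: float,
) -> EnergyDelta:
    """ΔE = E(t_end) − E(t_start) between two trajectory frames.

    ``scorer(frame, topology) -> EnergyBreakdown``; the frames used are the
    stored frames nearest the requested times (which must lie within the
    trajectory's span).
    """
    times = traj.times_ns
    for t in (t_start_ns, t_end_ns):
        if not (times[0] <= t <= times[-1]):
            raise ValueError(f"time {t} ns outside trajectory span")
    i0 = int(np.argmin(np.abs(times - t_start_ns)))
    i1 = int(np.argmin(np.abs(times - t_end_ns)))
    try:
        b0 = scorer(traj.frame(i0), traj.topology)
        b1 = scorer(traj.frame(i1), traj.topology)
    except Exception as exc:
        raise RuntimeError(
            f"scorer failed on frames {i0}/{i1} "
            f"(t = {times[i0]:.3f}/{times[i1]:.3f} ns): {exc}"
        ) from exc
    return EnergyDelta(
        delta_E=b1.E_pot - b0.E_pot,
        t_start_ns=float(times[i0]),
        t_end_ns=float(times[i1]),
        breakdown_start=b0,
        breakdown_end=b1,
    )
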