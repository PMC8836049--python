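"""Ring centroids, interaction-band persistence and cluster events."""

import numpy as np
import pytest

from crysdyn.aromatics import (
    RING_ATOMS,
    RingGeometryError,
    cluster_formation_events,
    detect_aromatic_clusters,
    pair_distance_series,
    persistence_percentage,
    ring_centroid,
)
from crysdyn.io_model import Atom, Structure, Trajectory
from crysdyn.synthetic_data import ClusterEvent, UnfoldingScript, build_toy_two_domain, preset, simulate_trajectory

from conftest import static_trajectory


def ring_structure(centers, resname="PHE"):
    """One aromatic residue (ring atoms only) per given centroid."""
    atoms = []
    coords = []
    serial = 0
    names = RING_ATOMS[resname]
    template = 1.39 * np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in np.radians(np.arange(0, 360, 60))]
    )[: len(names)]
    for r, center in enumerate(centers, start=1):
        for name, off in zip(names, template):
            serial += 1
            atoms.append(Atom(serial, name, name[0], r, resname, "A", r))
            coords.append(np.asarray(center, float) + off)
    return Structure(atoms, [np.array(coords)])


class TestCentroid:
    def test_regular_hexagon_centroid_origin(self):
        s = ring_structure([[0.0, 0, 0]])
        np.testing.assert_allclose(ring_centroid(s, 1, s.coords(0)), 0.0, atol=1e-12)

    def test_centroid_translates_with_ring(self):
        s = ring_structure([[3.0, -2.0, 7.0]])
        np.testing.assert_allclose(ring_centroid(s, 1, s.coords(0)), [3.0, -2.0, 7.0], atol=1e-12)

    def test_trp_nine_atom_mean(self, rng):
        coords = rng.normal(size=(9, 3))
        atoms = [
            Atom(i + 1, n, n[0], 1, "TRP", "A", 1)
            for i, n in enumerate(RING_ATOMS["TRP"])
        ]
        s = Structure(atoms, [coords])
        np.testing.assert_allclose(ring_centroid(s, 1, coords), coords.mean(axis=0))

    def test_missing_ring_atom_named_in_error(self):
        s = ring_structure([[0.0, 0, 0]])
        partial = Structure(s.atoms[:5], [s.coords(0)[:5]])
        with pytest.raises(RingGeometryError, match="CZ"):
            ring_centroid(partial, 1, partial.coords(0))

    def test_non_aromatic_rejected(self, toy_two_domain):
        structure, _ = toy_two_domain
        with pytest.raises(RingGeometryError):
            ring_centroid(structure, 1, structure.coords(0))


class TestDistanceSeries:
    def test_constant_separation(self):
        s = ring_structure([[0.0, 0, 0], [5.0, 0, 0]])
        traj = static_trajectory(s, 4)
        ts = pair_distance_series(traj, 1, 2)
        np.testing.assert_allclose(ts.values, 5.0, atol=1e-12)

    def test_symmetric_in_residue_order(self):
        s = ring_structure([[0.0, 0, 0], [6.0, 1.0, 0]])
        traj = static_trajectory(s, 3)
        a = pair_distance_series(traj, 1, 2).values
        b = pair_distance_series(traj, 2, 1).values
        np.testing.assert_allclose(a, b)

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        s = ring_structure([[0.0, 0, 0], [6.0, 1.0, 0]])
        traj = static_trajectory(s, 2)
        base = pair_distance_series(traj, 1, 2).values
        R = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        moved = Trajectory(s, traj.times_ns, traj.coords @ R.T + 7.0)
        np.testing.assert_allclose(pair_distance_series(moved, 1, 2).values, base, atol=1e-9)

    def test_ramp_crosses_band_edge_at_scripted_frame(self):
        s = ring_structure([[0.0, 0, 0], [5.0, 0, 0]])
        n = 100
        sep = np.full(n, 5.0)
        sep[40:60] = np.linspace(5.0, 12.0, 20)
        sep[60:] = 12.0
        frames = np.repeat(s.coords(0)[None], n, axis=0)
        frames[:, 6:, 0] += (sep - 5.0)[:, None]
        traj = Trajectory(s, np.arange(n) * 0.25, frames)
        d = pair_distance_series(traj, 1, 2).values
        crossing = np.argmax(d > 7.0)
        scripted = 40 + int(np.ceil(2.0 / (7.0 / 19)))  # first ramp step past 7 Å
        assert abs(int(crossing) - scripted) <= 1


class TestPersistence:
    @pytest.mark.parametrize(
        "distance,expected", [(5.5, 100.0), (10.0, 0.0), (4.5, 100.0), (7.0, 100.0)]
    )
    def test_constant_distance_band_membership(self, distance, expected):
        s = ring_structure([[0.0, 0, 0], [distance, 0, 0]])
        traj = static_trajectory(s, 10)
        assert persistence_percentage(traj, 1, 2) == pytest.approx(expected)

    def test_partial_presence_counting(self):
        s = ring_structure([[0.0, 0, 0], [5.5, 0, 0]])
        n = 100
        frames = np.repeat(s.coords(0)[None], n, axis=0)
        frames[30:, 6:, 0] += 10.0  # in band for exactly 30 of 100 frames
        traj = Trajectory(s, np.arange(n) * 0.25, frames)
        assert persistence_percentage(traj, 1, 2) == pytest.approx(30.0)

    def test_narrower_band_is_monotone(self):
        s = ring_structure([[0.0, 0, 0], [5.2, 0, 0], [13.0, 0, 0]])
        traj = static_trajectory(s, 5)
        wide = persistence_percentage(traj, 1, 2, band=(4.5, 7.0))
        narrow = persistence_percentage(traj, 1, 2, band=(4.5, 5.0))
        assert narrow <= wide


def _brute_components(centroids, band, min_size):
    # independent connected components by breadth-first search
    residues = sorted(centroids)
    adj = {r: set() for r in residues}
    for i, a in enumerate(residues):
        for b in residues[i + 1 :]:
            d = np.linalg.norm(centroids[a] - centroids[b])
            if band[0] <= d <= band[1]:
                adj[a].add(b)
                adj[b].add(a)
    seen = set()
    comps = []
    for r in residues:
        if r in seen:
            continue
        stack, comp = [r], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        if len(comp) >= min_size:
            comps.append(frozenset(comp))
    return set(comps)


class TestClusters:
    def test_triangle_forms_single_cluster(self):
        s = ring_structure([[0.0, 0, 0], [5.5, 0, 0], [2.75, 4.76, 0]])
        found = detect_aromatic_clusters(s.coords(0), s)
        assert len(found) == 1 and found[0].members == frozenset({1, 2, 3})

    def test_out_of_band_rings_form_nothing(self):
        s = ring_structure([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]])
        assert detect_aromatic_clusters(s.coords(0), s) == []

    def test_chain_is_transitively_connected(self):
        s = ring_structure([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        found = detect_aromatic_clusters(s.coords(0), s)
        # 1-2 and 2-3 in band, 1-3 at 10 Å: still one component
        assert found[0].members == frozenset({1, 2, 3})

    def test_matches_bruteforce_components_on_random_frames(self, rng):
        for _ in range(100):
            centers = rng.uniform(0, 25, size=(8, 3))
            s = ring_structure(centers)
            found = {c.members for c in detect_aromatic_clusters(s.coords(0), s)}
            centroids = {r + 1: ring_centroid(s, r + 1, s.coords(0)) for r in range(8)}
            assert found == _brute_components(centroids, (4.5, 7.0), 3)

    def test_static_native_trajectory_has_no_formation_events(self):
        structure, regions, script = preset("static")
        traj, _ = simulate_trajectory(structure, script, regions)
        assert cluster_formation_events(traj) == []

    def test_scripted_formation_recovered(self):
        structure, regions, script = preset("urea_like", seed=21)
        traj, truth = simulate_trajectory(structure, script, regions)
        events = cluster_formation_events(traj)
        assert len(events) == 1
        assert events[0].members == frozenset(truth.cluster_onsets[0]["members"])
        assert abs(events[0].onset_ns - truth.cluster_onsets[0]["onset_ns"]) <= 2 * script.dt_ns

    def test_transient_contact_suppressed_by_persistence(self):
        structure, regions = build_toy_two_domain(
            4, 6, aromatic_positions={3: "TYR", 9: "TYR", 15: "TYR"}
        )
        script = UnfoldingScript(
            seed=1,
            n_frames=30,
            noise_sigma=0.0,
            cluster_events=[ClusterEvent((3, 9, 15), 28, 5.5)],  # only 2 frames long
        )
        traj, _ = simulate_trajectory(structure, script, regions)
        assert cluster_formation_events(traj, persistence=5) == []
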