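"""Elastic network construction, Hessian analysis and reductions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rnaenm as r
from rnaenm.enm_core import network_energy, project_out_rigid, rigid_mode_basis

from conftest import dof_indices


def two_bead_structure(distance=1.0):
    labels = [r.BeadLabel("A", 1, "S"), r.BeadLabel("A", 2, "S")]
    coords = np.array([[0.0, 0, 0], [distance, 0, 0]])
    return r.BeadStructure(labels, coords)


class TestBuildNetwork:
    def test_two_beads_within_cutoff(self):
        net = r.build_network(two_bead_structure(), cutoff=2.0)
        assert net.n_springs == 1
        assert net.reference_distances[0] == pytest.approx(1.0)

    def test_two_beads_beyond_cutoff(self):
        net = r.build_network(two_bead_structure(), cutoff=0.5)
        assert net.n_springs == 0

    def test_spring_count_matches_pair_scan(self):
        cloud = r.random_cloud(20, box=18.0, min_separation=2.0, seed=11)
        net = r.build_network(cloud, cutoff=8.0)
        brute = sum(
            1
            for i in range(20)
            for j in range(i + 1, 20)
            if np.linalg.norm(cloud.coords[i] - cloud.coords[j]) < 8.0
        )
        assert net.n_springs == brute

    def test_monotone_in_cutoff(self):
        cloud = r.random_cloud(15, seed=2)
        counts = [r.build_network(cloud, c).n_springs for c in np.arange(3, 30, 1.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_distance_dependent_constants(self):
        cloud = r.random_cloud(8, seed=3)
        net = r.build_network(cloud, 12.0, spring_function=lambda d: 1.0 / d)
        np.testing.assert_allclose(net.spring_constants, 1.0 / net.reference_distances)


class TestRandomNetwork:
    def test_fully_connected_count(self):
        cloud = r.random_cloud(4, seed=0)
        net = r.build_random_network(cloud, seed=1)
        assert net.n_springs == 6
        assert net.cutoff is None

    def test_deterministic(self):
        cloud = r.random_cloud(9, seed=0)
        a = r.build_random_network(cloud, seed=42)
        b = r.build_random_network(cloud, seed=42)
        np.testing.assert_array_equal(a.spring_constants, b.spring_constants)

    def test_uniform_mean(self):
        # 142 beads -> 10011 spring constants
        cloud = r.random_cloud(142, box=60.0, min_separation=1.0, seed=5)
        ks = r.build_random_network(cloud, seed=7).spring_constants
        se = np.sqrt(1.0 / 12.0 / len(ks))
        assert abs(ks.mean() - 0.5) < 3 * se


class TestHessian:
    def test_two_bead_spectrum(self):
        h = r.hessian(r.build_network(two_bead_structure(), 2.0))
        evals = np.linalg.eigvalsh(h.entries)
        np.testing.assert_allclose(evals[:5], 0.0, atol=1e-12)
        assert evals[5] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, cloud_network_factory, seed):
        cloud, net = cloud_network_factory(n=6, seed=seed, cutoff=9.0)
        h = r.hessian(net).entries
        fd = finite_difference_hessian(net, cloud.coords)
        assert np.abs(h - fd).max() < 1e-4

    def test_translation_in_null_space(self, cloud_network_factory):
        _, net = cloud_network_factory(n=8, seed=4)
        h = r.hessian(net).entries
        t = np.tile([1.0, 0.0, 0.0], 8)
        assert np.abs(h @ t).max() < 1e-12

    def test_rotation_conjugates_hessian(self, cloud_network_factory):
        cloud, net = cloud_network_factory(n=7, seed=5)
        evals = np.linalg.eigvalsh(r.hessian(net).entries)
        rot = Rotation.from_euler("zyx", [0.4, -1.1, 2.2]).as_matrix()
        rotated = r.BeadStructure(cloud.labels, cloud.coords @ rot.T, cloud.scheme)
        net2 = r.build_network(rotated, net.cutoff)
        evals2 = np.linalg.eigvalsh(r.hessian(net2).entries)
        np.testing.assert_allclose(evals, evals2, atol=1e-10 * max(evals.max(), 1))

    def test_coincident_beads_rejected(self):
        labels = [r.BeadLabel("A", 1, "S"), r.BeadLabel("A", 2, "S")]
        coords = np.zeros((2, 3))
        s = r.BeadStructure(labels, coords)
        net = r.ElasticNetwork(s, [[0, 1]], [1.0], [1.0], 2.0)
        with pytest.raises(r.DegenerateGeometryError):
            r.hessian(net)


def finite_difference_hessian(net, coords, step=1e-4):
    """Central second differences of the explicit pairwise harmonic energy."""
    n3 = coords.size
    flat = coords.ravel()
    fd = np.zeros((n3, n3))
    for a in range(n3):
        for b in range(a, n3):
            vals = []
            for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                x = flat.copy()
                x[a] += sa * step
                x[b] += sb * step
                vals.append(network_energy(net, x.reshape(-1, 3)))
            fd[a, b] = fd[b, a] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * step**2)
    return fd


class TestZeroModes:
    def test_connected_cloud_has_six(self, cloud_network_factory):
        _, net = cloud_network_factory(n=10, seed=6)
        count, modes = r.zero_modes(r.hessian(net))
        assert count == 6
        assert modes.shape == (30, 6)

    def test_two_components_have_twelve(self):
        a = r.random_cloud(5, box=8.0, seed=1)
        far = a.coords + np.array([100.0, 0.0, 0.0])
        labels = a.labels + [r.BeadLabel("B", i + 1, "S") for i in range(5)]
        s = r.BeadStructure(labels, np.vstack([a.coords, far]))
        count, _ = r.zero_modes(r.hessian(r.build_network(s, 15.0)))
        assert count == 12

    def test_collinear_chain_has_seven(self):
        labels = [r.BeadLabel("A", i + 1, "S") for i in range(3)]
        s = r.BeadStructure(labels, np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]]))
        count, _ = r.zero_modes(r.hessian(r.build_network(s, 10.0)))
        assert count == 7


class TestMinViableCutoff:
    def test_matches_exhaustive_scan(self, duplex):
        result = r.min_viable_cutoff(duplex)
        for cutoff in np.arange(3.0, 31.0, 1.0):
            count, _ = r.zero_modes(r.hessian(r.build_network(duplex, cutoff)))
            if count == 6:
                assert result == pytest.approx(cutoff)
                break
            assert cutoff < result

    def test_collinear_never_viable(self):
        labels = [r.BeadLabel("A", i + 1, "S") for i in range(4)]
        coords = np.array([[2.0 * i, 0.0, 0.0] for i in range(4)])
        s = r.BeadStructure(labels, coords)
        with pytest.raises(r.CutoffNotFoundError):
            r.min_viable_cutoff(s)


class TestCovariance:
    def test_two_bead_single_mode(self):
        h = r.hessian(r.build_network(two_bead_structure(), 2.0))
        model = r.covariance_from_hessian(h)
        nonzero = model.eigenvalues[model.eigenvalues > 1e-12]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pseudoinverse_identities(self, cloud_network_factory, seed):
        _, net = cloud_network_factory(n=9, seed=seed)
        h = r.hessian(net)
        c = r.covariance_from_hessian(h).covariance
        m = h.entries
        scale = np.abs(c).max()
        assert np.abs(c @ m @ c - c).max() < 1e-8 * scale
        assert np.abs(m @ c @ m - m).max() < 1e-8 * np.abs(m).max()

    def test_disconnected_rejected(self):
        a = r.random_cloud(5, box=8.0, seed=1)
        far = a.coords + np.array([100.0, 0.0, 0.0])
        labels = a.labels + [r.BeadLabel("B", i + 1, "S") for i in range(5)]
        s = r.BeadStructure(labels, np.vstack([a.coords, far]))
        with pytest.raises(r.ConnectivityError):
            r.covariance_from_hessian(r.hessian(r.build_network(s, 15.0)))

    def test_spring_scaling_inverts_covariance(self, cloud_network_factory):
        cloud, net = cloud_network_factory(n=8, seed=9)
        c1 = r.covariance_from_hessian(r.hessian(net)).covariance
        scaled = r.ElasticNetwork(cloud, net.pairs, 4.0 * net.spring_constants,
                                  net.reference_distances, net.cutoff)
        c2 = r.covariance_from_hessian(r.hessian(scaled)).covariance
        np.testing.assert_allclose(c2, c1 / 4.0, atol=1e-10 * np.abs(c1).max())

    def test_sampling_reproduces_covariance(self, cloud_network_factory):
        cloud, net = cloud_network_factory(n=4, seed=12)
        model = r.covariance_from_hessian(r.hessian(net))
        ens = r.sample_ensemble(model, cloud, 100_000, amplitude=1.0, seed=3)
        dev = ens.frames.reshape(ens.n_frames, -1) - cloud.coords.ravel()
        emp = dev.T @ dev / ens.n_frames
        c = model.covariance
        n = ens.n_frames
        se = np.sqrt((np.outer(np.diag(c), np.diag(c)) + c**2) / n)
        se = np.maximum(se, 1e-12)
        assert (np.abs(emp - c) / se).max() < 3.0


class TestMsf:
    def test_two_bead_split(self):
        h = r.hessian(r.build_network(two_bead_structure(), 2.0))
        profile = r.msf(r.covariance_from_hessian(h))
        np.testing.assert_allclose(profile.values, [0.25, 0.25])

    def test_sums_to_trace(self, duplex_model):
        profile = r.msf(duplex_model)
        assert profile.values.sum() == pytest.approx(np.trace(duplex_model.covariance))

    def test_palindromic_duplex_symmetry(self, duplex, duplex_model):
        profile = r.msf(duplex_model, duplex.labels)
        index = {(b.chain_id, b.residue_index, b.role): k
                 for k, b in enumerate(duplex.labels)}
        n = 16
        rel_dev = 0.0
        for k, b in enumerate(duplex.labels):
            partner = ("B" if b.chain_id == "A" else "A", n + 1 - b.residue_index, b.role)
            rel_dev = max(rel_dev, abs(profile.values[k] - profile.values[index[partner]]))
        assert rel_dev / profile.values.max() < 1e-10


class TestEffectiveHessian:
    def test_keep_all_is_identity(self, cloud_network_factory):
        _, net = cloud_network_factory(n=6, seed=1)
        h = r.hessian(net)
        out = r.effective_hessian(h, np.arange(6))
        np.testing.assert_array_equal(out.entries, h.entries)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_marginalization_identity(self, cloud_network_factory, seed):
        """Reduced covariance equals the rigid-projected covariance sub-block."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 14))
        cloud, net = cloud_network_factory(n=n, seed=100 + seed)
        h = r.hessian(net)
        keep = np.sort(rng.choice(n, size=int(rng.integers(3, n)), replace=False))
        reduced = r.covariance_from_hessian(r.effective_hessian(h, keep)).covariance
        full = r.covariance_from_hessian(h).covariance
        sub = full[np.ix_(dof_indices(keep), dof_indices(keep))]
        projected = project_out_rigid(sub, cloud.coords[keep])
        assert np.abs(reduced - projected).max() < 1e-8 * np.abs(projected).max()

    def test_tetrahedron_apex_elimination(self):
        """Symbolic Schur elimination of one bead matches the implementation.

        The eliminated bead needs springs in three independent directions
        for its block to be invertible, so the smallest clean case is a
        tetrahedron with the apex integrated out.
        """
        import sympy

        coords = np.array([
            [0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [1.5, 2.6, 0.0], [1.5, 0.9, 2.4],
        ])
        labels = [r.BeadLabel("A", i + 1, "S") for i in range(4)]
        s = r.BeadStructure(labels, coords)
        h = r.hessian(r.build_network(s, 10.0))
        out = r.effective_hessian(h, [0, 1, 2])
        m = sympy.Matrix(h.entries)
        a_idx = list(range(9))
        b_idx = [9, 10, 11]
        ma = m[a_idx, a_idx]
        mb = m[b_idx, b_idx]
        w = m[a_idx, b_idx]
        expected = np.array(ma - w * mb.inv() * w.T, dtype=float)
        np.testing.assert_allclose(out.entries, expected, atol=1e-9)

    def test_chain_middle_bead_block_is_singular(self):
        """A bead held by only two springs cannot be integrated out alone."""
        coords = np.array([[0.0, 0, 0], [2.0, 0.5, 0.3], [4.0, 0, 0]])
        labels = [r.BeadLabel("A", i + 1, "S") for i in range(3)]
        h = r.hessian(r.build_network(r.BeadStructure(labels, coords), 10.0))
        with pytest.raises(r.ReductionError):
            r.effective_hessian(h, [0, 2])

    def test_decoupled_block_raises(self):
        a = r.random_cloud(5, box=8.0, seed=1)
        far = a.coords + np.array([100.0, 0.0, 0.0])
        labels = a.labels + [r.BeadLabel("B", i + 1, "S") for i in range(5)]
        s = r.BeadStructure(labels, np.vstack([a.coords, far]))
        h = r.hessian(r.build_network(s, 15.0))
        with pytest.raises(r.ReductionError):
            r.effective_hessian(h, np.arange(5))


class TestNeighborCount:
    def test_fully_connected(self):
        cloud = r.random_cloud(10, seed=1)
        net = r.build_random_network(cloud, seed=0)
        assert r.neighbor_count(net) == pytest.approx(9.0)

    def test_no_springs(self):
        net = r.build_network(two_bead_structure(), cutoff=0.5)
        assert r.neighbor_count(net) == 0.0

    def test_equals_pair_scan(self):
        cloud = r.random_cloud(25, box=20.0, seed=8)
        net = r.build_network(cloud, 8.0)
        degree = np.zeros(25)
        for i in range(25):
            for j in range(25):
                if i != j and np.linalg.norm(cloud.coords[i] - cloud.coords[j]) < 8.0:
                    degree[i] += 1
        assert r.neighbor_count(net) == pytest.approx(degree.mean())


def test_rigid_mode_basis_spans_hessian_null_space(cloud_network_factory):
    cloud, net = cloud_network_factory(n=9, seed=21)
    h = r.hessian(net)
    basis = rigid_mode_basis(cloud.coords)
    assert basis.shape[1] == 6
    assert np.abs(h.entries @ basis).max() < 1e-9
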