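"""Elastic network assembly, normal modes, and the stiffness indicator."""

import numpy as np
import pytest

from cutofflens import (
    ENMParams,
    build_contact_graph,
    build_hessian,
    compute_modes,
    spectral_stiffness,
)
from cutofflens.enm import CoincidentAtomsError, DegenerateStructureError
from cutofflens.structures import CAStructure, Residue

from conftest import random_point_structure


def points(coords, sid="test"):
    return CAStructure(
        sid, [Residue("A", i + 1, "", tuple(map(float, c)))
              for i, c in enumerate(coords)]
    )


class TestContactGraph:
    def test_two_points_within_cutoff(self):
        g = build_contact_graph(points([[0, 0, 0], [5, 0, 0]]), 10.0)
        assert g.n_edges == 1
        assert g.eq_dist[0] == pytest.approx(5.0)

    def test_boundary_is_inclusive(self):
        g = build_contact_graph(points([[0, 0, 0], [10, 0, 0]]), 10.0)
        assert g.n_edges == 1

    def test_collinear_chain_nearest_neighbours_only(self):
        s = points([[i * 3.8, 0, 0] for i in range(4)])
        g = build_contact_graph(s, 4.0)
        assert set(map(tuple, g.edges)) == {(0, 1), (1, 2), (2, 3)}

    def test_degenerate_structure_raises(self):
        with pytest.raises(DegenerateStructureError):
            build_contact_graph(points([[0, 0, 0]]), 10.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_thresholding(self, seed):
        s = random_point_structure(50, seed, box=20.0)
        cutoff = 6.0 + seed * 0.7
        g = build_contact_graph(s, cutoff)
        c = s.coords()
        d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        expected = {
            (i, j)
            for i in range(len(s)) for j in range(i + 1, len(s))
            if d[i, j] <= cutoff
        }
        assert set(map(tuple, g.edges)) == expected


class TestHessian:
    def test_two_particle_block_structure(self):
        """Dimer on x: the analytic 6×6 has only xx components, ±k2/M."""
        g = build_contact_graph(points([[0, 0, 0], [5, 0, 0]]), 10.0)
        p = ENMParams()
        h = build_hessian(g, p)
        gamma = p.k2 / p.M
        expected = np.zeros((6, 6))
        expected[0, 0] = expected[3, 3] = gamma
        expected[0, 3] = expected[3, 0] = -gamma
        assert np.allclose(h, expected, atol=1e-14)

    def test_row_sums_vanish_per_component(self, globule40):
        h = build_hessian(build_contact_graph(globule40, 12.0))
        n = len(globule40)
        rows = h.reshape(n, 3, n, 3).sum(axis=2)  # sum over partner residues
        assert np.allclose(rows, 0.0, atol=1e-12)

    def test_linear_in_k2(self, globule40):
        g = build_contact_graph(globule40, 12.0)
        h1 = build_hessian(g, ENMParams(k2=5.0))
        h2 = build_hessian(g, ENMParams(k2=10.0))
        assert np.allclose(h2, 2 * h1)

    def test_coincident_atoms_raise(self):
        with pytest.raises(CoincidentAtomsError):
            build_contact_graph(points([[0, 0, 0], [0, 0, 0], [5, 0, 0]]), 10.0)


class TestModes:
    def test_dimer_spectrum_analytic(self):
        """One stretch mode at 2·k2/M, five rigid-body zero modes."""
        p = ENMParams()
        g = build_contact_graph(points([[0, 0, 0], [5, 0, 0]]), 10.0)
        m = compute_modes(build_hessian(g, p))
        assert m.n_zero == 5
        assert m.eigenvalues[-1] == pytest.approx(2 * p.k2 / p.M)
        assert m.eigenvalues[-1] == pytest.approx(1 / 12)

    def test_connected_noncollinear_has_six_zero_modes(self, globule40):
        m = compute_modes(build_hessian(build_contact_graph(globule40, 12.0)))
        assert m.n_zero == 6
        assert np.all(m.eigenvalues >= -1e-9 * m.eigenvalues[-1])

    def test_collinear_chain_transverse_modes_are_floppy(self):
        """Pairwise-distance springs carry no transverse restoring force:
        a collinear N-chain has 2N+1 zero modes (N-1 stretch modes only).
        The familiar 5 rigid-body zeros appear exactly at N=2."""
        s = points([[i * 3.8, 0, 0] for i in range(5)])
        m = compute_modes(build_hessian(build_contact_graph(s, 4.0)))
        assert m.n_zero == 2 * 5 + 1

    def test_disconnected_components_add_zero_modes(self):
        # two far-apart triangles: 2 components -> 12 zero modes
        tri = [[0, 0, 0], [3, 0, 0], [0, 3, 0]]
        far = [[100 + x, y, z] for x, y, z in tri]
        m = compute_modes(build_hessian(build_contact_graph(points(tri + far), 5.0)))
        assert m.n_zero == 12

    def test_spectral_reconstruction(self, globule40):
        h = build_hessian(build_contact_graph(globule40, 12.0))
        m = compute_modes(h)
        rebuilt = (m.eigenvectors * m.eigenvalues) @ m.eigenvectors.T
        assert np.allclose(rebuilt, h, atol=1e-8)

    def test_eigenvectors_orthonormal(self, globule40):
        m = compute_modes(build_hessian(build_contact_graph(globule40, 12.0)))
        gram = m.eigenvectors.T @ m.eigenvectors
        assert np.allclose(gram, np.eye(len(m.eigenvalues)), atol=1e-8)


class TestSpectralStiffness:
    def test_sums_to_number_of_modes(self, globule40):
        m = compute_modes(build_hessian(build_contact_graph(globule40, 12.0)))
        chi = spectral_stiffness(m, ENMParams(n_top_modes=5))
        assert np.all(chi.values >= 0)
        assert chi.values.sum() == pytest.approx(5.0)

    def test_all_internal_modes_by_completeness(self, globule40):
        m = compute_modes(build_hessian(build_contact_graph(globule40, 12.0)))
        n_internal = m.n_modes - m.n_zero
        chi = spectral_stiffness(m, ENMParams(n_top_modes=n_internal))
        assert chi.values.sum() == pytest.approx(n_internal)

    def test_too_many_modes_requested(self):
        g = build_contact_graph(points([[0, 0, 0], [5, 0, 0]]), 10.0)
        m = compute_modes(build_hessian(g))
        with pytest.raises(ValueError, match="n_top_modes"):
            spectral_stiffness(m, ENMParams(n_top_modes=5))

    def test_invariant_under_rigid_motion(self, globule40):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = points(globule40.coords() @ rot.T + np.array([5.0, -3.0, 8.0]))
        chi_a = spectral_stiffness(
            compute_modes(build_hessian(build_contact_graph(globule40, 12.0)))
        )
        chi_b = spectral_stiffness(
            compute_modes(build_hessian(build_contact_graph(moved, 12.0)))
        )
        assert np.allclose(chi_a.values, chi_b.values, atol=1e-8)

    def test_pattern_invariant_under_k2_rescaling(self, globule40):
        g = build_contact_graph(globule40, 12.0)
        chi_a = spectral_stiffness(compute_modes(build_hessian(g, ENMParams(k2=5.0))))
        chi_b = spectral_stiffness(compute_modes(build_hessian(g, ENMParams(k2=50.0))))
        assert np.allclose(chi_a.values, chi_b.values, atol=1e-8)

    def test_hub_hosts_the_stiffness_maximum(self, planted_hub):
        s, _, hub = planted_hub
        m = compute_modes(build_hessian(build_contact_graph(s, 10.0)))
        chi = spectral_stiffness(m)
        assert int(np.argmax(chi.values)) in hub

    def test_inverse_omega2_weighting_keeps_locations(self, planted_hub):
        s, _, hub = planted_hub
        m = compute_modes(build_hessian(build_contact_graph(s, 10.0)))
        chi_w = spectral_stiffness(m, ENMParams(mode_weighting="inverse_omega2"))
        assert int(np.argmax(chi_w.values)) in hub
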