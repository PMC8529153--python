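"""TET10 elasticity: patch tests, closed-form oracles, contact contracts."""

import warnings

import numpy as np
import pytest

import tibfrac as tf
from tibfrac import phantom as ph
from tibfrac.mesh import boundary_faces, facet_nodes, find_interface_pairs
from tibfrac.phantom import VoxelImage
from tibfrac.solver import (ContactSpec, LoadCase, assemble_system,
                            external_work, solve_static, strain_energy)

from .conftest import box_mesh, tag_plane, uniform_materials


def _single_tet_mesh():
    corners = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2.0]])
    edges = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    nodes = np.vstack([corners] + [(corners[i] + corners[j]) / 2
                                   for i, j in edges])
    return tf.LabeledMesh(nodes, np.arange(10)[None, :], np.array([ph.PLATEAU]))


class TestAssembly:
    def test_single_element_symmetric_with_rigid_modes(self):
        mesh = _single_tet_mesh()
        system = assemble_system(mesh, uniform_materials(mesh))
        K = system.K.toarray()
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w) < 1e-8 * w.max()).sum() == 6
        assert np.all(w[6:] > 0)

    def test_nonpositive_materials_rejected(self):
        mesh = _single_tet_mesh()
        mats = uniform_materials(mesh)
        mats.young_modulus[:] = -1.0
        with pytest.raises(ValueError, match="positive definite"):
            assemble_system(mesh, mats)

    def test_patch_test_linear_field_exact(self):
        """TET10 reproduces arbitrary linear displacement fields exactly."""
        mesh = box_mesh(2, 2, 2, h=2.0)
        system = assemble_system(mesh, uniform_materials(mesh))
        A = np.array([[1e-3, 2e-4, -1e-4],
                      [3e-4, -2e-3, 5e-4],
                      [1e-4, 2e-4, 1.5e-3]])
        bf_el, bf_loc = boundary_faces(mesh)
        bnodes = np.unique(facet_nodes(mesh, bf_el, bf_loc))
        system.fix_nodes(bnodes, mesh.nodes[bnodes] @ A.T)
        sol = solve_static(system)
        u_exact = mesh.nodes @ A.T
        assert np.abs(sol.displacements - u_exact).max() < 1e-10
        eps = 0.5 * (A + A.T)
        E, nu = 1000.0, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        sig = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
        assert np.abs(sol.stress_tensors() - sig).max() < 1e-10


def _uniaxial_bar(nx=2, ny=2, nz=10, h=2.0, E=5000.0, p=2.0):
    mesh = box_mesh(nx, ny, nz, h=h)
    system = assemble_system(mesh, uniform_materials(mesh, E=E))
    nod = mesh.nodes
    system.fix_component(np.flatnonzero(nod[:, 2] < 1e-9), 2)
    system.fix_component(np.flatnonzero(nod[:, 0] < 1e-9), 0)
    system.fix_component(np.flatnonzero(nod[:, 1] < 1e-9), 1)
    tag_plane(mesh, "top", 2, float(nz), +1)
    total = system.apply_pressure("top", p, (0, 0, -1))
    return mesh, system, total


class TestClosedForms:
    def test_uniaxial_bar_stress(self):
        """Homogeneous bar under end pressure: sigma = F/A everywhere."""
        p = 2.0
        mesh, system, total = _uniaxial_bar(p=p)
        assert total == pytest.approx(p * 4.0, rel=1e-12)
        sol = solve_static(system)
        assert np.abs(sol.stress[:, 2] + p).max() / p < 1e-8
        assert np.abs(np.delete(sol.stress, 2, axis=1)).max() / p < 1e-8

    def test_two_material_series_bar(self):
        """End displacement F*(L1/E1 + L2/E2)/A for two materials in series."""
        E1, E2, p = 2000.0, 8000.0, 3.0
        mesh = box_mesh(2, 2, 10, h=2.0)
        # nu = 0 and a material boundary on a lattice plane: the 1-D series
        # formula is then exact (Poisson mismatch would couple the segments)
        mats = uniform_materials(mesh, E=E1, nu=0.0)
        upper = mesh.element_centroids()[:, 2] > 6.0
        mats.young_modulus[upper] = E2
        system = assemble_system(mesh, mats)
        nod = mesh.nodes
        system.fix_component(np.flatnonzero(nod[:, 2] < 1e-9), 2)
        system.fix_component(np.flatnonzero(nod[:, 0] < 1e-9), 0)
        system.fix_component(np.flatnonzero(nod[:, 1] < 1e-9), 1)
        tag_plane(mesh, "top", 2, 10.0, +1)
        system.apply_pressure("top", p, (0, 0, -1))
        sol = solve_static(system)
        expected = -p * (6.0 / E1 + 4.0 / E2)
        uz = sol.displacements[np.abs(nod[:, 2] - 10.0) < 1e-9, 2]
        assert np.abs(uz - expected).max() / abs(expected) < 1e-8

    def test_cantilever_tip_deflection(self):
        """Slender cantilever within 3% of Euler-Bernoulli PL^3/3EI."""
        E, P, L, b = 2000.0, 1.0, 40.0, 4.0
        mesh = box_mesh(4, 4, 40, h=2.0)
        system = assemble_system(mesh, uniform_materials(mesh, E=E))
        nod = mesh.nodes
        system.fix_nodes(np.flatnonzero(nod[:, 2] < 1e-9))
        tip = np.flatnonzero(np.abs(nod[:, 2] - L) < 1e-9)
        system.add_nodal_forces(tip, np.array([P / len(tip), 0.0, 0.0]))
        sol = solve_static(system)
        delta = P * L**3 / (3 * E * (b**4 / 12))
        tip_ux = sol.displacements[tip, 0].mean()
        assert abs(tip_ux - delta) / delta < 0.03


class TestConvergence:
    def test_refinement_stability(self):
        """Peak deflection changes < 5% under one uniform refinement."""
        E, P, L = 2000.0, 1.0, 24.0
        peaks = []
        for h in (4.0, 2.0):
            mesh = box_mesh(8, 8, 24, h=h)
            system = assemble_system(mesh, uniform_materials(mesh, E=E))
            nod = mesh.nodes
            system.fix_nodes(np.flatnonzero(nod[:, 2] < 1e-9))
            tip = np.flatnonzero(np.abs(nod[:, 2] - L) < 1e-9)
            system.add_nodal_forces(tip, np.array([P / len(tip), 0.0, 0.0]))
            sol = solve_static(system)
            peaks.append(np.abs(sol.displacements).max())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.05


class TestEquilibrium:
    def test_zero_load_zero_displacement(self):
        mesh, system, _ = _uniaxial_bar()
        system.f[:] = 0.0
        sol = solve_static(system)
        assert np.abs(sol.displacements).max() == 0.0

    def test_reactions_balance_applied_load(self):
        p = 2.0
        mesh, system, total = _uniaxial_bar(p=p)
        sol = solve_static(system)
        assert sol.reactions[:, 2].sum() == pytest.approx(total, rel=1e-8)
        assert sol.residual < 1e-6

    def test_energy_consistency(self):
        mesh, system, _ = _uniaxial_bar()
        sol = solve_static(system)
        W = external_work(system, sol)
        U = strain_energy(system, sol)
        assert abs(W - U) / W < 1e-6

    def test_unconstrained_system_rejected(self):
        mesh = box_mesh(2, 2, 2)
        system = assemble_system(mesh, uniform_materials(mesh))
        with pytest.raises(ValueError, match="singular|supports"):
            solve_static(system)


class TestLoadCase:
    def test_total_force_arithmetic(self):
        lc = LoadCase(body_mass=80.0)
        assert lc.total_force() == pytest.approx(2.59 * 80 * 9.81, rel=1e-12)
        assert lc.total_force() == pytest.approx(2032.6, abs=0.1)
        lat = lc.lateral_fraction * lc.total_force()
        assert lat == pytest.approx(752.1, abs=0.1)
        assert lat / lc.lateral_patch_area == pytest.approx(1.866, abs=2e-3)
        assert lc.medial_fraction == pytest.approx(0.63)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            LoadCase(body_mass=80.0, lateral_fraction=1.2)

    def test_patch_pressure_consistency(self, phantom_mesh, phantom_bundle):
        """Integral of applied tractions equals the prescribed total force."""
        calibrated, _ = tf.calibrate_phantom(phantom_bundle.density_image,
                                             phantom_bundle.insert_spec)
        rho = tf.sample_element_density(phantom_mesh, calibrated,
                                        phantom_bundle.label_image)
        mats = tf.classify_and_assign(rho, phantom_mesh.labels)
        system = assemble_system(phantom_mesh, mats)
        lc = LoadCase(body_mass=80.0)
        tf.apply_loads(system, lc)
        fz = system.f[2::3].sum()
        assert fz == pytest.approx(-lc.total_force(), rel=1e-10)

    def test_patch_area_mismatch_warns(self):
        mesh, system, _ = _uniaxial_bar()
        mesh.boundary_facets["lateral_patch"] = mesh.boundary_facets["top"]
        mesh.boundary_facets["medial_patch"] = mesh.boundary_facets["top"]
        with pytest.warns(UserWarning, match="deviates"):
            tf.apply_loads(system, LoadCase(body_mass=80.0))


def _stacked_blocks(h=2.0):
    vals = np.full((6, 6, 12), ph.PLATEAU, dtype=np.int16)
    vals[:, :, 6:] = ph.FRAG_DEPRESSED
    img = VoxelImage(vals, (1, 1, 1), units="label")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mesh = tf.mesh_domains(img, h)
    return mesh


def _compression_setup(mesh, p=1.5):
    system = assemble_system(mesh, uniform_materials(mesh, E=3000.0))
    nod = mesh.nodes
    system.fix_component(np.flatnonzero(nod[:, 2] < 1e-9), 2)
    system.fix_component(np.flatnonzero(nod[:, 0] < 1e-9), 0)
    system.fix_component(np.flatnonzero(nod[:, 1] < 1e-9), 1)
    tag_plane(mesh, "top", 2, 12.0, +1)
    system.apply_pressure("top", p, (0, 0, -1))
    return system


class TestContact:
    def test_flat_interface_compression_matches_monolithic(self):
        """Closed frictionless contact reproduces the one-body solution."""
        from scipy.spatial import cKDTree
        mesh = _stacked_blocks()
        pairs = find_interface_pairs(mesh, "depressed", cutoff=0.1)
        sol = solve_static(_compression_setup(mesh),
                           ContactSpec([pairs], mode="frictionless"))
        mono = box_mesh(6, 6, 12, h=2.0)
        sol_m = solve_static(_compression_setup(mono))
        _, idx = cKDTree(mono.nodes).query(mesh.nodes)
        err = np.abs(sol.displacements - sol_m.displacements[idx]).max()
        assert err / np.abs(sol_m.displacements).max() < 0.01

    def test_open_gap_matches_no_contact_solve(self):
        """Pairs far beyond any displacement stay inactive and inert."""
        mesh = _stacked_blocks()
        pairs = find_interface_pairs(mesh, "depressed", cutoff=0.1)
        pairs.gaps[:] = 5.0          # artificial wide-open gap
        system = _compression_setup(mesh)
        # support the upper block independently so it cannot float
        upper = np.unique(mesh.elements[mesh.labels == ph.FRAG_DEPRESSED])
        base = upper[np.abs(mesh.nodes[upper, 2] - 6.0) < 1e-9]
        system.fix_component(base, 2)
        sol_c = solve_static(system, ContactSpec([pairs], mode="frictionless"))
        system2 = _compression_setup(mesh)
        system2.fix_component(base, 2)
        sol_n = solve_static(system2)
        assert not sol_c.contact_active["depressed"].any()
        assert np.abs(sol_c.displacements - sol_n.displacements).max() < 1e-12

    def test_contact_kkt_contract(self):
        """Active pairs in compression; inactive pairs within tolerance."""
        mesh = _stacked_blocks()
        pairs = find_interface_pairs(mesh, "depressed", cutoff=0.1)
        spec = ContactSpec([pairs], mode="frictionless")
        sol = solve_static(_compression_setup(mesh), spec)
        g = sol.contact_gaps["depressed"]
        act = sol.contact_active["depressed"]
        assert act.any()
        assert np.all(g[act] <= 1e-12)                      # compression only
        assert np.all(g[~act] >= -spec.penetration_tol)     # no penetration

    def test_penalty_insensitivity(self):
        """A 10x stiffer penalty changes peak displacement by < 1%."""
        mesh = _stacked_blocks()
        pairs = find_interface_pairs(mesh, "depressed", cutoff=0.1)
        sols = [solve_static(_compression_setup(mesh),
                             ContactSpec([pairs], mode="frictionless",
                                         penalty=kp))
                for kp in (3e5, 3e6)]
        peaks = [np.abs(s.displacements).max() for s in sols]
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.01

    def test_bonded_ties_suppress_interface_motion(self):
        mesh = _stacked_blocks()
        pairs = find_interface_pairs(mesh, "depressed", cutoff=0.1)
        sol = solve_static(_compression_setup(mesh),
                           ContactSpec([pairs], mode="bonded", penalty=3e5))
        jump = np.abs(sol.contact_gaps["depressed"] - pairs.gaps).max()
        assert jump < 1e-4
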