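"""Axisymmetric FEM: meshing, solver correctness, and device simulations.

The solver's primary oracle is cross-solver equivalence with the filament
model at mu_r = 1; high-contrast behaviour is verified against the exact
permeable-sphere solution and manufactured solutions on structured meshes.
"""

from dataclasses import replace

import numpy as np
import pytest

import stimcoil as sc
from stimcoil import axisym
from stimcoil.axisym import (REGION_AIR, REGION_COIL, REGION_CORE,
                             MaterialMap)
from stimcoil.errors import SolverError


def _vacuum_materials():
    return MaterialMap(mu_r={REGION_AIR: 1.0, REGION_CORE: 1.0, REGION_COIL: 1.0},
                       current_density={REGION_AIR: 0.0, REGION_CORE: 0.0,
                                        REGION_COIL: 0.0})


class TestMeshing:
    def test_structured_rectangle_counts(self):
        mesh = axisym.rectangle_mesh(0.0, 1.0, -1.0, 1.0, 7, 11)
        assert len(mesh.nodes) == 8 * 12
        assert len(mesh.triangles) == 2 * 7 * 11

    def test_far_boundary_precondition(self, pot):
        with pytest.raises(ValueError):
            axisym.build_mesh(pot, far_boundary_factor=2.0)

    def test_device_mesh_quality_and_labels(self, rod):
        mesh = axisym.build_mesh(rod, 5.0, target_edge=2e-3)
        assert mesh.aspect_ratios().max() <= 10.0
        assert np.all(mesh.nodes[:, 0] >= -1e-12)
        # all three material regions present, coil area close to geometric
        assert set(np.unique(mesh.region)) == {REGION_AIR, REGION_CORE,
                                               REGION_COIL}
        coil_area = mesh.areas()[mesh.region == REGION_COIL].sum()
        geo_area = (rod.coil.outer_radius - rod.coil.inner_radius) * rod.coil.height
        assert coil_area == pytest.approx(geo_area, rel=0.05)

    def test_gmsh_export(self, pot, tmp_path):
        mesh = axisym.build_mesh(pot, 4.0, target_edge=2e-3)
        out = tmp_path / "pot.msh"
        axisym.write_gmsh(mesh, out)
        text = out.read_text()
        assert "$MeshFormat" in text
        assert f"$Nodes\n{len(mesh.nodes)}" in text
        assert f"$Elements\n{len(mesh.triangles)}" in text


class TestSolverCore:
    def test_manufactured_solution_second_order(self):
        # u = r^2 (uniform B_z), J = 0: nonzero Dirichlet drives the interior
        errs = []
        for n in (8, 16, 32):
            mesh = axisym.rectangle_mesh(0.0, 1.0, 0.0, 1.0, n, n)
            bn = mesh.boundary_nodes()
            sol = axisym.solve(mesh, _vacuum_materials(),
                               dirichlet=(bn, mesh.nodes[bn, 0] ** 2))
            errs.append(np.sqrt(np.mean((sol.u - mesh.nodes[:, 0] ** 2) ** 2)))
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_stiffness_symmetric_positive_definite(self):
        mesh = axisym.rectangle_mesh(0.0, 1.0, 0.0, 1.0, 6, 6)
        K, _ = axisym.assemble(mesh, _vacuum_materials())
        free = np.setdiff1d(np.arange(len(mesh.nodes)), mesh.boundary_nodes())
        Kff = K[free][:, free].toarray()
        assert np.allclose(Kff, Kff.T, rtol=1e-12)
        assert np.linalg.eigvalsh(Kff).min() > 0

    def test_no_dirichlet_is_singular(self):
        mesh = axisym.rectangle_mesh(0.0, 1.0, 0.0, 1.0, 4, 4)
        with pytest.raises(SolverError):
            axisym.solve(mesh, _vacuum_materials(),
                         dirichlet=(np.array([], dtype=int), np.array([])))

    def test_zero_current_gives_zero_field(self, air_coil):
        mesh = axisym.build_mesh(air_coil, 4.0, target_edge=2e-3)
        mats = axisym.materials_for(air_coil, sc.DriveCondition(15.0, "off"), mesh)
        sol = axisym.solve(mesh, mats)
        assert np.all(sol.u == 0.0)

    def test_solution_linear_in_current(self, air_coil):
        mesh = axisym.build_mesh(air_coil, 4.0, target_edge=2e-3)
        s1 = axisym.solve(mesh, axisym.materials_for(
            air_coil, sc.DriveCondition(1.0), mesh))
        s15 = axisym.solve(mesh, axisym.materials_for(
            air_coil, sc.DriveCondition(15.0), mesh))
        assert np.allclose(15 * s1.u, s15.u, rtol=1e-9, atol=1e-16)

    def test_stored_energy_positive(self, air_coil, drive15):
        mesh = axisym.build_mesh(air_coil, 4.0, target_edge=2e-3)
        sol = axisym.solve(mesh, axisym.materials_for(air_coil, drive15, mesh))
        assert sol.stored_energy() > 0

    def test_materials_require_driven_coil(self, air_coil, drive15):
        mesh = axisym.build_mesh(air_coil, 4.0, target_edge=2e-3)
        mesh.region[mesh.region == REGION_COIL] = REGION_AIR
        with pytest.raises(SolverError):
            axisym.materials_for(air_coil, drive15, mesh)


class TestCrossSolverOracle:
    def test_air_core_matches_filament_model(self, air_coil, drive15):
        """mu_r = 1 FEM against Biot-Savart on axis, >= 2 mm from windings."""
        mesh = axisym.build_mesh(air_coil, 5.0, target_edge=0.8e-3)
        sol = axisym.solve(mesh, axisym.materials_for(air_coil, drive15, mesh))
        z = np.arange(0.0, 0.0305, 2.5e-3)
        fem = np.abs(sol.b_axis(z, r_probe=1.0e-3))
        ref = sc.line_scan(air_coil, drive15, (0, 0, 0), (0, 0, 1),
                           np.maximum(z, 1e-9)).magnitude
        assert np.abs(fem / ref - 1).max() < 0.02

    def test_rod_with_unit_permeability_is_bare_coil(self, rod, drive15):
        pos = axisym.default_scan_positions(1.0, 30.0)
        scan = axisym.simulate_rod_core(rod, drive15, positions=pos,
                                        mu_r_override=1.0)
        ref = sc.line_scan(rod.coil, drive15, (0, 0, 0), (0, 0, 1),
                           pos + rod.core_length / 2).magnitude
        assert np.abs(scan.magnitude / ref - 1).max() < 0.02


class TestPermeableSphereOracle:
    def test_high_contrast_against_exact_solution(self):
        """Sphere (mu_r=1000) in a uniform field: dipole response exact."""
        B0, a, mu = 0.01, 0.02, 1000.0
        mesh = axisym.rectangle_mesh(0, 0.2, -0.2, 0.2, 100, 200)
        cent = mesh.centroids()
        mesh.region[cent[:, 0] ** 2 + cent[:, 1] ** 2 <= a ** 2] = REGION_CORE
        mats = MaterialMap(mu_r={REGION_AIR: 1.0, REGION_CORE: mu,
                                 REGION_COIL: 1.0},
                          current_density={REGION_AIR: 0.0, REGION_CORE: 0.0,
                                           REGION_COIL: 0.0})
        bn = mesh.boundary_nodes()
        sol = axisym.solve(mesh, mats,
                           dirichlet=(bn, B0 / 2 * mesh.nodes[bn, 0] ** 2))
        inside = cent[:, 0] ** 2 + cent[:, 1] ** 2 < (a / 2.5) ** 2
        ratio = sol.b_elements[inside, 1].mean() / B0
        assert ratio == pytest.approx(3 * mu / (mu + 2), rel=0.05)
        on_axis = (np.abs(cent[:, 1] - 2 * a) < 2e-3) & (cent[:, 0] < 4e-3)
        far = sol.b_elements[on_axis, 1].mean() / B0
        assert far == pytest.approx(1 + 2 * (mu - 1) / (mu + 2) / 8, rel=0.02)


class TestDeviceSimulations:
    def test_rod_scan_decays_monotonically(self, rod_solution):
        assert np.all(np.diff(rod_solution.magnitude) < 0)
        assert rod_solution.magnitude[0] > 0.1  # strong near-tip field, T

    def test_pot_zero_current_gives_zero_scan(self, pot):
        scan = axisym.simulate_pot_core(pot, sc.DriveCondition(0.0),
                                        target_edge=1.5e-3)
        assert np.allclose(scan.magnitude, 0.0, atol=1e-15)

    def test_pot_linear_in_ampere_turns(self, pot, drive15):
        mesh = axisym.build_mesh(pot, 4.0, target_edge=1.2e-3)
        base = axisym.simulate_pot_core(pot, drive15, mesh=mesh)
        doubled_dev = replace(pot, coil=replace(pot.coil, turns=2 * pot.coil.turns))
        doubled = axisym.simulate_pot_core(doubled_dev, drive15, mesh=mesh)
        assert np.allclose(doubled.magnitude, 2 * base.magnitude, rtol=1e-9)

    def test_boundary_independence(self, pot, drive15):
        near = axisym.simulate_pot_core(pot, drive15, far_boundary_factor=5.0)
        far = axisym.simulate_pot_core(pot, drive15, far_boundary_factor=10.0)
        v5, v10 = near.value_at(0.010), far.value_at(0.010)
        assert abs(v5 - v10) / v10 < 0.01

    def test_permeability_sensitivity_band(self, pot, drive15):
        lo, nom, hi = axisym.permeability_sensitivity(pot, drive15, 0.3,
                                                      target_edge=1.2e-3)
        assert np.all(lo.magnitude <= nom.magnitude + 1e-12)
        assert np.all(nom.magnitude <= hi.magnitude + 1e-12)
        # flux is geometry-limited at mu_r ~ 1e4: the +-30% band barely moves
        spread = (hi.value_at(0.010) - lo.value_at(0.010)) / nom.value_at(0.010)
        assert 0 <= spread < 0.05

    def test_zero_tolerance_band_is_degenerate(self, pot, drive15):
        lo, nom, hi = axisym.permeability_sensitivity(pot, drive15, 0.0,
                                                      target_edge=1.5e-3)
        assert np.allclose(lo.magnitude, nom.magnitude)
        assert np.allclose(nom.magnitude, hi.magnitude)
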