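"""LPBE solver physics: dielectric maps, closed-form oracles, linearity."""

import numpy as np
import pytest

import mifscan as m
from mifscan.electrostatics import debye_boundary, spread_charges
from mifscan.errors import GeometryError, SolverError
from mifscan.structures import Atom, Structure

from conftest import single_atom_structure


def radial_errors(field, solvent, r_lo, r_hi, exact_fn):
    """Max relative error of a spherically-symmetric field vs a closed form."""
    pts = field.grid.points()
    r = np.linalg.norm(pts, axis=1)
    sel = (r >= r_lo) & (r <= r_hi)
    exact = exact_fn(r[sel])
    return np.max(np.abs(field.values.ravel()[sel] - exact) / np.abs(exact))


class TestDielectricMaps:
    def test_far_field_is_solvent_and_interior_is_protein(self):
        s = single_atom_structure(radius=2.0)
        g = m.GridSpec((-16, -16, -16), 1.0, (33, 33, 33))
        solvent = m.SolventSpec()
        eps, ion = m.build_dielectric_maps(s, g, solvent)
        center = tuple(n // 2 for n in g.shape)
        assert eps.values[center] == solvent.eps_interior
        # a point 15 Å out is bulk solvent
        assert eps.values[center[0] + 15, center[1], center[2]] == 78.0
        # re-opened interior is approximately the 2 Å atom sphere
        interior = eps.values == solvent.eps_interior
        d = np.linalg.norm(g.points(), axis=1).reshape(g.shape)
        assert interior[d <= 1.0].all()
        assert not interior[d > 4.0].any()

    def test_zero_probe_interior_is_union_of_spheres(self):
        backbone = m.make_backbone(6, seed=0)
        g = m.GridSpec.auto(backbone.coords, spacing=1.0, shape=None)
        solvent = m.SolventSpec(surface_probe_radius=0.0)
        eps, _ = m.build_dielectric_maps(backbone, g, solvent)
        interior = eps.values == solvent.eps_interior
        # brute-force point-in-sphere oracle
        pts = g.points()
        expected = np.zeros(len(pts), dtype=bool)
        for pos, r in zip(backbone.coords, backbone.radii):
            expected |= np.linalg.norm(pts - pos, axis=1) < r
        assert np.array_equal(interior.ravel(), expected)

    def test_ion_exclusion_shell(self):
        s = single_atom_structure(radius=2.0)
        g = m.GridSpec((-16, -16, -16), 1.0, (33, 33, 33))
        solvent = m.SolventSpec(surface_probe_radius=1.4, stern_layer=2.0)
        _, ion = m.build_dielectric_maps(s, g, solvent)
        d = np.linalg.norm(g.points(), axis=1).reshape(g.shape)
        cutoff = 2.0 + 1.4 + 2.0  # radius + probe + stern
        assert (ion.values[d < cutoff - 1e-9] == 0.0).all()
        assert (ion.values[d > cutoff + 1e-9] == 1.0).all()

    def test_structure_hugging_box_edge_rejected(self):
        s = single_atom_structure(position=(15.5, 0.0, 0.0), radius=2.0)
        g = m.GridSpec((-16, -16, -16), 1.0, (33, 33, 33))
        with pytest.raises(GeometryError):
            m.build_dielectric_maps(s, g, m.SolventSpec())


class TestChargeSpreading:
    def test_on_node_charge_stays_on_node(self):
        s = single_atom_structure(position=(0.0, 0.0, 0.0))
        g = m.GridSpec((-8, -8, -8), 1.0, (17, 17, 17))
        q = spread_charges(s, g)
        assert q[8, 8, 8] == pytest.approx(1.0)
        assert q.sum() == pytest.approx(1.0)

    def test_off_node_charge_conserved_trilinearly(self):
        s = single_atom_structure(position=(0.25, 0.5, -0.75))
        g = m.GridSpec((-8, -8, -8), 1.0, (17, 17, 17))
        q = spread_charges(s, g)
        assert q.sum() == pytest.approx(1.0)
        assert (q != 0).sum() == 8


class TestSolverOracles:
    def test_zero_charges_give_zero_field(self):
        s = m.make_backbone(6, seed=0)  # all charges zero
        g = m.GridSpec.auto(s.coords, spacing=1.0, shape=None)
        f = m.solve_lpbe(s, g, m.SolventSpec())
        assert np.all(f.values == 0.0)

    def test_coulomb_limit(self, point_charge, box65, uniform_water):
        """Uniform ε=78, no salt: FD potential matches q·C/(ε r) in kT/e."""
        f = m.solve_lpbe(point_charge, box65, uniform_water)
        C = uniform_water.bjerrum_vacuum
        err = radial_errors(f, uniform_water, 10.0, 20.0, lambda r: C / (78.0 * r))
        assert err < 0.05

    def test_debye_hueckel_limit(self, box65):
        """50 mM salt, no exclusion layer: matches q·C·exp(−κr)/(ε r)."""
        s = single_atom_structure(radius=0.1)
        solvent = m.SolventSpec(
            eps_interior=78.0,
            eps_exterior=78.0,
            ionic_strength=0.050,
            surface_probe_radius=0.0,
            stern_layer=0.0,
        )
        f = m.solve_lpbe(s, box65, solvent)
        C, kap = solvent.bjerrum_vacuum, solvent.kappa
        err = radial_errors(
            f, solvent, 10.0, 20.0, lambda r: C * np.exp(-kap * r) / (78.0 * r)
        )
        assert err < 0.05

    def test_grid_refinement_tightens_coulomb_error(
        self, point_charge, uniform_water
    ):
        """Halving the spacing drops the Coulomb error bound from 5% to ≤3%."""
        errs = {}
        for spacing, n in ((1.5, 33), (0.75, 65)):
            g = m.GridSpec((-24.0,) * 3, spacing, (n,) * 3)
            f = m.solve_lpbe(point_charge, g, uniform_water)
            C = uniform_water.bjerrum_vacuum
            errs[spacing] = radial_errors(
                f, uniform_water, 10.0, 16.0, lambda r: C / (78.0 * r)
            )
        assert errs[1.5] < 0.05
        assert errs[0.75] < 0.03
        assert errs[0.75] < errs[1.5]

    def test_boundary_faces_carry_analytic_debye_values(self, charge_flip_pair):
        s = charge_flip_pair[0]
        g = m.GridSpec.auto(s.coords, spacing=1.5, shape=None)
        solvent = m.SolventSpec()
        f = m.solve_lpbe(s, g, solvent, tol=1e-3)
        bc = debye_boundary(s, g, solvent)
        for face in (
            (0, slice(None), slice(None)),
            (-1, slice(None), slice(None)),
            (slice(None), 0, slice(None)),
            (slice(None), slice(None), -1),
        ):
            assert np.array_equal(f.values[face], bc[face])


@pytest.fixture(scope="module")
def two_atom_setup():
    def make(q1, q2):
        atoms = [
            Atom((-3.0, 0, 0), q1, 1.5, "CA", 0, "GLY", True),
            Atom((3.0, 0, 0), q2, 1.5, "CA", 1, "GLY", True),
        ]
        return Structure(atoms, label=f"q{q1}_{q2}")

    grid = m.GridSpec((-16, -16, -16), 1.0, (33, 33, 33))
    return make, grid, m.SolventSpec()


class TestLinearity:
    def test_negation_flips_field_exactly(self, two_atom_setup):
        make, grid, solvent = two_atom_setup
        f = m.solve_lpbe(make(1.0, -0.5), grid, solvent)
        f_neg = m.solve_lpbe(make(-1.0, 0.5), grid, solvent)
        assert np.array_equal(f_neg.values, -f.values)

    def test_scaling_by_two(self, two_atom_setup):
        make, grid, solvent = two_atom_setup
        f1 = m.solve_lpbe(make(1.0, -0.5), grid, solvent, tol=1e-6)
        f2 = m.solve_lpbe(make(2.0, -1.0), grid, solvent, tol=1e-6)
        scale = np.abs(f1.values).max()
        assert np.abs(f2.values - 2.0 * f1.values).max() <= 1e-5 * scale

    def test_superposition_of_two_charges(self, two_atom_setup):
        make, grid, solvent = two_atom_setup
        fa = m.solve_lpbe(make(1.0, 0.0), grid, solvent, tol=1e-6)
        fb = m.solve_lpbe(make(0.0, -0.5), grid, solvent, tol=1e-6)
        fab = m.solve_lpbe(make(1.0, -0.5), grid, solvent, tol=1e-6)
        scale = np.abs(fab.values).max()
        assert np.abs(fab.values - (fa.values + fb.values)).max() <= 1e-5 * scale


class TestSolverControl:
    def test_divergence_raises_with_trace(self, point_charge):
        g = m.GridSpec((-8, -8, -8), 1.0, (17, 17, 17))
        with pytest.raises(SolverError) as exc:
            m.solve_lpbe(
                point_charge,
                g,
                m.SolventSpec(eps_interior=78.0, eps_exterior=78.0),
                omega=2.05,  # over-relaxation beyond the stable range
                max_iter=5000,
            )
        assert len(exc.value.trace) >= 10

    def test_bad_tolerance_rejected(self, point_charge, box65):
        with pytest.raises(ValueError):
            m.solve_lpbe(point_charge, box65, m.SolventSpec(), tol=2.0)

    def test_atom_outside_grid_rejected(self):
        s = single_atom_structure(position=(100.0, 0, 0))
        g = m.GridSpec((-8, -8, -8), 1.0, (17, 17, 17))
        with pytest.raises(GeometryError):
            m.solve_lpbe(s, g, m.SolventSpec())
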