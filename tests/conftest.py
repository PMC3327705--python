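"""Shared fixtures: small synthetic structures, grids and solved fields.

Expensive LPBE solves are session-scoped so several tests can share them.
"""

import numpy as np
import pytest

import mifscan as m
from mifscan.structures import Atom, Structure


def single_atom_structure(charge=1.0, radius=1.0, position=(0.0, 0.0, 0.0)):
    atom = Atom(
        position=position,
        charge=charge,
        radius=radius,
        name="CA",
        residue_index=0,
        residue_name="GLY",
        is_calpha=True,
    )
    return Structure([atom], label="point")


@pytest.fixture(scope="session")
def point_charge():
    return single_atom_structure()


@pytest.fixture(scope="session")
def box65():
    """65^3 grid at 1 Å centered on the origin (desk-scale production box)."""
    return m.GridSpec(origin=(-32.0, -32.0, -32.0), spacing=1.0, shape=(65, 65, 65))


@pytest.fixture(scope="session")
def uniform_water():
    """Uniform ε=78 with no ions or exclusion layers: the Coulomb regime."""
    return m.SolventSpec(
        eps_interior=78.0,
        eps_exterior=78.0,
        ionic_strength=0.0,
        surface_probe_radius=0.0,
        stern_layer=0.0,
    )


@pytest.fixture(scope="session")
def small_backbone():
    return m.make_backbone(10, seed=1)


def _flip_one_charge_pair():
    """Two pseudo-proteins with identical geometry differing by one flipped
    charge at residue 2; the chain is long enough that residues near the far
    end are > 25 Å from the perturbation."""
    backbone = m.make_backbone(24, seed=3)
    pattern = [(2, 1.0), (8, -1.0), (14, 1.0), (20, -1.0)]
    a = m.decorate_charges(backbone, pattern)
    a.label = "wild"
    flipped = [(2, -1.0)] + pattern[1:]
    b = m.decorate_charges(backbone, flipped)
    b.label = "mutant"
    return a, b


@pytest.fixture(scope="session")
def charge_flip_pair():
    return _flip_one_charge_pair()


@pytest.fixture(scope="session")
def pair_grid(charge_flip_pair):
    """65^3 grid at 1 Å auto-centered on the flipped-charge pair."""
    return m.GridSpec.auto(charge_flip_pair[0].coords, spacing=1.0, shape=(65, 65, 65))


@pytest.fixture(scope="session")
def charge_flip_fields(charge_flip_pair, pair_grid):
    """Electrostatic fields of the flipped-charge pair on the shared grid."""
    solvent = m.SolventSpec()
    return tuple(m.solve_lpbe(s, pair_grid, solvent) for s in charge_flip_pair)


@pytest.fixture()
def random_field_pair():
    """Two random fields plus a random nonempty mask on a small grid."""
    rng = np.random.default_rng(7)
    grid = m.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, shape=(10, 10, 10))
    a = m.ScalarField(grid, rng.normal(size=grid.shape), "kT/e", "electrostatic")
    b = m.ScalarField(grid, rng.normal(size=grid.shape), "kT/e", "electrostatic")
    mask = m.SkinMask(grid, rng.random(grid.shape) < 0.4)
    return a, b, mask
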