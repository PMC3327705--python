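"""Hydrophobic interaction fields with a DRY-style probe.

At every grid point the energy is assembled as

    E = Σ_atoms E_LJ  +  WENT  −  Σ_polar E_HB,

a Lennard-Jones attraction to the protein surface, a constant water-entropy
reward inside the first solvation shell, and a hydrogen-bond term that
rewards water (and therefore penalizes the hydrophobic probe) near donors
and acceptors. Grid points where the total is positive — highly polar
regions — are reset to zero, as are points inside atom cores, so the field
is everywhere ≤ 0 and similarity indices simply see no signal where water
out-competes an apolar probe.

The parameterization here is an openly documented surrogate: a 12-6 LJ with
per-class (apolar C/S vs polar N/O) well depths, a constant entropy reward
in the first shell, and a quartic-switched H-bond penalty. It reproduces the
qualitative shape of hydrophobic molecular interaction fields — apolar
patches carry negative shells, polar patches clamp to zero — which is what
field-similarity comparison needs; absolute energies are not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ClassificationError
from .grid import GridSpec, ScalarField, surface_distance_field
from .structures import Structure

#: element → probe-interaction class
ELEMENT_CLASS = {
    "C": "apolar",
    "S": "apolar",
    "N": "polar",
    "O": "polar",
    "P": "polar",
    "H": "apolar",
}


def classify_atom(atom, strict: bool = True) -> str:
    """Apolar vs polar (H-bond donor/acceptor) class from the element guess."""
    cls = ELEMENT_CLASS.get(atom.element)
    if cls is None:
        if strict:
            raise ClassificationError(
                f"cannot classify atom {atom.name!r} (element {atom.element!r}) "
                "as apolar or polar; use strict=False to default to apolar"
            )
        return "apolar"
    return cls


@dataclass(frozen=True)
class HydrophobicParams:
    """Surrogate DRY-probe parameters (kcal/mol, Å).

    lj_epsilon/lj_sigma: per-class 12-6 parameters for the probe-atom
    attraction; entropy_reward: constant favorable term applied inside the
    first solvation shell (shell_width beyond the atom surface);
    hbond_penalty_strength: magnitude of the water H-bond energy near each
    donor/acceptor, switched off quartically at hbond_cutoff; lj_cutoff
    truncates the LJ sum (keeps the field local to each atom).
    """

    lj_epsilon: dict = dc_field(
        default_factory=lambda: {"apolar": 0.15, "polar": 0.10}
    )
    lj_sigma: dict = dc_field(default_factory=lambda: {"apolar": 3.4, "polar": 3.1})
    entropy_reward: float = -0.85
    shell_width: float = 3.0
    hbond_penalty_strength: float = 2.5
    hbond_cutoff: float = 4.0
    lj_cutoff: float = 8.0
    spacing: float = 0.5

    def __post_init__(self):
        if min(self.hbond_cutoff, self.lj_cutoff, self.shell_width, self.spacing) <= 0:
            raise ValueError("cutoffs, shell width and spacing must be positive")
        if self.hbond_penalty_strength < 0:
            raise ValueError("hbond_penalty_strength must be >= 0")
        if self.entropy_reward > 0:
            raise ValueError("entropy_reward is a favorable term and must be <= 0")


def probe_energy(
    point: np.ndarray, structure: Structure, params: HydrophobicParams,
    strict: bool = True,
) -> float:
    """Direct (unclamped) evaluation of the probe energy at one point.

    Reference implementation of the same formula used by :func:`dry_field`;
    kept separate so grid values can be checked pointwise.
    """
    point = np.asarray(point, dtype=float)
    e = 0.0
    in_shell = False
    for atom in structure.atoms:
        cls = classify_atom(atom, strict=strict)
        d = float(np.linalg.norm(point - atom.position))
        sd = d - atom.radius
        if sd <= params.shell_width:
            in_shell = True
        if d <= params.lj_cutoff:
            sr6 = (params.lj_sigma[cls] / max(d, 0.7)) ** 6
            e += 4.0 * params.lj_epsilon[cls] * (sr6 * sr6 - sr6)
        if cls == "polar" and d < params.hbond_cutoff:
            s = (1.0 - (d / params.hbond_cutoff) ** 2) ** 2
            e += params.hbond_penalty_strength * s
    if in_shell:
        e += params.entropy_reward
    return e


def dry_field(
    structure: Structure,
    grid: GridSpec | None = None,
    params: HydrophobicParams | None = None,
    strict: bool = True,
) -> ScalarField:
    """Hydrophobic interaction field of ``structure`` on ``grid``.

    Values are in kcal/mol and are ≤ 0 everywhere: positive (polar-region)
    energies and atom-core points are reset to zero.
    """
    if params is None:
        params = HydrophobicParams()
    if grid is None:
        grid = GridSpec.auto(structure.coords, spacing=params.spacing, shape=None)

    classes = [classify_atom(a, strict=strict) for a in structure.atoms]

    ax, ay, az = grid.axes()
    # per-axis offsets reused for every atom: d² = dx² + dy² + dz² broadcast
    energy = np.zeros(grid.shape)
    for atom, cls in zip(structure.atoms, classes):
        dx = ax - atom.position[0]
        dy = ay - atom.position[1]
        dz = az - atom.position[2]
        d2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        d = np.sqrt(d2)
        lj_mask = d <= params.lj_cutoff
        if lj_mask.any():
            dd = np.maximum(d[lj_mask], 0.7)
            sr6 = (params.lj_sigma[cls] / dd) ** 6
            energy[lj_mask] += 4.0 * params.lj_epsilon[cls] * (sr6 * sr6 - sr6)
        if cls == "polar":
            hb_mask = d < params.hbond_cutoff
            if hb_mask.any():
                s = (1.0 - (d[hb_mask] / params.hbond_cutoff) ** 2) ** 2
                energy[hb_mask] += params.hbond_penalty_strength * s

    dsurf = surface_distance_field(structure.coords, structure.radii, grid)
    energy[dsurf <= params.shell_width] += params.entropy_reward

    energy[dsurf < 0] = 0.0  # atom cores carry no probe energy
    np.minimum(energy, 0.0, out=energy)  # polar regions reset to zero
    return ScalarField(grid, energy, units="kcal/mol", kind="hydrophobic")
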