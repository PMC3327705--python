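"""Charged protein structures: PQR/PDB readers, PQR writer, residue bookkeeping.

The canonical input is PQR (coordinates + per-atom charge + radius, APBS
whitespace dialect). PDB is accepted as a convenience and requires an
explicit :class:`ParameterRuleset` that assigns charges and radii — the field
calculators themselves never see a force field. Chain identifiers are
ignored; only the first model of multi-model files is read.

Residues are renumbered 0..R−1 in file order, and every residue must carry
exactly one CA atom: the regional conservation scan is anchored on Cα
positions, so a structure without them cannot be scanned and is rejected at
read time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .errors import ParseError, StructureError


@dataclass
class Atom:
    """One atom: position (Å), partial charge (e), radius (Å) and bookkeeping."""

    position: np.ndarray
    charge: float
    radius: float
    name: str
    residue_index: int
    residue_name: str
    is_calpha: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.charge = float(self.charge)
        self.radius = float(self.radius)
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: non-finite position")
        if not math.isfinite(self.charge):
            raise StructureError(f"atom {self.name}: non-finite charge")
        if not self.radius > 0:
            raise StructureError(
                f"atom {self.name}: radius must be > 0, got {self.radius}"
            )

    @property
    def element(self) -> str:
        """Crude element guess: first alphabetic character of the atom name."""
        for ch in self.name:
            if ch.isalpha():
                return ch.upper()
        return "X"


@dataclass
class Structure:
    """An ordered collection of atoms with contiguous residue numbering."""

    atoms: list[Atom]
    label: str = ""
    conformation_tag: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise StructureError(f"structure {self.label!r} has no atoms")
        indices = sorted({a.residue_index for a in self.atoms})
        if indices != list(range(len(indices))):
            raise StructureError(
                f"structure {self.label!r}: residue indices are not a "
                f"contiguous 0..R-1 set: {indices[:10]}..."
            )
        missing, multiple = [], []
        for r in indices:
            n_ca = sum(1 for a in self.atoms if a.residue_index == r and a.is_calpha)
            if n_ca == 0:
                missing.append(r)
            elif n_ca > 1:
                multiple.append(r)
        if missing or multiple:
            raise StructureError(
                f"structure {self.label!r}: residues without a CA atom: {missing}; "
                f"residues with multiple CA atoms: {multiple}"
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return max(a.residue_index for a in self.atoms) + 1

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def calpha_positions(self) -> np.ndarray:
        """(R, 3) array of Cα coordinates ordered by residue index."""
        out = np.empty((self.n_residues, 3))
        for a in self.atoms:
            if a.is_calpha:
                out[a.residue_index] = a.position
        return out

    def translated(self, shift) -> "Structure":
        shift = np.asarray(shift, dtype=float).reshape(3)
        atoms = [replace(a, position=a.position + shift) for a in self.atoms]
        return Structure(atoms, label=self.label, conformation_tag=self.conformation_tag)

    def with_charges_scaled(self, factor: float) -> "Structure":
        atoms = [replace(a, charge=a.charge * factor) for a in self.atoms]
        return Structure(atoms, label=self.label, conformation_tag=self.conformation_tag)


# --------------------------------------------------------------------- rulesets

#: Bondi-like van der Waals radii per element, Å.
DEFAULT_ELEMENT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70


@dataclass
class ParameterRuleset:
    """(residue_name, atom_name) → (charge, radius), with element fallback.

    Lookups that miss the table fall through to zero charge and the element
    default radius; the caller counts these as warnings.
    """

    charges: dict = dc_field(default_factory=dict)
    element_radii: dict = dc_field(default_factory=lambda: dict(DEFAULT_ELEMENT_RADII))
    default_radius: float = DEFAULT_RADIUS

    def __post_init__(self):
        for key, (q, r) in self.charges.items():
            if r is not None and r <= 0:
                raise ValueError(f"ruleset entry {key}: radius must be positive")
        for el, r in self.element_radii.items():
            if r <= 0:
                raise ValueError(f"element {el}: radius must be positive")

    def lookup(self, residue_name: str, atom_name: str, element: str = ""):
        """Return (charge, radius, resolved). ``resolved`` False on fallback."""
        key = (residue_name.upper(), atom_name.upper())
        if key in self.charges:
            q, r = self.charges[key]
            if r is None:
                r = self.element_radii.get(element.upper(), self.default_radius)
            return q, r, True
        r = self.element_radii.get(element.upper())
        if r is None:
            return 0.0, self.default_radius, False
        return 0.0, r, True


def default_ruleset() -> ParameterRuleset:
    """Minimal formal-charge ruleset.

    Unit formal charges are spread over the terminal atoms of charged side
    chains (Asp/Glu carboxylate oxygens −0.5 each, Lys NZ +1, Arg NH1/NH2
    +0.5 each, His neutral); the backbone is neutral. This reproduces the
    sign structure of surface potentials, which is what comparative
    similarity indices respond to; it makes no claim about absolute energies.
    """
    charges = {
        ("ASP", "OD1"): (-0.5, None),
        ("ASP", "OD2"): (-0.5, None),
        ("GLU", "OE1"): (-0.5, None),
        ("GLU", "OE2"): (-0.5, None),
        ("LYS", "NZ"): (1.0, None),
        ("ARG", "NH1"): (0.5, None),
        ("ARG", "NH2"): (0.5, None),
    }
    return ParameterRuleset(charges=charges)


def load_ruleset(path) -> ParameterRuleset:
    """Read a ruleset from a key-value text file.

    Lines: ``RES ATOM charge radius`` (radius ``*`` = element default),
    ``element X radius``, ``default radius``; ``#`` comments.
    """
    charges = {}
    element_radii = dict(DEFAULT_ELEMENT_RADII)
    default_radius = DEFAULT_RADIUS
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            try:
                if toks[0].lower() == "element" and len(toks) == 3:
                    element_radii[toks[1].upper()] = float(toks[2])
                elif toks[0].lower() == "default" and len(toks) == 2:
                    default_radius = float(toks[1])
                elif len(toks) == 4:
                    radius = None if toks[3] == "*" else float(toks[3])
                    charges[(toks[0].upper(), toks[1].upper())] = (float(toks[2]), radius)
                else:
                    raise ValueError("unrecognized ruleset line")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ParameterRuleset(charges, element_radii, default_radius)


# --------------------------------------------------------------------- PQR I/O


def read_pqr(path, label: str | None = None) -> Structure:
    """Read a whitespace-delimited PQR file (APBS dialect).

    Residues are renumbered 0-based contiguously in file order; the Cα flag
    is set from atom name "CA". Raises :class:`ParseError` naming the line on
    malformed records and :class:`StructureError` if any residue lacks a CA.
    """
    atoms = []
    last_resid_key = None
    residue_index = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            toks = raw.split()
            # with or without a chain-id column: x y z q r are the last five
            if len(toks) not in (10, 11):
                raise ParseError(
                    f"{path}:{lineno}: expected 10 or 11 whitespace-delimited "
                    f"fields in PQR record, got {len(toks)}"
                )
            try:
                name = toks[2]
                resname = toks[3]
                resid = toks[-6]
                x, y, z, q, r = (float(t) for t in toks[-5:])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed PQR record") from exc
            if resid != last_resid_key:
                residue_index += 1
                last_resid_key = resid
            atoms.append(
                Atom(
                    position=(x, y, z),
                    charge=q,
                    radius=r,
                    name=name,
                    residue_index=residue_index,
                    residue_name=resname,
                    is_calpha=(name.upper() == "CA"),
                )
            )
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if label is None:
        import os

        label = os.path.splitext(os.path.basename(str(path)))[0]
    return Structure(atoms, label=label)


def write_pqr(structure: Structure, path) -> None:
    """Write an APBS-dialect PQR; round-trips numeric fields to better than 1e-3."""
    with open(path, "w") as fh:
        fh.write(f"REMARK mifscan structure label={structure.label}\n")
        for i, a in enumerate(structure.atoms, start=1):
            fh.write(
                f"ATOM  {i:>5d} {a.name:<4s} {a.residue_name:<4s}"
                f"{a.residue_index + 1:>5d}    "
                f"{a.position[0]:>10.4f}{a.position[1]:>10.4f}{a.position[2]:>10.4f}"
                f" {a.charge:>8.4f} {a.radius:>7.4f}\n"
            )


# --------------------------------------------------------------------- PDB I/O


def read_pdb(path, ruleset: ParameterRuleset, label: str | None = None):
    """Read a PDB file through gemmi, assigning charges/radii from ``ruleset``.

    Atoms the ruleset cannot resolve get charge 0 and the element-default
    radius; the number of such fallbacks is returned so callers can warn.
    Waters are skipped; only the first model is used.

    Returns (Structure, n_fallback_atoms).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no models in PDB file")
    model = st[0]
    atoms = []
    n_fallback = 0
    residue_index = -1
    for chain in model:
        for residue in chain:
            if residue.name in ("HOH", "WAT", "DOD"):
                continue
            residue_index += 1
            for at in residue:
                element = at.element.name if at.element else ""
                q, r, resolved = ruleset.lookup(residue.name, at.name, element)
                if not resolved:
                    n_fallback += 1
                atoms.append(
                    Atom(
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        charge=q,
                        radius=r,
                        name=at.name,
                        residue_index=residue_index,
                        residue_name=residue.name,
                        is_calpha=(at.name.upper() == "CA"),
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: no ATOM records found")
    if label is None:
        import os

        label = os.path.splitext(os.path.basename(str(path)))[0]
    return Structure(atoms, label=label), n_fallback
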