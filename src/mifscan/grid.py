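"""Regular 3-D grids and scalar fields.

A :class:`GridSpec` is an axis-aligned regular lattice (origin, isotropic
spacing, shape); a :class:`ScalarField` is one real value per lattice node.
Fields are serialized in the OpenDX "regular positions regular connections"
dialect used by APBS, with z varying fastest, so output is directly viewable
in PyMOL/VMD/Chimera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import GeometryError, ParseError

#: units expected for each known field kind
_KIND_UNITS = {"electrostatic": "kT/e", "hydrophobic": "kcal/mol"}


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid: ``node(i,j,k) = origin + (i,j,k) * spacing``."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if not self.spacing > 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("origin and shape must be 3-vectors")
        if any(n < 8 for n in self.shape):
            raise ValueError(f"each grid dimension must be >= 8, got {self.shape}")
        if not all(math.isfinite(x) for x in self.origin):
            raise ValueError("grid origin must be finite")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def upper(self) -> tuple[float, float, float]:
        """Coordinates of the last node in each dimension."""
        return tuple(o + (n - 1) * self.spacing for o, n in zip(self.origin, self.shape))

    @property
    def diagonal(self) -> float:
        """Length of the box body diagonal, in Å."""
        return self.spacing * math.sqrt(sum((n - 1) ** 2 for n in self.shape))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def points(self) -> np.ndarray:
        """All node coordinates as an (N, 3) array in C (z-fastest) order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def contains(self, coords: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean per row of ``coords``: inside the box by at least ``margin``."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = np.asarray(self.origin) + margin
        hi = np.asarray(self.upper) - margin
        return np.all((coords >= lo) & (coords <= hi), axis=1)

    def min_face_distance(self, coords: np.ndarray) -> np.ndarray:
        """Distance of each point to the nearest box face (negative if outside)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = np.asarray(self.origin)
        hi = np.asarray(self.upper)
        return np.minimum((coords - lo).min(axis=1), (hi - coords).min(axis=1))

    @classmethod
    def auto(
        cls,
        coords: np.ndarray,
        spacing: float = 1.0,
        shape: tuple[int, int, int] | None = (110, 110, 110),
        margin: float = 10.0,
    ) -> "GridSpec":
        """Grid centered on the coordinate centroid.

        With an explicit ``shape`` (default: the conventional 110^3 production
        box at 1 Å) the box is centered on the centroid and must still leave
        ``margin`` Å of clearance around every atom center; with ``shape=None``
        the smallest odd shape providing the margin is chosen.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        center = coords.mean(axis=0)
        half_extent = np.abs(coords - center).max(axis=0)
        if shape is None:
            n = 2 * np.ceil((half_extent + margin) / spacing).astype(int) + 1
            n = np.maximum(n, 9)
            shape = tuple(int(v) for v in n)
        origin = tuple(center[d] - (shape[d] - 1) * spacing / 2.0 for d in range(3))
        spec = cls(origin=origin, spacing=spacing, shape=tuple(shape))
        clearance = spec.min_face_distance(coords).min()
        if clearance < margin:
            raise GeometryError(
                f"auto grid {shape} @ {spacing} Å leaves only {clearance:.2f} Å "
                f"margin around the structure (need >= {margin} Å); enlarge the grid"
            )
        return spec

    def compatible(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass
class ScalarField:
    """A scalar molecular interaction field sampled on a :class:`GridSpec`.

    ``kind`` is "electrostatic" (units kT/e) or "hydrophobic" (kcal/mol);
    auxiliary maps (dielectric, ion accessibility, masks) use free-form kinds
    with empty units.
    """

    grid: GridSpec
    values: np.ndarray
    units: str = ""
    kind: str = ""
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite everywhere")
        expected = _KIND_UNITS.get(self.kind)
        if expected is not None and self.units != expected:
            raise ValueError(
                f"kind {self.kind!r} requires units {expected!r}, got {self.units!r}"
            )

    def scaled(self, factor: float) -> "ScalarField":
        return ScalarField(self.grid, self.values * factor, self.units, self.kind)

    def negated(self) -> "ScalarField":
        return self.scaled(-1.0)

    def downsample(self, factor: int = 2) -> "ScalarField":
        """Take every ``factor``-th node along each axis (grids must be nested)."""
        if factor < 1:
            raise ValueError("downsample factor must be >= 1")
        for n in self.grid.shape:
            if (n - 1) % factor != 0:
                raise ValueError(
                    f"shape {self.grid.shape} is not nested under factor {factor}"
                )
        sub = self.values[::factor, ::factor, ::factor]
        grid = GridSpec(
            origin=self.grid.origin,
            spacing=self.grid.spacing * factor,
            shape=sub.shape,
        )
        return ScalarField(grid, sub.copy(), self.units, self.kind)

    # ------------------------------------------------------------------ DX I/O

    def write_dx(self, path) -> None:
        nx, ny, nz = self.grid.shape
        h = self.grid.spacing
        ox, oy, oz = self.grid.origin
        flat = self.values.ravel(order="C")  # z fastest, per the DX convention
        with open(path, "w") as fh:
            fh.write(f"# mifscan scalar field kind={self.kind or 'unknown'} "
                     f"units={self.units or 'none'}\n")
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {ox:.6e} {oy:.6e} {oz:.6e}\n")
            fh.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
            fh.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
            fh.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {flat.size} "
                "data follows\n"
            )
            for start in range(0, flat.size, 3):
                row = flat[start : start + 3]
                fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "regular positions regular connections" class field\n')
            fh.write('component "positions" value 1\n')
            fh.write('component "connections" value 2\n')
            fh.write('component "data" value 3\n')

    @classmethod
    def read_dx(cls, path, units: str = "", kind: str = "") -> "ScalarField":
        shape = None
        origin = None
        deltas = []
        data = []
        n_items = None
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                toks = line.split()
                if line.startswith("object") and "gridpositions" in line:
                    shape = tuple(int(t) for t in toks[-3:])
                elif line.startswith("origin"):
                    origin = tuple(float(t) for t in toks[1:4])
                elif line.startswith("delta"):
                    deltas.append([float(t) for t in toks[1:4]])
                elif line.startswith("object") and "class array" in line:
                    n_items = int(toks[toks.index("items") + 1])
                elif line.startswith(("object", "attribute", "component")):
                    continue
                else:
                    try:
                        data.extend(float(t) for t in toks)
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad DX data line") from exc
        if shape is None or origin is None or len(deltas) != 3:
            raise ParseError(f"{path}: incomplete DX header")
        diag = [deltas[i][i] for i in range(3)]
        off_diag = sum(abs(deltas[i][j]) for i in range(3) for j in range(3) if i != j)
        if off_diag > 1e-12 or max(diag) - min(diag) > 1e-9:
            raise ParseError(f"{path}: only isotropic axis-aligned DX grids supported")
        if n_items is not None and len(data) != n_items:
            raise ParseError(
                f"{path}: expected {n_items} data values, found {len(data)}"
            )
        values = np.asarray(data, dtype=float).reshape(shape, order="C")
        grid = GridSpec(origin=origin, spacing=diag[0], shape=shape)
        return cls(grid, values, units=units, kind=kind)


def surface_distance_field(
    coords: np.ndarray, radii: np.ndarray, grid: GridSpec
) -> np.ndarray:
    """min over atoms of (|node − atom center| − atom radius), per grid node.

    Negative inside an atom sphere, zero on a sphere surface, positive in
    solvent. Computed per distinct radius with a KD-tree so cohorts of
    pseudo-atoms with one or two radii stay fast on production grids.
    """
    from scipy.spatial import cKDTree

    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    radii = np.asarray(radii, dtype=float)
    pts = grid.points()
    out = np.full(pts.shape[0], np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(pts, k=1)
        np.minimum(out, d - r, out=out)
    return out.reshape(grid.shape)
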