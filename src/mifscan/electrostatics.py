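"""Finite-difference linearized Poisson-Boltzmann electrostatics.

The potential u (in kT/e) satisfies

    ∇·(ε(r) ∇u) − κ̄²(r) u = −4π C Σ_i q_i δ(r − r_i),

with ε(r) the position-dependent relative dielectric (protein interior vs
solvent), κ̄² = ε_solv κ² restricted to the ion-accessible region, and
C = e²/(4π ε₀ kT) the vacuum Bjerrum length (≈560.7 Å at 298.15 K), which
makes q·C/(ε·r) the Coulomb potential of a point charge in kT/e.

Discretization follows standard practice for this equation family:

* molecular-surface dielectric boundary by a two-pass morphological method —
  atom spheres inflated by the water-probe radius, then re-opened by a
  probe-radius erosion (grid-native approximation of the solvent-excluded
  surface);
* trilinear spreading of point charges to the 8 surrounding nodes;
* Dirichlet boundary values from the sum of per-atom Debye-Hückel sphere
  potentials;
* red-black successive over-relaxation on the 7-point stencil with
  harmonic-mean face dielectrics.

The operator is linear in the source charges, so negation, scaling and
superposition hold to solver tolerance — properties the comparison layer
relies on and the tests exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as const
from scipy import ndimage

from .errors import GeometryError, SolverError
from .grid import GridSpec, ScalarField, surface_distance_field
from .structures import Structure


@dataclass(frozen=True)
class SolventSpec:
    """Continuum-solvent parameters.

    eps_interior/eps_exterior: relative dielectrics of protein and solvent;
    ionic_strength in mol/L (1:1 salt); temperature in K (sets the kT/e
    scale); surface_probe_radius: water probe defining the dielectric
    boundary; stern_layer: extra ion-exclusion shell beyond the probe.
    """

    eps_interior: float = 4.0
    eps_exterior: float = 78.0
    ionic_strength: float = 0.050
    temperature: float = 298.15
    surface_probe_radius: float = 1.4
    stern_layer: float = 2.0

    def __post_init__(self):
        if min(self.eps_interior, self.eps_exterior, self.temperature) <= 0:
            raise ValueError("dielectrics and temperature must be positive")
        if self.ionic_strength < 0 or self.surface_probe_radius < 0 or self.stern_layer < 0:
            raise ValueError("ionic strength, probe and Stern layer must be >= 0")
        if self.eps_exterior < self.eps_interior:
            raise ValueError("eps_exterior must be >= eps_interior")

    @property
    def bjerrum_vacuum(self) -> float:
        """e² / (4π ε₀ kT) in Å: Coulomb prefactor for potentials in kT/e."""
        lb_m = const.e**2 / (4 * math.pi * const.epsilon_0 * const.k * self.temperature)
        return lb_m * 1e10

    @property
    def kappa(self) -> float:
        """Inverse Debye length in Å⁻¹ for a 1:1 electrolyte."""
        if self.ionic_strength == 0:
            return 0.0
        # kappa^2 = 2 e^2 N_A (1000 I) / (eps0 eps_s k T), converted m^-2 -> Å^-2
        k2 = (
            2
            * const.e**2
            * const.N_A
            * (1000.0 * self.ionic_strength)
            / (const.epsilon_0 * self.eps_exterior * const.k * self.temperature)
        )
        return math.sqrt(k2) * 1e-10


def _check_inside(structure: Structure, grid: GridSpec, clearance: float) -> None:
    face = grid.min_face_distance(structure.coords)
    needed = structure.radii + clearance
    bad = np.nonzero(face < needed)[0]
    if bad.size:
        raise GeometryError(
            f"{bad.size} atom(s) outside or hugging the grid box "
            f"(first: atom {bad[0]} at face distance {face[bad[0]]:.2f} Å, "
            f"needs {needed[bad[0]]:.2f} Å); enlarge the grid"
        )


def build_dielectric_maps(
    structure: Structure, grid: GridSpec, solvent: SolventSpec
) -> tuple[ScalarField, ScalarField]:
    """Node dielectric map and ion-accessibility (0/1) map.

    The interior region is the morphological solvent-excluded surface: nodes
    within (radius + probe) of any atom center that are farther than the
    probe radius from the nearest solvent-reachable node. Ions are excluded
    within (radius + probe + stern_layer) of any atom.
    """
    _check_inside(structure, grid, solvent.surface_probe_radius)
    dsurf = surface_distance_field(structure.coords, structure.radii, grid)

    probe = solvent.surface_probe_radius
    inflated = dsurf < probe
    if probe > 0 and inflated.any():
        # distance (Å) from each inflated node to the nearest solvent node
        edt = ndimage.distance_transform_edt(inflated, sampling=grid.spacing)
        interior = inflated & (edt > probe)
    else:
        interior = inflated

    eps = np.where(interior, solvent.eps_interior, solvent.eps_exterior)
    ion_excluded = dsurf < probe + solvent.stern_layer
    ion_access = np.where(ion_excluded, 0.0, 1.0)
    return (
        ScalarField(grid, eps, units="", kind="dielectric"),
        ScalarField(grid, ion_access, units="", kind="ion-accessibility"),
    )


def spread_charges(structure: Structure, grid: GridSpec) -> np.ndarray:
    """Trilinear assignment of point charges to the 8 surrounding nodes."""
    q_grid = np.zeros(grid.shape)
    origin = np.asarray(grid.origin)
    h = grid.spacing
    frac = (structure.coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    nx, ny, nz = grid.shape
    if np.any(base < 0) or np.any(base + 1 >= np.array([nx, ny, nz])):
        raise GeometryError("charge outside the grid interior; enlarge the grid")
    for (i, j, k), (tx, ty, tz), q in zip(base, t, structure.charges):
        for di, wx in ((0, 1 - tx), (1, tx)):
            for dj, wy in ((0, 1 - ty), (1, ty)):
                for dk, wz in ((0, 1 - tz), (1, tz)):
                    q_grid[i + di, j + dj, k + dk] += q * wx * wy * wz
    return q_grid


def debye_boundary(
    structure: Structure, grid: GridSpec, solvent: SolventSpec
) -> np.ndarray:
    """Dirichlet boundary values: sum of per-atom Debye-Hückel sphere potentials.

    Each charge contributes q·C·exp(−κ(d − a)) / (ε_s (1 + κ a) d) with
    a = atom radius + Stern layer; at zero ionic strength this reduces to
    the Coulomb potential in the solvent dielectric. Returned as a full grid
    array that is nonzero only on the 6 box faces.
    """
    u = np.zeros(grid.shape)
    kappa = solvent.kappa
    c_over_eps = solvent.bjerrum_vacuum / solvent.eps_exterior
    face_mask = np.zeros(grid.shape, dtype=bool)
    face_mask[0, :, :] = face_mask[-1, :, :] = True
    face_mask[:, 0, :] = face_mask[:, -1, :] = True
    face_mask[:, :, 0] = face_mask[:, :, -1] = True
    pts = grid.points().reshape(grid.shape + (3,))[face_mask]
    vals = np.zeros(pts.shape[0])
    for pos, q, r in zip(structure.coords, structure.charges, structure.radii):
        if q == 0.0:
            continue
        a = r + solvent.stern_layer
        d = np.linalg.norm(pts - pos, axis=1)
        d = np.maximum(d, 1e-6)
        vals += q * c_over_eps * np.exp(-kappa * np.maximum(d - a, 0.0)) / (
            (1.0 + kappa * a) * d
        )
    u[face_mask] = vals
    return u


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def solve_lpbe(
    structure: Structure,
    grid: GridSpec | None = None,
    solvent: SolventSpec | None = None,
    tol: float = 1e-5,
    max_iter: int = 10000,
    omega: float | None = None,
    return_info: bool = False,
):
    """Solve the LPBE for ``structure``; returns the potential in kT/e.

    ``tol`` is the relative residual (vs. the source norm) at which the
    red-black SOR iteration stops; ``omega`` defaults to the Poisson-optimal
    2/(1+sin(π/n)). With ``return_info=True`` also returns a dict with the
    iteration count, final residual and residual trace. Divergence (residual
    growing over a 10-check window) raises :class:`SolverError`.
    """
    if solvent is None:
        solvent = SolventSpec()
    if grid is None:
        grid = GridSpec.auto(structure.coords)
    if not 0 < tol < 1:
        raise ValueError("tol must be in (0, 1)")

    eps_f, ion_f = build_dielectric_maps(structure, grid, solvent)
    eps = eps_f.values
    h = grid.spacing

    q_grid = spread_charges(structure, grid)
    source = 4.0 * math.pi * solvent.bjerrum_vacuum * q_grid / h

    kappa = solvent.kappa
    kbar2_h2 = ion_f.values * solvent.eps_exterior * kappa**2 * h**2

    u = debye_boundary(structure, grid, solvent)

    # face dielectrics, harmonic mean of the two adjacent nodes
    ex = _harmonic(eps[:-1, :, :], eps[1:, :, :])
    ey = _harmonic(eps[:, :-1, :], eps[:, 1:, :])
    ez = _harmonic(eps[:, :, :-1], eps[:, :, 1:])

    # per-interior-node stencil pieces
    exm = ex[:-1, 1:-1, 1:-1]
    exp_ = ex[1:, 1:-1, 1:-1]
    eym = ey[1:-1, :-1, 1:-1]
    eyp = ey[1:-1, 1:, 1:-1]
    ezm = ez[1:-1, 1:-1, :-1]
    ezp = ez[1:-1, 1:-1, 1:]
    denom = exm + exp_ + eym + eyp + ezm + ezp + kbar2_h2[1:-1, 1:-1, 1:-1]
    src = source[1:-1, 1:-1, 1:-1]

    ii, jj, kk = np.indices(denom.shape)
    parity = (ii + jj + kk) % 2
    colors = (parity == 0, parity == 1)

    if omega is None:
        omega = 2.0 / (1.0 + math.sin(math.pi / max(grid.shape)))

    src_norm = float(np.linalg.norm(src))
    bc_norm = float(np.linalg.norm(u))
    ref_norm = max(src_norm, bc_norm, 1e-300)

    def neighbor_sum():
        return (
            exm * u[:-2, 1:-1, 1:-1]
            + exp_ * u[2:, 1:-1, 1:-1]
            + eym * u[1:-1, :-2, 1:-1]
            + eyp * u[1:-1, 2:, 1:-1]
            + ezm * u[1:-1, 1:-1, :-2]
            + ezp * u[1:-1, 1:-1, 2:]
        )

    trace = []
    n_iter = 0
    residual = math.inf
    check_every = 10
    for n_iter in range(1, max_iter + 1):
        for color in colors:
            gs = (neighbor_sum() + src) / denom
            inner = u[1:-1, 1:-1, 1:-1]
            inner[color] += omega * (gs[color] - inner[color])
        if n_iter % check_every == 0 or n_iter == max_iter:
            res = neighbor_sum() + src - denom * u[1:-1, 1:-1, 1:-1]
            residual = float(np.linalg.norm(res)) / ref_norm
            trace.append((n_iter, residual))
            if residual <= tol:
                break
            if not math.isfinite(residual):
                raise SolverError(
                    f"LPBE iteration diverged: non-finite residual at iteration "
                    f"{n_iter}",
                    trace=trace,
                )
            if len(trace) >= 10 and all(
                trace[-i][1] > trace[-i - 1][1] for i in range(1, 10)
            ):
                raise SolverError(
                    f"LPBE iteration diverging: residual grew over the last "
                    f"{9 * check_every} iterations (now {residual:.3e})",
                    trace=trace,
                )

    field = ScalarField(
        grid,
        u,
        units="kT/e",
        kind="electrostatic",
        meta={"residual": residual, "iterations": n_iter, "converged": residual <= tol},
    )
    if return_info:
        info = {
            "iterations": n_iter,
            "residual": residual,
            "converged": residual <= tol,
            "trace": trace,
            "omega": omega,
        }
        return field, info
    return field
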