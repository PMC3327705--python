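"""Molecular-interaction-field comparison: skins, Hodgkin indices, scans.

Fields are compared only over a "skin" — the shell of grid points just
outside the protein surface (between probe-offset and probe-offset plus a
fixed thickness) where binding partners actually feel the field. On a skin
(or on a 15 Å sphere of it around a residue's Cα) two fields a, b are scored
with the Hodgkin similarity index

    SI = 2 Σ a·b / (Σ a² + Σ b²),

which is +1 for identical fields, −1 for anticorrelated ones, and 2k/(1+k²)
for a pair differing by a scale factor k. The derived distance
d = sqrt(2 − 2·SI) runs from 0 (identical) to 2 (anticorrelated) and feeds
the clustering layer.

Undefined comparisons — too few mask points, or both fields identically
zero on the mask (e.g. an all-clamped hydrophobic sphere) — are flagged as
NaN in similarity matrices, never silently scored 0; only the conservation
profile converts flags to a 0 score, mirroring the convention of marking
such regions black.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateSkinError,
    MifScanError,
    UndefinedSIError,
)
from .grid import GridSpec, ScalarField, surface_distance_field
from .structures import Structure


@dataclass(frozen=True)
class ComparisonSpec:
    """Skin and scan geometry (Å) plus the defined-SI threshold.

    skin_probe/skin_thickness: the comparison shell spans surface distances
    [skin_probe, skin_probe + skin_thickness]; sphere_radius: local-scan
    sphere around each Cα; min_points: fewer masked points than this flags
    the comparison undefined.
    """

    skin_probe: float = 2.0
    skin_thickness: float = 3.0
    sphere_radius: float = 15.0
    min_points: int = 50

    def __post_init__(self):
        if min(self.skin_probe, self.skin_thickness, self.sphere_radius) <= 0:
            raise ValueError("skin and sphere dimensions must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class SkinMask:
    """Boolean selection of grid points forming a comparison shell."""

    grid: GridSpec
    selected: np.ndarray

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def intersect(self, other: "SkinMask") -> "SkinMask":
        if not self.grid.compatible(other.grid):
            raise MifScanError("cannot intersect masks on different grids")
        return SkinMask(self.grid, self.selected & other.selected)

    def union(self, other: "SkinMask") -> "SkinMask":
        if not self.grid.compatible(other.grid):
            raise MifScanError("cannot union masks on different grids")
        return SkinMask(self.grid, self.selected | other.selected)

    def to_field(self) -> ScalarField:
        """0/1 field for OpenDX export of the mask."""
        return ScalarField(self.grid, self.selected.astype(float), units="", kind="mask")


def skin_mask(
    structure: Structure, grid: GridSpec, spec: ComparisonSpec | None = None
) -> SkinMask:
    """Shell of nodes with surface distance in [skin_probe, skin_probe+thickness].

    Raises :class:`DegenerateSkinError` when fewer than ``min_points`` nodes
    qualify.
    """
    if spec is None:
        spec = ComparisonSpec()
    dsurf = surface_distance_field(structure.coords, structure.radii, grid)
    sel = (dsurf >= spec.skin_probe) & (dsurf <= spec.skin_probe + spec.skin_thickness)
    mask = SkinMask(grid, sel)
    if mask.n_selected < spec.min_points:
        raise DegenerateSkinError(
            f"skin of {structure.label!r} selected {mask.n_selected} grid points "
            f"(< min_points={spec.min_points}); grid too coarse or skin too thin"
        )
    return mask


def sphere_mask(base: SkinMask, center, spec: ComparisonSpec | None = None) -> SkinMask:
    """Restrict ``base`` to points within ``sphere_radius`` of ``center``.

    An empty result is allowed here; the caller flags it downstream.
    """
    if spec is None:
        spec = ComparisonSpec()
    center = np.asarray(center, dtype=float).reshape(3)
    ax, ay, az = base.grid.axes()
    d2 = (
        (ax - center[0])[:, None, None] ** 2
        + (ay - center[1])[None, :, None] ** 2
        + (az - center[2])[None, None, :] ** 2
    )
    return SkinMask(base.grid, base.selected & (d2 <= spec.sphere_radius**2))


def hodgkin_si(field_a: ScalarField, field_b: ScalarField, mask: SkinMask) -> float:
    """Hodgkin similarity index of two fields over the masked points.

    Raises :class:`UndefinedSIError` when both fields vanish on the mask —
    "no signal" is distinct from "uncorrelated" (SI 0).
    """
    if not (
        field_a.grid.compatible(mask.grid) and field_b.grid.compatible(mask.grid)
    ):
        raise MifScanError("fields and mask must share one grid")
    m = mask.selected
    if not m.any():
        raise UndefinedSIError("mask selects no grid points")
    a = field_a.values[m]
    b = field_b.values[m]
    denom = float(np.dot(a, a) + np.dot(b, b))
    if denom == 0.0:
        raise UndefinedSIError(
            "both fields are identically zero on the mask; SI undefined"
        )
    si = 2.0 * float(np.dot(a, b)) / denom
    # |2ab| <= a²+b² exactly; clip only float round-off
    return min(1.0, max(-1.0, si))


def si_to_distance(si: float) -> float:
    """Epogram distance d = sqrt(2 − 2·SI): 0 (identical) to 2 (anticorrelated)."""
    if not -1.0 - 1e-9 <= si <= 1.0 + 1e-9:
        raise ValueError(f"similarity index {si} outside [-1, 1]")
    si = min(1.0, max(-1.0, si))
    return math.sqrt(2.0 - 2.0 * si)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Hodgkin indices; NaN marks undefined entries."""

    labels: list[str]
    si: np.ndarray
    field_kind: str = ""
    scope: str = "global"

    def __post_init__(self):
        self.si = np.asarray(self.si, dtype=float)
        n = len(self.labels)
        if self.si.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if np.any(np.nan_to_num(np.abs(self.si - self.si.T)) > 1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.isnan(self.si) != np.isnan(self.si.T)):
            raise ValueError("undefined entries must be placed symmetrically")
        finite = self.si[np.isfinite(self.si)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("similarity entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.si)

    @property
    def fully_defined(self) -> bool:
        return bool(self.defined.all())

    def distance(self) -> np.ndarray:
        """Elementwise d = sqrt(2 − 2·SI); NaN propagates."""
        return np.sqrt(np.maximum(2.0 - 2.0 * np.clip(self.si, -1.0, 1.0), 0.0))

    def to_tsv(self, path, as_distance: bool = False) -> None:
        mat = self.distance() if as_distance else self.si
        pd.DataFrame(mat, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path, field_kind: str = "", scope: str = "global"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            labels=[str(c) for c in df.columns],
            si=df.to_numpy(dtype=float),
            field_kind=field_kind,
            scope=scope,
        )


@dataclass
class ConservationProfile:
    """Per-residue average pairwise SI; flagged residues carry score 0."""

    scores: np.ndarray
    flagged: np.ndarray
    field_kind: str = ""
    conformation_tag: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.scores.shape != self.flagged.shape:
            raise ValueError("scores and flags must have equal length")
        if np.any(self.scores[self.flagged] != 0.0):
            raise ValueError("flagged residues must carry score 0")
        ok = self.scores[~self.flagged]
        if ok.size and (ok.min() < -1 - 1e-9 or ok.max() > 1 + 1e-9):
            raise ValueError("conservation scores must lie in [-1, 1]")

    @property
    def n_residues(self) -> int:
        return self.scores.size

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "residue_index": np.arange(self.n_residues),
                "score": self.scores,
                "flagged": self.flagged.astype(int),
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, field_kind: str = "", conformation_tag: str = ""):
        df = pd.read_csv(path, sep="\t")
        return cls(
            scores=df["score"].to_numpy(dtype=float),
            flagged=df["flagged"].to_numpy(dtype=bool),
            field_kind=field_kind,
            conformation_tag=conformation_tag,
        )


def _check_common_setup(fields, structures):
    if len(fields) != len(structures):
        raise MifScanError("need one field per structure")
    if len(fields) < 2:
        raise MifScanError("need at least two proteins to compare")
    kinds = {f.kind for f in fields}
    if len(kinds) != 1:
        raise MifScanError(f"mixed field kinds cannot be compared: {sorted(kinds)}")
    grid = fields[0].grid
    for f in fields[1:]:
        if not grid.compatible(f.grid):
            raise MifScanError("all fields must share one common grid")
    return grid, kinds.pop()


def _pair_mask(skins, i, j, mask_policy):
    if mask_policy == "intersection":
        return skins[i].intersect(skins[j])
    if mask_policy == "union":
        return skins[i].union(skins[j])
    if mask_policy == "reference":
        return skins[0]
    raise MifScanError(f"unknown mask_policy {mask_policy!r}")


def _masked_si(a_vals, b_vals, min_points):
    """SI on pre-extracted values; NaN when undefined."""
    if a_vals.size < min_points:
        return math.nan
    denom = float(np.dot(a_vals, a_vals) + np.dot(b_vals, b_vals))
    if denom == 0.0:
        return math.nan
    return min(1.0, max(-1.0, 2.0 * float(np.dot(a_vals, b_vals)) / denom))


def pairwise_global(
    fields: list[ScalarField],
    structures: list[Structure],
    spec: ComparisonSpec | None = None,
    mask_policy: str = "intersection",
) -> SimilarityMatrix:
    """All-pairs Hodgkin SI over whole-protein skins.

    Each unordered pair is scored on the two structures' combined skin
    (intersection by default; "union" and "reference" are available).
    Diagonal entries use the protein's own skin and are +1 whenever defined.
    """
    if spec is None:
        spec = ComparisonSpec()
    grid, kind = _check_common_setup(fields, structures)
    skins = [skin_mask(s, grid, spec) for s in structures]
    n = len(fields)
    si = np.full((n, n), math.nan)
    for i in range(n):
        vals = fields[i].values[skins[i].selected]
        si[i, i] = _masked_si(vals, vals, spec.min_points)
        for j in range(i + 1, n):
            m = _pair_mask(skins, i, j, mask_policy).selected
            s = _masked_si(fields[i].values[m], fields[j].values[m], spec.min_points)
            si[i, j] = si[j, i] = s
    return SimilarityMatrix(
        labels=[s.label for s in structures], si=si, field_kind=kind, scope="global"
    )


def consensus_calpha(structures: list[Structure], centers: str = "consensus"):
    """(R, 3) sphere centers: mean Cα across the cohort, or the first structure's."""
    counts = {s.n_residues for s in structures}
    if len(counts) != 1:
        raise AlignmentError(
            f"structures have unequal residue counts {sorted(counts)}; supply a "
            "residue mapping (pre-align the cohort on a common template)"
        )
    if centers == "first":
        return structures[0].calpha_positions()
    if centers == "consensus":
        return np.mean([s.calpha_positions() for s in structures], axis=0)
    raise MifScanError(f"unknown centers policy {centers!r}")


def residue_scan(
    fields: list[ScalarField],
    structures: list[Structure],
    spec: ComparisonSpec | None = None,
    mask_policy: str = "intersection",
    centers: str = "consensus",
) -> list[SimilarityMatrix]:
    """Per-residue local comparison: SI matrices on 15 Å spheres around each Cα.

    Sphere centers are the consensus (cohort-mean) Cα positions by default.
    Undefined spheres (too few points, or both fields zero — e.g. an
    all-clamped hydrophobic region) are NaN-flagged in the matrices.
    """
    if spec is None:
        spec = ComparisonSpec()
    grid, kind = _check_common_setup(fields, structures)
    centers_xyz = consensus_calpha(structures, centers)
    skins = [skin_mask(s, grid, spec) for s in structures]
    n = len(fields)

    pts = grid.points()
    # pre-extract per-pair mask point coordinates and field values
    pair_data = {}
    for i in range(n):
        for j in range(i, n):
            m = (
                skins[i].selected
                if i == j
                else _pair_mask(skins, i, j, mask_policy).selected
            )
            flat = m.ravel()
            pair_data[(i, j)] = (
                pts[flat],
                fields[i].values.ravel()[flat],
                fields[j].values.ravel()[flat],
            )

    labels = [s.label for s in structures]
    out = []
    r2 = spec.sphere_radius**2
    for r, center in enumerate(centers_xyz):
        si = np.full((n, n), math.nan)
        for (i, j), (coords, a, b) in pair_data.items():
            inside = np.einsum("ij,ij->i", coords - center, coords - center) <= r2
            s = _masked_si(a[inside], b[inside], spec.min_points)
            si[i, j] = si[j, i] = s
        out.append(
            SimilarityMatrix(labels=labels, si=si, field_kind=kind, scope=f"residue_{r}")
        )
    return out


def conservation_profile(
    scan: list[SimilarityMatrix], conformation_tag: str = ""
) -> ConservationProfile:
    """Average the upper-triangle SIs of each residue's matrix.

    Residues whose sphere produced no defined pair (all flagged — e.g. the
    hydrophobic probe saw only clamped-to-zero energies there) score 0 and
    are flagged for black rendering downstream.
    """
    if not scan:
        raise MifScanError("empty residue scan")
    scores = np.zeros(len(scan))
    flagged = np.zeros(len(scan), dtype=bool)
    for r, mat in enumerate(scan):
        iu = np.triu_indices(mat.n, k=1)
        vals = mat.si[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            flagged[r] = True
        else:
            scores[r] = vals.mean()
    return ConservationProfile(
        scores=scores,
        flagged=flagged,
        field_kind=scan[0].field_kind,
        conformation_tag=conformation_tag,
    )
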