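"""Skin masks, Hodgkin indices, distances, scans and conservation scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mifscan as m
from mifscan.compare import consensus_calpha
from mifscan.errors import (
    AlignmentError,
    DegenerateSkinError,
    MifScanError,
    UndefinedSIError,
)

from conftest import single_atom_structure


def field_on(grid, values, kind="electrostatic"):
    units = {"electrostatic": "kT/e", "hydrophobic": "kcal/mol"}[kind]
    return m.ScalarField(grid, values, units, kind)


class TestSkinMask:
    def test_single_atom_skin_matches_brute_force(self):
        s = single_atom_structure(radius=1.5)
        g = m.GridSpec((-10, -10, -10), 1.0, (21, 21, 21))
        spec = m.ComparisonSpec(skin_probe=2.0, skin_thickness=3.0, min_points=1)
        mask = m.skin_mask(s, g, spec)
        d = np.linalg.norm(g.points(), axis=1)
        expected = (d >= 3.5) & (d <= 6.5)  # center distance in [r+2, r+5]
        assert np.array_equal(mask.selected.ravel(), expected)
        assert mask.n_selected == int(expected.sum())

    def test_identical_structures_identical_masks(self, charge_flip_pair, pair_grid):
        a, b = charge_flip_pair  # same geometry, different charges
        ma = m.skin_mask(a, pair_grid)
        mb = m.skin_mask(b, pair_grid)
        assert np.array_equal(ma.selected, mb.selected)

    def test_too_thin_skin_is_degenerate(self):
        s = single_atom_structure(radius=1.5)
        g = m.GridSpec((-10, -10, -10), 1.0, (21, 21, 21))
        spec = m.ComparisonSpec(skin_thickness=0.01)
        with pytest.raises(DegenerateSkinError):
            m.skin_mask(s, g, spec)


class TestSphereMask:
    @pytest.fixture()
    def base(self):
        s = single_atom_structure(radius=1.5)
        g = m.GridSpec((-10, -10, -10), 1.0, (21, 21, 21))
        return m.skin_mask(s, g, m.ComparisonSpec(min_points=1))

    def test_huge_sphere_returns_base_unchanged(self, base):
        spec = m.ComparisonSpec(sphere_radius=base.grid.diagonal + 1)
        out = m.sphere_mask(base, (0, 0, 0), spec)
        assert np.array_equal(out.selected, base.selected)

    def test_far_center_gives_empty_mask(self, base):
        spec = m.ComparisonSpec(sphere_radius=2.0)
        out = m.sphere_mask(base, (100.0, 0, 0), spec)
        assert out.n_selected == 0

    def test_counts_match_brute_force(self, base):
        spec = m.ComparisonSpec(sphere_radius=4.0)
        center = np.array([2.0, 1.0, -1.0])
        out = m.sphere_mask(base, center, spec)
        d = np.linalg.norm(base.grid.points() - center, axis=1)
        expected = base.selected.ravel() & (d <= 4.0)
        assert np.array_equal(out.selected.ravel(), expected)

    def test_mask_monotone_in_radius(self, base):
        sizes = [
            m.sphere_mask(base, (0, 0, 0), m.ComparisonSpec(sphere_radius=r)).n_selected
            for r in (2.0, 4.0, 8.0, 16.0)
        ]
        assert sizes == sorted(sizes)


class TestHodgkinSI:
    def test_identity_scaling_and_negation(self, random_field_pair):
        a, _, mask = random_field_pair
        assert m.hodgkin_si(a, a, mask) == pytest.approx(1.0, abs=1e-12)
        assert m.hodgkin_si(a, a.negated(), mask) == pytest.approx(-1.0, abs=1e-12)
        assert m.hodgkin_si(a, a.scaled(2.0), mask) == pytest.approx(0.8, abs=1e-12)

    def test_both_zero_fields_undefined(self, random_field_pair):
        a, _, mask = random_field_pair
        zero = field_on(a.grid, np.zeros(a.grid.shape))
        with pytest.raises(UndefinedSIError):
            m.hodgkin_si(zero, zero, mask)

    def test_empty_mask_undefined(self, random_field_pair):
        a, b, _ = random_field_pair
        empty = m.SkinMask(a.grid, np.zeros(a.grid.shape, dtype=bool))
        with pytest.raises(UndefinedSIError):
            m.hodgkin_si(a, b, empty)

    def test_grid_mismatch_rejected(self, random_field_pair):
        a, _, mask = random_field_pair
        other = m.GridSpec((5, 5, 5), 1.0, (10, 10, 10))
        b = field_on(other, np.ones(other.shape))
        with pytest.raises(MifScanError):
            m.hodgkin_si(a, b, mask)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_by_cauchy_schwarz(self, seed):
        rng = np.random.default_rng(seed)
        g = m.GridSpec((0, 0, 0), 1.0, (8, 8, 8))
        a = field_on(g, rng.normal(size=g.shape))
        b = field_on(g, rng.normal(size=g.shape))
        mask = m.SkinMask(g, rng.random(g.shape) < 0.5)
        if mask.n_selected == 0:
            return
        si = m.hodgkin_si(a, b, mask)
        assert -1.0 <= si <= 1.0
        av, bv = a.values[mask.selected], b.values[mask.selected]
        assert abs(2 * np.dot(av, bv)) <= np.dot(av, av) + np.dot(bv, bv) + 1e-12


class TestSiToDistance:
    @pytest.mark.parametrize(
        "si,expected",
        [(-1.0, 2.0), (1.0, 0.0), (0.0, math.sqrt(2.0))],
    )
    def test_endpoints_and_midpoint(self, si, expected):
        assert m.si_to_distance(si) == expected

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            m.si_to_distance(1.5)
        # within round-off tolerance is accepted and clipped
        assert m.si_to_distance(1.0 + 5e-10) == 0.0


def _relabel(structure, label):
    s = m.Structure([a for a in structure.atoms], label=label)
    s.conformation_tag = structure.conformation_tag
    return s


@pytest.fixture(scope="module")
def cohort_setup():
    backbone = m.make_backbone(10, seed=5)
    s = m.decorate_charges(backbone, [(1, 1.0), (5, -1.0), (8, 1.0)])
    grid = m.GridSpec.auto(s.coords, spacing=1.0, shape=None)
    rng = np.random.default_rng(11)
    base = rng.normal(size=grid.shape)
    return s, grid, base


class TestPairwiseGlobal:
    def test_identical_fields_give_all_ones(self, cohort_setup):
        s, grid, base = cohort_setup
        structures = [_relabel(s, f"p{i}") for i in range(3)]
        fields = [field_on(grid, base.copy()) for _ in range(3)]
        mat = m.pairwise_global(fields, structures)
        assert np.allclose(mat.si, 1.0)

    def test_sign_pattern_matrix(self, cohort_setup):
        s, grid, base = cohort_setup
        structures = [_relabel(s, f"p{i}") for i in range(3)]
        f = field_on(grid, base)
        fields = [f, f.negated(), field_on(grid, base.copy())]
        mat = m.pairwise_global(fields, structures)
        expected = np.array([[1, -1, 1], [-1, 1, -1], [1, -1, 1]], dtype=float)
        assert np.allclose(mat.si, expected, atol=1e-12)

    def test_mixed_kinds_rejected(self, cohort_setup):
        s, grid, base = cohort_setup
        structures = [_relabel(s, f"p{i}") for i in range(2)]
        fields = [field_on(grid, base), field_on(grid, base, kind="hydrophobic")]
        with pytest.raises(MifScanError, match="mixed"):
            m.pairwise_global(fields, structures)

    def test_graded_charge_scaling_through_solver(self, cohort_setup):
        """Charge scaling 1, 0.5, 0.25 under identical geometry: the LPBE is
        linear, so SI(1,2)=SI(2,3)=0.8 and SI(1,3)=2*0.25/(1+0.0625)."""
        s, grid, _ = cohort_setup
        solvent = m.SolventSpec()
        structures = [
            _relabel(s.with_charges_scaled(k), f"scale_{k}") for k in (1.0, 0.5, 0.25)
        ]
        fields = [m.solve_lpbe(st_, grid, solvent, tol=1e-6) for st_ in structures]
        mat = m.pairwise_global(fields, structures)
        assert mat.si[0, 1] == pytest.approx(0.8, abs=1e-4)
        assert mat.si[1, 2] == pytest.approx(0.8, abs=1e-4)
        assert mat.si[0, 2] == pytest.approx(2 * 0.25 / (1 + 0.0625), abs=1e-4)


class TestResidueScan:
    def test_identical_structures_score_one_everywhere(self):
        backbone = m.make_backbone(8, seed=2)
        s = m.decorate_charges(backbone, [(1, 1.0), (6, -1.0)])
        grid = m.GridSpec.auto(s.coords, spacing=1.0, shape=None)
        rng = np.random.default_rng(3)
        base = rng.normal(size=grid.shape)
        structures = [_relabel(s, "a"), _relabel(s, "b")]
        fields = [field_on(grid, base.copy()) for _ in range(2)]
        spec = m.ComparisonSpec(min_points=5)
        scan = m.residue_scan(fields, structures, spec)
        assert len(scan) == 8
        for mat in scan:
            defined = mat.defined
            assert np.allclose(mat.si[defined], 1.0)

    def test_scan_equals_global_for_huge_sphere(self):
        backbone = m.make_backbone(8, seed=2)
        s = m.decorate_charges(backbone, [(1, 1.0)])
        grid = m.GridSpec.auto(s.coords, spacing=1.0, shape=None)
        rng = np.random.default_rng(4)
        structures = [_relabel(s, "a"), _relabel(s, "b")]
        fields = [field_on(grid, rng.normal(size=grid.shape)) for _ in range(2)]
        spec = m.ComparisonSpec(sphere_radius=grid.diagonal + 1.0)
        scan = m.residue_scan(fields, structures, spec)
        ref = m.pairwise_global(fields, structures, m.ComparisonSpec())
        for mat in scan:
            assert np.nanmax(np.abs(mat.si - ref.si)) <= 1e-12

    def test_unequal_residue_counts_rejected(self):
        a = m.make_backbone(8, seed=0)
        b = m.make_backbone(9, seed=0)
        with pytest.raises(AlignmentError, match="residue mapping"):
            consensus_calpha([a, b])

    def test_all_clamped_hydrophobic_sphere_flagged(self):
        """Spheres where the clamp removed all signal are flagged undefined."""
        backbone = m.make_backbone(12, seed=6)
        grid = m.GridSpec.auto(backbone.coords, spacing=1.0, shape=None)
        structures = [_relabel(backbone, "a"), _relabel(backbone, "b")]
        # hydrophobic-like fields: signal only near the last residue
        ca = backbone.calpha_positions()
        d_last = np.linalg.norm(grid.points() - ca[-1], axis=1).reshape(grid.shape)
        vals = np.where(d_last < 6.0, -1.0, 0.0)
        fields = [field_on(grid, vals.copy(), kind="hydrophobic") for _ in range(2)]
        spec = m.ComparisonSpec(sphere_radius=6.0, min_points=1)
        scan = m.residue_scan(fields, structures, spec)
        first, last = scan[0], scan[-1]
        assert not np.isfinite(first.si[0, 1])  # all-zero sphere: flagged
        assert last.si[0, 1] == pytest.approx(1.0)
        prof = m.conservation_profile(scan, conformation_tag="synthetic")
        assert prof.flagged[0]
        assert prof.scores[0] == 0.0
        assert prof.scores[-1] == pytest.approx(1.0)


class TestConservationProfile:
    def _mat(self, si_value_pairs, labels=("a", "b", "c")):
        n = len(labels)
        si = np.eye(n)
        iu = np.triu_indices(n, 1)
        for k, v in enumerate(si_value_pairs):
            si[iu[0][k], iu[1][k]] = v
            si[iu[1][k], iu[0][k]] = v
        return m.SimilarityMatrix(list(labels), si, "electrostatic", "residue_0")

    def test_mean_of_upper_triangle(self):
        scan = [self._mat([1.0, 0.5, 0.0])]
        prof = m.conservation_profile(scan)
        assert prof.scores[0] == pytest.approx(0.5)

    def test_two_protein_profile_is_the_single_si(self):
        scan = [
            m.SimilarityMatrix(["a", "b"], np.array([[1.0, 0.37], [0.37, 1.0]]),
                               "electrostatic", "residue_0")
        ]
        prof = m.conservation_profile(scan)
        assert prof.scores[0] == pytest.approx(0.37)

    def test_identical_cohort_profile_constant_one(self):
        scan = [self._mat([1.0, 1.0, 1.0]) for _ in range(4)]
        prof = m.conservation_profile(scan)
        assert np.allclose(prof.scores, 1.0)
        assert not prof.flagged.any()


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        si = np.array([[1.0, 0.25], [0.25, 1.0]])
        mat = m.SimilarityMatrix(["x", "y"], si, "electrostatic")
        p = tmp_path / "si.tsv"
        mat.to_tsv(p)
        back = m.SimilarityMatrix.from_tsv(p, field_kind="electrostatic")
        assert back.labels == ["x", "y"]
        assert np.allclose(back.si, si)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            m.SimilarityMatrix(["x", "y"], np.array([[1.0, 0.2], [0.3, 1.0]]))
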