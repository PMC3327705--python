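# Methods

`mifscan` implements comparative molecular-interaction-field (MIF) analysis
for protein families: electrostatic potentials and hydrophobic interaction
fields are computed on regular grids around each structure, compared
pairwise with skin-masked Hodgkin similarity indices, and summarized as
epograms (dendrograms in field-distance space), ordered heatmaps and
per-residue conservation profiles. This note records the models, the
defaults and the design choices a maintainer would want to know.

## Electrostatics: the linearized Poisson-Boltzmann model

The dimensionless potential u = eΦ/kT satisfies

    ∇·(ε ∇u) − κ̄² u = −4π C Σᵢ qᵢ δ(r − rᵢ),      C = e²/(4π ε₀ kT),

with lengths in Å, charges in units of e, and C ≈ 560.7 Å at 298.15 K so
that a point charge in a uniform dielectric gives u = qC/(εr) in kT/e.
ε(r) is `eps_interior` (default 4.0) inside the molecular-surface region
and `eps_exterior` (default 78.0) outside; κ̄² = ε_ext·κ² in the
ion-accessible region and 0 within (atom radius + probe + Stern layer) of
any atom. κ is the inverse Debye length of a 1:1 electrolyte at
`ionic_strength` (default 0.050 M): 1/κ ≈ 13.6 Å at 50 mM.

Discretization and numerics:

* **Dielectric boundary.** The solvent-excluded surface is approximated on
  the grid by a two-pass morphological method: nodes within
  (radius + probe) of an atom center are solvent-excluded candidates, then
  candidates within the probe radius (1.4 Å, a water molecule) of a
  solvent-reachable node are re-opened (Euclidean distance transform).
  This grid-native construction deviates from analytic SES codes by up to
  a node spacing; comparative similarity indices are insensitive to it,
  absolute surface potentials less so.
* **Charge spreading.** Trilinear assignment of each point charge to its 8
  surrounding nodes.
* **Boundary conditions.** Dirichlet faces from the sum of per-atom
  Debye-Hückel sphere potentials q·C·e^{−κ(d−a)} / (ε_ext (1+κa) d) with
  a = radius + Stern layer. At zero ionic strength this is the Coulomb sum.
* **Solver.** Red-black successive over-relaxation on the 7-point stencil
  with harmonic-mean face dielectrics; ω defaults to the Poisson-optimal
  2/(1+sin(π/n)). Convergence at relative residual 1e-5 (vs. the larger of
  the source and boundary norms); divergence detection on a 10-check
  residual-growth window; the residual trace is reported.
* **Stern layer** 2.0 Å by default, configurable; **temperature** 298.15 K
  fixes the kT/e scale.

Verified limits (tests): a unit charge in uniform ε = 78 matches the
Coulomb form within 0.3% at r = 10–20 Å on a 65³ × 1 Å grid (the contract
is 5%); with 50 mM salt and no exclusion layer it matches the
Debye-Hückel form within 1%; halving the spacing tightens the Coulomb
bound from 5% to 3%. The operator is linear, so charge negation flips the
field exactly and superposition holds to solver tolerance — the comparison
layer's graded-similarity tests rest on this.

The production default grid is 110³ nodes at 1 Å spacing, auto-centered on
the structure centroid. Desk-scale work (tests, synthetic cohorts) uses
65³ at 1 Å, which keeps one solve near 2 s on one CPU; all grid-dependent
contracts are stated relative to closed forms, not to a particular box.
Single-grid solves only; no coarse-to-fine focusing.

## Hydrophobic interaction fields

At each node, E = Σ E_LJ + W_ENT − Σ E_HB: a 12-6 Lennard-Jones probe-atom
term, a constant water-entropy reward, and a hydrogen-bond term that makes
water win near donors/acceptors. Nodes with E > 0 (highly polar regions)
are reset to 0, as are nodes inside atom cores, so the field is ≤ 0
everywhere and "no hydrophobic signal" is represented by exact zeros.

The classic hydrophobic-probe parameterizations are proprietary, so the
functional forms here are an openly documented surrogate:

| parameter | default | meaning |
|---|---|---|
| lj_epsilon | 0.15 / 0.10 kcal/mol | LJ well depth, apolar (C,S) / polar (N,O,P) atoms |
| lj_sigma | 3.4 / 3.1 Å | LJ diameter per class |
| entropy_reward | −0.85 kcal/mol | constant inside the first solvation shell |
| shell_width | 3.0 Å | first-shell extent beyond the atom surface |
| hbond_penalty_strength | 2.5 kcal/mol | water H-bond energy near each donor/acceptor |
| hbond_cutoff | 4.0 Å | quartic switch (1−(d/c)²)² reaches 0 here |
| lj_cutoff | 8.0 Å | LJ truncation; keeps each atom's influence local |
| spacing | 0.5 Å | default HIF grid spacing |

Atom classes come from the element guess (first alphabetic character of
the atom name): C/S/H apolar, N/O/P polar; strict mode raises on anything
else, lenient mode defaults to apolar. The surrogate reproduces the
qualitative field structure that similarity comparison needs — negative
shells over apolar patches, clamped zeros over polar ones — and makes no
claim about absolute energies.

When hydrophobic and electrostatic fields must share skin masks, the
hydrophobic field is computed on the half-spacing nested grid and
downsampled by taking every other node, which lands exactly on the
electrostatic grid.

## Field comparison

* **Skin.** A node belongs to the comparison skin iff its distance to the
  nearest atom *surface* lies in [skin_probe, skin_probe + skin_thickness]
  (defaults 2.0 and 3.0 Å) — the shell where binding partners feel the
  field. Pairs are compared on the *intersection* of the two skins by
  default; union and reference-skin policies are available. For cohorts
  modeled on one template the choice is nearly immaterial (skins almost
  coincide); intersection is robust to synthetic coordinate jitter.
* **Hodgkin index.** SI = 2Σab/(Σa²+Σb²) over masked nodes; +1 identical,
  −1 anticorrelated, 2k/(1+k²) for a scale factor k. A comparison with
  fewer than `min_points` = 50 masked nodes, or where both fields are
  identically zero, is *undefined* (NaN), never 0: "no data" and
  "uncorrelated" are different statements. Undefined entries become score
  0 only in the conservation profile (rendered black), matching the
  convention for all-clamped hydrophobic spheres.
* **Distance.** d = √(2 − 2·SI) ∈ [0, 2]. The endpoints pin the form:
  d = 2 at SI = −1, d = 0 at SI = +1, d = √2 at SI = 0.
* **Regional scan.** For each residue, the pair mask is further restricted
  to a sphere of radius 15 Å around the residue's Cα; sphere centers are
  the cohort-mean ("consensus") Cα positions by default, identical to any
  member's under single-template modeling, with a "first structure" option.
  The conservation score of a residue is the mean of all defined pairwise
  SIs there. Scan and global comparison coincide exactly when the sphere
  radius exceeds the grid diagonal (tested to 1e-12).

Electrostatic conservation lives in [−1, 1]; hydrophobic conservation is
reported on [0, 1] for coloring (negative hydrophobic SIs are rare because
the clamp removes sign structure; the raw value is kept in the TSV and
only the color scale floors at 0).

## Clustering and rendering

UPGMA (average linkage) over d builds the epogram; single and complete
linkage are available. The linkage is implemented directly (naive O(n³),
ample for family-sized cohorts) so the tie-break is explicit: among
equal-distance candidate pairs, the pair whose lexicographically smallest
leaf labels sort first merges. This makes trees deterministic and
invariant to input order; cophenetic structure is cross-checked against
scipy's average linkage in the tests. Merge heights are d/2, so the tree
is ultrametric and root-to-leaf path lengths are equal; Newick branch
lengths are height differences. Heatmaps permute the distance matrix to
the dendrogram leaf order (red at d = 0 through to blue at d = 2);
conservation colors run blue (variable) → green → red (conserved), with
flagged residues black. TSV and Newick are the tested artifacts; PNGs are
conveniences.

## Synthetic cohorts

The generator emulates the real use case — dozens of homology models
sharing one template backbone and differing in surface properties — at
desk scale: an ideal α-helical Cα trace (rise 1.5 Å, 100° turn, radius
2.3 Å; consecutive Cα ≈ 3.8 Å apart) with one side-chain pseudo-atom per
residue (radius 1.9 Å, 3 Å radial offset), alternating apolar/polar along
the chain. Group archetypes share charged-residue positions and differ by
a fixed number of charge sign flips; members add rare within-group flips
and small coordinate jitter.

Defaults (the study conditions for all recovery tests): 24 residues,
12 proteins, 3 groups, 8 charged residues (±1 e), 4 between-group flips,
within-group flip probability 0.02, jitter 0.1 Å, seed 42. The sizes were
chosen so the cohort fits a 65³ × 1 Å grid with > 10 Å margins and a full
electrostatic pipeline run completes in well under a minute per CPU, while
4-of-8 sign flips separate groups decisively (between-group SI ≈ −0.5 to
+0.3 vs within-group ≈ 1). Under these conditions cutting the epogram at
3 clusters recovers the generator's labels with adjusted Rand index 1.0.

What the generator does *not* emulate: all-atom side chains and rotamers,
sequence realism, backbone divergence between family members, partial
charges from a force field, and unstructured terminal regions. Passing
recovery tests therefore demonstrate the correctness of the pipeline's
statistics and plumbing on fields with known relationships — not that any
particular real protein family separates into k groups.

## Degenerate inputs and tie-breaks

* Structures must have contiguous 0-based residue indices and exactly one
  Cα per residue (the scan anchors there); readers verify or fail.
* A skin with fewer than `min_points` nodes is an error at mask-building
  time; an empty *sphere* is not — it flags the residue.
* Both-zero fields raise a distinct undefined-SI error in direct calls and
  propagate as NaN in matrices.
* Similarity matrices with NaN entries refuse clustering with instructions
  to impute or exclude; they never silently drop proteins.
* SOR divergence (10 consecutive residual increases, or a non-finite
  residual) raises with the residual trace attached.
* `si_to_distance` accepts |SI| ≤ 1 + 1e-9 and clips round-off; beyond
  that it is a domain error.

## Problem sizes used by the test and acceptance runs

Desk-scale runs use 65³ × 1 Å grids (closed-form solver checks, the
two-protein locality scan, the 12-protein recovery cohort) and smaller
auto-sized boxes (≈33³) for linearity/superposition properties; the
refinement check compares 1.5 Å vs 0.75 Å spacings on a fixed 48 Å box.
These sizes were picked so the whole suite exercises every contract —
including two full pipeline runs — in a few minutes on one CPU; the
production 110³ grid default is unchanged and used when no grid is given
for real structures.

## Known limitations

* Single-grid LPBE solves; no focusing, so very large boxes trade accuracy
  near the molecule for boundary distance.
* The PDB charge ruleset is a formal-charge surrogate (Asp/Glu −0.5 per
  carboxylate O, Lys +1, Arg +0.5 per NH, His neutral, Bondi-like radii);
  it reproduces sign structure, not a force field. PQR input is canonical.
* The hydrophobic surrogate is qualitative by design (above).
* No structural superposition: cohorts are assumed pre-aligned on a common
  template, and the scan requires equal residue counts.
* Printed similarity values from studies using other solvers depend on
  their exact charge sets and surface algorithms; this package's contracts
  are therefore stated against closed forms and constructed cohorts.
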