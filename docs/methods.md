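# Methods

## Model and assumptions

`gbcplx` treats a molecular complex as a rigid set of charged spheres in a
two-dielectric continuum: solute dielectric ε_in inside the solvent-excluded
volume, solvent ε_out outside, optional Debye screening κ in the solvent.
All electrostatics is Generalized Born: each atom's self-solvation is that of
an equivalent Born sphere of effective radius R_i, and pair solvation uses
the canonical interpolation f_GB(d, R_i, R_j) = sqrt(d² + R_i R_j
exp(−d²/(4 R_i R_j))). The hydrophobic term is a single surface-tension
coefficient γ times the total solvent-accessible area — no atom-type
dependence. Molecules are rigid: the same coordinates are used bound and
free, so binding differences reflect desolvation and interaction only, not
relaxation. Binding energetics from rigid implicit-solvent models are
qualitative; the package's emphasis is on interface descriptors
(complementarity, contacts, buried area), which are robust to the overall
energy scale.

Three calculations per run: the complex and each isolated partner. Surfaces
of the partners are computed in the absence of the other — the potentials
entering the complementarity statistic are those of the *free* molecules,
evaluated at surface points that come into contact in the complex.

## Effective Born radii

R_i is computed from the R6 surface integral over the closed SES,

    R_i^-3 = (1/4π) Σ_k A_k ((c_k − x_i)·n̂_k) / |c_k − x_i|^6,

with patches (c_k, n̂_k, A_k) taken per mesh vertex (area = one third of
incident triangle areas, so patch areas partition the mesh area exactly).
The form is sphere-exact, which anchors the desk-scale validation. The whole
surface is integrated for every atom by default; a cutoff hook exists but is
off. Integrals that come out non-positive, or radii below 0.5·r_i, are
clamped to 0.5·r_i and flagged — this only happens on degenerate geometry
(an atom outside its own surface). No empirical rescaling is applied
(scale = 1.0 hook).

## Surface potential and complementarity

The potential at a surface point is that felt by a probe charge placed
there, with its own Born radius R_t (default 1.4 Å, configurable):
φ(c_k) = k_e Σ_i q_i [1/(ε_in d_ik) − τ(f_GB(d_ik, R_i, R_t))/f_GB(...)],
in kJ/(mol·e). Electrostatic complementarity is ec = −r, the sign-changed
Pearson correlation over *all* cross-entity surface-point pairs within the
contact cutoff δ (default 1 Å) — all pairs, not nearest-neighbor matching,
so densely meshed regions carry proportionally more weight, and the
companion sum-of-products statistic depends on mesh density by design.
The concordant fraction counts pairs whose potentials share a sign; an
exactly zero product counts as non-concordant (a deterministic rule for a
measure-zero event). ec is invariant under positive rescaling of either
side's potentials — hence also under the choice of ε_out or a global charge
scale — which is why correlation-based complementarity is far more portable
than the raw energies.

Atom contacts use the same δ against the vdW surface gap: d₁₂ < r₁ + r₂ + δ.
The interface-atom subsets written to the `_int*.pqr` files are exactly the
atoms appearing in at least one such contact pair.

## Internal SES construction

The SES interior is realized by its morphological definition: the set of
points at distance ≥ probe radius r_p from the solvent-accessible region
(equivalently, the closing of the vdW volume by the probe ball). The scalar
field sampled on a regular grid (default spacing 0.5 Å) is the *exact*
Euclidean distance to a dense sample of the SAS — the exposed points of
probe-inflated atomic spheres (default 1024 directions per atom, deterministic
golden-spiral set), queried through a KD-tree — signed negative outside the
SAS volume. Marching cubes extracts the r_p level set; the mesh is then
refined once by midpoint subdivision with every vertex snapped back onto the
exact level set (closed-form projection: onto the r_p-sphere around the
nearest cloud point). Normals are the negative field gradient — the
direction toward the nearest SAS sample — and point into the solvent.

Accuracy notes: because distance is measured to the true SAS rather than a
voxelized boundary, surface placement error is set by the cloud sampling
(ripple ≈ s²/8r_p for inter-sample spacing s, about 0.01 Å at defaults), not
by the grid; the subdivision step removes most of the inscribed-facet area
deficit of marching cubes. At defaults a single sphere's area is reproduced
to ~0.2%, its Born radius to ~0.5%. Connected components are labeled;
the largest-area component is the external surface and the rest are internal
cavities, kept (and flagged) by default since they bound the solvent-excluded
region and belong in the GB integral; `--drop-cavities` removes them.
Closure (every edge shared by exactly two triangles) is verified at
construction and the divergence-theorem volume is made positive.

External meshes in MSMS `.vert`/`.face` format are accepted instead
(`-ns`/`-msms BASE` read `BASE.vert/.face`, `BASE_mol_1.*`, `BASE_mol_2.*`;
no external binaries are ever executed). NanoShaper-style `.xyzr` and
parameter files can be generated with the safe fallback parameters
Grid_scale 2.0 / Grid_perfil 95; `-rpns` preserves a user-supplied
parameter file.

## SAS

Per-atom SASA uses uniform test points (default 960, golden-spiral) on each
probe-inflated sphere; a point is exposed when outside every other inflated
sphere, and the area is the exposed fraction × 4π(r_i + r_p)². Buried SASA
is SASA(mol1) + SASA(mol2) − SASA(complex), computed with one probe radius
and sampling for all three.

## Statistics

ROC AUC is the Mann–Whitney rank statistic with ties counted ½; the "best"
single threshold maximizes Youden's J = TPR − FPR, ties broken toward higher
specificity. Decoy nulls resample one point uniformly (with replacement)
from each *full* surface per pair — not restricted to interface points — and
default to matched pair counts. The symmetrized scatter (each pair plotted
twice with coordinates swapped) has identical marginals, so its OLS slope
equals the Pearson r of the symmetrized set exactly and its intercept is
mean·(1 − slope); against the single-counted pair list the agreement is
statistical, not exact. Docking-model rescoring sorts by descending ec
(stable on ties), reports per-label histograms on fixed 0.1-wide bins over
[−0.5, 1], and the label composition of the top decile; quality labels are
consumed from the caller, never recomputed.

## Synthetic study systems

The generators provide everything the tests and the acceptance script use:

- `make_sphere`: one charged sphere — closed-form Born energy, SES area and
  GB radius.
- `make_planar_complex`: two parallel square lattices (chains A/B), default
  16 atoms per side, radius 1.7 Å, spacing 3.5 Å, gap 3.9 Å, charge scale
  0.5 e. Chain-B charges are −c·q_A + √(1−c²)·noise, so the expected
  charge-pair correlation across the interface is −c and the surface
  potentials inherit tunable complementarity. The geometry was chosen so
  each slab's SES is one connected component (probe cannot pass between
  lattice neighbors), facing surfaces sit ~0.5 Å apart (inside the 1 Å
  cutoff), and only directly opposing atoms form vdW contacts.
- `make_separated`: rigid recombination at large distance — the
  non-interacting limit.

What these toys do *not* emulate: realistic protein shape, heterogeneous
radii/charges, re-entrant interface topography, or buried waters. Passing
tests therefore validate the numerics and the statistical machinery, not
force-field-level realism; conclusions about real complexes still depend on
upstream charge/radius assignment. One physical caveat verified explicitly:
partners with net charge retain their monopole Coulomb interaction at any
separation — only the solvent-screened total (Coulomb + cross solvation)
vanishes at long range — so the strict "every component → 0" limit applies
to net-neutral partners.

## Defaults and numerical choices

| parameter | default | notes |
|---|---|---|
| ε_in / ε_out | 1.0 / 78.54 | conventional; correlations are scale-invariant |
| κ | 0 Å⁻¹ | salt off; enters only exp(−κf)/ε_out |
| γ | 0.021 kJ/(mol·Å²) | uniform surface tension |
| probe r_p | 1.4 Å | water |
| test-charge radius R_t | 1.4 Å | configurable stand-in for the PB-calibrated value |
| contact cutoff δ | 1 Å | atoms and surface points alike |
| grid spacing | 0.5 Å | internal surfacer |
| SAS samples | 960/atom | sampling-limited accuracy ~0.1% |
| k_e | 1389.35 kJ·Å/(mol·e²) | Coulomb constant |

Pair energy terms are split half/half between the two atoms for the per-atom
decomposition (self terms stay whole), so per-atom contributions sum to the
electrostatic total by construction. Coincident atom/patch geometry
(< 10⁻⁶ Å) is rejected rather than regularized. Runs are deterministic:
fixed sampling directions, no randomness outside the seeded decoy/toy
generators, bit-identical reruns.

Problem sizes used in the test suite and acceptance script (toy complexes of
32 atoms, 20 seeds per complementarity level, 30 complexes for decoy
discrimination, voxel oracles at 0.2–0.25 Å) were chosen to keep the full
validation in the one-minute range while leaving comfortable margins to the
asserted tolerances.

## Known limitations

- Rigid molecules; no conformational relaxation or ensemble averaging.
- GB is an approximation to Poisson–Boltzmann; the test-charge surface
  potential is a calibrated surrogate, not a PB solution.
- Uniform γ ignores atom-type hydrophobicity differences.
- The internal surfacer targets desk-scale accuracy; very large complexes
  are better served by external meshes fed through the MSMS parser.
- Absolute energies are dominated by the charge/radius model of the input
  PQR; cross-complex comparisons of raw energies are fragile, while
  correlation-based descriptors transfer well.
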