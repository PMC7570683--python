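# Methods

## Scope and model

`cdftkit` computes chemical-reactivity descriptors *from* electronic-structure
results; it performs no SCF, conformer search or property prediction itself.
Inputs are (a) frontier-orbital energies of the neutral molecule (HOMO ε_H,
LUMO ε_L) plus optionally the radical anion's SOMO, (b) ground-state total
energies of the N, N−1, N+1 electron systems, and (c) volumetric densities /
spin densities on Gaussian-cube grids. The canonical internal energy unit is
eV (hartree accepted on input, converted with 1 Ha = 27.211386245988 eV);
lengths are bohr throughout (XYZ input in angstrom is converted on read).

## Global descriptors and provenance modes

All global indices derive from a vertical I and A. Two provenance modes
exist and are never mixed silently:

* **orbital** — I = −ε_H, A = −ε_L. Valid exactly when the functional is
  Koopmans-compliant; η then equals the HOMO–LUMO gap identically and
  ω− − ω+ = χ holds to machine precision (both are regression-tested).
* **deltascf** — I = E(N−1) − E(N), A = E(N) − E(N+1). Negative A (unbound
  anion) is legal and propagates.

Every `GlobalDescriptors` instance carries its mode tag, and table rendering
refuses mixed-mode lists: published tables in this field routinely mix ΔSCF
χ/η/ω/S with orbital ω−/ω+/Δω± in one layout, which is exactly the confusion
the tag prevents. The HOMO–LUMO gap and the nucleophilicity N are orbital
quantities in either mode.

Softness is S = 1/η. Some literature uses 1/(2η); 1/η is what reproduces the
bundled reference table (seven of its eight softness cells to 4 decimals; the
eighth — discodermin E, printed 0.2584 vs 1/η = 0.2684 — is inconsistent
with its own hardness column and is treated as a printed digit typo, noted in
`cdftkit.datasets`).

The nucleophilicity reference defaults to ε_H(TCE) = −9.1212 eV. The value is
back-derived from the bundled dataset's A row (ε_H − N = −5.6567 − 3.4645)
because the original scale's reference energy is rarely printed alongside
such tables; it is a plain keyword argument wherever N is computed. The
strong-nucleophile classification threshold is N > 3 eV.

The KID compliance verdict uses J_HL ≤ 0.10 eV by default. Compliant
functionals in this family of studies sit below ~0.06 eV and clearly broken
ones an order of magnitude higher, so the verdict is insensitive to the
exact ceiling; it is configurable per call and on the CLI.

## Local descriptors

Fukui fields are pointwise finite differences of grid-compatible densities;
two grids count as identical when origin, axes and shape agree within 1e-8
bohr absolute (cube headers print ~6 significant digits, so anything tighter
would reject legitimate re-reads). The dual descriptor is fixed as
Δf = f+ − f−, the standard finite-difference reading in which Δf > 0 marks
nucleophilic-attack-prone regions. Parr functions are pass-throughs of the
radical-ion spin densities — not re-normalized, because practitioners
tabulate raw atomic spin densities — with a diagnostic that warns when a
field integrates outside [0.9, 1.1] electrons (a clean doublet gives 1). The
Parr-difference descriptor is P+ − P−.

Quadrature is the midpoint rule, Σ values · det(axes), with no adaptive
refinement; grid convergence is the user's responsibility and the
normalization diagnostics are the check. Non-orthogonal axes are supported
(the volume element is the determinant).

### Condensation

Two partition-of-unity schemes condense any field to atoms:

* **hirshfeld** (default) — promolecule weights w_A = g_A / Σ_B g_B with g_A
  a normalized spherical Gaussian centred on atom A, width = covalent radius
  × scale (scale defaults to 1; per-atom widths can be overridden). Single
  Gaussians instead of tabulated free-atom densities are a deliberate
  simplification: they keep the weights closed-form and oracle-checkable,
  and only synthetic-fixture accuracy is asserted anywhere. Grid points
  where the promolecule falls below 1e-30 contribute zero (guards the
  far-field division).
* **voronoi** — each grid point wholly assigned to its nearest atom, ties to
  the lowest atom index. Offered as a cross-check; for atoms separated by
  several widths both schemes agree to a few hundredths of an electron.

Both schemes partition unity, so condensed values sum to the field integral
to 1e-10 relative regardless of the field — this is the invariant the tests
lean on hardest.

## Synthetic fixtures

The generator emulates just enough structure to make every operation
testable without an electronic-structure run: promolecule densities as sums
of normalized Gaussians with chosen per-atom electron masses on an
orthogonal voxel-centred grid, padded ≥ 4σ so ≥ 1 − 1e-4 of each Gaussian is
in the box. `make_fukui_pair` adds a unit of electron mass with known
per-atom placement, making the exact condensed Fukui vector available as an
oracle; `make_kid_records` builds charge-state energies (anchored at
E(N) = 0, since only differences enter any formula) whose KID residuals are
exactly the requested deviations. Randomized fixtures are seeded and
bit-reproducible; atoms are placed at least 4× the largest relevant length
scale apart — including the condensation weight width, since "well
separated" must hold for the partition, not only the densities.

What these fixtures do **not** emulate: shell structure, density cusps,
solvation, or realistic peptide charge distributions. Passing tests
demonstrate the descriptor algebra, quadrature and partitioning are correct,
not that any particular molecule's reactivity is predicted.

Default fixture grids are 64³ (48³/40³ in the quicker randomized property
tests), which keeps each fixture under a second and integral accuracy at the
1e-3 level the assertions use.

## Numerical and formatting choices

* Cube output writes one canonical dialect (positive natoms, z-fastest,
  six values per line); negative-natoms orbital headers are read but never
  written. Headers carry full float precision so read∘write is exact on the
  grid and values survive at ≤ 5e-13 relative.
* Table rendering rounds half-even — 4 decimals for energies/descriptors,
  3 for KID residuals, matching how such tables are printed. Rendering is
  pure; stdout carries data and stderr carries logs.
* Record order is preserved everywhere (tables reproduce input row order);
  unicode minus signs are accepted on input and normalized to ASCII on
  output.
* The CLI's `report` subcommand is the KID-table renderer; `global`, `local`
  and `synth` cover the descriptor table, the cube pipeline and fixture
  emission.

## Known limitations

* Orbital-mode descriptors are only as good as the functional's Koopmans
  compliance — that is what the KID report is for; run it first.
* Hirshfeld condensation with single-Gaussian promolecules is not the
  tabulated-density Hirshfeld of population-analysis codes; absolute
  condensed values on real molecules will differ, though sign patterns and
  orderings are robust for well-separated sites.
* No Mulliken/basis-set population analysis, no frozen-orbital Fukui
  functions, no isosurface rendering, no log-file parsing (fchk/molden are
  out of scope; feed cubes and energy tables instead).
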