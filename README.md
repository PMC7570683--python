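# cdftkit

Conceptual-DFT reactivity descriptors for molecules — built for computational
chemists who already have frontier-orbital energies, charge-state total
energies or density cubes from an electronic-structure code and want the
reactivity analysis layered on top: global indices, a Koopmans-compliance
audit of the functional, and grid-based local descriptors condensed to atoms.
It ships with the discodermin A–H marine cyclodepsipeptides as a worked
dataset.

## The descriptors

From a vertical ionization potential I and electron affinity A — either the
orbital identifications I = −ε_H, A = −ε_L, or the ΔSCF differences
I = E(N−1) − E(N), A = E(N) − E(N+1) — the global indices are

    χ   = (I + A)/2          electronegativity (chemical potential μ = −χ)
    η   = I − A              global hardness        S = 1/η   softness
    ω   = χ²/(2η)            electrophilicity
    ω−  = (3I + A)²/(16η)    electrodonating power
    ω+  = (I + 3A)²/(16η)    electroaccepting power
    Δω± = ω− + ω+            net electrophilicity
    N   = ε_H − ε_H(TCE)     nucleophilicity (tetracyanoethylene reference;
                             N > 3 eV ⇒ strong nucleophile)

Whether the orbital identifications are trustworthy is itself measurable: the
Koopmans-in-DFT (KID) residuals

    J_I = |ε_H + E(N−1) − E(N)|,  J_A = |ε_L + E(N) − E(N+1)|,
    J_HL = √(J_I² + J_A²),        ΔSL = |ε_SOMO(anion) − ε_L(neutral)|

vanish for a perfectly Koopmans-compliant functional; `cdftkit` issues a
verdict against a configurable J_HL threshold (default 0.10 eV).

Locally, the Fukui functions f± and the dual descriptor Δf = f+ − f− are
finite differences of N, N±1 electron densities on a cube grid; the Parr
functions P+/P− are the radical anion/cation spin densities; and the
Parr-difference descriptor P+ − P− is a dual-descriptor analogue built from
them. Any field condenses to per-atom values by Hirshfeld-style promolecule
weights or a Voronoi partition.

## Worked example

```python
from cdftkit.datasets import frontier_records
from cdftkit.global_descriptors import global_descriptors

g = global_descriptors(frontier_records()[0])   # Discodermin A, orbital mode
print(f"{g.label}: w- = {g.omega_minus:.4f} eV, w+ = {g.omega_plus:.4f} eV, "
      f"net = {g.net_electrophilicity:.4f} eV, N = {g.nucleophilicity:.4f} eV")
```

prints

```
Discodermin A: w- = 5.2671 eV, w+ = 1.6510 eV, net = 6.9182 eV, N = 3.4645 eV
```

— discodermin A donates electron density far more readily than it accepts it
(ω− ≫ ω+), and its nucleophilicity N > 3 eV classifies it as a strong
nucleophile. The `examples/` scripts walk through the full global table, the
KID audit, and the local-descriptor pipeline on synthetic densities; the same
operations are available from the shell via the `cdftkit global`, `report`,
`local` and `synth` subcommands.

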