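"""Fukui functions, the dual descriptor and the Parr-difference descriptor.

A synthetic two-atom molecule donates an electron from atom C1 (the f− site)
and accepts one onto atom O2 (the f+ site). Condensing the fields to atoms
shows DD < 0 on the donor and DD > 0 on the acceptor, and the
Parr-difference descriptor P+ − P− built from matched radical-ion spin
densities reproduces the same sign pattern.
"""

from cdftkit.fields import AtomSite
from cdftkit.local_descriptors import (
    condense,
    dual_descriptor,
    fukui_minus,
    fukui_plus,
    integrate,
    parr_dual,
    parr_functions,
)
from cdftkit.reporting import ReportConfig, render_condensed_table
from cdftkit.synthetic import FixtureSpec, make_density, make_fukui_pair

atoms = (AtomSite("C", 6.0, (0.0, 0.0, 0.0)), AtomSite("O", 8.0, (5.0, 0.0, 0.0)))
base = FixtureSpec(atoms=atoms, per_atom_masses=(4.0, 4.0), widths=(0.5, 0.5),
                   grid_shape=(64, 64, 64), padding=2.0)

# N+1 electrons: the extra electron lands on O2; N-1: one is taken from C1
rho_n, rho_np1, _ = make_fukui_pair(base, (0.0, 1.0))
_, rho_n_plus_donor, _ = make_fukui_pair(base, (1.0, 0.0))
rho_nm1 = rho_n.with_values(2 * rho_n.values - rho_n_plus_donor.values, "density")

f_plus = fukui_plus(rho_np1, rho_n)
f_minus = fukui_minus(rho_n, rho_nm1)
dd = dual_descriptor(f_plus, f_minus)

# matched radical-ion spin densities: cation spin on the donor, anion on the acceptor
spin_cation = make_density(FixtureSpec(atoms=atoms, per_atom_masses=(1.0, 0.0),
                                       widths=(0.5, 0.5), grid_shape=(64, 64, 64),
                                       padding=2.0), quantity="spin_density")
spin_anion = make_density(FixtureSpec(atoms=atoms, per_atom_masses=(0.0, 1.0),
                                      widths=(0.5, 0.5), grid_shape=(64, 64, 64),
                                      padding=2.0), quantity="spin_density")
p_plus, p_minus = parr_functions(spin_cation, spin_anion)
pd = parr_dual(p_plus, p_minus)

vectors = [condense(f, "hirshfeld") for f in (f_plus, f_minus, dd, p_plus, p_minus, pd)]
print(render_condensed_table(vectors, ReportConfig(output_format="markdown")))
print(
    f"integral of f+ = {integrate(f_plus):.4f} (one added electron), "
    f"integral of DD = {integrate(dd):+.4f} (balances to zero).\n"
    "DD and the Parr-difference descriptor agree in sign on every atom: "
    "electrophiles attack O2, nucleophiles attack C1."
)
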