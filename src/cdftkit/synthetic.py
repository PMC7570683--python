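"""Analytic promolecule fixtures with known answers.

Every local descriptor in this package is a pointwise combination of density
grids followed by a quadrature, so it can be exercised end-to-end on fields
whose integrals are known in closed form. The generator builds promolecule
densities as sums of normalized spherical Gaussians — one per atom, each
carrying a chosen electron mass — on an orthogonal grid padded far enough
that at least 1 − 1e-4 of every Gaussian lies inside the box. These are
deliberately non-physical model densities (no shell structure, no cusps);
they exist so that condensation and Fukui/Parr algebra can be checked against
exact per-atom masses.

For the global side, :func:`make_kid_records` manufactures matched
frontier/charge-state records whose KID residuals are exactly the requested
Koopmans deviations, letting threshold logic be tested without any electronic
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import InvariantError
from .fields import AtomSite, ScalarField
from .records import ChargeStateEnergies, FrontierRecord

__all__ = [
    "FixtureSpec",
    "make_density",
    "make_fukui_pair",
    "make_kid_records",
    "random_fixture_spec",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for an analytic promolecule density.

    ``per_atom_masses`` are the electrons each Gaussian carries; ``widths``
    its standard deviations σ (bohr). ``padding`` extends the grid box beyond
    the atom bounding box and must be at least 4× the largest width so the
    tails truncated by the box carry under 1e-4 of each atom's mass.
    """

    atoms: tuple[AtomSite, ...]
    per_atom_masses: tuple[float, ...]
    widths: tuple[float, ...]
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    padding: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if len(self.per_atom_masses) != n or len(self.widths) != n:
            raise InvariantError("per-atom masses and widths must match atom count")
        if any(m < 0 for m in self.per_atom_masses):
            raise InvariantError("masses must be nonnegative")
        if any(w <= 0 for w in self.widths):
            raise InvariantError("widths must be positive")
        pad = self.effective_padding
        if pad < 4.0 * max(self.widths) - 1e-12:
            raise InvariantError("padding must be at least 4x the largest width")

    @property
    def effective_padding(self) -> float:
        return 4.0 * max(self.widths) if self.padding is None else self.padding

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(origin, axes) of the orthogonal fixture grid.

        Grid points sit at voxel centers, so the midpoint-rule quadrature is
        exact to the stated tolerance and a box symmetric under an atom swap
        yields a sampled field with the same symmetry.
        """
        pos = np.array([a.position for a in self.atoms])
        lo = pos.min(axis=0) - self.effective_padding
        hi = pos.max(axis=0) + self.effective_padding
        steps = (hi - lo) / np.asarray(self.grid_shape)
        return lo + 0.5 * steps, np.diag(steps)


def make_density(spec: FixtureSpec, quantity: str = "density") -> ScalarField:
    """Sum-of-Gaussians promolecule density on the spec's grid.

    ρ(r) = Σ_A mass_A (2πσ_A²)^(−3/2) exp(−|r−R_A|²/(2σ_A²)); the grid
    integral matches Σ masses to better than 1e-3 relative by construction.
    """
    origin, axes = spec.grid()
    nx, ny, nz = spec.grid_shape
    i = np.arange(nx)[:, None, None, None]
    j = np.arange(ny)[None, :, None, None]
    k = np.arange(nz)[None, None, :, None]
    pts = origin + i * axes[0] + j * axes[1] + k * axes[2]
    values = np.zeros(spec.grid_shape)
    for atom, mass, sigma in zip(spec.atoms, spec.per_atom_masses, spec.widths):
        if mass == 0.0:
            continue
        d2 = np.sum((pts - np.asarray(atom.position)) ** 2, axis=-1)
        values += mass * (2.0 * np.pi * sigma**2) ** -1.5 * np.exp(-d2 / (2.0 * sigma**2))
    return ScalarField(
        origin=origin, axes=axes, values=values, atoms=list(spec.atoms), quantity=quantity
    )


def make_fukui_pair(
    spec_n: FixtureSpec, delta_masses
) -> tuple[ScalarField, ScalarField, tuple[float, ...]]:
    """Densities (ρ_N, ρ_N±1) differing by one electron with known placement.

    The second field adds ``delta_masses`` (which must sum to 1) to the
    per-atom masses on the *same* grid, so the Fukui function of the pair has
    exact per-atom condensed masses equal to ``delta_masses`` — returned as
    the analytic oracle.
    """
    deltas = tuple(float(d) for d in delta_masses)
    if len(deltas) != len(spec_n.atoms):
        raise InvariantError("one delta mass per atom required")
    if abs(sum(deltas) - 1.0) > 1e-12:
        raise InvariantError(f"delta masses must sum to 1, got {sum(deltas)!r}")
    rho_n = make_density(spec_n)
    spec_pm = FixtureSpec(
        atoms=spec_n.atoms,
        per_atom_masses=tuple(m + d for m, d in zip(spec_n.per_atom_masses, deltas)),
        widths=spec_n.widths,
        grid_shape=spec_n.grid_shape,
        padding=spec_n.effective_padding,
        seed=spec_n.seed,
    )
    rho_pm = make_density(spec_pm)
    return rho_n, rho_pm, deltas


def make_kid_records(
    label: str,
    eps_h: float,
    eps_l: float,
    delta_i: float = 0.0,
    delta_a: float = 0.0,
    eps_somo_offset: float = 0.0,
) -> tuple[FrontierRecord, ChargeStateEnergies]:
    """Frontier/charge-state pair with prescribed Koopmans deviations.

    With the N-electron total energy anchored at 0, the charge-state energies
    are built so that I = −ε_H + δ_I and A = −ε_L − δ_A; the resulting KID
    residuals are exactly |δ_I|, |δ_A|, and ΔSL is |eps_somo_offset|. Only
    energy differences enter any downstream formula, so the anchor is
    immaterial.
    """
    for name, v in (("eps_h", eps_h), ("eps_l", eps_l), ("delta_i", delta_i),
                    ("delta_a", delta_a), ("eps_somo_offset", eps_somo_offset)):
        if not math.isfinite(v):
            raise InvariantError(f"{name} must be finite")
    fr = FrontierRecord(
        label=label,
        epsilon_homo=eps_h,
        epsilon_lumo=eps_l,
        epsilon_somo_anion=eps_l + eps_somo_offset,
        source="synthetic",
    )
    e_n = 0.0
    i_pot = -eps_h + delta_i
    e_aff = -eps_l - delta_a
    cs = ChargeStateEnergies(
        label=label, e_n=e_n, e_n_minus_1=e_n + i_pot, e_n_plus_1=e_n - e_aff
    )
    return fr, cs


def random_fixture_spec(
    seed: int,
    n_atoms: int = 2,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    min_separation_sigmas: float = 4.0,
) -> FixtureSpec:
    """Seeded random promolecule spec (bit-reproducible for a fixed seed).

    Atoms are placed with pairwise separation of at least
    ``min_separation_sigmas`` × the largest length scale in play — the two
    density widths and the condensation (promolecule weight) width of the
    element — so that "well separated" holds for the partition as well as for
    the densities. Masses are drawn from [0.5, 6.0] electrons and widths from
    [0.4, 0.9] bohr.
    """
    from .local_descriptors import atomic_width

    rng = np.random.default_rng(seed)
    widths = tuple(rng.uniform(0.4, 0.9) for _ in range(n_atoms))
    masses = tuple(rng.uniform(0.5, 6.0) for _ in range(n_atoms))
    weight_width = atomic_width(AtomSite(element="C", nuclear_charge=6.0, position=(0, 0, 0)))
    positions: list[np.ndarray] = []
    while len(positions) < n_atoms:
        cand = rng.uniform(-4.0, 4.0, size=3)
        ok = all(
            np.linalg.norm(cand - p)
            >= min_separation_sigmas
            * max(widths[len(positions)], widths[i], weight_width)
            for i, p in enumerate(positions)
        )
        if ok:
            positions.append(cand)
    atoms = tuple(
        AtomSite(element="C", nuclear_charge=6.0, position=tuple(p)) for p in positions
    )
    return FixtureSpec(
        atoms=atoms,
        per_atom_masses=masses,
        widths=widths,
        grid_shape=grid_shape,
        seed=seed,
    )
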