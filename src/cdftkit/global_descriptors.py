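"""Global conceptual-DFT reactivity descriptors and Koopmans-compliance checks.

All descriptors derive from a vertical ionization potential I and electron
affinity A, obtained either from frontier-orbital energies (``orbital`` mode,
I = −ε_H, A = −ε_L — the Koopmans-like identification valid for functionals
such as MN12SX) or from ΔSCF total-energy differences (``deltascf`` mode,
I = E(N−1) − E(N), A = E(N) − E(N+1)):

    χ   = (I + A)/2              electronegativity  (μ = −χ)
    η   = I − A                  global hardness
    ω   = χ²/(2η)                electrophilicity
    S   = 1/η                    global softness
    ω−  = (3I + A)²/(16η)        electrodonating power
    ω+  = (I + 3A)²/(16η)        electroaccepting power
    Δω± = ω− + ω+                net electrophilicity

The nucleophilicity index N = ε_H − ε_H(TCE) shifts the HOMO energy by a
tetracyanoethylene reference; molecules with N > 3 eV count as strong
nucleophiles. N and the HOMO–LUMO gap are always orbital quantities
regardless of mode.

The KID (Koopmans-in-DFT) metrics quantify how well a functional obeys the
identifications above:

    J_I  = |ε_H + E(N−1) − E(N)|
    J_A  = |ε_L + E(N) − E(N+1)|
    J_HL = sqrt(J_I² + J_A²)
    ΔSL  = |ε_SOMO(anion) − ε_L(neutral)|

Values near zero mean the orbital energies can stand in for ΔSCF I and A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateHardnessError, InvariantError, MissingDataError
from .records import ChargeStateEnergies, FrontierRecord

__all__ = [
    "TCE_HOMO_EV",
    "KID_THRESHOLD_EV",
    "STRONG_NUCLEOPHILE_EV",
    "GlobalDescriptors",
    "KIDReport",
    "ionization_potential",
    "electron_affinity",
    "electrophilicity_from_chi_eta",
    "nucleophilicity",
    "global_descriptors",
    "kid_report",
]

#: Default HOMO energy (eV) of the tetracyanoethylene (TCE) reference used by
#: the nucleophilicity index. Back-derived from the discodermin A record:
#: ε_H(TCE) = ε_H(A) − N(A) = −5.6567 − 3.4645 = −9.1212 eV. Override per call
#: if a different reference level is wanted.
TCE_HOMO_EV = -9.1212

#: Default J_HL ceiling (eV) for the Koopmans-compliance verdict. Functionals
#: whose combined KID residual stays below ~0.1 eV behave Koopmans-like.
KID_THRESHOLD_EV = 0.10

#: Nucleophilicity above which a molecule counts as a strong nucleophile (eV).
STRONG_NUCLEOPHILE_EV = 3.0


@dataclass(frozen=True)
class GlobalDescriptors:
    """Global reactivity descriptors of one molecule, all in eV (S in eV⁻¹).

    ``mode`` records whether I and A came from orbital energies or from ΔSCF
    total-energy differences; instances of different modes are never merged
    into one table silently.
    """

    label: str
    chi: float
    eta: float
    omega: float
    softness: float
    nucleophilicity: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float
    gap: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("orbital", "deltascf"):
            raise InvariantError(f"{self.label!r}: unknown mode {self.mode!r}")
        if not self.eta > 0:
            raise InvariantError(f"{self.label!r}: stored hardness must be positive")
        if abs(self.net_electrophilicity - (self.omega_plus + self.omega_minus)) > 1e-10:
            raise InvariantError(f"{self.label!r}: Δω± must equal ω+ + ω−")
        if abs((self.omega_minus - self.omega_plus) - self.chi) > 1e-9:
            raise InvariantError(f"{self.label!r}: ω− − ω+ must equal χ")

    @property
    def mu(self) -> float:
        """Chemical potential μ = −χ (eV)."""
        return -self.chi

    @property
    def is_strong_nucleophile(self) -> bool:
        return self.nucleophilicity > STRONG_NUCLEOPHILE_EV


@dataclass(frozen=True)
class KIDReport:
    """KID residuals (eV) and the compliance verdict for one molecule."""

    label: str
    j_i: float
    j_a: float
    j_hl: float
    delta_sl: float | None
    compliant: bool
    threshold: float

    def __post_init__(self) -> None:
        if self.j_i < 0 or self.j_a < 0:
            raise InvariantError(f"{self.label!r}: KID residuals must be nonnegative")
        hi = max(self.j_i, self.j_a)
        if not (hi - 1e-12 <= self.j_hl <= self.j_i + self.j_a + 1e-12):
            raise InvariantError(f"{self.label!r}: J_HL outside its triangle bounds")


def ionization_potential(cs: ChargeStateEnergies) -> float:
    """Vertical ionization potential I = E(N−1) − E(N) in eV."""
    return cs.e_n_minus_1 - cs.e_n


def electron_affinity(cs: ChargeStateEnergies) -> float:
    """Vertical electron affinity A = E(N) − E(N+1) in eV.

    Negative values (unbound anion) are legal and propagate unchanged.
    """
    return cs.e_n - cs.e_n_plus_1


def electrophilicity_from_chi_eta(chi: float, eta: float) -> float:
    """ω = χ²/(2η); raises on η ≤ 0."""
    if not eta > 0:
        raise DegenerateHardnessError(f"hardness must be positive, got {eta:g} eV")
    return chi * chi / (2.0 * eta)


def nucleophilicity(fr: FrontierRecord, tce_homo: float = TCE_HOMO_EV) -> float:
    """Nucleophilicity index N = ε_H − ε_H(TCE) in eV."""
    if not math.isfinite(tce_homo):
        raise InvariantError("TCE reference HOMO must be finite")
    return fr.epsilon_homo - tce_homo


def _ia(
    fr: FrontierRecord,
    cs: ChargeStateEnergies | None,
    mode: str,
) -> tuple[float, float]:
    if mode == "orbital":
        return -fr.epsilon_homo, -fr.epsilon_lumo
    if mode == "deltascf":
        if cs is None:
            raise MissingDataError(
                f"{fr.label!r}: deltascf mode needs charge-state energies"
            )
        return ionization_potential(cs), electron_affinity(cs)
    raise InvariantError(f"unknown mode {mode!r}")


def global_descriptors(
    fr: FrontierRecord,
    cs: ChargeStateEnergies | None = None,
    mode: str = "orbital",
    tce_homo: float = TCE_HOMO_EV,
) -> GlobalDescriptors:
    """Compute the full global-descriptor set for one molecule.

    In ``orbital`` mode I = −ε_H and A = −ε_L; in ``deltascf`` mode they come
    from the charge-state total energies. The HOMO–LUMO gap and the
    nucleophilicity N are orbital quantities in either mode.
    """
    i_pot, e_aff = _ia(fr, cs, mode)
    eta = i_pot - e_aff
    if not eta > 0:
        raise DegenerateHardnessError(
            f"{fr.label!r}: hardness η = I − A = {eta:g} eV is not positive"
        )
    chi = 0.5 * (i_pot + e_aff)
    omega = electrophilicity_from_chi_eta(chi, eta)
    omega_minus = (3.0 * i_pot + e_aff) ** 2 / (16.0 * eta)
    omega_plus = (i_pot + 3.0 * e_aff) ** 2 / (16.0 * eta)
    return GlobalDescriptors(
        label=fr.label,
        chi=chi,
        eta=eta,
        omega=omega,
        softness=1.0 / eta,
        nucleophilicity=nucleophilicity(fr, tce_homo),
        omega_minus=omega_minus,
        omega_plus=omega_plus,
        net_electrophilicity=omega_minus + omega_plus,
        gap=fr.gap,
        mode=mode,
    )


def kid_report(
    fr: FrontierRecord,
    cs: ChargeStateEnergies,
    threshold: float = KID_THRESHOLD_EV,
) -> KIDReport:
    """Compute the KID residuals for one molecule and issue a verdict.

    ΔSL is filled only when the record carries the radical anion's SOMO.
    """
    if cs is None:
        raise MissingDataError(f"{fr.label!r}: KID analysis needs charge-state energies")
    if not threshold > 0:
        raise InvariantError("KID threshold must be positive")
    j_i = abs(fr.epsilon_homo + cs.e_n_minus_1 - cs.e_n)
    j_a = abs(fr.epsilon_lumo + cs.e_n - cs.e_n_plus_1)
    j_hl = math.hypot(j_i, j_a)
    delta_sl = (
        abs(fr.epsilon_somo_anion - fr.epsilon_lumo)
        if fr.epsilon_somo_anion is not None
        else None
    )
    return KIDReport(
        label=fr.label,
        j_i=j_i,
        j_a=j_a,
        j_hl=j_hl,
        delta_sl=delta_sl,
        compliant=j_hl <= threshold,
        threshold=threshold,
    )
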