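"""Bundled reference dataset: discodermins A–H.

Frontier-orbital energies (HOMO and LUMO of the neutral, SOMO of the radical
anion, all eV) of the eight discodermin cyclodepsipeptides computed with the
MN12SX/Def2TZVP model chemistry in water, together with the published global
descriptors and KID residuals reported alongside them. The orbital energies
are inputs here — reproducing them would require the original DFT runs — and
the published descriptor values serve as regression references for the
descriptor algebra.

Note on published-value provenance: the tabulated χ, η, ω, S are ΔSCF-based
while ω−, ω+, Δω± are orbital-based; the reference softness entry for
discodermin E (0.2584) is inconsistent with 1/η = 0.2684 and is suspected to
carry a digit typo.
"""

from __future__ import annotations

from .records import FrontierRecord

__all__ = [
    "DISCODERMIN_LABELS",
    "DISCODERMIN_FRONTIER",
    "DISCODERMIN_KID_PUBLISHED",
    "DISCODERMIN_GLOBAL_PUBLISHED",
    "frontier_records",
]

DISCODERMIN_LABELS = tuple(f"Discodermin {x}" for x in "ABCDEFGH")

#: label -> (HOMO, LUMO, SOMO of radical anion), eV.
DISCODERMIN_FRONTIER = {
    "Discodermin A": (-5.6567, -1.5755, -1.5356),
    "Discodermin B": (-5.6589, -1.4055, -1.3577),
    "Discodermin C": (-5.6347, -1.3674, -1.5245),
    "Discodermin D": (-5.6793, -1.4667, -1.4257),
    "Discodermin E": (-5.8352, -2.1002, -2.1114),
    "Discodermin F": (-5.6423, -1.3260, -1.3223),
    "Discodermin G": (-5.5677, -0.9766, -0.9822),
    "Discodermin H": (-5.7182, -1.1391, -1.1123),
}

#: label -> (J_I, J_A, J_HL, ΔSL), eV, as published (3 decimals).
DISCODERMIN_KID_PUBLISHED = {
    "Discodermin A": (0.048, 0.013, 0.050, 0.040),
    "Discodermin B": (0.039, 0.022, 0.045, 0.048),
    "Discodermin C": (0.048, 0.013, 0.050, 0.040),
    "Discodermin D": (0.044, 0.018, 0.047, 0.041),
    "Discodermin E": (0.002, 0.007, 0.007, 0.011),
    "Discodermin F": (0.060, 0.005, 0.060, 0.003),
    "Discodermin G": (0.047, 0.003, 0.047, 0.005),
    "Discodermin H": (0.051, 0.019, 0.054, 0.029),
}

#: label -> (χ, η, ω, S, N, ω−, ω+, Δω±); eV (S in eV⁻¹), as published.
DISCODERMIN_GLOBAL_PUBLISHED = {
    "Discodermin A": (3.6339, 4.1418, 1.5941, 0.2414, 3.4645, 5.2672, 1.6511, 6.9183),
    "Discodermin B": (3.5410, 4.3143, 1.4531, 0.2318, 3.4622, 4.9652, 1.4330, 6.3981),
    "Discodermin C": (3.5524, 4.2590, 1.4816, 0.2348, 3.4865, 4.8896, 1.3885, 6.2781),
    "Discodermin D": (3.5858, 4.2747, 1.5040, 0.2339, 3.4420, 5.0803, 1.5073, 6.5876),
    "Discodermin E": (3.9703, 3.7254, 2.1157, 0.2584, 3.2860, 6.4321, 2.4644, 8.8966),
    "Discodermin F": (3.5118, 4.3812, 1.4075, 0.2283, 3.4789, 4.8243, 1.3401, 6.1644),
    "Discodermin G": (3.2971, 4.6348, 1.1728, 0.2158, 3.5535, 4.2552, 0.9830, 5.2382),
    "Discodermin H": (3.4446, 4.6494, 1.2760, 0.2151, 3.4029, 4.5677, 1.1391, 5.7068),
}


def frontier_records() -> list[FrontierRecord]:
    """The eight discodermin frontier records, in published row order."""
    return [
        FrontierRecord(
            label=label,
            epsilon_homo=h,
            epsilon_lumo=l,
            epsilon_somo_anion=s,
            source="MN12SX/Def2TZVP/H2O",
        )
        for label, (h, l, s) in DISCODERMIN_FRONTIER.items()
    ]
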