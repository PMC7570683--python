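"""Unit constants. The canonical internal energy unit is eV; lengths are bohr."""

#: CODATA 2018 hartree-to-electronvolt conversion.
EV_PER_HARTREE = 27.211386245988

#: Bohr radii per angstrom.
BOHR_PER_ANGSTROM = 1.8897259886


def to_ev(value: float, unit: str) -> float:
    """Convert an energy in ``unit`` ('eV' or 'hartree') to eV."""
    u = unit.lower()
    if u in ("ev", "electronvolt"):
        return float(value)
    if u in ("hartree", "ha", "au"):
        return float(value) * EV_PER_HARTREE
    raise ValueError(f"unknown energy unit: {unit!r}")
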