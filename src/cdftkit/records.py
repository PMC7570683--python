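"""Frontier-orbital and charge-state energy records with file readers.

Input files are either delimited text (CSV/TSV with a header row) or a JSON
array of objects. Column/key names are matched case-insensitively:

* frontier records: ``label``, ``homo``, ``lumo``, optional ``somo``
* charge-state energies: ``label``, ``e_n``, ``e_n_minus_1``, ``e_n_plus_1``

Energies may be given in eV (default) or hartree; everything is normalized to
eV on ingestion. Unicode minus signs (U+2212) are accepted anywhere a number
is expected. Record order is preserved — tables render in input order.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import FormatError, InvariantError
from .units import to_ev

__all__ = [
    "FrontierRecord",
    "ChargeStateEnergies",
    "read_frontier_records",
    "read_charge_state_energies",
    "write_frontier_records",
]


def _parse_float(text: str) -> float:
    return float(str(text).strip().replace("−", "-"))


@dataclass(frozen=True)
class FrontierRecord:
    """Frontier-orbital energies (eV) of one molecule.

    ``epsilon_somo_anion`` is the HOMO of the N+1-electron radical anion (the
    SOMO), used by the ΔSL Koopmans-compliance diagnostic.
    """

    label: str
    epsilon_homo: float
    epsilon_lumo: float
    epsilon_somo_anion: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        values = [self.epsilon_homo, self.epsilon_lumo]
        if self.epsilon_somo_anion is not None:
            values.append(self.epsilon_somo_anion)
        if not all(math.isfinite(v) for v in values):
            raise InvariantError(f"{self.label!r}: non-finite orbital energy")
        if self.epsilon_homo > self.epsilon_lumo:
            raise InvariantError(
                f"{self.label!r}: HOMO ({self.epsilon_homo:g} eV) lies above "
                f"LUMO ({self.epsilon_lumo:g} eV)"
            )

    @property
    def gap(self) -> float:
        """HOMO–LUMO gap ε_L − ε_H in eV."""
        return self.epsilon_lumo - self.epsilon_homo


@dataclass(frozen=True)
class ChargeStateEnergies:
    """Ground-state total energies (eV) of the N, N−1 and N+1 electron systems.

    These feed the ΔSCF identifications I = E(N−1) − E(N) and
    A = E(N) − E(N+1). All three energies are mandatory; a partial record is
    rejected at read time with a distinct error.
    """

    label: str
    e_n: float
    e_n_minus_1: float
    e_n_plus_1: float

    def __post_init__(self) -> None:
        for name in ("e_n", "e_n_minus_1", "e_n_plus_1"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise InvariantError(f"{self.label!r}: {name} missing or non-finite")


# ---------------------------------------------------------------------------
# readers


def _rows_from_source(source: str | Path | IO[str]) -> tuple[list[dict], str]:
    """Return (list of row dicts with lower-cased keys, format tag)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        data = json.loads(text)
        if isinstance(data, dict):
            data = [data]
        rows = [{str(k).strip().lower(): v for k, v in row.items()} for row in data]
        return rows, "json"
    # delimited text; sniff comma vs tab vs semicolon
    sample = stripped.splitlines()[0] if stripped else ""
    delim = "\t" if "\t" in sample else (";" if ";" in sample and "," not in sample else ",")
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    rows = []
    for row in reader:
        rows.append(
            {
                (k or "").strip().lower(): (v.strip() if isinstance(v, str) else v)
                for k, v in row.items()
                if k is not None
            }
        )
    return rows, "delimited"


def _require(row: dict, names: Sequence[str], what: str, index: int) -> str:
    for n in names:
        if n in row and row[n] not in (None, ""):
            return row[n]
    raise FormatError(
        f"record {index}: missing required column {names[0]!r} for {what}"
    )


def _optional(row: dict, names: Sequence[str]) -> str | None:
    for n in names:
        if n in row and row[n] not in (None, ""):
            return row[n]
    return None


def read_frontier_records(
    source: str | Path | IO[str], unit: str = "eV"
) -> list[FrontierRecord]:
    """Read frontier-orbital records from delimited text or JSON.

    Parameters
    ----------
    source:
        Path or open text stream.
    unit:
        ``'eV'`` or ``'hartree'``; all energies are converted to eV using
        1 hartree = 27.211386245988 eV.
    """
    rows, _ = _rows_from_source(source)
    records: list[FrontierRecord] = []
    for i, row in enumerate(rows):
        label = str(_require(row, ("label", "name", "molecule"), "frontier record", i))
        homo = to_ev(_parse_float(_require(row, ("homo", "epsilon_homo"), "frontier record", i)), unit)
        lumo = to_ev(_parse_float(_require(row, ("lumo", "epsilon_lumo"), "frontier record", i)), unit)
        somo_raw = _optional(row, ("somo", "epsilon_somo_anion", "somo_anion"))
        somo = to_ev(_parse_float(somo_raw), unit) if somo_raw is not None else None
        src = str(_optional(row, ("source",)) or "")
        records.append(
            FrontierRecord(
                label=label,
                epsilon_homo=homo,
                epsilon_lumo=lumo,
                epsilon_somo_anion=somo,
                source=src,
            )
        )
    return records


def read_charge_state_energies(
    source: str | Path | IO[str], unit: str = "eV"
) -> list[ChargeStateEnergies]:
    """Read N/N−1/N+1 total-energy records; same formats as frontier records."""
    rows, _ = _rows_from_source(source)
    out: list[ChargeStateEnergies] = []
    for i, row in enumerate(rows):
        label = str(_require(row, ("label", "name", "molecule"), "charge-state record", i))
        vals = {}
        for attr, names in (
            ("e_n", ("e_n", "en", "e(n)")),
            ("e_n_minus_1", ("e_n_minus_1", "e_nm1", "e(n-1)")),
            ("e_n_plus_1", ("e_n_plus_1", "e_np1", "e(n+1)")),
        ):
            vals[attr] = to_ev(
                _parse_float(_require(row, names, "charge-state record", i)), unit
            )
        out.append(ChargeStateEnergies(label=label, **vals))
    return out


def write_frontier_records(records: Iterable[FrontierRecord], path: str | Path) -> None:
    """Write records as CSV (eV) with columns label, homo, lumo, somo."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "homo", "lumo", "somo"])
        for r in records:
            somo = "" if r.epsilon_somo_anion is None else repr(r.epsilon_somo_anion)
            w.writerow([r.label, repr(r.epsilon_homo), repr(r.epsilon_lumo), somo])
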