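"""Table renderers for global descriptors, KID reports and condensed values.

Output formats: ``csv``, ``json``, ``markdown``. Numbers are rounded
half-even — descriptors at the configured decimals (default 4), KID residuals
and ΔSL at 3 decimals to match the precision such tables are usually printed
at. Rendering is pure: the same records and config always produce
byte-identical text. Any unicode minus in labels/inputs is normalized to the
ASCII hyphen-minus on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

from .errors import InvariantError
from .global_descriptors import GlobalDescriptors, KIDReport
from .local_descriptors import CondensedVector
from .records import FrontierRecord

__all__ = ["ReportConfig", "render_global_table", "render_kid_table", "render_condensed_table"]

_FORMATS = ("csv", "json", "markdown")
_KID_DECIMALS = 3


@dataclass(frozen=True)
class ReportConfig:
    output_format: str = "markdown"
    decimals: int = 4
    mode: str = "orbital"
    tce_homo: float = -9.1212
    kid_threshold: float = 0.10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.output_format not in _FORMATS:
            raise InvariantError(f"unknown output format {self.output_format!r}")
        if self.decimals < 0:
            raise InvariantError("decimals must be >= 0")


def fmt(value: float | None, decimals: int) -> str:
    """Round half-even and render with fixed decimals; None renders as an em dash."""
    if value is None:
        return "—"
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    d = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN)
    return str(d).replace("−", "-")


def _table(header: Sequence[str], rows: Sequence[Sequence[str]], cfg: ReportConfig,
           footnote: str | None = None) -> str:
    if cfg.output_format == "csv":
        lines = [",".join(header)]
        lines += [",".join(r) for r in rows]
        if footnote:
            lines.append(f"# {footnote}")
        return "\n".join(lines) + "\n"
    if cfg.output_format == "markdown":
        lines = ["| " + " | ".join(header) + " |"]
        lines.append("|" + "|".join(" --- " for _ in header) + "|")
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        if footnote:
            lines.append("")
            lines.append(f"*{footnote}*")
        return "\n".join(lines) + "\n"
    # json
    payload: dict = {"columns": list(header), "rows": [list(r) for r in rows]}
    if footnote:
        payload["footnote"] = footnote
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"


def render_global_table(records: Sequence[GlobalDescriptors], cfg: ReportConfig) -> str:
    """Render a global-descriptor table (χ η ω S N ω− ω+ Δω±), one row per molecule.

    All records must share a provenance mode; the mode is always emitted as a
    footnote so orbital and ΔSCF numbers can never be confused.
    """
    if not records:
        raise InvariantError("no records to render")
    modes = {r.mode for r in records}
    if len(modes) > 1:
        raise InvariantError(f"mixed descriptor modes in one table: {sorted(modes)}")
    header = ["label", "chi", "eta", "omega", "S", "N", "omega-", "omega+", "net"]
    d = cfg.decimals
    rows = [
        [
            r.label,
            fmt(r.chi, d), fmt(r.eta, d), fmt(r.omega, d), fmt(r.softness, d),
            fmt(r.nucleophilicity, d), fmt(r.omega_minus, d), fmt(r.omega_plus, d),
            fmt(r.net_electrophilicity, d),
        ]
        for r in records
    ]
    mode = next(iter(modes))
    note = f"mode: {mode} (I,A from " + (
        "frontier orbital energies)" if mode == "orbital" else "ΔSCF total-energy differences)"
    )
    return _table(header, rows, cfg, note)


def render_kid_table(
    reports: Sequence[KIDReport], frontier: Sequence[FrontierRecord], cfg: ReportConfig
) -> str:
    """Render a Koopmans-compliance table: orbital energies, gap, J and ΔSL columns.

    ``reports`` and ``frontier`` are matched by label; an orphan on either
    side is an error. Orbital energies and the gap print at ``cfg.decimals``;
    J and ΔSL at 3 decimals.
    """
    if not reports:
        raise InvariantError("no records to render")
    by_label = {f.label: f for f in frontier}
    for r in reports:
        if r.label not in by_label:
            raise InvariantError(f"no frontier record for label {r.label!r}")
    header = ["label", "HOMO", "LUMO", "SOMO", "gap", "J(I)", "J(A)", "J(HL)", "dSL", "compliant"]
    d = cfg.decimals
    rows = []
    for r in reports:
        f = by_label[r.label]
        rows.append(
            [
                r.label,
                fmt(f.epsilon_homo, d), fmt(f.epsilon_lumo, d),
                fmt(f.epsilon_somo_anion, d), fmt(f.gap, d),
                fmt(r.j_i, _KID_DECIMALS), fmt(r.j_a, _KID_DECIMALS),
                fmt(r.j_hl, _KID_DECIMALS), fmt(r.delta_sl, _KID_DECIMALS),
                "yes" if r.compliant else "no",
            ]
        )
    note = f"compliant: J(HL) <= {fmt(reports[0].threshold, 2)} eV"
    return _table(header, rows, cfg, note)


def render_condensed_table(vectors: Sequence[CondensedVector], cfg: ReportConfig) -> str:
    """Render condensed per-atom values, one column per descriptor."""
    if not vectors:
        raise InvariantError("no condensed vectors to render")
    labels = vectors[0].labels
    for v in vectors:
        if v.labels != labels:
            raise InvariantError("condensed vectors disagree on atom labels")
    header = ["atom"] + [v.quantity for v in vectors]
    rows = [
        [labels[i]] + [fmt(v.values[i], cfg.decimals) for v in vectors]
        for i in range(len(labels))
    ]
    note = f"scheme: {vectors[0].scheme}"
    return _table(header, rows, cfg, note)
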