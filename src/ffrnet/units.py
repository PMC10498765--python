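"""Unit conversion constants and helpers.

All internal computation is in SI (m, m², Pa, Pa·s/m³, m³/s). File and CLI
interfaces accept the clinical units the field reports in (mm, mmHg, L/min,
mL/s) with explicit declarations.
"""

from __future__ import annotations

MMHG_TO_PA: float = 133.322
PA_TO_MMHG: float = 1.0 / MMHG_TO_PA

LMIN_TO_M3S: float = 1.0e-3 / 60.0  # L/min -> m³/s
MLS_TO_M3S: float = 1.0e-6          # mL/s -> m³/s

MM_TO_M: float = 1.0e-3
CM_TO_M: float = 1.0e-2

#: Pa·s/m³ per (mmHg·s/mL) — the clinical resistance unit.
MMHG_S_ML_TO_SI: float = MMHG_TO_PA / MLS_TO_M3S

_LENGTH_FACTORS = {"m": 1.0, "mm": MM_TO_M, "cm": CM_TO_M}


def length_to_si(value: float, unit: str) -> float:
    """Convert a length from a declared unit ('m', 'mm' or 'cm') to metres."""
    try:
        return value * _LENGTH_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}; expected one of m, mm, cm")


def length_from_si(value: float, unit: str) -> float:
    try:
        return value / _LENGTH_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}; expected one of m, mm, cm")
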