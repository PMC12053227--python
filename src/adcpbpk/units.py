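"""Centralized unit registry for analyte concentrations.

The simulator works internally in nM and hours; observed data arrive in
whatever unit the source study reported (µg/mL for antibodies, ng/mL for
the payload).  All conversions between mass-based units and molarity go
through this module so that molecular weights are applied in exactly one
place.
"""

from __future__ import annotations

#: default molecular weight of an IgG-class antibody (g/mol)
MW_MAB = 150_000.0
#: molecular weight of monomethyl auristatin E (g/mol)
MW_MMAE = 717.98

HOURS_PER_DAY = 24.0

#: units accepted for observed concentration records
SUPPORTED_UNITS = ("nM", "ng/mL", "ug/mL")


class UnitError(ValueError):
    """Raised when a concentration unit is not recognized."""


def to_nanomolar(value: float, unit: str, mw: float) -> float:
    """Convert a concentration to nM.

    Parameters
    ----------
    value : concentration in ``unit``
    unit : one of ``nM``, ``ng/mL``, ``ug/mL`` (``µg/mL`` accepted)
    mw : molecular weight of the analyte in g/mol
    """
    u = unit.replace("µ", "u").strip()
    if u == "nM":
        return value
    if u == "ng/mL":
        # ng/mL == µg/L; / MW (g/mol) -> µmol/L * 1e-3 -> nM * 1e3 / MW
        return value * 1e3 / mw
    if u == "ug/mL":
        return value * 1e6 / mw
    raise UnitError(f"unsupported concentration unit {unit!r}; expected one of {SUPPORTED_UNITS}")


def from_nanomolar(value: float, unit: str, mw: float) -> float:
    """Convert a concentration in nM to ``unit`` (inverse of :func:`to_nanomolar`)."""
    u = unit.replace("µ", "u").strip()
    if u == "nM":
        return value
    if u == "ng/mL":
        return value * mw / 1e3
    if u == "ug/mL":
        return value * mw / 1e6
    raise UnitError(f"unsupported concentration unit {unit!r}; expected one of {SUPPORTED_UNITS}")


def dose_mgkg_to_nmol(dose_mgkg: float, body_weight_kg: float, mw: float) -> float:
    """Convert an mg/kg dose to nmol for a given body weight and molecular weight."""
    dose_mg = dose_mgkg * body_weight_kg
    return dose_mg * 1e6 / mw
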