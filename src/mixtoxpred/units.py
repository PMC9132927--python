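"""Concentration units and their inter-conversion.

The package works with five aquatic-toxicology concentration units split
into two families: molar (nM, uM, mM) and mass-per-volume (ug/L, mg/L).
Conversions within a family are exact metric-prefix arithmetic; crossing
the family boundary requires the molecular weight (g/mol) of the chemical.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "UNITS",
    "MOLAR_UNITS",
    "MASS_UNITS",
    "ConcentrationValue",
    "UnitError",
    "normalize_unit",
    "convert",
    "convert_concentration",
]


class UnitError(ValueError):
    """Unknown unit or a molar<->mass conversion without a molecular weight."""


# factors to the family reference unit (uM for molar, mg/L for mass)
MOLAR_UNITS = {"nM": 1e-3, "uM": 1.0, "mM": 1e3}
MASS_UNITS = {"ug/L": 1e-3, "mg/L": 1.0}
UNITS = tuple(MOLAR_UNITS) + tuple(MASS_UNITS)

_ALIASES = {
    "nm": "nM",
    "um": "uM",
    "µm": "uM",   # micro sign
    "μm": "uM",   # greek mu
    "µg/l": "ug/L",
    "μg/l": "ug/L",
    "ug/l": "ug/L",
    "mg/l": "mg/L",
    "mm": "mM",
}


def normalize_unit(unit: str) -> str:
    """Map unit spellings (μM, uM, µM ...) onto the canonical registry names."""
    if unit in MOLAR_UNITS or unit in MASS_UNITS:
        return unit
    key = str(unit).strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnitError(f"unknown concentration unit: {unit!r} (expected one of {UNITS})")


def convert(value: float, unit: str, target_unit: str, mw: float | None = None) -> float:
    """Convert a concentration magnitude between registry units.

    ``mw`` (g/mol) is required only when the conversion crosses the
    molar/mass family boundary; 1 mg/L of a 100 g/mol chemical is 10 uM.
    """
    unit = normalize_unit(unit)
    target_unit = normalize_unit(target_unit)
    if unit == target_unit:
        return float(value)
    src_molar = unit in MOLAR_UNITS
    dst_molar = target_unit in MOLAR_UNITS
    if src_molar and dst_molar:
        return float(value) * MOLAR_UNITS[unit] / MOLAR_UNITS[target_unit]
    if not src_molar and not dst_molar:
        return float(value) * MASS_UNITS[unit] / MASS_UNITS[target_unit]
    if mw is None or not mw > 0:
        raise UnitError(
            f"molecular weight required to convert {unit} -> {target_unit}"
        )
    if src_molar:
        # uM -> mg/L: umol/L * g/mol = ug/L
        um = float(value) * MOLAR_UNITS[unit]
        mg_per_l = um * mw * 1e-3
        return mg_per_l / MASS_UNITS[target_unit]
    mg_per_l = float(value) * MASS_UNITS[unit]
    um = mg_per_l / mw * 1e3
    return um / MOLAR_UNITS[target_unit]


@dataclass(frozen=True)
class ConcentrationValue:
    """A non-negative concentration magnitude with its unit."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        if not self.value >= 0:
            raise ValueError(f"concentration must be non-negative, got {self.value}")

    def to(self, target_unit: str, mw: float | None = None) -> "ConcentrationValue":
        return ConcentrationValue(convert(self.value, self.unit, target_unit, mw), target_unit)


def convert_concentration(
    x: ConcentrationValue, target_unit: str, mw: float | None = None
) -> ConcentrationValue:
    """Functional form of :meth:`ConcentrationValue.to`."""
    return x.to(target_unit, mw)
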