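"""Minimal concentration-unit handling.

Every concentration in the package carries a unit tag (``"M"``, ``"mM"``,
``"uM"``, ``"nM"``).  Arithmetic across tags is never done implicitly:
callers either convert explicitly with :func:`convert` or the consuming
routine raises :class:`UnitError`.  This is deliberately lighter than a
full quantity package — kinetic fitting only ever needs one substrate
unit and one modifier unit per dataset.
"""

from __future__ import annotations

__all__ = ["UnitError", "canonical_unit", "convert", "require_same_unit"]

# decimal exponent relative to molar (kept as integers so conversion
# factors are exact powers of ten)
_EXPONENTS = {"M": 0, "mM": -3, "uM": -6, "nM": -9}

_ALIASES = {
    "m": "M",
    "mm": "mM",
    "um": "uM",
    "µm": "uM",
    "μm": "uM",
    "nm": "nM",
}


class UnitError(ValueError):
    """Inconsistent or unknown concentration units."""


def canonical_unit(unit: str) -> str:
    """Normalize a unit spelling (``"µM"``, ``"um"`` ... -> ``"uM"``)."""
    if unit in _EXPONENTS:
        return unit
    key = unit.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnitError(f"unknown concentration unit {unit!r}; expected one of {sorted(_EXPONENTS)}")


def convert(value, from_unit: str, to_unit: str):
    """Convert ``value`` between concentration units."""
    f, t = canonical_unit(from_unit), canonical_unit(to_unit)
    return value * 10.0 ** (_EXPONENTS[f] - _EXPONENTS[t])


def require_same_unit(unit_a: str, unit_b: str, what: str) -> str:
    """Raise :class:`UnitError` naming ``what`` unless the two tags agree."""
    a, b = canonical_unit(unit_a), canonical_unit(unit_b)
    if a != b:
        raise UnitError(f"unit mismatch for {what}: {a} vs {b} (convert explicitly first)")
    return a
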