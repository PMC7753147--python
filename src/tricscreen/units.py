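"""Concentration unit handling.

Internal storage is always molar.  Files and configs carry explicit unit
tags (``"12.1 uM"``, or value + unit columns) to avoid silent unit bugs
across the nine-orders-of-magnitude range typical of displacement assays
(nanomolar tracer, hundreds-of-micromolar competitor).
"""

from __future__ import annotations

import re

_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "μM": 1e-6,  # μM (greek mu)
    "nM": 1e-9,
    "pM": 1e-12,
}

_PATTERN = re.compile(r"^\s*([-+0-9.eE]+)\s*([pnumµμ]?M)\s*$")


def to_molar(value: "float | str", unit: "str | None" = None) -> float:
    """Convert a tagged concentration to molar.

    ``to_molar("12.1 uM")``, ``to_molar(12.1, "uM")`` and ``to_molar(1.21e-5)``
    (already molar) are all accepted.
    """
    if isinstance(value, str):
        m = _PATTERN.match(value)
        if not m:
            raise ValueError(f"cannot parse concentration {value!r}")
        value, unit = float(m.group(1)), m.group(2)
    if unit is None:
        return float(value)
    try:
        return float(value) * _FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def from_molar(value_m: float, unit: str) -> float:
    """Express a molar concentration in the given unit."""
    try:
        return value_m / _FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None
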