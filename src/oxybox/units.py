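"""Unit constants.

Internal conventions: concentrations in mmol m^-3 (identical to uM),
volumes in m^3, time in years, amounts in mmol, transports in m^3 yr^-1.
Global inventories are reported in Pmol (1e15 mol).
"""

SECONDS_PER_YEAR = 3.15576e7  # Julian year

#: 1 Sverdrup in m^3 yr^-1
SV = 1.0e6 * SECONDS_PER_YEAR

#: mmol per Pmol (1 Pmol = 1e15 mol = 1e18 mmol)
MMOL_PER_PMOL = 1.0e18

#: mmol per mol
MMOL_PER_MOL = 1.0e3


def mmol_to_pmol(x: float) -> float:
    """Convert an amount in mmol to Pmol."""
    return x / MMOL_PER_PMOL


def pmol_to_mmol(x: float) -> float:
    """Convert an amount in Pmol to mmol."""
    return x * MMOL_PER_PMOL
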