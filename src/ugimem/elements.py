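"""Pinned atomic constants.

Monoisotopic masses (mass of the most abundant isotope, Da) are pinned to
IUPAC/CODATA values so that computed product masses are bit-reproducible
across environments and library versions.
"""

from __future__ import annotations

# Da; most abundant isotope of each element.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "Li": 7.01600455,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Al": 26.98153863,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370649,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "Se": 73.9224764,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS = 0.00054857990907  # Da

# 13C natural abundance and the 13C-12C mass difference used by the
# carbon-binomial isotope model.
C13_ABUNDANCE = 0.0107
C13_MASS_SHIFT = 1.0033548378  # Da

WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]
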