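"""Physical constants and isotope data used throughout the package.

All constants are frozen here so every module draws from one table.
CODATA 2018 values for the fundamental constants; isotopic masses and
abundances from the IUPAC/CIAAW compilation (Meija et al., Pure Appl.
Chem. 2016, and the 2021 CIAAW abundance revision for Se).
"""

from __future__ import annotations

# --- fundamental constants (CODATA 2018, exact where SI-defined) ---
BOLTZMANN_J_PER_K = 1.380649e-23  # k_B, J/K (exact)
PLANCK_J_S = 6.62607015e-34  # h, J*s (exact)
AVOGADRO_PER_MOL = 6.02214076e23  # N_A, 1/mol (exact)

# Gas constant expressed in kcal/(mol*K): R = N_A * k_B / 4184
R_KCAL_PER_MOL_K = 1.987204e-3

# Mass of a proton (H+ adduct) in Da, the standard ESI charge carrier.
PROTON_MASS_DA = 1.007276

# Default thermodynamic conditions of the free-energy profile.
STANDARD_TEMPERATURE_K = 298.15


# --- isotope tables: element -> list of (mass in Da, fractional abundance) ---
# Sorted by mass; abundances sum to 1 per element.  Selenium's six isotopes
# give Se-containing species their diagnostic envelope; 80Se (49.80%) is the
# most abundant isotope, which is why the "monoisotopic" convention for Se
# species in HRMS uses 79.9165 Da rather than the lightest isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548351, 0.0107)],
    "N": [(14.0030740044, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317565, 0.00038), (17.9991596129, 0.00205)],
    "F": [(18.9984031627, 1.0)],
    "Na": [(22.9897692820, 1.0)],
    "P": [(30.9737619984, 1.0)],
    "S": [
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.9678670040, 0.0425),
        (35.9670807100, 0.0001),
    ],
    "Se": [
        (73.9224759350, 0.0086),
        (75.9192137040, 0.0923),
        (76.9199141550, 0.0760),
        (77.9173092430, 0.2369),
        (79.9165217620, 0.4980),
        (81.9166994970, 0.0882),
    ],
}


def most_abundant_mass(element: str) -> float:
    """Mass of the most abundant isotope of *element* (HRMS 'monoisotopic')."""
    return max(ISOTOPES[element], key=lambda p: p[1])[0]


def average_mass(element: str) -> float:
    """Abundance-weighted mean isotopic mass of *element*."""
    return sum(m * a for m, a in ISOTOPES[element])
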