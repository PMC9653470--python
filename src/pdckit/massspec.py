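"""Selenium-aware mass bookkeeping for diselenide/selenoether species.

Covers molecular formulas of Sec-containing peptides and their dimers,
polyisotopic envelope computation (selenium's six isotopes give Se species
their diagnostic multi-peak signature), protonated charge-state ladders,
the -1 Se contraction mass shift, and the charge-state-averaged conversion
statistic computed from extracted-ion-chromatogram integrals.

Conventions: "monoisotopic" for Se species follows standard HRMS practice
and uses the most abundant isotope (80Se, 79.9165 Da) rather than the
lightest, the two differing by ~6 Da.  Per-charge conversion assumes equal
ionization efficiency of reactant and product at each charge state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ISOTOPES, PROTON_MASS_DA, average_mass, most_abundant_mass

__all__ = [
    "MolecularFormula",
    "IsotopeEnvelope",
    "XicIntegrals",
    "peptide_formula",
    "isotope_pattern",
    "contraction_mass_shift",
    "charge_ladder",
    "conversion_from_xic",
    "RESIDUE_FORMULAS",
]


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with elemental-composition arithmetic."""

    counts: tuple  # sorted tuple of (element, count)

    @classmethod
    def from_dict(cls, d: dict) -> "MolecularFormula":
        items = tuple(sorted((el, int(n)) for el, n in d.items() if n != 0))
        for el, n in items:
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        if not items:
            raise ValueError("formula must contain at least one atom")
        return cls(items)

    def as_dict(self) -> dict:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return MolecularFormula.from_dict(d)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
        return MolecularFormula.from_dict(d)

    def __mul__(self, n: int) -> "MolecularFormula":
        return MolecularFormula.from_dict({el: c * n for el, c in self.counts})

    __rmul__ = __mul__

    def monoisotopic_mass(self) -> float:
        return sum(most_abundant_mass(el) * n for el, n in self.counts)

    def average_mass(self) -> float:
        return sum(average_mass(el) * n for el, n in self.counts)

    def __str__(self) -> str:
        order = ["C", "H", "N", "O", "P", "S", "Se"]
        d = self.as_dict()
        parts = [f"{el}{d[el]}" for el in order if el in d]
        parts += [f"{el}{n}" for el, n in sorted(d.items()) if el not in order]
        return "".join(parts)


def F(**kwargs) -> MolecularFormula:
    return MolecularFormula.from_dict(kwargs)


# Amino-acid residue formulas (chain units; free peptide = residues + H2O).
# U is selenocysteine: cysteine with Se in place of S.
RESIDUE_FORMULAS: dict[str, MolecularFormula] = {
    "G": F(C=2, H=3, N=1, O=1),
    "A": F(C=3, H=5, N=1, O=1),
    "S": F(C=3, H=5, N=1, O=2),
    "P": F(C=5, H=7, N=1, O=1),
    "V": F(C=5, H=9, N=1, O=1),
    "T": F(C=4, H=7, N=1, O=2),
    "C": F(C=3, H=5, N=1, O=1, S=1),
    "L": F(C=6, H=11, N=1, O=1),
    "I": F(C=6, H=11, N=1, O=1),
    "N": F(C=4, H=6, N=2, O=2),
    "D": F(C=4, H=5, N=1, O=3),
    "Q": F(C=5, H=8, N=2, O=2),
    "K": F(C=6, H=12, N=2, O=1),
    "E": F(C=5, H=7, N=1, O=3),
    "M": F(C=5, H=9, N=1, O=1, S=1),
    "H": F(C=6, H=7, N=3, O=1),
    "F": F(C=9, H=9, N=1, O=1),
    "R": F(C=6, H=12, N=4, O=1),
    "Y": F(C=9, H=9, N=1, O=2),
    "W": F(C=11, H=10, N=2, O=1),
    "U": F(C=3, H=5, N=1, O=1, Se=1),
}

_WATER = F(H=2, O=1)
_H = F(H=1)
_SE = F(Se=1)


def peptide_formula(
    sequence: str,
    termini: str = "free",
    linkage: str = "none",
    partner: MolecularFormula | None = None,
) -> MolecularFormula:
    """Molecular formula of a (seleno)peptide chain or Se-bridged dimer.

    ``sequence`` uses one-letter codes with U = selenocysteine; ``termini``
    is "free" (H-/-OH) or "amide" (H-/-NH2).  Linkages:

    - ``none``: the single chain (selenol as Se-H);
    - ``diselenide_dimer``: 2 x chain - 2 H (Se-Se bond between chains);
    - ``selenoether_dimer``: the diselenide minus one Se (the contraction
      product, formal extrusion of a single selenium atom);
    - ``asymmetric_diselenide``: chain + ``partner`` - 2 H, where the partner
      formula must itself contain selenium.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    chain = None
    for aa in sequence:
        if aa not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue code {aa!r}")
        chain = RESIDUE_FORMULAS[aa] if chain is None else chain + RESIDUE_FORMULAS[aa]
    chain = chain + _WATER
    if termini == "amide":
        chain = MolecularFormula.from_dict(
            {**chain.as_dict(), "O": chain.as_dict()["O"] - 1,
             "N": chain.as_dict().get("N", 0) + 1,
             "H": chain.as_dict()["H"] + 1}
        )
    elif termini != "free":
        raise ValueError(f"unknown termini {termini!r}")

    n_sec = sequence.count("U")
    if linkage == "none":
        return chain
    if n_sec == 0:
        raise ValueError(f"linkage {linkage!r} requires a Sec (U) residue")
    if linkage == "diselenide_dimer":
        return 2 * chain - 2 * _H
    if linkage == "selenoether_dimer":
        return 2 * chain - 2 * _H - _SE
    if linkage == "asymmetric_diselenide":
        if partner is None:
            raise ValueError("asymmetric_diselenide requires a partner formula")
        if partner.as_dict().get("Se", 0) < 1:
            raise ValueError("partner formula must contain selenium")
        return chain + partner - 2 * _H
    raise ValueError(f"unknown linkage {linkage!r}")


@dataclass
class IsotopeEnvelope:
    """Isotopologue (mass, abundance) distribution of a formula.

    ``abundances`` follow the probability convention (sum = 1); the
    ``max_normalized`` view rescales so the base peak is 1, matching how
    spectra are usually drawn.
    """

    masses: np.ndarray  # Da, strictly increasing
    abundances: np.ndarray  # probabilities, sum to 1

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("envelope masses must be strictly increasing")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")

    @property
    def max_normalized(self) -> np.ndarray:
        return self.abundances / self.abundances.max()

    @property
    def base_peak_mass(self) -> float:
        return float(self.masses[np.argmax(self.abundances)])

    def to_tsv(self) -> str:
        lines = ["mass_da\tabundance"]
        lines += [f"{m:.6f}\t{a:.10g}" for m, a in zip(self.masses, self.abundances)]
        return "\n".join(lines) + "\n"


def _aggregate(masses, abunds, resolution):
    """Merge peaks closer than *resolution* Da (abundance-weighted mass)."""
    order = np.argsort(masses)
    masses, abunds = masses[order], abunds[order]
    keys = np.round(masses / resolution).astype(np.int64)
    out_m, out_a = [], []
    start = 0
    for i in range(1, len(keys) + 1):
        if i == len(keys) or keys[i] != keys[start]:
            a = abunds[start:i].sum()
            m = float(np.sum(masses[start:i] * abunds[start:i]) / a)
            out_m.append(m)
            out_a.append(a)
            start = i
    return np.array(out_m), np.array(out_a)


def _convolve(m1, a1, m2, a2, resolution, prune, max_terms=150_000):
    masses = (m1[:, None] + m2[None, :]).ravel()
    abunds = (a1[:, None] * a2[None, :]).ravel()
    keep = abunds > prune
    if keep.any():
        masses, abunds = masses[keep], abunds[keep]
    # Merge at the exact-composition level (distinct isotopologue
    # compositions differ by >= ~1e-4 Da, so a 1e-9 Da grid only collapses
    # true duplicates); coarsen only if the term list still explodes, which
    # perturbs sub-resolution fine structure and is reserved for formulas
    # far beyond the exact regime.
    masses, abunds = _aggregate(masses, abunds, 1e-9)
    if len(masses) > max_terms:
        masses, abunds = _aggregate(masses, abunds, resolution / 10.0)
    if len(masses) > max_terms:
        masses, abunds = _aggregate(masses, abunds, resolution)
    return masses, abunds


def isotope_pattern(
    formula: MolecularFormula,
    prune_threshold: float = 1e-6,
    resolution: float = 1e-3,
) -> IsotopeEnvelope:
    """Isotope envelope of a formula by multinomial convolution.

    Per element the n-atom distribution is built by binary-power
    self-convolution of the elemental isotope table; element distributions
    are then convolved together.  Peaks are aggregated at ``resolution`` Da
    and pruned below ``prune_threshold`` (relative probability) with final
    renormalisation to the probability convention.
    """
    if not (0 < prune_threshold < 0.1):
        raise ValueError("prune_threshold must be in (0, 0.1)")
    for el, _ in formula.counts:
        if el not in ISOTOPES:
            raise ValueError(f"no isotope table for element {el!r}")
    # absolute floor for terms kept during accumulation; everything above
    # it survives to the final binning, where the relative threshold applies
    prune = 1e-16
    masses = np.array([0.0])
    abunds = np.array([1.0])
    for el, n in formula.counts:
        em = np.array([m for m, _ in ISOTOPES[el]])
        ea = np.array([a for _, a in ISOTOPES[el]])
        # binary powering: el^n
        acc_m, acc_a = None, None
        base_m, base_a = em, ea
        k = n
        while k:
            if k & 1:
                if acc_m is None:
                    acc_m, acc_a = base_m, base_a
                else:
                    acc_m, acc_a = _convolve(acc_m, acc_a, base_m, base_a,
                                             resolution, prune)
            k >>= 1
            if k:
                base_m, base_a = _convolve(base_m, base_a, base_m, base_a,
                                           resolution, prune)
        masses, abunds = _convolve(masses, abunds, acc_m, acc_a,
                                   resolution, prune)
    masses, abunds = _aggregate(masses, abunds, resolution)
    keep = abunds / abunds.sum() >= prune_threshold
    masses, abunds = masses[keep], abunds[keep]
    abunds = abunds / abunds.sum()
    return IsotopeEnvelope(masses, abunds)


def contraction_mass_shift(convention: str = "monoisotopic") -> float:
    """Mass shift (Da) of the diselenide -> selenoether contraction: the
    formal extrusion of one selenium atom."""
    if convention == "monoisotopic":
        return -most_abundant_mass("Se")
    if convention == "average":
        return -average_mass("Se")
    raise ValueError(f"unknown mass convention {convention!r}")


def charge_ladder(neutral_mass: float, charges) -> list[float]:
    """m/z values of the [M + zH]z+ ions for each charge in *charges*."""
    if not (neutral_mass > 0 and math.isfinite(neutral_mass)):
        raise ValueError("neutral mass must be positive and finite")
    charges = list(charges)
    if not charges:
        raise ValueError("at least one charge state required")
    out = []
    for z in charges:
        if int(z) != z or z < 1:
            raise ValueError(f"charge must be a positive integer, got {z}")
        out.append((neutral_mass + z * PROTON_MASS_DA) / z)
    return out


@dataclass
class XicIntegrals:
    """Extracted-ion-chromatogram integrals per charge state.

    ``integrals`` maps charge -> (reactant integral, product integral).
    """

    integrals: dict

    def __post_init__(self) -> None:
        if not self.integrals:
            raise ValueError("at least one charge state required")
        for z, (r, p) in self.integrals.items():
            if r < 0 or p < 0 or not (math.isfinite(r) and math.isfinite(p)):
                raise ValueError(f"invalid integrals at charge {z}: ({r}, {p})")


def conversion_from_xic(x: XicIntegrals) -> tuple[float, float]:
    """Charge-state-averaged conversion from XIC integrals.

    Per charge state z, conversion = product / (product + reactant);
    the statistic is the unweighted mean over charge states and the sample
    standard deviation (ddof = 1) of the per-charge conversions, mirroring
    how intact-mass conversions are reported from a single experiment.
    The implicit assumption of equal reactant/product ionization efficiency
    at each z is recorded in the result's interpretation, not corrected for.
    """
    per_charge = []
    for z in sorted(x.integrals):
        r, p = x.integrals[z]
        if r + p > 0:
            per_charge.append(p / (p + r))
    if not per_charge:
        raise ValueError("conversion undefined: all charge states have zero signal")
    mean = float(np.mean(per_charge))
    if len(per_charge) == 1:
        warnings.warn(
            "single usable charge state: standard deviation reported as 0",
            stacklevel=2,
        )
        return mean, 0.0
    return mean, float(np.std(per_charge, ddof=1))
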