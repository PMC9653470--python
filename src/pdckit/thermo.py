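"""Transition-state-theory rates from Gibbs free-energy profiles.

The mechanistic analysis consumes a computed free-energy profile (stationary
points in kcal/mol at 298.15 K) and turns activation barriers into rate
constants with the Eyring equation

    k = kappa * (k_B * T / h) * exp(-dG_act / (R * T)),

with a standard-state correction for bimolecular steps and a diffusion cap so
that "barrierless" encounters stay physical.  Printed electronic-structure
energies are authoritative inputs; nothing here recomputes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .constants import (
    BOLTZMANN_J_PER_K,
    PLANCK_J_S,
    R_KCAL_PER_MOL_K,
    STANDARD_TEMPERATURE_K,
)

__all__ = [
    "RateParameters",
    "StationaryPoint",
    "FreeEnergyProfile",
    "eyring_rate",
    "reverse_barrier",
    "equilibrium_constant",
    "steric_barrier",
    "STERIC_BARRIERS_KCAL",
    "pdc_free_energy_profile",
]


@dataclass(frozen=True)
class RateParameters:
    """Settings of the TST conversion.

    temperature
        Kelvin; default matches the SMD/298.15 K convention of the profile.
    transmission_coefficient
        Eyring kappa in (0, 1]; 1 means no recrossing correction.
    standard_state_concentration
        mol/L; the concentration standard state in which bimolecular barriers
        are expressed (1 M is the quantum-chemistry convention).
    diffusion_limit
        L mol^-1 s^-1 cap applied to bimolecular rate constants.
    """

    temperature: float = STANDARD_TEMPERATURE_K
    transmission_coefficient: float = 1.0
    standard_state_concentration: float = 1.0
    diffusion_limit: float = 1e10

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not (0 < self.transmission_coefficient <= 1):
            raise ValueError(
                "transmission_coefficient must be in (0, 1], got "
                f"{self.transmission_coefficient}"
            )
        if not (self.standard_state_concentration > 0):
            raise ValueError("standard_state_concentration must be positive")
        if not (self.diffusion_limit > 0):
            raise ValueError("diffusion_limit must be positive")


@dataclass(frozen=True)
class StationaryPoint:
    label: str
    g_kcal_mol: float
    kind: str  # "minimum" | "transition_state"

    def __post_init__(self) -> None:
        if self.kind not in ("minimum", "transition_state"):
            raise ValueError(f"unknown stationary-point kind {self.kind!r}")
        if not math.isfinite(self.g_kcal_mol):
            raise ValueError(f"non-finite energy for point {self.label!r}")


@dataclass(frozen=True)
class BranchPoint:
    """A competitive transition state branching off a main-path minimum.

    Absolute Gibbs energy; the barrier it implies is g - G(from_label).
    """

    label: str
    g_kcal_mol: float
    from_label: str


@dataclass
class FreeEnergyProfile:
    """Ordered stationary points of a reaction free-energy profile.

    Energies are relative to a declared reference point (G = 0).  Transition
    states on the main path must sit between minima; competitive pathways
    (e.g. the homolytic-substitution and diselenide-reformation transition
    states) live in ``branch_points``, anchored to the minimum they depart
    from.
    """

    points: list[StationaryPoint]
    reference_label: str
    temperature: float = STANDARD_TEMPERATURE_K
    branch_points: list[BranchPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate stationary-point labels")
        refs = [p for p in self.points if p.label == self.reference_label]
        if len(refs) != 1:
            raise ValueError(f"reference label {self.reference_label!r} not found")
        if refs[0].g_kcal_mol != 0.0:
            raise ValueError("reference point must have G = 0")
        for i, p in enumerate(self.points):
            if p.kind == "transition_state":
                if i == 0 or i == len(self.points) - 1:
                    raise ValueError(f"transition state {p.label!r} at profile edge")
                left, right = self.points[i - 1], self.points[i + 1]
                if left.kind != "minimum" or right.kind != "minimum":
                    raise ValueError(
                        f"transition state {p.label!r} not flanked by minima"
                    )
                if p.g_kcal_mol < left.g_kcal_mol:
                    raise ValueError(
                        f"negative forward barrier at {p.label!r}: "
                        f"{p.g_kcal_mol} < {left.g_kcal_mol}"
                    )
        known = set(labels)
        for b in self.branch_points:
            if b.from_label not in known:
                raise ValueError(f"branch {b.label!r} anchored to unknown "
                                 f"label {b.from_label!r}")
            if b.g_kcal_mol < self.energy(b.from_label):
                raise ValueError(f"branch {b.label!r} implies a negative barrier")

    def energy(self, label: str) -> float:
        for p in self.points:
            if p.label == label:
                return p.g_kcal_mol
        for b in self.branch_points:
            if b.label == label:
                return b.g_kcal_mol
        raise KeyError(f"no stationary point labelled {label!r}")

    def barrier(self, ts_label: str) -> float:
        """Forward barrier of a transition state relative to its preceding
        minimum (main path) or its anchor minimum (branch)."""
        for i, p in enumerate(self.points):
            if p.label == ts_label:
                if p.kind != "transition_state":
                    raise ValueError(f"{ts_label!r} is not a transition state")
                return p.g_kcal_mol - self.points[i - 1].g_kcal_mol
        for b in self.branch_points:
            if b.label == ts_label:
                return b.g_kcal_mol - self.energy(b.from_label)
        raise KeyError(f"no stationary point labelled {ts_label!r}")

    # -- serialization (config-document round trip, lossless: floats are
    #    emitted via repr, which YAML round-trips exactly) --
    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "reference_label": self.reference_label,
            "points": [
                {"label": p.label, "G_kcal_mol": p.g_kcal_mol, "kind": p.kind}
                for p in self.points
            ],
            "branch_points": [
                {"label": b.label, "G_kcal_mol": b.g_kcal_mol,
                 "from_label": b.from_label}
                for b in self.branch_points
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FreeEnergyProfile":
        return cls(
            points=[
                StationaryPoint(p["label"], float(p["G_kcal_mol"]), p["kind"])
                for p in d["points"]
            ],
            reference_label=d["reference_label"],
            temperature=float(d.get("temperature_K", STANDARD_TEMPERATURE_K)),
            branch_points=[
                BranchPoint(b["label"], float(b["G_kcal_mol"]), b["from_label"])
                for b in d.get("branch_points", [])
            ],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FreeEnergyProfile":
        return cls.from_dict(yaml.safe_load(text))


def _check_finite(value: float, name: str) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


def eyring_rate(
    dg_act: float,
    params: RateParameters = RateParameters(),
    molecularity: int = 1,
) -> float:
    """Eyring rate constant from an activation free energy.

    Parameters
    ----------
    dg_act
        Activation Gibbs energy in kcal/mol (>= 0).
    molecularity
        1 -> unimolecular rate in s^-1; 2 -> bimolecular rate in
        L mol^-1 s^-1 (a standard-state division by c_std converts the
        1 M-standard-state barrier into a concentration rate constant),
        capped at ``params.diffusion_limit``.
    """
    _check_finite(dg_act, "activation free energy")
    if dg_act < 0:
        raise ValueError(
            f"negative activation free energy ({dg_act} kcal/mol) for this step"
        )
    if molecularity not in (1, 2):
        raise ValueError(f"molecularity must be 1 or 2, got {molecularity}")
    T = params.temperature
    prefactor = params.transmission_coefficient * BOLTZMANN_J_PER_K * T / PLANCK_J_S
    k = prefactor * math.exp(-dg_act / (R_KCAL_PER_MOL_K * T))
    if molecularity == 2:
        k /= params.standard_state_concentration
        k = min(k, params.diffusion_limit)
    return k


def reverse_barrier(dg_act_fwd: float, dg_rxn: float) -> float:
    """Reverse activation energy by detailed balance: dG_rev = dG_fwd - dG_rxn."""
    _check_finite(dg_act_fwd, "forward activation free energy")
    _check_finite(dg_rxn, "reaction free energy")
    if dg_act_fwd < 0:
        raise ValueError("forward activation free energy must be >= 0")
    if dg_act_fwd < dg_rxn:
        raise ValueError(
            f"forward barrier {dg_act_fwd} below reaction free energy {dg_rxn}: "
            "the implied reverse barrier would be negative"
        )
    return dg_act_fwd - dg_rxn


def equilibrium_constant(
    dg_rxn: float, temperature: float = STANDARD_TEMPERATURE_K
) -> float:
    """K = exp(-dG/RT) for a reaction free energy in kcal/mol."""
    _check_finite(dg_rxn, "reaction free energy")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-dg_rxn / (R_KCAL_PER_MOL_K * temperature))


# Activation barriers (kcal/mol) of the productive alpha-carbon substitution
# (TS-IV) as a function of the steric bulk flanking the diselenide: small/small
# 17.2, mixed 17.8, bulky/bulky 25.4.  The last gates the reaction off and
# rationalises why bulky protein diselenides fail to dimerize.
STERIC_BARRIERS_KCAL: dict[frozenset, float] = {
    frozenset(["small"]): 17.2,
    frozenset(["small", "bulky"]): 17.8,
    frozenset(["bulky"]): 25.4,
}


def steric_barrier(substituent_left: str, substituent_right: str) -> float:
    """TS-IV barrier (kcal/mol) for a given pair of substituent size classes.

    Symmetric in its arguments; classes are the two-level scale
    {"small", "bulky"}.
    """
    for s in (substituent_left, substituent_right):
        if s not in ("small", "bulky"):
            raise ValueError(f"unknown substituent class {s!r}")
    return STERIC_BARRIERS_KCAL[frozenset([substituent_left, substituent_right])]


def pdc_free_energy_profile(
    steric: tuple[str, str] = ("small", "small"),
    set_barrier: float = 2.0,
    bet_dg_rxn: float = -20.0,
    pairing_dg_rxn: float = -5.0,
    contraction_dg_rxn: float = -15.0,
    reformation_barrier: float | None = None,
) -> FreeEnergyProfile:
    """The photocatalytic diselenide-contraction free-energy profile.

    Houses the printed stationary-point energies: the 56.6 kcal/mol catalyst
    triplet, the -8.0 kcal/mol single-electron oxidation of the phosphine,
    the barrierless -6.1 kcal/mol capture of the phosphine radical cation by
    the diselenide, the 2.6 kcal/mol back-electron-transfer barrier, the
    steric TS-IV series (17.2/17.8/25.4) and the 29.4 kcal/mol homolytic
    branch.  Energies not printed for the profile (the exergonicity of
    back-ET, ion pairing and the contraction step, and the reformation
    barrier) are documented package defaults, exposed as arguments.
    """
    ts4 = steric_barrier(*steric)
    g_t1 = 56.6
    g_set_ts = g_t1 + set_barrier
    g_radcat = g_t1 - 8.0
    g_capture = g_radcat - 6.1
    g_bet_ts = g_capture + 2.6
    g_pair = g_capture + bet_dg_rxn + pairing_dg_rxn
    g_ts4 = g_pair + ts4
    g_products = g_pair + contraction_dg_rxn
    ts8 = ts4 + 2.0 if reformation_barrier is None else reformation_barrier
    points = [
        StationaryPoint("ground", 0.0, "minimum"),
        StationaryPoint("T1", g_t1, "minimum"),
        StationaryPoint("TS-SET", g_set_ts, "transition_state"),
        StationaryPoint("I-radical-cation", g_radcat, "minimum"),
        StationaryPoint("II-III-radical-pair", g_capture, "minimum"),
        StationaryPoint("TS-BET", g_bet_ts, "transition_state"),
        StationaryPoint("ion-pair", g_pair, "minimum"),
        StationaryPoint("TS-IV", g_ts4, "transition_state"),
        StationaryPoint("products", g_products, "minimum"),
    ]
    branches = [
        BranchPoint("TS-VII", g_capture + 29.4, "II-III-radical-pair"),
        BranchPoint("TS-VIII", g_pair + ts8, "ion-pair"),
    ]
    return FreeEnergyProfile(points, "ground", branch_points=branches)
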