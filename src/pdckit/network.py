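"""The photocatalytic diselenide-contraction reaction network.

Encodes the proposed catalytic cycle as a validated, atom-balanced set of
elementary steps with a stoichiometry matrix:

    PC   --hv-->  PC*                      photoexcitation (effective rate)
    PC*  -->      PC                       intrinsic excited-state decay
    PC* + I  -->  PC_red + I(+.)          single-electron oxidation of the
                                           phosphine by the excited catalyst
    I(+.) + RSeSeR --> II(+) + III(.)      barrierless capture of the radical
                                           cation by the diselenide
    PC_red + III(.) --> PC + III(-)        back electron transfer
    II(+) + III(-)  --> IP                 diffusion-limited ion pairing
    IP  --> V + VI                         SN2 at the alpha-carbon (TS-IV):
                                           productive contraction
    IP  --> RSeSeR + I                     SN2 at Se (TS-VIII): diselenide
                                           reformation (optional, default on)
    II(+) + III(.) --> V + VI(+.)          SH2 homolytic branch (TS-VII),
                                           optional, off by default
    PC_red + VI(+.) --> PC + VI            closing reduction for the SH2 branch

R-group identity is abstracted away; only the balance-relevant Se and P atom
counts, the net charge and the radical parity of each species are tracked,
which is what the per-step validation enforces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .thermo import (
    FreeEnergyProfile,
    RateParameters,
    eyring_rate,
    equilibrium_constant,
    pdc_free_energy_profile,
    reverse_barrier,
    steric_barrier,
)

__all__ = [
    "Species",
    "ElementaryStep",
    "ReactionNetwork",
    "build_pdc_network",
    "stoichiometry_matrix",
    "validate_network",
    "assign_rate_constants",
]

BARRIERLESS = "barrierless"
PHOTON_DRIVEN = "photon-driven"

STEP_TYPES = {
    "photoexcitation",
    "SET",
    "substitution_C",
    "substitution_Se",
    "homolytic_substitution",
    "association",
    "decay",
}

#: Stationary-point labels build_pdc_network reads from the profile.
REQUIRED_PROFILE_LABELS = (
    "ground",
    "T1",
    "I-radical-cation",
    "II-III-radical-pair",
    "TS-BET",
    "ion-pair",
    "TS-IV",
)


@dataclass(frozen=True)
class Species:
    name: str
    mechanism_label: str = "user-defined"
    charge: int = 0
    radical: bool = False
    atom_counts: dict = field(default_factory=dict)  # element -> count (Se, P, ...)

    def __post_init__(self) -> None:
        for el, n in self.atom_counts.items():
            if n < 0:
                raise ValueError(f"negative {el} count in species {self.name!r}")

    def count(self, element: str) -> int:
        return int(self.atom_counts.get(element, 0))


@dataclass
class ElementaryStep:
    name: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    step_type: str
    barrier: float | str  # kcal/mol, or "barrierless" / "photon-driven"
    dg_rxn: float = 0.0
    reversible: bool = False
    k_fwd_override: float | None = None  # explicit first-order rate (e.g. decay)
    k_fwd: float | None = None
    k_rev: float | None = None

    def __post_init__(self) -> None:
        if self.step_type not in STEP_TYPES:
            raise ValueError(f"unknown step type {self.step_type!r}")
        if isinstance(self.barrier, str) and self.barrier not in (
            BARRIERLESS,
            PHOTON_DRIVEN,
        ):
            raise ValueError(f"unknown barrier annotation {self.barrier!r}")

    @property
    def molecularity(self) -> int:
        return sum(c for _, c in self.reactants)


@dataclass
class ReactionNetwork:
    species: list[Species]
    steps: list[ElementaryStep]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        labels = [s.mechanism_label for s in self.species
                  if s.mechanism_label != "user-defined"]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate mechanism labels")
        self._index = {n: i for i, n in enumerate(names)}
        for step in self.steps:
            for n, c in step.reactants + step.products:
                if n not in self._index:
                    raise ValueError(
                        f"step {step.name!r} references unknown species {n!r}"
                    )
                if c <= 0:
                    raise ValueError(f"non-positive coefficient in {step.name!r}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_by_name(self, name: str) -> Species:
        return self.species[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    def atom_vector(self, element: str) -> np.ndarray:
        return np.array([s.count(element) for s in self.species], dtype=int)

    # -- serialization --
    def to_dict(self) -> dict:
        return {
            "species": [
                {
                    "name": s.name,
                    "mechanism_label": s.mechanism_label,
                    "charge": s.charge,
                    "radical": s.radical,
                    "atom_counts": dict(s.atom_counts),
                }
                for s in self.species
            ],
            "steps": [
                {
                    "name": st.name,
                    "reactants": [[n, c] for n, c in st.reactants],
                    "products": [[n, c] for n, c in st.products],
                    "step_type": st.step_type,
                    "barrier": st.barrier,
                    "dg_rxn": st.dg_rxn,
                    "reversible": st.reversible,
                    "k_fwd_override": st.k_fwd_override,
                    "k_fwd": st.k_fwd,
                    "k_rev": st.k_rev,
                }
                for st in self.steps
            ],
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        species = [
            Species(
                name=s["name"],
                mechanism_label=s.get("mechanism_label", "user-defined"),
                charge=int(s.get("charge", 0)),
                radical=bool(s.get("radical", False)),
                atom_counts=dict(s.get("atom_counts", {})),
            )
            for s in d["species"]
        ]
        steps = [
            ElementaryStep(
                name=st["name"],
                reactants=[(n, int(c)) for n, c in st["reactants"]],
                products=[(n, int(c)) for n, c in st["products"]],
                step_type=st["step_type"],
                barrier=st["barrier"],
                dg_rxn=float(st.get("dg_rxn", 0.0)),
                reversible=bool(st.get("reversible", False)),
                k_fwd_override=st.get("k_fwd_override"),
                k_fwd=st.get("k_fwd"),
                k_rev=st.get("k_rev"),
            )
            for st in d["steps"]
        ]
        return cls(species, steps, metadata=dict(d.get("metadata", {})))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(yaml.safe_load(text))


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Species x steps integer matrix; column j is products minus reactants
    of step j."""
    S = np.zeros((len(network.species), len(network.steps)), dtype=int)
    for j, step in enumerate(network.steps):
        for name, coeff in step.reactants:
            S[network.index(name), j] -= coeff
        for name, coeff in step.products:
            S[network.index(name), j] += coeff
    return S


def validate_network(network: ReactionNetwork) -> list[str]:
    """Check per-step Se/P balance, charge balance and radical parity, plus
    catalyst closure of the core contraction cycle when present.

    Returns a list of human-readable violations; an empty list means valid.
    """
    violations: list[str] = []
    S = stoichiometry_matrix(network)
    for element in ("Se", "P"):
        vec = network.atom_vector(element)
        imbalance = vec @ S
        for j, step in enumerate(network.steps):
            if imbalance[j] != 0:
                violations.append(
                    f"step {step.name!r}: {element} imbalance of {imbalance[j]:+d}"
                )
    charge = np.array([s.charge for s in network.species])
    dq = charge @ S
    for j, step in enumerate(network.steps):
        if dq[j] != 0:
            violations.append(f"step {step.name!r}: charge imbalance of {dq[j]:+d}")
    radical = np.array([int(s.radical) for s in network.species])
    dr = radical @ S
    for j, step in enumerate(network.steps):
        change = abs(int(dr[j]))
        # SET moves exactly one electron; decay steps may quench a radical
        # against an untracked partner (solvent H-abstraction); everything
        # else conserves the radical count.
        ok = change == 1 if step.step_type == "SET" else (
            change <= 1 if step.step_type == "decay" else change == 0
        )
        if not ok:
            violations.append(
                f"step {step.name!r}: radical-count change {int(dr[j]):+d} "
                f"inconsistent with step type {step.step_type!r}"
            )
    # Catalyst closure: one pass through the core cycle must regenerate the
    # catalyst states and consume exactly one diselenide + one phosphine into
    # one selenoether + one phosphine selenide.
    core = ["photoexcitation", "SET-oxidation", "radical-cation-capture",
            "back-electron-transfer", "ion-pairing", "contraction-TS-IV"]
    step_names = {st.name: j for j, st in enumerate(network.steps)}
    if all(n in step_names for n in core):
        net = S[:, [step_names[n] for n in core]].sum(axis=1)
        expected_net = {"RSeSeR": -1, "I": -1, "V": 1, "VI": 1}
        by_label: dict[str, int] = {}
        for s in network.species:
            by_label[s.mechanism_label] = net[network.index(s.name)]
        for label, want in expected_net.items():
            if by_label.get(label, 0) != want:
                violations.append(
                    f"cycle closure: net change of {label} is "
                    f"{by_label.get(label, 0):+d}, expected {want:+d}"
                )
        for label in ("PC", "PC*", "PC_red"):
            if by_label.get(label, 0) != 0:
                violations.append(
                    f"cycle closure: catalyst state {label} not regenerated "
                    f"(net {by_label.get(label, 0):+d})"
                )
    return violations


def assign_rate_constants(
    network: ReactionNetwork,
    params: RateParameters = RateParameters(),
    k_exc: float = 0.0,
) -> ReactionNetwork:
    """Return a copy of the network with numeric forward (and, for reversible
    steps, detailed-balance reverse) rate constants.

    Annotation rules: photon-driven steps get the effective excitation rate
    ``k_exc``; barrierless bimolecular steps get the diffusion cap (a
    barrierless unimolecular step gets the full kT/h prefactor); explicit rate
    overrides (excited-state decay) are taken as-is; numeric barriers go
    through the Eyring equation at the step's molecularity.
    """
    if k_exc < 0 or not math.isfinite(k_exc):
        raise ValueError("k_exc must be a finite non-negative rate")
    new_steps = []
    for step in network.steps:
        mol = step.molecularity
        if step.k_fwd_override is not None:
            k_fwd = float(step.k_fwd_override)
        elif step.barrier == PHOTON_DRIVEN:
            k_fwd = k_exc
        elif step.barrier == BARRIERLESS:
            k_fwd = params.diffusion_limit if mol == 2 else eyring_rate(0.0, params, 1)
        elif isinstance(step.barrier, (int, float)):
            k_fwd = eyring_rate(float(step.barrier), params, mol)
        else:
            raise ValueError(f"step {step.name!r} has no barrier annotation")
        k_rev = None
        if step.reversible:
            # K_eq in concentration units at the parameter standard state.
            dn = sum(c for _, c in step.products) - mol
            keq = equilibrium_constant(step.dg_rxn, params.temperature)
            keq *= params.standard_state_concentration ** (-dn)
            k_rev = k_fwd / keq
        new_steps.append(replace(step, k_fwd=k_fwd, k_rev=k_rev))
    return ReactionNetwork(network.species, new_steps, metadata=dict(network.metadata))


def _pdc_species(include_SH2: bool, include_deselenization: bool) -> list[Species]:
    species = [
        Species("PC", "PC", charge=1, atom_counts={}),
        Species("PC*", "PC*", charge=1, atom_counts={}),
        Species("PC_red", "PC_red", charge=0, atom_counts={}),
        Species("I", "I", charge=0, atom_counts={"P": 1}),
        Species("I_rad_cation", "I_rad_cation", charge=1, radical=True,
                atom_counts={"P": 1}),
        Species("RSeSeR", "RSeSeR", charge=0, atom_counts={"Se": 2}),
        Species("II_plus", "II_plus", charge=1, atom_counts={"Se": 1, "P": 1}),
        Species("III_rad", "III_rad", charge=0, radical=True,
                atom_counts={"Se": 1}),
        Species("III_anion", "III_anion", charge=-1, atom_counts={"Se": 1}),
        Species("IP", "ion_pair", charge=0, atom_counts={"Se": 2, "P": 1}),
        Species("V", "V", charge=0, atom_counts={"Se": 1}),
        Species("VI", "VI", charge=0, atom_counts={"Se": 1, "P": 1}),
    ]
    if include_SH2:
        species.append(
            Species("VI_rad_cation", "VI_rad_cation", charge=1, radical=True,
                    atom_counts={"Se": 1, "P": 1})
        )
    if include_deselenization:
        species += [
            Species("R_rad", "R_rad", charge=0, radical=True, atom_counts={}),
            Species("RH", "RH", charge=0, atom_counts={}),
        ]
    return species


def build_pdc_network(
    profile: FreeEnergyProfile | None = None,
    steric: tuple[str, str] = ("small", "small"),
    include_SH2: bool = False,
    include_reformation: bool = True,
    include_deselenization_channel: bool = False,
    set_barrier: float = 2.0,
    reformation_barrier: float | None = None,
    deselenization_barrier: float = 12.0,
    excited_state_lifetime_s: float = 1e-6,
) -> ReactionNetwork:
    """Build the validated contraction network from a free-energy profile.

    The profile must contain the labels in :data:`REQUIRED_PROFILE_LABELS`
    (plus ``TS-VII``/``TS-VIII`` branches when the corresponding optional
    channels are enabled); by default the canonical profile for the requested
    steric pair is constructed.  The productive SN2 and the reformation SN2
    are unimolecular steps out of the selanylphosphonium/selenolate ion pair,
    which is where the profile measures their barriers; the ion pair itself
    forms at the diffusion limit.

    The diselenide-reformation barrier (TS-VIII) is not printed in the
    source profile; its default (TS-IV + 2.0 kcal/mol, so contraction
    dominates) is a calibration knob, as is the effective deselenization
    barrier of the optional side channel.
    """
    if profile is None:
        profile = pdc_free_energy_profile(
            steric=steric, set_barrier=set_barrier,
            reformation_barrier=reformation_barrier,
        )
    for label in REQUIRED_PROFILE_LABELS:
        try:
            profile.energy(label)
        except KeyError:
            raise ValueError(f"profile is missing required label {label!r}") from None

    g = profile.energy
    dg_set = g("I-radical-cation") - g("T1")  # -8.0 printed
    dg_capture = g("II-III-radical-pair") - g("I-radical-cation")  # -6.1 printed
    bet_barrier = g("TS-BET") - g("II-III-radical-pair")  # 2.6 printed
    ts4_barrier = profile.barrier("TS-IV")
    set_eff_barrier = g("TS-SET") - g("T1") if _has(profile, "TS-SET") else set_barrier

    species = _pdc_species(include_SH2, include_deselenization_channel)
    steps = [
        ElementaryStep(
            "photoexcitation", [("PC", 1)], [("PC*", 1)],
            "photoexcitation", PHOTON_DRIVEN, dg_rxn=g("T1"),
        ),
        ElementaryStep(
            "excited-state-decay", [("PC*", 1)], [("PC", 1)],
            "decay", 0.0, dg_rxn=-g("T1"),
            k_fwd_override=1.0 / excited_state_lifetime_s,
        ),
        ElementaryStep(
            "SET-oxidation", [("PC*", 1), ("I", 1)],
            [("PC_red", 1), ("I_rad_cation", 1)],
            "SET", set_eff_barrier, dg_rxn=dg_set,
        ),
        ElementaryStep(
            "radical-cation-capture", [("I_rad_cation", 1), ("RSeSeR", 1)],
            [("II_plus", 1), ("III_rad", 1)],
            "substitution_Se", BARRIERLESS, dg_rxn=dg_capture,
        ),
        ElementaryStep(
            "back-electron-transfer", [("PC_red", 1), ("III_rad", 1)],
            [("PC", 1), ("III_anion", 1)],
            "SET", bet_barrier,
            dg_rxn=g("ion-pair") - g("II-III-radical-pair") + 5.0,
        ),
        ElementaryStep(
            "ion-pairing", [("II_plus", 1), ("III_anion", 1)], [("IP", 1)],
            "association", BARRIERLESS, dg_rxn=-5.0,
        ),
        ElementaryStep(
            "contraction-TS-IV", [("IP", 1)], [("V", 1), ("VI", 1)],
            "substitution_C", ts4_barrier,
            dg_rxn=g("products") - g("ion-pair") if _has(profile, "products") else -15.0,
        ),
    ]
    if include_reformation:
        ts8 = (profile.barrier("TS-VIII") if _has(profile, "TS-VIII")
               else ts4_barrier + 2.0)
        steps.append(
            ElementaryStep(
                "reformation-TS-VIII", [("IP", 1)],
                [("RSeSeR", 1), ("I", 1)],
                "substitution_Se", ts8, dg_rxn=-5.0,
            )
        )
    if include_SH2:
        ts7 = profile.barrier("TS-VII") if _has(profile, "TS-VII") else 29.4
        steps += [
            ElementaryStep(
                "homolytic-TS-VII", [("II_plus", 1), ("III_rad", 1)],
                [("V", 1), ("VI_rad_cation", 1)],
                "homolytic_substitution", ts7, dg_rxn=-10.0,
            ),
            ElementaryStep(
                "selenide-radical-reduction", [("PC_red", 1), ("VI_rad_cation", 1)],
                [("PC", 1), ("VI", 1)],
                "SET", set_eff_barrier, dg_rxn=-20.0,
            ),
        ]
    if include_deselenization_channel:
        steps += [
            ElementaryStep(
                "deselenization", [("III_rad", 1), ("I", 1)],
                [("R_rad", 1), ("VI", 1)],
                "substitution_Se", deselenization_barrier, dg_rxn=-10.0,
            ),
            ElementaryStep(
                "H-abstraction", [("R_rad", 1)], [("RH", 1)],
                "decay", 0.0, dg_rxn=-20.0, k_fwd_override=1e3,
            ),
        ]
    network = ReactionNetwork(
        species, steps,
        metadata={
            "steric": list(steric),
            "ts4_barrier_kcal_mol": ts4_barrier,
            "include_SH2": include_SH2,
            "include_reformation": include_reformation,
            "include_deselenization_channel": include_deselenization_channel,
        },
    )
    report = validate_network(network)
    if report:
        raise AssertionError("built network failed validation: " + "; ".join(report))
    return network


def _has(profile: FreeEnergyProfile, label: str) -> bool:
    try:
        profile.energy(label)
        return True
    except KeyError:
        return False


def stoichiometry_tsv(network: ReactionNetwork) -> str:
    """Stoichiometry matrix as TSV with species rows and step columns."""
    S = stoichiometry_matrix(network)
    lines = ["species\t" + "\t".join(st.name for st in network.steps)]
    for i, s in enumerate(network.species):
        lines.append(s.name + "\t" + "\t".join(str(x) for x in S[i]))
    return "\n".join(lines) + "\n"
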