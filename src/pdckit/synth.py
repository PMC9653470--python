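"""Seeded synthetic-data generators.

Each generator returns a (data, truth) pair so parameter-recovery tests can
consume only the data and compare against the stored truth.  Noise models:
multiplicative lognormal for kinetic concentration observations (positive
quantities), Poisson for TCSPC photon counts (counting statistics), and
multiplicative Gaussian for MS intensities.  All randomness flows through an
explicit integer seed; identical seeds give byte-identical output.

What these emulate — and what they do not: noisy readouts of the package's
own kinetic model, ideal single-exponential-mixture photon statistics, and
clean centroided Se-isotope envelopes at exact charge-ladder positions.
Real instrument data add baseline drift, instrument response, detector
dead-time, chromatographic and matrix effects that are deliberately absent.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .kinetics import ConcentrationTrajectory, ReactionConditions, simulate
from .constants import PROTON_MASS_DA
from .massspec import MolecularFormula, XicIntegrals, isotope_pattern
from .photophysics import DecayFit, DecayTrace, decay_model

__all__ = [
    "gen_kinetics_observations",
    "gen_tcspc",
    "gen_spectrum",
]


def gen_kinetics_observations(
    network,
    conditions: ReactionConditions,
    sampling_times,
    noise_cv: float,
    seed: int,
    species: list[str] | None = None,
) -> tuple[pd.DataFrame, ConcentrationTrajectory]:
    """Noisy concentration-versus-time observations of the kinetic model.

    Simulates the network, samples it at ``sampling_times`` and applies
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv``.  Returns (observations, true trajectory).
    """
    sampling_times = np.asarray(sampling_times, dtype=float)
    if np.any(sampling_times < 0) or np.any(sampling_times > conditions.t_end):
        raise ValueError("sampling times must lie within the simulation span")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    traj = simulate(network, conditions, t_eval=np.unique(sampling_times))
    species = species or traj.species_names
    rows = []
    # lognormal with unit mean and stated CV
    sigma2 = math.log(1.0 + noise_cv**2)
    for sp in species:
        true_c = traj[sp]
        if noise_cv > 0:
            factor = rng.lognormal(mean=-sigma2 / 2.0,
                                   sigma=math.sqrt(sigma2), size=true_c.size)
        else:
            factor = np.ones_like(true_c)
        for t, c_true, f in zip(traj.time, true_c, factor):
            rows.append({"time_s": t, "species": sp,
                         "observed_M": c_true * f, "true_M": c_true})
    return pd.DataFrame(rows), traj


def gen_tcspc(
    true_lifetimes,
    amplitudes,
    background: float,
    total_counts: int,
    bin_width: float = 4.0,
    t_max: float = 3000.0,
    quencher_concentration: float = 0.0,
    seed: int = 0,
) -> DecayTrace:
    """Synthetic TCSPC decay trace (Poisson counts per bin).

    ``true_lifetimes``/``amplitudes`` define the relative multi-exponential
    shape (amplitudes in arbitrary units, rescaled so the expected total
    photon count equals ``total_counts``); ``background`` is the flat rate in
    the same arbitrary units.  The default 3 microsecond window matches a
    phosphorescent photocatalyst measurement.  The generating truth is
    stored in the trace metadata.
    """
    lifetimes = [float(x) for x in np.atleast_1d(true_lifetimes)]
    amps = [float(x) for x in np.atleast_1d(amplitudes)]
    if len(lifetimes) != len(amps):
        raise ValueError("lifetimes and amplitudes must have equal length")
    if total_counts < 1:
        raise ValueError("total_counts must be >= 1")
    if lifetimes and t_max < 3 * max(lifetimes):
        raise ValueError("t_max must cover at least three lifetimes")
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, t_max + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shape_fit = DecayFit(
        components=list(zip(lifetimes, amps)) or [(1.0, 0.0)],
        background=background,
    )
    mu = decay_model(centers, shape_fit)
    mu = mu * (total_counts / mu.sum())
    counts = rng.poisson(mu)
    return DecayTrace(
        bin_edges=edges,
        counts=counts,
        quencher_concentration=quencher_concentration,
        metadata={
            "truth": {
                "lifetimes_ns": lifetimes,
                "amplitudes": amps,
                "background": background,
                "total_counts": int(total_counts),
                "seed": int(seed),
            }
        },
    )


def gen_spectrum(
    reactant_formula: MolecularFormula,
    product_formula: MolecularFormula,
    conversion: float,
    charges,
    resolution: float = 0.01,
    intensity_noise: float = 0.0,
    seed: int = 0,
    prune_threshold: float = 1e-4,
) -> tuple[pd.DataFrame, XicIntegrals, dict]:
    """Centroided charge-state spectrum of a reactant/product pair at a set
    conversion, plus the per-charge XIC integrals it implies.

    Peak positions are the isotope envelopes of each species placed on the
    protonated charge ladder; total intensity per charge state splits
    (1 - conversion) : conversion between reactant and product.  Gaussian
    multiplicative noise of relative width ``intensity_noise`` perturbs each
    centroid intensity.  Returns (spectrum, integrals, truth); reactant and
    product envelopes that overlap within ``resolution`` m/z at any charge
    are flagged in the truth dict rather than silently merged.
    """
    if not (0.0 <= conversion <= 1.0):
        raise ValueError("conversion must be in [0, 1]")
    charges = [int(z) for z in charges]
    if not charges:
        raise ValueError("at least one charge state required")
    rng = np.random.default_rng(seed)
    env_r = isotope_pattern(reactant_formula, prune_threshold=prune_threshold)
    env_p = isotope_pattern(product_formula, prune_threshold=prune_threshold)

    rows = []
    integrals = {}
    overlap_flags = []
    for z in charges:
        mz_r = (env_r.masses + z * PROTON_MASS_DA) / z
        mz_p = (env_p.masses + z * PROTON_MASS_DA) / z
        lo_r, hi_r = mz_r.min(), mz_r.max()
        lo_p, hi_p = mz_p.min(), mz_p.max()
        if max(lo_r, lo_p) <= min(hi_r, hi_p) + resolution:
            overlap_flags.append(z)
        total_r, total_p = 0.0, 0.0
        for mz, ab in zip(mz_r, env_r.abundances):
            inten = (1.0 - conversion) * ab
            if intensity_noise > 0 and inten > 0:
                inten *= max(1.0 + intensity_noise * rng.standard_normal(), 0.0)
            if inten > 0:
                rows.append({"mz": mz, "intensity": inten,
                             "species": "reactant", "charge": z})
                total_r += inten
        for mz, ab in zip(mz_p, env_p.abundances):
            inten = conversion * ab
            if intensity_noise > 0 and inten > 0:
                inten *= max(1.0 + intensity_noise * rng.standard_normal(), 0.0)
            if inten > 0:
                rows.append({"mz": mz, "intensity": inten,
                             "species": "product", "charge": z})
                total_p += inten
        integrals[z] = (total_r, total_p)
    spectrum = pd.DataFrame(rows).sort_values("mz").reset_index(drop=True)
    truth = {
        "conversion": conversion,
        "seed": int(seed),
        "charges": charges,
        "envelope_overlap_at_charges": overlap_flags,
    }
    return spectrum, XicIntegrals(integrals), truth
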