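# Methods

`pdckit` analyses the mechanism of the photocatalytic diselenide
contraction (PDC): the conversion of a diselenide R–Se–Se–R′ to a
reductively stable selenoether R–Se–R′ with formal extrusion of one
selenium atom, driven by an iridium photocatalyst, the water-soluble
phosphine PTA (1,3,5-triaza-7-phosphaadamantane), and 450 nm light. This
note records the models, their assumptions, the defaults that matter, and
what the synthetic-data tests do and do not establish.

## Free-energy profile and transition-state theory

The mechanistic input is a computed Gibbs free-energy profile (kcal/mol,
SMD acetonitrile, 298.15 K) over the stationary points of the proposed
cycle: photoexcitation to the long-lived catalyst triplet (56.6 kcal/mol
above the ground state), single-electron oxidation of the phosphine by the
excited catalyst (ΔG = −8.0 kcal/mol, small effective barrier), barrierless
capture of the phosphine radical cation by the diselenide (ΔG = −6.1
kcal/mol) forming the selanylphosphonium cation II⁺ and selanyl radical
III•, back electron transfer reducing III• to the selenolate III⁻
(ΔG‡ = 2.6 kcal/mol), and, from the II⁺/III⁻ ion pair, SN2 substitution at
the α-carbon (TS-IV, the productive contraction) or at selenium (TS-VIII,
diselenide reformation). A homolytic SH2 branch (TS-VII, ΔG‡ = 29.4
kcal/mol) is retained as an optional channel; its barrier makes it
irrelevant at room temperature.

These electronic-structure energies are **inputs**, never recomputed.
Rates come from the Eyring equation k = κ(k_BT/h)·exp(−ΔG‡/RT) with κ = 1
(no tunnelling or recrossing correction is available for these steps).
Bimolecular barriers are interpreted at a 1 M standard state — the
quantum-chemistry convention of the profile — and divided by the
standard-state concentration to give L mol⁻¹ s⁻¹; the standard state is an
explicit `RateParameters` field so alternative conventions are visible,
not silent. Bimolecular rates are capped at a diffusion limit of
1×10¹⁰ L mol⁻¹ s⁻¹ (typical for small molecules in MeCN/water), so
"barrierless" steps stay physical. Constants are frozen in one table
(CODATA 2018; R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹).

The steric series for TS-IV — 17.2 kcal/mol for two small substituents,
17.8 for small/bulky, 25.4 for bulky/bulky — is exposed as
`steric_barrier(left, right)`, symmetric in its arguments. The 8.2 kcal/mol
spread corresponds to a ~10⁶-fold rate ratio at 298.15 K, which is the
quantitative content of the observation that bulky protein diselenides do
not dimerize while small peptide diselenides convert within minutes.

## Reaction network

The cycle is encoded as twelve species and seven to ten elementary steps
with explicit Se and P atom counts, net charges and radical flags; R-group
identity is abstracted away. Validation enforces, per step: selenium and
phosphorus balance, charge balance, and radical-count parity (a
single-electron-transfer step changes the radical count by exactly one;
decay steps may quench a radical against an untracked solvent partner;
every other step conserves it). A network-level check confirms that one
pass through the core cycle consumes one diselenide and one phosphine into
one selenoether and one phosphine selenide with all catalyst states
regenerated — the per-turnover statement of "two diselenide Se → one
selenoether Se + one phosphine-selenide Se".

Two modelling choices deserve explanation:

- **The SN2 steps are unimolecular decays of an explicit ion-pair
  species.** The profile measures the TS-IV and TS-VIII barriers from the
  selanylphosphonium/selenolate ion-pair minimum, so the network forms
  that ion pair by diffusion-limited association (II⁺ + III⁻ → IP) and
  applies the printed barriers as first-order rates out of it
  (k = 1.53 s⁻¹ at 17.2 kcal/mol). Treating the substitution instead as a
  direct bimolecular reaction at a 1 M standard state would make the
  observed minutes-scale completion at millimolar concentrations
  impossible (k[II⁺][III⁻] ≈ 10⁻⁵ M/s), in contradiction with both the
  ion-pair reading of the profile and the experimental timescale.
- **Unprinted reaction free energies are nominal defaults.** The
  exergonicity of back electron transfer ("highly exergonic", −20), of ion
  pairing (−5) and of the contraction step (−15 kcal/mol) are not printed;
  the default network is irreversible, so these values never enter the
  default rates and matter only if a user marks a step reversible (reverse
  rates then follow detailed balance, k_f/k_r = exp(−ΔG/RT)).

Other documented defaults: the SET oxidation carries a small effective
barrier of 2.0 kcal/mol (stated only as "small"; at 10 mM phosphine the
step is diffusion-capped regardless, so this knob is inert in practice);
TS-VIII defaults to TS-IV + 2.0 kcal/mol so that contraction dominates —
this is a calibration knob, not a profile value; the excited state decays
with a 1 µs intrinsic lifetime so quenching competition is physical; the
deselenization side channel observed for a bulky protein substrate is
available but off by default because its energetics are not printed.
Counter-ions are not modelled; only net charge balance per step is
enforced.

## Microkinetics

The deterministic simulator integrates dc/dt = S·v(c) (S the stoichiometry
matrix, v mass-action fluxes) with scipy's BDF stiff integrator and an
analytic Jacobian, at rtol = 10⁻⁸ and atol = 10⁻¹² mol/L — rates span
10⁻⁶ to 10¹⁰ and concentrations µM (catalyst) to mM (substrate), so a
stiff implicit method is required. Solver failures raise an error carrying
the last accepted time; they are never silently truncated. Se, P and
catalyst totals are conserved to well within 10× the solver tolerance.

The stochastic cross-check is an exact Gillespie direct-method sampler
over copy numbers (c·N_A·V at a chosen volume) with the standard
concentration-to-propensity conversion; replicate means converge to the
ODE solution up to the O(1/N) mesoscopic correction for bimolecular steps,
which the tests keep below the Monte-Carlo standard error by using ≳10³–10⁴
copies. A fixed seed gives a bit-identical event sequence; a
zero-propensity deadlock freezes the state and flags the trajectory as
absorbed.

**Default scenario.** 2.5 mM peptide diselenide, 4 equivalents (10 mM)
phosphine, 1 mol% (25 µM) photocatalyst, 360 s of irradiation — the
standard dimerization conditions; the protein-functionalization variant
(0.5 mM protein, 66 eq. phosphine) is one `default_pdc_conditions` call
away. The effective photoexcitation rate k_exc is the single calibration
knob: no photon flux or LED power is specified, so k_exc absorbs them. The
default 5 s⁻¹ brings the small/small scenario to ≥95% conversion within
~21 s, on the observed minutes timescale; k_exc = 0 is the dark control,
which is exactly static.

**Conversion accounting.** Conversion is reported in selenium-equivalents:
a diselenide carries two substrate equivalents, a selenoether one. One
contraction event moves both equivalents of a diselenide into products —
one into the selenoether V, one into the phosphine selenide VI — so the
product pool for conversion is {V, VI} and complete contraction reads
1.0. The denominator is the substrate-derived pool at t = 0, which makes
the fraction insensitive to material transiently parked in the ion pair;
with the bulky/bulky barrier the cycle stalls exactly there, and the
conversion correctly reads <0.1% rather than spuriously approaching 1.
For selenium-free toy networks every species counts as one equivalent.

## Photoluminescence kinetics

TCSPC decays are modelled as Σᵢ Aᵢ·exp(−t/τᵢ) + B over time bins and
fitted by maximising the Poisson likelihood (equivalently minimising the
Poisson deviance). Counts are Poisson, so weighted least squares would
mis-weight the low-count tail that carries most of the lifetime
information. Optimisation runs in log-parameter space (positivity for
free) with a moment-based initialisation; fits on traces with fewer than
1000 total photons are refused as unreliable. Lifetime confidence
intervals come from the profile likelihood at deviance increments of 1.0
(≈68%) and 3.84 (≈95%). Two-component fits with lifetimes closer than
1.5× are flagged as degenerate.

No instrument-response deconvolution is applied by default: the catalyst
lifetimes of interest (hundreds of ns to µs) dwarf the ~200 ps excitation
pulse, so a tail fit is adequate; an optional Gaussian-IRF convolution
(exponentially modified Gaussian) is available behind `irf_sigma_ns`.

Stern–Volmer analysis fits τ₀/τ − 1 = K_SV[Q] through the origin
(least squares; a single point solves exactly) and reports
k_q = K_SV/τ₀. Whether a reported quenching factor refers to the
dominant-component lifetime or the amplitude-weighted mean is often left
unstated in practice, so the package computes both (`lifetime_ratio`,
which refuses fits without a ≥80%-dominant component, and
`mean_lifetime`). The steady-state spectral-shift experiment on a
dye-labelled diselenide is out of scope beyond container support; no
photophysical model of the shift is attempted.

## Selenium mass spectrometry

Peptide formulas are summed residue compositions (21 proteinogenic
residues, U = selenocysteine) plus terminal corrections; a diselenide
homodimer is 2×chain − 2H, the contracted selenoether additionally −1 Se,
and asymmetric diselenides take an explicit partner formula. Isotope
envelopes are multinomial convolutions of the elemental isotope
distributions (IUPAC/CIAAW masses and abundances, frozen in
`constants.py`): per element by binary-power self-convolution, then across
elements, merging terms at the exact-composition level (10⁻⁹ Da) and
binning the final envelope at 10⁻³ Da with a relative prune threshold of
10⁻⁶ and renormalisation to probabilities. Coarser mid-convolution
aggregation is applied only if the working term list exceeds 1.5×10⁵
entries, which perturbs sub-resolution fine structure and never triggers
for the peptide-scale formulas used here.

"Monoisotopic" for selenium species follows HRMS practice and uses the
most abundant isotope ⁸⁰Se (79.9165 Da), not the lightest — the two
conventions differ by ~6 Da, which matters when matching intact-mass
shifts. The contraction shift is therefore −79.9165 Da monoisotopic and
−78.97 Da average. Charge ladders use m/z = (M + z·1.007276)/z.

Conversion from extracted-ion-chromatogram integrals is computed per
charge state as product/(product + reactant), then averaged (unweighted)
across charge states with the sample standard deviation (ddof = 1)
reported as the error — the convention used for intact-protein conversion
reporting from a single experiment. This assumes equal ionization
efficiency of reactant and product at each charge state; the package
states the assumption and does not correct for it. A single usable charge
state returns SD = 0 with a warning.

## Synthetic data

Generators return (data, truth) pairs; recovery tests consume only the
data. Noise models: multiplicative lognormal (stated CV, unit mean) for
kinetic concentration observations, since concentrations are positive;
Poisson per-bin counts for TCSPC; multiplicative Gaussian for MS centroid
intensities. All randomness flows through explicit integer seeds; equal
seeds give byte-identical output.

What passing tests show — and what they do not: the generators emulate the
statistical structure the estimators assume (exponential mixtures with
Poisson counting noise, clean centroided envelopes at exact ladder
positions, noisy readouts of the package's own kinetic model). Real
instrument data add baseline drift, IRF, detector dead-time,
chromatographic tailing, ionization suppression and matrix effects that
are deliberately absent, so parameter recovery here validates the
estimators' correctness, not their robustness to instrument artefacts.

## Problem sizes and numerical choices

Default test and analysis sizes: 360 s simulations on a ~12-species
network (sub-second each); 200 Gillespie replicates on 10³–10⁴-copy toy
networks; TCSPC traces of 10⁴–10⁵ photons in ~1000 bins with 20-seed
recovery batches; isotope envelopes up to ~150-atom peptide dimers.
Ties and degeneracies: conversion clips at 0 from below (solver-level
negative dust), envelope peaks merge by abundance-weighted centroid,
charge-state conversions with zero total signal are skipped (all-zero
pools are an error), and the barrier sweep records per-point failures in
its output table instead of aborting.

## Known limitations

- Network topology is fixed to the proposed cycle plus documented optional
  channels; no mechanism discovery.
- No photon transport or absorbance modelling: k_exc is an effective rate,
  and reactor geometry is out of scope.
- Electron-transfer steps take effective barriers as inputs; no Marcus
  machinery.
- No fitting of rate constants to experimental time courses; the fitting
  surface is synthetic data only.
- The ~10⁶ steric gating ratio and the default TS-VIII offset are
  sensitive to barriers that carry the usual DFT uncertainty (±1–2
  kcal/mol ≈ one to two orders of magnitude in rate at 298 K); conclusions
  here are about the structure of the kinetics, not ±10% rate accuracy.
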