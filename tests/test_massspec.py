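"""Formulas, isotope envelopes, charge ladders, conversion statistics."""

import re
import warnings

import numpy as np
import pytest

from pdckit.constants import ISOTOPES, PROTON_MASS_DA
from pdckit.massspec import (
    MolecularFormula,
    XicIntegrals,
    charge_ladder,
    contraction_mass_shift,
    conversion_from_xic,
    isotope_pattern,
    peptide_formula,
)


def formula(text: str) -> MolecularFormula:
    return MolecularFormula.from_dict(
        {el: int(n) for el, n in re.findall(r"([A-Z][a-z]?)(\d+)", text)}
    )


def brute_force_envelope(f: MolecularFormula, prune_threshold=1e-6,
                         resolution=1e-3):
    """Independent oracle: exact atom-by-atom polynomial expansion, binned
    and pruned the way the envelope convention states."""
    dist = {0.0: 1.0}
    for el, n in f.counts:
        for _ in range(n):
            new = {}
            for m, a in dist.items():
                for mi, ai in ISOTOPES[el]:
                    new[m + mi] = new.get(m + mi, 0.0) + a * ai
            dist = new
    masses = np.array(sorted(dist))
    ab = np.array([dist[m] for m in masses])
    keys = np.round(masses / resolution).astype(np.int64)
    agg = {}
    for k, m, a in zip(keys, masses, ab):
        s, sm = agg.get(k, (0.0, 0.0))
        agg[k] = (s + a, sm + m * a)
    km = sorted(agg)
    A = np.array([agg[k][0] for k in km])
    M = np.array([agg[k][1] / agg[k][0] for k in km])
    keep = A / A.sum() >= prune_threshold
    return M[keep], A[keep] / A[keep].sum()


class TestPeptideFormula:
    def test_glycine(self):
        assert peptide_formula("G").as_dict() == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_amide_terminus(self):
        free = peptide_formula("G").as_dict()
        amide = peptide_formula("G", termini="amide").as_dict()
        assert amide == {"C": 2, "H": 6, "N": 2, "O": 1}
        assert amide["O"] == free["O"] - 1

    def test_diselenide_dimer_is_two_chains_minus_two_H(self):
        chain = peptide_formula("USPGYS", termini="amide")
        dimer = peptide_formula("USPGYS", termini="amide",
                                linkage="diselenide_dimer")
        assert dimer.as_dict() == (2 * chain - MolecularFormula.from_dict(
            {"H": 2})).as_dict()
        assert dimer.as_dict()["Se"] == 2

    def test_contraction_removes_exactly_one_selenium(self):
        dimer = peptide_formula("USPGYS", termini="amide",
                                linkage="diselenide_dimer")
        ether = peptide_formula("USPGYS", termini="amide",
                                linkage="selenoether_dimer")
        diff = (dimer - ether).as_dict()
        assert diff == {"Se": 1}

    def test_asymmetric_diselenide(self):
        peg = formula("C12H26O6Se1")
        asym = peptide_formula("U", linkage="asymmetric_diselenide", partner=peg)
        assert asym.as_dict()["Se"] == 2

    def test_linkage_without_sec_rejected(self):
        with pytest.raises(ValueError, match="Sec"):
            peptide_formula("GASP", linkage="diselenide_dimer")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            peptide_formula("GXZ")


class TestIsotopePattern:
    @pytest.mark.parametrize(
        "text",
        ["H2", "Se1", "Se2", "C2H5N1O2", "C3H5N1O1Se1", "C6H10N2O2S1Se1",
         "C10H12O4Se2", "C14H4F10Se2", "C5H8N1O2P1", "C4H6N2O2S2"],
    )
    def test_matches_brute_force_polynomial_expansion(self, text):
        f = formula(text)
        env = isotope_pattern(f)
        M, A = brute_force_envelope(f)
        assert len(M) == len(env.masses)
        assert np.max(np.abs(M - env.masses)) < 1e-6
        assert np.max(np.abs(A - env.abundances)) < 1e-10

    def test_h2_dominated_by_light_isotopologue(self):
        env = isotope_pattern(formula("H2"), prune_threshold=1e-9)
        assert len(env.masses) == 3
        assert env.base_peak_mass == pytest.approx(2.01565, abs=1e-4)

    def test_selenium_base_peak_is_se80(self):
        env = isotope_pattern(formula("Se1"))
        assert env.base_peak_mass == pytest.approx(79.9165, abs=1e-4)
        assert len(env.masses) == 6

    def test_se2_is_self_convolution_of_se1(self):
        se1 = isotope_pattern(formula("Se1"), prune_threshold=1e-8)
        se2 = isotope_pattern(formula("Se2"), prune_threshold=1e-8)
        m = (se1.masses[:, None] + se1.masses[None, :]).ravel()
        a = (se1.abundances[:, None] * se1.abundances[None, :]).ravel()
        agg = {}
        for mi, ai in zip(np.round(m, 3), a):
            agg[mi] = agg.get(mi, 0.0) + ai
        for mass, ab in zip(se2.masses, se2.abundances):
            assert agg[round(mass, 3)] == pytest.approx(ab, abs=1e-9)

    def test_probability_normalization(self):
        env = isotope_pattern(formula("C6H10N2O2S1Se1"))
        assert env.abundances.sum() == pytest.approx(1.0, abs=1e-12)
        assert env.max_normalized.max() == 1.0

    def test_selenoether_envelope_is_diselenide_deconvolved_by_one_se(self):
        """Re-convolving the contraction product's envelope with one Se
        distribution reproduces the diselenide envelope."""
        dimer = peptide_formula("US", termini="amide", linkage="diselenide_dimer")
        ether = peptide_formula("US", termini="amide", linkage="selenoether_dimer")
        env_d = isotope_pattern(dimer, prune_threshold=1e-8)
        env_e = isotope_pattern(ether, prune_threshold=1e-8)
        se = isotope_pattern(formula("Se1"), prune_threshold=1e-8)
        m = (env_e.masses[:, None] + se.masses[None, :]).ravel()
        a = (env_e.abundances[:, None] * se.abundances[None, :]).ravel()
        # compare probability mass per 0.1 Da bin: coarse enough that the
        # sub-nominal fine structure cannot straddle bin edges
        def coarse(masses, abunds):
            agg = {}
            for k, ai in zip(np.round(masses / 0.1).astype(np.int64), abunds):
                agg[k] = agg.get(k, 0.0) + ai
            return agg
        recon = coarse(m, a)
        direct = coarse(env_d.masses, env_d.abundances)
        # tolerance reflects the 1e-8 envelope pruning and renormalisation
        for k, ab in direct.items():
            if ab > 1e-5:
                assert recon.get(k, 0.0) == pytest.approx(ab, rel=1e-2)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="isotope table"):
            isotope_pattern(MolecularFormula.from_dict({"Zz": 1}))

    def test_prune_threshold_domain(self):
        with pytest.raises(ValueError, match="prune"):
            isotope_pattern(formula("H2"), prune_threshold=0.5)


class TestMassShiftAndLadder:
    def test_contraction_shift_conventions(self):
        assert contraction_mass_shift("monoisotopic") == pytest.approx(
            -79.9165, abs=1e-4
        )
        assert contraction_mass_shift("average") == pytest.approx(-78.97, abs=5e-3)

    def test_shift_consistent_with_formula_arithmetic(self):
        dimer = peptide_formula("USPGYS", termini="amide",
                                linkage="diselenide_dimer")
        ether = peptide_formula("USPGYS", termini="amide",
                                linkage="selenoether_dimer")
        assert ether.monoisotopic_mass() - dimer.monoisotopic_mass() == (
            pytest.approx(contraction_mass_shift("monoisotopic"), abs=1e-9)
        )
        assert ether.average_mass() - dimer.average_mass() == pytest.approx(
            contraction_mass_shift("average"), abs=1e-9
        )

    def test_singly_protonated(self):
        assert charge_ladder(1000.0, [1])[0] == pytest.approx(1001.007276)

    def test_protein_scale_charge_state(self):
        mz = charge_ladder(16700.0, [10])[0]
        assert mz == pytest.approx((16700.0 + 10 * PROTON_MASS_DA) / 10)
        assert mz == pytest.approx(1671.007, abs=1e-3)

    def test_ladder_decreasing_in_charge(self):
        ladder = charge_ladder(16700.0, [7, 8, 9, 10, 11])
        assert all(later < earlier for earlier, later in zip(ladder, ladder[1:]))

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError, match="charge"):
            charge_ladder(1000.0, [0])


class TestConversionFromXic:
    def test_equal_integrals_give_half(self):
        x = XicIntegrals({9: (3.0, 3.0), 10: (7.0, 7.0), 11: (1.0, 1.0)})
        mean, sd = conversion_from_xic(x)
        assert mean == 0.5 and sd == 0.0

    def test_three_charge_state_worked_example(self):
        # (reactant, product) integrals per z: conversions 0.9, 1.0, 11/12
        x = XicIntegrals({11: (1.0, 9.0), 10: (0.0, 10.0), 9: (1.0, 11.0)})
        mean, sd = conversion_from_xic(x)
        assert mean == pytest.approx(0.939, abs=1e-3)
        assert sd == pytest.approx(0.053, abs=1e-3)

    def test_single_charge_state_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning, match="single"):
            mean, sd = conversion_from_xic(XicIntegrals({10: (1.0, 3.0)}))
        assert mean == pytest.approx(0.75) and sd == 0.0

    def test_scale_invariance(self):
        base = {9: (1.0, 9.0), 10: (2.0, 8.0), 11: (3.0, 7.0)}
        scaled = {z: (r * 1e6, p * 1e6) for z, (r, p) in base.items()}
        assert conversion_from_xic(XicIntegrals(base)) == pytest.approx(
            conversion_from_xic(XicIntegrals(scaled))
        )

    def test_all_zero_pool_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            conversion_from_xic(XicIntegrals({10: (0.0, 0.0)}))
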