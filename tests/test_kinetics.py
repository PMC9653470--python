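"""Deterministic and stochastic microkinetics of the contraction cycle."""

import math

import numpy as np
import pytest

from pdckit.constants import R_KCAL_PER_MOL_K
from pdckit.kinetics import (
    ConcentrationTrajectory,
    ReactionConditions,
    barrier_sweep,
    conversion,
    default_pdc_conditions,
    pdc_network_for_barrier,
    simulate,
    simulate_stochastic,
)
from pdckit.network import (
    ElementaryStep,
    ReactionNetwork,
    Species,
    assign_rate_constants,
    build_pdc_network,
)


def toy_network(steps, species):
    return assign_rate_constants(ReactionNetwork(species, steps))


def first_order_ab(k=0.1):
    net = ReactionNetwork(
        [Species("A"), Species("B")],
        [ElementaryStep("ab", [("A", 1)], [("B", 1)], "decay", 0.0,
                        k_fwd_override=k)],
    )
    return assign_rate_constants(net)


@pytest.fixture(scope="module")
def rate_assigned_default():
    return assign_rate_constants(build_pdc_network())


class TestDeterministic:
    def test_dark_control_is_static(self, rate_assigned_default):
        """Without photoexcitation nothing reacts: the light-off control."""
        cond = default_pdc_conditions(k_exc=0.0, t_end=300.0)
        traj = simulate(rate_assigned_default, cond)
        for sp in ("RSeSeR", "I", "PC", "V"):
            assert np.allclose(traj[sp], traj[sp][0], atol=1e-12)
        assert np.all(traj["V"] == 0.0)

    def test_irreversible_first_order_matches_closed_form(self):
        net = first_order_ab(k=0.1)
        cond = ReactionConditions({"A": 1.0}, t_end=10.0)
        traj = simulate(net, cond)
        expected = 1.0 - np.exp(-0.1 * traj.time)
        conv = conversion(traj, "A", "B")
        assert np.max(np.abs(conv - expected)) < 1e-6
        assert conv[-1] == pytest.approx(1 - math.e**-1, abs=1e-6)

    def test_reversible_isomerization_reaches_boltzmann_ratio(self):
        dg = -1.5
        net = assign_rate_constants(
            ReactionNetwork(
                [Species("A"), Species("B")],
                [ElementaryStep("iso", [("A", 1)], [("B", 1)], "decay", 3.0,
                                dg_rxn=dg, reversible=True)],
            )
        )
        cond = ReactionConditions({"A": 1.0}, t_end=50.0)
        traj = simulate(net, cond)
        ratio = traj["B"][-1] / traj["A"][-1]
        assert ratio == pytest.approx(
            math.exp(-dg / (R_KCAL_PER_MOL_K * 298.15)), rel=1e-6
        )

    def test_conservation_and_nonnegativity(self, rate_assigned_default):
        cond = default_pdc_conditions()
        traj = simulate(rate_assigned_default, cond)
        names = traj.species_names
        for element in ("Se", "P"):
            w = np.array(
                [rate_assigned_default.species_by_name(s).count(element)
                 for s in names], dtype=float,
            )
            total = traj.concentrations @ w
            assert np.max(np.abs(total - total[0])) < 10 * (
                cond.rtol * total[0] + cond.atol * len(names)
            )
        cat = sum(traj[s] for s in ("PC", "PC*", "PC_red"))
        assert np.max(np.abs(cat - cat[0])) < 10 * (cond.rtol * cat[0] + cond.atol)
        assert traj.concentrations.min() >= -cond.atol

    def test_phosphine_selenide_tracks_selenoether(self, rate_assigned_default):
        """The extruded-Se byproduct accumulates monotonically, 1:1 with
        the selenoether product."""
        traj = simulate(rate_assigned_default, default_pdc_conditions())
        assert np.all(np.diff(traj["VI"]) >= -1e-12)
        assert traj["VI"][-1] == pytest.approx(traj["V"][-1], rel=1e-6)


class TestStochastic:
    def test_fixed_seed_is_bit_identical(self):
        net = first_order_ab()
        cond = ReactionConditions({"A": 1e-18}, t_end=10.0)
        t1 = simulate_stochastic(net, cond, system_volume=1e-3, seed=42)
        t2 = simulate_stochastic(net, cond, system_volume=1e-3, seed=42)
        assert np.array_equal(t1.concentrations, t2.concentrations)

    def test_replicate_mean_matches_closed_form(self):
        # 1000 copies of A, k = 0.1/s: conversion at t = 10 near 1 - 1/e
        net = first_order_ab()
        scale = 6.02214076e23 * 1e-3
        cond = ReactionConditions({"A": 1000 / scale}, t_end=10.0)
        n_rep = 200
        finals = []
        for seed in range(n_rep):
            traj = simulate_stochastic(net, cond, 1e-3, seed=seed, n_points=5)
            finals.append(traj["B"][-1] / (1000 / scale))
        mean = np.mean(finals)
        se = np.std(finals, ddof=1) / math.sqrt(n_rep)
        assert abs(mean - (1 - math.e**-1)) < 3 * se + 1e-12

    def test_integer_selenium_conservation_every_checkpoint(self):
        net = assign_rate_constants(
            ReactionNetwork(
                [
                    Species("D", atom_counts={"Se": 2}),
                    Species("M", atom_counts={"Se": 1}),
                    Species("X", atom_counts={"Se": 1}),
                ],
                [
                    ElementaryStep("split", [("D", 1)], [("M", 1), ("X", 1)],
                                   "decay", 0.0, k_fwd_override=0.5),
                    ElementaryStep("join", [("M", 1), ("X", 1)], [("D", 1)],
                                   "association", "barrierless"),
                ],
            ),
            # modest bimolecular rate so both directions fire
        )
        scale = 6.02214076e23 * 1e-18
        cond = ReactionConditions({"D": 200 / scale}, t_end=5.0)
        traj = simulate_stochastic(net, cond, 1e-18, seed=7, n_points=40)
        se_total = (traj.concentrations * scale) @ np.array([2.0, 1.0, 1.0])
        assert np.allclose(se_total, se_total[0], atol=1e-9)

    def test_deadlock_flagged_as_absorbed(self):
        net = first_order_ab(k=50.0)
        scale = 6.02214076e23 * 1e-3
        cond = ReactionConditions({"A": 5 / scale}, t_end=100.0)
        traj = simulate_stochastic(net, cond, 1e-3, seed=1)
        assert traj.metadata["absorbed"] is True
        assert traj["A"][-1] == 0.0


class TestConversion:
    def test_toy_three_point_arithmetic(self):
        traj = ConcentrationTrajectory(
            time=np.array([0.0, 1.0, 2.0]),
            concentrations=np.array([[1.0, 0.0], [0.6, 0.4], [0.1, 0.9]]),
            species_names=["S", "P"],
            se_counts={"S": 0, "P": 0},
        )
        conv = conversion(traj, "S", "P")
        assert conv.tolist() == pytest.approx([0.0, 0.4, 0.9])

    def test_selenium_equivalents_weighting(self):
        # diselenide (2 Se) splitting into selenoether (1 Se) + selenide (1 Se)
        traj = ConcentrationTrajectory(
            time=np.array([0.0, 1.0]),
            concentrations=np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
            species_names=["D", "V", "VI"],
            se_counts={"D": 2, "V": 1, "VI": 1},
        )
        conv = conversion(traj, "D", ["V", "VI"])
        assert conv[1] == pytest.approx(0.5)
        # counting the selenoether alone covers half the Se pool at most
        assert conversion(traj, "D", "V")[1] == pytest.approx(0.25)

    def test_full_conversion_reads_one(self, rate_assigned_default):
        traj = simulate(rate_assigned_default, default_pdc_conditions(t_end=600.0))
        conv = conversion(traj, "RSeSeR", ["V", "VI"])
        assert conv[0] == 0.0
        assert conv[-1] == pytest.approx(1.0, abs=1e-4)
        assert np.all(np.diff(conv) >= -1e-9)

    def test_zero_pool_reported_undefined(self):
        traj = ConcentrationTrajectory(
            time=np.array([0.0, 1.0]),
            concentrations=np.zeros((2, 2)),
            species_names=["S", "P"],
            se_counts={"S": 1, "P": 1},
        )
        with pytest.raises(ValueError, match="undefined"):
            conversion(traj, "S", "P")


class TestBarrierSweepAndGating:
    def test_steric_grid_is_ordered_and_gated(self):
        cond = default_pdc_conditions()
        table = barrier_sweep(pdc_network_for_barrier, [17.2, 17.8, 25.4], cond)
        c = table["final_conversion"].to_numpy()
        assert c[0] >= c[1] >= c[2]
        assert c[0] >= 0.90
        assert c[2] <= 0.01

    def test_single_point_grid(self):
        table = barrier_sweep(
            pdc_network_for_barrier, [20.0], default_pdc_conditions(t_end=60.0)
        )
        assert len(table) == 1

    def test_zero_barrier_is_supply_limited(self):
        """At a vanishing substitution barrier the photon/electron supply,
        not the substitution, limits conversion: halving k_exc roughly
        halves early progress."""
        cond_fast = default_pdc_conditions(k_exc=5.0, t_end=20.0)
        cond_slow = default_pdc_conditions(k_exc=2.5, t_end=20.0)
        c_fast = barrier_sweep(pdc_network_for_barrier, [0.0], cond_fast)
        c_slow = barrier_sweep(pdc_network_for_barrier, [0.0], cond_slow)
        ratio = (c_fast["final_conversion"] / c_slow["final_conversion"]).iloc[0]
        assert 1.5 < ratio <= 2.5

    def test_out_of_range_barrier_rejected(self):
        with pytest.raises(ValueError, match="40"):
            barrier_sweep(pdc_network_for_barrier, [45.0], default_pdc_conditions())

    def test_time_to_half_conversion_gap_spans_four_decades(self):
        """Bulky/bulky gating: t50 at 25.4 kcal/mol exceeds t50 at 17.2 by
        >= 4 orders of magnitude, consistent with the ~1e6 Eyring ratio."""
        t50 = {}
        for barrier, t_end in ((17.2, 360.0), (25.4, 2e6)):
            net = pdc_network_for_barrier(barrier)
            cond = default_pdc_conditions(t_end=t_end)
            traj = simulate(net, cond, n_points=400)
            conv = conversion(traj, "RSeSeR", ["V", "VI"])
            assert conv[-1] > 0.5
            t50[barrier] = float(np.interp(0.5, conv, traj.time))
        assert t50[25.4] / t50[17.2] >= 1e4
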