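"""Maxwell–Boltzmann survival function, kinetic dominance, and verdicts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from qcfill.feasibility import (
    ExplorationStats,
    FeasibilityConfig,
    TargetReaction,
    assess,
    dominance_ratio,
    mb_survival,
    thermo_filter,
)
from qcfill.molecule_io import connectivity_key, parse_smiles
from qcfill.reaction_network import ElementaryStep, ReactionNetwork


def mb_survival_quadrature(energy, config):
    """Independent oracle: numerical quadrature of the 3-DOF MB kinetic-energy
    density f(E) = (2/√π)·√(E)/(RT)^{3/2}·e^(−E/RT), integrated from E to ∞.

    The exponential tail e^(−E/RT) is factored out analytically so the
    quadrature stays relatively accurate even when the survival probability
    is ~1e-35 (barriers of hundreds of kJ/mol)."""
    rt = config.rt
    x = energy / rt

    def shifted_density(t):  # density at E + t·RT, scaled by e^{x}
        return (2.0 / math.sqrt(math.pi)) * math.sqrt(x + t) * math.exp(-t)

    integral, _ = integrate.quad(shifted_density, 0.0, np.inf)
    return math.exp(-x) * integral


# ----------------------------------------------------------------------
# survival function
# ----------------------------------------------------------------------


class TestSurvival:
    def test_zero_threshold_means_certainty(self):
        assert mb_survival(0.0) == pytest.approx(1.0)

    def test_value_at_thermal_energy(self):
        config = FeasibilityConfig(temperature=373.15)
        assert mb_survival(config.rt, config) == pytest.approx(0.5724, abs=1e-4)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            mb_survival(-1.0)

    @pytest.mark.parametrize("temperature", [298.15, 373.15, 500.0])
    def test_matches_quadrature_oracle_on_grid(self, temperature):
        config = FeasibilityConfig(temperature=temperature)
        for energy in range(0, 301, 10):
            closed = mb_survival(float(energy), config)
            oracle = mb_survival_quadrature(float(energy), config)
            assert closed == pytest.approx(oracle, rel=1e-6)

    @given(
        e1=st.floats(min_value=0.0, max_value=400.0),
        e2=st.floats(min_value=0.0, max_value=400.0),
    )
    def test_strictly_decreasing(self, e1, e2):
        lo, hi = sorted((e1, e2))
        if hi - lo > 1e-9:
            assert mb_survival(lo) > mb_survival(hi)


class TestDominanceRatio:
    def test_case_study_window_is_four_orders_of_magnitude(self):
        config = FeasibilityConfig(temperature=373.15)
        ratio = dominance_ratio(218.0, 250.0, config)
        assert 1e4 <= ratio < 1e5
        assert math.floor(math.log10(ratio)) == 4

    def test_agrees_with_quadrature_oracle(self):
        config = FeasibilityConfig(temperature=373.15)
        closed = dominance_ratio(100.0, 132.0, config)
        s_lo = mb_survival_quadrature(100.0, config)
        s_hi = mb_survival_quadrature(132.0, config)
        assert closed == pytest.approx((s_lo - s_hi) / s_hi, rel=1e-6)

    def test_vanishing_window_vanishes(self):
        assert dominance_ratio(100.0, 100.0 + 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            dominance_ratio(250.0, 218.0)


# ----------------------------------------------------------------------
# network-level verdicts
# ----------------------------------------------------------------------

SPECIES = {
    "A": "CCI",
    "B": "Oc1ccccc1",
    "target": "CCOc1ccccc1",
    "ortho": "CCc1ccccc1O",
    "para": "CCc1ccc(O)cc1",
    "endo": "OCCI",
}


def build_network(channels):
    """Small reaction network over the ether-synthesis species.

    ``channels``: list of (product label, barrier, reaction energy).
    Connectivity keys stand in for real structures (graph identity is all
    aggregation needs)."""
    from qcfill.molecule_io import Atom, MolGraph, Structure

    net = ReactionNetwork()
    sids = {}
    for label, smiles in SPECIES.items():
        graph = MolGraph(atoms=(Atom(element="C"),), bonds=())
        s = Structure(graph=graph, elements=("C",), coordinates=[[0, 0, 0]],
                      charge=0, multiplicity=1)
        sids[label] = net.add_structure(s, key=connectivity_key(parse_smiles(smiles)))
    for n, (product, barrier, de) in enumerate(channels):
        net.register_step(
            ElementaryStep(
                id=f"st{n}",
                reactant_structure_ids=(sids["A"], sids["B"]),
                product_structure_ids=(sids[product],),
                e_react=0.0,
                e_ts=barrier,
                e_prod=de,
            )
        )
    return net


def target():
    return TargetReaction(
        reactant_keys=(
            connectivity_key(parse_smiles(SPECIES["A"])),
            connectivity_key(parse_smiles(SPECIES["B"])),
        ),
        product_keys=(connectivity_key(parse_smiles(SPECIES["target"])),),
    )


CASE_STUDY = [
    ("target", 218.0, -34.0),
    ("ortho", 250.0, -48.0),
    ("para", 253.0, -52.0),
    ("endo", 160.0, +10.0),
]


class TestThermoFilter:
    def test_sign_rule_removes_only_endothermic(self):
        net = build_network(CASE_STUDY)
        survivors = thermo_filter(net)
        assert len(survivors) == 3
        energies = {net.reactions[r].reaction_energy for r in survivors}
        assert energies == {-34.0, -48.0, -52.0}

    def test_all_endothermic_leaves_nothing(self):
        net = build_network([("endo", 160.0, 10.0), ("ortho", 250.0, 5.0)])
        assert thermo_filter(net) == []


class TestAssess:
    def test_dominant_target_is_validated(self):
        verdict = assess(build_network(CASE_STUDY), target())
        assert verdict.status == "validated"
        assert verdict.target_barrier == 218.0
        assert verdict.target_energy == -34.0
        assert len(verdict.competitors) == 2  # only the more exothermic pair
        assert verdict.dominance_ratio > 1e4

    def test_dominance_reversal_invalidates(self):
        reversed_case = [
            ("target", 260.0, -34.0),
            ("ortho", 250.0, -48.0),
            ("para", 253.0, -52.0),
        ]
        verdict = assess(build_network(reversed_case), target())
        assert verdict.status == "invalidated"

    def test_endothermic_target_invalidated(self):
        verdict = assess(build_network([("target", 218.0, +20.0)]), target())
        assert verdict.status == "invalidated"
        assert any("endothermic" in d for d in verdict.diagnostics)

    def test_all_errors_is_inconclusive(self):
        net = build_network([])
        stats = ExplorationStats(
            n_trials_planned=10, n_trials_run=10, n_errors=10, error_budget=0
        )
        verdict = assess(net, target(), exploration=stats)
        assert verdict.status == "inconclusive"

    def test_incomplete_exploration_without_target_is_inconclusive(self):
        stats = ExplorationStats(n_trials_planned=84, n_trials_run=10)
        verdict = assess(build_network([]), target(), exploration=stats)
        assert verdict.status == "inconclusive"

    def test_missing_target_in_complete_exploration_invalidates(self):
        net = build_network([("ortho", 250.0, -48.0)])
        stats = ExplorationStats(n_trials_planned=84, n_trials_run=84)
        verdict = assess(net, target(), exploration=stats)
        assert verdict.status == "invalidated"
        assert not verdict.target_found

    @pytest.mark.parametrize("threshold", [1.0, 100.0, 1e4, 1e6])
    def test_monotone_in_dominance_threshold(self, threshold):
        # raising the threshold can only flip validated → invalidated
        config = FeasibilityConfig(dominance_threshold=threshold)
        verdict = assess(build_network(CASE_STUDY), target(), config)
        expected = "validated" if threshold <= dominance_ratio(218.0, 250.0, config) else "invalidated"
        assert verdict.status == expected
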