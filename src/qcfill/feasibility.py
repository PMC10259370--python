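"""Feasibility verdicts: thermodynamic rule-out and kinetic dominance.

Given an explored reaction network and a target reaction, a verdict is
reached in two stages.  First, assuming thermodynamic control, endothermic
reactions (ΔE above a tolerance) are ruled out.  Second, among the surviving
exothermic alternatives, the target must dominate kinetically: for every
competitor that is *more* exothermic than the target but has a higher
barrier, the fraction of the reactant ensemble with kinetic energy above the
target's barrier but below the competitor's must exceed the fraction able to
cross the competitor's barrier by a configurable factor.  The kinetic-energy
distribution is the three-translational-degree-of-freedom Maxwell–Boltzmann
form, whose survival function has the closed form

    P(KE > E) = erfc(√x) + (2/√π)·√x·e^(−x),   x = E/(RT),

i.e. the regularized upper incomplete gamma function Q(3/2, x).  The analysis
uses total electronic energies only — no zero-point, thermal, or entropic
corrections — matching the barrier data the exploration provides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .reaction_network import Reaction, ReactionNetwork

__all__ = [
    "FeasibilityConfig",
    "TargetReaction",
    "ExplorationStats",
    "Verdict",
    "GAS_CONSTANT_KJ",
    "mb_survival",
    "dominance_ratio",
    "thermo_filter",
    "assess",
]

#: Molar gas constant in kJ mol⁻¹ K⁻¹.
GAS_CONSTANT_KJ = 8.3144626e-3


@dataclass(frozen=True)
class FeasibilityConfig:
    """Thresholds of the feasibility analysis.

    ``temperature``: reaction temperature in K (default 373.15 K = 100 °C).
    ``endo_tol``: reactions with ΔE above this (kJ/mol) are ruled out.
    ``dominance_threshold``: minimum population ratio for the target to be
    declared kinetically dominant (≥ 1; the default 100 is deliberately
    conservative — clear-cut cases exceed 10⁴).
    """

    temperature: float = 373.15  # K
    endo_tol: float = 0.0  # kJ/mol
    dominance_threshold: float = 100.0
    gas_constant: float = GAS_CONSTANT_KJ  # kJ/(mol K)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dominance_threshold < 1:
            raise ValueError("dominance_threshold must be ≥ 1")

    @property
    def rt(self) -> float:
        """Thermal energy RT in kJ/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class TargetReaction:
    """The reaction the AI model proposed, as compound connectivity keys.

    ``product_keys`` may name only the compound of interest; a network
    reaction matches when its reactant multiset equals ``reactant_keys`` and
    its product multiset contains every listed product (unnamed byproducts
    such as the leaving group are tolerated).
    """

    reactant_keys: tuple[str, ...]
    product_keys: tuple[str, ...]


@dataclass(frozen=True)
class ExplorationStats:
    """Bookkeeping the verdict needs about how the exploration went."""

    n_trials_planned: int = 0
    n_trials_run: int = 0
    n_errors: int = 0
    error_budget: int = 0

    @property
    def complete(self) -> bool:
        return self.n_trials_run >= self.n_trials_planned

    @property
    def within_error_budget(self) -> bool:
        return self.n_errors <= self.error_budget


@dataclass(frozen=True)
class Verdict:
    status: str  # "validated" | "invalidated" | "inconclusive"
    target_found: bool
    target_barrier: Optional[float] = None  # kJ/mol
    target_energy: Optional[float] = None  # kJ/mol
    competitors: tuple[tuple[str, float, float], ...] = ()  # (reaction id, barrier, ΔE)
    dominance_ratio: Optional[float] = None
    diagnostics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status == "validated" and not self.target_found:
            raise ValueError("a validated verdict requires the target reaction")


# --------------------------------------------------------------------------
# Maxwell–Boltzmann kinetics
# --------------------------------------------------------------------------


def mb_survival(energy: float, config: FeasibilityConfig = FeasibilityConfig()) -> float:
    """P(KE > E) for the 3-DOF Maxwell–Boltzmann kinetic-energy distribution.

    ``energy`` in kJ/mol, ≥ 0.  Closed form Q(3/2, E/RT); equals 1 at E = 0
    and decays as (2/√π)·√x·e^(−x) for large x.
    """
    if energy < 0:
        raise ValueError("kinetic energy threshold must be non-negative")
    x = energy / config.rt
    sx = math.sqrt(x)
    return math.erfc(sx) + (2.0 / math.sqrt(math.pi)) * sx * math.exp(-x)


def dominance_ratio(
    barrier_lo: float,
    barrier_hi: float,
    config: FeasibilityConfig = FeasibilityConfig(),
) -> float:
    """Population able to cross only the lower barrier, relative to the
    population able to cross the higher one.

    [P(lo < KE) − P(hi < KE)] / P(hi < KE): the number of molecules with
    kinetic energy in the window (lo, hi] per molecule above hi.  A large
    ratio means the low-barrier channel overwhelmingly dominates.
    """
    if barrier_lo < 0:
        raise ValueError("barriers must be non-negative")
    if barrier_lo >= barrier_hi:
        raise ValueError("barrier_lo must be strictly below barrier_hi")
    s_lo = mb_survival(barrier_lo, config)
    s_hi = mb_survival(barrier_hi, config)
    return (s_lo - s_hi) / s_hi


# --------------------------------------------------------------------------
# filters and verdicts
# --------------------------------------------------------------------------


def thermo_filter(
    network: ReactionNetwork, config: FeasibilityConfig = FeasibilityConfig()
) -> list[str]:
    """Reaction ids surviving the endothermic rule-out (ΔE ≤ ``endo_tol``)."""
    return [
        r.id
        for r in network.reactions.values()
        if r.reaction_energy <= config.endo_tol
    ]


def _find_target(network: ReactionNetwork, target: TargetReaction) -> Optional[Reaction]:
    want_reactants = tuple(
        sorted(filter(None, (network.compound_by_key(k) for k in target.reactant_keys)))
    )
    if len(want_reactants) != len(target.reactant_keys):
        return None  # some target compound never entered the network
    want_products = [network.compound_by_key(k) for k in target.product_keys]
    if any(p is None for p in want_products):
        return None
    for reaction in network.reactions.values():
        if reaction.reactant_compounds != want_reactants:
            continue
        pool = list(reaction.product_compounds)
        if all(p in pool and (pool.remove(p) or True) for p in want_products):
            return reaction
    return None


def assess(
    network: ReactionNetwork,
    target: TargetReaction,
    config: FeasibilityConfig = FeasibilityConfig(),
    exploration: Optional[ExplorationStats] = None,
) -> Verdict:
    """Combine the thermodynamic and kinetic screens into a verdict.

    * ``validated`` — the target reaction was found, is not endothermic, and
      kinetically dominates every surviving competitor that is more
      exothermic than it (population ratio ≥ ``dominance_threshold``).
    * ``invalidated`` — the target was not found although the exploration
      completed, is ruled out thermodynamically, or is dominated by a
      competitor with an equal or lower barrier / insufficient ratio.
    * ``inconclusive`` — the exploration was incomplete or exceeded its
      error budget, so absence of evidence is not evidence of absence.
    """
    diagnostics: list[str] = []
    exploration_ok = exploration is None or (
        exploration.complete and exploration.within_error_budget
    )
    if exploration is not None and not exploration.complete:
        diagnostics.append(
            f"exploration incomplete: {exploration.n_trials_run} of "
            f"{exploration.n_trials_planned} trials run"
        )
    if exploration is not None and not exploration.within_error_budget:
        diagnostics.append(
            f"backend errors ({exploration.n_errors}) exceeded budget "
            f"({exploration.error_budget})"
        )

    reaction = _find_target(network, target)
    if reaction is None:
        if exploration_ok:
            return Verdict(
                status="invalidated",
                target_found=False,
                diagnostics=tuple(diagnostics + ["target reaction not found"]),
            )
        return Verdict(
            status="inconclusive", target_found=False, diagnostics=tuple(diagnostics)
        )

    barrier = reaction.best_barrier
    energy = reaction.reaction_energy
    if not exploration_ok:
        return Verdict(
            status="inconclusive",
            target_found=True,
            target_barrier=barrier,
            target_energy=energy,
            diagnostics=tuple(diagnostics),
        )

    survivors = set(thermo_filter(network, config))
    if reaction.id not in survivors:
        return Verdict(
            status="invalidated",
            target_found=True,
            target_barrier=barrier,
            target_energy=energy,
            diagnostics=tuple(
                diagnostics
                + [f"target is endothermic (ΔE = {energy:+.1f} kJ/mol)"]
            ),
        )

    # competitors: surviving reactions more exothermic than the target
    competitors = tuple(
        (r.id, r.best_barrier, r.reaction_energy)
        for r in network.reactions.values()
        if r.id in survivors and r.id != reaction.id and r.reaction_energy < energy
    )
    min_ratio: Optional[float] = None
    for rid, comp_barrier, comp_energy in competitors:
        if comp_barrier <= barrier:
            return Verdict(
                status="invalidated",
                target_found=True,
                target_barrier=barrier,
                target_energy=energy,
                competitors=competitors,
                diagnostics=tuple(
                    diagnostics
                    + [
                        f"competitor {rid} is more exothermic with a barrier "
                        f"≤ the target's ({comp_barrier:.1f} vs {barrier:.1f} kJ/mol)"
                    ]
                ),
            )
        ratio = dominance_ratio(barrier, comp_barrier, config)
        min_ratio = ratio if min_ratio is None else min(min_ratio, ratio)
        if ratio < config.dominance_threshold:
            return Verdict(
                status="invalidated",
                target_found=True,
                target_barrier=barrier,
                target_energy=energy,
                competitors=competitors,
                dominance_ratio=ratio,
                diagnostics=tuple(
                    diagnostics
                    + [
                        f"population ratio vs competitor {rid} is {ratio:.3g} "
                        f"< threshold {config.dominance_threshold:g}"
                    ]
                ),
            )
    return Verdict(
        status="validated",
        target_found=True,
        target_barrier=barrier,
        target_energy=energy,
        competitors=competitors,
        dominance_ratio=min_ratio,
        diagnostics=tuple(diagnostics),
    )
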