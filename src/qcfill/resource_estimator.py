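"""Compute-budget arithmetic for reactive explorations.

The number of elementary-step trials, not the cost of any single one,
dominates the bill for larger explorations.  With semiempirical energies one
reaction trial averages out near 20 CPU seconds, so a single core sustains
604 800 / 20 = 30 240 trials in a week and a 100-core allocation about three
million.  Scaling is punishing: energy evaluations grow roughly
quadratically with system size and so does the number of candidate atom
pairs, so doubling the system size cuts weekly reaction coverage by
2² × 2² = 16.  These models turn a planned trial count into a simple
fits-or-not answer before any calculation is launched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BudgetModel",
    "ResourceReport",
    "SECONDS_PER_WEEK",
    "trials_in_budget",
    "coverage_factor",
    "feasibility_report",
]

SECONDS_PER_WEEK = 7 * 24 * 3600  # 604 800 s


@dataclass(frozen=True)
class BudgetModel:
    """Cost model of an exploration campaign.

    ``sec_per_trial`` is the average CPU cost of one elementary-step trial
    (successful and dead-end trials pooled; their ratio is roughly constant
    for a fixed exploration protocol, which is what makes the average
    usable).  The two exponents describe how per-evaluation cost and trial
    count grow with system size; both default to quadratic.
    ``success_fraction`` is an optional, purely informational estimate of
    the fraction of trials that discover a step.
    """

    cores: int = 1
    walltime_s: float = float(SECONDS_PER_WEEK)
    sec_per_trial: float = 20.0
    cost_scaling_exponent: float = 2.0
    trial_scaling_exponent: float = 2.0
    success_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.cores < 1:
            raise ValueError("cores must be a positive integer")
        if self.walltime_s < 0:
            raise ValueError("walltime must be non-negative")
        if self.sec_per_trial <= 0:
            raise ValueError("sec_per_trial must be positive")


def trials_in_budget(model: BudgetModel) -> int:
    """Number of whole trials the budget affords:
    ⌊cores × walltime / sec_per_trial⌋."""
    return int(math.floor(model.cores * model.walltime_s / model.sec_per_trial))


def coverage_factor(size_ratio: float, model: BudgetModel = BudgetModel()) -> float:
    """Factor by which reaction coverage shrinks when system size grows by
    ``size_ratio``: size_ratio^(cost exponent + trial exponent).

    Multiplicative: coverage_factor(a·b) = coverage_factor(a)·coverage_factor(b).
    """
    if size_ratio <= 0:
        raise ValueError("size_ratio must be positive")
    return size_ratio ** (model.cost_scaling_exponent + model.trial_scaling_exponent)


@dataclass(frozen=True)
class ResourceReport:
    fits: bool
    capacity: int
    planned_trials: int
    utilization: float
    advisory: str


def feasibility_report(model: BudgetModel, planned_trials: int) -> ResourceReport:
    """Check a planned trial count against the budget.

    ``utilization`` is planned/capacity (0 when nothing is planned).  The
    advisory is informational text only — it flags over-budget plans and
    reminds that switching to DFT energies costs a hardware-dependent factor
    of roughly 100–1000, which is never used in any computation here.
    """
    capacity = trials_in_budget(model)
    if planned_trials <= 0:
        utilization = 0.0
    elif capacity == 0:
        utilization = math.inf
    else:
        utilization = planned_trials / capacity
    fits = planned_trials <= capacity
    lines = [
        f"{planned_trials} planned trials vs capacity {capacity} "
        f"({model.cores} cores × {model.walltime_s:.0f} s at "
        f"{model.sec_per_trial:g} s/trial)."
    ]
    if not fits:
        lines.append(
            "Plan exceeds budget: tighten constraints (atom mapping, roles, "
            "stoichiometry) or raise the core count."
        )
    lines.append(
        "Note: DFT-quality energies typically cost a further factor of "
        "100–1000 per evaluation (hardware- and system-dependent)."
    )
    return ResourceReport(
        fits=fits,
        capacity=capacity,
        planned_trials=planned_trials,
        utilization=utilization,
        advisory=" ".join(lines),
    )
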