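"""Automated mass-balancing by iterative diet-matrix adjustment.

When a solved model has groups with EE > 1 (demand exceeds production), the
standard remedy is to shave the diet links that put the most pressure on the
over-consumed prey and redistribute the removed proportion across the
predator's other prey.  The redistribution weight of alternative prey *j*
for predator *i* is

    (DC_j^max - DC_j^mean) / sum_j (DC_j^max - DC_j^mean)

where max and mean are taken across the predators of *j* in the current diet
matrix: prey that some predator already exploits heavily relative to the
average absorbs more of the shifted proportion.  Each iteration moves a
fixed fraction of the offending link; columns stay exactly stochastic, and
predator consumption (B Q/B) is untouched -- only its composition moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balance import solve
from .model import FoodWebModel

__all__ = ["BalanceAudit", "DietEdit", "auto_balance"]


@dataclass
class DietEdit:
    iteration: int
    predator: str
    prey_reduced: str
    amount: float
    prey_raised: dict[str, float]


@dataclass
class BalanceAudit:
    iterations: int = 0
    converged: bool = False
    edits: list[DietEdit] = field(default_factory=list)
    ee_trajectory: list[dict[str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _redistribution_weights(dc: np.ndarray, predator: int, exclude: int, consumer_cols) -> np.ndarray:
    """Redistribution weights (DC_max - DC_mean) over the predator's other prey."""
    n = dc.shape[0]
    weights = np.zeros(n)
    for j in range(n):
        if j == exclude or dc[j, predator] <= 0:
            continue
        row = dc[j, consumer_cols]
        nonzero = row[row > 0]
        if nonzero.size == 0:
            continue
        weights[j] = nonzero.max() - nonzero.mean()
    if weights.sum() <= 0:
        # degenerate: every alternative prey has a flat predator profile;
        # fall back to the predator's current diet proportions
        for j in range(n):
            if j != exclude:
                weights[j] = dc[j, predator]
    return weights


def auto_balance(
    model: FoodWebModel,
    max_iter: int = 200,
    step_fraction: float = 0.1,
) -> tuple[FoodWebModel, BalanceAudit]:
    """Iteratively edit diets until every EE <= 1 (or max_iter is reached).

    Each iteration targets the worst offending prey (highest EE, ties by
    group index), finds the predator contributing the largest predation flow
    on it, removes ``step_fraction`` of that diet proportion and
    redistributes it over the predator's other prey.  Returns the edited
    model and a full audit; non-convergence is flagged, not raised.
    """
    if not (0 < step_fraction < 1):
        raise ValueError("step_fraction must be in (0, 1)")
    work = model.copy()
    audit = BalanceAudit()
    consumer_cols = work.consumer_indices()
    names = work.names

    for iteration in range(1, max_iter + 1):
        balanced = solve(work)
        offenders = [
            (balanced.ee[i], i)
            for i, g in enumerate(work.groups)
            if g.is_living and balanced.ee[i] > 1.0 + 1e-12
        ]
        audit.ee_trajectory.append(
            {names[i]: float(balanced.ee[i]) for _, i in offenders}
        )
        if not offenders:
            audit.converged = True
            audit.iterations = iteration - 1
            return work, audit

        # worst offender first; ties broken by group index
        offenders.sort(key=lambda t: (-t[0], t[1]))
        _, prey = offenders[0]

        dc = work.diet.entries
        pred_flows = dc[prey, :] * balanced.consumption
        order = np.argsort(-pred_flows)
        edited = False
        for predator in order:
            if pred_flows[predator] <= 0:
                continue
            if np.count_nonzero(dc[:, predator]) < 2:
                msg = (
                    f"predator {names[predator]!r} feeds only on "
                    f"{names[prey]!r}; cannot redistribute"
                )
                if msg not in audit.warnings:
                    audit.warnings.append(msg)
                continue
            amount = step_fraction * dc[prey, predator]
            weights = _redistribution_weights(dc, predator, prey, consumer_cols)
            total_w = weights.sum()
            if total_w <= 0:
                continue
            raised = {}
            for j in np.nonzero(weights)[0]:
                delta = amount * weights[j] / total_w
                dc[j, predator] += delta
                raised[names[j]] = float(delta)
            dc[prey, predator] -= amount
            audit.edits.append(
                DietEdit(
                    iteration=iteration,
                    predator=names[predator],
                    prey_reduced=names[prey],
                    amount=float(amount),
                    prey_raised=raised,
                )
            )
            edited = True
            break
        if not edited:
            audit.warnings.append(
                f"no editable predator link found for {names[prey]!r}"
            )
            audit.iterations = iteration
            return work, audit

    audit.iterations = max_iter
    audit.warnings.append(f"not converged within {max_iter} iterations")
    return work, audit
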