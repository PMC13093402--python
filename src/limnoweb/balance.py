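"""Steady-state mass balance: solve for missing B/EE and derive group statistics.

Each living group *i* must satisfy the balance

    B_i (P/B)_i EE_i  =  sum_j B_j (Q/B)_j DC_ji  +  EX_i

where the sum runs over predators *j* and EX_i is the export (fishery
landings plus net migration and biomass accumulation).  Exactly one of
``B``/``EE`` may be unknown per group.  The equation is linear in every
unknown, so all unknown biomasses are obtained from one linear solve (the
production term B_i (P/B)_i EE_i and any predation terms B_j (Q/B)_j DC_ji
with unknown B_j appear on the same side); unknown EEs then follow by direct
substitution.  The result is independent of group order.

The detritus pool has no production of its own: its EE is the fraction of
the total inflow (everyone's flow to detritus) that detritivores consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FoodWebModel, GroupType

__all__ = ["BalancedModel", "UnsolvableModelError", "solve", "detritus_ee", "derived_statistics"]

#: relative tolerance on the per-group balance residual
RESIDUAL_RTOL = 1e-9


class UnsolvableModelError(ValueError):
    """The unknown-biomass system is structurally singular."""


@dataclass
class BalancedModel:
    """A solved model with every derived per-group statistic.

    All vectors are aligned with ``model.groups``.  Detritus entries use
    NaN where a statistic is undefined (P/B, Q/B, respiration...), and the
    detritus "production" for EE purposes is its total inflow.
    """

    model: FoodWebModel
    biomass: np.ndarray
    ee: np.ndarray
    production: np.ndarray          # B * P/B, t/km2/yr (NaN for detritus)
    consumption: np.ndarray         # B * Q/B, t/km2/yr (0 for non-consumers)
    predation_mortality_flow: np.ndarray  # total predation on each group
    respiration: np.ndarray
    assimilation: np.ndarray
    flow_to_detritus: np.ndarray
    exports: np.ndarray             # landings (+ net migration/accumulation)
    trophic_level: np.ndarray
    omnivory: np.ndarray
    unbalanced_groups: list[str] = field(default_factory=list)
    negative_respiration_groups: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return self.model.names

    @property
    def is_balanced(self) -> bool:
        return not self.unbalanced_groups

    # per-group efficiency ratios ---------------------------------------
    @property
    def pq(self) -> np.ndarray:
        """Production/consumption (gross food-conversion efficiency)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.consumption > 0, self.production / self.consumption, np.nan)

    @property
    def net_efficiency(self) -> np.ndarray:
        """Production/assimilation."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.assimilation > 0, self.production / self.assimilation, np.nan)

    @property
    def pr(self) -> np.ndarray:
        """Production/respiration."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.respiration > 0, self.production / self.respiration, np.nan)

    @property
    def ra(self) -> np.ndarray:
        """Respiration/assimilation."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.assimilation > 0, self.respiration / self.assimilation, np.nan)

    def group(self, name: str) -> dict:
        """All statistics of one group as a plain dict."""
        i = self.model.index(name)
        return {
            "name": name,
            "trophic_level": self.trophic_level[i],
            "biomass": self.biomass[i],
            "pb": self.model.groups[i].pb,
            "qb": self.model.groups[i].qb,
            "ee": self.ee[i],
            "pq": self.pq[i],
            "flow_to_detritus": self.flow_to_detritus[i],
            "net_efficiency": self.net_efficiency[i],
            "omnivory": self.omnivory[i],
            "pr": self.pr[i],
            "ra": self.ra[i],
            "production": self.production[i],
            "consumption": self.consumption[i],
            "respiration": self.respiration[i],
            "predation_mortality_flow": self.predation_mortality_flow[i],
            "exports": self.exports[i],
        }

    def summary_frame(self) -> pd.DataFrame:
        """Per-group table of inputs and computed values."""
        return pd.DataFrame([self.group(n) for n in self.names]).set_index("name")

    def residuals(self) -> np.ndarray:
        """Balance residual per living group (should be ~0)."""
        res = np.zeros(self.model.n)
        for i, g in enumerate(self.model.groups):
            if g.is_living:
                res[i] = (
                    self.biomass[i] * g.pb * self.ee[i]
                    - self.predation_mortality_flow[i]
                    - self.exports[i]
                )
        return res


def _exports(model: FoodWebModel) -> np.ndarray:
    return np.array(
        [g.landings + g.net_migration + g.biomass_accumulation for g in model.groups]
    )


def solve(model: FoodWebModel) -> BalancedModel:
    """Fill in the unknown B/EE values and compute all derived statistics.

    Raises :class:`UnsolvableModelError` when the unknown biomasses form a
    structurally singular system (e.g. a cycle of unknown-B groups preying
    only on each other); the offending groups are named.  Groups whose
    solved EE falls outside [0, 1] do not abort the solve: they are listed
    in ``unbalanced_groups`` so the re-balancing routine can act on them.
    """
    n = model.n
    names = model.names
    dc = model.diet.entries  # dc[i, j]: prey i in diet of predator j
    ex = _exports(model)

    qb = np.array([g.qb if g.is_consumer else 0.0 for g in model.groups])
    pb = np.array([g.pb if g.is_living else np.nan for g in model.groups])

    unknown_b = [i for i, g in enumerate(model.groups) if g.is_living and g.biomass is None]
    biomass = np.array(
        [g.biomass if g.biomass is not None else np.nan for g in model.groups]
    )

    # Linear system in the unknown biomasses.  Row = balance of an
    # unknown-B group i (its EE is known):
    #   B_i pb_i ee_i - sum_{j unknown} B_j qb_j dc[i, j]
    #     = ex_i + sum_{j known} B_j qb_j dc[i, j]
    if unknown_b:
        m = len(unknown_b)
        A = np.zeros((m, m))
        rhs = np.zeros(m)
        col_of = {j: k for k, j in enumerate(unknown_b)}
        for r, i in enumerate(unknown_b):
            gi = model.groups[i]
            A[r, col_of[i]] += gi.pb * gi.ee
            for j in range(n):
                if dc[i, j] == 0.0 or qb[j] == 0.0:
                    continue
                if j in col_of:
                    A[r, col_of[j]] -= qb[j] * dc[i, j]
                else:
                    rhs[r] += biomass[j] * qb[j] * dc[i, j]
            rhs[r] += ex[i]
        if np.linalg.matrix_rank(A) < m:
            raise UnsolvableModelError(
                "unknown biomasses form a singular system among groups: "
                + ", ".join(names[i] for i in unknown_b)
            )
        sol = np.linalg.solve(A, rhs)
        if np.any(~np.isfinite(sol)):
            raise UnsolvableModelError("non-finite biomass solution")
        for k, i in enumerate(unknown_b):
            biomass[i] = sol[k]

    consumption = biomass * qb
    consumption = np.where(np.isnan(consumption), 0.0, consumption)
    predation = dc @ consumption  # total predation flow on each prey

    production = biomass * pb  # NaN for detritus
    ee = np.empty(n)
    for i, g in enumerate(model.groups):
        if g.is_detritus:
            ee[i] = np.nan  # filled below from detritus inflow
        elif g.ee is not None and g.biomass is not None:
            # fully specified; keep the given EE (idempotence) -- the
            # residual check below will flag any inconsistency
            ee[i] = g.ee
        elif g.ee is not None:
            ee[i] = g.ee
        else:
            ee[i] = (predation[i] + ex[i]) / production[i]

    gs = np.array([g.unassimilated if g.is_consumer else 0.0 for g in model.groups])
    assimilation = consumption * (1.0 - gs)
    respiration = np.where(
        [g.is_consumer for g in model.groups], assimilation - production, 0.0
    )
    respiration = np.where(np.isnan(respiration), 0.0, respiration)

    # flow to detritus: egestion plus the unused share of production
    flow_to_det = np.zeros(n)
    for i, g in enumerate(model.groups):
        if g.is_consumer:
            flow_to_det[i] = gs[i] * consumption[i] + (1.0 - ee[i]) * production[i]
        elif g.is_producer:
            flow_to_det[i] = (1.0 - ee[i]) * production[i]

    balanced = BalancedModel(
        model=model,
        biomass=biomass,
        ee=ee,
        production=production,
        consumption=consumption,
        predation_mortality_flow=predation,
        respiration=respiration,
        assimilation=assimilation,
        flow_to_detritus=flow_to_det,
        exports=ex,
        trophic_level=np.full(n, np.nan),
        omnivory=np.full(n, np.nan),
    )
    for i in model.detritus_indices():
        balanced.ee[i] = detritus_ee(balanced, i)

    balanced.unbalanced_groups = [
        names[i]
        for i, g in enumerate(model.groups)
        if g.is_living and not (0.0 <= ee[i] <= 1.0 + 1e-12)
    ]
    balanced.negative_respiration_groups = [
        names[i]
        for i, g in enumerate(model.groups)
        if g.is_consumer and respiration[i] < -1e-12 * max(assimilation[i], 1.0)
    ]

    # attach trophic structure (cheap, and every downstream stage needs it)
    from .trophic import omnivory_index, trophic_levels

    types = [g.group_type for g in model.groups]
    balanced.trophic_level = trophic_levels(model.diet, types)
    balanced.omnivory = omnivory_index(
        model.diet, balanced.trophic_level, types, flow_to_detritus=flow_to_det
    )
    return balanced


def detritus_ee(balanced: BalancedModel, det_index: int | None = None) -> float:
    """EE of the detritus pool: consumed inflow / total inflow.

    Total inflow is the sum of every group's flow to detritus; consumption
    is what detritivores take out again.
    """
    model = balanced.model
    if det_index is None:
        det_index = model.detritus_indices()[0]
    inflow = balanced.flow_to_detritus.sum()
    if inflow <= 0:
        raise ValueError("detritus pool receives no inflow")
    consumed = float(model.diet.entries[det_index, :] @ balanced.consumption)
    return consumed / inflow


def derived_statistics(balanced: BalancedModel) -> BalancedModel:
    """Recompute the derived per-group statistics in place and return them.

    :func:`solve` already fills everything; this entry point exists for
    models whose biomass/EE vectors were edited after solving.
    """
    return solve(balanced.model)
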