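"""Mixed trophic impacts, keystoneness, and Pianka niche overlap.

The mixed trophic impact (MTI) matrix gives the net direct-plus-indirect
effect of a marginal biomass increase of one group on every other group.
With the net-impact coefficients

    q_ij = DC_ij - FC_ji

(DC_ij: fraction of predator *j*'s diet made of prey *i*; FC_ji: fraction of
the total predation-plus-catch on *j* taken by predator *i*), the MTI matrix
is ``M = (I - q)^-1 - I`` -- the convergent sum over all impact paths.  The
fishing fleet enters both as a predator (its catch share in FC) and as an
impacted "consumer" whose diet is the landings composition.

Keystoneness ranks groups by overall impact: the total impact
``epsilon_i = sqrt(sum_{j != i} M_ij^2)`` (fleet column excluded), its value
relative to the maximum, and a biomass-penalised index
``log10(epsilon_i * (1 - p_i))`` with p_i the group's share of living
biomass, so that high-impact low-biomass groups score highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import BalancedModel

__all__ = [
    "ImpactResult",
    "OverlapMatrices",
    "mti_matrix",
    "keystone_analysis",
    "niche_overlap",
]

FLEET = "Fleet"


@dataclass
class ImpactResult:
    """MTI matrix (impacting rows x impacted columns) and keystone statistics."""

    names: list[str]  # group names, plus the fleet when included
    mti: np.ndarray
    epsilon: np.ndarray
    relative_total_impact: np.ndarray
    keystoneness: np.ndarray
    includes_fleet: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mti, index=self.names, columns=self.names)

    def keystone_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total_impact": self.epsilon,
                "relative_total_impact": self.relative_total_impact,
                "keystoneness": self.keystoneness,
            },
            index=pd.Index(self.names, name="group"),
        )


@dataclass
class OverlapMatrices:
    """Symmetric Pianka overlap matrices in [0, 1]."""

    names: list[str]
    prey_overlap: np.ndarray
    predator_overlap: np.ndarray

    def prey_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prey_overlap, index=self.names, columns=self.names)

    def predator_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.predator_overlap, index=self.names, columns=self.names)


def _net_impact_matrix(balanced: BalancedModel, include_fleet: bool) -> tuple[np.ndarray, list[str]]:
    model = balanced.model
    n = model.n
    dc = model.diet.entries.copy()  # dc[prey, predator]
    catches = balanced.exports
    total_catch = float(catches.sum())

    m = n + 1 if include_fleet else n
    names = model.names + ([FLEET] if include_fleet else [])

    # diet matrix extended with the fleet as a consumer of the landings mix
    d = np.zeros((m, m))
    d[:n, :n] = dc
    if include_fleet and total_catch > 0:
        d[:n, n] = catches / total_catch

    # FC[j, i]: share of the total predation + catch on j taken by i
    pred_flows = dc * balanced.consumption[np.newaxis, :]  # prey j -> pred i flows
    mortality = pred_flows.sum(axis=1) + catches
    fc = np.zeros((m, m))
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(n):
            if mortality[j] > 0:
                fc[j, :n] = pred_flows[j, :] / mortality[j]
                if include_fleet:
                    fc[j, n] = catches[j] / mortality[j]

    # q[i, j]: net impact of i on j = (i feeds j) - (j is preyed on by i)
    q = d - fc.T
    return q, names


def mti_matrix(balanced: BalancedModel, include_fleet: bool = True) -> ImpactResult:
    """Mixed trophic impact matrix and keystone statistics.

    Raises ``ValueError`` when ``I - q`` is singular (reporting the spectral
    radius of q, which must be below 1 for the impact path-sum to converge).
    """
    q, names = _net_impact_matrix(balanced, include_fleet)
    eye = np.eye(len(names))
    try:
        mti = np.linalg.inv(eye - q) - eye
    except np.linalg.LinAlgError as err:
        rho = max(abs(np.linalg.eigvals(q)))
        raise ValueError(
            f"impact matrix not invertible (spectral radius {rho:.3f})"
        ) from err
    result = ImpactResult(
        names=names,
        mti=mti,
        epsilon=np.zeros(len(names)),
        relative_total_impact=np.zeros(len(names)),
        keystoneness=np.full(len(names), np.nan),
        includes_fleet=include_fleet,
    )
    keystone_analysis(result, balanced)
    return result


def keystone_analysis(
    impact: ImpactResult,
    balanced: BalancedModel,
    variant: str = "biomass_proportion",
) -> pd.DataFrame:
    """Fill in epsilon / relative total impact / keystoneness on ``impact``.

    ``variant`` selects the biomass penalty: ``biomass_proportion`` uses
    ``log10(eps_i * (1 - p_i))`` with p_i the living-biomass share;
    ``rank`` uses ``log10(eps_i * (1 - 1/rank_i))`` on descending-biomass
    ranks.  Fleet and self columns are excluded from epsilon.
    """
    model = balanced.model
    n = model.n
    mti = impact.mti
    ncols = n  # exclude the fleet column from impact magnitudes
    eps = np.zeros(len(impact.names))
    for i in range(len(impact.names)):
        row = mti[i, :ncols].copy()
        if i < ncols:
            row[i] = 0.0
        eps[i] = float(np.sqrt((row**2).sum()))
    impact.epsilon = eps
    max_eps = eps[:n].max()
    rel = eps / max_eps if max_eps > 0 else eps.copy()
    rel[n:] = np.nan  # the fleet is not ranked among the functional groups
    impact.relative_total_impact = rel

    living = np.array([g.is_living for g in model.groups])
    b = np.where(living, balanced.biomass, 0.0)
    p = b / b.sum()
    keystone = np.full(len(impact.names), np.nan)
    if variant == "biomass_proportion":
        penalty = 1.0 - p
    elif variant == "rank":
        order = np.argsort(-b)
        rank = np.empty(n)
        rank[order] = np.arange(1, n + 1)
        penalty = 1.0 - 1.0 / rank
    else:
        raise ValueError(f"unknown keystoneness variant {variant!r}")
    with np.errstate(divide="ignore"):
        keystone[:n] = np.log10(np.where(eps[:n] * penalty > 0, eps[:n] * penalty, np.nan))
    impact.keystoneness = keystone
    return impact.keystone_frame()


def _pianka(profiles: np.ndarray) -> np.ndarray:
    """Pianka overlap between columns of a profile matrix."""
    norms = np.sqrt((profiles**2).sum(axis=0))
    m = profiles.shape[1]
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            if norms[a] > 0 and norms[b] > 0:
                val = float(profiles[:, a] @ profiles[:, b]) / (norms[a] * norms[b])
            else:
                val = 0.0
            out[a, b] = out[b, a] = val
    return out


def niche_overlap(balanced: BalancedModel) -> OverlapMatrices:
    """Pianka prey- and predator-overlap matrices for all groups.

    Prey overlap compares diet-proportion columns.  Predator overlap
    compares, for each group, the composition of the predation mortality it
    suffers (the share of its total predation taken by each predator).
    """
    model = balanced.model
    dc = model.diet.entries
    pred_flows = dc * balanced.consumption[np.newaxis, :]
    tot_pred = pred_flows.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pred_profile = np.where(tot_pred[:, None] > 0, pred_flows / tot_pred[:, None], 0.0)
    return OverlapMatrices(
        names=model.names,
        prey_overlap=_pianka(dc),
        predator_overlap=_pianka(pred_profile.T),
    )
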