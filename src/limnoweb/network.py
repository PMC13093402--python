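"""Whole-system network indices: throughput, cycling, ascendancy, diversity.

The balanced model is first assembled into a compartment flow network
(prey -> predator flows, flows into the detritus pool, fishery/detritus
exports, respiration, imports).  On that network the module computes the
standard ecosystem accounting of flow analysis: total system throughput and
its four components, production ratios, mean trophic level of the catch,
connectance and system omnivory, Finn's cycling index and mean path length
(input-output analysis on the Leontief structure matrix), and Ulanowicz's
ascendancy / overhead / development capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import BalancedModel
from .model import GroupType

__all__ = [
    "FlowNetwork",
    "SystemSummary",
    "build_flow_network",
    "system_summary",
    "finn_cycling",
    "ascendancy",
    "shannon_diversity",
    "connectance_index",
    "system_omnivory_index",
    "pedigree_index",
]


@dataclass
class FlowNetwork:
    """Compartment flow matrix plus boundary vectors (all t/km2/yr).

    ``flows[i, j]`` is the flow from compartment *i* to *j*: predation flows
    ``B_j (Q/B)_j DC_ij`` plus each group's flow into the detritus pool.
    ``exports`` holds fishery landings and, for detritus, the surplus inflow
    that is neither consumed nor recycled.  ``negative_export_groups`` flags
    compartments whose computed export went negative (over-consumption).
    """

    names: list[str]
    flows: np.ndarray
    imports: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray
    living: np.ndarray  # bool mask
    detritus: np.ndarray  # bool mask
    negative_export_groups: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.names)

    def compartment_inflow(self) -> np.ndarray:
        return self.flows.sum(axis=0) + self.imports

    def total_internal_flow(self) -> float:
        return float(self.flows.sum())

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flows, index=self.names, columns=self.names)
        df["export"] = self.exports
        df["respiration"] = self.respiration
        return df


def build_flow_network(balanced: BalancedModel) -> FlowNetwork:
    """Assemble the balance terms into an explicit flow network."""
    model = balanced.model
    n = model.n
    dc = model.diet.entries
    flows = dc * balanced.consumption[np.newaxis, :]  # prey i -> predator j

    det_idx = model.detritus_indices()
    for i in range(n):
        if i in det_idx:
            continue
        # a group's flow to detritus is split equally across detritus pools
        # (a single pool in practice)
        for d in det_idx:
            flows[i, d] += balanced.flow_to_detritus[i] / len(det_idx)

    imports = model.diet.imports * balanced.consumption
    exports = balanced.exports.astype(float).copy()
    negative = []
    for d in det_idx:
        inflow = flows[:, d].sum()
        consumed = flows[d, :].sum()
        surplus = inflow - consumed
        if surplus < 0:
            negative.append(model.names[d])
        exports[d] += surplus

    return FlowNetwork(
        names=model.names,
        flows=flows,
        imports=imports,
        exports=exports,
        respiration=balanced.respiration.copy(),
        living=np.array([g.is_living for g in model.groups]),
        detritus=np.array([g.is_detritus for g in model.groups]),
        negative_export_groups=negative,
    )


# ---------------------------------------------------------------------------
# individual indices
# ---------------------------------------------------------------------------

def shannon_diversity(biomass: np.ndarray) -> float:
    """Shannon index (natural log) of the living-biomass proportions."""
    b = np.asarray(biomass, dtype=float)
    b = b[b > 0]
    p = b / b.sum()
    return float(-(p * np.log(p)).sum())


def connectance_index(balanced: BalancedModel, convention: str = "n_squared") -> float:
    """Realized fraction of possible predator-prey links.

    ``n_squared`` (default) counts nonzero diet entries (any prey, living or
    detritus, in a consumer column) over N_living**2; ``n_n_minus_1`` uses
    N_living*(N_living-1) possible links instead.
    """
    model = balanced.model
    links = int(np.count_nonzero(model.diet.entries))
    n_living = sum(g.is_living for g in model.groups)
    if convention == "n_squared":
        possible = n_living**2
    elif convention == "n_n_minus_1":
        possible = n_living * (n_living - 1)
    else:
        raise ValueError(f"unknown connectance convention {convention!r}")
    return links / possible


def system_omnivory_index(balanced: BalancedModel) -> float:
    """Consumption-log-weighted mean omnivory index over consumers."""
    model = balanced.model
    idx = model.consumer_indices()
    q = balanced.consumption[idx]
    oi = balanced.omnivory[idx]
    keep = q > 0
    w = np.log(q[keep])
    denom = w.sum()
    if denom == 0:
        return float("nan")
    return float((oi[keep] * w).sum() / denom)


def finn_cycling(net: FlowNetwork) -> tuple[float, float, float]:
    """Finn's cycling index, cycled throughput, and mean path length.

    Input-output analysis on the column-normalised flow matrix
    ``G[i, j] = T_ij / inflow_j``: with ``L = (I - G)^-1``, the cycled share
    of compartment *j*'s throughput is ``(L_jj - 1) / L_jj`` and the cycled
    throughput is that share times the compartment inflow.  FCI expresses
    the summed cycled throughput as a percentage of total system throughput;
    FMPL is TST / (exports + respiration).
    """
    inflow = net.compartment_inflow()
    n = net.n
    G = np.zeros((n, n))
    nz = inflow > 0
    G[:, nz] = net.flows[:, nz] / inflow[nz]
    try:
        L = np.linalg.inv(np.eye(n) - G)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"structure matrix is singular: {err}") from err
    diag = np.diag(L)
    cycled_share = np.where(diag > 0, (diag - 1.0) / diag, 0.0)
    cycled = float((cycled_share * inflow).sum())
    tst = total_system_throughput(net)
    fci = 100.0 * cycled / tst if tst > 0 else float("nan")
    sinks = float(net.exports.sum() + net.respiration.sum())
    fmpl = tst / sinks if sinks > 0 else float("nan")
    return fci, cycled, fmpl


def total_system_throughput(net: FlowNetwork) -> float:
    """TST = consumption + exports + respiration + flows into detritus."""
    consumption = float(net.flows[:, ~net.detritus].sum() + net.imports.sum())
    to_detritus = float(net.flows[:, net.detritus].sum())
    return consumption + float(net.exports.sum()) + float(net.respiration.sum()) + to_detritus


def ascendancy(net: FlowNetwork) -> tuple[float, float, float]:
    """Ascendancy and overhead as percentages of development capacity.

    The compartment matrix is extended with three boundary nodes (import
    source, export sink, dissipation sink).  Primary production is not a
    boundary flow: producers are source compartments with no inflow, which
    matches the flow accounting of the standard ecosystem summary.  On the
    extended matrix T with grand total T..:

        A = sum T_ij log2(T_ij T.. / (T_i. T_.j)),   C = -sum T_ij log2(T_ij / T..)

    and overhead O = C - A.  Ratios A/C, O/C are invariant to flow rescaling.
    """
    n = net.n
    m = n + 3
    T = np.zeros((m, m))
    T[:n, :n] = net.flows
    imp, exp_, dis = n, n + 1, n + 2
    T[imp, :n] = net.imports
    T[:n, exp_] = net.exports
    T[:n, dis] = net.respiration

    total = T.sum()
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    A = 0.0
    C = 0.0
    nz = T > 0
    for i, j in zip(*np.nonzero(nz)):
        t = T[i, j]
        A += t * math.log2(t * total / (row[i] * col[j]))
        C -= t * math.log2(t / total)
    if total == 0:
        return float("nan"), float("nan"), 0.0
    if C <= 1e-12:
        # a single nonzero flow: zero capacity, fully determined network
        return 100.0, 0.0, 0.0
    return 100.0 * A / C, 100.0 * (C - A) / C, C


def pedigree_index(scores, weights=None) -> tuple[float, float]:
    """Aggregate user-supplied per-parameter pedigree scores.

    ``scores`` is an iterable of per-group, per-parameter data-quality
    scores in [0, 1] (local data ~ 1, guesswork ~ 0).  Returns the pedigree
    index P (weighted mean) and the associated fit measure
    ``t* = P sqrt(n - 2) / sqrt(1 - P^2)``.  No scores are bundled for any
    particular system; this is a scaffold for user-provided tables.
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise ValueError("no pedigree scores supplied")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("pedigree scores must lie in [0, 1]")
    w = np.ones_like(s) if weights is None else np.asarray(list(weights), dtype=float)
    p = float((s * w).sum() / w.sum())
    nn = s.size
    tstar = p * math.sqrt(max(nn - 2, 0)) / math.sqrt(1 - p**2) if p < 1 else float("inf")
    return p, tstar


# ---------------------------------------------------------------------------
# full summary
# ---------------------------------------------------------------------------

@dataclass
class SystemSummary:
    """All whole-system scalars, mirroring the standard summary table."""

    total_consumption: float
    total_exports: float
    total_respiration: float
    total_flows_to_detritus: float
    tst: float
    total_production: float
    tnpp: float
    nsp: float
    tpp_tr: float
    tpp_tb: float
    tb_tst: float
    mtlc: float | None
    gross_efficiency: float | None
    total_biomass: float
    total_catch: float
    ci: float
    soi: float
    fci_percent: float
    throughput_cycled: float
    fmpl: float
    ascendancy_percent: float
    overhead_percent: float
    capacity: float
    shannon: float

    UNITS = {
        "total_consumption": "t/km2/yr",
        "total_exports": "t/km2/yr",
        "total_respiration": "t/km2/yr",
        "total_flows_to_detritus": "t/km2/yr",
        "tst": "t/km2/yr",
        "total_production": "t/km2/yr",
        "tnpp": "t/km2/yr",
        "nsp": "t/km2/yr",
        "tpp_tr": "-",
        "tpp_tb": "-",
        "tb_tst": "-",
        "mtlc": "-",
        "gross_efficiency": "-",
        "total_biomass": "t/km2",
        "total_catch": "t/km2/yr",
        "ci": "-",
        "soi": "-",
        "fci_percent": "% of TST",
        "throughput_cycled": "t/km2/yr",
        "fmpl": "-",
        "ascendancy_percent": "% of capacity",
        "overhead_percent": "% of capacity",
        "capacity": "flowbits",
        "shannon": "-",
    }

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.UNITS}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": pd.Series(self.to_dict()),
                "units": pd.Series(self.UNITS),
            }
        ).rename_axis("parameter")


def system_summary(
    net: FlowNetwork,
    balanced: BalancedModel,
    ci_convention: str = "n_squared",
) -> SystemSummary:
    """Compute every whole-system scalar from the flow network."""
    model = balanced.model
    living = np.array([g.is_living for g in model.groups])

    total_consumption = float(balanced.consumption.sum() + 0.0)
    total_exports = float(net.exports.sum())
    total_respiration = float(net.respiration.sum())
    total_fd = float(balanced.flow_to_detritus.sum())
    tst = total_consumption + total_exports + total_respiration + total_fd

    production_living = np.where(living, np.nan_to_num(balanced.production), 0.0)
    total_production = float(production_living.sum())
    producer = np.array([g.is_producer for g in model.groups])
    tnpp = float(production_living[producer].sum())
    nsp = tnpp - total_respiration

    total_biomass = float(balanced.biomass[living].sum())
    catches = balanced.exports
    total_catch = float(catches.sum())

    mtlc = None
    gross_efficiency = None
    if total_catch > 0:
        mtlc = float((catches * balanced.trophic_level).sum() / total_catch)
        gross_efficiency = total_catch / tnpp if tnpp > 0 else None

    fci, cycled, fmpl = finn_cycling(net)
    asc, over, capacity = ascendancy(net)

    return SystemSummary(
        total_consumption=total_consumption,
        total_exports=total_exports,
        total_respiration=total_respiration,
        total_flows_to_detritus=total_fd,
        tst=tst,
        total_production=total_production,
        tnpp=tnpp,
        nsp=nsp,
        tpp_tr=tnpp / total_respiration if total_respiration > 0 else float("inf"),
        tpp_tb=tnpp / total_biomass,
        tb_tst=total_biomass / tst,
        mtlc=mtlc,
        gross_efficiency=gross_efficiency,
        total_biomass=total_biomass,
        total_catch=total_catch,
        ci=connectance_index(balanced, ci_convention),
        soi=system_omnivory_index(balanced),
        fci_percent=fci,
        throughput_cycled=cycled,
        fmpl=fmpl,
        ascendancy_percent=asc,
        overhead_percent=over,
        capacity=capacity,
        shannon=shannon_diversity(balanced.biomass[living]),
    )
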