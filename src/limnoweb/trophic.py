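"""Trophic structure: fractional trophic levels, omnivory, and the Lindeman spine.

Fractional trophic levels solve the linear fixed point

    TL_i = 1 + sum_j DC_ji TL_j

with producers and detritus pinned at TL = 1.  The omnivory index of a
consumer is the diet-weighted variance of its prey trophic levels.

The Lindeman spine maps the web onto discrete integer levels.  Each group is
split across levels by the flow-fraction recursion (a producer or detritus
pool is 100% level 1; a consumer's level-(k+1) fraction is its diet-weighted
mean of prey level-k fractions), and its consumption, predation losses,
catches, respiration and detritus flows are apportioned by those fractions.
Self-predation (cannibalism) is netted out of consumption and predation
before aggregation, as is standard for trophic aggregation: a cannibalistic
loop would otherwise smear a group across ever-higher levels and inflate the
apparent inter-level transfers.  Producer-origin and detritus-origin
pathways are tracked separately so transfer efficiencies can be partitioned
by the level-1 source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DietMatrix, GroupType

__all__ = [
    "trophic_levels",
    "omnivory_index",
    "TrophicDecomposition",
    "decompose_levels",
    "LindemanSpine",
    "lindeman_spine",
    "transfer_efficiency_table",
]

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
         "XI", "XII", "XIII", "XIV", "XV"]


def _level_label(k: int) -> str:
    """Label for integer trophic level k+1 (0-based index)."""
    return ROMAN[k] if k < len(ROMAN) else str(k + 1)


def trophic_levels(diet: DietMatrix, group_types) -> np.ndarray:
    """Fractional trophic level per group (exact linear solve).

    Producers and detritus are pinned at 1; consumers satisfy
    ``TL_i = 1 + sum_j DC_ji TL_j``.  A consumer column is renormalised over
    its in-system diet if part of its intake is imported (imports carry no
    trophic information).
    """
    types = [GroupType(t) for t in group_types]
    n = len(types)
    dc = diet.entries
    A = np.eye(n)
    b = np.ones(n)
    for i, t in enumerate(types):
        if t is GroupType.CONSUMER:
            col = dc[:, i].copy()
            s = col.sum()
            if s > 0:
                col = col / s
            A[i, :] -= col  # TL_i - sum_j DC_ji TL_j = 1
    try:
        tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"trophic-level system is singular: {err}") from err
    return tl


def omnivory_index(
    diet: DietMatrix,
    trophic_level: np.ndarray,
    group_types,
    flow_to_detritus: np.ndarray | None = None,
) -> np.ndarray:
    """Omnivory index: diet-weighted variance of prey trophic levels.

    ``OI_i = sum_j DC_ji (TL_j - (TL_i - 1))^2`` for consumers; 0 for a
    specialist feeding on a single trophic level, and 0 for producers.  When
    ``flow_to_detritus`` is supplied, the detritus pool gets the analogous
    statistic on its inflow composition: the variance of contributor trophic
    levels about their flow-weighted mean.
    """
    types = [GroupType(t) for t in group_types]
    n = len(types)
    oi = np.zeros(n)
    for i, t in enumerate(types):
        if t is GroupType.CONSUMER:
            col = diet.entries[:, i]
            s = col.sum()
            if s <= 0:
                continue
            col = col / s
            oi[i] = float(col @ (trophic_level - (trophic_level[i] - 1.0)) ** 2)
        elif t is GroupType.DETRITUS and flow_to_detritus is not None:
            total = flow_to_detritus.sum()
            if total > 0:
                p = flow_to_detritus / total
                mean_tl = float(p @ trophic_level)
                oi[i] = float(p @ (trophic_level - mean_tl) ** 2)
    return oi


@dataclass
class TrophicDecomposition:
    """Per-group apportionment across integer trophic levels.

    ``tl_fractions[i, k]`` is the share of group *i*'s activity at integer
    level k+1; rows sum to 1.  ``detritus_fractions``/``producer_fractions``
    split each share by its level-1 origin (they add up to ``tl_fractions``).
    Fractions are computed on the cannibalism-free diet.
    """

    trophic_level: np.ndarray
    tl_fractions: np.ndarray
    producer_fractions: np.ndarray
    detritus_fractions: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.tl_fractions.shape[1]


def _cannibalism_free(diet: DietMatrix, consumer_mask: np.ndarray):
    """Diet with self-predation removed and columns renormalised."""
    dc = diet.entries.copy()
    self_frac = np.diag(dc).copy()
    np.fill_diagonal(dc, 0.0)
    sums = dc.sum(axis=0)
    for j in np.nonzero(consumer_mask)[0]:
        if sums[j] > 0:
            dc[:, j] /= sums[j]
    return dc, self_frac


def decompose_levels(balanced, tol: float = 1e-12, max_levels: int = 64) -> TrophicDecomposition:
    """Split every group across integer trophic levels (with origin tracking)."""
    model = balanced.model
    n = model.n
    types = [g.group_type for g in model.groups]
    consumer_mask = np.array([t is GroupType.CONSUMER for t in types])
    dc, _ = _cannibalism_free(model.diet, consumer_mask)

    base = np.zeros(n)  # level-1 mass
    origin_d = np.zeros(n)
    for i, t in enumerate(types):
        if t is not GroupType.CONSUMER:
            base[i] = 1.0
            origin_d[i] = 1.0 if t is GroupType.DETRITUS else 0.0

    frac_all, frac_d = [base], [base * origin_d]
    cur_all, cur_d = base, base * origin_d
    for _ in range(max_levels - 1):
        nxt_all = dc.T @ cur_all * consumer_mask
        nxt_d = dc.T @ cur_d * consumer_mask
        if nxt_all.max(initial=0.0) < tol:
            break
        frac_all.append(nxt_all)
        frac_d.append(nxt_d)
        cur_all, cur_d = nxt_all, nxt_d

    fa = np.column_stack(frac_all)
    fd = np.column_stack(frac_d)
    return TrophicDecomposition(
        trophic_level=balanced.trophic_level,
        tl_fractions=fa,
        producer_fractions=fa - fd,
        detritus_fractions=fd,
    )


@dataclass
class LindemanSpine:
    """Flows, biomass and transfer efficiency aggregated on integer levels.

    All per-level arrays are indexed by integer level (entry 0 = level I).
    ``te_percent`` rows are NaN where a level has no throughput of that
    origin.  ``detritus_flow_fraction`` is the detritus-origin share of the
    summed level throughputs.
    """

    throughput_in: np.ndarray
    flow_to_next: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray
    flow_to_detritus: np.ndarray
    biomass: np.ndarray
    te_all_percent: np.ndarray
    te_producer_percent: np.ndarray
    te_detritus_percent: np.ndarray
    detritus_flow_fraction: float
    mean_te_levels: tuple[int, ...] = (2, 3, 4)

    @property
    def n_levels(self) -> int:
        return len(self.throughput_in)

    def mean_te(self, origin: str = "all", levels: tuple[int, ...] | None = None) -> float:
        """Geometric-mean transfer efficiency over ``levels`` (default II-IV)."""
        levels = levels or self.mean_te_levels
        te = {
            "all": self.te_all_percent,
            "producer": self.te_producer_percent,
            "detritus": self.te_detritus_percent,
        }[origin]
        vals = np.array([te[k - 1] for k in levels if k - 1 < len(te)])
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.size == 0:
            return float("nan")
        return float(np.exp(np.mean(np.log(vals))))

    def frame(self) -> pd.DataFrame:
        lv = [_level_label(k) for k in range(self.n_levels)]
        return pd.DataFrame(
            {
                "throughput_in": self.throughput_in,
                "flow_to_next": self.flow_to_next,
                "exports": self.exports,
                "respiration": self.respiration,
                "flow_to_detritus": self.flow_to_detritus,
                "biomass": self.biomass,
                "te_percent": self.te_all_percent,
            },
            index=pd.Index(lv, name="level"),
        )


def lindeman_spine(balanced, decomposition: TrophicDecomposition | None = None) -> LindemanSpine:
    """Aggregate the balanced web onto the integer-level Lindeman spine."""
    model = balanced.model
    if decomposition is None:
        decomposition = decompose_levels(balanced)
    n = model.n
    types = [g.group_type for g in model.groups]
    consumer_mask = np.array([t is GroupType.CONSUMER for t in types])
    producer_mask = np.array([t is GroupType.PRODUCER for t in types])
    detritus_mask = np.array([t is GroupType.DETRITUS for t in types])

    dc = model.diet.entries
    self_flow = np.diag(dc) * balanced.consumption  # cannibalistic intake
    q_net = balanced.consumption - self_flow
    pred_net = balanced.predation_mortality_flow - self_flow

    fa = decomposition.tl_fractions
    fd = decomposition.detritus_fractions
    n_levels = fa.shape[1]

    # per-compartment boundary flows
    catches = balanced.exports.copy()
    resp = balanced.respiration
    to_det = balanced.flow_to_detritus
    biomass = balanced.biomass

    det_inflow = to_det.sum()
    det_consumed = float((dc[detritus_mask, :] @ balanced.consumption).sum())
    det_surplus = det_inflow - det_consumed  # exported/buried detritus

    def level_sums(frac):
        inflow = frac.T @ q_net  # consumer intake attributed per level
        flow_next = np.zeros(n_levels)
        for k in range(n_levels - 1):
            flow_next[k] = float(frac[:, k] @ pred_net)
        return inflow, flow_next

    inflow_all, next_all = level_sums(fa)
    inflow_det, next_det = level_sums(fd)

    # level I throughput: primary production plus detritus inflow
    tnpp = float(np.nansum(balanced.production[producer_mask]))
    inflow_all[0] = tnpp + det_inflow
    inflow_det[0] = det_inflow
    # flow I -> II is the consumption of producers and detritus
    base_mask = (producer_mask | detritus_mask).astype(float)
    next_all[0] = float(base_mask @ pred_net)
    next_det[0] = float(detritus_mask.astype(float) @ pred_net)

    exports_lv = fa.T @ catches
    exports_lv_d = fd.T @ catches
    resp_lv = fa.T @ resp
    fd_lv = fa.T @ to_det
    biomass_lv = fa.T @ biomass
    # the detritus surplus leaves the system at level 1
    exports_lv[0] += det_surplus
    exports_lv_d[0] += det_surplus

    inflow_prod = inflow_all - inflow_det
    next_prod = next_all - next_det
    exports_lv_p = exports_lv - exports_lv_d

    def te(next_flow, exports, inflow):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * (next_flow + exports) / inflow
        out[~np.isfinite(out)] = np.nan
        out[0] = np.nan  # TE is reported from level II upward
        return out

    total_flow = inflow_all.sum()
    return LindemanSpine(
        throughput_in=inflow_all,
        flow_to_next=next_all,
        exports=exports_lv,
        respiration=resp_lv,
        flow_to_detritus=fd_lv,
        biomass=biomass_lv,
        te_all_percent=te(next_all, exports_lv, inflow_all),
        te_producer_percent=te(next_prod, exports_lv_p, inflow_prod),
        te_detritus_percent=te(next_det, exports_lv_d, inflow_det),
        detritus_flow_fraction=float(inflow_det.sum() / total_flow) if total_flow else float("nan"),
    )


def transfer_efficiency_table(spine: LindemanSpine, max_level: int = 7) -> pd.DataFrame:
    """Origin-partitioned transfer-efficiency table (percent, levels II..).

    The ``mean`` column is the geometric mean over the configured level
    range (II-IV by default).
    """
    levels = list(range(2, min(max_level, spine.n_levels) + 1))
    cols = [_level_label(k - 1) for k in levels]
    rows = {}
    for label, origin in (
        ("Producer", "producer"),
        ("Detritus", "detritus"),
        ("All flows", "all"),
    ):
        te = {
            "producer": spine.te_producer_percent,
            "detritus": spine.te_detritus_percent,
            "all": spine.te_all_percent,
        }[origin]
        rows[label] = [te[k - 1] for k in levels] + [spine.mean_te(origin)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=cols + ["mean"]
    ).rename_axis("source")
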