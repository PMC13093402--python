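"""Random solvable food-web generator with known ground truth.

The generator emulates the structure of a small lake model: one (or more)
producers, an optional detritus pool, and consumers arranged in trophic
layers with sparse column-stochastic diets biased toward lower layers.
Gross food-conversion efficiencies P/Q are kept in the ecologically
plausible 0.05-0.3 band.  All EE values are set by construction: predation
is computed forward from the sampled parameters and per-group landings are
chosen (fishing pressure being the free variable) so that every living
group's EE lands inside the requested interval.  Every true parameter is
recorded, so a masked B or EE can be checked against the solver's estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DietMatrix, FoodWebModel, FunctionalGroup, GroupType

__all__ = ["SyntheticWebSpec", "generate_web", "mask_parameter", "unmask_parameter"]


@dataclass
class SyntheticWebSpec:
    """Parameters of the random-web generator (reproducible given ``seed``)."""

    n_consumers: int = 6
    n_producers: int = 1
    #: when False the detritus pool is an inert sink that no consumer feeds
    #: on (the web is then acyclic unless cannibalism is enabled)
    has_detritus: bool = True
    tl_layers: int = 3
    diet_sparsity: float = 0.4
    cannibalism_prob: float = 0.0
    ee_target_range: tuple[float, float] = (0.3, 0.95)
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.ee_target_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ee_target_range must be an interval inside (0, 1)")
        for p in (self.diet_sparsity, self.cannibalism_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_producers < 1:
            raise ValueError("at least one producer is required")
        if self.tl_layers < 1:
            raise ValueError("at least one consumer layer is required")


def generate_web(spec: SyntheticWebSpec) -> tuple[FoodWebModel, dict]:
    """Generate a random solvable web; returns (model, ground-truth ledger).

    The ledger records the seed and, per group, the true biomass, EE and
    landings, so tests can mask a parameter and compare the solver's
    estimate against truth.  Raises ``RuntimeError`` if no admissible web is
    found within ``spec.max_retries`` attempts.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ee_target_range
    last_err = "no attempt made"
    for _ in range(spec.max_retries):
        model, ee_true, last_err = _attempt(spec, rng, lo, hi)
        if model is not None:
            # the model keeps EE unknown (as in real use); truth lives here
            ledger = {
                "seed": spec.seed,
                "groups": {
                    g.name: {
                        "biomass": g.biomass,
                        "ee": None if np.isnan(ee_true[i]) else float(ee_true[i]),
                        "landings": g.landings,
                    }
                    for i, g in enumerate(model.groups)
                },
            }
            return model, ledger
    raise RuntimeError(f"spec unsatisfiable after {spec.max_retries} retries: {last_err}")


def _attempt(spec: SyntheticWebSpec, rng: np.random.Generator, lo: float, hi: float):
    names: list[str] = []
    types: list[GroupType] = []
    layer_of: list[int] = []

    n_cons = spec.n_consumers
    for c in range(n_cons):
        names.append(f"consumer_{c + 1}")
        types.append(GroupType.CONSUMER)
        layer_of.append(c % spec.tl_layers + 1)
    for p in range(spec.n_producers):
        names.append(f"producer_{p + 1}")
        types.append(GroupType.PRODUCER)
        layer_of.append(0)
    det_index = len(names)
    names.append("detritus")
    types.append(GroupType.DETRITUS)
    layer_of.append(0)
    n = len(names)

    # parameters: producers are plankton-like, consumers shrink up the layers
    biomass = np.zeros(n)
    pb = np.full(n, np.nan)
    qb = np.zeros(n)
    for i, t in enumerate(types):
        if t is GroupType.PRODUCER:
            biomass[i] = rng.uniform(5.0, 20.0)
            pb[i] = rng.uniform(50.0, 250.0)
        elif t is GroupType.CONSUMER:
            layer = layer_of[i]
            biomass[i] = rng.uniform(0.5, 5.0) * 0.1 ** (layer - 1)
            qb[i] = rng.uniform(10.0, 80.0) * 0.5 ** (layer - 1)
            pq = rng.uniform(0.05, 0.3)
            pb[i] = pq * qb[i]
        else:
            biomass[i] = 1.0

    # sparse layered diets (Dirichlet column draws)
    dc = np.zeros((n, n))
    for j, t in enumerate(types):
        if t is not GroupType.CONSUMER:
            continue
        layer = layer_of[j]
        base = [
            i
            for i, ti in enumerate(types)
            if ti is GroupType.PRODUCER
            or (ti is GroupType.DETRITUS and spec.has_detritus)
        ]
        candidates = [
            i
            for i, ti in enumerate(types)
            if ti is GroupType.CONSUMER and 0 < layer_of[i] < layer
        ]
        # layer-1 consumers graze the base; higher layers may also reach it
        candidates = base + candidates if layer == 1 else candidates + base
        keep = [i for i in candidates if rng.random() > spec.diet_sparsity]
        if not keep:
            keep = [candidates[rng.integers(len(candidates))]]
        props = rng.dirichlet(np.ones(len(keep)))
        for i, frac in zip(keep, props):
            dc[i, j] += frac
        if spec.cannibalism_prob and rng.random() < spec.cannibalism_prob:
            self_frac = rng.uniform(0.01, 0.1)
            dc[:, j] *= 1.0 - self_frac
            dc[j, j] += self_frac

    consumption = biomass * qb
    production = biomass * pb

    # landings are the free variable used to hit the EE targets; shrink
    # consumer biomass (and hence predation) when demand exceeds them
    for _ in range(60):
        predation = dc @ consumption
        floors = np.zeros(n)
        living = [i for i, t in enumerate(types) if t is not GroupType.DETRITUS]
        for i in living:
            floors[i] = predation[i] / production[i]
        worst = max(floors[i] for i in living)
        if worst <= hi * 0.999:
            break
        shrink = (hi * 0.9) / worst
        for i, t in enumerate(types):
            if t is GroupType.CONSUMER:
                biomass[i] *= shrink
        consumption = biomass * qb
        production = biomass * pb
    else:
        return None, None, "could not bring predation below the EE ceiling"

    predation = dc @ consumption
    ee_true = np.full(n, np.nan)
    landings = np.zeros(n)
    for i, t in enumerate(types):
        if t is GroupType.DETRITUS:
            continue
        floor = predation[i] / production[i]
        target = rng.uniform(max(lo, floor), hi)
        ee_true[i] = target
        landings[i] = target * production[i] - predation[i]

    # detritus must not be over-consumed
    if spec.has_detritus:
        gs = 0.2
        fd = np.zeros(n)
        for i, t in enumerate(types):
            if t is GroupType.CONSUMER:
                fd[i] = gs * consumption[i] + (1 - ee_true[i]) * production[i]
            elif t is GroupType.PRODUCER:
                fd[i] = (1 - ee_true[i]) * production[i]
        det_consumed = float(dc[det_index, :] @ consumption)
        if det_consumed > fd.sum():
            return None, None, "detritus pool over-consumed"

    groups = []
    for i, t in enumerate(types):
        groups.append(
            FunctionalGroup(
                name=names[i],
                group_type=t,
                biomass=float(biomass[i]),
                pb=float(pb[i]) if t is not GroupType.DETRITUS else None,
                qb=float(qb[i]) if t is GroupType.CONSUMER else None,
                ee=None,
                landings=float(landings[i]),
                unassimilated=0.2 if t is GroupType.CONSUMER else 0.0,
            )
        )
    diet = DietMatrix(group_names=names, entries=dc)
    try:
        model = FoodWebModel(groups=groups, diet=diet)
    except Exception as err:  # pragma: no cover - structural rejection
        return None, None, str(err)
    return model, ee_true, ""


def mask_parameter(
    model: FoodWebModel,
    group: str,
    which: str,
    ledger: dict | None = None,
) -> FoodWebModel:
    """Copy of ``model`` with one parameter hidden (to be recovered by the solver).

    ``which`` is ``"biomass"`` or ``"ee"``.  Masking biomass requires a
    known EE for the group, so the true EE implied by the current balance is
    written into the masked group first.  The true value of the masked
    parameter is appended to ``ledger["masked"]`` when a ledger is given.
    """
    if which not in {"biomass", "ee"}:
        raise ValueError("which must be 'biomass' or 'ee'")
    from .balance import solve

    masked = model.copy()
    i = masked.index(group)
    g = masked.groups[i]
    if not g.is_living:
        raise ValueError("only living-group parameters can be masked")

    balanced = solve(model)
    truth = g.biomass if which == "biomass" else float(balanced.ee[i])
    if which == "biomass":
        g.ee = float(balanced.ee[i])
        g.biomass = None
    else:
        if g.biomass is None:
            raise ValueError(f"cannot mask EE of {group!r}: biomass already unknown")
        g.ee = None
    g.validate()
    if ledger is not None:
        ledger.setdefault("masked", []).append(
            {"group": group, "which": which, "true_value": float(truth)}
        )
    return masked


def unmask_parameter(model: FoodWebModel, group: str, which: str, value: float) -> FoodWebModel:
    """Inverse of :func:`mask_parameter`: restore the hidden value."""
    restored = model.copy()
    g = restored.groups[restored.index(group)]
    if which == "biomass":
        g.biomass = value
        g.ee = None
    elif which == "ee":
        g.ee = None if value is None else value
        g.ee = value
    else:
        raise ValueError("which must be 'biomass' or 'ee'")
    return restored
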