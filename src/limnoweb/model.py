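"""Core data model for mass-balanced food webs, plus file input/output.

A food web is described by an ordered list of functional groups (consumers,
producers and a detritus pool), a column-stochastic diet-composition matrix
(prey rows x predator columns, plus an import row), and per-group fishery
landings.  Each living group carries biomass ``B`` (t/km2), a
production/biomass ratio ``P/B`` (/yr), for consumers a consumption/biomass
ratio ``Q/B`` (/yr), and an ecotrophic efficiency ``EE`` (the fraction of
production used by predation or fishery).  Exactly one of ``B``/``EE`` may be
left unknown per group; the steady-state balance solver fills it in.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroupType",
    "FunctionalGroup",
    "DietMatrix",
    "FoodWebModel",
    "LifeHistoryRecord",
    "ModelValidationError",
    "load_model",
    "save_model",
    "convert_landings",
    "DIET_COLUMN_TOL",
]

#: tolerance on consumer diet-column sums
DIET_COLUMN_TOL = 1e-9

MISSING = None  # sentinel for an unknown B or EE


class GroupType(str, Enum):
    CONSUMER = "consumer"
    PRODUCER = "producer"
    DETRITUS = "detritus"


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class FunctionalGroup:
    """One compartment of the food web.

    Parameters follow the standard mass-balance convention: ``biomass`` in
    t/km2, ``pb`` and ``qb`` in /yr, ``ee`` dimensionless, ``landings`` in
    t/km2/yr, ``unassimilated`` the fraction of consumption egested to
    detritus (0.2 is the conventional value for fish and invertebrates).
    ``biomass`` or ``ee`` may be ``None`` (unknown, to be solved), but not
    both.
    """

    name: str
    group_type: GroupType = GroupType.CONSUMER
    biomass: float | None = None
    pb: float | None = None
    qb: float | None = None
    ee: float | None = None
    landings: float = 0.0
    unassimilated: float = 0.2
    biomass_accumulation: float = 0.0
    net_migration: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.group_type, str):
            self.group_type = GroupType(self.group_type)
        self.validate()

    # -- predicates -------------------------------------------------------
    @property
    def is_consumer(self) -> bool:
        return self.group_type is GroupType.CONSUMER

    @property
    def is_producer(self) -> bool:
        return self.group_type is GroupType.PRODUCER

    @property
    def is_detritus(self) -> bool:
        return self.group_type is GroupType.DETRITUS

    @property
    def is_living(self) -> bool:
        return not self.is_detritus

    def validate(self) -> None:
        if self.is_living:
            if self.biomass is None and self.ee is None:
                raise ModelValidationError(
                    f"group {self.name!r}: both biomass and EE are missing; "
                    "at most one may be unknown"
                )
            if self.pb is None or self.pb <= 0:
                raise ModelValidationError(
                    f"group {self.name!r}: P/B must be positive for living groups"
                )
        if self.is_consumer and (self.qb is None or self.qb <= 0):
            raise ModelValidationError(
                f"group {self.name!r}: Q/B must be positive for consumers"
            )
        if not (0.0 <= self.unassimilated < 1.0):
            raise ModelValidationError(
                f"group {self.name!r}: unassimilated fraction must be in [0, 1)"
            )
        if self.landings < 0:
            raise ModelValidationError(
                f"group {self.name!r}: landings must be non-negative"
            )
        if self.biomass is not None and self.biomass <= 0 and self.is_living:
            raise ModelValidationError(
                f"group {self.name!r}: biomass must be positive when given"
            )


@dataclass
class DietMatrix:
    """Column-stochastic diet proportions: rows are prey, columns predators.

    ``entries`` is an (n_groups, n_groups) array where ``entries[i, j]`` is
    the proportion of predator *j*'s diet made up of prey *i*.  ``imports``
    holds the per-predator import-diet fraction (food taken from outside the
    system); each consumer column plus its import entry sums to one.
    """

    group_names: list[str]
    entries: np.ndarray
    imports: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.group_names)
        if self.entries.shape != (n, n):
            raise ModelValidationError(
                f"diet matrix shape {self.entries.shape} does not match "
                f"{n} groups"
            )
        if self.imports is None:
            self.imports = np.zeros(n)
        self.imports = np.asarray(self.imports, dtype=float)
        if np.any(self.entries < -DIET_COLUMN_TOL) or np.any(
            self.entries > 1 + 1e-9
        ):
            raise ModelValidationError("diet proportions must lie in [0, 1]")

    def column(self, j: int) -> np.ndarray:
        return self.entries[:, j]

    def validate_columns(self, consumer_mask: Sequence[bool]) -> None:
        """Check consumer columns sum to 1 and non-consumer columns are zero."""
        sums = self.entries.sum(axis=0) + self.imports
        for j, is_cons in enumerate(consumer_mask):
            if is_cons:
                if abs(sums[j] - 1.0) > 1e-6:
                    raise ModelValidationError(
                        f"diet column {self.group_names[j]!r} sums to "
                        f"{sums[j]:.9f}, expected 1"
                    )
            elif sums[j] > DIET_COLUMN_TOL:
                raise ModelValidationError(
                    f"non-consumer column {self.group_names[j]!r} has "
                    "nonzero diet entries"
                )


@dataclass
class LifeHistoryRecord:
    """Per-species life-history data used by the empirical estimators.

    ``Z = M + F`` within 0.02 and ``Winf ~ a * Linf**b`` within 5% are
    enforced whenever all the quantities involved are supplied.
    """

    species: str
    annual_catch: float | None = None  # t/yr
    Linf: float | None = None  # cm
    K: float | None = None  # /yr
    a: float | None = None
    b: float | None = None
    Winf: float | None = None  # g
    M: float | None = None  # /yr
    F: float | None = None  # /yr
    Z: float | None = None  # /yr
    aspect_ratio: float | None = None
    feeding_type: str = "carnivore"

    def __post_init__(self) -> None:
        if None not in (self.M, self.F, self.Z):
            if abs((self.M + self.F) - self.Z) > 0.02:
                raise ModelValidationError(
                    f"{self.species}: Z={self.Z} inconsistent with "
                    f"M+F={self.M + self.F:.3f}"
                )
        if None not in (self.a, self.b, self.Linf, self.Winf):
            pred = self.a * self.Linf**self.b
            if abs(pred - self.Winf) > 0.05 * self.Winf:
                raise ModelValidationError(
                    f"{self.species}: Winf={self.Winf} inconsistent with "
                    f"a*Linf^b={pred:.1f}"
                )


@dataclass
class FoodWebModel:
    """An (un)balanced food-web model: groups + diet + landings."""

    groups: list[FunctionalGroup]
    diet: DietMatrix
    area_km2: float | None = None
    life_history: list[LifeHistoryRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ModelValidationError("group names must be unique")
        if names != self.diet.group_names:
            raise ModelValidationError(
                "diet matrix group order does not match model group order"
            )
        if not any(g.is_producer for g in self.groups):
            raise ModelValidationError("model needs at least one producer")
        if not any(g.is_detritus for g in self.groups):
            raise ModelValidationError("model needs at least one detritus pool")
        self.diet.validate_columns([g.is_consumer for g in self.groups])

    # -- convenience ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> FunctionalGroup:
        return self.groups[self.index(name)]

    @property
    def fleet_landings(self) -> np.ndarray:
        """Per-group landings vector (the fleet's 'diet' in impact analysis)."""
        return np.array([g.landings for g in self.groups])

    def consumer_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.groups) if g.is_consumer]

    def producer_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.groups) if g.is_producer]

    def detritus_indices(self) -> list[int]:
        return [i for i, g in enumerate(self.groups) if g.is_detritus]

    def copy(self) -> "FoodWebModel":
        return copy.deepcopy(self)

    # -- tabular views ----------------------------------------------------
    def groups_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            rows.append(
                {
                    "name": g.name,
                    "group_type": g.group_type.value,
                    "biomass": g.biomass,
                    "pb": g.pb,
                    "qb": g.qb,
                    "ee": g.ee,
                    "landings": g.landings,
                    "unassimilated": g.unassimilated,
                    "biomass_accumulation": g.biomass_accumulation,
                    "net_migration": g.net_migration,
                }
            )
        return pd.DataFrame(rows)

    def diet_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.diet.entries, index=self.names, columns=self.names
        )
        df.loc["Import"] = self.diet.imports
        return df


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def convert_landings(catch_tonnes: float, area_km2: float) -> float:
    """Convert a whole-lake annual catch (t/yr) to areal units (t/km2/yr)."""
    if area_km2 <= 0:
        raise ValueError("lake area must be positive")
    return catch_tonnes / area_km2


# ---------------------------------------------------------------------------
# file input / output
# ---------------------------------------------------------------------------

_GROUP_COLUMNS = [
    "name",
    "group_type",
    "biomass",
    "pb",
    "qb",
    "ee",
    "landings",
    "unassimilated",
    "biomass_accumulation",
    "net_migration",
]


def _group_from_record(rec: dict) -> FunctionalGroup:
    def val(key, default=None):
        v = rec.get(key, default)
        if v is None:
            return default
        if isinstance(v, float) and math.isnan(v):
            return default
        return v

    gtype = GroupType(val("group_type", "consumer"))
    kwargs = dict(
        name=str(rec["name"]),
        group_type=gtype,
        biomass=val("biomass"),
        pb=val("pb"),
        qb=val("qb"),
        ee=val("ee"),
        landings=float(val("landings", 0.0)),
        unassimilated=float(
            val("unassimilated", 0.2 if gtype is GroupType.CONSUMER else 0.0)
        ),
        biomass_accumulation=float(val("biomass_accumulation", 0.0)),
        net_migration=float(val("net_migration", 0.0)),
    )
    for k in ("biomass", "pb", "qb", "ee"):
        if kwargs[k] is not None:
            kwargs[k] = float(kwargs[k])
    return FunctionalGroup(**kwargs)


def _model_from_frames(
    groups_df: pd.DataFrame, diet_df: pd.DataFrame, area_km2: float | None
) -> FoodWebModel:
    if "name" not in groups_df.columns:
        raise ModelValidationError("groups table is missing a 'name' column")
    groups = [_group_from_record(rec) for rec in groups_df.to_dict("records")]
    names = [g.name for g in groups]
    imports = np.zeros(len(names))
    if "Import" in diet_df.index:
        imports = diet_df.loc["Import", names].to_numpy(dtype=float)
        diet_df = diet_df.drop(index="Import")
    missing = [n for n in names if n not in diet_df.index or n not in diet_df.columns]
    if missing:
        raise ModelValidationError(f"diet table is missing groups: {missing}")
    entries = diet_df.loc[names, names].to_numpy(dtype=float)
    entries = np.nan_to_num(entries)
    diet = DietMatrix(group_names=names, entries=entries, imports=imports)
    return FoodWebModel(groups=groups, diet=diet, area_km2=area_km2)


def load_model(path: str | Path, format: str | None = None) -> FoodWebModel:
    """Load a food-web model from disk.

    Two layouts are supported:

    * a directory holding ``groups.csv`` (one row per group, landings merged
      in) and ``diet.csv`` (prey rows x predator columns with an optional
      ``Import`` row);
    * a single YAML or JSON document with ``groups``, ``diet`` and optional
      ``area_km2``/``imports`` keys.

    Violated invariants raise :class:`ModelValidationError` naming the
    offending group or column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "csv"
        elif path.suffix in {".yaml", ".yml"}:
            format = "yaml"
        elif path.suffix == ".json":
            format = "json"
        else:
            raise ValueError(f"cannot infer format of {path}")

    if format == "csv":
        groups_df = pd.read_csv(path / "groups.csv")
        diet_df = pd.read_csv(path / "diet.csv", index_col=0)
        area = None
        meta = path / "meta.json"
        if meta.exists():
            area = json.loads(meta.read_text()).get("area_km2")
        return _model_from_frames(groups_df, diet_df, area)

    text = path.read_text()
    doc = yaml.safe_load(text) if format == "yaml" else json.loads(text)
    groups = [_group_from_record(rec) for rec in doc["groups"]]
    names = [g.name for g in groups]
    entries = np.array(
        [[float(doc["diet"][prey].get(pred, 0.0)) for pred in names] for prey in names]
    )
    imports = np.array([float(doc.get("imports", {}).get(n, 0.0)) for n in names])
    diet = DietMatrix(group_names=names, entries=entries, imports=imports)
    return FoodWebModel(groups=groups, diet=diet, area_km2=doc.get("area_km2"))


def save_model(model: FoodWebModel, path: str | Path, format: str = "csv") -> Path:
    """Write ``model`` to disk in the layout understood by :func:`load_model`.

    Numeric fields are written at 15 significant digits so that a
    save -> load round trip is exact to 1e-12.
    """
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        model.groups_frame().to_csv(
            path / "groups.csv", index=False, float_format="%.15g"
        )
        model.diet_frame().to_csv(path / "diet.csv", float_format="%.15g")
        (path / "meta.json").write_text(
            json.dumps({"area_km2": model.area_km2}) + "\n"
        )
        return path

    names = model.names
    doc = {
        "area_km2": model.area_km2,
        "groups": [
            {k: v for k, v in rec.items() if v is not None and v == v}
            for rec in model.groups_frame().to_dict("records")
        ],
        "diet": {
            prey: {
                pred: float(model.diet.entries[i, j])
                for j, pred in enumerate(names)
                if model.diet.entries[i, j] != 0.0
            }
            for i, prey in enumerate(names)
        },
        "imports": {
            n: float(v) for n, v in zip(names, model.diet.imports) if v != 0.0
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "yaml":
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    elif format == "json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
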