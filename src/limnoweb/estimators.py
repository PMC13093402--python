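"""Empirical parameter estimators used to populate a food-web model.

These are the standard fisheries relations for filling in B, P/B, Q/B and
detritus standing stock from life-history data:

* biomass from catch and fishing mortality, ``B = Y / F``;
* total mortality (and hence P/B at steady state) from the Beverton-Holt
  length-based estimator ``Z = K (Linf - Lavg) / (Lavg - Lc)`` or from
  ``Z = M + F``;
* consumption rate from the Palomares-Pauly multiple regression on
  asymptotic weight, temperature, caudal-fin aspect ratio and feeding type;
* detritus standing stock from primary production and euphotic depth, with
  the euphotic depth taken as 2.5x the Secchi-disk depth.

All logarithms in the regressions are base 10, as in the source relations.
"""

from __future__ import annotations

import math

__all__ = [
    "biomass_from_catch",
    "z_from_mf",
    "pb_beverton_holt",
    "qb_palomares_pauly",
    "aspect_ratio",
    "euphotic_depth",
    "detritus_biomass",
]


def biomass_from_catch(catch: float, fishing_mortality: float) -> float:
    """Standing biomass from annual catch Y and fishing mortality F: B = Y/F.

    Units follow the inputs: Y in t/yr gives B in t (divide by the surveyed
    area for areal density).
    """
    if fishing_mortality <= 0:
        raise ValueError("fishing mortality must be positive")
    return catch / fishing_mortality


def z_from_mf(natural_mortality: float, fishing_mortality: float) -> float:
    """Total mortality Z = M + F (equals P/B at steady state)."""
    return natural_mortality + fishing_mortality


def pb_beverton_holt(K: float, Linf: float, Lavg: float, Lc: float) -> float:
    """Length-based total mortality Z = K (Linf - Lavg) / (Lavg - Lc).

    ``K`` is the von Bertalanffy growth coefficient (/yr), ``Linf`` the
    asymptotic length, ``Lavg`` the mean length in the catch and ``Lc`` the
    mean length at first capture (all cm, with Linf > Lavg > Lc).
    """
    if not (Linf > Lavg > Lc):
        raise ValueError("lengths must satisfy Linf > Lavg > Lc")
    return K * (Linf - Lavg) / (Lavg - Lc)


def aspect_ratio(fin_height: float, fin_area: float) -> float:
    """Caudal-fin aspect ratio A = h^2 / s (height squared over surface area)."""
    if fin_area <= 0:
        raise ValueError("fin surface area must be positive")
    return fin_height**2 / fin_area


def qb_palomares_pauly(
    Winf: float,
    Tc: float,
    A: float,
    herbivore: bool = False,
    detritivore: bool = False,
) -> float:
    """Consumption/biomass ratio (/yr) from the Palomares-Pauly regression.

    ``log10(Q/B) = 7.964 - 0.204 log10(Winf) - 1.965 T' + 0.083 A
    + 0.532 h + 0.398 d`` with ``T' = 1000 / (Tc + 273.1)`` (Tc in deg C),
    ``Winf`` the asymptotic weight in g, ``A`` the caudal-fin aspect ratio,
    and h/d the herbivore/detritivore dummies (both zero for carnivores).
    """
    if Winf <= 0:
        raise ValueError("asymptotic weight must be positive")
    if A < 0:
        raise ValueError("aspect ratio must be non-negative")
    if herbivore and detritivore:
        raise ValueError("feeding dummies h and d cannot both be 1")
    t_prime = 1000.0 / (Tc + 273.1)
    exponent = (
        7.964
        - 0.204 * math.log10(Winf)
        - 1.965 * t_prime
        + 0.083 * A
        + 0.532 * (1 if herbivore else 0)
        + 0.398 * (1 if detritivore else 0)
    )
    return 10.0**exponent


def euphotic_depth(secchi_depth: float) -> float:
    """Euphotic-zone depth (m) from Secchi-disk depth: E = 2.5 SD."""
    if secchi_depth <= 0:
        raise ValueError("Secchi depth must be positive")
    return 2.5 * secchi_depth


def detritus_biomass(primary_production: float, secchi_depth: float) -> float:
    """Detritus standing stock D (g C/m2) from PP (g C/m2) and Secchi depth.

    ``log10 D = 0.954 log10 PP + 0.863 log10 E - 2.41`` with E = 2.5 SD.
    """
    if primary_production <= 0:
        raise ValueError("primary production must be positive")
    E = euphotic_depth(secchi_depth)
    return 10.0 ** (0.954 * math.log10(primary_production) + 0.863 * math.log10(E) - 2.41)
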