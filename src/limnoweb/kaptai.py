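"""Bundled Kaptai Lake (Bangladesh) food-web model.

Kaptai Lake is a large man-made reservoir (58,300 ha of water surface, i.e.
583 km2) in the Chittagong hill tracts, dominated by small clupeids.  The
model has fifteen functional groups: ten fish groups, Whisker Shrimp,
Insects/larvae, Zooplankton, Phytoplankton and a Detritus pool.  Inputs are
the published biomass, P/B and Q/B values, the diet-composition matrix, and
the 2024 landing-centre catches converted to t/km2/yr with the 583 km2 lake
area.

Snakehead lacks reliable biomass data; its EE is fixed at 0.95 and the
balance solver estimates its biomass.  Every other living group enters with
known biomass and unknown EE.

The Whisker Shrimp landing is not reported with the landing-centre data.  It
is back-derived here from the steady-state balance identity

    landings = EE * B * (P/B) - sum_j B_j * (Q/B)_j * DC_shrimp,j

using the published shrimp B = 0.135, P/B = 3.16, EE = 0.982 and the
predation column of the diet matrix (with the solved Snakehead biomass
0.07204 in the predator term, so the balanced fixture reproduces the
published shrimp EE exactly), which gives 0.21143 t/km2/yr.  The value is
frozen below so the fixture is self-contained.
"""

from __future__ import annotations

import numpy as np

from .model import (
    DietMatrix,
    FoodWebModel,
    FunctionalGroup,
    GroupType,
    LifeHistoryRecord,
    convert_landings,
)

__all__ = ["KAPTAI_AREA_KM2", "WHISKER_SHRIMP_LANDING", "kaptai_fixture", "kaptai_life_history"]

#: lake water-surface area used for all tonnes -> t/km2 conversions
KAPTAI_AREA_KM2 = 583.0

#: back-derived Whisker Shrimp landing, t/km2/yr (see module docstring)
WHISKER_SHRIMP_LANDING = 0.2114285

# name, type, biomass t/km2 (None = solve), P/B /yr, Q/B /yr, EE (None = solve),
# whole-lake annual catch t/yr
_GROUPS = [
    ("Sheatfish", "consumer", 0.012, 2.8, 10.9, None, 7.599),
    ("Snakehead", "consumer", None, 2.27, 8.93, 0.95, 22.961),
    ("Catfish", "consumer", 0.368, 2.78, 12.12, None, 350.275),
    ("Knifefish", "consumer", 0.091, 1.12, 7.4, None, 18.014),
    ("Spiny eel", "consumer", 0.035, 0.75, 9.5, None, 8.881),
    ("Glassfish", "consumer", 0.066, 3.11, 23.3, None, 57.13),
    ("Carp", "consumer", 0.055, 2.29, 19.14, None, 41.345),
    ("Cichlid", "consumer", 0.017, 1.39, 14.1, None, 6.076),
    ("Clupeid", "consumer", 3.264, 6.29, 35.3, None, 5337.94),
    ("Minnow", "consumer", 0.302, 3.26, 76.2, None, 359.234),
    ("Whisker Shrimp", "consumer", 0.135, 3.16, 12.64, None, None),
    ("Insects/larvae", "consumer", 4.125, 4.0, 30.0, None, 0.0),
    ("Zooplankton", "consumer", 12.85, 35.0, 140.0, None, 0.0),
    ("Phytoplankton", "producer", 11.7, 203.0, None, None, 0.0),
    ("Detritus", "detritus", 1.0, None, None, None, 0.0),
]

# Diet composition: prey rows x predator columns (13 consumer columns, in
# group order).  Producer and detritus columns are all zero; the import row
# is all zero.  Each consumer column sums to 1.
_DIET = {
    "Sheatfish":      [0, 0.002, 0.001, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Snakehead":      [0, 0, 0.026, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Catfish":        [0.093, 0.024, 0.020, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Knifefish":      [0, 0, 0.003, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Spiny eel":      [0, 0.005, 0.0003, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Glassfish":      [0.093, 0.026, 0.002, 0.037, 0.093, 0, 0, 0, 0, 0, 0, 0, 0],
    "Carp":           [0.072, 0, 0.01, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Cichlid":        [0.031, 0, 0.002, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "Clupeid":        [0.155, 0.243, 0.640, 0.309, 0.229, 0.055, 0, 0, 0, 0, 0, 0, 0],
    "Minnow":         [0.186, 0.213, 0.013, 0.1, 0.206, 0, 0, 0, 0, 0, 0, 0, 0],
    "Whisker Shrimp": [0.175, 0.1, 0.005, 0.013, 0.05, 0.035, 0, 0, 0, 0, 0.011, 0, 0],
    "Insects/larvae": [0, 0.196, 0.131, 0.278, 0.286, 0.504, 0.075, 0.05, 0.1, 0, 0.208, 0, 0],
    "Zooplankton":    [0, 0.097, 0.061, 0.139, 0.023, 0.329, 0.055, 0.246, 0.425, 0.13, 0.208, 0.125, 0.05],
    "Phytoplankton":  [0.082, 0.041, 0.044, 0.077, 0.069, 0.044, 0.52, 0.7, 0.375, 0.85, 0.104, 0.305, 0.8],
    "Detritus":       [0.113, 0.052, 0.044, 0.046, 0.046, 0.033, 0.35, 0.004, 0.1, 0.02, 0.469, 0.57, 0.15],
}

# Life-history parameters of the representative species:
# species, group, annual catch t, Linf cm, K /yr, a, b, Winf g, M /yr, F /yr, Z /yr
_LIFE_HISTORY = [
    ("Wallago attu", "Sheatfish", 6.667, 99.75, 1.3, 0.0074, 3.05, 9259, 1.47, 1.9, 3.37),
    ("Ompok pabda", "Sheatfish", 0.932, 21, 1.0, 0.0048, 3.1, 60.3, 1.92, 0.29, 2.22),
    # the published Z (3.13) contradicts M+F (3.73) for C. punctata; Z is
    # left unset and recomputed as M+F when needed
    ("Channa punctata", "Snakehead", 1.237, 24, 0.9, 0.0457, 2.83, 368, 2.16, 1.57, None),
    ("Channa striata", "Snakehead", 6.389, 63, 0.77, 0.0107, 2.933, 2027, 1.24, 1.27, 2.51),
    ("Channa marulius", "Snakehead", 15.335, 40.95, 0.3, 0.006, 3.033, 467, 0.68, 0.5, 1.18),
    ("Sperata seenghala", "Catfish", 225.055, 117.6, 0.37, 0.004, 3.047, 8139, 0.56, 0.44, 1.0),
    ("Ailia coila", "Catfish", 57.822, 18.9, 0.68, 0.08, 3.13, 791, 0.81, 1.84, 2.65),
    ("Eutropiichthys vacha", "Catfish", 6.653, 44.4, 0.7, 0.0088, 2.96, 662, 1.27, 2.96, 4.23),
    ("Mystus tengara", "Catfish", 51.331, 11.19, 0.72, 0.0125, 3.01, 18, 1.72, 1.28, 3.0),
    ("Mystus cavasius", "Catfish", 3.261, 21.5, 0.56, 0.0166, 3.03, 180.9, 1.35, 2.51, 3.86),
    ("Heteropneustes fossilis", "Catfish", 6.153, 25, 0.5, 0.0012, 3.5, 93.7, 1.15, 0.8, 1.95),
    ("Notopterus notopterus", "Knifefish", 14.543, 34.91, 0.38, 0.0176, 2.99, 722, 0.91, 0.28, 1.19),
    ("Notopterus chitala", "Knifefish", 3.471, 82.95, 0.39, 0.0126, 2.896, 4550, 0.64, 0.4, 1.04),
    ("Mastacembelus armatus", "Spiny eel", 8.881, 58.8, 0.13, 0.004, 2.8733, 485, 0.32, 0.43, 0.75),
    ("Chanda nama", "Glassfish", 57.13, 10.25, 0.55, 0.0071, 3.13, 10.5, 1.63, 1.48, 3.11),
    ("Labeo rohita", "Carp", 6.538, 93.28, 0.92, 0.0154, 2.971, 10966, 1.22, 1.31, 2.53),
    ("Catla catla", "Carp", 8.917, 93.68, 0.57, 0.0047, 3.293, 14623, 0.9, 1.01, 1.91),
    ("Cirrhinus cirrhosus", "Carp", 1.751, 85.07, 0.43, 0.0114, 3.001, 7057, 0.75, 1.29, 2.04),
    ("Labeo calbasu", "Carp", 6.655, 52.5, 0.76, 0.0036, 3.47, 3352, 1.25, 1.64, 2.89),
    ("Labeo bata", "Carp", 17.484, 40.2, 1.3, 0.012, 3.08, 1048, 0.96, 1.13, 2.09),
    ("Oreochromis niloticus", "Cichlid", 6.076, 55.59, 0.39, 0.0366, 2.844, 3361, 0.8, 0.59, 1.39),
    ("Corica soborna", "Clupeid", 2291.67, 5.7, 2.62, 0.0084, 2.968, 1.5, 5.11, 3.4, 8.51),
    ("Gudusia chapra", "Clupeid", 3046.27, 19.95, 0.89, 0.0079, 2.98, 59.5, 1.85, 2.21, 4.06),
    ("Amblypharyngodon mola", "Minnow", 359.234, 10.47, 0.95, 0.0067, 3.21, 12.7, 1.22, 2.04, 3.26),
]


def kaptai_fixture() -> FoodWebModel:
    """Return the Kaptai Lake model ready for the mass-balance solver."""
    groups = []
    for name, gtype, b, pb, qb, ee, catch_t in _GROUPS:
        if catch_t is None:  # Whisker Shrimp: back-derived areal landing
            landings = WHISKER_SHRIMP_LANDING
        elif catch_t:
            landings = convert_landings(catch_t, KAPTAI_AREA_KM2)
        else:
            landings = 0.0
        groups.append(
            FunctionalGroup(
                name=name,
                group_type=GroupType(gtype),
                biomass=b,
                pb=pb,
                qb=qb,
                ee=ee,
                landings=landings,
                unassimilated=0.2 if gtype == "consumer" else 0.0,
            )
        )
    names = [g.name for g in groups]
    n = len(names)
    entries = np.zeros((n, n))
    n_cons = 13  # consumer columns in group order
    for i, name in enumerate(names):
        entries[i, :n_cons] = _DIET[name]
    # the published proportions are rounded (columns sum to 0.999-1.0023);
    # restore exact column stochasticity by absorbing each column's rounding
    # residual into its largest entry, leaving every other printed
    # proportion untouched (residuals are at most 0.0023)
    for j in range(n_cons):
        residual = 1.0 - entries[:, j].sum()
        entries[np.argmax(entries[:, j]), j] += residual
    diet = DietMatrix(group_names=names, entries=entries)
    model = FoodWebModel(
        groups=groups,
        diet=diet,
        area_km2=KAPTAI_AREA_KM2,
        life_history=kaptai_life_history(),
    )
    return model


def kaptai_life_history() -> list[LifeHistoryRecord]:
    """Life-history table of the representative species (24 fish species)."""
    records = []
    for (species, _group, catch, linf, k, a, b, winf, m, f, z) in _LIFE_HISTORY:
        records.append(
            LifeHistoryRecord(
                species=species,
                annual_catch=catch,
                Linf=linf,
                K=k,
                a=a,
                b=b,
                Winf=winf,
                M=m,
                F=f,
                Z=z,
            )
        )
    return records
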