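"""Published reference values from a golden-jackal field study in seasonally dry forest.

These constants are worked-example *inputs*: the printed seasonal diet
composition of a dry-deciduous-forest golden jackal population (percent
biomass at the finest identified item level), ungulate densities and adult
female body masses for the same landscape, and the four annual 95% kernel
home-range areas of its collared animals. The package's own functions are run
on them in the README example, the test suite, and ``scripts/acceptance.py``
to reproduce the study's derived quantities (niche breadth, availability
shares, electivity, mean home range).

Values below the table's printable precision (shown as "< 0.1") are stored as
0.0. Biomass columns therefore sum to slightly less than 100 and must be
renormalized (``jackalkit.metrics.as_proportions``) before computing metrics.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DIET_BIOMASS_PERCENT",
    "diet_biomass_table",
    "UNGULATE_DENSITY_PER_KM2",
    "UNGULATE_ADULT_FEMALE_MASS_KG",
    "UNGULATE_CONSUMED_BIOMASS_PERCENT",
    "UNGULATE_CATEGORY_BIOMASS_PERCENT",
    "KDE95_AREAS_KM2",
]

#: Percent of ingested biomass per identified item (rows) and season (columns).
#: Finest-granularity rows only — the category roll-ups (ungulate, reptile,
#: arthropod) are excluded, so each column is a complete partition of the diet.
DIET_BIOMASS_PERCENT: dict[str, tuple[float, float, float]] = {
    # taxon: (cool_dry, hot_dry, total)
    "muntjac": (21.6, 18.7, 20.1),
    "wild_pig": (17.7, 22.8, 20.3),
    "large_cervid": (0.0, 0.4, 0.2),
    "civet": (21.8, 12.9, 17.2),
    "hare": (8.1, 1.3, 4.6),
    "porcupine": (0.0, 0.2, 0.1),
    "small_rodent": (6.8, 5.3, 6.0),
    "bird": (1.7, 4.8, 3.3),
    "small_lizard": (0.3, 0.6, 0.4),
    "small_snake": (0.1, 0.1, 0.1),
    "small_tortoise": (0.0, 0.0, 0.0),
    "unidentified_reptile": (0.3, 1.4, 0.9),
    "termite": (20.4, 30.4, 25.6),
    "beetle": (0.1, 0.7, 0.4),
    "grasshopper": (0.0, 0.0, 0.0),
    "crab": (0.8, 0.4, 0.6),
    "egg_shell": (0.0, 0.0, 0.0),
    "seeds": (0.3, 0.0, 0.1),
}

#: Scat sample sizes per column: cool-dry 69, hot-dry 78, total 147.
DIET_N_SCATS: dict[str, int] = {"cool_dry": 69, "hot_dry": 78, "total": 147}

#: Dry-season ungulate densities (individuals/km²) from line-transect surveys.
UNGULATE_DENSITY_PER_KM2: dict[str, float] = {
    "banteng": 2.3,
    "muntjac": 2.1,
    "wild_pig": 6.5,
}

#: Adult female body masses (kg) used to convert densities to biomass.
UNGULATE_ADULT_FEMALE_MASS_KG: dict[str, float] = {
    "banteng": 600.0,
    "muntjac": 20.0,
    "wild_pig": 75.0,
}

#: Consumed biomass percents of the availability species (total column).
UNGULATE_CONSUMED_BIOMASS_PERCENT: dict[str, float] = {
    "muntjac": 20.1,
    "wild_pig": 20.3,
    "banteng": 0.0,
}

#: Total-column biomass percent of the whole ungulate category (includes the
#: unidentified large cervid item).
UNGULATE_CATEGORY_BIOMASS_PERCENT: float = 40.7

#: Annual 95% kernel home-range areas (km²) of the four collared animals.
KDE95_AREAS_KM2: tuple[float, float, float, float] = (50.7, 46.7, 40.1, 50.8)


def diet_biomass_table() -> pd.DataFrame:
    """The published biomass composition as a tidy frame (taxon × season)."""
    rows = [
        (taxon, season, value)
        for taxon, vals in DIET_BIOMASS_PERCENT.items()
        for season, value in zip(("cool_dry", "hot_dry", "total"), vals)
    ]
    return pd.DataFrame(rows, columns=["taxon", "season", "biomass_percent"])
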