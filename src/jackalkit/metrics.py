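"""Dietary niche metrics: Levins breadth, Horn overlap, availability, Jacobs electivity.

All metrics operate on proportion vectors (per-taxon shares summing to 1).
Vectors whose sum is within 1e-6 of 1 are silently renormalized; anything
further off is rejected, since it usually signals percents passed where
proportions were meant (use :func:`as_proportions` to convert explicitly).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "as_proportions",
    "levins_B",
    "horns_R0",
    "available_biomass",
    "jacobs_D",
    "ungulate_selection",
    "diet_overlap",
]


def as_proportions(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Normalize nonnegative values (e.g. percents) into a proportion vector."""
    s = pd.Series(values, dtype=float)
    if (s < 0).any():
        raise ValueError("values must be nonnegative")
    total = s.sum()
    if total <= 0:
        raise ValueError("values sum to 0")
    return s / total


def _validated(p: Mapping[str, float] | pd.Series, name: str = "p") -> pd.Series:
    s = pd.Series(p, dtype=float)
    if (s < 0).any():
        raise ValueError(f"{name}: proportions must be nonnegative")
    total = s.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"{name}: proportions sum to {total!r}, not 1 (tolerance 1e-6); "
            "use as_proportions() to normalize percents"
        )
    return s / total


def levins_B(p: Mapping[str, float] | pd.Series) -> float:
    """Levins niche breadth B = 1 / Σ p_i² — effective number of equally used taxa.

    Bounded by 1 (single taxon) and the number of taxa (uniform use).
    """
    s = _validated(p)
    return float(1.0 / np.sum(np.square(s.to_numpy())))


def horns_R0(
    p: Mapping[str, float] | pd.Series, q: Mapping[str, float] | pd.Series
) -> float:
    """Horn's overlap R0 between two diet proportion vectors (0 = disjoint, 1 = identical).

    R0 = [Σ (p+q) ln(p+q) − Σ p ln p − Σ q ln q] / (2 ln 2), with 0·ln 0 := 0,
    computed over the union of the two taxon sets (zero-filled). Base-invariant
    by construction; symmetric in its arguments.
    """
    ps = _validated(p, "p")
    qs = _validated(q, "q")
    taxa = ps.index.union(qs.index)
    pa = ps.reindex(taxa, fill_value=0.0).to_numpy()
    qa = qs.reindex(taxa, fill_value=0.0).to_numpy()

    def xlogx(v: np.ndarray) -> float:
        vv = v[v > 0]
        return float(np.sum(vv * np.log(vv)))

    r0 = (xlogx(pa + qa) - xlogx(pa) - xlogx(qa)) / (2.0 * np.log(2.0))
    return float(min(max(r0, 0.0), 1.0))


def available_biomass(
    densities: Mapping[str, float], masses: Mapping[str, float]
) -> pd.DataFrame:
    """Biomass availability shares from per-species density × individual mass.

    ``biomass_share_i = density_i · mass_i / Σ_j density_j · mass_j``; invariant
    to common rescaling of either input. Densities are individuals/km²; masses
    are kg of an average (adult female) individual.
    """
    if set(densities) != set(masses):
        raise ValueError(
            f"species sets differ: {sorted(densities)} vs {sorted(masses)}"
        )
    species = sorted(densities)
    d = np.array([densities[s] for s in species], dtype=float)
    m = np.array([masses[s] for s in species], dtype=float)
    if np.any(d <= 0) or np.any(m <= 0):
        raise ValueError("densities and masses must be > 0")
    biomass = d * m
    return pd.DataFrame(
        {
            "species": species,
            "density_per_km2": d,
            "adult_female_mass_kg": m,
            "biomass_kg_per_km2": biomass,
            "biomass_share": biomass / biomass.sum(),
        }
    )


def jacobs_D(r: float, p: float) -> float:
    """Jacobs electivity D = (r − p) / (r + p − 2 r p) for used share r vs available share p.

    D = −1 is complete avoidance (r = 0), D = +1 complete selection (p = 0 or
    r = 1); D = 0 when use matches availability. Antisymmetric: D(r, p) = −D(p, r).
    """
    if not (0 <= r <= 1 and 0 <= p <= 1):
        raise ValueError("r and p must lie in [0, 1]")
    if r == 0 and p == 0:
        raise ValueError("Jacobs D undefined for r = p = 0")
    return float((r - p) / (r + p - 2.0 * r * p))


def ungulate_selection(
    composition: pd.DataFrame | Mapping[str, float],
    avail: pd.DataFrame,
    season: str = "total",
    category: str = "ungulate",
    category_total: float | None = None,
) -> pd.DataFrame:
    """Jacobs D per availability species from a diet composition and an availability table.

    The consumed share ``r`` of each species is its item-level biomass percent
    divided by the total biomass percent of the whole ``category`` roll-up
    (so unidentified members of the category dilute every species equally —
    this is the normalization that reproduces published electivities from the
    printed composition table). Availability ``p`` comes from
    :func:`available_biomass`. A species absent from the composition has
    r = 0 and hence D = −1.
    """
    if isinstance(composition, pd.DataFrame):
        block = composition[composition["season"] == season]
        if block.empty:
            raise ValueError(f"no composition rows for season {season!r}")
        items = block[block["level"] == "item"].set_index("taxon")["biomass_percent"]
        cats = block[block["level"] == "category"].set_index("taxon")["biomass_percent"]
        consumed = {sp: float(items.get(sp, 0.0)) for sp in avail["species"]}
        total = float(cats.get(category, sum(consumed.values())))
    else:
        consumed = {sp: float(composition.get(sp, 0.0)) for sp in avail["species"]}
        total = float(sum(composition.values()))
    if category_total is not None:
        total = float(category_total)
    if total <= 0 or all(v == 0 for v in consumed.values()):
        raise ValueError(f"no {category} biomass consumed; Jacobs D undefined")

    shares = avail.set_index("species")["biomass_share"]
    rows = []
    for sp in avail["species"]:
        r = consumed[sp] / total
        p = float(shares[sp])
        rows.append((sp, r, p, jacobs_D(r, p)))
    return pd.DataFrame(rows, columns=["species", "r", "p", "D"])


def diet_overlap(
    comp_a: pd.DataFrame | Mapping[str, float],
    comp_b: pd.DataFrame | Mapping[str, float],
    season: str = "total",
    level: str = "category",
) -> float:
    """Horn's R0 between two diets expressed on a shared category scheme.

    Accepts either tidy composition frames (from
    :func:`jackalkit.diet.composition_table`) or plain proportion/percent
    mappings. Disjoint diets give 0, identical diets 1.
    """

    def extract(comp) -> pd.Series:
        if isinstance(comp, pd.DataFrame):
            block = comp[(comp["season"] == season) & (comp["level"] == level)]
            if block.empty:
                raise ValueError(f"no rows for season {season!r} / level {level!r}")
            return as_proportions(block.set_index("taxon")["biomass_percent"])
        return as_proportions(comp)

    return horns_R0(extract(comp_a), extract(comp_b))
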