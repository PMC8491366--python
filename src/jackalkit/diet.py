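"""Scat-based diet composition.

Converts raw scat records (dry weight plus visually estimated per-item volume
percentages) into seasonal diet-composition tables expressed three ways:

* **percent biomass** — scat dry weight is allocated to items by volume share,
  then converted to biomass consumed with per-taxon correction factors (CF,
  grams of fresh biomass ingested per gram of dry remains, from feeding
  trials);
* **percent volume** — arithmetic mean over all scats of each taxon's per-scat
  volume percentage (zero where absent);
* **frequency of occurrence** — percentage of scats containing the taxon.

Seasons are assigned from the collection month; a chi-square contingency test
compares occurrence counts between seasons.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScatRecord",
    "CorrectionFactorTable",
    "SeasonDefinition",
    "DEFAULT_CF_TABLE",
    "scats_from_frame",
    "scats_to_frame",
    "exclude_trace",
    "biomass_consumed",
    "percent_volume",
    "frequency_occurrence",
    "composition_table",
    "seasonal_occurrence_counts",
    "seasonal_chi_square",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatRecord:
    """One scat: collection date, dry weight, and per-item volume percentages."""

    scat_id: str
    collection_date: _dt.date
    dry_weight_g: float
    items: tuple[tuple[str, float], ...]
    diameter_cm: float | None = None

    def __post_init__(self) -> None:
        if self.dry_weight_g <= 0:
            raise ValueError(f"scat {self.scat_id}: dry weight must be > 0")
        if self.diameter_cm is not None and self.diameter_cm <= 0:
            raise ValueError(f"scat {self.scat_id}: diameter must be > 0")
        taxa = [t for t, _ in self.items]
        if len(set(taxa)) != len(taxa):
            raise ValueError(f"scat {self.scat_id}: duplicate item taxa")
        total = 0.0
        for taxon, vol in self.items:
            if not (0 < vol <= 100):
                raise ValueError(
                    f"scat {self.scat_id}: volume percent {vol} for {taxon!r} "
                    "outside (0, 100]"
                )
            total += vol
        if total > 100 + 1e-6:
            raise ValueError(
                f"scat {self.scat_id}: item volumes sum to {total:.3f} > 100"
            )

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.items)


#: Correction factors (g biomass consumed per g dry remains) from red-fox
#: feeding trials, as applied to a dry-forest jackal diet. Keys are the item
#: taxa used by the study-like synthetic generator.
DEFAULT_CF_ROWS: tuple[tuple[str, float, str], ...] = (
    ("muntjac", 118.0, "ungulate"),
    ("wild_pig", 84.0, "ungulate"),
    ("large_cervid", 118.0, "ungulate"),
    ("civet", 50.0, "medium_mammal"),
    ("hare", 50.0, "medium_mammal"),
    ("porcupine", 50.0, "medium_mammal"),
    ("small_rodent", 23.0, "small_mammal"),
    ("bird", 35.0, "bird"),
    ("reptile", 18.0, "reptile"),
    ("small_lizard", 18.0, "reptile"),
    ("small_snake", 18.0, "reptile"),
    ("small_tortoise", 18.0, "reptile"),
    ("termite", 12.0, "arthropod"),
    ("beetle", 5.0, "arthropod"),
    ("grasshopper", 5.0, "arthropod"),
    ("crab", 5.0, "arthropod"),
    ("egg_shell", 15.0, "egg_shell"),
    ("seeds", 14.0, "seeds"),
)


class CorrectionFactorTable:
    """Per-taxon correction factor and category label."""

    def __init__(self, rows: Iterable[tuple[str, float, str]]):
        self._cf: dict[str, float] = {}
        self._category: dict[str, str] = {}
        for taxon, cf, category in rows:
            if cf <= 0:
                raise ValueError(f"CF for {taxon!r} must be > 0, got {cf}")
            self._cf[taxon] = float(cf)
            self._category[taxon] = str(category)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._cf

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self._cf)

    def cf(self, taxon: str) -> float:
        return self._cf[taxon]

    def category(self, taxon: str) -> str:
        return self._category[taxon]

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self._category.values():
            seen.setdefault(c)
        return tuple(seen)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CorrectionFactorTable":
        cols = {"taxon", "cf", "category"}
        if not cols.issubset(frame.columns):
            raise ValueError(f"CF table needs columns {sorted(cols)}")
        return cls(frame[["taxon", "cf", "category"]].itertuples(index=False, name=None))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, self._cf[t], self._category[t]) for t in self._cf],
            columns=["taxon", "cf", "category"],
        )


DEFAULT_CF_TABLE = CorrectionFactorTable(DEFAULT_CF_ROWS)


@dataclass(frozen=True)
class SeasonDefinition:
    """Calendar-month → season-label map.

    Defaults follow the dry-forest study calendar: November–February is the
    cool-dry season, March–May the hot-dry season, June–October the rainy
    season (when scats typically cannot be collected).
    """

    months: Mapping[int, str] = field(
        default_factory=lambda: {
            11: "cool_dry", 12: "cool_dry", 1: "cool_dry", 2: "cool_dry",
            3: "hot_dry", 4: "hot_dry", 5: "hot_dry",
            6: "rainy", 7: "rainy", 8: "rainy", 9: "rainy", 10: "rainy",
        }
    )

    def __post_init__(self) -> None:
        if set(self.months) != set(range(1, 13)):
            raise ValueError("every month 1..12 must map to exactly one season")

    def season_of(self, date: _dt.date) -> str:
        return self.months[date.month]

    @property
    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in range(1, 13):
            seen.setdefault(self.months[m])
        return tuple(seen)


# ---------------------------------------------------------------------------
# Frame round trip (long CSV format)
# ---------------------------------------------------------------------------

def scats_from_frame(frame: pd.DataFrame) -> list[ScatRecord]:
    """Build records from a long-format frame (scat_id, date, dry_weight_g, taxon, volume_percent)."""
    required = {"scat_id", "date", "dry_weight_g", "taxon", "volume_percent"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"scat frame missing columns {sorted(missing)}")
    records = []
    for sid, grp in frame.groupby("scat_id", sort=True):
        date = grp["date"].iloc[0]
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        elif isinstance(date, pd.Timestamp):
            date = date.date()
        diam = None
        if "diameter_cm" in grp.columns and not pd.isna(grp["diameter_cm"].iloc[0]):
            diam = float(grp["diameter_cm"].iloc[0])
        records.append(
            ScatRecord(
                scat_id=str(sid),
                collection_date=date,
                dry_weight_g=float(grp["dry_weight_g"].iloc[0]),
                items=tuple(
                    (str(t), float(v))
                    for t, v in zip(grp["taxon"], grp["volume_percent"])
                ),
                diameter_cm=diam,
            )
        )
    return records


def scats_to_frame(scats: Sequence[ScatRecord]) -> pd.DataFrame:
    rows = [
        (s.scat_id, s.collection_date, s.dry_weight_g, t, v)
        for s in scats
        for t, v in s.items
    ]
    return pd.DataFrame(
        rows, columns=["scat_id", "date", "dry_weight_g", "taxon", "volume_percent"]
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def exclude_trace(scat: ScatRecord, threshold_percent: float = 2.0) -> ScatRecord:
    """Drop trace items (volume percent ≤ threshold); remaining volumes untouched.

    Threshold 0 is the identity. The returned scat may have an empty item list,
    in which case it contributes nothing to any composition.
    """
    if threshold_percent < 0:
        raise ValueError("threshold_percent must be >= 0")
    kept = tuple((t, v) for t, v in scat.items if v > threshold_percent)
    return replace(scat, items=kept)


def _check_nonempty(scats: Sequence[ScatRecord]) -> None:
    if len(scats) == 0:
        raise ValueError("empty scat list")


def biomass_consumed(
    scats: Sequence[ScatRecord], cf: CorrectionFactorTable
) -> pd.DataFrame:
    """Per-taxon biomass consumed (grams and percent of total).

    Each item's dry remains are ``dry_weight × volume_percent / 100``; the
    correction factor converts them to biomass. Volume not allocated to any
    identified item contributes nothing.
    """
    _check_nonempty(scats)
    mass: dict[str, float] = {}
    for s in scats:
        for taxon, vol in s.items:
            if taxon not in cf:
                raise KeyError(
                    f"taxon {taxon!r} (scat {s.scat_id}) missing from the CF table"
                )
            dry = s.dry_weight_g * vol / 100.0
            mass[taxon] = mass.get(taxon, 0.0) + dry * cf.cf(taxon)
    total = sum(mass.values())
    out = pd.DataFrame(
        {
            "taxon": list(mass),
            "biomass_g": list(mass.values()),
        }
    )
    out["biomass_percent"] = 100.0 * out["biomass_g"] / total if total > 0 else 0.0
    return out.sort_values("taxon", ignore_index=True)


def percent_volume(scats: Sequence[ScatRecord], method: str = "mean") -> pd.Series:
    """Per-taxon volume percent.

    ``method="mean"`` (default) is the arithmetic mean over ALL scats of each
    taxon's per-scat volume percent, zero where absent — the conventional
    reading of a "percent volume" diet column. ``method="aggregate"`` instead
    reports each taxon's share of the total dry mass across scats (items
    weighted by scat dry weight); the two differ when scat weights vary.
    """
    _check_nonempty(scats)
    taxa = sorted({t for s in scats for t in s.taxa})
    if method == "mean":
        acc = {t: 0.0 for t in taxa}
        for s in scats:
            for t, v in s.items:
                acc[t] += v
        n = len(scats)
        return pd.Series({t: acc[t] / n for t in taxa}, name="volume_percent")
    if method == "aggregate":
        dry = {t: 0.0 for t in taxa}
        total = 0.0
        for s in scats:
            total += s.dry_weight_g
            for t, v in s.items:
                dry[t] += s.dry_weight_g * v / 100.0
        return pd.Series(
            {t: 100.0 * dry[t] / total for t in taxa}, name="volume_percent"
        )
    raise ValueError(f"unknown method {method!r}; use 'mean' or 'aggregate'")


def frequency_occurrence(
    scats: Sequence[ScatRecord],
    members: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Percent of scats containing each taxon.

    With ``members`` given (category → member taxa), category occurrence counts
    a scat once if it contains ANY member (set union), so a category's
    occurrence can be less than the sum of its members'.
    """
    _check_nonempty(scats)
    n = len(scats)
    if members is None:
        taxa = sorted({t for s in scats for t in s.taxa})
        counts = {t: sum(1 for s in scats if t in s.taxa) for t in taxa}
    else:
        counts = {
            cat: sum(1 for s in scats if set(s.taxa) & set(mem))
            for cat, mem in members.items()
        }
    return pd.Series({t: 100.0 * c / n for t, c in counts.items()}, name="occurrence_percent")


def composition_table(
    scats: Sequence[ScatRecord],
    cf: CorrectionFactorTable,
    seasons: SeasonDefinition | None = None,
) -> pd.DataFrame:
    """Seasonal + pooled diet composition, at item level and category roll-up.

    Returns a tidy frame with columns ``season, level, taxon, biomass_percent,
    volume_percent, occurrence_percent, n_scats``. ``level`` is ``"item"`` for
    the finest identified taxa and ``"category"`` for roll-ups of the CF
    table's category labels. Biomass percents sum to 100 within each
    (season, level) block.
    """
    _check_nonempty(scats)
    seasons = seasons or SeasonDefinition()
    groups: dict[str, list[ScatRecord]] = {}
    for s in scats:
        groups.setdefault(seasons.season_of(s.collection_date), []).append(s)
    blocks = [(label, groups[label]) for label in seasons.labels if label in groups]
    blocks.append(("total", list(scats)))

    frames = []
    for label, block in blocks:
        nonempty = [s for s in block if s.items]
        if not nonempty:
            continue
        bio = biomass_consumed(nonempty, cf).set_index("taxon")["biomass_percent"]
        vol = percent_volume(nonempty)
        occ = frequency_occurrence(nonempty)
        taxa = sorted(set(bio.index) | set(vol.index) | set(occ.index))
        item = pd.DataFrame(
            {
                "season": label,
                "level": "item",
                "taxon": taxa,
                "biomass_percent": [bio.get(t, 0.0) for t in taxa],
                "volume_percent": [vol.get(t, 0.0) for t in taxa],
                "occurrence_percent": [occ.get(t, 0.0) for t in taxa],
                "n_scats": len(nonempty),
            }
        )
        members: dict[str, list[str]] = {}
        for t in taxa:
            members.setdefault(cf.category(t), []).append(t)
        occ_cat = frequency_occurrence(nonempty, members=members)
        cat = pd.DataFrame(
            {
                "season": label,
                "level": "category",
                "taxon": list(members),
                "biomass_percent": [
                    float(sum(bio.get(t, 0.0) for t in mem)) for mem in members.values()
                ],
                "volume_percent": [
                    float(sum(vol.get(t, 0.0) for t in mem)) for mem in members.values()
                ],
                "occurrence_percent": [occ_cat[c] for c in members],
                "n_scats": len(nonempty),
            }
        )
        frames.append(item)
        frames.append(cat)
    return pd.concat(frames, ignore_index=True)


def seasonal_occurrence_counts(
    scats: Sequence[ScatRecord],
    cf: CorrectionFactorTable,
    seasons: SeasonDefinition | None = None,
) -> pd.DataFrame:
    """Season × category table of scat occurrence counts (for the chi-square test)."""
    _check_nonempty(scats)
    seasons = seasons or SeasonDefinition()
    rows: dict[str, dict[str, int]] = {}
    for s in scats:
        if not s.items:
            continue
        label = seasons.season_of(s.collection_date)
        cats = {cf.category(t) for t in s.taxa}
        row = rows.setdefault(label, {})
        for c in cats:
            row[c] = row.get(c, 0) + 1
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    return table.loc[:, table.sum(axis=0) > 0]


def seasonal_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a seasons × categories count table.

    Returns (chi2, df, upper-tail p). Raises when any expected cell is 0; logs
    a warning when an expected cell is below 5 (the classical validity rule).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 rows and 2 columns")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("expected cell count of 0; drop empty rows/columns first")
    if np.any(expected < 5):
        logger.warning(
            "chi-square: %d expected cells < 5; test may be unreliable",
            int(np.sum(expected < 5)),
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)
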