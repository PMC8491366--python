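"""Synthetic landscapes, movement tracks, territory scenarios, and scat datasets.

Every generator is seeded and fully reproducible, and each carries the ground
truth it was generated from, so the analysis modules can be validated without
any field data:

* :func:`gen_landscape` draws random road/stream polylines and forest patches
  (the distance-covariate layers of a habitat-selection analysis),
* :func:`gen_movement` draws relocations from a habitat-biased availability
  model — a bivariate-normal proposal thinned by an exponential
  resource-selection weight ``exp(x · beta_true)`` — so the fitted selection
  coefficients of :mod:`jackalkit.rsf` have a known recovery target,
* :func:`gen_scats` draws scats whose expected correction-factor-reconstructed
  biomass equals a configured true diet,
* :func:`gen_territories` wraps a group-count density scenario with known truth.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import unary_union

FEATURE_TYPES = ("road", "stream", "dense_forest", "ddf")

__all__ = [
    "FEATURE_TYPES",
    "LandscapeConfig",
    "LandscapeLayers",
    "MovementConfig",
    "DietConfig",
    "DensityScenario",
    "gen_landscape",
    "gen_movement",
    "gen_availability",
    "movement_standardizer",
    "gen_scats",
    "gen_territories",
]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration for a random landscape of linear and patch features.

    The extent is a projected planar bounding box in meters
    ``(xmin, ymin, xmax, ymax)``. Feature counts may be zero, in which case the
    corresponding layer is empty (and any downstream distance covariate that
    references it must be rejected by the covariate builder).
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 20_000.0, 20_000.0)
    n_roads: int = 4
    n_streams: int = 3
    n_forest_patches: int = 6
    n_ddf_patches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {self.extent!r}")
        for name in ("n_roads", "n_streams", "n_forest_patches", "n_ddf_patches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LandscapeLayers:
    """Feature layers keyed by type: road, stream, dense_forest, ddf."""

    layers: dict[str, list]
    extent: tuple[float, float, float, float]
    _merged: dict = field(default_factory=dict, repr=False, compare=False)

    def geometries(self, feature_type: str) -> list:
        if feature_type not in self.layers:
            raise KeyError(f"unknown feature type {feature_type!r}")
        return self.layers[feature_type]

    def merged(self, feature_type: str):
        """Union of all features of one type (cached); None when empty."""
        if feature_type not in self._merged:
            geoms = self.geometries(feature_type)
            self._merged[feature_type] = unary_union(geoms) if geoms else None
        return self._merged[feature_type]

    def is_empty(self, feature_type: str) -> bool:
        return len(self.geometries(feature_type)) == 0

    # -- GeoJSON round trip -------------------------------------------------
    def to_geojson(self) -> str:
        feats = []
        for ftype in FEATURE_TYPES:
            for geom in self.layers.get(ftype, []):
                gj = mapping(shapely.set_precision(geom, 0.001))
                feats.append(
                    {
                        "type": "Feature",
                        "properties": {"feature_type": ftype},
                        "geometry": gj,
                    }
                )
        doc = {
            "type": "FeatureCollection",
            "bbox": list(self.extent),
            "features": feats,
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_geojson(cls, text: str) -> "LandscapeLayers":
        doc = json.loads(text)
        layers: dict[str, list] = {ftype: [] for ftype in FEATURE_TYPES}
        for feat in doc.get("features", []):
            ftype = feat.get("properties", {}).get("feature_type")
            if ftype not in layers:
                raise ValueError(f"feature_type {ftype!r} not one of {FEATURE_TYPES}")
            layers[ftype].append(shape(feat["geometry"]))
        if "bbox" in doc:
            extent = tuple(doc["bbox"])
        else:
            bounds = unary_union([g for gs in layers.values() for g in gs]).bounds
            extent = bounds
        return cls(layers=layers, extent=extent)  # type: ignore[arg-type]


def _random_polyline(rng: np.random.Generator, extent, n_steps: int = 40) -> LineString:
    """Random-walk polyline with direction persistence, clipped to the extent."""
    xmin, ymin, xmax, ymax = extent
    span = min(xmax - xmin, ymax - ymin)
    step = span / 30.0
    x = rng.uniform(xmin, xmax)
    y = rng.uniform(ymin, ymax)
    heading = rng.uniform(0, 2 * math.pi)
    xs, ys = [x], [y]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.35)
        x = float(np.clip(x + step * math.cos(heading), xmin, xmax))
        y = float(np.clip(y + step * math.sin(heading), ymin, ymax))
        xs.append(x)
        ys.append(y)
    return LineString(zip(xs, ys))


def _random_patch(rng: np.random.Generator, extent, rel_radius: tuple[float, float]):
    xmin, ymin, xmax, ymax = extent
    span = min(xmax - xmin, ymax - ymin)
    r = rng.uniform(*rel_radius) * span
    cx = rng.uniform(xmin, xmax)
    cy = rng.uniform(ymin, ymax)
    patch = Point(cx, cy).buffer(r, quad_segs=12)
    return patch.intersection(shapely.box(xmin, ymin, xmax, ymax))


def gen_landscape(config: LandscapeConfig) -> LandscapeLayers:
    """Generate road/stream polylines and dense-forest/DDF patches.

    Identical seeds yield byte-identical :meth:`LandscapeLayers.to_geojson`
    output; all vertices lie inside the extent.
    """
    rng = np.random.default_rng(config.seed)
    layers: dict[str, list] = {
        "road": [_random_polyline(rng, config.extent) for _ in range(config.n_roads)],
        "stream": [_random_polyline(rng, config.extent) for _ in range(config.n_streams)],
        "dense_forest": [
            _random_patch(rng, config.extent, (0.02, 0.06))
            for _ in range(config.n_forest_patches)
        ],
        "ddf": [
            _random_patch(rng, config.extent, (0.08, 0.18))
            for _ in range(config.n_ddf_patches)
        ],
    }
    return LandscapeLayers(layers=layers, extent=config.extent)


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementConfig:
    """Habitat-biased movement model for one animal.

    Relocations are independent draws: a bivariate-normal availability proposal
    (``center``, isotropic ``sigma`` meters) is thinned by the selection weight
    ``exp(x . beta_true)``, where ``x`` holds log-distance covariates
    standardized against the proposal distribution itself. ``beta_true`` maps
    feature-type names (e.g. ``"road"``) to coefficients on the standardized
    scale; negative values mean selection for (short distances to) the feature.
    """

    center: tuple[float, float]
    sigma: float = 3_500.0
    beta_true: Mapping[str, float] = field(default_factory=dict)
    n_fixes: int = 737
    fix_interval_h: float = 6.0
    animal_id: str = "A1"
    source: str = "gps"
    start: _dt.datetime = _dt.datetime(2015, 3, 13, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_fixes < 1:
            raise ValueError("n_fixes must be >= 1")


def _raw_distances(xy: np.ndarray, layers: LandscapeLayers, names: Sequence[str]) -> np.ndarray:
    """Distance in meters from each point to the nearest feature of each type."""
    pts = shapely.points(xy[:, 0], xy[:, 1])
    cols = []
    for name in names:
        merged = layers.merged(name)
        if merged is None:
            raise ValueError(f"layer {name!r} is empty; cannot compute distances")
        cols.append(shapely.distance(pts, merged))
    return np.column_stack(cols) if cols else np.empty((len(xy), 0))


def movement_standardizer(
    layers: LandscapeLayers, config: MovementConfig, n_ref: int = 4096
) -> dict[str, tuple[float, float]]:
    """Mean/SD of log(distance + 1) covariates under the availability proposal.

    Deterministic given the config seed; shared by :func:`gen_movement` and
    :func:`gen_availability` so that ``beta_true`` refers to a fixed scale.
    """
    names = list(config.beta_true)
    ss = np.random.SeedSequence([config.seed, 0x5D])
    rng = np.random.default_rng(ss)
    xy = rng.normal(loc=config.center, scale=config.sigma, size=(n_ref, 2))
    d = _raw_distances(xy, layers, names)
    v = np.log1p(d)
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate covariate (zero spread) under the proposal")
    return {n: (float(m), float(s)) for n, m, s in zip(names, mean, sd)}


def _standardized_covariates(
    xy: np.ndarray, layers: LandscapeLayers, std: Mapping[str, tuple[float, float]]
) -> np.ndarray:
    names = list(std)
    d = _raw_distances(xy, layers, names)
    v = np.log1p(d)
    m = np.array([std[n][0] for n in names])
    s = np.array([std[n][1] for n in names])
    return (v - m) / s


def gen_movement(
    layers: LandscapeLayers, config: MovementConfig, min_acceptance: float = 1e-4
) -> pd.DataFrame:
    """Simulate relocations by rejection sampling from the habitat-biased model.

    Returns a frame with columns ``animal_id, timestamp, x, y, source``;
    timestamps are spaced ``fix_interval_h`` hours apart starting at
    ``config.start``. Raises if the overall acceptance rate drops below
    ``min_acceptance`` (beta_true too extreme for the landscape).
    """
    names = list(config.beta_true)
    beta = np.array([config.beta_true[n] for n in names])
    std = movement_standardizer(layers, config) if names else {}

    ss = np.random.SeedSequence([config.seed, 0x4D])
    rng = np.random.default_rng(ss)

    if names:
        # acceptance-ratio cap from a reference availability sample (+ margin)
        ref = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5D]))
        xy_ref = ref.normal(loc=config.center, scale=config.sigma, size=(4096, 2))
        cap = float(np.max(_standardized_covariates(xy_ref, layers, std) @ beta)) + 1.0
    else:
        cap = 0.0

    accepted: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    batch = max(4 * config.n_fixes, 2000)
    while n_acc < config.n_fixes:
        xy = rng.normal(loc=config.center, scale=config.sigma, size=(batch, 2))
        if names:
            score = _standardized_covariates(xy, layers, std) @ beta
            keep = rng.random(batch) < np.exp(score - cap)
        else:
            keep = np.ones(batch, dtype=bool)
        n_prop += batch
        xy = xy[keep]
        n_acc += len(xy)
        accepted.append(xy)
        if n_prop >= 50_000 and n_acc / n_prop < min_acceptance:
            raise RuntimeError(
                f"acceptance rate {n_acc / n_prop:.2e} below {min_acceptance:.0e}; "
                "beta_true too extreme for this landscape"
            )
    xy = np.concatenate(accepted)[: config.n_fixes]
    times = [
        config.start + _dt.timedelta(hours=config.fix_interval_h * i)
        for i in range(config.n_fixes)
    ]
    return pd.DataFrame(
        {
            "animal_id": config.animal_id,
            "timestamp": times,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "source": config.source,
        }
    )


def gen_availability(
    layers: LandscapeLayers, config: MovementConfig, n: int, draw: int = 0
) -> pd.DataFrame:
    """Draw availability points from the movement model's bivariate-normal proposal.

    This is the availability distribution the generative model actually uses,
    so a used--available logistic fit contrasting :func:`gen_movement` output
    against these points consistently recovers ``beta_true``. ``draw`` selects
    an independent seeded stream.
    """
    ss = np.random.SeedSequence([config.seed, 0xA7, draw])
    rng = np.random.default_rng(ss)
    xy = rng.normal(loc=config.center, scale=config.sigma, size=(n, 2))
    return pd.DataFrame({"animal_id": config.animal_id, "x": xy[:, 0], "y": xy[:, 1]})


# ---------------------------------------------------------------------------
# Scats
# ---------------------------------------------------------------------------

#: Default per-scat item-count distribution over 1..5 items, matching the
#: observed mix in dry-forest jackal scats (14.4 / 38.4 / 27.4 / 17.1 / 2.7 %).
DEFAULT_ITEMS_PER_SCAT = (0.144, 0.384, 0.274, 0.171, 0.027)

#: Study-like true diet (biomass proportions) and correction factors.
STUDY_DIET_TRUTH: dict[str, float] = {
    "termite": 0.256,
    "wild_pig": 0.204,
    "muntjac": 0.202,
    "civet": 0.172,
    "small_rodent": 0.060,
    "hare": 0.046,
    "bird": 0.033,
    "reptile": 0.014,
    "crab": 0.013,
}

STUDY_DIET_CF: dict[str, float] = {
    "termite": 12.0,
    "wild_pig": 84.0,
    "muntjac": 118.0,
    "civet": 50.0,
    "small_rodent": 23.0,
    "hare": 50.0,
    "bird": 35.0,
    "reptile": 18.0,
    "crab": 5.0,
}


@dataclass(frozen=True)
class DietConfig:
    """Ground-truth diet for the scat generator.

    ``proportions`` are true biomass shares (sum to 1); ``cf`` are correction
    factors in grams of biomass consumed per gram of dry scat remains. Per
    scat, the number of items follows ``items_per_scat`` (probabilities over
    1..5 items) and dry weight is lognormal in grams.
    """

    proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_DIET_TRUTH)
    )
    cf: Mapping[str, float] = field(default_factory=lambda: dict(STUDY_DIET_CF))
    items_per_scat: Sequence[float] = DEFAULT_ITEMS_PER_SCAT
    dry_weight_log_mean: float = math.log(10.0)
    dry_weight_log_sd: float = 0.5
    n_scats: int = 147
    start_date: _dt.date = _dt.date(2013, 11, 1)
    end_date: _dt.date = _dt.date(2014, 5, 31)
    seed: int = 0
    volume_concentration: float = 6.0

    def __post_init__(self) -> None:
        p = np.array(list(self.proportions.values()), dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {p.sum()!r}, expected 1 +- 1e-9")
        if np.any(p < 0):
            raise ValueError("proportions must be >= 0")
        for taxon, c in self.cf.items():
            if c <= 0:
                raise ValueError(f"CF for {taxon!r} must be > 0")
        missing = set(self.proportions) - set(self.cf)
        if missing:
            raise ValueError(f"no CF for taxa: {sorted(missing)}")
        k = np.array(self.items_per_scat, dtype=float)
        if abs(k.sum() - 1.0) > 1e-6 or np.any(k < 0):
            raise ValueError("items_per_scat must be a probability vector over 1..k")
        if len(k) > len([q for q in p if q > 0]):
            raise ValueError("more items per scat than taxa with positive share")


def _expected_volume_share(
    w_sample: np.ndarray,
    w_volume: np.ndarray,
    kprobs: np.ndarray,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Monte-Carlo E[per-taxon volume share] under the two-weight scat model."""
    m = len(w_sample)
    ks = rng.choice(np.arange(1, len(kprobs) + 1), size=n, p=kprobs)
    keys = np.log(w_sample)[None, :] + rng.gumbel(size=(n, m))
    order = np.argsort(-keys, axis=1)
    ev = np.zeros(m)
    for k in range(1, len(kprobs) + 1):
        idx = order[ks == k, :k]
        if idx.size == 0:
            continue
        wv = w_volume[idx]
        shares = wv / wv.sum(axis=1, keepdims=True)
        ev += np.bincount(idx.ravel(), weights=shares.ravel(), minlength=m)
    return ev / ev.sum()


def _calibrated_weights(config: DietConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Sampling and volume weights whose expected reconstructed biomass is the truth.

    Item sets are weighted draws without replacement, and within-scat volume
    shares are Dirichlet with mean proportional to the volume weights. Raw
    inverse-CF weights are biased under without-replacement set sampling
    (inclusion probabilities saturate for dominant taxa), so both weight
    vectors are adjusted by a seeded Monte-Carlo fixed point until the expected
    volume share of each taxon matches ``truth / CF``. Residual bias is about
    0.1 biomass points for study-like configurations.
    """
    taxa = [t for t, p in config.proportions.items() if p > 0]
    truth = np.array([config.proportions[t] for t in taxa])
    cfs = np.array([config.cf[t] for t in taxa])
    target = truth / cfs
    target = target / target.sum()
    kprobs = np.asarray(config.items_per_scat, dtype=float)
    kprobs = kprobs / kprobs.sum()

    if len(taxa) == 1:
        return np.array([1.0]), np.array([1.0]), taxa

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA11]))
    ws = target.copy()
    wv = target.copy()
    for _ in range(8):
        ev = _expected_volume_share(ws, wv, kprobs, rng, n=30_000)
        ratio = target / np.maximum(ev, 1e-12)
        ws = ws * ratio**0.7
        wv = wv * ratio**0.3
        ws /= ws.sum()
        wv /= wv.sum()
    return ws, wv, taxa


def gen_scats(config: DietConfig) -> pd.DataFrame:
    """Generate scats in long format: scat_id, date, dry_weight_g, taxon, volume_percent.

    The pipeline property this construction guarantees: applying
    correction-factor biomass reconstruction (:func:`jackalkit.diet.biomass_consumed`,
    without trace exclusion) to many generated scats recovers
    ``config.proportions`` — checked to within ±2 biomass points at
    ``n_scats = 10,000`` in the test suite.
    """
    ws, wv, taxa = _calibrated_weights(config)
    m = len(taxa)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5CA7]))
    n = config.n_scats
    kprobs = np.asarray(config.items_per_scat, dtype=float)
    kprobs = kprobs / kprobs.sum()
    kmax = len(kprobs)
    ks = rng.choice(np.arange(1, kmax + 1), size=n, p=kprobs) if m > 1 else np.ones(n, int)
    ks = np.minimum(ks, m)

    keys = np.log(ws)[None, :] + rng.gumbel(size=(n, m))
    order = np.argsort(-keys, axis=1)

    dry = np.exp(rng.normal(config.dry_weight_log_mean, config.dry_weight_log_sd, size=n))
    span_days = (config.end_date - config.start_date).days
    day_offsets = rng.integers(0, span_days + 1, size=n)

    rows: list[tuple] = []
    width = len(str(n))
    for i in range(n):
        k = int(ks[i])
        idx = order[i, :k]
        w_set = wv[idx]
        alpha = config.volume_concentration * w_set / w_set.sum()
        v = rng.gamma(np.maximum(alpha, 1e-12))
        v = np.maximum(v, 1e-300)
        v = np.minimum(100.0 * v / v.sum(), 100.0)  # guard FP overshoot
        sid = f"S{i + 1:0{width}d}"
        date = config.start_date + _dt.timedelta(days=int(day_offsets[i]))
        for j, t_idx in enumerate(idx):
            rows.append((sid, date, float(dry[i]), taxa[t_idx], float(v[j])))
    return pd.DataFrame(
        rows, columns=["scat_id", "date", "dry_weight_g", "taxon", "volume_percent"]
    )


# ---------------------------------------------------------------------------
# Territories / density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityScenario:
    """Ground-truth group-count density scenario."""

    n_groups: float
    group_size: float
    area_km2: float

    @property
    def true_density(self) -> float:
        return self.n_groups * self.group_size / self.area_km2

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_groups": self.n_groups,
                "group_size": self.group_size,
                "area_km2": self.area_km2,
                "true_density_per_km2": self.true_density,
            },
            sort_keys=True,
        )


def gen_territories(n_groups: float, group_size: float, area_km2: float) -> DensityScenario:
    """Scenario whose true density is ``n_groups × group_size / area_km2``."""
    if n_groups <= 0 or group_size <= 0:
        raise ValueError("n_groups and group_size must be > 0")
    if area_km2 <= 0:
        raise ValueError("area_km2 must be > 0")
    return DensityScenario(n_groups, group_size, area_km2)
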