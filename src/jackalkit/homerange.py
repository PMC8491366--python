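"""Home-range estimation: kernel utilization distributions, MCPs, overlap, density.

The kernel workflow follows the field protocol for territorial canids: a
bivariate Gaussian kernel on a regular grid, bandwidth set to 0.8 × the
reference bandwidth (Worton's rule for a bivariate normal) unless the ad hoc
bandwidth — the smallest fraction of h_ref that still yields a single
contiguous 95% isopleth without interior holes — is larger, in which case the
larger of the two is used. Home ranges are the 95% isopleth, core areas the
50% isopleth. Overlap between two utilization distributions is quantified with
the UDOI (the overlap area times the integral of the UD product), and between
polygons with directed percent area overlap. Density is groups × mean adults
per group / area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPolygon, Polygon
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "UtilizationDistribution",
    "BandwidthSpec",
    "IsoplethPolygon",
    "KernelHomeRange",
    "href",
    "adhoc_bandwidth",
    "kde_ud",
    "isopleth",
    "mcp",
    "udoi",
    "percent_area_overlap",
    "monthly_ranges",
    "summarize_ranges",
    "density_estimate",
    "exclude_forays",
    "grid_from_points",
]


# ---------------------------------------------------------------------------
# Grids and UDs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular raster: origin at the lower-left corner, square cells of ``cell`` meters."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.nx < 1 or self.ny < 1:
            raise ValueError("cell size and cell counts must be positive")

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.cell * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.cell * (np.arange(self.ny) + 0.5)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.cell * self.nx,
            self.y0 + self.cell * self.ny,
        )

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell


def grid_from_points(
    points: np.ndarray, h: float, n_cells: int = 256, margin_factor: float = 3.0
) -> GridSpec:
    """Square-cell grid over the data bounding box expanded by ``margin_factor × h``."""
    pts = np.asarray(points, dtype=float)
    xmin, ymin = pts.min(axis=0) - margin_factor * h
    xmax, ymax = pts.max(axis=0) + margin_factor * h
    cell = max(xmax - xmin, ymax - ymin) / n_cells
    nx = int(np.ceil((xmax - xmin) / cell))
    ny = int(np.ceil((ymax - ymin) / cell))
    return GridSpec(float(xmin), float(ymin), cell, nx, ny)


@dataclass
class UtilizationDistribution:
    """Gridded probability surface; cell masses are nonnegative and sum to 1."""

    grid: GridSpec
    masses: np.ndarray  # shape (ny, nx)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"masses shape {self.masses.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if np.any(self.masses < 0):
            raise ValueError("cell masses must be nonnegative")
        total = float(self.masses.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell masses sum to {total!r}, expected 1 +- 1e-6")


@dataclass(frozen=True)
class BandwidthSpec:
    """Bandwidths in meters; the rule is h_used = max(factor × h_ref, h_adhoc)."""

    h_ref: float
    h_adhoc: float
    factor: float = 0.8

    def __post_init__(self) -> None:
        if self.h_ref <= 0 or self.h_adhoc <= 0 or self.factor <= 0:
            raise ValueError("bandwidths and factor must be > 0")

    @property
    def h_used(self) -> float:
        return max(self.factor * self.h_ref, self.h_adhoc)


@dataclass
class IsoplethPolygon:
    """Smallest highest-density cell set whose mass reaches ``level``, as polygons."""

    level: float
    grid: GridSpec
    cell_mask: np.ndarray  # (ny, nx) bool
    _polygon: MultiPolygon | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.grid.cell_area / 1e6

    @property
    def polygon(self) -> MultiPolygon:
        """Union of the selected cells' squares (computed lazily)."""
        if self._polygon is None:
            g = self.grid
            iy, ix = np.nonzero(self.cell_mask)
            boxes = shapely.box(
                g.x0 + ix * g.cell,
                g.y0 + iy * g.cell,
                g.x0 + (ix + 1) * g.cell,
                g.y0 + (iy + 1) * g.cell,
            )
            merged = shapely.coverage_union_all(boxes)
            if isinstance(merged, Polygon):
                merged = MultiPolygon([merged])
            self._polygon = merged
        return self._polygon


# ---------------------------------------------------------------------------
# Bandwidths
# ---------------------------------------------------------------------------

def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def href(points) -> float:
    """Reference bandwidth h_ref = σ̂ · n^(−1/6), σ̂ = sqrt((s_x² + s_y²) / 2).

    The plug-in rule for a bivariate Gaussian kernel on bivariate-normal data;
    scale-equivariant in the coordinates.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 5:
        raise ValueError(f"need >= 5 points for a bandwidth, got {n}")
    var = pts.var(axis=0, ddof=1)
    sigma = float(np.sqrt(var.sum() / 2.0))
    if sigma == 0:
        raise ValueError("all points identical; bandwidth undefined")
    return sigma * n ** (-1.0 / 6.0)


def _is_single_contiguous_no_holes(mask: np.ndarray) -> bool:
    """One 8-connected component and no interior holes (4-connected background)."""
    if not mask.any():
        return False
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        return False
    # holes: background components not touching the array border
    bg, n_bg = ndimage.label(~mask)
    border = set(bg[0, :]) | set(bg[-1, :]) | set(bg[:, 0]) | set(bg[:, -1])
    border.discard(0)
    return n_bg == len(border)


def adhoc_bandwidth(
    points,
    level: float = 0.95,
    step: float = 0.05,
    floor: float = 0.05,
    n_cells: int = 128,
) -> float:
    """Smallest multiple of h_ref keeping the ``level`` isopleth one unbroken polygon.

    Scans multipliers 1.00, 0.95, …, ``floor`` of h_ref and returns the
    smallest m·h_ref whose isopleth cell set is a single 8-connected component
    without interior holes; the grid is rebuilt for each candidate bandwidth.
    If even m = 1 fragments the isopleth, returns h_ref with a warning.
    """
    pts = _as_points(points)
    h0 = href(pts)
    multipliers = np.arange(1.0, floor - 1e-9, -step)
    best = None
    for m in multipliers:
        h = m * h0
        grid = grid_from_points(pts, h, n_cells=n_cells)
        ud = kde_ud(pts, h, grid)
        iso = isopleth(ud, level)
        if _is_single_contiguous_no_holes(iso.cell_mask):
            best = h
        else:
            break
    if best is None:
        warnings.warn(
            "isopleth fragmented even at the reference bandwidth; returning h_ref",
            stacklevel=2,
        )
        return h0
    return float(best)


# ---------------------------------------------------------------------------
# KDE, isopleths, MCP
# ---------------------------------------------------------------------------

def kde_ud(points, h: float, grid: GridSpec) -> UtilizationDistribution:
    """Bivariate Gaussian kernel density on the grid, normalized to total mass 1.

    The grid must cover the points with at least a 3h margin so that no
    appreciable kernel mass is clipped.
    """
    pts = _as_points(points)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    gx0, gy0, gx1, gy1 = grid.bounds
    pad = 3.0 * h - grid.cell  # allow the margin to fall inside the outermost cell
    if gx0 > xmin - pad or gy0 > ymin - pad or gx1 < xmax + pad or gy1 < ymax + pad:
        raise ValueError("grid does not cover the points with a 3h margin")

    xc = grid.x_centers
    yc = grid.y_centers
    inv2h2 = 1.0 / (2.0 * h * h)
    dens = np.zeros((grid.ny, grid.nx))
    # chunk over points to bound memory at ~ n_chunk × nx × ny
    chunk = max(1, int(2e7 / (grid.nx * grid.ny)))
    for i in range(0, len(pts), chunk):
        block = pts[i : i + chunk]
        dx2 = np.square(xc[None, :] - block[:, 0, None])  # (m, nx)
        dy2 = np.square(yc[None, :] - block[:, 1, None])  # (m, ny)
        ex = np.exp(-dx2 * inv2h2)
        ey = np.exp(-dy2 * inv2h2)
        dens += np.einsum("my,mx->yx", ey, ex)
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel density vanished on the grid")
    return UtilizationDistribution(grid=grid, masses=dens / total)


def isopleth(ud: UtilizationDistribution, level: float) -> IsoplethPolygon:
    """Highest-density cell set with cumulative mass ≥ level.

    Cells are ranked by (mass descending, flat index ascending) and accumulated
    until the level is first reached; ties beyond the crossing are excluded, so
    a uniform UD over 100 cells at level 0.95 yields exactly 95 cells.
    """
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    flat = ud.masses.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    # number of cells needed to first reach the level (tolerate FP rounding)
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    k = min(k, flat.size)
    # never include zero-mass cells
    chosen = order[:k]
    chosen = chosen[flat[chosen] > 0]
    mask = np.zeros(flat.size, dtype=bool)
    mask[chosen] = True
    return IsoplethPolygon(
        level=level, grid=ud.grid, cell_mask=mask.reshape(ud.masses.shape)
    )


def mcp(points, percent: float = 0.95) -> tuple[Polygon, float]:
    """Minimum convex polygon after peeling the farthest points from the centroid.

    Removes ``floor((1 − percent) · n)`` points farthest (Euclidean) from the
    arithmetic mean of all points, then returns the convex hull of the
    remainder and its area in km².
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 5:
        raise ValueError(f"need >= 5 points, got {n}")
    if not (0 < percent <= 1):
        raise ValueError("percent must be in (0, 1]")
    center = pts.mean(axis=0)
    n_drop = int(np.floor((1.0 - percent) * n))
    if n_drop > 0:
        d = np.linalg.norm(pts - center, axis=1)
        keep = np.argsort(d, kind="stable")[: n - n_drop]
        pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("fewer than 3 points survive the removal")
    hull = ConvexHull(pts)
    poly = Polygon(pts[hull.vertices])
    return poly, float(poly.area / 1e6)


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def _level_mask_with_ties(ud: UtilizationDistribution, level: float) -> np.ndarray:
    """Isopleth cell set including all cells tied at the crossing mass.

    The tie-inclusive form makes the UDOI of two identical uniform UDs exactly
    1 (the whole support is the overlap region); for continuous UDs ties have
    measure zero and this coincides with :func:`isopleth`.
    """
    base = isopleth(ud, level).cell_mask
    if not base.any():
        return base
    threshold = ud.masses[base].min()
    return ud.masses >= threshold


def udoi(
    ud_a: UtilizationDistribution, ud_b: UtilizationDistribution, level: float = 0.95
) -> float:
    """Utilization distribution overlap index (discrete form).

    UDOI = A_overlap × Σ_cells UD_a(c) · UD_b(c) / cell_area, where A_overlap
    is the area of intersection of the two level-isopleth cell sets. 0 means
    no overlap, 1 matches two identical uniform distributions, and values > 1
    indicate concentrated shared use.
    """
    if ud_a.grid != ud_b.grid:
        raise ValueError("both UDs must live on the identical grid")
    inter = _level_mask_with_ties(ud_a, level) & _level_mask_with_ties(ud_b, level)
    a_overlap = inter.sum() * ud_a.grid.cell_area
    product = float(np.sum(ud_a.masses * ud_b.masses)) / ud_a.grid.cell_area
    return float(a_overlap * product)


def percent_area_overlap(poly_a, poly_b) -> tuple[float, float, float]:
    """Directed percent overlaps (A∩B as % of A, % of B) and their mean."""
    if poly_a.area <= 0 or poly_b.area <= 0:
        raise ValueError("polygons must have positive area")
    inter = poly_a.intersection(poly_b).area
    a_on_b = 100.0 * inter / poly_a.area
    b_on_a = 100.0 * inter / poly_b.area
    return a_on_b, b_on_a, (a_on_b + b_on_a) / 2.0


# ---------------------------------------------------------------------------
# Relocation-level operations
# ---------------------------------------------------------------------------

def exclude_forays(
    relocations: pd.DataFrame,
    exclusion_list: Sequence[tuple[str, object, object]] | None = None,
    auto_threshold_km: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove listed extraterritorial forays; optionally flag candidates for review.

    ``exclusion_list`` holds (animal_id, start, end) windows that are dropped
    outright (the manual protocol: a known foray is excised from home-range
    analysis). With ``auto_threshold_km`` set, fixes farther than the threshold
    from the animal's median location are *flagged* in the returned second
    frame — never silently removed.
    """
    out = relocations.copy()
    ts = pd.to_datetime(out["timestamp"])
    if exclusion_list:
        drop = pd.Series(False, index=out.index)
        for animal_id, start, end in exclusion_list:
            drop |= (
                (out["animal_id"] == animal_id)
                & (ts >= pd.Timestamp(start))
                & (ts <= pd.Timestamp(end))
            )
        out = out[~drop]
    flagged = out.iloc[0:0]
    if auto_threshold_km is not None:
        masks = []
        for _, grp in out.groupby("animal_id"):
            med = grp[["x", "y"]].median()
            dist_km = np.hypot(grp["x"] - med["x"], grp["y"] - med["y"]) / 1000.0
            masks.append(grp[dist_km >= auto_threshold_km])
        flagged = pd.concat(masks) if masks else flagged
    return out, flagged


def monthly_ranges(
    relocations: pd.DataFrame,
    min_locations: int = 28,
    min_span_days: int = 14,
    factor: float = 0.8,
    n_cells: int = 128,
) -> pd.DataFrame:
    """Per-month 95% kernel home-range areas for each animal.

    A month qualifies only with at least ``min_locations`` fixes spanning at
    least ``min_span_days`` days within the month; each qualifying month gets
    its own bandwidth (max of factor × h_ref and the ad hoc bandwidth) and UD.
    """
    relocs = relocations.copy()
    ts = pd.to_datetime(relocs["timestamp"])
    relocs["_ym"] = ts.dt.to_period("M")
    relocs["_date"] = ts.dt.date
    rows = []
    for (animal, period), grp in relocs.groupby(["animal_id", "_ym"]):
        span = (max(grp["_date"]) - min(grp["_date"])).days
        if len(grp) < min_locations or span < min_span_days:
            continue
        pts = grp[["x", "y"]].to_numpy()
        spec = BandwidthSpec(
            h_ref=href(pts), h_adhoc=adhoc_bandwidth(pts, n_cells=n_cells), factor=factor
        )
        grid = grid_from_points(pts, spec.h_used, n_cells=n_cells)
        ud = kde_ud(pts, spec.h_used, grid)
        area = isopleth(ud, 0.95).area_km2
        rows.append((animal, str(period), len(grp), span, spec.h_used, area))
    out = pd.DataFrame(
        rows,
        columns=["animal_id", "month", "n_locations", "span_days", "h_used_m", "kde95_km2"],
    )
    if out.empty:
        warnings.warn("no month passed the location-count and span filters", stacklevel=2)
    return out


def summarize_ranges(areas: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD with n − 1, over √n) of home-range areas."""
    a = np.asarray(areas, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 areas for a standard error")
    return float(a.mean()), float(a.std(ddof=1) / np.sqrt(len(a)))


def density_estimate(n_groups: float, mean_group_size: float, area_km2: float) -> float:
    """Group-count density: groups × mean adults per group / total area (animals/km²)."""
    if area_km2 <= 0:
        raise ValueError("area_km2 must be > 0")
    if n_groups <= 0 or mean_group_size <= 0:
        raise ValueError("n_groups and mean_group_size must be > 0")
    return n_groups * mean_group_size / area_km2


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class KernelHomeRange(BaseEstimator):
    """Kernel + MCP home-range estimator for one animal's relocations.

    Parameters
    ----------
    factor : multiplier applied to the reference bandwidth (default 0.8).
    levels : isopleth levels to extract (default home range 0.95, core 0.5).
    n_cells : grid resolution along the longer side of the bounding box.
    use_adhoc : whether to floor the bandwidth at the ad hoc estimate.

    After ``fit(X)`` (X an (n, 2) array of projected coordinates in meters):

    ``bandwidth_`` — the :class:`BandwidthSpec` actually used;
    ``ud_`` — the fitted :class:`UtilizationDistribution`;
    ``isopleths_`` — dict level → :class:`IsoplethPolygon`;
    ``kde_areas_km2_`` — dict level → area;
    ``mcp_polygons_`` / ``mcp_areas_km2_`` — dict percent → polygon / area.
    """

    def __init__(
        self,
        factor: float = 0.8,
        levels: tuple[float, ...] = (0.95, 0.5),
        mcp_percents: tuple[float, ...] = (0.95, 0.5),
        n_cells: int = 256,
        use_adhoc: bool = True,
    ):
        self.factor = factor
        self.levels = levels
        self.mcp_percents = mcp_percents
        self.n_cells = n_cells
        self.use_adhoc = use_adhoc

    def fit(self, X, y=None):
        pts = _as_points(X)
        h_ref = href(pts)
        h_adhoc = adhoc_bandwidth(pts) if self.use_adhoc else h_ref * self.factor
        self.bandwidth_ = BandwidthSpec(h_ref=h_ref, h_adhoc=h_adhoc, factor=self.factor)
        h = self.bandwidth_.h_used
        grid = grid_from_points(pts, h, n_cells=self.n_cells)
        self.ud_ = kde_ud(pts, h, grid)
        self.isopleths_ = {lvl: isopleth(self.ud_, lvl) for lvl in self.levels}
        self.kde_areas_km2_ = {lvl: iso.area_km2 for lvl, iso in self.isopleths_.items()}
        self.mcp_polygons_ = {}
        self.mcp_areas_km2_ = {}
        for pct in self.mcp_percents:
            poly, area = mcp(pts, pct)
            self.mcp_polygons_[pct] = poly
            self.mcp_areas_km2_[pct] = area
        self.n_locations_ = len(pts)
        return self
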