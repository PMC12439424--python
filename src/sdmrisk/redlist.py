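"""Range geometry (EOO, AOO) and the IUCN Red List rule engine.

Implements the geographic-range criterion B (with the B1/B2 sub-criteria
and conditions a-c), the small-population criterion C2a(i), and the
projected-reduction criterion A3(c) under full and limited dispersal.
Geometry is planar in an equal-area km frame: EOO is the convex-hull area
of the occurrence points; AOO counts occupied cells of a 2 x 2 km grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .grid import RasterGrid, require_aligned

CATEGORY_ORDER = ("LC", "NT", "VU", "EN", "CR")

# criterion B thresholds (km^2) and the location counts of condition (a)
B1_EOO = {"CR": 100.0, "EN": 5000.0, "VU": 20000.0}
B2_AOO = {"CR": 10.0, "EN": 500.0, "VU": 2000.0}
B_LOCATIONS = {"CR": 1, "EN": 5, "VU": 10}
# criterion C2a(i): total mature individuals and largest-subpopulation caps
C2_TOTAL = {"CR": 250, "EN": 2500, "VU": 10000}
C2_SUBPOP = {"CR": 50, "EN": 250, "VU": 1000}


def category_rank(cat: str) -> int:
    return CATEGORY_ORDER.index(cat)


def most_threatened(categories: list[str]) -> str:
    return max(categories, key=category_rank) if categories else "LC"


@dataclass(frozen=True)
class ConditionFlags:
    """Criterion B conditions: fragmentation, decline, fluctuation.

    ``continuing_decline`` lists the observed decline sub-criteria
    (i extent, ii area of occupancy, iii habitat, iv locations,
    v mature individuals).
    """

    severely_fragmented: bool = False
    continuing_decline: tuple[str, ...] = ()
    extreme_fluctuation: bool = False

    def __post_init__(self) -> None:
        bad = set(self.continuing_decline) - {"i", "ii", "iii", "iv", "v"}
        if bad:
            raise ValueError(f"unknown decline sub-criteria: {sorted(bad)}")


@dataclass(frozen=True)
class RangeMetrics:
    eoo_km2: float
    aoo_km2: float
    n_locations: int
    occupied_cells: int


@dataclass
class Assessment:
    """Final category with the per-criterion basis behind it."""

    category: str
    criteria_string: str
    basis: dict[str, str] = field(default_factory=dict)


def eoo(points: np.ndarray) -> float:
    """Extent of occurrence: minimum-convex-polygon area, km^2.

    Fewer than three non-collinear points give 0. The IUCN floor of EOO to
    AOO is applied in :func:`assess`, not here.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    if len(pts) < 3:
        return 0.0
    return float(MultiPoint(pts.tolist()).convex_hull.area)


def occupied_cells(points: np.ndarray, cell_km: float = 2.0,
                   origin: tuple[float, float] = (0.0, 0.0)) -> int:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point")
    cols = np.floor((pts[:, 0] - origin[0]) / cell_km).astype(int)
    rows = np.floor((pts[:, 1] - origin[1]) / cell_km).astype(int)
    return len(set(zip(rows.tolist(), cols.tolist())))


def aoo(points: np.ndarray, cell_km: float = 2.0,
        origin: tuple[float, float] = (0.0, 0.0)) -> float:
    """Area of occupancy: cell_km^2 per distinct occupied grid cell.

    The IUCN convention is a 2 x 2 km grid, so one occupied cell counts
    4 km^2.
    """
    return cell_km**2 * occupied_cells(points, cell_km, origin)


def aoo_origin_sensitivity(points: np.ndarray, cell_km: float = 2.0,
                           n_offsets: int = 4) -> tuple[float, float]:
    """(min, max) AOO over sub-cell shifts of the counting grid.

    AOO depends on where the 2-km grid is anchored; this scans
    ``n_offsets x n_offsets`` fractional origins.
    """
    offs = np.arange(n_offsets) / n_offsets * cell_km
    vals = [aoo(points, cell_km, (ox, oy)) for ox in offs for oy in offs]
    return float(min(vals)), float(max(vals))


def _b_conditions_met(category: str, n_locations: int,
                      flags: ConditionFlags) -> int:
    a = flags.severely_fragmented or n_locations <= B_LOCATIONS[category]
    b = len(flags.continuing_decline) > 0
    c = flags.extreme_fluctuation
    return int(a) + int(b) + int(c)


def criterion_b(eoo_km2: float, aoo_km2: float, n_locations: int,
                flags: ConditionFlags) -> tuple[str, str]:
    """Criterion B category and criteria string, e.g. ``EN B1ab(i,iv,v)+2ab(i,iv,v)``.

    B1 applies EOO thresholds, B2 AOO thresholds; a category needs its
    size threshold plus at least two of conditions (a) few/fragmented
    locations, (b) continuing decline, (c) extreme fluctuation. The
    overall category is the most threatened of B1 and B2.
    """
    if min(eoo_km2, aoo_km2) < 0 or n_locations < 0:
        raise ValueError("inputs must be non-negative")

    def best(thresholds: dict[str, float], value: float) -> str | None:
        for cat in ("CR", "EN", "VU"):  # most to least severe
            if value < thresholds[cat] and _b_conditions_met(cat, n_locations, flags) >= 2:
                return cat
        return None

    b1 = best(B1_EOO, eoo_km2)
    b2 = best(B2_AOO, aoo_km2)
    if b1 is None and b2 is None:
        return "LC", ""
    category = most_threatened([c for c in (b1, b2) if c])

    def letters(cat: str) -> str:
        s = ""
        if flags.severely_fragmented or n_locations <= B_LOCATIONS[cat]:
            s += "a"
        if flags.continuing_decline:
            s += "b(" + ",".join(flags.continuing_decline) + ")"
        if flags.extreme_fluctuation:
            s += "c"
        return s

    parts = []
    if b1 == category:
        parts.append("B1" + letters(category))
    if b2 == category:
        parts.append(("B2" if not parts else "2") + letters(category))
    return category, "+".join(parts)


def criterion_c(n_mature: int, largest_subpop_mature: int,
                continuing_decline: bool) -> tuple[str, str]:
    """Criterion C2a(i): small declining population in small subpopulations."""
    if n_mature < 0 or largest_subpop_mature < 0:
        raise ValueError("counts must be non-negative")
    if largest_subpop_mature > n_mature:
        raise ValueError("largest subpopulation exceeds the total population")
    if not continuing_decline:
        return "LC", ""
    for cat in ("CR", "EN", "VU"):
        if n_mature < C2_TOTAL[cat] and largest_subpop_mature <= C2_SUBPOP[cat]:
            return cat, f"{cat} C2a(i)"
    return "LC", ""


def projected_aoo(current: RasterGrid, future: RasterGrid,
                  dispersal: str = "full", cell_km: float = 2.0
                  ) -> tuple[float, float]:
    """Future AOO and AOO loss percentage under a dispersal assumption.

    Full dispersal counts every future-suitable cell; limited dispersal
    only cells suitable both now and in the future. Loss is floored at 0,
    so range expansion reports 0% loss. The AOO grid is the IUCN 2-km
    grid laid over the suitable 1-km cell centres.
    """
    if dispersal not in ("full", "limited"):
        raise ValueError("dispersal must be 'full' or 'limited'")
    require_aligned(current, future)

    def suitable_points(mask_vals: np.ndarray) -> np.ndarray:
        rows, cols = np.nonzero(mask_vals)
        return current.cell_centers(rows, cols)

    cur = current.mask & (current.values == 1)
    fut = future.mask & (future.values == 1)
    if not cur.any():
        raise ValueError("current AOO is zero")
    occupied = fut if dispersal == "full" else (fut & cur)
    aoo_current = aoo(suitable_points(cur), cell_km)
    aoo_future = 0.0 if not occupied.any() else aoo(suitable_points(occupied), cell_km)
    loss_pct = 100.0 * max(aoo_current - aoo_future, 0.0) / aoo_current
    return aoo_future, loss_pct


def a3c_category(loss_pct: float) -> str:
    """Category from projected future range loss, criterion A3(c) bands.

    Loss below 15% is Least Concern; 15-30% Near Threatened; the standard
    A3 bands place 30-50% in VU, 50-80% in EN and 80%+ in CR.
    """
    if not 0 <= loss_pct <= 100:
        raise ValueError("loss percentage must lie in [0, 100]")
    if loss_pct < 15:
        return "LC"
    if loss_pct < 30:
        return "NT"
    if loss_pct < 50:
        return "VU"
    if loss_pct < 80:
        return "EN"
    return "CR"


def assess(range_metrics: RangeMetrics, flags: ConditionFlags,
           population: tuple[int, int, bool] | None = None,
           projected_losses: dict[str, float] | None = None) -> Assessment:
    """Combine criteria B, C and A3(c) into one assessment.

    ``population`` is (mature individuals, largest subpopulation, declining).
    ``projected_losses`` maps a scenario label to an AOO loss percentage;
    each contributes a proposed A3(c) category to the basis. The final
    category is the most threatened among the current-status criteria
    (B, C); EOO is floored to AOO before B1, per IUCN guidance.
    """
    eoo_val = max(range_metrics.eoo_km2, range_metrics.aoo_km2)
    basis: dict[str, str] = {}
    cats: list[str] = []

    b_cat, b_string = criterion_b(eoo_val, range_metrics.aoo_km2,
                                  range_metrics.n_locations, flags)
    if b_cat != "LC":
        basis["B"] = f"{b_cat} {b_string}"
        cats.append(b_cat)

    c_string = ""
    if population is not None:
        c_cat, c_string = criterion_c(*population)
        if c_cat != "LC":
            basis["C"] = c_string
            cats.append(c_cat)

    if projected_losses:
        for label, loss in projected_losses.items():
            basis[f"A3c:{label}"] = a3c_category(loss)

    if not basis:
        return Assessment("LC", "", {})
    category = most_threatened(cats) if cats else "LC"
    parts = [p for p in (b_string if b_cat == category else "",
                         c_string if population and cats and
                         c_string.startswith(category) else "") if p]
    return Assessment(category, "; ".join(parts), basis)


def assessment_table(species_rows: list[dict]) -> pd.DataFrame:
    """Assessment report: one row per species x scenario x dispersal.

    Each input dict needs keys ``species``, ``scenario``, ``current_status``
    and the full/limited loss percentages; proposed categories come from
    :func:`a3c_category` on the limited-dispersal loss (the more
    precautionary of the two).
    """
    rows = []
    for r in species_rows:
        rows.append({
            "species": r["species"],
            "scenario": r["scenario"],
            "aoo_loss_pct_full": r["loss_full"],
            "aoo_loss_pct_limited": r["loss_limited"],
            "current_status": r["current_status"],
            "proposed_status": a3c_category(r["loss_limited"]),
        })
    return pd.DataFrame(rows)
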