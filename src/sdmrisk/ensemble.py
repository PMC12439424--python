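"""TSS-weighted ensembling, suitability classes, binarization, change maps.

The ensemble is a cellwise weighted mean of per-model probability maps
with weights proportional to each model's TSS (negatives floored at 0).
Habitat change between two binary maps is coded ``current + 2 * future``:
0 unsuitable in both, 1 loss, 2 gain, 3 stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid, require_aligned

SUITABILITY_CLASSES = {0: "low", 1: "moderate", 2: "high"}
CHANGE_CODES = {0: "unsuitable", 1: "loss", 2: "gain", 3: "stable"}


def ensemble_map(maps: list[RasterGrid], tss_weights: list[float]) -> RasterGrid:
    """Cellwise weighted mean with weights max(TSS, 0) / sum."""
    if len(maps) != len(tss_weights):
        raise ValueError("one TSS weight per map required")
    if not maps:
        raise ValueError("no maps to ensemble")
    require_aligned(*maps)
    w = np.maximum(np.asarray(tss_weights, dtype=float), 0.0)
    if w.sum() <= 0:
        raise ValueError("all TSS weights are non-positive")
    w = w / w.sum()
    acc = np.zeros(maps[0].shape)
    for m, wi in zip(maps, w):
        acc = acc + wi * np.where(m.mask, m.values, 0.0)
    acc[~maps[0].mask] = np.nan
    return maps[0].with_values(acc)


def classify_suitability(m: RasterGrid, low: float = 0.3,
                         high: float = 0.5) -> RasterGrid:
    """Class codes 0=low [0, low), 1=moderate [low, high], 2=high (high, 1].

    Both class bounds are included in "moderate" so the three classes
    partition [0, 1] totally.
    """
    vals = m.values[m.mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    codes = np.full(m.shape, -1, dtype=float)
    codes[m.mask & (m.values < low)] = 0
    codes[m.mask & (m.values >= low) & (m.values <= high)] = 1
    codes[m.mask & (m.values > high)] = 2
    codes[~m.mask] = np.nan
    return m.with_values(codes)


def binarize(m: RasterGrid, threshold: float) -> RasterGrid:
    """Presence (1) iff value >= threshold; nodata preserved."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    out = np.where(m.values >= threshold, 1.0, 0.0)
    out[~m.mask] = np.nan
    return m.with_values(out)


def change_map(current: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Code current + 2*future: 0 neither, 1 loss, 2 gain, 3 stable."""
    require_aligned(current, future)
    for m in (current, future):
        vals = m.values[m.mask]
        if not set(np.unique(vals)) <= {0.0, 1.0}:
            raise ValueError("change_map needs binary maps")
    mask = current.mask & future.mask
    out = current.values + 2.0 * future.values
    out[~mask] = np.nan
    return RasterGrid(out, current.cell_km, current.origin, mask)


@dataclass(frozen=True)
class ChangeSummary:
    """Loss/gain/stable accounting between a current and a future range.

    Percentages follow the conventions of standard change tables:
    ``loss_pct`` is relative to the current suitable area, ``gain_pct``
    relative to current + gain (equivalently future + loss), and the
    area fractions are relative to the full study area.
    """

    current_km2: float
    future_km2: float
    loss_km2: float
    gain_km2: float
    stable_km2: float
    loss_pct: float
    gain_pct: float
    current_pct_of_area: float
    future_pct_of_area: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Report view with percentages rounded half-even to 1 decimal."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, ndigits) if k.endswith("pct") or k.endswith(
                "pct_of_area") else v
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def change_summary(cm: RasterGrid, cell_area_km2: float | None = None,
                   study_area_cells: int | None = None) -> ChangeSummary:
    """Areas and percentages from a coded change map.

    ``study_area_cells`` defaults to the change map's valid-cell count;
    ``cell_area_km2`` to the map's own cell area.
    """
    vals = cm.values[cm.mask]
    if not set(np.unique(vals)) <= {0.0, 1.0, 2.0, 3.0}:
        raise ValueError("invalid change codes")
    if cell_area_km2 is None:
        cell_area_km2 = cm.cell_area_km2
    if study_area_cells is None:
        study_area_cells = cm.n_valid
    loss = float(np.sum(vals == 1)) * cell_area_km2
    gain = float(np.sum(vals == 2)) * cell_area_km2
    stable = float(np.sum(vals == 3)) * cell_area_km2
    current = loss + stable
    future = gain + stable
    total = study_area_cells * cell_area_km2
    loss_pct = 100.0 * loss / current if current > 0 else float("nan")
    gain_pct = 100.0 * gain / (current + gain) if current + gain > 0 else float("nan")
    return ChangeSummary(
        current_km2=current, future_km2=future, loss_km2=loss, gain_km2=gain,
        stable_km2=stable, loss_pct=loss_pct, gain_pct=gain_pct,
        current_pct_of_area=100.0 * current / total,
        future_pct_of_area=100.0 * future / total,
    )


def summary_from_counts(n_loss: int, n_gain: int, n_stable: int,
                        study_area_cells: int,
                        cell_area_km2: float = 1.0) -> ChangeSummary:
    """Change accounting straight from cell counts (no map needed).

    Convenience for worked examples where a published table prints the
    loss/gain/stable cell counts of a 1-km analysis.
    """
    n_unsuitable = study_area_cells - n_loss - n_gain - n_stable
    if n_unsuitable < 0:
        raise ValueError("counts exceed the study area")
    side = int(np.ceil(np.sqrt(study_area_cells)))
    codes = np.zeros(side * side)
    codes[:n_loss] = 1
    codes[n_loss:n_loss + n_gain] = 2
    codes[n_loss + n_gain:n_loss + n_gain + n_stable] = 3
    mask = np.zeros(side * side, dtype=bool)
    mask[:study_area_cells] = True
    cm = RasterGrid(codes.reshape(side, side),
                    cell_km=float(np.sqrt(cell_area_km2)),
                    mask=mask.reshape(side, side))
    return change_summary(cm, cell_area_km2, study_area_cells)
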