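"""Predictor-stack preparation: alignment, collinearity filtering, importance.

The collinearity filter mirrors the two-phase pairwise-correlation /
stepwise-VIF procedure common in SDM practice: first resolve pairs with
|r| at or above ``cor_max`` by dropping the pair member with the larger
VIF, then drop variables until every VIF is at or below ``vif_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr

from .grid import EnvStack, RasterGrid


def align_resample(layers: dict[str, RasterGrid], template: RasterGrid,
                   method: str = "bilinear") -> EnvStack:
    """Re-grid layers onto a template geometry by nearest or bilinear rule.

    Template cells whose centre falls outside a source layer's coverage (or
    whose interpolation touches nodata) become nodata; the final stack mask
    is the intersection over layers with the template mask.
    """
    if not layers:
        raise ValueError("no layers to align")
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    nr, nc = template.shape
    if nr < 1 or nc < 1:
        raise ValueError("degenerate template")
    rows, cols = np.mgrid[0:nr, 0:nc]
    centers_x = template.origin[0] + (cols + 0.5) * template.cell_km
    centers_y = template.origin[1] + (rows + 0.5) * template.cell_km

    out: dict[str, np.ndarray] = {}
    mask = template.mask.copy()
    for name, src in layers.items():
        # fractional index of each template centre in the source grid
        fi = (centers_y - src.origin[1]) / src.cell_km - 0.5
        fj = (centers_x - src.origin[0]) / src.cell_km - 0.5
        vals = np.asarray(src.values, dtype=float).copy()
        vals[~src.mask] = np.nan
        order = 0 if method == "nearest" else 1
        res = map_coordinates(vals, [fi, fj], order=order, mode="constant",
                              cval=np.nan, prefilter=False)
        inside = (
            (fi > -0.5 - 1e-9) & (fi < src.shape[0] - 0.5 + 1e-9)
            & (fj > -0.5 - 1e-9) & (fj < src.shape[1] - 0.5 + 1e-9)
        )
        res[~inside] = np.nan
        out[name] = res
        mask &= ~np.isnan(res)
    for name in out:
        out[name][~mask] = np.nan
    return EnvStack(out, template.cell_km, template.origin, mask)


@dataclass
class VifReport:
    """Outcome of the two-phase collinearity filter."""

    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (name, reason in {correlation, vif}, value)
    final_vifs: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"name": n, "status": "retained", "reason": "",
                 "value": self.final_vifs.get(n, np.nan)} for n in self.retained]
        rows += [{"name": n, "status": "dropped", "reason": r, "value": v}
                 for n, r, v in self.dropped]
        return pd.DataFrame(rows)


def vif_scores(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per column: 1 / (1 - R^2 on the others).

    R^2 comes from an OLS regression (with intercept) of each column on all
    remaining columns; exact collinearity reports +inf.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("need at least two columns")
    if X.dropna().shape[0] < 3:
        raise ValueError("need at least three complete rows")
    X = X.dropna()
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"rank deficient: {X.shape[0]} rows for {X.shape[1]} predictors")
    arr = X.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    if np.any(sds == 0):
        bad = list(X.columns[sds == 0])
        raise ValueError(f"constant columns: {bad}")
    arr = (arr - arr.mean(axis=0)) / sds  # affine-invariant by construction
    out: dict[str, float] = {}
    for i, name in enumerate(X.columns):
        y = arr[:, i]
        others = np.delete(arr, i, axis=1)
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _abs_corr(X: pd.DataFrame) -> pd.DataFrame:
    c = X.corr().abs()
    np.fill_diagonal(c.values, 0.0)
    return c


def vif_filter(X: pd.DataFrame, cor_max: float = 0.75,
               vif_max: float = 5.0) -> VifReport:
    """Two-phase collinearity filter.

    Phase 1: while any pair has |r| >= cor_max, take the max-|r| pair and
    drop the member with the larger VIF (ties: the lexicographically later
    name). Phase 2: while max VIF > vif_max, drop the max-VIF variable.
    The retained set satisfies both thresholds.
    """
    X = pd.DataFrame(X).dropna()
    current = list(X.columns)
    dropped: list[tuple[str, str, float]] = []

    def drop(name: str, reason: str, value: float) -> None:
        current.remove(name)
        dropped.append((name, reason, float(value)))
        if len(current) == 0:
            raise ValueError("collinearity filter eliminated every variable")

    # phase 1: pairwise correlation
    while len(current) >= 2:
        corr = _abs_corr(X[current])
        # deterministic max pair: scan in (sorted) name order
        names = sorted(current)
        best = (0.0, None)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = corr.loc[a, b]
                if r > best[0]:
                    best = (r, (a, b))
        r, pair = best
        if pair is None or r < cor_max:
            break
        a, b = pair
        vifs = vif_scores(X[current]) if len(current) > 2 else {a: 1.0, b: 1.0}
        va, vb = vifs.get(a, 1.0), vifs.get(b, 1.0)
        if va > vb:
            victim = a
        elif vb > va:
            victim = b
        else:
            victim = max(a, b)  # lexicographically later
        drop(victim, "correlation", r)

    # phase 2: stepwise VIF
    while len(current) >= 2:
        vifs = vif_scores(X[current])
        worst = max(sorted(vifs), key=lambda n: (vifs[n], n))
        if vifs[worst] <= vif_max:
            break
        drop(worst, "vif", vifs[worst])

    final = vif_scores(X[current]) if len(current) >= 2 else {n: 1.0 for n in current}
    return VifReport(retained=current, dropped=dropped, final_vifs=final)


def variable_importance(predict, X: pd.DataFrame, n_perm: int = 5,
                        seed: int = 0) -> dict[str, float]:
    """Permutation importance of each predictor, normalized to percent.

    Raw importance of a variable is ``1 - cor(predictions, predictions with
    that variable's rows permuted)``, averaged over ``n_perm`` seeded
    permutations and floored at zero; values are reported as percentages of
    their sum, so they add to 100.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = pd.DataFrame(X)
    base = np.asarray(predict(X), dtype=float)
    rng = np.random.default_rng(seed)
    raw: dict[str, float] = {}
    for name in X.columns:
        scores = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[name] = rng.permutation(Xp[name].to_numpy())
            pred = np.asarray(predict(Xp), dtype=float)
            if base.std() == 0 or pred.std() == 0:
                scores.append(0.0 if np.allclose(pred, base) else 1.0)
            else:
                scores.append(1.0 - pearsonr(base, pred).statistic)
        raw[name] = max(float(np.mean(scores)), 0.0)
    total = sum(raw.values())
    if total == 0:
        raise ValueError("all permutation importances are zero")
    return {n: 100.0 * v / total for n, v in raw.items()}
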