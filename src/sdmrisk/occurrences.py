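"""Occurrence handling: thinning, spatial diagnostics, background, splits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import EnvStack


@dataclass
class OccurrenceSet:
    """Species-tagged presence points in a planar km frame."""

    species: str
    points: np.ndarray  # (n, 2) of x, y
    source: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if not self.source:
            self.source = ["unknown"] * len(self.points)
        if len(self.source) != len(self.points):
            raise ValueError("one source tag per point required")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "x": self.points[:, 0],
            "y": self.points[:, 1],
            "source": self.source,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        species = str(df["species"].iloc[0]) if len(df) else "unknown"
        src = list(df["source"]) if "source" in df else []
        return cls(species, df[["x", "y"]].to_numpy(dtype=float), src)


@dataclass
class SplitSet:
    """One train/test replicate of presences and background points."""

    replicate_id: int
    train_presence: np.ndarray
    train_background: np.ndarray
    test_presence: np.ndarray
    test_background: np.ndarray

    def training_xy(self, stack: EnvStack) -> tuple[pd.DataFrame, np.ndarray]:
        X = pd.concat([stack.extract(self.train_presence),
                       stack.extract(self.train_background)], ignore_index=True)
        y = np.r_[np.ones(len(self.train_presence)),
                  np.zeros(len(self.train_background))]
        return X, y

    def testing_xy(self, stack: EnvStack) -> tuple[pd.DataFrame, np.ndarray]:
        X = pd.concat([stack.extract(self.test_presence),
                       stack.extract(self.test_background)], ignore_index=True)
        y = np.r_[np.ones(len(self.test_presence)),
                  np.zeros(len(self.test_background))]
        return X, y


def thin_to_grid(occ: OccurrenceSet, cell_km: float = 1.0,
                 origin: tuple[float, float] = (0.0, 0.0)) -> OccurrenceSet:
    """Keep at most one record per grid cell (the first in input order).

    Removes the pseudo-replication of multiple records inside one ~1-km
    cell; output order follows input order of the retained records.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if len(occ) == 0:
        warnings.warn("thinning an empty occurrence set", stacklevel=2)
        return OccurrenceSet(occ.species, np.empty((0, 2)), [])
    cols = np.floor((occ.points[:, 0] - origin[0]) / cell_km).astype(int)
    rows = np.floor((occ.points[:, 1] - origin[1]) / cell_km).astype(int)
    seen: set[tuple[int, int]] = set()
    keep = []
    for i, key in enumerate(zip(rows, cols)):
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return OccurrenceSet(occ.species, occ.points[keep],
                         [occ.source[i] for i in keep])


def drop_nodata_points(occ: OccurrenceSet, stack: EnvStack) -> OccurrenceSet:
    """Drop records outside the stack or on nodata cells."""
    vals = stack[stack.names[0]].sample(occ.points)
    keep = np.nonzero(~np.isnan(vals))[0]
    return OccurrenceSet(occ.species, occ.points[keep],
                         [occ.source[i] for i in keep])


def nearest_neighbor_index(points: np.ndarray, study_area_km2: float) -> float:
    """Clark-Evans ratio R of observed to expected nearest-neighbour distance.

    R = mean NN distance / (0.5 * sqrt(area / n)); R < 1 flags clustering,
    R ~ 1 complete spatial randomness.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least two points")
    if study_area_km2 <= 0:
        raise ValueError("study area must be positive")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    mean_nn = float(d[:, 1].mean())
    if mean_nn == 0:
        warnings.warn("all nearest-neighbour distances are zero", stacklevel=2)
    expected = 0.5 * np.sqrt(study_area_km2 / len(pts))
    return mean_nn / expected


def generate_background(stack: EnvStack, n: int, seed: int,
                        exclude: OccurrenceSet | None = None) -> OccurrenceSet:
    """Uniform background (pseudo-absence) cells avoiding presence cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = stack.mask.copy()
    if exclude is not None and len(exclude):
        rows, cols = stack[stack.names[0]].index_of(exclude.points)
        inside = stack[stack.names[0]].contains(exclude.points)
        valid[rows[inside], cols[inside]] = False
    rows, cols = np.nonzero(valid)
    if n > len(rows):
        raise ValueError(f"requested {n} background cells, only {len(rows)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    pts = stack[stack.names[0]].cell_centers(rows[idx], cols[idx])
    return OccurrenceSet("background", pts, ["background"] * n)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def train_test_split(presences: OccurrenceSet, backgrounds: OccurrenceSet,
                     test_fraction: float = 0.3, n_replicates: int = 5,
                     seed: int = 0) -> list[SplitSet]:
    """Replicated stratified subsampling into train and test partitions.

    Presences and backgrounds are split independently; the test partition
    holds round-half-up(test_fraction * n) points of each class. Replicates
    draw from spawned sub-seeds and are individually reproducible.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(presences) < 5:
        raise ValueError("need at least 5 presences to split")

    def split_class(points: np.ndarray, rng: np.random.Generator):
        n = len(points)
        n_test = _round_half_up(test_fraction * n)
        if n_test == 0 or n_test == n:
            raise ValueError("class too small to populate both partitions")
        perm = rng.permutation(n)
        return points[perm[n_test:]], points[perm[:n_test]]

    out = []
    for rep, ss in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        p_train, p_test = split_class(presences.points, rng)
        b_train, b_test = split_class(backgrounds.points, rng)
        out.append(SplitSet(rep, p_train, b_train, p_test, b_test))
    return out
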