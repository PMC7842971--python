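"""Structure-guided sample design.

Reference cells for model training are selected so the sample spans the
full range of forest structure: the response rasters are k-means clustered
(after per-band standardization), then cells are drawn at random within
clusters proportionally to cluster area, with a minimum pairwise distance
to blunt spatial autocorrelation.  Cross-validation folds are dealt so
each fold preserves the cluster balance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grid import GridRaster
from .points import SamplePoints

__all__ = [
    "SampleDesign",
    "FoldAssignment",
    "kmeans_stratify",
    "draw_sample",
    "get_sample_values",
    "partition",
    "largest_remainder_quotas",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleDesign:
    """Stratified-sampling parameters: sample size ``n`` over ``n_strata``
    k-means clusters with pairwise minimum distance ``min_dist`` (map units)."""

    n: int
    n_strata: int
    min_dist: float = 0.0
    seed: int = 0
    max_attempts_factor: int = 50  # candidate visits bounded by factor * n

    def __post_init__(self) -> None:
        if not (self.n >= self.n_strata >= 1):
            raise ValueError("need n >= n_strata >= 1")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")


@dataclass
class FoldAssignment:
    """Per-point fold indices (1..kfold) or train/test flags for holdout."""

    fold: np.ndarray  # int fold per point (1-based); 0 marks "train" in holdout
    kfold: int
    seed: int
    scheme: str = "kfold"

    @property
    def n_points(self) -> int:
        return len(self.fold)

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (train, test) masks for one held-out fold."""
        test = self.fold == fold
        return ~test, test


def kmeans_stratify(
    responses: GridRaster, n_strata: int, seed: int = 0, n_init: int = 10
) -> tuple[GridRaster, pd.DataFrame]:
    """Cluster the response space into strata.

    Bands are standardized (zero mean, unit variance over finite cells)
    before a seeded k-means++ clustering; every finite cell gets a label in
    1..n_strata, NoData cells stay NoData.  Returns the label raster and a
    per-stratum table of mean response values (original units).
    """
    mask = responses.finite_mask()
    X = responses.values[:, mask].T  # (n_cells, n_bands)
    if X.shape[0] < n_strata:
        raise ValueError(
            f"only {X.shape[0]} finite cells for {n_strata} strata"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    km = KMeans(n_clusters=n_strata, random_state=seed, n_init=n_init)
    labels = km.fit_predict(Xs) + 1  # 1-based strata

    label_grid = np.full((responses.n_rows, responses.n_cols), np.nan)
    label_grid[mask] = labels
    strata = responses.with_values(label_grid[np.newaxis], band_names=["stratum"])

    centers = pd.DataFrame(
        [X[labels == s].mean(axis=0) for s in range(1, n_strata + 1)],
        columns=responses.band_names,
        index=pd.Index(range(1, n_strata + 1), name="stratum"),
    )
    return strata, centers


def largest_remainder_quotas(counts: np.ndarray, n: int) -> np.ndarray:
    """Apportion n among strata proportionally to cell counts
    (largest-remainder / Hare method; ties go to the lower stratum index)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no eligible cells in any stratum")
    exact = n * counts / total
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n - base.sum()
    # stable sort descending on remainder -> ties broken by stratum order
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def draw_sample(strata: GridRaster, design: SampleDesign) -> SamplePoints:
    """Draw a stratified random sample of cell centroids.

    Per-stratum quotas are the largest-remainder apportionment of ``n`` by
    stratum area; candidates within each stratum are visited in seeded
    random order and accepted greedily if at least ``min_dist`` from every
    already-accepted point (across all strata).  If a quota cannot be
    filled within the attempt budget the stratum falls short with a logged
    warning.
    """
    label_grid = strata.values[0]
    mask = np.isfinite(label_grid)
    if not mask.any():
        raise ValueError("strata raster has no labeled cells")
    labels_present = np.unique(label_grid[mask]).astype(int)
    counts = np.array([(label_grid == s).sum() for s in labels_present])
    quotas = largest_remainder_quotas(counts, design.n)

    rng = np.random.default_rng(design.seed)
    spec = strata.spec
    acc_xy: list[tuple[float, float]] = []
    records = []
    budget = design.max_attempts_factor * design.n
    visits = 0
    min_d2 = design.min_dist**2

    for stratum, quota in zip(labels_present, quotas):
        rows, cols = np.nonzero(label_grid == stratum)
        order = rng.permutation(len(rows))
        taken = 0
        for idx in order:
            if taken >= quota:
                break
            if visits >= budget:
                break
            visits += 1
            r, c = int(rows[idx]), int(cols[idx])
            x, y = spec.cell_center(r, c)
            x, y = float(x), float(y)
            if min_d2 > 0 and acc_xy:
                pts = np.asarray(acc_xy)
                d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
                if d2.min() < min_d2:
                    continue
            acc_xy.append((x, y))
            records.append({"x": x, "y": y, "row": r, "col": c, "stratum": int(stratum)})
            taken += 1
        if taken < quota:
            msg = (
                f"stratum {stratum}: drew {taken} of {quota} requested points "
                f"(min_dist={design.min_dist} too restrictive or stratum too small)"
            )
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)

    df = pd.DataFrame(records, columns=["x", "y", "row", "col", "stratum"])
    return SamplePoints(df, crs_id=strata.crs_id)


def get_sample_values(source: GridRaster, points: SamplePoints) -> SamplePoints:
    """Extract raster values at sample points (containing cell, no
    interpolation); one new column per source band.  Out-of-extent points
    get missing values and a warning but are retained."""
    if points.crs_id and source.crs_id and points.crs_id != source.crs_id:
        raise ValueError(
            f"CRS mismatch: points {points.crs_id!r} vs raster {source.crs_id!r}"
        )
    spec = source.spec
    row, col = spec.index_of(points.data["x"].to_numpy(), points.data["y"].to_numpy())
    inside = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} point(s) outside raster extent; values set missing",
            stacklevel=2,
        )
    ri = np.clip(row, 0, spec.n_rows - 1).astype(int)
    ci = np.clip(col, 0, spec.n_cols - 1).astype(int)
    frame = {}
    for b, name in enumerate(source.band_names):
        vals = source.values[b][ri, ci]
        frame[name] = np.where(inside, vals, np.nan)
    return points.with_columns(pd.DataFrame(frame))


def partition(
    strata_labels,
    scheme: str = "kfold",
    kfold: int = 5,
    train_fraction: float | None = None,
    seed: int = 0,
) -> FoldAssignment:
    """Cluster-balanced train/test partitioning.

    ``kfold``: within each stratum, points are shuffled (seeded) and dealt
    round-robin to folds; the dealing pointer carries over between strata so
    overall fold sizes also differ by at most one.  ``holdout``: per
    stratum, ``train_fraction`` of points (at least leaving one) go to
    training; test points get fold 1, train fold 0.
    """
    labels = np.asarray(strata_labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    fold = np.zeros(n, dtype=int)

    if scheme == "kfold":
        if kfold < 2:
            raise ValueError("kfold must be >= 2")
        strata = np.unique(labels)
        smallest = min((labels == s).sum() for s in strata)
        if kfold > smallest:
            warnings.warn(
                f"kfold={kfold} exceeds smallest stratum size {smallest}; "
                "some folds will lack that stratum",
                stacklevel=2,
            )
        pointer = 0
        for s in strata:
            idx = np.nonzero(labels == s)[0]
            idx = rng.permutation(idx)
            for i in idx:
                fold[i] = pointer % kfold + 1
                pointer += 1
        return FoldAssignment(fold=fold, kfold=kfold, seed=seed, scheme="kfold")

    if scheme == "holdout":
        if train_fraction is None or not (0 < train_fraction < 1):
            raise ValueError("holdout requires 0 < train_fraction < 1")
        for s in np.unique(labels):
            idx = np.nonzero(labels == s)[0]
            idx = rng.permutation(idx)
            n_train = min(int(np.floor(train_fraction * len(idx))), len(idx) - 1)
            fold[idx[n_train:]] = 1  # test
        return FoldAssignment(fold=fold, kfold=1, seed=seed, scheme="holdout")

    raise ValueError(f"unknown partition scheme {scheme!r}")
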