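"""Random-forest-proximity k-NN imputation and accuracy assessment.

The model keeps the reference observations themselves: one regression
forest is grown per response variable, and the nearness between a target
and a reference is the proportion of trees — pooled over all response
forests — in which the two fall into the same terminal node.  The k
nearest references under that proximity supply the imputed response
vector: with k = 1 a real observation vector is copied verbatim (which
preserves among-attribute allometry), with k > 1 a simple or
proximity-weighted mean is taken.  Euclidean and Mahalanobis nearness are
available as alternative methods.

Accuracy is reported as the coefficient of determination
R^2 = 1 - SSR/SST, the root mean square error and the mean bias of
predicted minus observed, each also expressed relative to the mean of the
observed values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor

from .grid import GridRaster
from .sampling import FoldAssignment

__all__ = [
    "KnnModel",
    "NeighborResult",
    "AccuracyReport",
    "ImportanceReport",
    "CrossValResult",
    "fit_knn",
    "train_nn",
    "rf_proximity",
    "impute",
    "predict_targets",
    "accuracy",
    "var_imp",
    "scatter_report",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class KnnModel:
    """Reference matrices plus the trained nearness machinery.

    ``ref_leaf_nodes`` stores the terminal-node index of every reference in
    every tree (columns pooled over the per-response forests), which is all
    that is needed to compute proximities to new targets.
    """

    X_ref: pd.DataFrame
    Y_ref: pd.DataFrame
    k: int
    method: str = "random_forest"
    aggregation: str = "distance_weighted_mean"
    ntree: int = 200
    mtry: int = 3
    seed: int = 0
    forests: dict[str, RandomForestRegressor] = field(default_factory=dict, repr=False)
    ref_leaf_nodes: np.ndarray | None = field(default=None, repr=False)
    mahalanobis_standardized: bool = False
    _vi: np.ndarray | None = field(default=None, repr=False)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X_ref.columns)

    @property
    def response_names(self) -> list[str]:
        return list(self.Y_ref.columns)

    @property
    def n_ref(self) -> int:
        return len(self.X_ref)

    @property
    def n_trees_total(self) -> int:
        return 0 if self.ref_leaf_nodes is None else self.ref_leaf_nodes.shape[1]

    def apply_forests(self, X: np.ndarray) -> np.ndarray:
        """Terminal-node indices of targets in every tree, pooled over the
        per-response forests (column order matches ``ref_leaf_nodes``)."""
        return np.hstack([self.forests[r].apply(X) for r in self.response_names])

    def save(self, path) -> None:
        """Serialize the whole model (references, forests, settings) to one
        archive."""
        import sklearn
        from joblib import dump

        dump({"model": self, "sklearn_version": sklearn.__version__}, path)

    @classmethod
    def load(cls, path) -> "KnnModel":
        from joblib import load as _load

        payload = _load(path)
        return payload["model"] if isinstance(payload, dict) else payload


@dataclass
class NeighborResult:
    """Per-target nearest references and imputed responses."""

    neighbor_ids: np.ndarray  # (n_targets, k) reference row positions
    proximities: np.ndarray  # (n_targets, k) proximity (or -distance rank weights)
    predictions: pd.DataFrame  # (n_targets, q)


def _check_columns(model: KnnModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != model.predictor_names:
            missing = [c for c in model.predictor_names if c not in X.columns]
            extra = [c for c in X.columns if c not in model.predictor_names]
            if missing or extra:
                raise ValueError(
                    f"predictor mismatch: missing {missing}, unexpected {extra}"
                )
            raise ValueError(
                f"predictor order mismatch: expected {model.predictor_names}, "
                f"got {list(X.columns)}"
            )
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.predictor_names):
        raise ValueError(
            f"target matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {len(model.predictor_names)}"
        )
    return X


def fit_knn(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    k: int = 1,
    method: str = "random_forest",
    ntree: int = 200,
    mtry: int = 3,
    aggregation: str = "distance_weighted_mean",
    seed: int = 0,
    mahalanobis_standardized: bool = False,
) -> KnnModel:
    """Fit the k-NN model on reference predictors X and responses Y.

    For ``method="random_forest"`` one regression forest of ``ntree`` trees
    with ``mtry`` split candidates is grown per response column.
    """
    if not isinstance(X, pd.DataFrame) or not isinstance(Y, pd.DataFrame):
        raise TypeError("X and Y must be DataFrames with named columns")
    if len(X) != len(Y):
        raise ValueError("X and Y must be row-aligned")
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} must be in [1, n_ref={len(X)}]")
    if method not in ("random_forest", "euclidean", "mahalanobis"):
        raise ValueError(f"unknown method {method!r}")
    if aggregation not in ("nearest", "mean", "distance_weighted_mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if method == "random_forest" and mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds predictor count {X.shape[1]}")

    model = KnnModel(
        X_ref=X.reset_index(drop=True),
        Y_ref=Y.reset_index(drop=True),
        k=k,
        method=method,
        aggregation=aggregation,
        ntree=ntree,
        mtry=mtry,
        seed=seed,
        mahalanobis_standardized=mahalanobis_standardized,
    )
    Xa = model.X_ref.to_numpy(dtype=float)
    if method == "random_forest":
        leaves = []
        for i, resp in enumerate(model.response_names):
            rf = RandomForestRegressor(
                n_estimators=ntree,
                max_features=mtry,
                random_state=(seed * 7919 + i) % (2**31 - 1),
                bootstrap=True,
                n_jobs=1,
            )
            rf.fit(Xa, model.Y_ref[resp].to_numpy(dtype=float))
            model.forests[resp] = rf
            leaves.append(rf.apply(Xa))
        model.ref_leaf_nodes = np.hstack(leaves)
    elif method == "mahalanobis":
        Z = Xa
        if mahalanobis_standardized:
            sd = Z.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (Z - Z.mean(axis=0)) / sd
        cov = np.cov(Z, rowvar=False)
        model._vi = np.linalg.pinv(np.atleast_2d(cov))
    return model


def rf_proximity(model: KnnModel, X_targets) -> np.ndarray:
    """Proximity of each target to every reference: the proportion of trees
    (pooled over all response forests) in which both land in the same
    terminal node.  Values lie in [0, 1]."""
    if model.method != "random_forest":
        raise ValueError("rf_proximity requires a random_forest model")
    Xt = _check_columns(model, X_targets)
    leaves_t = model.apply_forests(Xt)  # (n_t, T)
    ref_leaves = model.ref_leaf_nodes
    n_t, T = leaves_t.shape
    n_ref = ref_leaves.shape[0]
    prox = np.empty((n_t, n_ref))
    # reference-blockwise so peak memory stays O(n_t * block * T) booleans
    block = max(1, int(2e7 // max(1, n_t * T)))
    for b0 in range(0, n_ref, block):
        b1 = min(b0 + block, n_ref)
        prox[:, b0:b1] = (
            leaves_t[:, None, :] == ref_leaves[None, b0:b1, :]
        ).mean(axis=2)
    return prox


def _neighbor_order(model: KnnModel, X_targets) -> tuple[np.ndarray, np.ndarray]:
    """(ids, weights) of the k nearest references per target.

    Ties in proximity/distance are broken by lowest reference position
    (stable argsort), making imputed maps bit-reproducible.
    """
    Xt = _check_columns(model, X_targets)
    k = model.k
    if model.method == "random_forest":
        prox = rf_proximity(model, Xt)
        dead = ~np.any(prox > 0, axis=1)
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} degenerate target(s) with zero proximity to "
                "every reference; imputing from the lowest-ID references",
                stacklevel=2,
            )
        order = np.argsort(-prox, axis=1, kind="stable")[:, :k]
        weights = np.take_along_axis(prox, order, axis=1)
        if dead.any():
            order[dead] = np.arange(k)
            weights[dead] = 1.0
        return order, weights
    Xr = model.X_ref.to_numpy(dtype=float)
    if model.method == "euclidean":
        dist = cdist(Xt, Xr)
    else:
        Z_t, Z_r = Xt, Xr
        if model.mahalanobis_standardized:
            mu = Xr.mean(axis=0)
            sd = Xr.std(axis=0)
            sd[sd == 0] = 1.0
            Z_t = (Xt - mu) / sd
            Z_r = (Xr - mu) / sd
        dist = cdist(Z_t, Z_r, metric="mahalanobis", VI=model._vi)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(dist, order, axis=1)
    weights = 1.0 / (d + _EPS)  # similarity weights for weighted aggregation
    return order, weights


def impute(model: KnnModel, X_targets) -> NeighborResult:
    """Impute all response variables simultaneously for each target.

    With k = 1 the nearest reference's full response vector is copied; with
    k > 1 the responses are the simple or proximity-weighted mean over the
    k nearest references, per the model's aggregation setting.
    """
    ids, weights = _neighbor_order(model, X_targets)
    Y = model.Y_ref.to_numpy(dtype=float)
    if model.k == 1 or model.aggregation == "nearest":
        pred = Y[ids[:, 0]]
    elif model.aggregation == "mean":
        pred = Y[ids].mean(axis=1)
    else:  # distance_weighted_mean
        w = weights.copy()
        wsum = w.sum(axis=1, keepdims=True)
        flat = wsum[:, 0] <= 0
        w[flat] = 1.0
        wsum[flat] = model.k
        w = w / wsum
        pred = np.einsum("tk,tkq->tq", w, Y[ids])
    predictions = pd.DataFrame(pred, columns=model.response_names)
    return NeighborResult(neighbor_ids=ids, proximities=weights, predictions=predictions)


@dataclass
class AccuracyReport:
    """Observed/predicted agreement statistics for one response variable."""

    name: str
    n: int
    r2: float
    rmse: float
    bias: float
    rmse_pct: float
    bias_pct: float
    ssr: float
    sst: float
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "bias": self.bias,
            "rmse_pct": self.rmse_pct,
            "bias_pct": self.bias_pct,
        }


def accuracy(observed, predicted, name: str = "response") -> AccuracyReport:
    """Agreement between observed and imputed values.

    R^2 = 1 - SSR/SST (may be negative), RMSE = sqrt(mean squared error),
    bias = mean(predicted - observed); RMSE% and bias% are 100x the
    statistic divided by the mean of the observed values (undefined, with a
    warning, when that mean is zero).  Pairs with missing entries are
    dropped.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    n = obs.size
    if n < 2:
        raise ValueError("need at least two finite observed/predicted pairs")
    resid = pred - obs
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(ssr / n))
    bias = float(resid.mean())
    mean_obs = obs.mean()
    if mean_obs == 0:
        warnings.warn("mean of observed values is zero; relative forms undefined", stacklevel=2)
        rmse_pct = bias_pct = float("nan")
    else:
        rmse_pct = 100.0 * rmse / mean_obs
        bias_pct = 100.0 * bias / mean_obs
    return AccuracyReport(
        name=name, n=n, r2=r2, rmse=rmse, bias=bias,
        rmse_pct=rmse_pct, bias_pct=bias_pct, ssr=ssr, sst=sst,
        observed=obs, predicted=pred,
    )


@dataclass
class CrossValResult:
    """Held-out imputations across folds plus the final model."""

    observed: pd.DataFrame
    predicted: pd.DataFrame
    fold: np.ndarray
    fold_models: dict[int, KnnModel]
    final_model: KnnModel | None

    def accuracy(self, pooled: bool = True) -> dict[str, AccuracyReport]:
        """Pooled (or per-fold, as ``{resp}: {fold: report}``) accuracy."""
        if pooled:
            return {
                resp: accuracy(self.observed[resp], self.predicted[resp], name=resp)
                for resp in self.observed.columns
            }
        out: dict[str, dict[int, AccuracyReport]] = {}
        for resp in self.observed.columns:
            out[resp] = {}
            for f in np.unique(self.fold):
                m = self.fold == f
                out[resp][int(f)] = accuracy(
                    self.observed[resp][m], self.predicted[resp][m], name=resp
                )
        return out

    def accuracy_table(self) -> pd.DataFrame:
        rows = [rep.as_dict() for rep in self.accuracy(pooled=True).values()]
        return pd.DataFrame(rows).set_index("name")


def train_nn(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    k: int = 1,
    folds: FoldAssignment | None = None,
    method: str = "random_forest",
    ntree: int = 200,
    mtry: int = 3,
    aggregation: str = "distance_weighted_mean",
    seed: int = 0,
    refit_final: bool = True,
) -> CrossValResult:
    """Cross-validated k-NN training: fit on each fold's training rows,
    impute its held-out rows, and (optionally) refit a final model on all
    rows.  Rows with missing predictor or response values are dropped with
    a logged count."""
    if len(X) != len(Y):
        raise ValueError("X and Y must be row-aligned")
    finite = np.isfinite(X.to_numpy(dtype=float)).all(axis=1) & np.isfinite(
        Y.to_numpy(dtype=float)
    ).all(axis=1)
    if not finite.all():
        log.warning("dropping %d row(s) with missing values", int((~finite).sum()))
    X = X.loc[finite].reset_index(drop=True)
    Y = Y.loc[finite].reset_index(drop=True)
    fold_arr = (
        np.ones(len(X), dtype=int)
        if folds is None
        else np.asarray(folds.fold)[finite]
    )

    fold_models: dict[int, KnnModel] = {}
    obs_parts, pred_parts, fold_parts = [], [], []
    if folds is None:
        eval_folds = []
    elif folds.scheme == "holdout":
        eval_folds = [1]
    else:
        eval_folds = sorted(int(f) for f in np.unique(fold_arr))
    for f in eval_folds:
        test = fold_arr == f
        train = ~test if folds.scheme == "kfold" else fold_arr == 0
        if test.sum() == 0 or train.sum() == 0:
            continue
        m = fit_knn(
            X.loc[train], Y.loc[train], k=k, method=method, ntree=ntree,
            mtry=mtry, aggregation=aggregation, seed=(seed * 31 + f) % (2**31 - 1),
        )
        fold_models[f] = m
        res = impute(m, X.loc[test])
        obs_parts.append(Y.loc[test].reset_index(drop=True))
        pred_parts.append(res.predictions)
        fold_parts.append(np.full(int(test.sum()), f))

    observed = (
        pd.concat(obs_parts, ignore_index=True) if obs_parts else Y.iloc[:0].copy()
    )
    predicted = (
        pd.concat(pred_parts, ignore_index=True) if pred_parts else Y.iloc[:0].copy()
    )
    fold_vec = np.concatenate(fold_parts) if fold_parts else np.empty(0, dtype=int)
    final = (
        fit_knn(
            X, Y, k=k, method=method, ntree=ntree, mtry=mtry,
            aggregation=aggregation, seed=seed,
        )
        if refit_final
        else None
    )
    return CrossValResult(
        observed=observed, predicted=predicted, fold=fold_vec,
        fold_models=fold_models, final_model=final,
    )


def predict_targets(
    model: KnnModel, predictors: GridRaster, chunk_rows: int = 64
) -> GridRaster:
    """Impute responses wall-to-wall over a predictor raster.

    The output carries one band per response plus a ``nn_id`` band with the
    nearest reference's row position.  Cells with any NoData predictor are
    NoData in every output band.  Rows are processed in chunks of
    ``chunk_rows`` (clamped to the raster height); the result is identical
    for any chunk size.
    """
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")
    have = set(predictors.band_names)
    want = model.predictor_names
    missing = [c for c in want if c not in have]
    extra = sorted(have - set(want))
    if missing or extra:
        raise ValueError(f"predictor band mismatch: missing {missing}, unexpected {extra}")
    src = predictors.select_bands(want)

    q = len(model.response_names)
    n_rows, n_cols = src.n_rows, src.n_cols
    chunk_rows = min(chunk_rows, n_rows)
    out = np.full((q + 1, n_rows, n_cols), np.nan)
    for r0 in range(0, n_rows, chunk_rows):
        r1 = min(r0 + chunk_rows, n_rows)
        block = src.values[:, r0:r1, :].reshape(len(want), -1).T  # (cells, p)
        ok = np.isfinite(block).all(axis=1)
        if not ok.any():
            continue
        res = impute(model, block[ok])
        flat = np.full((q + 1, block.shape[0]), np.nan)
        flat[:q, ok] = res.predictions.to_numpy().T
        flat[q, ok] = res.neighbor_ids[:, 0]
        out[:, r0:r1, :] = flat.reshape(q + 1, r1 - r0, n_cols)
    return src.with_values(out, band_names=model.response_names + ["nn_id"])


@dataclass
class ImportanceReport:
    """Permutation importance of each predictor for each response forest."""

    raw: pd.DataFrame  # predictors x responses, OOB MSE increase
    scaled: pd.DataFrame | None  # z-scored within each response
    mean_scaled: pd.Series | None  # mean z-score across responses

    def as_frame(self) -> pd.DataFrame:
        out = self.raw.add_suffix("_raw")
        if self.scaled is not None:
            out = out.join(self.scaled.add_suffix("_scaled"))
            out["mean_scaled"] = self.mean_scaled
        return out


def var_imp(
    model: KnnModel, scaled: bool = True, seed: int = 0, n_repeats: int = 1
) -> ImportanceReport:
    """Out-of-bag permutation importance per predictor and response.

    For every tree, the mean squared error on that tree's out-of-bag
    references is compared with the error after permuting one predictor;
    the raw importance is the mean error increase over trees.  Scaled
    importance z-scores the raw values across predictors within each
    response, so a predictor below the mean importance is negative.
    """
    if model.method != "random_forest":
        raise ValueError("variable importance requires a random_forest model")
    rng = np.random.default_rng(seed)
    X = model.X_ref.to_numpy(dtype=float)
    n, p = X.shape
    raw = pd.DataFrame(
        0.0, index=model.predictor_names, columns=model.response_names
    )
    for resp in model.response_names:
        forest = model.forests[resp]
        y = model.Y_ref[resp].to_numpy(dtype=float)
        totals = np.zeros(p)
        used = 0
        for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
            oob = np.ones(n, dtype=bool)
            oob[inbag] = False
            if not oob.any():
                continue
            Xo, yo = X[oob], y[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            for j in range(p):
                inc = 0.0
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, j] = Xp[rng.permutation(Xo.shape[0]), j]
                    inc += np.mean((tree.predict(Xp) - yo) ** 2) - base
                totals[j] += inc / n_repeats
            used += 1
        raw[resp] = totals / max(used, 1)

    scaled_df = mean_scaled = None
    if scaled:
        if p == 1:
            warnings.warn("z-scored importance undefined with a single predictor; reporting 0", stacklevel=2)
            scaled_df = raw * 0.0
        else:
            mu = raw.mean(axis=0)
            sd = raw.std(axis=0, ddof=0)
            scaled_df = (raw - mu) / sd.replace(0.0, np.nan)
            scaled_df = scaled_df.fillna(0.0)
        mean_scaled = scaled_df.mean(axis=1)
    return ImportanceReport(raw=raw, scaled=scaled_df, mean_scaled=mean_scaled)


def scatter_report(result, out_path) -> str:
    """Observed-vs-predicted scatterplots, one panel per response, with the
    1:1 line, the least-squares fit and the accuracy metrics annotated.
    ``result`` is a CrossValResult (folds colored) or a single
    AccuracyReport."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(result, AccuracyReport):
        panels = {result.name: (result, None)}
    else:
        if len(result.observed) == 0:
            raise ValueError("empty report: nothing to plot")
        panels = {
            resp: (rep, result.fold)
            for resp, rep in result.accuracy(pooled=True).items()
        }
    n_panel = len(panels)
    fig, axes = plt.subplots(1, n_panel, figsize=(5 * n_panel, 4.5), squeeze=False)
    for ax, (resp, (rep, fold)) in zip(axes[0], panels.items()):
        if fold is not None and len(fold) == len(rep.observed):
            sc = ax.scatter(rep.observed, rep.predicted, c=fold, cmap="viridis", s=14, alpha=0.8)
            fig.colorbar(sc, ax=ax, label="fold")
        else:
            ax.scatter(rep.observed, rep.predicted, s=14, alpha=0.8)
        lo = min(rep.observed.min(), rep.predicted.min())
        hi = max(rep.observed.max(), rep.predicted.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="1:1")
        if np.var(rep.observed) > 0:
            slope, intercept = np.polyfit(rep.observed, rep.predicted, 1)
            xs = np.array([lo, hi])
            ax.plot(xs, slope * xs + intercept, "r-", lw=1, label="fit")
        ax.set_xlabel(f"observed {resp}")
        ax.set_ylabel(f"predicted {resp}")
        ax.set_title(
            f"{resp}: R²={rep.r2:.2f} RMSE%={rep.rmse_pct:.1f} bias%={rep.bias_pct:.1f}"
        )
        ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return str(out_path)
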