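"""Binary tissue classification with repeated stratified cross-validation.

Trains a plain maximum-likelihood logistic regression (features
standardized on the training folds only) under a repeated stratified
k-fold protocol: per repeat the out-of-fold posterior probabilities are
pooled and a full metric panel evaluated, so the mean and SD across
repeats quantify both performance and stability.  Also runs the
feature-subset comparison, held-out-core prediction, and the
subdivision-level (tiles-per-side) sweep.

Metric panel: accuracy, F1, TPR, TNR, PPV, NPV, FPR, FNR, FOR (false
omission rate), FDR, AUROC and the Brier score.  AUROC is computed as the
midrank (Mann-Whitney) statistic, ties counted one half; Brier is the
mean squared error of the probabilities against the 0/1 labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .polarimetry import ParameterMaps
from .texture import build_feature_table, feature_columns

__all__ = [
    "CvProtocol",
    "METRIC_NAMES",
    "compute_metrics",
    "fit_logistic_cv",
    "standard_subsets",
    "subset_experiment",
    "predict_held_out",
    "subdivision_sweep",
    "select_predictors",
]

METRIC_NAMES = (
    "accuracy",
    "f1",
    "tpr",
    "tnr",
    "ppv",
    "npv",
    "fpr",
    "fnr",
    "fom",
    "fdr",
    "auroc",
    "brier",
)


@dataclass
class CvProtocol:
    """Repeated stratified k-fold protocol parameters."""

    k_folds: int = 5
    repeats: int = 1000
    stratified: bool = True
    threshold: float = 0.5
    seed: int = 0
    ridge_alpha: float = 0.0  # 0 = plain maximum likelihood

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _auroc(y: np.ndarray, p: np.ndarray) -> float:
    """Midrank AUROC (equivalent to the Mann-Whitney U statistic)."""
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_metrics(
    y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Full metric panel for one evaluation.

    ``y_true`` must be 0/1; ``proba`` the predicted positive-class
    probabilities.  Confusion metrics use the given posterior threshold;
    metrics whose denominator is empty (e.g. AUROC with a single-class
    truth, TPR with no positives) are NaN.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(proba, dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    return {
        "accuracy": ratio(tp + tn, y.size),
        "f1": f1,
        "tpr": tpr,
        "tnr": tnr,
        "ppv": ppv,
        "npv": npv,
        "fpr": ratio(fp, fp + tn),
        "fnr": ratio(fn, fn + tp),
        "fom": ratio(fn, fn + tn),
        "fdr": ratio(fp, fp + tp),
        "auroc": _auroc(y, p),
        "brier": float(np.mean((p - y) ** 2)),
    }


def _make_model(protocol: CvProtocol) -> LogisticRegression:
    if protocol.ridge_alpha > 0:
        return LogisticRegression(
            penalty="l2", C=1.0 / protocol.ridge_alpha, max_iter=5000
        )
    return LogisticRegression(penalty=None, max_iter=5000)


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def fit_logistic_cv(
    X: np.ndarray,
    y: np.ndarray,
    protocol: CvProtocol,
    max_redraws: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated stratified k-fold logistic regression.

    Per repeat: a repeat-specific split seed is derived from the master
    seed, features are standardized with training-fold statistics only,
    a logistic model is fitted per fold, out-of-fold probabilities are
    pooled and the metric panel evaluated once per repeat.  Degenerate
    splits leaving a fold single-class are redrawn (and counted in
    ``per_repeat.attrs["n_redraws"]``).

    Returns
    -------
    (panel, per_repeat)
        ``panel``: DataFrame indexed by metric with ``mean`` and ``sd``
        columns; ``per_repeat``: one row per repeat with all metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2D with one row per label")
    if np.isnan(X).any():
        raise ValueError("missing feature values; drop incomplete rows first")
    ss = np.random.SeedSequence(protocol.seed)
    split_seeds = ss.generate_state(protocol.repeats * (max_redraws + 1)) % (2**31)
    rows = []
    n_redraws = 0
    seed_i = 0
    for rep in range(protocol.repeats):
        for attempt in range(max_redraws + 1):
            skf = StratifiedKFold(
                n_splits=protocol.k_folds,
                shuffle=True,
                random_state=int(split_seeds[seed_i]),
            )
            seed_i += 1
            folds = list(skf.split(X, y))
            ok = all(len(np.unique(y[tr])) == 2 for tr, _ in folds)
            if ok:
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate stratified split")
        proba = np.empty_like(y, dtype=float)
        for tr, te in folds:
            xtr, xte = _standardize(X[tr], X[te])
            model = _make_model(protocol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(xtr, y[tr])
            proba[te] = model.predict_proba(xte)[:, 1]
        rows.append({"repeat": rep, **compute_metrics(y, proba, protocol.threshold)})
    per_repeat = pd.DataFrame(rows)
    per_repeat.attrs["n_redraws"] = n_redraws
    panel = pd.DataFrame(
        {
            "mean": per_repeat[list(METRIC_NAMES)].mean(),
            "sd": per_repeat[list(METRIC_NAMES)].std(ddof=1)
            if protocol.repeats > 1
            else 0.0,
        }
    )
    return panel, per_repeat


def select_predictors(
    table: pd.DataFrame, exclude: list[str] | None = None
) -> list[str]:
    """All feature columns of a table minus an exclusion list."""
    cols = [c for c in feature_columns() if c in table.columns]
    if exclude:
        cols = [c for c in cols if c not in exclude]
    return cols


def standard_subsets(exclude: list[str] | None = None) -> dict[str, list[str]]:
    """The four canonical predictor subsets.

    1. SHG intensity (ICP mean + MAD) and pixel density.
    2. Subset 1 plus the five ICP texture features.
    3. Mean + MAD of all five polarimetric parameters plus pixel density.
    4. The complete predictor set (all features minus the exclusion list).
    """
    texture_stats = ("contrast", "correlation", "entropy", "asm", "idm")
    params = ("icp", "r_ratio", "dcp", "shg_cd", "shg_ld")
    s1 = ["icp_mean", "icp_mad", "pixel_density"]
    s2 = s1 + [f"icp_{t}" for t in texture_stats]
    s3 = [f"{p}_{s}" for p in params for s in ("mean", "mad")] + ["pixel_density"]
    s4 = [c for c in feature_columns() if not exclude or c not in exclude]
    return {"intensity_pd": s1, "intensity_pd_texture": s2, "all_params_pd": s3, "complete": s4}


def _drop_incomplete(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    complete = table.dropna(subset=cols)
    n_dropped = len(table) - len(complete)
    if n_dropped:
        complete = complete.copy()
        complete.attrs["n_dropped_rows"] = n_dropped
    return complete

def _encode_labels(labels: pd.Series, positive: str) -> np.ndarray:
    return (labels == positive).astype(int).to_numpy()


def subset_experiment(
    table: pd.DataFrame,
    protocol: CvProtocol,
    exclude: list[str] | None = None,
    positive_label: str = "tumor",
) -> dict[str, pd.DataFrame]:
    """Run the CV protocol on each canonical predictor subset.

    Returns a mapping subset name -> metric panel, in increasing subset
    order (intensity only ... complete predictor set).
    """
    out = {}
    for name, cols in standard_subsets(exclude).items():
        cols = [c for c in cols if c in table.columns]
        sub = _drop_incomplete(table, cols)
        X = sub[cols].to_numpy(dtype=float)
        y = _encode_labels(sub["label"], positive_label)
        panel, _ = fit_logistic_cv(X, y, protocol)
        out[name] = panel
    return out


def predict_held_out(
    table: pd.DataFrame,
    held_out_core_ids: list[str],
    feature_cols: list[str],
    threshold: float = 0.5,
    positive_label: str = "tumor",
    ridge_alpha: float = 0.0,
) -> dict:
    """Refit on all training cores and predict the held-out cores.

    The held-out cores must not appear in the training rows (enforced by
    ``core_id``).  Returns per-tile probabilities/labels, a tile-grid
    label map per held-out core, and the metric panel against the known
    labels.
    """
    held = set(held_out_core_ids)
    test = table[table["core_id"].isin(held)]
    train = table[~table["core_id"].isin(held)]
    if test.empty:
        raise ValueError("no rows for the held-out cores")
    if train["core_id"].isin(held).any():
        raise ValueError("held-out cores leaked into training rows")
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns not in table: {missing}")
    train = _drop_incomplete(train, feature_cols)
    test = _drop_incomplete(test, feature_cols)
    xtr, xte = _standardize(
        train[feature_cols].to_numpy(float), test[feature_cols].to_numpy(float)
    )
    ytr = _encode_labels(train["label"], positive_label)
    yte = _encode_labels(test["label"], positive_label)
    model = (
        LogisticRegression(penalty=None, max_iter=5000)
        if ridge_alpha == 0
        else LogisticRegression(penalty="l2", C=1.0 / ridge_alpha, max_iter=5000)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(xtr, ytr)
    proba = model.predict_proba(xte)[:, 1]
    pred = (proba >= threshold).astype(int)
    tiles = test[["core_id", "tile_row", "tile_col"]].copy()
    tiles["proba"] = proba
    tiles["pred"] = pred
    tiles["true"] = yte
    label_maps = {}
    for cid, sub in tiles.groupby("core_id"):
        n = int(max(sub["tile_row"].max(), sub["tile_col"].max())) + 1
        grid = np.full((n, n), -1, dtype=int)
        grid[sub["tile_row"].to_numpy(), sub["tile_col"].to_numpy()] = sub[
            "pred"
        ].to_numpy()
        label_maps[cid] = grid
    return {
        "tiles": tiles,
        "label_maps": label_maps,
        "metrics": compute_metrics(yte, proba, threshold),
    }


def subdivision_sweep(
    maps_by_core: dict[str, tuple[ParameterMaps, str]],
    levels: list[int],
    protocol: CvProtocol,
    exclude: list[str] | None = None,
    positive_label: str = "tumor",
    **table_kwargs,
) -> dict[int, pd.DataFrame]:
    """Metric panels across sub-image subdivision levels.

    Rebuilds the feature table at each ``tiles_per_side`` level and runs
    the CV protocol (use a reduced ``protocol.repeats`` for desk-scale
    sweeps).  The accuracy SD column across repeats is the stability
    measure: finer subdivisions give more samples and more stable panels.
    """
    out = {}
    for level in levels:
        tables = [
            build_feature_table(pm, cid, lab, tiles_per_side=level, **table_kwargs)
            for cid, (pm, lab) in maps_by_core.items()
        ]
        table = pd.concat(tables, ignore_index=True)
        cols = select_predictors(table, exclude)
        sub = _drop_incomplete(table, cols)
        X = sub[cols].to_numpy(float)
        y = _encode_labels(sub["label"], positive_label)
        panel, _ = fit_logistic_cv(X, y, protocol)
        out[level] = panel
    return out
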