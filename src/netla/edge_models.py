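"""Edge-level association estimates and prediction metrics.

Four estimation methods produce one scalar per connectome edge, later fed to
network-level enrichment:

``pearson``
    marginal Pearson correlation of each edge with age (a forward model);
``pearson_fs_lsvr``
    k-best marginal-correlation feature selection followed by linear support
    vector regression (LSVR); unselected edges carry weight 0;
``lsvr``
    raw LSVR weights on all edges (a backward model — not directly
    interpretable);
``lsvr_inverted``
    the forward pattern recovered from the LSVR by Haufe inversion: the
    covariance of each edge with the model's predicted age.

The LSVR tunes its L2 penalty parameter by nested k-fold cross-validation
inside each training set, minimizing mean validation MSE. Features are
z-scored with training-set statistics only (applied unchanged to test data),
so the penalty acts comparably across edges and no test information leaks
into the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVR

__all__ = [
    "METHODS",
    "LSVRConfig",
    "FeatureSelectionConfig",
    "EdgeWeightMap",
    "PredictionMetrics",
    "FittedLSVR",
    "pearson_edge_map",
    "kbest_select",
    "fit_lsvr",
    "haufe_invert",
    "evaluate_predictions",
    "icc21",
    "run_method",
    "MethodResult",
]

METHODS = ("pearson", "pearson_fs_lsvr", "lsvr", "lsvr_inverted")


@dataclass
class LSVRConfig:
    """LSVR hyperparameters. ``penalty_grid`` holds the candidate values of
    the tuned L2 penalty parameter (scikit-learn's ``C``); ties in inner-CV
    MSE resolve to the smaller value (stronger regularization)."""

    penalty_grid: tuple = tuple(np.logspace(-4, 2, 7))
    epsilon: float = 0.1
    max_iter: int = 5000
    tol: float = 1e-4

    def __post_init__(self):
        grid = tuple(float(c) for c in self.penalty_grid)
        if not grid or any(c <= 0 for c in grid):
            raise ValueError("penalty grid must be nonempty and positive")
        self.penalty_grid = tuple(sorted(grid))
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class FeatureSelectionConfig:
    """k-best marginal screening: keep the k edges with the largest absolute
    Pearson correlation with age in the training set."""

    k: int = 1000

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class EdgeWeightMap:
    """One scalar per edge from one estimation method.

    ``selected_mask`` is all-true except under feature selection, where
    unselected edges carry value 0 and mask False. ``repetition`` is the
    repetition index or the string ``"mean"`` for an across-repetition mean.
    """

    method: str
    values: np.ndarray
    selected_mask: np.ndarray | None = None
    repetition: int | str = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("weight map contains non-finite values")
        if self.method not in METHODS:
            raise ValueError(f"unknown method '{self.method}'")
        if self.selected_mask is None:
            self.selected_mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.selected_mask = np.asarray(self.selected_mask, dtype=bool)
            if self.selected_mask.shape != self.values.shape:
                raise ValueError("selected_mask must match values in shape")


@dataclass
class PredictionMetrics:
    """Accuracy of predicted vs actual ages for one evaluation set."""

    r: float
    mae: float  # years
    mse: float  # years^2
    n: int


def _standardize_columns(x: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
    return (x - mean) / sd, mean, sd


def pearson_edge_map(x: np.ndarray, y: np.ndarray, repetition=0) -> EdgeWeightMap:
    """Marginal Pearson correlation of every edge with age.

    Zero-variance edges get value 0 (and remain in the map so edge indexing
    stays aligned across methods).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if y.shape != (n,):
        raise ValueError("y must have one age per subject")
    sy = y.std(ddof=0)
    if sy == 0:
        raise ValueError("ages are constant; correlation undefined")
    xc = x - x.mean(axis=0)
    sx = x.std(axis=0, ddof=0)
    yc = (y - y.mean()) / sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (n * sx)
    r = np.where(sx == 0, 0.0, r)
    return EdgeWeightMap("pearson", np.clip(r, -1.0, 1.0), repetition=repetition)


def kbest_select(weight_map: EdgeWeightMap, k: int) -> np.ndarray:
    """Boolean mask of the k largest |values|; ties break to lower edge id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.abs(weight_map.values)
    e = values.shape[0]
    k_eff = min(k, e)
    # stable sort on -|v| keeps lower edge ids first among ties
    order = np.argsort(-values, kind="stable")
    mask = np.zeros(e, dtype=bool)
    mask[order[:k_eff]] = True
    return mask


@dataclass
class FittedLSVR:
    """A trained LSVR pipeline (train-set standardization + linear model).

    ``weights`` live in the standardized feature space; ``predict`` applies
    the stored standardization and the linear rule ``x @ w + b``.
    """

    weights: np.ndarray
    intercept: float
    penalty: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    inner_mse: np.ndarray | None = None  # grid x folds table

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_sd
        return xs @ self.weights + self.intercept


def _fit_linear_svr(xs, y, c, config) -> LinearSVR:
    model = LinearSVR(
        C=c,
        epsilon=config.epsilon,
        loss="epsilon_insensitive",
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=0,
    )
    model.fit(xs, y)
    return model


def fit_lsvr(
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: LSVRConfig,
    inner_folds=None,
) -> FittedLSVR:
    """Fit an LSVR with the penalty chosen by inner cross-validation.

    For each grid value the mean validation MSE over the inner folds is
    computed (inner standardization uses inner-train rows only); the penalty
    with minimal mean MSE wins, ties going to the smaller value. The final
    model is refit on the full training set.

    ``inner_folds`` holds (inner_train, validation) index pairs; indices are
    positions into ``x_train`` rows (absolute indices are remapped if they
    cover exactly the training rows). ``inner_folds=None`` skips tuning and
    uses the smallest grid value.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = x_train.shape[0]
    grid = config.penalty_grid

    inner_mse = None
    if inner_folds is not None and len(grid) > 1:
        folds = _as_local_folds(inner_folds, n)
        inner_mse = np.empty((len(grid), len(folds)))
        for fi, (tr, val) in enumerate(folds):
            xs_tr, mean, sd = _standardize_columns(x_train[tr])
            xs_val = (x_train[val] - mean) / sd
            for ci, c in enumerate(grid):
                model = _fit_linear_svr(xs_tr, y_train[tr], c, config)
                pred = xs_val @ model.coef_ + model.intercept_
                inner_mse[ci, fi] = np.mean((pred - y_train[val]) ** 2)
        mean_mse = inner_mse.mean(axis=1)
        chosen = grid[int(np.argmin(mean_mse))]  # argmin takes first = smallest C
    else:
        chosen = grid[0]

    xs, mean, sd = _standardize_columns(x_train)
    model = _fit_linear_svr(xs, y_train, chosen, config)
    return FittedLSVR(
        weights=np.asarray(model.coef_, dtype=float).ravel(),
        intercept=float(np.atleast_1d(model.intercept_)[0]),
        penalty=float(chosen),
        feature_mean=mean,
        feature_sd=sd,
        inner_mse=inner_mse,
    )


def _as_local_folds(folds, n):
    """Remap absolute dataset indices to local 0..n-1 row positions."""
    all_idx = np.sort(np.concatenate([np.concatenate([tr, val]) for tr, val in [folds[0]]]))
    if all_idx.size == n and all_idx[0] == 0 and all_idx[-1] == n - 1:
        return folds  # already local
    pos = {int(g): i for i, g in enumerate(all_idx)}
    remap = lambda a: np.array([pos[int(g)] for g in a], dtype=np.int64)
    return [(remap(tr), remap(val)) for tr, val in folds]


def haufe_invert(
    x_train: np.ndarray, y_hat_train: np.ndarray, repetition=0
) -> EdgeWeightMap:
    """Forward pattern from a backward model: cov(edge, predicted age).

    For a linear model the activation pattern is ``a = Sigma_x @ w`` up to a
    scalar; computing the sample covariance of each feature with the model's
    predictions realizes it without forming ``Sigma_x``.
    """
    x = np.asarray(x_train, dtype=float)
    y_hat = np.asarray(y_hat_train, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if y_hat.std(ddof=0) == 0:
        warnings.warn("constant predictions; inverted map is all zero")
        return EdgeWeightMap(
            "lsvr_inverted", np.zeros(x.shape[1]), repetition=repetition
        )
    cov = (x - x.mean(axis=0)).T @ (y_hat - y_hat.mean()) / (n - 1)
    return EdgeWeightMap("lsvr_inverted", cov, repetition=repetition)


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> PredictionMetrics:
    """Pearson r, MAE (years) and MSE (years^2, 1/n normalization)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between actual and predicted ages")
    n = y_true.shape[0]
    if n < 2:
        raise ValueError("need at least 2 predictions")
    err = y_pred - y_true
    if y_true.std() == 0 or y_pred.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return PredictionMetrics(
        r=r, mae=float(np.mean(np.abs(err))), mse=float(np.mean(err**2)), n=n
    )


def icc21(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n x k matrix (here k=2: predicted ages from the two
    cross-day models). From the two-way ANOVA decomposition::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be n x k with k >= 2")
    n, k = ratings.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_total = np.sum((ratings - grand) ** 2)
    if ss_total == 0:
        raise ValueError("zero total variance; ICC undefined")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("degenerate variance decomposition; ICC undefined")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Per-method resampled pipeline


@dataclass
class MethodResult:
    """Everything one estimation method produces over the resampling runs."""

    method: str
    mean_map_day1: EdgeWeightMap
    mean_map_day2: EdgeWeightMap
    metrics_day1: list  # within-day PredictionMetrics per repetition
    metrics_day2: list
    metrics_cross: list  # averaged cross-day r per repetition
    icc: float | None
    strong_counts: np.ndarray | None = None  # per-edge |Z|>thr tallies, 2J masks
    n_masks: int = 0

    def mean_r(self, which: str = "test") -> dict:
        out = {}
        for name, ms in (
            ("day1", self.metrics_day1),
            ("day2", self.metrics_day2),
        ):
            rs = np.array([m.r for m in ms])
            out[name] = (float(rs.mean()), float(rs.std(ddof=1))) if rs.size else None
        rs = np.array(self.metrics_cross)
        out["cross"] = (float(rs.mean()), float(rs.std(ddof=1))) if rs.size else None
        return out


def _fit_one(x_tr, y_tr, method, folds, lsvr_config, fs_config, repetition):
    """Fit one repetition of one method; returns (weight map, predictor)."""
    if method == "pearson":
        # forward model: association map only, no predictor
        return pearson_edge_map(x_tr, y_tr, repetition=repetition), None
    if method == "pearson_fs_lsvr":
        marg = pearson_edge_map(x_tr, y_tr, repetition=repetition)
        mask = kbest_select(marg, fs_config.k)
        model = fit_lsvr(x_tr[:, mask], y_tr, lsvr_config, folds)
        values = np.zeros(marg.values.shape[0])
        values[mask] = model.weights
        wmap = EdgeWeightMap(
            "pearson_fs_lsvr", values, selected_mask=mask, repetition=repetition
        )
        return wmap, ("masked", model, mask)
    if method in ("lsvr", "lsvr_inverted"):
        model = fit_lsvr(x_tr, y_tr, lsvr_config, folds)
        if method == "lsvr":
            wmap = EdgeWeightMap("lsvr", model.weights, repetition=repetition)
        else:
            y_hat = model.predict(x_tr)
            wmap = haufe_invert(x_tr, y_hat, repetition=repetition)
        return wmap, ("full", model, None)
    raise ValueError(f"unknown method '{method}'")


def _predict(predictor, x):
    kind, model, mask = predictor
    if kind == "masked":
        return model.predict(x[:, mask])
    return model.predict(x)


def run_method(
    dataset_day1,
    dataset_day2,
    method: str,
    splits_day1,
    splits_day2,
    lsvr_config: LSVRConfig | None = None,
    fs_config: FeatureSelectionConfig | None = None,
    z_threshold: float | None = 2.0,
) -> MethodResult:
    """Run one estimation method over paired two-day resampling repetitions.

    Per repetition and day the model is fit on that day's training subjects;
    prediction accuracy is evaluated within-day on the held-out test set and
    cross-day on the other day's test subjects. Weight maps are averaged
    across repetitions (the enrichment input); per-repetition |Z|-thresholded
    masks are tallied for the overlap-percentage matrix; cross-day prediction
    pairs pooled over repetitions yield the test-retest ICC(2,1).

    ``pearson`` is a forward model with no predictor, so its accuracy
    metrics and ICC are empty; its weight maps and overlap tallies are still
    produced.
    """
    from .enrichment import zscore_binarize  # local import, no cycle at load

    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'")
    if len(splits_day1) != len(splits_day2):
        raise ValueError("need the same number of repetitions for both days")
    if dataset_day1.n_subjects != dataset_day2.n_subjects:
        raise ValueError("the two days must share subjects")
    lsvr_config = lsvr_config or LSVRConfig()
    fs_config = fs_config or FeatureSelectionConfig()

    e_count = dataset_day1.edge_count
    sum_maps = {1: np.zeros(e_count), 2: np.zeros(e_count)}
    sel_counts = {1: np.zeros(e_count, dtype=np.int64), 2: np.zeros(e_count, dtype=np.int64)}
    strong_counts = np.zeros(e_count) if z_threshold is not None else None
    n_masks = 0
    metrics = {1: [], 2: []}
    cross_r = []
    icc_pairs = []

    datasets = {1: dataset_day1, 2: dataset_day2}
    for plan1, plan2 in zip(splits_day1, splits_day2):
        plans = {1: plan1, 2: plan2}
        fits = {}
        for day in (1, 2):
            ds, plan = datasets[day], plans[day]
            x_tr, y_tr = ds.edges[plan.train], ds.ages[plan.train]
            wmap, predictor = _fit_one(
                x_tr, y_tr, method, plan.inner_folds, lsvr_config, fs_config,
                plan.repetition,
            )
            sum_maps[day] += wmap.values
            sel_counts[day] += wmap.selected_mask
            if strong_counts is not None:
                try:
                    strong_counts += zscore_binarize(wmap, z_threshold)
                    n_masks += 1
                except ValueError:
                    pass  # degenerate map contributes no mask
            fits[day] = predictor

        if fits[1] is not None:
            cross_day_r = []
            for day, other in ((1, 2), (2, 1)):
                ds, plan = datasets[day], plans[day]
                pred = _predict(fits[day], ds.edges[plan.test])
                metrics[day].append(evaluate_predictions(ds.ages[plan.test], pred))
                # cross-day: model from `day` applied to the other day's data
                ds_o, plan_o = datasets[other], plans[other]
                pred_o = _predict(fits[day], ds_o.edges[plan_o.test])
                cross_day_r.append(
                    evaluate_predictions(ds_o.ages[plan_o.test], pred_o).r
                )
            cross_r.append(float(np.mean(cross_day_r)))

            common = np.intersect1d(plans[1].test, plans[2].test)
            if common.size:
                p_from_1 = _predict(fits[1], datasets[2].edges[common])
                p_from_2 = _predict(fits[2], datasets[1].edges[common])
                icc_pairs.append(np.column_stack([p_from_1, p_from_2]))

    j = len(splits_day1)
    icc = None
    if icc_pairs:
        pooled = np.vstack(icc_pairs)
        if pooled.shape[0] >= 3:
            try:
                icc = icc21(pooled)
            except ValueError:
                icc = None
    return MethodResult(
        method=method,
        mean_map_day1=EdgeWeightMap(
            method, sum_maps[1] / j, selected_mask=sel_counts[1] > 0,
            repetition="mean",
        ),
        mean_map_day2=EdgeWeightMap(
            method, sum_maps[2] / j, selected_mask=sel_counts[2] > 0,
            repetition="mean",
        ),
        metrics_day1=metrics[1],
        metrics_day2=metrics[2],
        metrics_cross=cross_r,
        icc=icc,
        strong_counts=strong_counts,
        n_masks=n_masks,
    )
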