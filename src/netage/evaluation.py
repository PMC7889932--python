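"""Statistical machinery for comparing age descriptors.

Task-prediction models regress the 4-area task descriptor (fractions per
bee-day, weighted by the number of in-area samples) on a feature such as
network age or biological age, under a multinomial (softmax link) or
per-area binomial (sigmoid link) likelihood; scalar behavioral targets use
a Gaussian model. Goodness of fit is McFadden's pseudo R^2,
R^2_McF = 1 - l1/l0 on log-likelihoods (R^2 for Gaussian targets).

Model comparisons use bootstrapped CIs of the paired score difference and
likelihood-ratio chi^2 tests for nested models. The future-prediction
protocol fits the factor-to-network-age map and the task model on a 12-day
training window only and evaluates 1-11 days past the window against a
persistence null (the current-day prediction carried forward), with a
paired binomial test on per-row squared-error improvements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from scipy.stats import binomtest, chi2

from .model import DESCRIPTOR_COLUMNS, fit_cca_map, robust_scale

# ---------------------------------------------------------------------------
# likelihood models


@dataclass
class ModelFit:
    """A fitted task/behavior model with its null for pseudo-R^2 and LRT."""

    family: str
    model_class: str
    loglik: float
    null_loglik: float
    n_rows: int
    n_params: int
    params: object = field(repr=False, default=None)
    predict: object = field(repr=False, default=None)

    @property
    def score(self) -> float:
        """McFadden pseudo-R^2 (or R^2 for the gaussian family)."""
        return mcfadden_r2(self.loglik, self.null_loglik)


def mcfadden_r2(l1: float, l0: float) -> float:
    """1 - l1/l0 on log-likelihoods."""
    if l0 == 0:
        return 0.0
    return 1.0 - l1 / l0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xlogy(x, y):
    out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y)))
    mask = np.asarray(x) != 0
    np.log(y, out=out, where=mask)
    return np.asarray(x) * out


def _multinomial_ll(Y, P, w):
    return float(np.sum(w[:, None] * _xlogy(Y, P)))


def _fit_softmax(X: np.ndarray, Y: np.ndarray, w: np.ndarray
                 ) -> tuple[np.ndarray, float]:
    """Weighted fractional multinomial regression; reference-class coding."""
    n, p = X.shape
    A = Y.shape[1]

    def unpack(theta):
        B = np.zeros((p, A))
        B[:, :A - 1] = theta.reshape(p, A - 1)
        return B

    def objective(theta):
        B = unpack(theta)
        P = _softmax(X @ B)
        ll = _multinomial_ll(Y, P, w)
        G = X.T @ (w[:, None] * (P - Y))
        return -ll, G[:, :A - 1].ravel()

    res = minimize(objective, np.zeros(p * (A - 1)), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    B = unpack(res.x)
    return B, -res.fun


def _fit_logistic_fractional(X: np.ndarray, y: np.ndarray, w: np.ndarray
                             ) -> tuple[np.ndarray, float]:
    """Weighted binomial regression with fractional outcomes."""
    def objective(beta):
        z = X @ beta
        p = 1.0 / (1.0 + np.exp(-z))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w * (_xlogy(y, p) + _xlogy(1 - y, 1 - p))))
        g = X.T @ (w * (p - y))
        return -ll, g

    res = minimize(objective, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    return res.x, -res.fun


def _gaussian_ll(y: np.ndarray, pred: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    sigma2 = float(np.sum(w * (y - pred) ** 2) / wsum)
    sigma2 = max(sigma2, 1e-300)
    return float(-0.5 * wsum * (np.log(2 * np.pi * sigma2) + 1.0))


# ---- small neural network (2 fully connected layers, tanh hidden) ---------


def _fit_small_nn(X: np.ndarray, Y: np.ndarray, w: np.ndarray, family: str,
                  hidden: int = 8, seed: int = 0):
    """Full-batch L-BFGS fit of a 1-hidden-layer (width 8, tanh) network."""
    n, p = X.shape
    A = Y.shape[1]
    rng = np.random.default_rng(seed)
    sizes = [(p, hidden), (hidden,), (hidden, A), (A,)]
    theta0 = np.concatenate([0.1 * rng.standard_normal(np.prod(s)) for s in sizes])

    def unpack(theta):
        parts, off = [], 0
        for s in sizes:
            k = int(np.prod(s))
            parts.append(theta[off:off + k].reshape(s))
            off += k
        return parts

    def forward(theta):
        W1, b1, W2, b2 = unpack(theta)
        H = np.tanh(X @ W1 + b1)
        Z = H @ W2 + b2
        return W1, b1, W2, b2, H, Z

    def objective(theta):
        W1, b1, W2, b2, H, Z = forward(theta)
        if family == "multinomial":
            P = _softmax(Z)
            loss = -_multinomial_ll(Y, P, w)
            dZ = w[:, None] * (P - Y)
        elif family == "binomial":
            P = np.clip(1.0 / (1.0 + np.exp(-Z)), 1e-12, 1 - 1e-12)
            loss = -float(np.sum(w[:, None] * (_xlogy(Y, P) + _xlogy(1 - Y, 1 - P))))
            dZ = w[:, None] * (P - Y)
        else:  # gaussian: least squares, likelihood profiled afterwards
            loss = 0.5 * float(np.sum(w[:, None] * (Z - Y) ** 2))
            dZ = w[:, None] * (Z - Y)
        dW2 = H.T @ dZ
        db2 = dZ.sum(axis=0)
        dH = dZ @ W2.T
        dZ1 = dH * (1 - H ** 2)
        dW1 = X.T @ dZ1
        db1 = dZ1.sum(axis=0)
        grad = np.concatenate([dW1.ravel(), db1, dW2.ravel(), db2])
        return loss, grad

    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    theta = res.x

    def predict(Xn):
        W1, b1, W2, b2 = unpack(theta)
        Z = np.tanh(Xn @ W1 + b1) @ W2 + b2
        if family == "multinomial":
            return _softmax(Z)
        if family == "binomial":
            return 1.0 / (1.0 + np.exp(-Z))
        return Z

    return theta, predict


# ---------------------------------------------------------------------------
# fit_task_model


def fit_task_model(features: pd.DataFrame, descriptor: pd.DataFrame,
                   family: str = "multinomial", model_class: str = "linear",
                   area: str | None = None, weight_col: str = "n_samples",
                   seed: int = 0) -> ModelFit:
    """Fit a task/behavior prediction model and its intercept-only null.

    ``features`` holds ``bee_id, day`` plus one or more feature columns;
    rows are matched to ``descriptor`` on (bee_id, day). Families:

    * ``multinomial`` — joint softmax model of the 4 area fractions,
      weighted per row by ``n_samples`` (fractional counts);
    * ``binomial`` — sigmoid model of a single area's fraction (``area``);
    * ``gaussian`` — identity-link model of a scalar column named by
      ``area``, for behavior-related targets.

    ``model_class`` is ``linear`` (GLM) or ``small_nn`` (two fully connected
    layers, hidden width 8, tanh).
    """
    feat_cols = [c for c in features.columns if c not in ("bee_id", "day")]
    merged = features.merge(descriptor, on=["bee_id", "day"], how="inner").dropna(
        subset=feat_cols)
    if family == "multinomial":
        Y = merged[DESCRIPTOR_COLUMNS].to_numpy(dtype=float)
        if not np.allclose(Y.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("multinomial rows must sum to 1")
        target_cols = DESCRIPTOR_COLUMNS
    else:
        if area is None:
            raise ValueError(f"{family} family requires the target column name")
        Y = merged[[area]].to_numpy(dtype=float)
        target_cols = [area]
    mask = np.all(np.isfinite(Y), axis=1)
    merged, Y = merged[mask], Y[mask]
    Xf = merged[feat_cols].to_numpy(dtype=float)
    w = (merged[weight_col].to_numpy(dtype=float)
         if weight_col and weight_col in merged.columns else np.ones(len(merged)))
    n = len(merged)

    # null: intercept only (closed form for every family)
    if family == "multinomial":
        p0 = np.average(Y, axis=0, weights=w)
        l0 = _multinomial_ll(Y, np.tile(p0, (n, 1)), w)
    elif family == "binomial":
        p0 = float(np.average(Y[:, 0], weights=w))
        p0 = min(max(p0, 1e-12), 1 - 1e-12)
        l0 = float(np.sum(w * (_xlogy(Y[:, 0], p0) + _xlogy(1 - Y[:, 0], 1 - p0))))
    else:
        mu0 = float(np.average(Y[:, 0], weights=w))
        l0 = _gaussian_ll(Y[:, 0], np.full(n, mu0), w)

    if model_class == "linear":
        X = np.column_stack([np.ones(n), Xf])
        if family == "multinomial":
            B, l1 = _fit_softmax(X, Y, w)
            n_params = X.shape[1] * (Y.shape[1] - 1)
            def predict(Xnew):
                return _softmax(np.column_stack([np.ones(len(Xnew)), Xnew]) @ B)
            params = B
        elif family == "binomial":
            beta, l1 = _fit_logistic_fractional(X, Y[:, 0], w)
            n_params = X.shape[1]
            def predict(Xnew):
                z = np.column_stack([np.ones(len(Xnew)), Xnew]) @ beta
                return 1.0 / (1.0 + np.exp(-z))
            params = beta
        else:
            beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                                       Y[:, 0] * np.sqrt(w), rcond=None)
            pred = X @ beta
            l1 = _gaussian_ll(Y[:, 0], pred, w)
            n_params = X.shape[1]
            def predict(Xnew):
                return np.column_stack([np.ones(len(Xnew)), Xnew]) @ beta
            params = beta
    elif model_class == "small_nn":
        theta, nn_predict = _fit_small_nn(Xf, Y, w, family, seed=seed)
        if family == "gaussian":
            l1 = _gaussian_ll(Y[:, 0], nn_predict(Xf)[:, 0], w)
        elif family == "multinomial":
            l1 = _multinomial_ll(Y, nn_predict(Xf), w)
        else:
            P = nn_predict(Xf)
            l1 = float(np.sum(w[:, None] * (_xlogy(Y, P) + _xlogy(1 - Y, 1 - P))))
        n_params = theta.size
        params = theta
        def predict(Xnew):
            out = nn_predict(np.asarray(Xnew, dtype=float))
            return out[:, 0] if family != "multinomial" else out
    else:
        raise ValueError(f"unknown model_class {model_class!r}")
    if not np.isfinite(l1):
        raise ValueError("non-finite likelihood")

    if family == "gaussian":
        # report the standard coefficient of determination for scalar targets
        pred = predict(Xf)
        pred = pred if pred.ndim == 1 else pred[:, 0]
        sst = float(np.sum(w * (Y[:, 0] - np.average(Y[:, 0], weights=w)) ** 2))
        sse = float(np.sum(w * (Y[:, 0] - pred) ** 2))
        fit = ModelFit(family=family, model_class=model_class, loglik=l1,
                       null_loglik=l0, n_rows=n, n_params=n_params,
                       params=params, predict=predict)
        fit.r2 = 1.0 - sse / sst if sst > 0 else 0.0
        return fit
    return ModelFit(family=family, model_class=model_class, loglik=l1,
                    null_loglik=l0, n_rows=n, n_params=n_params,
                    params=params, predict=predict)


def model_score(fit: ModelFit) -> float:
    return getattr(fit, "r2", None) if fit.family == "gaussian" else fit.score


# ---------------------------------------------------------------------------
# bootstrap and LRT


def bootstrap_effect_ci(features_a: pd.DataFrame, features_b: pd.DataFrame,
                        descriptor: pd.DataFrame, n_boot: int = 128,
                        level: float = 95.0, family: str = "multinomial",
                        model_class: str = "linear", area: str | None = None,
                        seed: int = 0, block_by_bee: bool = False) -> dict:
    """Percentile CI of the paired score difference score(a) - score(b).

    Resamples (bee, day) rows with replacement (or whole bees when
    ``block_by_bee``), refits both models per replicate, and returns the
    two-sided CI of the score difference; the effect is significant when 0
    lies outside the CI.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rows = features_a[["bee_id", "day"]].merge(
        features_b[["bee_id", "day"]], on=["bee_id", "day"]).merge(
        descriptor[["bee_id", "day"]], on=["bee_id", "day"])
    fa = features_a.merge(rows, on=["bee_id", "day"]).reset_index(drop=True)
    fb = features_b.merge(rows, on=["bee_id", "day"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    bees = rows["bee_id"].unique()
    for i in range(n_boot):
        if block_by_bee:
            chosen = rng.choice(bees, size=bees.size, replace=True)
            idx = np.concatenate([np.flatnonzero(fa["bee_id"].to_numpy() == b)
                                  for b in chosen])
        else:
            idx = rng.integers(0, len(fa), len(fa))
        sub_a = fa.iloc[idx].reset_index(drop=True)
        sub_b = fb.iloc[idx].reset_index(drop=True)
        fit_a = fit_task_model(sub_a, descriptor, family=family,
                               model_class=model_class, area=area, seed=seed + i)
        fit_b = fit_task_model(sub_b, descriptor, family=family,
                               model_class=model_class, area=area, seed=seed + i)
        diffs[i] = model_score(fit_a) - model_score(fit_b)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(diffs, [alpha, 100.0 - alpha])
    return {"diffs": diffs, "ci": (float(lo), float(hi)),
            "median": float(np.median(diffs)),
            "significant": bool(lo > 0 or hi < 0)}


def likelihood_ratio_test(l0: float, l1: float, df: int) -> tuple[float, float]:
    """LR = 2(l1 - l0) on log-likelihoods; p from the chi^2 upper tail."""
    if l1 < l0 - 1e-9:
        raise ValueError("l1 < l0: models are not nested or the larger fit "
                         "did not converge")
    lr = max(0.0, 2.0 * (l1 - l0))
    return lr, float(chi2.sf(lr, df))


# ---------------------------------------------------------------------------
# future prediction


@dataclass
class FuturePredictionResult:
    """Per-window scores of the fitted model vs. the persistence null."""

    train_len: int
    windows: pd.DataFrame  # train_start, horizon, n, n_model_better, p, mse_model, mse_null

    def pooled_test(self, horizon: int, alternative: str = "greater"):
        """Binomial test pooled over windows at one horizon."""
        sub = self.windows[self.windows["horizon"] == horizon]
        k = int(sub["n_model_better"].sum())
        n = int(sub["n"].sum())
        return binomtest(k, n, 0.5, alternative=alternative)


def future_prediction(factors: pd.DataFrame, descriptors: pd.DataFrame,
                      train_len: int = 12, horizons=range(1, 12),
                      k: int = 3) -> FuturePredictionResult:
    """Train the network-age map and task model on a sliding 12-day window
    and predict task allocation 1-11 days past the window.

    For each window the factor-to-network-age CCA map and the multinomial
    task model are fitted on the train days only; the map is then applied to
    the held-out day's factors (spectral factors are per-day, so nothing
    leaks from the future). The persistence null carries the prediction for
    the last train day forward to the evaluation day. Rows are bees present
    on both days; the paired binomial test counts rows where the model's
    squared error beats the null's.
    """
    horizons = list(horizons)
    if min(horizons) < 1:
        raise ValueError("horizons must be >= 1 (no peeking at the train window)")
    days = sorted(factors["day"].unique())
    rows = []
    for start_idx in range(0, len(days) - train_len - min(horizons) + 1):
        train_days = days[start_idx:start_idx + train_len]
        train_end = train_days[-1]
        train_factors = factors[factors["day"].isin(train_days)]
        train_desc = descriptors[descriptors["day"].isin(train_days)]
        try:
            nmap = fit_cca_map(train_factors, train_desc, k=k)
        except ValueError:
            continue
        na_all = robust_scale(nmap.transform(factors))[["bee_id", "day", "network_age"]]
        train_na = na_all[na_all["day"].isin(train_days)]
        task_fit = fit_task_model(train_na, train_desc, family="multinomial")

        cur = na_all[na_all["day"] == train_end].set_index("bee_id")["network_age"]
        cur_pred = pd.DataFrame(task_fit.predict(cur.to_numpy()[:, None]),
                                index=cur.index, columns=DESCRIPTOR_COLUMNS)
        for h in horizons:
            eval_idx = start_idx + train_len - 1 + h
            if eval_idx >= len(days):
                continue
            eval_day = days[eval_idx]
            assert eval_day > train_end, "evaluation day must follow the train window"
            truth = descriptors[descriptors["day"] == eval_day].set_index("bee_id")
            na_eval = na_all[na_all["day"] == eval_day].set_index("bee_id")
            shared = truth.index.intersection(na_eval.index).intersection(cur_pred.index)
            if len(shared) == 0:
                continue
            Yt = truth.loc[shared, DESCRIPTOR_COLUMNS].to_numpy(dtype=float)
            pred_model = task_fit.predict(
                na_eval.loc[shared, "network_age"].to_numpy()[:, None])
            pred_null = cur_pred.loc[shared].to_numpy(dtype=float)
            err_model = np.sum((pred_model - Yt) ** 2, axis=1)
            err_null = np.sum((pred_null - Yt) ** 2, axis=1)
            better = int(np.sum(err_model < err_null))
            n = int(len(shared))
            p = binomtest(better, n, 0.5, alternative="greater").pvalue
            rows.append((train_days[0], h, n, better, p,
                         float(err_model.mean()), float(err_null.mean())))
    windows = pd.DataFrame(rows, columns=["train_start", "horizon", "n",
                                          "n_model_better", "p",
                                          "mse_model", "mse_null"])
    return FuturePredictionResult(train_len=train_len, windows=windows)


# ---------------------------------------------------------------------------
# repeatability


def repeatability(series: pd.DataFrame, ages: pd.DataFrame, bee,
                  age_span: float = 1.0) -> dict:
    """R = Var_p / (Var_i + Var_p) for one bee.

    Var_i is the bee's across-day network-age variance; Var_p is the
    variance of the daily mean network age of an age-matched control group
    (all bees within ``age_span`` days of the focal bee's biological age,
    on the days the focal bee was observed). R near 1 means individual
    variation is small relative to population variation.
    """
    data = series.merge(ages, on=["bee_id", "day"], how="inner")
    focal = data[data["bee_id"] == bee]
    if len(focal) < 2:
        raise ValueError("need >= 2 observed days for the focal bee")
    control_means = []
    for row in focal.itertuples(index=False):
        ctrl = data[(data["day"] == row.day)
                    & (np.abs(data["age"] - row.age) <= age_span)]
        if len(ctrl):
            control_means.append(ctrl["network_age"].mean())
    if not control_means:
        raise ValueError("empty control group")
    var_i = float(focal["network_age"].var(ddof=1))
    var_p = float(np.var(control_means, ddof=1)) if len(control_means) > 1 else 0.0
    denom = var_i + var_p
    return {"bee_id": bee, "var_i": var_i, "var_p": var_p,
            "R": var_p / denom if denom > 0 else np.nan}


def repeatability_all(series: pd.DataFrame, ages: pd.DataFrame,
                      age_span: float = 1.0, min_days: int = 2) -> pd.DataFrame:
    counts = series.groupby("bee_id")["day"].nunique()
    rows = []
    for bee in counts[counts >= min_days].index:
        try:
            rows.append(repeatability(series, ages, bee, age_span))
        except ValueError:
            continue
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# developmental trajectory clustering and the bimodal mode split


def cluster_trajectories(series: pd.DataFrame, k: int = 3) -> pd.Series:
    """Ward clustering of per-bee network-age trajectories.

    Each bee's feature vector holds its daily network ages over the pooled
    day range, with linear inter-/extrapolation of missing values; Euclidean
    distances and Ward agglomeration, cut at k clusters. Bees need >= 2
    observations. Returns bee_id -> cluster label (1..k).
    """
    wide = series.pivot_table(index="bee_id", columns="day", values="network_age")
    wide = wide[wide.notna().sum(axis=1) >= 2]
    if k > len(wide):
        raise ValueError(f"k={k} exceeds the {len(wide)} clusterable bees")
    days = wide.columns.to_numpy(dtype=float)
    X = np.empty(wide.shape)
    for i, (_, row) in enumerate(wide.iterrows()):
        vals = row.to_numpy(dtype=float)
        obs = np.isfinite(vals)
        interp = np.interp(days, days[obs], vals[obs])
        # np.interp clamps outside the observed range; extrapolate linearly
        # from the two nearest observations instead
        lo, hi = np.flatnonzero(obs)[[0, -1]]
        if lo > 0:
            slope = _edge_slope(days, vals, obs, side="left")
            interp[:lo] = vals[lo] + slope * (days[:lo] - days[lo])
        if hi < len(days) - 1:
            slope = _edge_slope(days, vals, obs, side="right")
            interp[hi + 1:] = vals[hi] + slope * (days[hi + 1:] - days[hi])
        X[i] = interp
    labels = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=wide.index, name="cluster")


def _edge_slope(days, vals, obs, side: str) -> float:
    idx = np.flatnonzero(obs)
    if idx.size < 2:
        return 0.0
    a, b = (idx[0], idx[1]) if side == "left" else (idx[-2], idx[-1])
    return (vals[b] - vals[a]) / (days[b] - days[a])


def two_means_1d(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact 2-means in one dimension by scanning sorted split points.

    Returns (boolean upper-cluster assignment, separation score). The
    separation score is the between-cluster sum of squares divided by the
    total, in [0, 1]; a configurable criterion on it flags days whose
    distribution is actually bimodal.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need >= 2 values")
    order = np.argsort(v, kind="mergesort")
    s = v[order]
    cum = np.cumsum(s)
    total = cum[-1]
    k = np.arange(1, n)
    mean_l = cum[:-1] / k
    mean_r = (total - cum[:-1]) / (n - k)
    # minimizing within-class SSE == maximizing weighted between-class spread
    between = k * (n - k) / n * (mean_l - mean_r) ** 2
    split = int(np.argmax(between))
    upper_sorted = np.zeros(n, dtype=bool)
    upper_sorted[split + 1:] = True
    upper = np.empty(n, dtype=bool)
    upper[order] = upper_sorted
    sst = float(np.sum((v - v.mean()) ** 2))
    sep = float(between[split] / sst) if sst > 0 else 0.0
    return upper, sep


def mode_split(series: pd.DataFrame, ages: pd.DataFrame, young_age_max: float = 6,
               min_separation: float = 0.0) -> pd.DataFrame:
    """Per-day 2-means split of the network-age distribution, and the first
    biological age at which each (initially young) bee joins the upper mode.

    Bees observed at least once below ``young_age_max`` days of biological
    age are followed; bees never assigned to the upper mode are reported
    with a missing ``first_upper_age``. Days whose 2-means separation score
    falls below ``min_separation`` are skipped (unimodal days).
    """
    data = series.merge(ages, on=["bee_id", "day"], how="inner")
    assignments = []
    for day, grp in data.groupby("day"):
        if len(grp) < 2:
            continue
        upper, sep = two_means_1d(grp["network_age"].to_numpy())
        if sep < min_separation:
            continue
        assignments.append(grp.assign(upper=upper))
    assigned = pd.concat(assignments, ignore_index=True)
    # the followed cohort is defined by all observations, including days
    # whose distribution was not bimodal enough to assign modes on
    young = data.groupby("bee_id")["age"].min()
    followed = young[young < young_age_max].index
    rows = []
    for bee in followed:
        bee_rows = assigned[(assigned["bee_id"] == bee) & assigned["upper"]]
        first = float(bee_rows["age"].min()) if len(bee_rows) else np.nan
        rows.append((bee, first))
    return pd.DataFrame(rows, columns=["bee_id", "first_upper_age"])
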