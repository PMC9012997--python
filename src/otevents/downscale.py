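"""Station-level logistic downscaling models of compound o-t-events.

Daily event occurrence (binary) is modeled on standardized meteorological
predictors (GH, MT, SH, SSRD) plus the standardized numeric weather-type
code.  Because events are the minority class, training data are
rebalanced with SMOTE before fitting; predictors are then pruned by Wald
backward elimination at the 5% level, drivers are ranked by the absolute
standardized coefficient (MID / SMID / TMID), and the probability
threshold is calibrated in an upstream tenfold cross-validation to the
point where precision and recall are closest.  Model evaluation wraps all
of this in an outer stratified tenfold cross-validation so that no
synthetic sample ever reaches a validation fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

PREDICTOR_ORDER = ("GH", "MT", "SH", "SSRD", "WT")


@dataclass
class LogisticModel:
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    converged: bool
    separation_flag: bool
    log_likelihood: float
    elimination_trace: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def retained(self) -> list[str]:
        return list(self.coefficients)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.retained if c not in X.columns]
        if missing:
            raise ValueError(f"predictors missing from input: {missing}")
        eta = np.full(len(X), self.intercept, dtype=float)
        for c in self.retained:
            eta += self.coefficients[c] * X[c].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class DriverRanking:
    mid: str | None
    smid: str | None
    tmid: str | None
    coefficients: dict[str, float]


@dataclass
class PerformanceReport:
    precision: float
    recall: float
    f1: float
    mcfadden_r2: float
    threshold: float
    events_per_variable: float
    per_fold: pd.DataFrame


def smote(
    X: np.ndarray, y: np.ndarray, *, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic sample is a uniform convex combination of a randomly
    chosen minority sample and one of its ``k_neighbors`` nearest minority
    neighbors (Euclidean).  Originals are preserved; already balanced
    input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    if len(Xm) < k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(Xm)} samples; needs > k_neighbors={k_neighbors}"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # first neighbor is the point itself
    base = rng.integers(0, len(Xm), size=n_needed)
    pick = rng.integers(1, k_neighbors + 1, size=n_needed)
    lam = rng.uniform(0.0, 1.0, size=n_needed)
    neigh = idx[base, pick]
    synth = Xm[base] + lam[:, None] * (Xm[neigh] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out


def fit_logistic(X: pd.DataFrame, y: np.ndarray, *, maxiter: int = 100) -> LogisticModel:
    """Maximum-likelihood logit fit (unpenalized) with Wald inference.

    Standard errors come from the observed information matrix.  Perfect or
    quasi-perfect separation is flagged and the capped-iteration fit
    returned with a warning rather than an exception, keeping coefficients
    interpretable.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const", *X.columns]
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, method="newton")
        except Exception:
            separation = True
            res = sm.Logit(y, design).fit(
                disp=0, maxiter=maxiter, method="bfgs", warn_convergence=False
            )
        for w in caught:
            if "separa" in str(w.message).lower():
                separation = True
    if separation:
        warnings.warn("possible separation in logistic fit", stacklevel=2)
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))
    return LogisticModel(
        intercept=params.pop("const"),
        coefficients={k: float(v) for k, v in params.items()},
        standard_errors={k: float(bse[k]) for k in params},
        p_values={k: float(pvals[k]) for k in params},
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation,
        log_likelihood=float(res.llf),
    )


def backward_eliminate(
    X: pd.DataFrame, y: np.ndarray, *, alpha: float = 0.05
) -> LogisticModel:
    """Wald backward elimination at significance level ``alpha``.

    Iteratively refit after dropping the single predictor with the
    largest p-value above alpha until all retained predictors are
    significant.  The intercept is never dropped.  If everything is
    eliminated, an intercept-only model is returned with the degenerate
    flag set.
    """
    cols = list(X.columns)
    trace: list[str] = []
    while cols:
        model = fit_logistic(X[cols], y)
        worst = max(cols, key=lambda c: model.p_values[c])
        if model.p_values[worst] <= alpha or np.isnan(model.p_values[worst]):
            model.elimination_trace = trace
            return model
        trace.append(worst)
        cols.remove(worst)
    # intercept-only fallback
    p = float(np.mean(y))
    p = min(max(p, 1e-12), 1 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    model = LogisticModel(
        intercept=float(np.log(p / (1 - p))),
        coefficients={},
        standard_errors={},
        p_values={},
        converged=True,
        separation_flag=False,
        log_likelihood=ll,
        elimination_trace=trace,
        degenerate=True,
    )
    return model


def rank_drivers(model: LogisticModel) -> DriverRanking:
    """Rank retained predictors by |standardized coefficient|.

    The top three are the most / second / third most important drivers
    (MID, SMID, TMID); ties follow the fixed column order GH, MT, SH,
    SSRD, WT.  Signs are preserved in the reported coefficients.
    """
    def order_key(name: str):
        fixed = (
            PREDICTOR_ORDER.index(name) if name in PREDICTOR_ORDER else len(PREDICTOR_ORDER)
        )
        return (-abs(model.coefficients[name]), fixed, name)

    ranked = sorted(model.coefficients, key=order_key)
    top = ranked + [None, None, None]
    return DriverRanking(
        mid=top[0], smid=top[1], tmid=top[2],
        coefficients=dict(model.coefficients),
    )


def mcfadden_r2(model: LogisticModel, y: np.ndarray) -> float:
    """McFadden pseudo-R^2: 1 - lnL(model) / lnL(intercept-only null)."""
    y = np.asarray(y, dtype=float)
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        raise ValueError("degenerate outcome: null log-likelihood is 0")
    ll_null = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return 1.0 - model.log_likelihood / ll_null


def mcfadden_r2_from_proba(y: np.ndarray, proba: np.ndarray) -> float:
    """McFadden pseudo-R^2 of out-of-sample probabilities against the null."""
    y = np.asarray(y, dtype=float)
    proba = np.clip(np.asarray(proba, dtype=float), 1e-12, 1 - 1e-12)
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        raise ValueError("degenerate outcome: null log-likelihood is 0")
    ll = float(np.sum(y * np.log(proba) + (1 - y) * np.log(1 - proba)))
    ll_null = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return 1.0 - ll / ll_null


def classification_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """Precision, recall and F1 at a probability threshold.

    A day is predicted an event iff its probability >= threshold.  A
    zero denominator yields metric 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if len(y_true) != len(y_prob):
        raise ValueError("length mismatch")
    pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


THRESHOLD_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


def calibrate_threshold(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    folds: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    k_neighbors: int = 5,
) -> float:
    """Cross-validated probability threshold where precision ~ recall.

    An upstream stratified ``folds``-fold CV: per fold, the training part
    is SMOTE-balanced, backward-eliminated and fit; P and R are computed
    on the validation part for every threshold in {0.01, ..., 0.99}.  The
    threshold minimizing the fold-mean |P - R| is returned (ties: nearest
    0.5, then smaller).
    """
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    diffs = np.zeros((folds, len(THRESHOLD_GRID)))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        if y[va].sum() == 0 or y[tr].sum() == 0:
            raise ValueError("fold without events; reduce fold count")
        Xb, yb = smote(X.iloc[tr].to_numpy(), y[tr], k_neighbors=k_neighbors,
                       seed=seed + f)
        Xb = pd.DataFrame(Xb, columns=X.columns)
        model = backward_eliminate(Xb, yb, alpha=alpha)
        proba = model.predict_proba(X.iloc[va])
        for t_i, t in enumerate(THRESHOLD_GRID):
            p, r, _ = classification_metrics(y[va], proba, t)
            diffs[f, t_i] = abs(p - r)
    mean_diff = diffs.mean(axis=0)
    best = np.min(mean_diff)
    ties = THRESHOLD_GRID[np.isclose(mean_diff, best)]
    return float(ties[np.lexsort((ties, np.abs(ties - 0.5)))[0]])


def evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    k_neighbors: int = 5,
) -> PerformanceReport:
    """Nested cross-validated performance of the full downscaling pipeline.

    Outer stratified ``folds``-fold CV.  Within each outer training fold:
    SMOTE rebalancing, Wald backward elimination, logit fit, and an inner
    threshold calibration on the (un-balanced) training data.  Metrics are
    computed on the untouched validation fold at the calibrated threshold;
    the report carries fold means, per-fold values, an out-of-sample
    McFadden pseudo-R^2 and the events-per-variable ratio.
    """
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    oos_proba = np.full(len(y), np.nan)
    for f, (tr, va) in enumerate(skf.split(X, y)):
        if y[va].sum() == 0 or y[tr].sum() == 0:
            raise ValueError("fold without events; reduce fold count")
        Xb, yb = smote(X.iloc[tr].to_numpy(), y[tr], k_neighbors=k_neighbors,
                       seed=seed + 1000 + f)
        Xb = pd.DataFrame(Xb, columns=X.columns)
        model = backward_eliminate(Xb, yb, alpha=alpha)
        thr = calibrate_threshold(
            X.iloc[tr], y[tr], folds=inner_folds, seed=seed + 2000 + f,
            alpha=alpha, k_neighbors=k_neighbors,
        )
        proba = model.predict_proba(X.iloc[va])
        oos_proba[va] = proba
        p, r, f1 = classification_metrics(y[va], proba, thr)
        rows.append({"fold": f, "threshold": thr, "precision": p, "recall": r,
                     "f1": f1, "n_validation": len(va)})
    per_fold = pd.DataFrame(rows)
    n_events = int(y.sum())
    return PerformanceReport(
        precision=float(per_fold["precision"].mean()),
        recall=float(per_fold["recall"].mean()),
        f1=float(per_fold["f1"].mean()),
        mcfadden_r2=mcfadden_r2_from_proba(y, oos_proba),
        threshold=float(per_fold["threshold"].mean()),
        events_per_variable=n_events / X.shape[1],
        per_fold=per_fold,
    )


def fit_station_model(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    seed: int = 0,
    alpha: float = 0.05,
    folds: int = 10,
    k_neighbors: int = 5,
) -> tuple[LogisticModel, float]:
    """Final station model: SMOTE -> backward elimination on all data,
    plus the cross-validated probability threshold used for projections."""
    y = np.asarray(y, dtype=int)
    Xb, yb = smote(X.to_numpy(), y, k_neighbors=k_neighbors, seed=seed)
    Xb = pd.DataFrame(Xb, columns=X.columns)
    model = backward_eliminate(Xb, yb, alpha=alpha)
    thr = calibrate_threshold(
        X, y, folds=folds, seed=seed, alpha=alpha, k_neighbors=k_neighbors
    )
    return model, thr
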