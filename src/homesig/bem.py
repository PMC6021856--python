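"""Behavior Explanatory Models (BEM).

A BEM is an interpretable regression of a daily behavioral quantity
(hours in bed, toilet-visit counts, ...) on a small pool of candidate
feature sets built from three features:

* ``bias`` — the average level (always included);
* ``linear_trend`` — day index scaled to [0, 1] over the window, so the
  coefficient reads directly as the *total change over the window*;
* ``weekend`` — indicator of Saturday/Sunday.

The pool is the four feature subsets containing the bias.  Real-valued
quantities are fitted by ordinary least squares; count quantities by
Poisson regression, refitted as negative binomial when the Pearson
dispersion exceeds 1.5 so that AIC can arbitrate between the two.  The
model minimising ``AIC = 2k - 2 ln L`` is selected: the best fit with the
fewest factors.  Gross outliers are removed beforehand with an IQR fence;
after fitting, days with large standardized residuals are flagged.

Per-quantity coefficients from rolling windows are concatenated into daily
feature vectors, which feed user-discrimination and one-class anomaly
detection helpers (established scikit-learn components behind a thin
interface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

__all__ = [
    "FEATURES",
    "DesignSpec",
    "ModelFit",
    "BEMResult",
    "prefilter_outliers",
    "fit_pool",
    "flag_model_outliers",
    "rolling_bem",
    "extract_daily_features",
    "evaluate_user_discrimination",
    "fit_anomaly_detector",
    "DiscriminationResult",
    "AnomalyDetector",
]

FEATURES = ("bias", "linear_trend", "weekend")

#: The model pool: every feature subset containing the bias.
POOL_DESIGNS = (
    ("bias",),
    ("bias", "linear_trend"),
    ("bias", "weekend"),
    ("bias", "linear_trend", "weekend"),
)

DISPERSION_LIMIT = 1.5  # Pearson chi2/df above which negbin is also fitted


@dataclass(frozen=True)
class DesignSpec:
    features: tuple[str, ...]
    family: str  # gaussian | poisson | negbin

    def __post_init__(self) -> None:
        if "bias" not in self.features:
            raise ValueError("every design includes the bias")
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features {unknown}")


@dataclass
class ModelFit:
    """One fitted pool member with its AIC and residual diagnostics."""

    design: DesignSpec
    coefficients: dict[str, float]
    loglik: float
    k: int
    aic: float
    residuals: pd.Series  # standardized (gaussian) / Pearson (counts)
    fitted: pd.Series
    stderr: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    alpha: float | None = None  # negbin dispersion
    converged: bool = True

    @property
    def trend_total(self) -> float:
        """Total change over the window (the linear_trend coefficient)."""
        return self.coefficients.get("linear_trend", 0.0)

    def trend_per_day(self, window_days: int) -> float:
        if window_days <= 1:
            return 0.0
        return self.trend_total / (window_days - 1)


@dataclass
class BEMResult:
    best: ModelFit
    pool: list[ModelFit]
    pre_outliers: set
    model_outliers: set
    quantity_id: str = ""
    window_days: int = 0
    failed: list[DesignSpec] = field(default_factory=list)


def prefilter_outliers(
    y: pd.Series, iqr_mult: float = 1.5
) -> tuple[pd.Series, set]:
    """Drop nulls and points outside the IQR fence.

    Quartiles use linear interpolation.  A constant series has IQR 0 and a
    degenerate fence [Q1, Q3]; points equal to the quartiles stay.
    """
    y = y.dropna()
    if len(y) < 4:
        raise ValueError("need at least 4 non-null observations")
    q1, q3 = np.quantile(y.to_numpy(dtype=float), [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_mult * iqr, q3 + iqr_mult * iqr
    keep = (y >= lo) & (y <= hi)
    if not keep.any():
        raise ValueError("degenerate series: prefilter removed every point")
    return y[keep], set(y.index[~keep])


def _design_matrix(
    index: pd.DatetimeIndex,
    features: tuple[str, ...],
    window: tuple[pd.Timestamp, pd.Timestamp],
) -> pd.DataFrame:
    cols = {"bias": np.ones(len(index))}
    if "linear_trend" in features:
        t0, t1 = window
        span = (t1 - t0).total_seconds()
        frac = (
            np.zeros(len(index))
            if span <= 0
            else np.array([(ts - t0).total_seconds() / span for ts in index])
        )
        cols["linear_trend"] = frac
    if "weekend" in features:
        cols["weekend"] = (index.dayofweek >= 5).astype(float)
    return pd.DataFrame({f: cols[f] for f in features}, index=index)


def _standardized_residuals(
    y: pd.Series, mu: np.ndarray, family: str, k: int, alpha: float | None
) -> pd.Series:
    resid = y.to_numpy(dtype=float) - mu
    if family == "gaussian":
        dof = max(len(y) - k, 1)
        scale = np.sqrt(np.sum(resid**2) / dof)
        scale = scale if scale > 0 else 1.0
        return pd.Series(resid / scale, index=y.index)
    if family == "poisson":
        var = np.maximum(mu, 1e-12)
    else:  # negbin
        var = np.maximum(mu + (alpha or 0.0) * mu**2, 1e-12)
    return pd.Series(resid / np.sqrt(var), index=y.index)


def _fit_one(
    y: pd.Series, X: pd.DataFrame, family: str
) -> ModelFit:
    if family == "gaussian":
        res = sm.OLS(y.to_numpy(dtype=float), X.to_numpy()).fit()
        k = len(res.params)
        llf = float(res.llf)
        mu = res.fittedvalues
        alpha = None
    elif family == "poisson":
        res = sm.GLM(
            y.to_numpy(dtype=float), X.to_numpy(), family=sm.families.Poisson()
        ).fit()
        k = len(res.params)
        llf = float(res.llf)
        mu = np.asarray(res.fittedvalues)
        alpha = None
    elif family == "negbin":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = NegativeBinomial(y.to_numpy(dtype=float), X.to_numpy())
            res = mod.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("negbin did not converge")
        k = len(res.params)  # includes the dispersion parameter
        llf = float(res.llf)
        alpha = float(res.params[-1])
        mu = np.exp(X.to_numpy() @ res.params[:-1])
    else:
        raise ValueError(f"unknown family {family!r}")

    n_feat = X.shape[1]
    coef = {f: float(res.params[i]) for i, f in enumerate(X.columns[:n_feat])}
    se_vec = np.asarray(res.bse, dtype=float)
    ci = np.asarray(res.conf_int())
    stderr = {f: float(se_vec[i]) for i, f in enumerate(X.columns[:n_feat])}
    conf = {f: (float(ci[i, 0]), float(ci[i, 1])) for i, f in enumerate(X.columns[:n_feat])}
    if not np.isfinite(llf):
        raise RuntimeError("non-finite log-likelihood")
    fit = ModelFit(
        design=DesignSpec(tuple(X.columns), family),
        coefficients=coef,
        loglik=llf,
        k=k,
        aic=2.0 * k - 2.0 * llf,
        residuals=_standardized_residuals(y, mu, family, k, alpha),
        fitted=pd.Series(mu, index=y.index),
        stderr=stderr,
        conf_int=conf,
        alpha=alpha,
    )
    return fit


def _pearson_dispersion(y: pd.Series, mu: np.ndarray, k: int) -> float:
    resid2 = (y.to_numpy(dtype=float) - mu) ** 2 / np.maximum(mu, 1e-12)
    dof = max(len(y) - k, 1)
    return float(resid2.sum() / dof)


def fit_pool(
    y: pd.Series,
    family: str = "gaussian",
    iqr_mult: float = 1.5,
    z_thresh: float = 3.0,
    prefilter: bool = True,
    quantity_id: str = "",
) -> BEMResult:
    """Fit the model pool on a daily series and select by AIC.

    ``y`` is indexed by day (DatetimeIndex).  For ``family='poisson'`` the
    values must be nonnegative integers; when the Poisson fit is
    overdispersed (Pearson chi2/df > 1.5) a negative-binomial fit of the
    same design joins the pool and AIC arbitrates.
    """
    if not isinstance(y.index, pd.DatetimeIndex):
        raise ValueError("y must be indexed by day (DatetimeIndex)")
    if family not in ("gaussian", "poisson"):
        raise ValueError("family must be 'gaussian' or 'poisson'")
    window = (y.index.min(), y.index.max())
    window_days = int((window[1] - window[0]).days) + 1
    if family == "poisson":
        vals = y.dropna().to_numpy(dtype=float)
        if ((vals < 0) | (vals != np.round(vals))).any():
            raise ValueError("poisson family requires nonnegative integer values")
    if prefilter:
        y_kept, removed = prefilter_outliers(y, iqr_mult)
    else:
        y_kept, removed = y.dropna(), set()
    if len(y_kept) < 5:
        raise ValueError("too few observations after prefiltering")

    pool: list[ModelFit] = []
    failed: list[DesignSpec] = []
    for features in POOL_DESIGNS:
        X = _design_matrix(y_kept.index, features, window)
        try:
            fit = _fit_one(y_kept, X, family)
            pool.append(fit)
        except Exception:
            failed.append(DesignSpec(features, family))
            continue
        if family == "poisson":
            disp = _pearson_dispersion(y_kept, fit.fitted.to_numpy(), fit.k)
            if disp > DISPERSION_LIMIT:
                try:
                    pool.append(_fit_one(y_kept, X, "negbin"))
                except Exception:
                    failed.append(DesignSpec(features, "negbin"))

    if not pool:
        raise RuntimeError("every pool member failed to fit")
    pool.sort(key=lambda f: f.aic)
    best = pool[0]
    result = BEMResult(
        best=best,
        pool=pool,
        pre_outliers=removed,
        model_outliers=flag_model_outliers(best, z_thresh),
        quantity_id=quantity_id,
        window_days=window_days,
        failed=failed,
    )
    return result


def flag_model_outliers(fit: ModelFit, z_thresh: float = 3.0) -> set:
    """Days whose standardized/Pearson residual exceeds ``z_thresh``."""
    r = fit.residuals
    return set(r.index[np.abs(r.to_numpy()) > z_thresh])


def rolling_bem(
    y: pd.Series,
    family: str = "gaussian",
    width: int = 15,
    step: int = 1,
    **kwargs,
) -> list[tuple[pd.Timestamp, BEMResult | None]]:
    """Fit the pool on trailing windows of ``width`` days every ``step`` days.

    Returns one ``(end_day, BEMResult)`` per window; a window that cannot
    be fitted (too few observations after prefiltering) yields ``None``.
    """
    if len(y) < width:
        raise ValueError("series shorter than the window width")
    out: list[tuple[pd.Timestamp, BEMResult | None]] = []
    days = y.index
    for end in range(width - 1, len(days), step):
        win = y.iloc[end - width + 1 : end + 1]
        try:
            res = fit_pool(win, family=family, **kwargs)
        except (ValueError, RuntimeError):
            res = None
        out.append((days[end], res))
    return out


def extract_daily_features(
    results: dict[str, list[tuple[pd.Timestamp, BEMResult | None]]],
    user_id: str = "",
) -> pd.DataFrame:
    """Concatenate best-model coefficients per quantity into daily vectors.

    For every quantity and day the (bias, linear_trend, weekend)
    coefficients of the selected model are exported in a fixed order;
    a feature absent from the selected model is exported as 0 — AIC
    deselection means no detectable effect.  Missing windows are rows of 0.
    The result has one row per day and a ``user_id`` attribute.
    """
    if not results:
        raise ValueError("no quantities given")
    qids = sorted(results)
    date_sets = [set(d for d, _ in results[q]) for q in qids]
    common = set.intersection(*date_sets)
    if not common:
        raise ValueError("quantities have disjoint date ranges")
    dates = sorted(common)
    cols = [f"{q}:{f}" for q in qids for f in FEATURES]
    mat = np.zeros((len(dates), len(cols)))
    pos = {d: i for i, d in enumerate(dates)}
    for qi, q in enumerate(qids):
        for d, res in results[q]:
            if d not in pos or res is None:
                continue
            for fi, f in enumerate(FEATURES):
                mat[pos[d], qi * 3 + fi] = res.best.coefficients.get(f, 0.0)
    df = pd.DataFrame(mat, index=pd.DatetimeIndex(dates), columns=cols)
    df.attrs["user_id"] = user_id
    return df


@dataclass
class DiscriminationResult:
    macro_f1: float
    confusion: np.ndarray
    classes: list
    projection: np.ndarray  # (n_samples, 2) manifold projection
    labels: np.ndarray


def evaluate_user_discrimination(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    test_size: float = 0.25,
    seed: int = 0,
) -> DiscriminationResult:
    """How well do daily feature vectors separate users?

    Trains a support-vector classifier on a stratified split and reports
    the held-out macro-F1 with the confusion matrix, plus a 2-D t-SNE
    projection of all vectors for visual inspection.  Both the classifier
    and the projector are established scikit-learn components.
    """
    from sklearn.manifold import TSNE
    from sklearn.metrics import confusion_matrix, f1_score
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two users")
    counts = pd.Series(y).value_counts()
    if (counts < 20).any():
        raise ValueError("need at least 20 days per user")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    f1 = float(f1_score(y_te, pred, average="macro"))
    cm = confusion_matrix(y_te, pred, labels=classes)
    perplexity = min(30.0, max(2.0, (len(X) - 1) / 3.0))
    proj = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca").fit_transform(X)
    return DiscriminationResult(
        macro_f1=f1, confusion=cm, classes=classes, projection=proj, labels=y
    )


@dataclass
class AnomalyDetector:
    """One-class scorer over a single user's daily feature vectors."""

    model: object
    scaler: object

    def score(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Anomaly score (higher = more anomalous)."""
        Z = self.scaler.transform(np.asarray(X, dtype=float))
        return -np.asarray(self.model.decision_function(Z))

    def flag(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(np.asarray(X, dtype=float))
        return np.asarray(self.model.predict(Z)) == -1


def fit_anomaly_detector(
    features: pd.DataFrame | np.ndarray,
    contamination: float = 0.05,
    method: str = "isolation_forest",
    seed: int = 0,
) -> AnomalyDetector:
    """Fit a one-class anomaly scorer on routine days (>= 30 required)."""
    from sklearn.ensemble import IsolationForest
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import OneClassSVM

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 30:
        raise ValueError("need at least 30 days of feature vectors")
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    if method == "isolation_forest":
        model = IsolationForest(contamination=contamination, random_state=seed).fit(Z)
    elif method == "one_class_svm":
        model = OneClassSVM(nu=contamination, kernel="rbf", gamma="scale").fit(Z)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AnomalyDetector(model=model, scaler=scaler)
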