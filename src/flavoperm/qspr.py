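"""Quantitative structure-permeability (QSPR) modelling engine.

The workflow mirrors standard 2D-QSPR practice on a small congeneric set:

1. Pearson correlation matrix of response and candidate descriptors.
2. Collinearity filter: of each descriptor pair with |r| above a threshold
   (default 0.7), drop the member less correlated with the response.
3. Stepwise selection (forward entry with backward removal) on partial-F
   p-values, classic enter/remove thresholds 0.05 / 0.10.
4. Linear fit by OLS or NIPALS-PLS (autoscaled, coefficients reported in
   original units), with R^2, adjusted R^2, F, SEE and training RMSE.
5. Leave-one-out cross-validation (Q^2 = 1 - PRESS/SS_tot), external
   validation on a held-out test set (R^2_pred against the training mean),
   and a one-pass residual screen for outliers.

The central estimator is :class:`QsprRegressor`, a scikit-learn compatible
regressor; the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.feature_selection import SelectorMixin

from ._nipals import nipals_pls1
from .records import DescriptorSet


# ---------------------------------------------------------------------------
# result containers


@dataclass
class QsprModel:
    """A fitted linear permeability model in original descriptor units."""

    intercept: float
    coefficients: dict[str, float]
    method: str = "ols"
    n_components: int | None = None
    training_ids: list = field(default_factory=list)
    scaling: str = "none"

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("model must have at least one coefficient")
        if self.n_components is not None and self.n_components > len(self.coefficients):
            raise ValueError("n_components exceeds number of descriptors")

    def to_json(self, stats: "ModelStats | None" = None) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "method": self.method,
            "n_components": self.n_components,
            "training_ids": list(self.training_ids),
            "scaling": self.scaling,
        }
        if stats is not None:
            payload["stats"] = {
                k: v
                for k, v in stats.__dict__.items()
                if k != "residuals" and v is not None
            }
            payload["stats"]["residuals"] = (
                {str(k): v for k, v in stats.residuals.items()}
                if isinstance(stats.residuals, dict)
                else list(np.asarray(stats.residuals))
            )
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QsprModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            method=d["method"],
            n_components=d["n_components"],
            training_ids=d["training_ids"],
            scaling=d["scaling"],
        )


@dataclass
class ModelStats:
    """Fit and validation statistics of a QSPR model."""

    r2: float
    r2_adj: float
    f_stat: float
    rmse: float
    see: float
    residuals: dict | np.ndarray
    q2: float | None = None
    press: float | None = None
    r2_pred: float | None = None


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix over response and descriptor labels."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def entry(self, a: str, b: str) -> float:
        return float(self.to_frame().loc[a, b])


# ---------------------------------------------------------------------------
# estimator


def _as_2d(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D array or DataFrame")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


class QsprRegressor(RegressorMixin, BaseEstimator):
    """Linear descriptor -> pPapp regressor (OLS or NIPALS-PLS).

    Parameters
    ----------
    method : {"ols", "pls"}
        "ols" solves the least-squares problem by QR; "pls" runs NIPALS on
        autoscaled data and back-transforms the coefficients to original
        units, so component truncation is meaningful while predictions stay
        on the original scale.
    n_components : int, "auto" or None
        PLS components. None uses as many components as descriptors (then
        PLS coincides with OLS on full-rank data); "auto" picks the count
        maximizing leave-one-out Q^2.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    r2_, r2_adj_, f_stat_, see_, rmse_ : float
        In-sample statistics; adjusted R^2 = 1-(1-R^2)(n-1)/(n-k-1) and
        F = (R^2/k)/((1-R^2)/(n-k-1)) with k = number of descriptors.
    residuals_ : ndarray
        Observed minus fitted on the training data.
    """

    def __init__(self, method: str = "ols", n_components=None):
        self.method = method
        self.n_components = n_components

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        Xa, names = _as_2d(X)
        ya = np.asarray(y, dtype=float).ravel()
        if Xa.shape[0] != ya.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if np.isnan(Xa).any() or np.isnan(ya).any():
            raise ValueError("missing values are not allowed in X or y")
        n, k = Xa.shape
        if self.method not in ("ols", "pls"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "ols" and n < k + 1:
            raise ValueError(f"OLS needs n >= k + 1 observations (n={n}, k={k})")

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = k

        if self.method == "ols":
            self._fit_ols(Xa, ya)
        else:
            self._fit_pls(Xa, ya)

        fitted = self.intercept_ + Xa @ self.coef_
        resid = ya - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(((ya - ya.mean()) ** 2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        dof = n - k - 1
        self.r2_adj_ = 1.0 - (1.0 - self.r2_) * (n - 1) / dof if dof > 0 else float("nan")
        self.f_stat_ = (
            (self.r2_ / k) / ((1.0 - self.r2_) / dof)
            if dof > 0 and self.r2_ < 1.0
            else float("inf")
        )
        self.see_ = float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan")
        self.rmse_ = float(np.sqrt(ss_res / n))
        self.residuals_ = resid
        return self

    def _fit_ols(self, X: np.ndarray, y: np.ndarray) -> None:
        n = X.shape[0]
        X1 = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(X1) < X1.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        q, r = np.linalg.qr(X1)
        beta = np.linalg.solve(r, q.T @ y)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_components_ = None

    def _fit_pls(self, X: np.ndarray, y: np.ndarray) -> None:
        k = X.shape[1]
        ncomp = self.n_components
        if ncomp is None:
            ncomp = k
        elif ncomp == "auto":
            ncomp = self._auto_components(X, y)
        if not 1 <= int(ncomp) <= k:
            raise ValueError(f"n_components must be in [1, {k}], got {ncomp}")
        x_mean, y_mean = X.mean(axis=0), y.mean()
        x_sd = X.std(axis=0, ddof=1)
        if np.any(x_sd == 0):
            bad = int(np.argmax(x_sd == 0))
            raise ValueError(
                f"descriptor {self.feature_names_in_[bad]!r} is constant; cannot autoscale"
            )
        y_sd = y.std(ddof=1)
        Xs = (X - x_mean) / x_sd
        ys = (y - y_mean) / y_sd
        coef_scaled, self.pls_details_ = nipals_pls1(Xs, ys, int(ncomp))
        self.coef_ = coef_scaled * y_sd / x_sd
        self.intercept_ = float(y_mean - x_mean @ self.coef_)
        self.n_components_ = int(ncomp)

    def _auto_components(self, X: np.ndarray, y: np.ndarray) -> int:
        best, best_q2 = 1, -np.inf
        for a in range(1, X.shape[1] + 1):
            est = QsprRegressor(method="pls", n_components=a)
            try:
                q2, _ = loo_q2(X, y, estimator=est)
            except ValueError:
                continue
            if q2 > best_q2:
                best, best_q2 = a, q2
        return best

    # -- prediction ---------------------------------------------------------

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        Xa, names = _as_2d(X)
        if isinstance(X, pd.DataFrame):
            want = list(self.feature_names_in_)
            if list(X.columns) != want:
                missing = [c for c in want if c not in X.columns]
                if missing:
                    raise KeyError(f"missing descriptor column(s): {missing}")
                Xa = X[want].to_numpy(dtype=float)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} features, model expects {self.n_features_in_}"
            )
        return self.intercept_ + Xa @ self.coef_

    # -- export -------------------------------------------------------------

    def to_model(self, training_ids: Sequence | None = None) -> QsprModel:
        return QsprModel(
            intercept=self.intercept_,
            coefficients={
                str(name): float(c)
                for name, c in zip(self.feature_names_in_, self.coef_)
            },
            method=self.method,
            n_components=getattr(self, "n_components_", None),
            training_ids=list(training_ids) if training_ids is not None else [],
            scaling="autoscale" if self.method == "pls" else "none",
        )

    def stats(self, q2: float | None = None, press: float | None = None,
              r2_pred: float | None = None, ids: Sequence | None = None) -> ModelStats:
        residuals = (
            dict(zip(ids, (float(r) for r in self.residuals_)))
            if ids is not None
            else self.residuals_
        )
        return ModelStats(
            r2=self.r2_,
            r2_adj=self.r2_adj_,
            f_stat=self.f_stat_,
            rmse=self.rmse_,
            see=self.see_,
            residuals=residuals,
            q2=q2,
            press=press,
            r2_pred=r2_pred,
        )


# ---------------------------------------------------------------------------
# screening operations


def correlation_matrix(response, descriptors: pd.DataFrame,
                       response_name: str = "ppapp") -> CorrelationMatrix:
    """Pairwise Pearson coefficients among the response and all descriptors.

    Raises ``ValueError`` naming the column if any column is constant
    (its correlation is undefined).
    """
    y = np.asarray(response, dtype=float)
    if isinstance(response, pd.Series) and response.name:
        response_name = str(response.name)
    X, names = _as_2d(descriptors)
    if len(y) != X.shape[0]:
        raise ValueError("response and descriptors have different lengths")
    if len(y) < 3:
        raise ValueError("need at least 3 compounds for a correlation matrix")
    data = np.column_stack([y, X])
    labels = (response_name, *names)
    sds = data.std(axis=0)
    for label, sd in zip(labels, sds):
        if sd == 0:
            raise ValueError(f"column {label!r} is constant; correlation undefined")
    return CorrelationMatrix(names=labels, values=np.corrcoef(data, rowvar=False))


def filter_collinear(
    matrix: CorrelationMatrix, threshold: float = 0.7
) -> tuple[list[str], list[tuple[str, str]]]:
    """Greedy collinearity filter over the inter-descriptor block.

    The first label of ``matrix`` is the response. While any descriptor
    pair has |r| > threshold, the member of the worst pair with the weaker
    |r| to the response is dropped. Returns (retained, dropped_pairs) with
    each dropped pair ordered (kept, dropped).
    """
    frame = matrix.to_frame()
    response = matrix.names[0]
    retained = [n for n in matrix.names[1:]]
    dropped: list[tuple[str, str]] = []
    while True:
        worst, worst_r = None, threshold
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = abs(frame.loc[a, b])
                if r > worst_r:
                    worst, worst_r = (a, b), r
        if worst is None:
            return retained, dropped
        a, b = worst
        keep, drop = (
            (a, b) if abs(frame.loc[response, a]) >= abs(frame.loc[response, b]) else (b, a)
        )
        retained.remove(drop)
        dropped.append((keep, drop))


def _partial_f_pvalues(
    X: pd.DataFrame, y: np.ndarray, included: list[str]
) -> dict[str, float]:
    """Two-sided p-value of each included variable's partial F (= t^2) test."""
    n = len(y)
    cols = [X[c].to_numpy(dtype=float) for c in included]
    X1 = np.column_stack([np.ones(n), *cols])
    dof = n - X1.shape[1]
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    out = {}
    if ss_res <= 1e-10 * max(ss_tot, 1e-300):
        # numerically exact fit: a term is decisive if it contributes to the
        # fitted variance, vacuous otherwise (plain t-ratios are 0/0 noise)
        y_scale = np.sqrt(ss_tot / max(n - 1, 1))
        for j, name in enumerate(included, start=1):
            contribution = abs(beta[j]) * float(np.std(X1[:, j], ddof=1))
            out[name] = 0.0 if contribution > 1e-8 * y_scale else 1.0
        return out
    mse = ss_res / dof
    cov = mse * np.linalg.inv(X1.T @ X1)
    for j, name in enumerate(included, start=1):
        t = beta[j] / np.sqrt(cov[j, j])
        out[name] = float(2.0 * stats.t.sf(abs(t), dof))
    return out


def stepwise_select(
    X: pd.DataFrame,
    y,
    enter_p: float = 0.05,
    remove_p: float = 0.10,
    max_steps: int = 100,
) -> list[str]:
    """Forward-with-backward stepwise descriptor selection on partial-F p-values.

    At each step the candidate with the lowest entry p-value (< ``enter_p``)
    enters; then any included descriptor whose p-value has risen above
    ``remove_p`` leaves (worst first). Ties break on the lower p-value, then
    alphabetically. Deterministic; raises ``ValueError`` if no descriptor
    ever passes entry.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(_as_2d(X)[0], columns=_as_2d(X)[1])
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)
    included: list[str] = []
    for _ in range(max_steps):
        changed = False
        candidates = [c for c in X.columns if c not in included]
        if candidates and n > len(included) + 1 + 2:
            entry_p = {}
            for c in candidates:
                entry_p[c] = _partial_f_pvalues(X, ya, included + [c])[c]
            best = min(sorted(entry_p), key=lambda c: entry_p[c])
            if entry_p[best] < enter_p:
                included.append(best)
                changed = True
        if included:
            pvals = _partial_f_pvalues(X, ya, included)
            worst = max(sorted(pvals), key=lambda c: pvals[c])
            if pvals[worst] > remove_p:
                included.remove(worst)
                changed = True
        if not changed:
            break
    if not included:
        raise ValueError(f"no descriptor passes the entry threshold {enter_p}")
    return included


class CollinearityFilter(SelectorMixin, BaseEstimator):
    """Descriptor selector dropping inter-correlated columns (|r| > threshold).

    Of each violating pair, the member with the weaker |r| to the response
    is dropped (greedy, worst pair first). Fitted attributes: ``support_``
    (boolean mask in column order), ``retained_`` and ``dropped_pairs_``.
    """

    def __init__(self, threshold: float = 0.7):
        self.threshold = threshold

    def fit(self, X, y):
        Xa, names = _as_2d(X)
        matrix = correlation_matrix(y, pd.DataFrame(Xa, columns=names))
        self.retained_, self.dropped_pairs_ = filter_collinear(matrix, self.threshold)
        self.support_ = np.array([n in self.retained_ for n in names])
        self.n_features_in_ = Xa.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def _get_support_mask(self):
        return self.support_


class StepwiseSelector(SelectorMixin, BaseEstimator):
    """Forward-with-backward stepwise descriptor selector (partial-F p-values).

    Thin estimator over :func:`stepwise_select`; ``selected_`` preserves the
    entry order, ``support_`` is the boolean mask in column order.
    """

    def __init__(self, enter_p: float = 0.05, remove_p: float = 0.10):
        self.enter_p = enter_p
        self.remove_p = remove_p

    def fit(self, X, y):
        Xa, names = _as_2d(X)
        frame = pd.DataFrame(Xa, columns=names)
        self.selected_ = stepwise_select(
            frame, y, enter_p=self.enter_p, remove_p=self.remove_p
        )
        self.support_ = np.array([n in self.selected_ for n in names])
        self.n_features_in_ = Xa.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def _get_support_mask(self):
        return self.support_


# ---------------------------------------------------------------------------
# fitting / validation wrappers


def fit_model(
    X, y, method: str = "ols", n_components=None, with_q2: bool = True
) -> tuple[QsprModel, ModelStats]:
    """Fit a QSPR model and compute its fit (and LOO) statistics."""
    ids = list(X.index) if isinstance(X, pd.DataFrame) else None
    est = QsprRegressor(method=method, n_components=n_components).fit(X, y)
    q2 = press = None
    if with_q2 and len(np.asarray(y).ravel()) >= 4:
        q2, press = loo_q2(X, y, method=method, n_components=n_components)
    return est.to_model(training_ids=ids), est.stats(q2=q2, press=press, ids=ids)


def loo_q2(X, y, method: str = "ols", n_components=None, estimator=None
           ) -> tuple[float, float]:
    """Leave-one-out Q^2 and PRESS.

    Each compound is held out in turn, the model refit on the rest and the
    held-out response predicted; Q^2 = 1 - PRESS / SS_tot.
    """
    Xa, _ = _as_2d(X)
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)
    if n < 4:
        raise ValueError(f"leave-one-out needs n >= 4, got {n}")
    base = estimator if estimator is not None else QsprRegressor(
        method=method, n_components=n_components
    )
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fold = clone(base).fit(Xa[mask], ya[mask])
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ValueError(f"leave-one-out refit failed on fold {i}: {exc}") from exc
        press += float((ya[i] - fold.predict(Xa[i:i + 1])[0]) ** 2)
    ss_tot = float(((ya - ya.mean()) ** 2).sum())
    return 1.0 - press / ss_tot, press


def rmse(observed, predicted) -> float:
    """Root-mean-square error between two equal-length vectors."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def validate_external(model, X_test, y_test, y_train_mean: float
                      ) -> tuple[float, float]:
    """External validation: R^2_pred and test RMSE.

    R^2_pred = 1 - sum((y - yhat)^2) / sum((y - y_train_mean)^2), the
    train-mean-referenced convention. ``model`` may be a fitted
    :class:`QsprRegressor` or a :class:`QsprModel`.
    """
    ya = np.asarray(y_test, dtype=float).ravel()
    if len(ya) < 2:
        raise ValueError(f"external validation needs >= 2 test compounds, got {len(ya)}")
    if isinstance(model, QsprModel):
        names = list(model.coefficients)
        if isinstance(X_test, pd.DataFrame):
            Xa = X_test[names].to_numpy(dtype=float)
        else:
            Xa = np.asarray(X_test, dtype=float)
        yhat = model.intercept + Xa @ np.array([model.coefficients[n] for n in names])
    else:
        yhat = model.predict(X_test)
    denom = float(((ya - y_train_mean) ** 2).sum())
    if denom == 0:
        raise ValueError("degenerate test set: all responses equal the training mean")
    r2_pred = 1.0 - float(((ya - yhat) ** 2).sum()) / denom
    return r2_pred, rmse(ya, yhat)


@dataclass
class OutlierScreen:
    excluded: list
    model: QsprRegressor
    residuals: dict


def screen_outliers(
    X: pd.DataFrame,
    y,
    residual_threshold: float = 0.600,
    method: str = "ols",
    n_components=None,
) -> OutlierScreen:
    """One-pass residual screen: fit on all compounds, drop large residuals, refit once.

    A compound is excluded when |observed - predicted| exceeds
    ``residual_threshold``. The screen is deliberately not iterated: it is a
    single pre-modelling pass, so a compound whose residual only rises above
    the threshold in the refit is retained.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(_as_2d(X)[0], columns=_as_2d(X)[1])
    ys = pd.Series(np.asarray(y, dtype=float).ravel(), index=X.index)
    first = QsprRegressor(method=method, n_components=n_components).fit(X, ys)
    resid = pd.Series(first.residuals_, index=X.index)
    excluded = [i for i in X.index if abs(resid[i]) > residual_threshold]
    keep = [i for i in X.index if i not in excluded]
    k = X.shape[1]
    if len(keep) <= k + 2:
        raise ValueError(
            f"outlier screen leaves n={len(keep)} <= k+2={k + 2} compounds"
        )
    refit = QsprRegressor(method=method, n_components=n_components).fit(
        X.loc[keep], ys.loc[keep]
    )
    return OutlierScreen(
        excluded=excluded,
        model=refit,
        residuals={i: float(resid[i]) for i in X.index},
    )


def predict(model: QsprModel, descriptors: DescriptorSet | Mapping[str, float]) -> float:
    """Predicted pPapp for one compound: intercept + sum(coef * value)."""
    values = descriptors.values if isinstance(descriptors, DescriptorSet) else descriptors
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in values:
            raise KeyError(f"descriptor {name!r} missing from input")
        total += coef * float(values[name])
    return total
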