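"""Calibrate UAV-extracted heights against manual measurements.

Polynomial regression (degrees 1-3) plus the standard suite of machine
learning regressors, scored with R^2, MAE, MSE, RMSE, RMSLE and MAPE, with
Spearman rank validation on held-out flights. The fitting itself is
delegated to scikit-learn / lightgbm; the metric formulas and the
train/validate protocol are implemented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plot_extraction import PlotHeightSeries

POLY_FAMILIES = ("poly1", "poly2", "poly3")
ML_FAMILIES = (
    "rfr",
    "knn",
    "huber",
    "lar",
    "ridge",
    "lightgbm",
    "dtr",
    "etr",
    "omp",
    "bayes_ridge",
    "adaboost",
    "catboost",
)
ALL_FAMILIES = POLY_FAMILIES + ML_FAMILIES


@dataclass
class CalibrationModel:
    """A fitted extracted-height -> measured-height mapping."""

    family: str
    training_n: int
    coefficients: np.ndarray | None = None  # polynomial families, ascending order
    estimator: object | None = None  # sklearn-style families

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.coefficients is not None:
            return np.polynomial.polynomial.polyval(x, self.coefficients)
        return self.estimator.predict(x.reshape(-1, 1))

    def to_json(self, path: str) -> None:
        if self.coefficients is None:
            raise ValueError("only closed-form (polynomial) models persist to JSON")
        with open(path, "w") as fh:
            json.dump(
                {
                    "family": self.family,
                    "training_n": self.training_n,
                    "coefficients": list(self.coefficients),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["family"], d["training_n"], np.asarray(d["coefficients"]))


@dataclass
class MetricReport:
    """Goodness-of-fit suite for measured (Zm) vs predicted (Zp) heights."""

    r2: float
    mae: float
    mse: float
    rmse: float
    rmsle: float
    mape: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "mae": self.mae,
            "mse": self.mse,
            "rmse": self.rmse,
            "rmsle": self.rmsle,
            "mape": self.mape,
        }


def fit_polynomial(x: np.ndarray, y: np.ndarray, degree: int) -> CalibrationModel:
    """Least-squares polynomial of the given degree (1, 2 or 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if x.size < degree + 1:
        raise ValueError("need at least degree+1 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("all x identical: design is rank deficient")
    # numpy's Polynomial.fit works on a scaled domain; convert back
    series = np.polynomial.Polynomial.fit(x, y, degree)
    coefs = series.convert().coef
    coefs = np.pad(coefs, (0, degree + 1 - coefs.size))
    return CalibrationModel(f"poly{degree}", x.size, coefficients=coefs)


def polynomial_confidence_intervals(
    x: np.ndarray, y: np.ndarray, degree: int, alpha: float = 0.05
) -> pd.DataFrame:
    """OLS confidence intervals for polynomial coefficients (ascending order)."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    X = np.column_stack([x**k for k in range(degree + 1)])
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = fit.conf_int(alpha=alpha)
    return pd.DataFrame(
        {"coef": fit.params, "ci_low": ci[:, 0], "ci_high": ci[:, 1]},
        index=[f"x^{k}" for k in range(degree + 1)],
    )


def _make_estimator(family: str, seed: int):
    from sklearn import ensemble, linear_model, neighbors, tree

    if family == "rfr":
        return ensemble.RandomForestRegressor(n_estimators=200, random_state=seed)
    if family == "knn":
        return neighbors.KNeighborsRegressor(n_neighbors=5)
    if family == "huber":
        return linear_model.HuberRegressor(alpha=0.0, max_iter=500, tol=1e-10)
    if family == "lar":
        return linear_model.Lars()
    if family == "ridge":
        # light penalty: the calibration design has a single predictor
        return linear_model.Ridge(alpha=0.01, random_state=seed)
    if family == "lightgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=200, random_state=seed, verbose=-1, min_child_samples=5
        )
    if family == "dtr":
        return tree.DecisionTreeRegressor(random_state=seed)
    if family == "etr":
        return ensemble.ExtraTreesRegressor(n_estimators=200, random_state=seed)
    if family == "omp":
        return linear_model.OrthogonalMatchingPursuit()
    if family == "bayes_ridge":
        return linear_model.BayesianRidge()
    if family == "adaboost":
        return ensemble.AdaBoostRegressor(n_estimators=100, random_state=seed)
    if family == "catboost":
        # boosted regression trees standing in for the CatBoost family
        return ensemble.GradientBoostingRegressor(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown regression family {family!r}")


def fit_regressor(
    family: str, x: np.ndarray, y: np.ndarray, seed: int = 0, **kwargs
) -> CalibrationModel:
    """Fit one named regression family on paired heights.

    ``kwargs`` override estimator hyperparameters (e.g. ``n_neighbors=1``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family in POLY_FAMILIES:
        return fit_polynomial(x, y, int(family[-1]))
    if x.size < 5:
        raise ValueError("need at least 5 training pairs")
    est = _make_estimator(family, seed)
    if kwargs:
        est.set_params(**kwargs)
    est.fit(x.reshape(-1, 1), y)
    return CalibrationModel(family, x.size, estimator=est)


def evaluate_predictions(predicted: np.ndarray, measured: np.ndarray) -> MetricReport:
    """Metric suite on paired predicted/measured heights.

    R^2 = 1 - sum((Zm - Zp)^2) / sum((Zm - mean(Zm))^2); MAE, MSE, RMSE as
    the usual error moments; RMSLE on log1p values; MAPE as mean |relative
    error|. A zero-variance measured vector leaves R^2 undefined (NaN).
    """
    zp = np.asarray(predicted, dtype=float)
    zm = np.asarray(measured, dtype=float)
    if zp.shape != zm.shape or zp.size < 2:
        raise ValueError("need >= 2 paired values")
    if not (np.all(np.isfinite(zp)) and np.all(np.isfinite(zm))):
        raise ValueError("inputs must be finite")
    err = zm - zp
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((zm - zm.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / ss_tot) if ss_tot > 0 else float("nan")
    if np.any(zm <= -1) or np.any(zp <= -1):
        rmsle = float("nan")
    else:
        rmsle = float(np.sqrt(np.mean((np.log1p(zp) - np.log1p(zm)) ** 2)))
    nonzero = zm != 0
    mape = (
        float(np.mean(np.abs(err[nonzero] / zm[nonzero])))
        if nonzero.any()
        else float("nan")
    )
    return MetricReport(r2, mae, mse, rmse, rmsle, mape)


def evaluate(model: CalibrationModel, x: np.ndarray, y: np.ndarray) -> MetricReport:
    """Score a fitted model on paired (extracted, measured) heights."""
    return evaluate_predictions(model.predict(np.asarray(x, float)), y)


def spearman(pred: np.ndarray, measured: np.ndarray) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    pred = np.asarray(pred, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pred) == 0 or np.ptp(measured) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    return float(stats.spearmanr(pred, measured).statistic)


@dataclass
class ProtocolReport:
    """Outcome of the train/validate protocol."""

    best_family: str
    models: dict[str, CalibrationModel]
    training_metrics: pd.DataFrame  # one row per family
    test_spearman: dict[int, float]  # per held-out time point, best family
    predicted: pd.DataFrame  # plots x times, best-family predictions


def train_test_protocol(
    series: PlotHeightSeries,
    train_plots: list[str],
    test_times: list[int],
    families: tuple[str, ...] = ALL_FAMILIES,
    seed: int = 0,
) -> ProtocolReport:
    """Fit candidate families on the surveyed training plots, validate on
    whole-field flights.

    Training pairs pool the train plots over all time points with both an
    extracted and a measured value (the field protocol: a small set of plots
    measured by hand at every flight). The best family is the largest
    training R^2, ties broken by smallest RMSE. Validation reports Spearman
    rank correlation between best-family predictions and measurements over
    all plots at the held-out time points.
    """
    if series.measured is None:
        raise ValueError("series carries no manual measurements")
    ext = series.extracted
    meas = series.measured
    train_mask = ext.index.isin(train_plots)
    pairs = []
    for t in ext.columns:
        x = ext.loc[train_mask, t]
        y = meas.loc[train_mask, t] if t in meas.columns else pd.Series(dtype=float)
        both = x.notna() & y.reindex(x.index).notna()
        for pid in x.index[both]:
            pairs.append((pid, t, x[pid], y[pid]))
    if not pairs:
        raise ValueError("no usable training pairs")
    train = pd.DataFrame(pairs, columns=["plot_id", "time", "x", "y"])

    if not test_times:
        raise ValueError("empty test set")

    models: dict[str, CalibrationModel] = {}
    rows = []
    for fam in families:
        model = fit_regressor(fam, train["x"].values, train["y"].values, seed=seed)
        rep = evaluate(model, train["x"].values, train["y"].values)
        models[fam] = model
        rows.append({"family": fam, **rep.as_dict()})
    metrics = pd.DataFrame(rows).set_index("family")
    best = metrics.sort_values(["r2", "rmse"], ascending=[False, True]).index[0]

    best_model = models[best]
    predicted = ext.copy()
    for t in predicted.columns:
        col = predicted[t]
        ok = col.notna()
        predicted.loc[ok, t] = best_model.predict(col[ok].values)

    test_rho: dict[int, float] = {}
    for t in test_times:
        if t not in meas.columns:
            raise ValueError(f"no measurements at test time {t}")
        p = predicted[t]
        m = meas[t].reindex(p.index)
        keep = p.notna() & m.notna()
        if train_mask.any():
            keep &= ~(pd.Series(train_mask, index=p.index) & (t in train["time"].values))
        if keep.sum() < 3:
            raise ValueError(f"too few test pairs at time {t}")
        test_rho[t] = spearman(p[keep].values, m[keep].values)

    return ProtocolReport(best, models, metrics, test_rho, predicted)
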