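"""Log-distance path-loss model for BLE received signal strength.

The system models RSS (dB) as a function of tag–station distance D (m) with
the standard log-distance form

    RSS(D) = -10 * n * log10(D) + A0,

where ``n`` is the path-loss exponent and ``A0`` the RSS at the 1 m reference
distance.  The pooled open-space fit shipped as the system default is
``n = 0.84``, ``A0 = -48.77 dB``; the exponent is far below the free-space
value of 2, a consequence of ground reflection and antenna pattern at the
deployment height, and is used as-is.

Fitting is ordinary least squares of measured RSS on the regressor
``-10*log10(D)`` with an intercept, so the slope estimates ``n`` and the
intercept estimates ``A0`` directly.  Coefficient standard errors are the
usual OLS standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class PathLossModel:
    """Log-distance path-loss model ``RSS = -10*n*log10(D) + A0``.

    Parameters
    ----------
    n : float
        Path-loss exponent (dimensionless).  Predicted RSS is strictly
        decreasing in distance iff ``n > 0``.
    a0 : float
        Path-loss constant in dB: the predicted RSS at the 1 m reference
        distance.
    """

    n: float
    a0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and np.isfinite(self.a0)):
            raise ValueError("path-loss coefficients must be finite")

    def predict(self, distance):
        """Predicted RSS (dB) at ``distance`` metres (scalar or array)."""
        d = np.asarray(distance, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be strictly positive")
        out = -10.0 * self.n * np.log10(d) + self.a0
        return out if out.ndim else float(out)


#: Pooled open-space fit used as the system default in the barn.
DEFAULT_MODEL = PathLossModel(n=0.84, a0=-48.77)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a path-loss regression."""

    model: PathLossModel
    r_squared: float
    n_std: float
    a0_std: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_std < 0 or self.a0_std < 0:
            raise ValueError("coefficient standard errors must be >= 0")


@dataclass(frozen=True)
class VariabilityStats:
    """Average spread of per-tag and per-station mean-RSS curves (dB)."""

    per_tag_std: float
    per_station_std: float


def predict_rss(model: PathLossModel, distance):
    """Evaluate the path-loss model; thin wrapper over ``model.predict``."""
    return model.predict(distance)


class PathLossRegressor(RegressorMixin, BaseEstimator):
    """Least-squares estimator of the log-distance path-loss model.

    ``fit(D, rss)`` regresses RSS on ``-10*log10(D)`` with an intercept;
    ``predict(D)`` evaluates the fitted curve.

    Attributes
    ----------
    n_ : float
        Fitted path-loss exponent.
    a0_ : float
        Fitted path-loss constant (dB).
    r_squared_ : float
        Coefficient of determination of the fit.
    n_std_, a0_std_ : float
        OLS standard errors of the two coefficients.
    model_ : PathLossModel
        The fitted model object.
    """

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).reshape(-1)
        rss = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != rss.shape:
            raise ValueError("distance and rss arrays must have equal length")
        if np.any(d <= 0):
            raise ValueError("distance must be strictly positive")
        if np.unique(d).size < 2:
            raise ValueError(
                "degenerate design: need samples at >= 2 distinct distances"
            )
        regressor = -10.0 * np.log10(d)
        design = sm.add_constant(regressor)
        res = sm.OLS(rss, design).fit()
        self.a0_ = float(res.params[0])
        self.n_ = float(res.params[1])
        self.a0_std_ = float(res.bse[0])
        self.n_std_ = float(res.bse[1])
        # constant data gives 0/0; define R^2 = 1 for a perfect constant fit
        self.r_squared_ = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
        self.r_squared_ = min(max(self.r_squared_, 0.0), 1.0)
        self.model_ = PathLossModel(n=self.n_, a0=self.a0_)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        d = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(self.model_.predict(d), dtype=float)

    def result_(self) -> FitResult:
        check_is_fitted(self, "model_")
        return FitResult(
            model=self.model_,
            r_squared=self.r_squared_,
            n_std=self.n_std_,
            a0_std=self.a0_std_,
        )


def fit_propagation_model(samples: Iterable[tuple[float, float]]) -> FitResult:
    """Fit the path-loss model to ``(distance_m, rss_db)`` pairs.

    Thin wrapper over :class:`PathLossRegressor`.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("no samples provided")
    reg = PathLossRegressor().fit(arr[:, 0], arr[:, 1])
    return reg.result_()


def aggregate_distance_rss(records: pd.DataFrame) -> pd.Series:
    """Mean RSS per distance bin from a propagation-experiment log.

    ``records`` needs columns ``distance_m`` and ``rss_db``.  Empty groups are
    simply absent from the output.  Returns a Series indexed by distance.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    return records.groupby("distance_m")["rss_db"].mean()


def variability_stats(records: pd.DataFrame) -> VariabilityStats:
    """Spread of the per-tag and per-station mean-RSS curves.

    For each distance bin the mean RSS of every tag (averaged over stations
    and samples) is computed; the standard deviation of those per-tag means
    across tags, averaged over distance bins, is the per-tag statistic.  The
    per-station statistic is computed the same way across stations.  This is
    the spread between the averaged RSS–distance curves one would draw per
    tag (resp. per station), and recovers the tag/station offset STDs when
    offsets are additive.

    ``records`` needs columns ``tag_id``, ``station_id``, ``distance_m``,
    ``rss_db``, with at least 2 tags and 2 stations.
    """
    n_tags = records["tag_id"].nunique()
    n_stations = records["station_id"].nunique()
    if n_tags < 2 or n_stations < 2:
        raise ValueError(
            "variability undefined: need >= 2 tags and >= 2 stations "
            f"(got {n_tags} tags, {n_stations} stations)"
        )
    per_tag_curves = records.pivot_table(
        index="distance_m", columns="tag_id", values="rss_db", aggfunc="mean"
    )
    per_station_curves = records.pivot_table(
        index="distance_m", columns="station_id", values="rss_db", aggfunc="mean"
    )
    per_tag = float(per_tag_curves.std(axis=1, ddof=1).mean())
    per_station = float(per_station_curves.std(axis=1, ddof=1).mean())
    return VariabilityStats(per_tag_std=per_tag, per_station_std=per_station)
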