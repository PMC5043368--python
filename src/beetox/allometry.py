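"""Allometric weight-sensitivity regression and LD50 extrapolation.

Across bee species, acute sensitivity scales with body size: the 48 h
LD50 follows an approximate power law of body weight,
``LD50 = 10**b * weight**a``, i.e. a straight line on log10-log10 axes.
This module fits that line by ordinary least squares (via statsmodels),
reports coefficient uncertainty and fit quality, extrapolates LD50s for
untested species from their weight alone, and draws a parametric bootstrap
confidence band around the fitted curve by resampling the coefficients
from their estimated sampling distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .endpoints import SpeciesEndpoint

__all__ = [
    "AllometricModel",
    "ExtrapolatedEndpoint",
    "RegressionBand",
    "fit_weight_sensitivity",
    "extrapolate_ld50",
    "regression_bootstrap_band",
]


@dataclass
class AllometricModel:
    """Fitted (or published) log10-log10 weight-sensitivity model.

    ``slope_a`` and ``intercept_b`` define ``log10(LD50) = a*log10(w) + b``
    with weight ``w`` in mg. Standard errors, p-values, R² and the
    coefficient covariance are None when the model was constructed from
    published coefficients rather than fitted to data.
    """

    slope_a: float
    intercept_b: float
    predictor: str
    include_literature: bool
    n: int
    se_a: float | None = None
    se_b: float | None = None
    p_a: float | None = None
    p_b: float | None = None
    r_squared: float | None = None
    cov_params: np.ndarray | None = None  # order (intercept, slope)
    log10_weight_range: tuple[float, float] | None = None
    _x: np.ndarray | None = None  # fitted log10 weights (for residual bootstrap)
    _y: np.ndarray | None = None  # fitted log10 LD50s

    @classmethod
    def from_coefficients(
        cls, slope_a: float, intercept_b: float, predictor: str = "dry",
        include_literature: bool = False, n: int = 0,
    ) -> "AllometricModel":
        """Wrap published coefficients for extrapolation without refitting."""
        return cls(
            slope_a=float(slope_a),
            intercept_b=float(intercept_b),
            predictor=predictor,
            include_literature=include_literature,
            n=n,
        )

    def predict(self, weight_mg: float | np.ndarray) -> np.ndarray | float:
        """Predicted LD50 (μg a.i./bee) at a body weight in mg."""
        w = np.asarray(weight_mg, dtype=float)
        out = 10.0 ** (self.intercept_b + self.slope_a * np.log10(w))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExtrapolatedEndpoint:
    """A weight-only LD50 prediction for an untested species."""

    species: str
    weight_mg: float
    predicted_ld50: float
    beyond_data: bool
    prediction_interval: tuple[float, float] | None = None


@dataclass(frozen=True)
class RegressionBand:
    """Pointwise bootstrap confidence band around the fitted power law."""

    weights_mg: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    seed: int
    method: str


def _usable(endpoints: Sequence[SpeciesEndpoint], predictor: str,
            include_literature: bool) -> list[SpeciesEndpoint]:
    if predictor not in ("fresh", "dry"):
        raise ValueError(f"predictor must be 'fresh' or 'dry', got {predictor!r}")
    attr = "mean_fresh_weight_mg" if predictor == "fresh" else "mean_dry_weight_mg"
    out = []
    for e in endpoints:
        if not include_literature and e.source == "literature":
            continue
        if getattr(e, attr) is not None and e.ld50 > 0:
            out.append(e)
    return out


def fit_weight_sensitivity(
    endpoints: Sequence[SpeciesEndpoint],
    predictor: str = "dry",
    include_literature: bool = False,
) -> AllometricModel:
    """OLS of log10(LD50) on log10(body weight) across species endpoints.

    ``predictor`` selects fresh or dry weight; literature endpoints are
    excluded unless ``include_literature`` is set. Needs at least three
    usable endpoints with non-zero weight variance.
    """
    use = _usable(endpoints, predictor, include_literature)
    if len(use) < 3:
        raise ValueError(
            f"need >= 3 endpoints with positive LD50 and {predictor} weight, got {len(use)}"
        )
    attr = "mean_fresh_weight_mg" if predictor == "fresh" else "mean_dry_weight_mg"
    x = np.log10([getattr(e, attr) for e in use])
    y = np.log10([e.ld50 for e in use])
    if np.allclose(x, x[0]):
        raise ValueError("zero weight variance: slope is not identifiable")

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    b, a = res.params  # (intercept, slope)
    se_b, se_a = res.bse
    p_b, p_a = res.pvalues
    return AllometricModel(
        slope_a=float(a),
        intercept_b=float(b),
        predictor=predictor,
        include_literature=include_literature,
        n=len(use),
        se_a=float(se_a),
        se_b=float(se_b),
        p_a=float(p_a),
        p_b=float(p_b),
        r_squared=float(res.rsquared),
        cov_params=np.asarray(res.cov_params()),
        log10_weight_range=(float(x.min()), float(x.max())),
        _x=x,
        _y=y,
    )


def extrapolate_ld50(
    model: AllometricModel, weight_mg: float, species: str = ""
) -> ExtrapolatedEndpoint:
    """Predict an untested species' LD50 from body weight alone.

    Predictions for weights outside the fitted range are flagged
    ``beyond_data``: the power law is being trusted where no endpoint
    constrains it.
    """
    if weight_mg <= 0:
        raise ValueError(f"weight_mg must be positive, got {weight_mg}")
    pred = model.predict(weight_mg)
    beyond = False
    if model.log10_weight_range is not None:
        lo, hi = model.log10_weight_range
        lw = math.log10(weight_mg)
        beyond = lw < lo or lw > hi
    return ExtrapolatedEndpoint(
        species=species,
        weight_mg=float(weight_mg),
        predicted_ld50=float(pred),
        beyond_data=beyond,
    )


def regression_bootstrap_band(
    model: AllometricModel,
    weight_grid: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "parametric",
) -> RegressionBand:
    """Pointwise bootstrap confidence band for the fitted power law.

    ``method="parametric"`` resamples (intercept, slope) from their
    bivariate-normal OLS sampling distribution; ``method="residual"``
    resamples residuals and refits. At each grid weight the band spans the
    (1±ci_level)/2 percentiles of the bootstrap predictions.
    """
    w = np.asarray(weight_grid, dtype=float)
    if (w <= 0).any():
        raise ValueError("weight_grid must be strictly positive")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    lx = np.log10(w)

    if method == "parametric":
        if model.cov_params is None:
            raise ValueError("model carries no coefficient covariance (published coefficients?)")
        if not np.all(np.isfinite(model.cov_params)) or np.linalg.det(model.cov_params) <= 0:
            raise ValueError("singular coefficient covariance")
        coefs = rng.multivariate_normal(
            [model.intercept_b, model.slope_a], model.cov_params, size=n_boot,
            method="cholesky",
        )
    elif method == "residual":
        if model._x is None or model._y is None:
            raise ValueError("residual bootstrap needs the fitted data; refit the model")
        X = sm.add_constant(model._x)
        fitted = model.intercept_b + model.slope_a * model._x
        resid = model._y - fitted
        coefs = np.empty((n_boot, 2))
        for i in range(n_boot):
            y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
            coefs[i] = sm.OLS(y_star, X).fit().params
    else:
        raise ValueError(f"method must be 'parametric' or 'residual', got {method!r}")

    preds = 10.0 ** (coefs[:, [0]] + coefs[:, [1]] * lx[None, :])
    tail = (1.0 - ci_level) / 2.0
    lower, upper = np.quantile(preds, [tail, 1.0 - tail], axis=0)
    return RegressionBand(
        weights_mg=w,
        point=np.asarray(model.predict(w)),
        lower=lower,
        upper=upper,
        n_boot=int(n_boot),
        seed=int(seed),
        method=method,
    )
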