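"""Species sensitivity distribution (SSD), hazardous dose and surrogate check.

The SSD models interspecific variation in sensitivity as a log-normal
distribution over species LD50s: log10(LD50) ~ Normal(mu, sigma), fitted by
maximum likelihood (mean and divisor-``n`` standard deviation). The p%
hazardous dose HDp — the dose affecting a fraction ``p`` of the community —
is the p-quantile ``10**(mu + sigma * z_p)``. Confidence limits for HDp come
from a parametric bootstrap: resample ``n`` log-endpoints from the fitted
normal, refit, recompute HDp, and take percentiles of the bootstrap
distribution. The lower limit HD5 is then compared with a surrogate
species' LD50 divided by a safety factor (the lower-tier regulatory
threshold).

Percentile bootstrap intervals for extreme quantiles are known to run
anti-conservative at small n; ``sigma_ddof=1`` and ``method="basic"`` are
available where frequentist coverage matters more than convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .endpoints import SpeciesEndpoint

__all__ = [
    "SSDFit",
    "HDEstimate",
    "SurrogateComparison",
    "DegenerateSSDError",
    "fit_ssd",
    "hd_quantile",
    "bootstrap_hd_ci",
    "surrogate_comparison",
    "plotting_positions",
]


class DegenerateSSDError(ValueError):
    """Raised when all endpoints coincide and the SSD has zero spread."""


@dataclass(frozen=True)
class SSDFit:
    """Normal fit to log10(LD50) across species.

    ``sigma_log10`` uses divisor ``sigma_ddof`` (default 0, the ML
    convention of distribution-fitting packages).
    """

    mu_log10: float
    sigma_log10: float
    n: int
    endpoint_ids: tuple[str, ...]
    sigma_ddof: int = 0


@dataclass(frozen=True)
class HDEstimate:
    """HDp point estimate with parametric-bootstrap confidence limits."""

    p: float
    hd: float
    lower_limit: float
    upper_limit: float
    n_boot: int
    seed: int
    method: str = "percentile"
    ci_level: float = 0.95


def _ld50_values(endpoints: Sequence) -> tuple[np.ndarray, tuple[str, ...]]:
    vals, ids = [], []
    for i, e in enumerate(endpoints):
        if isinstance(e, SpeciesEndpoint):
            vals.append(e.ld50)
            ids.append(e.label)
        else:
            vals.append(float(e))
            ids.append(f"endpoint-{i + 1}")
    return np.asarray(vals, dtype=float), tuple(ids)


def fit_ssd(endpoints: Sequence, sigma_ddof: int = 0) -> SSDFit:
    """ML normal fit to log10(LD50) of a set of species endpoints.

    Accepts :class:`SpeciesEndpoint` objects or bare LD50 values. Requires
    at least two endpoints with distinct positive values.
    """
    vals, ids = _ld50_values(endpoints)
    if vals.size < 2:
        raise ValueError(f"an SSD needs >= 2 endpoints, got {vals.size}")
    if (vals <= 0).any():
        raise ValueError("all LD50 values must be positive")
    logs = np.log10(vals)
    if np.allclose(logs, logs[0]):
        raise DegenerateSSDError("all endpoints identical: SSD spread is zero")
    return SSDFit(
        mu_log10=float(logs.mean()),
        sigma_log10=float(logs.std(ddof=sigma_ddof)),
        n=int(vals.size),
        endpoint_ids=ids,
        sigma_ddof=sigma_ddof,
    )


def hd_quantile(fit: SSDFit, p: float) -> float:
    """The p-quantile of the SSD: the dose affecting a fraction p of species."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return float(10.0 ** (fit.mu_log10 + fit.sigma_log10 * stats.norm.ppf(p)))


def bootstrap_hd_ci(
    fit: SSDFit,
    p: float = 0.05,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "percentile",
) -> HDEstimate:
    """Parametric-bootstrap confidence limits for HDp.

    Each iteration draws ``fit.n`` values from Normal(mu, sigma) on the
    log10 scale, refits by the same estimator, and recomputes HDp.
    ``method="percentile"`` takes the (1±ci_level)/2 percentiles of the
    bootstrap HDp distribution; ``method="basic"`` reflects them around the
    point estimate on the log10 scale (better small-n coverage).
    Deterministic given the seed.
    """
    if fit.sigma_log10 <= 0:
        raise DegenerateSSDError("cannot bootstrap a zero-spread SSD")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    if method not in ("percentile", "basic"):
        raise ValueError(f"method must be 'percentile' or 'basic', got {method!r}")

    z_p = stats.norm.ppf(p)
    rng = np.random.default_rng(seed)
    draws = rng.normal(fit.mu_log10, fit.sigma_log10, size=(n_boot, fit.n))
    mu_b = draws.mean(axis=1)
    sigma_b = draws.std(axis=1, ddof=fit.sigma_ddof)
    log_hd_b = mu_b + sigma_b * z_p

    tail = (1.0 - ci_level) / 2.0
    q_lo, q_hi = np.quantile(log_hd_b, [tail, 1.0 - tail])
    log_hd_hat = fit.mu_log10 + fit.sigma_log10 * z_p
    if method == "percentile":
        lo, hi = q_lo, q_hi
    else:  # basic: reflect bootstrap quantiles around the estimate
        lo, hi = 2.0 * log_hd_hat - q_hi, 2.0 * log_hd_hat - q_lo
    return HDEstimate(
        p=float(p),
        hd=float(10.0 ** log_hd_hat),
        lower_limit=float(10.0 ** lo),
        upper_limit=float(10.0 ** hi),
        n_boot=int(n_boot),
        seed=int(seed),
        method=method,
        ci_level=float(ci_level),
    )


@dataclass(frozen=True)
class SurrogateComparison:
    """Lower-limit HDp versus a surrogate LD50 divided by a safety factor."""

    surrogate_ld50: float
    safety_factor: float
    threshold: float
    lower_limit: float
    ratio: float
    decimals: int
    verdict: str


def surrogate_comparison(
    hd: HDEstimate,
    surrogate_ld50: float,
    safety_factor: float = 10.0,
    decimals: int = 2,
) -> SurrogateComparison:
    """Compare the lower-limit HDp with surrogate_ld50 / safety_factor.

    The verdict states whether the community-protective lower limit equals,
    exceeds or falls below the surrogate-based regulatory threshold at the
    stated rounding precision.
    """
    if surrogate_ld50 <= 0:
        raise ValueError(f"surrogate_ld50 must be positive, got {surrogate_ld50}")
    if safety_factor <= 0:
        raise ValueError(f"safety_factor must be positive, got {safety_factor}")
    threshold = surrogate_ld50 / safety_factor
    ratio = hd.lower_limit / threshold
    r_lo, r_th = round(hd.lower_limit, decimals), round(threshold, decimals)
    if r_lo == r_th:
        relation = "equal to"
    elif r_lo > r_th:
        relation = "above"
    else:
        relation = "below"
    verdict = (
        f"lower-limit HD{hd.p * 100:g} ({r_lo:.{decimals}f}) is {relation} "
        f"surrogate LD50/{safety_factor:g} ({r_th:.{decimals}f}) at {decimals} decimals"
    )
    return SurrogateComparison(
        surrogate_ld50=float(surrogate_ld50),
        safety_factor=float(safety_factor),
        threshold=float(threshold),
        lower_limit=float(hd.lower_limit),
        ratio=float(ratio),
        decimals=int(decimals),
        verdict=verdict,
    )


def plotting_positions(n: int) -> np.ndarray:
    """Hazen plotting positions (i - 0.5) / n for empirical SSD points."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (np.arange(1, n + 1) - 0.5) / n
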