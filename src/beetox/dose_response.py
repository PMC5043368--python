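"""Dose-response modelling of acute contact mortality.

Mortality counts per cage and dose are modelled as binomial draws with
expected mortality

    p(d) = c + (1 - c) * F(slope * (log10 d - log10 LD50))

where ``c`` is background (control) mortality and ``F`` a sigmoid chosen
from three two-parameter families on log10 dose: log-logistic, probit
(log-normal) and Weibull. Each family is parametrised by its median, so
``LD50`` is always the dose at 50% Abbott-corrected mortality. Folding the
Abbott correction into the likelihood this way is algebraically the same
correction applied to expected rather than observed proportions, which
keeps the binomial error structure and the corrected response inside
[0, 1].

The family is picked by AIC; confidence limits for the LD50 come from the
delta method on log10(LD50) using the inverse observed information.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .endpoints import SpeciesEndpoint

__all__ = [
    "MortalityRecord",
    "DoseResponseFit",
    "EndpointComparison",
    "NonEstimableError",
    "BoundaryMortalityError",
    "MODEL_FAMILIES",
    "abbott_correct",
    "fit_dose_response",
    "ld50_with_ci",
    "pooled_geometric_mean_ld50",
    "ci_overlap_groups",
    "qc_control_mortality",
]

_LN2 = math.log(2.0)


class NonEstimableError(ValueError):
    """Raised when records cannot support a dose-response fit."""


class BoundaryMortalityError(ValueError):
    """Raised when mortality sits on the 0% or 100% boundary at all doses."""


@dataclass(frozen=True)
class MortalityRecord:
    """One cage x treatment observation of an acute contact assay.

    ``dose`` is in μg a.i./bee; ``dose == 0`` marks a control cage.
    """

    species: str
    sex: str | None
    run_id: str
    cage_id: str
    dose: float
    n_exposed: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.n_exposed < 1:
            raise ValueError(f"n_exposed must be >= 1, got {self.n_exposed}")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError(
                f"n_dead must be in [0, n_exposed]: got {self.n_dead}/{self.n_exposed}"
            )


def _cdf(family: str, z: np.ndarray) -> np.ndarray:
    """Median-centred sigmoid on z = slope * (log10 dose - log10 LD50)."""
    if family == "log-logistic-2p":
        return expit(z)
    if family == "probit-2p":
        return stats.norm.cdf(z)
    if family == "weibull-2p":
        # 1 - exp(-ln2 * e^z) equals 0.5 at z = 0, so the location is the median
        return -np.expm1(-_LN2 * np.exp(np.minimum(z, 30.0)))
    raise ValueError(f"unknown model family: {family!r}")


MODEL_FAMILIES: tuple[str, ...] = ("log-logistic-2p", "probit-2p", "weibull-2p")


def abbott_correct(p_obs: float, p_control: float) -> float:
    """Abbott's correction of observed mortality for background mortality.

    Returns ``(p_obs - p_control) / (1 - p_control)`` clamped below at 0.
    """
    if not 0 <= p_obs <= 1:
        raise ValueError(f"p_obs must be in [0, 1], got {p_obs}")
    if not 0 <= p_control <= 1:
        raise ValueError(f"p_control must be in [0, 1], got {p_control}")
    if p_control == 1:
        raise ValueError("p_control = 1 leaves Abbott's correction undefined")
    return max(0.0, (p_obs - p_control) / (1.0 - p_control))


@dataclass
class DoseResponseFit:
    """A fitted dose-response model for one species/run.

    ``slope`` is per log10 dose unit; ``ld50`` and its CI are in
    μg a.i./bee. ``se_log10_ld50`` is None when the observed information
    is singular, in which case ``ci_available`` is False and ``ld50_ci``
    is None rather than an exception.
    """

    model_family: str
    slope: float
    log10_ld50: float
    aic: float
    loglik: float
    control_mortality_observed: float
    qc_pass: bool
    se_log10_ld50: float | None = None
    ld50_ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    n_total: int = 0
    species: str | None = None
    sex: str | None = None
    run_id: str | None = None

    @property
    def ld50(self) -> float:
        return 10.0 ** self.log10_ld50

    @property
    def ci_available(self) -> bool:
        return self.se_log10_ld50 is not None and np.isfinite(self.se_log10_ld50)

    def to_endpoint(
        self,
        mean_fresh_weight_mg: float | None = None,
        mean_dry_weight_mg: float | None = None,
    ) -> SpeciesEndpoint:
        """Package the fit as a species endpoint row."""
        return SpeciesEndpoint(
            species=self.species or "unknown",
            sex_or_caste=self.sex,
            ld50=self.ld50,
            ld50_ci=self.ld50_ci,
            ci_level=self.ci_level,
            mean_fresh_weight_mg=mean_fresh_weight_mg,
            mean_dry_weight_mg=mean_dry_weight_mg,
            source="tested",
        )


def _pool_by_dose(records: Sequence[MortalityRecord]):
    """Pool cages within treatment; returns (doses, n, k, c, n_control)."""
    pooled: dict[float, list[int]] = {}
    for r in records:
        tot = pooled.setdefault(float(r.dose), [0, 0])
        tot[0] += r.n_exposed
        tot[1] += r.n_dead
    if 0.0 not in pooled:
        raise NonEstimableError("records include no control (dose 0) group")
    n_ctrl, k_ctrl = pooled.pop(0.0)
    c = k_ctrl / n_ctrl
    doses = np.array(sorted(pooled), dtype=float)
    n = np.array([pooled[d][0] for d in doses], dtype=float)
    k = np.array([pooled[d][1] for d in doses], dtype=float)
    return doses, n, k, c, n_ctrl


def _neg_loglik(theta: np.ndarray, family: str, x: np.ndarray, n: np.ndarray,
                k: np.ndarray, c: float) -> float:
    slope = math.exp(theta[0])
    p = c + (1.0 - c) * _cdf(family, slope * (x - theta[1]))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = k * np.log(p) + (n - k) * np.log1p(-p)
    ll += gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return -float(ll.sum())


def _hessian(fun, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function of 2 params."""
    H = np.empty((2, 2))
    steps = [h * max(1.0, abs(t)) for t in theta]
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = steps[i]
            ej = np.zeros(2); ej[j] = steps[j]
            if i == j:
                f = (fun(theta + ei) - 2.0 * fun(theta) + fun(theta - ei)) / steps[i] ** 2
            else:
                f = (
                    fun(theta + ei + ej) - fun(theta + ei - ej)
                    - fun(theta - ei + ej) + fun(theta - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
            H[i, j] = H[j, i] = f
    return H


def _initial_log10_ld50(x: np.ndarray, n: np.ndarray, k: np.ndarray, c: float) -> float:
    """Interpolate where the Abbott-corrected mortality crosses 0.5."""
    with np.errstate(invalid="ignore"):
        pc = np.clip((k / n - c) / (1.0 - c), 0.0, 1.0)
    above = np.nonzero(pc >= 0.5)[0]
    if above.size == 0:
        return float(x[-1])
    j = int(above[0])
    if j == 0:
        return float(x[0])
    i = j - 1
    if pc[j] == pc[i]:
        return float(0.5 * (x[i] + x[j]))
    frac = (0.5 - pc[i]) / (pc[j] - pc[i])
    return float(x[i] + frac * (x[j] - x[i]))


def fit_dose_response(
    records: Sequence[MortalityRecord],
    families: Iterable[str] = MODEL_FAMILIES,
    confidence: float = 0.95,
    qc_threshold: float = 0.10,
) -> DoseResponseFit:
    """Fit candidate dose-response families by binomial ML; keep the AIC winner.

    Cages are pooled within treatment; controls enter only through the
    background-mortality parameter ``c`` (pooled observed control rate,
    held fixed), never through log dose. Requires at least three distinct
    non-zero doses and one control group.
    """
    families = tuple(families)
    if not families:
        raise ValueError("need at least one model family")
    for fam in families:
        if fam not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family: {fam!r}")

    doses, n, k, c, _ = _pool_by_dose(records)
    if doses.size < 3:
        raise NonEstimableError(
            f"need >= 3 distinct non-zero doses, got {doses.size}"
        )
    if k.sum() == 0:
        raise BoundaryMortalityError(
            "no deaths at any dose: LD50 lies above the tested range"
        )
    if (k == n).all():
        raise BoundaryMortalityError(
            "complete mortality at every dose: LD50 lies below the tested range"
        )
    if c >= 1.0:
        raise BoundaryMortalityError("complete control mortality: assay invalid")

    x = np.log10(doses)
    m0 = _initial_log10_ld50(x, n, k, c)

    best: tuple[float, str, np.ndarray] | None = None
    for fam in families:
        fam_best: tuple[float, np.ndarray] | None = None
        for s0 in (0.5, 2.0, 5.0):
            res = optimize.minimize(
                _neg_loglik,
                x0=np.array([math.log(s0), m0]),
                args=(fam, x, n, k, c),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
            )
            if fam_best is None or res.fun < fam_best[0]:
                fam_best = (float(res.fun), res.x)
        assert fam_best is not None
        aic = 2.0 * 2 + 2.0 * fam_best[0]
        if best is None or aic < best[0]:
            best = (aic, fam, fam_best[1])

    assert best is not None
    aic, family, theta = best
    nll = (aic - 4.0) / 2.0

    se = None
    H = _hessian(lambda t: _neg_loglik(t, family, x, n, k, c), theta)
    try:
        cov = np.linalg.inv(H)
        var_m = cov[1, 1]
        if np.isfinite(var_m) and var_m > 0:
            se = float(math.sqrt(var_m))
    except np.linalg.LinAlgError:
        se = None

    species = records[0].species if records else None
    sexes = {r.sex for r in records}
    runs = {r.run_id for r in records}
    fit = DoseResponseFit(
        model_family=family,
        slope=float(math.exp(theta[0])),
        log10_ld50=float(theta[1]),
        aic=float(aic),
        loglik=-float(nll),
        control_mortality_observed=float(c),
        qc_pass=c <= qc_threshold,
        se_log10_ld50=se,
        ci_level=confidence,
        n_total=int(n.sum()),
        species=species,
        sex=sexes.pop() if len(sexes) == 1 else None,
        run_id=runs.pop() if len(runs) == 1 else None,
    )
    fit.ld50_ci = ld50_with_ci(fit, confidence)
    return fit


def ld50_with_ci(fit: DoseResponseFit, confidence: float | None = None) -> tuple[float, float] | None:
    """Delta-method confidence limits for the LD50 (μg a.i./bee).

    The interval is ``10 ** (log10_ld50 ± z * SE)`` with the standard error
    from the inverse observed information. Returns None (CI unavailable)
    when the information matrix was singular.
    """
    if confidence is None:
        confidence = fit.ci_level
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if not fit.ci_available:
        return None
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    lo = 10.0 ** (fit.log10_ld50 - z * fit.se_log10_ld50)
    hi = 10.0 ** (fit.log10_ld50 + z * fit.se_log10_ld50)
    return (float(lo), float(hi))


def pooled_geometric_mean_ld50(values: Sequence[float]) -> float:
    """Geometric mean of replicate LD50 estimates."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one LD50 value")
    if (vals <= 0).any():
        raise ValueError("all LD50 values must be positive")
    return float(np.exp(np.mean(np.log(vals))))


@dataclass(frozen=True)
class EndpointComparison:
    """Pairwise CI-overlap comparison at a Bonferroni-adjusted level."""

    pair: tuple[str, str]
    adjusted_confidence: float
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    significant: bool


def _log_se_from_ci(e: SpeciesEndpoint) -> tuple[float, float]:
    """Back out (centre, SE) of log10(LD50) from a stated symmetric-log CI."""
    lo, hi = e.ld50_ci  # type: ignore[misc]
    z = stats.norm.ppf(0.5 + e.ci_level / 2.0)
    centre = 0.5 * (math.log10(lo) + math.log10(hi))
    se = (math.log10(hi) - math.log10(lo)) / (2.0 * z)
    return centre, se


def ci_overlap_groups(
    endpoints: Sequence[SpeciesEndpoint],
    alpha: float = 0.05,
) -> tuple[list[EndpointComparison], dict[str, str]]:
    """Compare endpoints pairwise by the Bonferroni-adjusted CI-overlap rule.

    Each endpoint's CI is recomputed at confidence ``1 - alpha / m`` where
    ``m = C(k, 2)`` is the number of pairwise comparisons; a pair differs
    significantly iff the adjusted intervals are disjoint. Grouping letters
    are assigned to the connected components of the non-significance graph
    (its transitive closure), ordered by ascending LD50. Endpoints without a
    CI are excluded with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    usable = []
    for e in endpoints:
        if e.ld50_ci is None:
            warnings.warn(f"endpoint {e.label!r} has no CI; excluded from CI-overlap test")
            continue
        usable.append(e)
    k = len(usable)
    if k < 2:
        raise ValueError("need at least two endpoints with CIs to compare")
    m = k * (k - 1) // 2
    adj_conf = 1.0 - alpha / m
    z_adj = stats.norm.ppf(0.5 + adj_conf / 2.0)

    adj_iv: dict[str, tuple[float, float]] = {}
    for e in usable:
        centre, se = _log_se_from_ci(e)
        adj_iv[e.label] = (10.0 ** (centre - z_adj * se), 10.0 ** (centre + z_adj * se))

    comparisons: list[EndpointComparison] = []
    nonsig_edges: dict[str, set[str]] = {e.label: set() for e in usable}
    for a, b in itertools.combinations(usable, 2):
        iv_a, iv_b = adj_iv[a.label], adj_iv[b.label]
        disjoint = iv_a[1] < iv_b[0] or iv_b[1] < iv_a[0]
        comparisons.append(
            EndpointComparison(
                pair=(a.label, b.label),
                adjusted_confidence=adj_conf,
                interval_a=iv_a,
                interval_b=iv_b,
                significant=disjoint,
            )
        )
        if not disjoint:
            nonsig_edges[a.label].add(b.label)
            nonsig_edges[b.label].add(a.label)

    # connected components of the non-significance graph, most sensitive first
    order = sorted(usable, key=lambda e: e.ld50)
    letters: dict[str, str] = {}
    next_letter = 0
    for e in order:
        if e.label in letters:
            continue
        stack, component = [e.label], []
        seen = {e.label}
        while stack:
            lbl = stack.pop()
            component.append(lbl)
            for nb in nonsig_edges[lbl]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        letter = chr(ord("a") + next_letter)
        next_letter += 1
        for lbl in component:
            letters[lbl] = letter
    return comparisons, letters


def qc_control_mortality(
    records: Sequence[MortalityRecord],
    threshold: float = 0.10,
):
    """Pooled control mortality per (species, run), flagged above threshold.

    Runs exceeding the threshold are flagged for scrutiny, not rejected —
    background mortality is already absorbed by the Abbott correction.
    Returns a DataFrame with columns species, run_id, n_control,
    control_mortality, flagged.
    """
    import pandas as pd

    controls = [r for r in records if r.dose == 0]
    if not controls:
        raise ValueError("no control (dose 0) records found")
    pooled: dict[tuple[str, str], list[int]] = {}
    for r in controls:
        tot = pooled.setdefault((r.species, r.run_id), [0, 0])
        tot[0] += r.n_exposed
        tot[1] += r.n_dead
    rows = [
        {
            "species": sp,
            "run_id": run,
            "n_control": tot[0],
            "control_mortality": tot[1] / tot[0],
            "flagged": tot[1] / tot[0] > threshold,
        }
        for (sp, run), tot in sorted(pooled.items())
    ]
    return pd.DataFrame(rows)
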