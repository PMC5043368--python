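"""Per-species toxicity endpoints and the endpoint summary table.

A :class:`SpeciesEndpoint` is one row of the study's endpoint table: a
species (optionally split by sex or caste), its 48 h contact LD50 in
μg a.i./bee with a confidence interval, mean fresh and dry body weight in
mg, and whether the value was measured here or taken from the literature.
Weight-normalised LD50s (μg a.i. per gram of bee) are derived on demand
from the full-precision stored values, never from rounded display values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesEndpoint",
    "normalize_ld50",
    "weight_ratio",
    "wilcoxon_weight_test",
    "endpoint_table",
]

SOURCE_TESTED = "tested"
SOURCE_LITERATURE = "literature"


def normalize_ld50(ld50: float, weight_mg: float) -> float:
    """Express a per-bee LD50 (μg a.i./bee) per gram of bee (μg a.i./g).

    ``weight_mg`` is the mean body weight in milligrams; the conversion is
    ``ld50 / (weight_mg / 1000)``.
    """
    if weight_mg <= 0:
        raise ValueError(f"weight_mg must be positive, got {weight_mg}")
    return ld50 / (weight_mg / 1000.0)


@dataclass
class SpeciesEndpoint:
    """One species (x sex/caste) toxicity endpoint.

    Parameters
    ----------
    species:
        Species name, e.g. ``"Bombus terrestris"``.
    ld50:
        48 h contact LD50 in μg a.i./bee.
    sex_or_caste:
        Optional label such as ``"F"``, ``"M"`` or ``"worker"``.
    ld50_ci:
        ``(lo, hi)`` confidence limits in μg a.i./bee at ``ci_level``,
        or ``None`` when no interval is available.
    ci_level:
        Confidence level of ``ld50_ci`` (default 0.95).
    mean_fresh_weight_mg, mean_dry_weight_mg:
        Mean body weights in mg; ``None`` when not measured.
    source:
        ``"tested"`` for endpoints measured in this study's assays,
        ``"literature"`` for endpoints taken from published studies.
    """

    species: str
    ld50: float
    sex_or_caste: str | None = None
    ld50_ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    mean_fresh_weight_mg: float | None = None
    mean_dry_weight_mg: float | None = None
    source: str = SOURCE_TESTED

    def __post_init__(self) -> None:
        if not self.ld50 > 0:
            raise ValueError(f"ld50 must be positive, got {self.ld50}")
        if self.source not in (SOURCE_TESTED, SOURCE_LITERATURE):
            raise ValueError(f"source must be 'tested' or 'literature', got {self.source!r}")
        for name in ("mean_fresh_weight_mg", "mean_dry_weight_mg"):
            w = getattr(self, name)
            if w is not None and not w > 0:
                raise ValueError(f"{name} must be positive when present, got {w}")
        if self.ld50_ci is not None:
            lo, hi = self.ld50_ci
            if not (0 < lo <= hi):
                raise ValueError(f"ld50_ci must satisfy 0 < lo <= hi, got {self.ld50_ci}")

    @property
    def label(self) -> str:
        """Display label combining species and sex/caste."""
        if self.sex_or_caste:
            return f"{self.species} ({self.sex_or_caste})"
        return self.species

    @property
    def ld50_per_g_fresh(self) -> float | None:
        """Fresh weight-normalised LD50 in μg a.i./g bee, or None."""
        if self.mean_fresh_weight_mg is None:
            return None
        return normalize_ld50(self.ld50, self.mean_fresh_weight_mg)

    @property
    def ld50_per_g_dry(self) -> float | None:
        """Dry weight-normalised LD50 in μg a.i./g bee, or None."""
        if self.mean_dry_weight_mg is None:
            return None
        return normalize_ld50(self.ld50, self.mean_dry_weight_mg)


def weight_ratio(endpoint_heavy: SpeciesEndpoint, endpoint_light: SpeciesEndpoint) -> float:
    """Fold difference in mean fresh weight between two endpoints.

    Returns the raw ratio (heavy/light); round to the nearest integer for
    display (e.g. 205.0/11.0 = 18.64 displays as a 19-fold difference).
    """
    wh = endpoint_heavy.mean_fresh_weight_mg
    wl = endpoint_light.mean_fresh_weight_mg
    if wh is None or wl is None:
        raise ValueError("both endpoints need a mean fresh weight for a weight ratio")
    return wh / wl


def wilcoxon_weight_test(weights_a: Sequence[float], weights_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum test of two weight samples.

    Uses exact enumeration when the combined sample size is at most 20 and
    the data are tie-free; otherwise the normal approximation with
    continuity correction. Returns the two-sided p-value.
    """
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    if combined.size <= 20 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def endpoint_table(endpoints: Iterable[SpeciesEndpoint]) -> pd.DataFrame:
    """Assemble the endpoint summary table, sorted by ascending LD50.

    Columns mirror the study's headline table: LD50 with CI, fresh/dry
    weights and the weight-normalised LD50s. Normalised values are computed
    from full-precision inputs; rounding is left to the caller.
    """
    rows = []
    for e in endpoints:
        lo, hi = e.ld50_ci if e.ld50_ci is not None else (math.nan, math.nan)
        rows.append(
            {
                "species": e.species,
                "sex": e.sex_or_caste,
                "source": e.source,
                "mean_fresh_weight_mg": e.mean_fresh_weight_mg,
                "mean_dry_weight_mg": e.mean_dry_weight_mg,
                "ld50_ug_per_bee": e.ld50,
                "ld50_lo": lo,
                "ld50_hi": hi,
                "ld50_per_g_fresh": e.ld50_per_g_fresh,
                "ld50_per_g_dry": e.ld50_per_g_dry,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values("ld50_ug_per_bee", kind="mergesort").reset_index(drop=True)
    return frame
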