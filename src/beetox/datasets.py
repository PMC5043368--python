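"""Built-in study data: the dimethoate bee-sensitivity endpoint table.

These are the published summary values of an acute contact toxicity study
of dimethoate (an organophosphate used as the toxic reference in bee
testing) on five European bee species, with Osmia bicornis sexes kept as
separate entries. They serve as desk-scale inputs for the surrogate-ratio,
weight-ratio, regression and extrapolation analyses; the raw per-cage
mortality data behind them are not redistributed here (the synthetic
module generates structurally equivalent assays instead).

The published mean honey-bee (Apis mellifera) 48 h contact LD50 of
0.18 μg a.i./bee is the geometric mean of literature values and is the
surrogate endpoint of the lower-tier risk comparison. Per-species LD50s
of the other literature species are not reproduced here.
"""

from __future__ import annotations

from .endpoints import SpeciesEndpoint

__all__ = [
    "tested_endpoints",
    "honey_bee_endpoint",
    "HONEY_BEE_MEAN_LD50",
    "SAFETY_FACTOR",
    "EXTRAPOLATION_DRY_WEIGHTS_MG",
    "PUBLISHED_COEFFICIENTS",
    "DOSE_SERIES",
]

#: Mean 48 h contact LD50 of the honey bee from literature (μg a.i./bee).
HONEY_BEE_MEAN_LD50: float = 0.18

#: Default lower-tier assessment safety factor applied to the surrogate LD50.
SAFETY_FACTOR: float = 10.0

#: Dry body weights (mg) of two very small untested species whose LD50s are
#: extrapolated from the weight-sensitivity model.
EXTRAPOLATION_DRY_WEIGHTS_MG: dict[str, float] = {
    "Hylaeus gredleri (M)": 1.0,
    "Nomioides minutissimus (F)": 0.8,
}

#: Published coefficients of log10(LD50) = a*log10(weight) + b, by
#: (predictor, literature-included) variant. The study fitted these on
#: unrounded LD50 estimates, so refits from the rounded endpoint table
#: reproduce them only approximately.
PUBLISHED_COEFFICIENTS: dict[tuple[str, bool], dict[str, float]] = {
    ("fresh", True): {"a": 0.8087, "b": -1.4550, "r_squared": 0.34},
    ("fresh", False): {"a": 1.0339, "b": -1.6938, "r_squared": 0.76},
    ("dry", True): {"a": 1.1068, "b": -1.5846, "r_squared": 0.37},
    ("dry", False): {"a": 1.0490, "b": -1.2693, "r_squared": 0.70},
}

#: Dose series used in the assays (μg a.i./bee), by species group.
DOSE_SERIES: dict[str, tuple[float, ...]] = {
    "Bombus terrestris": (1.25, 2.5, 5.0, 10.0, 20.0),
    "Osmia bicornis": (0.625, 1.25, 2.5, 5.0, 10.0),
    "small wild bees": (0.0896, 0.224, 0.56, 1.4, 3.5),
}

_TESTED = (
    # species, sex, ld50, (lo, hi), fresh mg, dry mg
    ("Lasioglossum malachurum", "F", 0.20, (0.16, 0.24), 11.0, 3.7),
    ("Andrena flavipes", "F", 0.73, (0.07, 1.39), 47.3, 21.6),
    ("Colletes hederae", "F", 1.14, (0.72, 1.57), 105.5, 43.4),
    ("Osmia bicornis", "M", 1.71, (1.37, 2.04), 37.7, 17.6),
    ("Osmia bicornis", "F", 4.29, (3.72, 4.91), 93.6, 30.4),
    ("Bombus terrestris", "worker", 5.13, (4.10, 6.15), 205.0, 55.8),
)


def tested_endpoints() -> list[SpeciesEndpoint]:
    """The six tested endpoint entries (LD50 in μg a.i./bee, weights in mg)."""
    return [
        SpeciesEndpoint(
            species=sp,
            sex_or_caste=sex,
            ld50=ld50,
            ld50_ci=ci,
            mean_fresh_weight_mg=fresh,
            mean_dry_weight_mg=dry,
            source="tested",
        )
        for sp, sex, ld50, ci, fresh, dry in _TESTED
    ]


def honey_bee_endpoint() -> SpeciesEndpoint:
    """The literature honey-bee surrogate endpoint (no CI, no weights)."""
    return SpeciesEndpoint(
        species="Apis mellifera",
        sex_or_caste="worker",
        ld50=HONEY_BEE_MEAN_LD50,
        source="literature",
    )
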