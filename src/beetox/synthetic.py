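"""Synthetic assay, community and allometric data generators.

Each generator draws from exactly the statistical model its downstream
estimator assumes, giving every analysis stage a ground-truth recovery
test:

* :func:`generate_acute_test` — cage-structured binomial mortality under a
  two-parameter log-logistic dose-response curve with background control
  mortality mixed in as ``c + (1 - c) * F(dose)`` (the Abbott-correction
  model). Default design mirrors an acute contact assay: five doses on a
  geometric series plus a control, 3 cages per treatment.
* :func:`generate_species_community` — a log-normal community of species
  LD50s (normal on log10 scale), the distribution the SSD stage fits.
* :func:`generate_allometric_endpoints` — LD50s following a power law of
  body weight, ``LD50 = 10**(b + a*log10(w) + eps)``, with log10-scale
  Gaussian noise.

Every generator takes an explicit seed and uses one private random stream
per call; identical config implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .dose_response import MortalityRecord
from .endpoints import SpeciesEndpoint

__all__ = [
    "AssaySimConfig",
    "CommunitySimConfig",
    "AllometrySimConfig",
    "expected_mortality",
    "generate_acute_test",
    "generate_species_community",
    "generate_allometric_endpoints",
]

#: Five-dose geometric series used for the smaller wild-bee assays (μg a.i./bee).
DEFAULT_DOSES: tuple[float, ...] = (0.0896, 0.224, 0.56, 1.4, 3.5)


def _check(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {message}")


@dataclass(frozen=True)
class AssaySimConfig:
    """Design and truth of one simulated acute contact assay.

    ``true_ld50`` (μg a.i./bee) and ``hill_slope`` (per log10 dose unit)
    set the underlying log-logistic curve; ``control_mortality`` is the
    background rate mixed in on [0, 1). The cage design defaults to 3
    cages of 10 bees per treatment.
    """

    true_ld50: float
    hill_slope: float = 2.0
    control_mortality: float = 0.0
    doses: tuple[float, ...] = DEFAULT_DOSES
    n_cages: int = 3
    bees_per_cage: int = 10
    seed: int = 0
    species: str = "Simulapis exemplaris"
    sex: str | None = "F"
    run_id: str = "sim-run-1"

    def __post_init__(self) -> None:
        _check(self.true_ld50 > 0, "true_ld50", "must be positive")
        _check(self.hill_slope > 0, "hill_slope", "must be positive")
        _check(0 <= self.control_mortality < 1, "control_mortality", "must be in [0, 1)")
        d = np.asarray(self.doses, dtype=float)
        _check(d.size >= 1 and (d > 0).all(), "doses", "must be strictly positive")
        _check((np.diff(d) > 0).all(), "doses", "must be strictly increasing")
        _check(self.n_cages >= 1, "n_cages", "must be >= 1")
        _check(self.bees_per_cage >= 1, "bees_per_cage", "must be >= 1")


def expected_mortality(config: AssaySimConfig, dose: float) -> float:
    """Expected mortality at a dose under the generating model.

    Controls (dose 0) die at the background rate ``c``; treated bees at
    ``c + (1 - c) * logistic(hill_slope * (log10 dose - log10 LD50))``.
    """
    c = config.control_mortality
    if dose == 0:
        return c
    z = config.hill_slope * (np.log10(dose) - np.log10(config.true_ld50))
    return float(c + (1.0 - c) * expit(z))


def generate_acute_test(config: AssaySimConfig) -> list[MortalityRecord]:
    """Simulate one assay: binomial deaths per cage at control + each dose."""
    rng = np.random.default_rng(config.seed)
    records: list[MortalityRecord] = []
    for dose in (0.0, *config.doses):
        p = expected_mortality(config, dose)
        deaths = rng.binomial(config.bees_per_cage, p, size=config.n_cages)
        for cage, n_dead in enumerate(deaths, start=1):
            records.append(
                MortalityRecord(
                    species=config.species,
                    sex=config.sex,
                    run_id=config.run_id,
                    cage_id=f"cage-{cage}",
                    dose=float(dose),
                    n_exposed=config.bees_per_cage,
                    n_dead=int(n_dead),
                )
            )
    return records


@dataclass(frozen=True)
class CommunitySimConfig:
    """A log-normal community of species sensitivities.

    log10(LD50) of each species is drawn i.i.d. from
    Normal(``mu_log10``, ``sigma_log10``).
    """

    mu_log10: float
    sigma_log10: float
    n_species: int
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.sigma_log10 >= 0, "sigma_log10", "must be >= 0")
        _check(self.n_species >= 2, "n_species", "must be >= 2 (an SSD needs two endpoints)")


def generate_species_community(config: CommunitySimConfig) -> list[SpeciesEndpoint]:
    """Draw a community of species endpoints; weights are left absent."""
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal(config.n_species)
    ld50s = 10.0 ** (config.mu_log10 + config.sigma_log10 * z)
    return [
        SpeciesEndpoint(species=f"species-{i:05d}", ld50=float(v), source="tested")
        for i, v in enumerate(ld50s, start=1)
    ]


@dataclass(frozen=True)
class AllometrySimConfig:
    """Power-law weight-sensitivity truth: LD50 = 10**b * weight**a.

    ``weights_mg`` are species body weights in mg; log10-scale Gaussian
    noise with SD ``noise_sd_log10`` is added to each log10(LD50).
    """

    slope_a: float
    intercept_b: float
    weights_mg: tuple[float, ...]
    noise_sd_log10: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights_mg, dtype=float)
        _check(w.size >= 1 and (w > 0).all(), "weights_mg", "must be strictly positive")
        _check(self.noise_sd_log10 >= 0, "noise_sd_log10", "must be >= 0")


def generate_allometric_endpoints(config: AllometrySimConfig) -> list[SpeciesEndpoint]:
    """Endpoints on (or scattered around) the power-law line.

    The generated weight is stored as both fresh and dry weight so the
    regression stage can be exercised with either predictor.
    """
    rng = np.random.default_rng(config.seed)
    w = np.asarray(config.weights_mg, dtype=float)
    eps = rng.normal(0.0, config.noise_sd_log10, size=w.size)
    log_ld50 = config.intercept_b + config.slope_a * np.log10(w) + eps
    return [
        SpeciesEndpoint(
            species=f"species-{i:05d}",
            ld50=float(10.0 ** y),
            mean_fresh_weight_mg=float(wi),
            mean_dry_weight_mg=float(wi),
            source="tested",
        )
        for i, (wi, y) in enumerate(zip(w, log_ld50), start=1)
    ]
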