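"""CSV schemas and run configuration.

Two plain-text formats tie the pipeline together:

* mortality CSV — one row per cage x treatment:
  ``species,sex,run_id,cage_id,dose_ug_per_bee,n_exposed,n_dead``
  (dose 0 marks controls; UTF-8; "." decimal separator)
* endpoint CSV — one row per species endpoint:
  ``species,sex,ld50,ld50_lo,ld50_hi,fresh_weight_mg,dry_weight_mg,source``

Schema violations raise :class:`SchemaError` naming the offending row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .dose_response import MortalityRecord
from .endpoints import SpeciesEndpoint

__all__ = [
    "SchemaError",
    "MORTALITY_COLUMNS",
    "ENDPOINT_COLUMNS",
    "read_mortality_csv",
    "write_mortality_csv",
    "read_endpoints_csv",
    "write_endpoints_csv",
    "AnalysisConfig",
]

MORTALITY_COLUMNS = [
    "species", "sex", "run_id", "cage_id", "dose_ug_per_bee", "n_exposed", "n_dead",
]
ENDPOINT_COLUMNS = [
    "species", "sex", "ld50", "ld50_lo", "ld50_hi",
    "fresh_weight_mg", "dry_weight_mg", "source",
]


class SchemaError(ValueError):
    """A CSV does not match its declared schema."""


def _check_header(frame: pd.DataFrame, expected: list[str], path) -> None:
    got = list(frame.columns)
    if got != expected:
        raise SchemaError(
            f"{path}: header mismatch: expected {expected}, got {got}"
        )


def _opt(value) -> str | None:
    if pd.isna(value) or value == "":
        return None
    return str(value)


def read_mortality_csv(path) -> list[MortalityRecord]:
    """Read and validate per-cage mortality records.

    Row numbers in error messages refer to file lines (header = line 1).
    An empty file with a valid header yields an empty list with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"species": str, "sex": str, "run_id": str, "cage_id": str})
    _check_header(frame, MORTALITY_COLUMNS, path)
    if frame.empty:
        warnings.warn(f"{path}: no data rows")
        return []
    records: list[MortalityRecord] = []
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            records.append(
                MortalityRecord(
                    species=str(row["species"]),
                    sex=_opt(row["sex"]),
                    run_id=str(row["run_id"]),
                    cage_id=str(row["cage_id"]),
                    dose=float(row["dose_ug_per_bee"]),
                    n_exposed=int(row["n_exposed"]),
                    n_dead=int(row["n_dead"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {line}: {exc}") from exc
    return records


def write_mortality_csv(records: Sequence[MortalityRecord], path) -> None:
    """Write mortality records in the canonical column order."""
    frame = pd.DataFrame(
        [
            {
                "species": r.species,
                "sex": r.sex,
                "run_id": r.run_id,
                "cage_id": r.cage_id,
                "dose_ug_per_bee": r.dose,
                "n_exposed": r.n_exposed,
                "n_dead": r.n_dead,
            }
            for r in records
        ],
        columns=MORTALITY_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_endpoints_csv(path) -> list[SpeciesEndpoint]:
    """Read a species endpoint table; empty cells become None."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"species": str, "sex": str, "source": str})
    _check_header(frame, ENDPOINT_COLUMNS, path)
    endpoints: list[SpeciesEndpoint] = []
    for idx, row in frame.iterrows():
        line = idx + 2
        lo, hi = row["ld50_lo"], row["ld50_hi"]
        has_lo, has_hi = pd.notna(lo), pd.notna(hi)
        if has_lo != has_hi:
            raise SchemaError(f"{path}: line {line}: ld50_lo/ld50_hi must both be present or both empty")
        try:
            endpoints.append(
                SpeciesEndpoint(
                    species=str(row["species"]),
                    sex_or_caste=_opt(row["sex"]),
                    ld50=float(row["ld50"]),
                    ld50_ci=(float(lo), float(hi)) if has_lo else None,
                    mean_fresh_weight_mg=float(row["fresh_weight_mg"]) if pd.notna(row["fresh_weight_mg"]) else None,
                    mean_dry_weight_mg=float(row["dry_weight_mg"]) if pd.notna(row["dry_weight_mg"]) else None,
                    source=str(row["source"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {line}: {exc}") from exc
    return endpoints


def write_endpoints_csv(endpoints: Sequence[SpeciesEndpoint], path) -> None:
    """Write endpoints so that a reread reproduces them exactly."""
    frame = pd.DataFrame(
        [
            {
                "species": e.species,
                "sex": e.sex_or_caste,
                "ld50": e.ld50,
                "ld50_lo": e.ld50_ci[0] if e.ld50_ci else None,
                "ld50_hi": e.ld50_ci[1] if e.ld50_ci else None,
                "fresh_weight_mg": e.mean_fresh_weight_mg,
                "dry_weight_mg": e.mean_dry_weight_mg,
                "source": e.source,
            }
            for e in endpoints
        ],
        columns=ENDPOINT_COLUMNS,
    )
    frame.to_csv(path, index=False)


@dataclass
class AnalysisConfig:
    """Configuration of one full pipeline run.

    Either ``mortality_csv`` (raw cage records, LD50s are fitted) or
    ``endpoints_csv`` (pre-computed endpoints) must be given; both may be,
    in which case the endpoint file supplies weights and literature
    entries to merge with the fitted LD50s.
    """

    seed: int
    mortality_csv: str | None = None
    endpoints_csv: str | None = None
    endpoint_set: str = "tested+literature"  # or "tested"
    alpha: float = 0.05
    hd_p: float = 0.05
    n_boot: int = 5000
    safety_factor: float = 10.0
    surrogate_ld50: float = 0.18
    rounding: int = 2
    qc_threshold: float = 0.10
    extrapolate_weights_mg: dict[str, float] = field(default_factory=dict)
    extrapolation_predictor: str = "dry"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "hd_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.endpoint_set not in ("tested", "tested+literature"):
            raise ValueError(f"endpoint_set must be 'tested' or 'tested+literature', got {self.endpoint_set!r}")
        if self.mortality_csv is None and self.endpoints_csv is None:
            raise ValueError("config needs mortality_csv and/or endpoints_csv")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
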