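"""End-to-end orchestration: records -> endpoints -> SSD -> allometry.

:func:`run_pipeline` executes the full analysis in order, mirroring how the
endpoint table, the hazardous-dose estimate and the weight-sensitivity
models fit together: per-species LD50s are fitted from raw cage records
(replicate runs pooled by geometric mean), merged with weights and any
literature endpoints, compared pairwise by the Bonferroni-adjusted
CI-overlap rule, summarised into a log-normal SSD with a bootstrap
lower-limit HD, checked against the surrogate-species threshold, and
regressed on body weight to extrapolate untested species. The resulting
:class:`PipelineReport` serialises to deterministic JSON: the same config
and seed yield byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .allometry import extrapolate_ld50, fit_weight_sensitivity
from .dose_response import (
    DoseResponseFit,
    ci_overlap_groups,
    fit_dose_response,
    pooled_geometric_mean_ld50,
    qc_control_mortality,
)
from .endpoints import SpeciesEndpoint, endpoint_table
from .io import AnalysisConfig, read_endpoints_csv, read_mortality_csv, write_endpoints_csv
from .ssd import bootstrap_hd_ci, fit_ssd, hd_quantile, surrogate_comparison

__all__ = ["PipelineReport", "run_pipeline"]

logger = logging.getLogger("beetox")


def _json_default(obj):
    """Coerce numpy scalars/arrays left over from computation to JSON types."""
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


@dataclass
class PipelineReport:
    """All results of one pipeline run, JSON-serialisable and seed-stamped."""

    endpoints: list[dict]
    comparisons: list[dict] | None
    groups: dict[str, str] | None
    qc: list[dict] | None
    ssd: dict | None
    hd: dict | None
    surrogate: dict | None
    allometry: dict[str, dict | None]
    extrapolations: list[dict]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2,
                          default=_json_default)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")


def _fit_endpoints(records, config: AnalysisConfig) -> list[SpeciesEndpoint]:
    """Fit one endpoint per (species, sex); geometric-mean pool across runs."""
    groups: dict[tuple[str, str | None, str], list] = {}
    for r in records:
        groups.setdefault((r.species, r.sex, r.run_id), []).append(r)

    by_subject: dict[tuple[str, str | None], list[DoseResponseFit]] = {}
    for (species, sex, run_id), recs in sorted(groups.items(), key=lambda kv: kv[0]):
        t0 = time.perf_counter()
        fit = fit_dose_response(recs, confidence=1 - config.alpha,
                                qc_threshold=config.qc_threshold)
        logger.info("fit %s/%s run %s: LD50=%.4g (%.2fs)", species, sex, run_id,
                    fit.ld50, time.perf_counter() - t0)
        by_subject.setdefault((species, sex), []).append(fit)

    endpoints: list[SpeciesEndpoint] = []
    for (species, sex), fits in by_subject.items():
        if len(fits) == 1:
            endpoints.append(fits[0].to_endpoint())
        else:
            # replicate runs: geometric-mean LD50, limits pooled the same way
            ld50 = pooled_geometric_mean_ld50([f.ld50 for f in fits])
            cis = [f.ld50_ci for f in fits if f.ld50_ci is not None]
            ci = None
            if len(cis) == len(fits):
                ci = (
                    pooled_geometric_mean_ld50([c[0] for c in cis]),
                    pooled_geometric_mean_ld50([c[1] for c in cis]),
                )
            endpoints.append(
                SpeciesEndpoint(
                    species=species, sex_or_caste=sex, ld50=ld50, ld50_ci=ci,
                    ci_level=1 - config.alpha, source="tested",
                )
            )
    return endpoints


def _merge_weights(fitted: list[SpeciesEndpoint], table: list[SpeciesEndpoint]):
    """Attach weights from an endpoint table to fitted endpoints; pass the rest through."""
    index = {(e.species, e.sex_or_caste): e for e in table}
    merged: list[SpeciesEndpoint] = []
    seen = set()
    for e in fitted:
        key = (e.species, e.sex_or_caste)
        ref = index.get(key)
        if ref is not None:
            e.mean_fresh_weight_mg = ref.mean_fresh_weight_mg
            e.mean_dry_weight_mg = ref.mean_dry_weight_mg
            seen.add(key)
        merged.append(e)
    for key, ref in index.items():
        if key not in seen:
            merged.append(ref)
    return merged


def run_pipeline(config: AnalysisConfig) -> PipelineReport:
    """Run every analysis stage the configuration enables.

    With only an endpoint CSV, the dose-response stage is skipped and the
    SSD/allometry stages run directly on the supplied endpoints.
    """
    t_start = time.perf_counter()
    records = None
    qc_rows = None
    if config.mortality_csv:
        records = read_mortality_csv(config.mortality_csv)

    table = read_endpoints_csv(config.endpoints_csv) if config.endpoints_csv else []

    if records:
        endpoints = _merge_weights(_fit_endpoints(records, config), table)
        qc_rows = qc_control_mortality(records, config.qc_threshold).to_dict("records")
    else:
        logger.info("no mortality records: skipping dose-response stage")
        endpoints = table
    if not endpoints:
        raise ValueError("pipeline produced no endpoints; check the input files")

    comparisons = groups = None
    with_ci = [e for e in endpoints if e.ld50_ci is not None]
    if len(with_ci) >= 2:
        comp, letters = ci_overlap_groups(with_ci, alpha=config.alpha)
        comparisons = [
            {
                "pair": list(c.pair),
                "adjusted_confidence": c.adjusted_confidence,
                "significant": c.significant,
            }
            for c in comp
        ]
        groups = letters

    if config.endpoint_set == "tested":
        ssd_endpoints = [e for e in endpoints if e.source == "tested"]
    else:
        ssd_endpoints = list(endpoints)

    ssd_dict = hd_dict = surrogate_dict = None
    if len({e.ld50 for e in ssd_endpoints}) >= 2:
        t0 = time.perf_counter()
        fit = fit_ssd(ssd_endpoints)
        hd_est = bootstrap_hd_ci(fit, p=config.hd_p, n_boot=config.n_boot, seed=config.seed)
        surr = surrogate_comparison(hd_est, config.surrogate_ld50,
                                    config.safety_factor, config.rounding)
        logger.info("SSD/HD%g with %d bootstrap iterations (%.2fs)",
                    config.hd_p * 100, config.n_boot, time.perf_counter() - t0)
        ssd_dict = {
            "mu_log10": fit.mu_log10,
            "sigma_log10": fit.sigma_log10,
            "n": fit.n,
            "endpoint_ids": list(fit.endpoint_ids),
        }
        hd_dict = dataclasses.asdict(hd_est)
        surrogate_dict = dataclasses.asdict(surr)

    allometry_results: dict[str, dict | None] = {}
    models = {}
    for predictor in ("fresh", "dry"):
        for include_lit in (False, True):
            key = f"{predictor}_{'with' if include_lit else 'no'}_literature"
            try:
                model = fit_weight_sensitivity(endpoints, predictor, include_lit)
                models[(predictor, include_lit)] = model
                allometry_results[key] = {
                    "slope_a": model.slope_a,
                    "intercept_b": model.intercept_b,
                    "se_a": model.se_a,
                    "se_b": model.se_b,
                    "p_a": model.p_a,
                    "p_b": model.p_b,
                    "r_squared": model.r_squared,
                    "n": model.n,
                }
            except ValueError as exc:
                logger.warning("allometric fit %s skipped: %s", key, exc)
                allometry_results[key] = None

    extrapolations = []
    extrap_model = models.get((config.extrapolation_predictor, False))
    if extrap_model is not None:
        for species, weight in sorted(config.extrapolate_weights_mg.items()):
            pred = extrapolate_ld50(extrap_model, weight, species=species)
            extrapolations.append(
                {
                    "species": pred.species,
                    "weight_mg": pred.weight_mg,
                    "predicted_ld50": pred.predicted_ld50,
                    "predicted_ld50_rounded": round(pred.predicted_ld50, config.rounding),
                    "beyond_data": pred.beyond_data,
                }
            )

    table_frame = endpoint_table(endpoints)
    report = PipelineReport(
        endpoints=json.loads(table_frame.to_json(orient="records")),
        comparisons=comparisons,
        groups=groups,
        qc=qc_rows,
        ssd=ssd_dict,
        hd=hd_dict,
        surrogate=surrogate_dict,
        allometry=allometry_results,
        extrapolations=extrapolations,
        provenance={
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
            "beetox_version": __version__,
        },
    )
    if config.out_dir:
        report.write(config.out_dir)
        write_endpoints_csv(endpoints, Path(config.out_dir) / "endpoints.csv")
    logger.info("pipeline complete (%.2fs)", time.perf_counter() - t_start)
    return report
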