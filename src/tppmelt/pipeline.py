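"""End-to-end orchestration of the temperature-range and concentration-range
analyses, with a run manifest recording configuration, counts and timings."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .differential import analyze_tr
from .doseresponse import classify_ccr, fit_dose_response
from .io import IntensityMatrix, RunConfig, read_intensity_table
from .normalize import NormalizationReport, normalize_ccr, normalize_tr

logger = logging.getLogger("tppmelt")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    mode: str
    config: dict
    seed: int
    version: str = ""
    input_hashes: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _version() -> str:
    from . import __version__
    return __version__


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


class StageError(RuntimeError):
    """Error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_tr_pipeline(
    matrix: IntensityMatrix, config: Optional[RunConfig] = None
) -> tuple[pd.DataFrame, NormalizationReport, RunManifest]:
    """Normalize (three steps), fit and differentially analyze a TR matrix."""
    config = config or RunConfig(mode="TR")
    manifest = RunManifest(mode="TR", config=asdict(config),
                           seed=config.rng_seed, version=_version(),
                           started=_now())
    manifest.counts["proteins_in"] = matrix.n_proteins
    manifest.counts["samples"] = matrix.n_samples

    t0 = time.perf_counter()
    try:
        normalized, report = normalize_tr(matrix, config)
    except Exception as exc:  # noqa: BLE001 - tag with stage and re-raise
        raise StageError("normalization", exc) from exc
    manifest.timings_s["normalization"] = round(time.perf_counter() - t0, 3)
    manifest.counts["proteins_excluded"] = len(report.excluded)
    manifest.counts["proteins_normalized"] = normalized.n_proteins
    logger.info("normalized %d proteins (%d excluded)",
                normalized.n_proteins, len(report.excluded))

    t0 = time.perf_counter()
    try:
        results = analyze_tr(normalized, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("differential", exc) from exc
    manifest.timings_s["differential"] = round(time.perf_counter() - t0, 3)
    manifest.counts["proteins_significant"] = int(results["significant"].sum())
    manifest.finished = _now()
    return results, report, manifest


def run_ccr_pipeline(
    matrix: IntensityMatrix, config: Optional[RunConfig] = None
) -> tuple[pd.DataFrame, RunManifest]:
    """Normalize and dose-response-analyze a concentration-range matrix.

    Per protein and assay temperature, the replicate measurements at the
    nonzero concentrations are pooled into one multi-start fit; responder
    direction and mechanism come from the 50 vs 37 deg C contrast.
    """
    config = config or RunConfig(mode="CCR")
    manifest = RunManifest(mode="CCR", config=asdict(config),
                           seed=config.rng_seed, version=_version(),
                           started=_now())
    manifest.counts["proteins_in"] = matrix.n_proteins
    manifest.counts["samples"] = matrix.n_samples

    t0 = time.perf_counter()
    try:
        normalized = normalize_ccr(matrix)
    except Exception as exc:  # noqa: BLE001
        raise StageError("normalization", exc) from exc
    manifest.timings_s["normalization"] = round(time.perf_counter() - t0, 3)

    samples = normalized.samples
    hot = samples["assay_temperature"] >= 45.0
    cols = {"hot": list(samples.index[hot]), "cold": list(samples.index[~hot])}
    concs = {k: samples.loc[v, "concentration"].to_numpy(float)
             for k, v in cols.items()}

    t0 = time.perf_counter()
    rows = []
    n_fit_failures = 0
    for pid in normalized.protein_ids:
        row = normalized.values.loc[pid]
        fits = {}
        for key in ("hot", "cold"):
            y = row[cols[key]].to_numpy(float)
            try:
                fits[key] = fit_dose_response(concs[key], y)
            except ValueError:
                fits[key] = None
        if fits["hot"] is None or fits["cold"] is None:
            n_fit_failures += 1
            continue
        res = classify_ccr(
            pid, fits["hot"], fits["cold"],
            r2_threshold=config.responder_r2_threshold,
            r2_difference_threshold=config.r2_difference_threshold,
        )
        p50 = res.fit_50.params
        rows.append({
            "protein_id": pid,
            "pec50": p50.pec50 if p50 else np.nan,
            "hill": p50.hill if p50 else np.nan,
            "r_low": p50.r_low if p50 else np.nan,
            "r_high": p50.r_high if p50 else np.nan,
            "ec50_nm": p50.ec50_nm if p50 else np.nan,
            "pseudo_r2_50": res.pseudo_r2_50,
            "pseudo_r2_37": res.pseudo_r2_37,
            "r2_difference": res.r2_difference,
            "on_bound": res.fit_50.on_bound,
            "direction": res.direction,
            "mechanism": res.mechanism,
        })
    manifest.timings_s["dose_response"] = round(time.perf_counter() - t0, 3)

    results = pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame()
    manifest.counts["proteins_fit"] = len(results)
    manifest.counts["fit_failures"] = n_fit_failures
    if len(results):
        manifest.counts["responders_positive"] = int(
            (results["direction"] == "positive").sum())
        manifest.counts["responders_negative"] = int(
            (results["direction"] == "negative").sum())
    manifest.finished = _now()
    return results, manifest


def run_tr_pipeline_from_files(
    intensity_path, annotation_path, config: Optional[RunConfig] = None
):
    matrix = read_intensity_table(intensity_path, annotation_path)
    results, report, manifest = run_tr_pipeline(matrix, config)
    manifest.input_hashes = {
        str(intensity_path): _file_hash(intensity_path),
        str(annotation_path): _file_hash(annotation_path),
    }
    return results, report, manifest


def run_ccr_pipeline_from_files(
    intensity_path, annotation_path, config: Optional[RunConfig] = None
):
    matrix = read_intensity_table(intensity_path, annotation_path)
    results, manifest = run_ccr_pipeline(matrix, config)
    manifest.input_hashes = {
        str(intensity_path): _file_hash(intensity_path),
        str(annotation_path): _file_hash(annotation_path),
    }
    return results, manifest
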