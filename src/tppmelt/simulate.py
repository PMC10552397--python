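"""Synthetic TMT thermal-profiling datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-protein sigmoidal melting over the ten-temperature grid, a paired
compound/vehicle TMT design, per-sample multiplicative scale errors
(pipetting and cell-count differences — exactly what step-1 normalization
must remove), log-normal replicate noise on the reporter intensities, and
random dropout.  Treatment effects are a melting-point shift (thermal
(de)stabilization), an abundance shift applied at all temperatures, or
neither.

Every protein draws from its own random substream derived from the master
seed and the protein index, so enlarging a simulated cohort never perturbs
the proteins already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import MeltingParams
from .doseresponse import dr_model
from .io import (
    IntensityMatrix,
    SampleAnnotation,
    annotations_to_frame,
    build_ccr_design,
    build_tr_design,
)

#: Heat-challenge temperatures (deg C) of the standard ten-point
#: temperature-range design.
TEMPERATURE_GRID = (36.5, 41.2, 44.0, 47.1, 49.8, 53.3, 56.0, 59.2, 64.0, 67.0)

AFFECTED_CLASSES = (
    "unaffected", "stabilized", "destabilized", "abundance_up", "abundance_down",
)


def make_temperature_grid() -> list[float]:
    """The ten heat-challenge temperatures, ascending, 36.5-67.0 deg C."""
    return list(TEMPERATURE_GRID)


def make_concentration_series(
    top: float = 6400.0, steps: int = 9, dilution: float = 4.0
) -> list[float]:
    """Vehicle plus a geometric dilution series up to ``top`` nM.

    Defaults give the standard ten-sample series 0, 0.098, 0.39, ...,
    6400 nM (fourfold dilutions; displayed values round to 2 significant
    figures).
    """
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if dilution <= 1:
        raise ValueError("dilution factor must exceed 1")
    series = [top / dilution**k for k in range(steps - 1, -1, -1)]
    return [0.0] + series


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth simulation parameters for one protein."""

    protein_id: str
    base_params: MeltingParams  # vehicle-arm melting curve (relative units)
    baseline: float             # absolute intensity scale
    delta_tm: float             # deg C added to T_m in the compound arm
    abundance_log2fc: float     # log2 shift of the compound arm, all temps
    affected_class: str
    pec50: Optional[float] = None
    hill: Optional[float] = None

    def __post_init__(self):
        if self.affected_class not in AFFECTED_CLASSES:
            raise ValueError(f"unknown class {self.affected_class!r}")
        if self.affected_class == "unaffected" and (
            self.delta_tm != 0 or self.abundance_log2fc != 0
        ):
            raise ValueError("unaffected proteins must have zero effects")

    @property
    def compound_params(self) -> MeltingParams:
        p = self.base_params
        return MeltingParams(p.i_min, p.i_max, p.tm + self.delta_tm, p.s)


@dataclass
class NoiseModel:
    """Noise structure of a simulated reporter-intensity dataset.

    cv
        Coefficient of variation of the multiplicative log-normal
        measurement noise (mean-one), per (protein, sample) cell.
    sample_scale_sd
        SD of per-sample log2 scale errors shared across proteins
        (pipetting / cell-count differences).
    missing_rate
        Bernoulli dropout probability per cell.
    """

    cv: float = 0.1
    sample_scale_sd: float = 0.1
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.cv < 0 or self.sample_scale_sd < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def log_sigma(self) -> float:
        """Log-scale SD giving multiplicative noise with the requested CV."""
        return float(np.sqrt(np.log1p(self.cv**2)))


@dataclass
class TruthSpec:
    """Cohort composition and effect sizes for a simulation.

    Default effect sizes: +2.0 deg C melting-point shift for stabilized
    proteins (the scale of a genuine small-molecule target engagement),
    -2.0 deg C for destabilized, and a twofold (+/-1 log2) abundance shift.
    Baseline abundances span three orders of magnitude (log-uniform);
    vehicle melting points are drawn within 42-60 deg C and slopes are
    negative so the curves are informative on the standard grid.
    """

    proportions: dict = field(default_factory=lambda: {"unaffected": 1.0})
    delta_tm: float = 2.0
    abundance_log2fc: float = 1.0
    pec50: float = 8.58
    hill: float = 1.0
    tm_range: tuple = (42.0, 60.0)
    slope_range: tuple = (-0.75, -0.3)  # melting transitions ~6-15 deg C wide
    i_min_range: tuple = (0.0, 0.15)
    baseline_range: tuple = (1e5, 1e8)

    def __post_init__(self):
        unknown = set(self.proportions) - set(AFFECTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in proportions: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    # stable per-protein substream: depends only on (seed, index)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, index)))


def _sample_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))


def _draw_truth(spec: TruthSpec, rng: np.random.Generator, pid: str) -> TruthRecord:
    classes = sorted(spec.proportions)  # sorted for seed stability
    probs = np.array([spec.proportions[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]

    lo, hi = np.log10(spec.baseline_range[0]), np.log10(spec.baseline_range[1])
    baseline = float(10 ** rng.uniform(lo, hi))
    params = MeltingParams(
        i_min=float(rng.uniform(*spec.i_min_range)),
        i_max=1.0,
        tm=float(rng.uniform(*spec.tm_range)),
        s=float(rng.uniform(*spec.slope_range)),
    )
    delta_tm = {"stabilized": spec.delta_tm, "destabilized": -spec.delta_tm}.get(cls, 0.0)
    ab = {"abundance_up": spec.abundance_log2fc,
          "abundance_down": -spec.abundance_log2fc}.get(cls, 0.0)
    return TruthRecord(
        protein_id=pid, base_params=params, baseline=baseline,
        delta_tm=delta_tm, abundance_log2fc=ab, affected_class=cls,
        pec50=spec.pec50 if cls != "unaffected" else None,
        hill=spec.hill if cls != "unaffected" else None,
    )


def _apply_noise(mu: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    sigma = noise.log_sigma
    if sigma > 0:
        # mean-one log-normal: marginal CV of the factor equals noise.cv
        mu = mu * np.exp(rng.normal(0.0, sigma, size=mu.shape) - 0.5 * sigma**2)
    if noise.missing_rate > 0:
        drop = rng.random(mu.shape) < noise.missing_rate
        mu = np.where(drop, np.nan, mu)
    return mu


def simulate_tr_experiment(
    n_proteins: int,
    truth_spec: Optional[TruthSpec] = None,
    noise: Optional[NoiseModel] = None,
    design: Optional[Sequence[SampleAnnotation]] = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, list[TruthRecord]]:
    """Simulate a paired compound/vehicle temperature-range experiment.

    Each intensity is baseline x sigmoid(T; arm parameters) x 2^(abundance
    shift, compound arm) x 2^(per-sample scale error) x log-normal noise,
    followed by dropout.  Returns the matrix and the per-protein truth.
    """
    truth_spec = truth_spec or TruthSpec()
    noise = noise or NoiseModel()
    if design is None:
        design = build_tr_design(make_temperature_grid(), replicates=3)
    ann = annotations_to_frame(list(design))

    scale_log2 = _sample_rng(seed).normal(0.0, noise.sample_scale_sd, len(ann)) \
        if noise.sample_scale_sd > 0 else np.zeros(len(ann))

    temps = ann["temperature"].to_numpy(float)
    is_compound = (ann["treatment"] == "compound").to_numpy()

    rows, truths = [], []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        rng = _protein_rng(seed, i)
        truth = _draw_truth(truth_spec, rng, pid)
        truths.append(truth)

        veh = truth.base_params.predict(temps)
        comp = truth.compound_params.predict(temps) * 2.0**truth.abundance_log2fc
        mu = truth.baseline * np.where(is_compound, comp, veh)
        mu = mu * 2.0**scale_log2
        rows.append(_apply_noise(mu, noise, rng))

    values = pd.DataFrame(rows, index=[t.protein_id for t in truths],
                          columns=ann.index)
    return IntensityMatrix(values, ann), truths


def simulate_ccr_experiment(
    n_proteins: int,
    truth_spec: Optional[TruthSpec] = None,
    noise: Optional[NoiseModel] = None,
    design: Optional[Sequence[SampleAnnotation]] = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, list[TruthRecord]]:
    """Simulate a compound-concentration-range experiment (50 + 37 deg C).

    At 50 deg C a (de)stabilized protein's soluble fraction follows a
    log-logistic dose-response between its vehicle survival and its
    shifted-curve survival; at 37 deg C it is flat.  Abundance-affected
    proteins show the same dose trend at both temperatures.
    """
    truth_spec = truth_spec or TruthSpec()
    noise = noise or NoiseModel()
    if design is None:
        design = build_ccr_design(make_concentration_series(), replicates=3)
    ann = annotations_to_frame(list(design))

    scale_log2 = _sample_rng(seed).normal(0.0, noise.sample_scale_sd, len(ann)) \
        if noise.sample_scale_sd > 0 else np.zeros(len(ann))

    concs = ann["concentration"].to_numpy(float)
    assay_t = ann["assay_temperature"].to_numpy(float)
    hot = assay_t >= 45.0

    rows, truths = [], []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        rng = _protein_rng(seed, i)
        truth = _draw_truth(truth_spec, rng, pid)
        truths.append(truth)

        surv_cold_0 = float(truth.base_params.predict(37.0))
        surv_hot_0 = float(truth.base_params.predict(50.0))
        surv_hot_sat = float(truth.compound_params.predict(50.0))

        mu = np.empty(len(ann))
        for j in range(len(ann)):
            base = surv_hot_0 if hot[j] else surv_cold_0
            sat = surv_hot_sat if hot[j] else surv_cold_0
            c = concs[j]
            if truth.affected_class in ("stabilized", "destabilized") and c > 0:
                level = dr_model(c, truth.pec50, truth.hill, base, sat)
            else:
                level = base
            if truth.affected_class in ("abundance_up", "abundance_down") and c > 0:
                frac = dr_model(c, truth.pec50, truth.hill, 0.0, 1.0)
                level *= 2.0 ** (truth.abundance_log2fc * frac)
            mu[j] = truth.baseline * level
        mu = mu * 2.0**scale_log2
        rows.append(_apply_noise(mu, noise, rng))

    values = pd.DataFrame(rows, index=[t.protein_id for t in truths],
                          columns=ann.index)
    return IntensityMatrix(values, ann), truths


def truth_to_frame(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Tabulate ground-truth records (for the truth TSV output)."""
    return pd.DataFrame([
        {
            "protein_id": t.protein_id,
            "affected_class": t.affected_class,
            "baseline": t.baseline,
            "i_min": t.base_params.i_min,
            "i_max": t.base_params.i_max,
            "tm": t.base_params.tm,
            "s": t.base_params.s,
            "delta_tm": t.delta_tm,
            "abundance_log2fc": t.abundance_log2fc,
            "pec50": t.pec50,
            "hill": t.hill,
        }
        for t in truths
    ]).set_index("protein_id")
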