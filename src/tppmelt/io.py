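"""Domain types, TSV readers/writers and experiment-design construction.

The single in-memory currency of the pipeline is :class:`IntensityMatrix`:
a protein x sample table of nonnegative TMT reporter-ion intensities plus a
sample annotation table (one row per sample).  Missing values are ``NaN``
and are distinct from zero; raw zeros are converted to missing on load
because reporter-ion zeros are non-detections, and treating them as real
measurements would make log-ratios degenerate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: TMT 10plex reporter channels in mass order.
TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)

ANNOTATION_COLUMNS = (
    "sample_id", "labeling_set", "channel", "temperature",
    "treatment", "replicate", "concentration", "assay_temperature",
)

TREATMENTS = ("vehicle", "compound")


@dataclass(frozen=True)
class SampleAnnotation:
    """Annotation of one TMT channel in one labeling set.

    ``concentration`` (nM) and ``assay_temperature`` (deg C, 37 or 50) are
    only used in compound-concentration-range (CCR) mode and are ``None``
    for temperature-range (TR) samples.
    """

    sample_id: str
    labeling_set: int
    channel: str
    temperature: float
    treatment: str  # "compound" | "vehicle"
    replicate: int
    concentration: Optional[float] = None
    assay_temperature: Optional[float] = None

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Tabulate annotations, indexed by sample_id (order preserved)."""
    rows = [dataclasses.asdict(a) for a in annotations]
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    seen = df["sample_id"].duplicated()
    if seen.any():
        raise ValueError(f"duplicate sample ids: {sorted(df['sample_id'][seen])}")
    dup = df.duplicated(subset=["labeling_set", "channel"])
    if dup.any():
        raise ValueError("duplicate (labeling_set, channel) pairs")
    return df.set_index("sample_id", drop=False)


class IntensityMatrix:
    """Protein x sample reporter intensities with sample annotations.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by protein id, columns by sample id; nonnegative
        floats with ``NaN`` for missing.
    samples : DataFrame
        Annotation table indexed by sample_id, aligned with the columns of
        ``values``.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if list(values.columns) != list(samples.index):
            raise ValueError("values columns and annotation rows differ")
        if values.index.duplicated().any():
            dups = sorted(set(values.index[values.index.duplicated()]))
            raise ValueError(f"duplicate protein ids: {dups}")
        vals = values.astype(float)
        if (vals.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        self.values = vals
        self.samples = samples

    @property
    def protein_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.samples.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values[list(sample_ids)], self.samples.loc[list(sample_ids)]
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(protein_ids)], self.samples)


@dataclass
class RunConfig:
    """Thresholds and solver settings for a pipeline run."""

    mode: str = "TR"  # TR | CCR | CETSA
    significance_alpha: float = 0.05
    per_temperature_alpha: float = 0.05
    responder_r2_threshold: float = 0.8
    r2_difference_threshold: float = 0.4
    min_valid_fraction: float = 0.8
    rng_seed: int = 0
    fit_xtol: float = 1e-8
    sf_convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.mode not in ("TR", "CCR", "CETSA"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in (
            "significance_alpha", "per_temperature_alpha",
            "responder_r2_threshold", "r2_difference_threshold",
            "min_valid_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` / ``key: value`` text config."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            sep = "=" if "=" in line else ":"
            if sep not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split(sep, 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "mode":
                kwargs[key] = value
            elif key == "rng_seed":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV I/O

def read_intensity_table(path, annotation_path) -> IntensityMatrix:
    """Read a wide protein x sample TSV plus its annotation TSV.

    The first column of the intensity table holds protein ids; the remaining
    column headers must each have a matching ``sample_id`` row in the
    annotation table.  Zeros are converted to missing.
    """
    values = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.duplicated().any():
        dups = sorted(set(values.index[values.index.duplicated()]))
        raise ValueError(f"duplicate protein ids in {path}: {dups}")

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str, "channel": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation {annotation_path} lacks columns {missing_cols}")
    ann = ann.set_index("sample_id", drop=False)

    unmatched = [c for c in values.columns if c not in ann.index]
    if unmatched:
        raise ValueError(
            f"no annotation for intensity column(s): {', '.join(unmatched)}"
        )
    ann = ann.loc[list(values.columns)]

    values = values.astype(float).replace(0.0, np.nan)
    return IntensityMatrix(values, ann)


def write_intensity_table(matrix: IntensityMatrix, path, annotation_path) -> None:
    """Write the matrix and its annotation as TSV (empty cell = missing).

    Floats are written with round-trip precision so that write-then-read
    reproduces values bit-identically.
    """
    matrix.values.to_csv(path, sep="\t", na_rep="", float_format="%.17g",
                         index_label="protein_id")
    out = matrix.samples.reset_index(drop=True)
    out.to_csv(annotation_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Experiment designs

def build_tr_design(
    temperatures: Sequence[float], replicates: int
) -> list[SampleAnnotation]:
    """Construct the paired-TMT temperature-range design.

    The paired design keeps the compound-treated and vehicle sample of each
    temperature within the same TMT 10plex labeling set; the temperature
    list is split across two sets per replicate by alternating ranks of the
    ascending-sorted list (set 1 takes ranks 1,3,5,...; set 2 the rest).
    Channels are assigned in descending temperature order, vehicle before
    compound, matching the standard printed scheme.
    """
    temps = sorted(float(t) for t in temperatures)
    if len(temps) % 2:
        raise ValueError("temperature count must be even (two sets per replicate)")
    if len(set(temps)) != len(temps):
        raise ValueError("temperatures must be distinct")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    half = len(temps) // 2
    if 2 * len(temps) > len(TMT10_CHANNELS) * 2:
        raise ValueError("more than 10 channels per labeling set required")

    set_temps = (temps[0::2], temps[1::2])
    annotations: list[SampleAnnotation] = []
    set_id = 0
    for rep in range(1, replicates + 1):
        for temps_in_set in set_temps:
            set_id += 1
            channel_iter = iter(TMT10_CHANNELS)
            for t in sorted(temps_in_set, reverse=True):
                for treatment in ("vehicle", "compound"):
                    channel = next(channel_iter)
                    annotations.append(SampleAnnotation(
                        sample_id=f"{set_id}:{channel}",
                        labeling_set=set_id,
                        channel=channel,
                        temperature=t,
                        treatment=treatment,
                        replicate=rep,
                    ))
    return annotations


def build_ccr_design(
    concentrations: Sequence[float],
    replicates: int,
    assay_temperatures: Sequence[float] = (37.0, 50.0),
) -> list[SampleAnnotation]:
    """Construct the compound-concentration-range design.

    One labeling set per (assay temperature, replicate), channels assigned
    in ascending concentration order (vehicle 0 nM on the first channel).
    The heat challenge is at a fixed temperature (50 deg C, with a 37 deg C
    arm as abundance control).
    """
    concs = [float(c) for c in concentrations]
    if len(concs) > len(TMT10_CHANNELS):
        raise ValueError("more concentrations than TMT channels")
    if sorted(concs) != concs:
        raise ValueError("concentrations must be ascending")
    annotations: list[SampleAnnotation] = []
    set_id = 0
    for rep in range(1, replicates + 1):
        for assay_t in assay_temperatures:
            set_id += 1
            for channel, conc in zip(TMT10_CHANNELS, concs):
                annotations.append(SampleAnnotation(
                    sample_id=f"{set_id}:{channel}",
                    labeling_set=set_id,
                    channel=channel,
                    temperature=float(assay_t),
                    treatment="vehicle" if conc == 0 else "compound",
                    replicate=rep,
                    concentration=conc,
                    assay_temperature=float(assay_t),
                ))
    return annotations
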