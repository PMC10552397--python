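"""Three-step normalization of paired-TMT temperature-range data, plus the
concentration-range normalization.

The three steps bring a raw reporter-intensity matrix onto a scale on which
compound/vehicle ratios at matched (temperature, replicate) are meaningful:

1. *Within each temperature*: the six samples (two arms x three replicates)
   of one heat-challenge temperature are aligned so the median log2 fold
   change of every sample against a selected reference sample is zero.
   This absorbs pipetting errors and cell-count differences and relies on
   most proteins being unaffected by the compound.
2. *Between temperatures*: a summary intensity per temperature (from the
   36 pairwise sample comparisons against the lowest temperature) is fitted
   with the melting sigmoid, and each temperature group is shifted onto the
   fitted global curve.  All six samples of a group share one constant, so
   within-temperature ratios are untouched.
3. *Per protein, per labeling set*: the labeling sets of each protein are
   leveled onto a common per-protein melting curve by iterated fit/scale
   rounds (three total), leaving within-set ratios untouched.

Steps 2 and 3 multiply whole sample groups or labeling sets by shared
constants, so every compound/vehicle intensity ratio within a labeling set
is preserved (exactly in real arithmetic; to a unit in the last place in
floating point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .curves import MeltingParams, fit_melting, fit_scaling_factor
from .io import IntensityMatrix, RunConfig


@dataclass
class NormalizationReport:
    """Constants, curves and exclusions recorded by the normalization."""

    step1_constants: dict = field(default_factory=dict)   # sample_id -> c
    reference_samples: dict = field(default_factory=dict)  # temperature -> sample_id
    step2_group_intensity: dict = field(default_factory=dict)  # T -> I(T)
    step2_constants: dict = field(default_factory=dict)    # T -> c(T)
    global_curve: Optional[MeltingParams] = None
    sf_table: Optional[pd.DataFrame] = None  # (protein, set, iteration) -> sf
    protein_params: Optional[pd.DataFrame] = None
    excluded: dict = field(default_factory=dict)  # protein_id -> reason
    messages: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Step 1 — within-temperature alignment

def select_reference_sample(group: pd.DataFrame) -> int:
    """Pick the reference sample of one within-temperature group.

    Returns the positional index of the column that maximizes the number of
    positive median log2(candidate/other) fold changes over the other
    samples, i.e. the highest-level sample.  Ties break to the lowest
    column index.
    """
    cols = list(group.columns)
    if len(cols) < 2:
        raise ValueError("need at least two samples in a group")
    log_vals = np.log2(group.to_numpy(dtype=float))
    counts = np.zeros(len(cols), dtype=int)
    for i in range(len(cols)):
        for j in range(len(cols)):
            if i == j:
                continue
            diff = log_vals[:, i] - log_vals[:, j]
            shared = np.isfinite(diff)
            if not shared.any():
                raise ValueError(
                    f"samples {cols[i]!r} and {cols[j]!r} share no quantified proteins"
                )
            if np.median(diff[shared]) > 0:
                counts[i] += 1
    return int(np.argmax(counts))  # argmax returns first maximum -> lowest index


def normalize_within_temperature(
    group: pd.DataFrame, reference=None
) -> tuple[pd.DataFrame, dict, str]:
    """Align one within-temperature sample group to its reference sample.

    Every non-reference sample is multiplied by
    ``c = 2**median(log2(reference/sample))`` so its median log2 fold
    change against the reference becomes zero.  Returns the scaled group,
    the per-sample constants, and the reference sample id.

    ``reference`` overrides the automatic selection (e.g. to re-apply the
    alignment of a previous run; with the reference retained the operation
    is exactly idempotent, whereas a fresh selection is only idempotent up
    to the non-transitivity of median fold changes).
    """
    if reference is None:
        ref_col = group.columns[select_reference_sample(group)]
    else:
        if reference not in group.columns:
            raise ValueError(f"reference {reference!r} not in group")
        ref_col = reference
    log_ref = np.log2(group[ref_col].to_numpy(dtype=float))

    constants: dict = {}
    scaled = group.copy()
    for col in group.columns:
        if col == ref_col:
            constants[col] = 1.0
            continue
        diff = log_ref - np.log2(group[col].to_numpy(dtype=float))
        shared = np.isfinite(diff)
        if shared.sum() < 3:
            warnings.warn(
                f"sample {col!r}: only {int(shared.sum())} proteins shared with "
                f"reference {ref_col!r}; constant from available values",
                stacklevel=2,
            )
        if not shared.any():
            raise ValueError(f"sample {col!r} shares no proteins with reference")
        c = float(2.0 ** np.median(diff[shared]))
        constants[col] = c
        scaled[col] = group[col] * c
    return scaled, constants, ref_col


def normalize_tr_step1(
    matrix: IntensityMatrix, report: Optional[NormalizationReport] = None,
    references: Optional[dict] = None,
) -> IntensityMatrix:
    """Apply within-temperature alignment to every temperature group.

    ``references`` optionally maps temperature to a fixed reference
    sample id (e.g. ``report.reference_samples`` of a previous run).
    """
    report = report if report is not None else NormalizationReport()
    values = matrix.values.copy()
    for temp, ann in matrix.samples.groupby("temperature"):
        cols = list(ann.index)
        ref_fixed = references.get(float(temp)) if references else None
        scaled, constants, ref = normalize_within_temperature(
            values[cols], reference=ref_fixed)
        values[cols] = scaled
        report.step1_constants.update(constants)
        report.reference_samples[float(temp)] = ref
    return IntensityMatrix(values, matrix.samples)


# ---------------------------------------------------------------------------
# Step 2 — alignment to a global melting curve

def _group_log2_mean(values: pd.DataFrame, cols_t, cols_low) -> float:
    """Mean of the pairwise median log2 fold changes of two sample groups."""
    log_t = np.log2(values[cols_t].to_numpy(dtype=float))
    log_low = np.log2(values[cols_low].to_numpy(dtype=float))
    medians = []
    for i in range(log_t.shape[1]):
        for j in range(log_low.shape[1]):
            diff = log_t[:, i] - log_low[:, j]
            shared = np.isfinite(diff)
            if not shared.any():
                raise ValueError("sample pair shares no quantified proteins")
            medians.append(np.median(diff[shared]))
    return float(np.mean(medians))


def normalize_to_global_curve(
    matrix: IntensityMatrix, report: Optional[NormalizationReport] = None,
) -> IntensityMatrix:
    """Shift each temperature group onto the fitted global melting curve.

    The per-temperature summary intensity is
    ``I(T) = 2**mean(36 pairwise median log2FCs of the T group vs the
    lowest-temperature group)``; the melting sigmoid is fitted to the
    ``(T, I(T))`` points and every sample of a group is multiplied by
    ``c(T) = I_fit(T) / I(T)``.
    """
    report = report if report is not None else NormalizationReport()
    temps = sorted(matrix.samples["temperature"].unique())
    if len(temps) < 4:
        raise ValueError("need >=4 temperatures for the global 4-parameter fit")
    t_low = temps[0]
    cols_low = list(matrix.samples.index[matrix.samples["temperature"] == t_low])

    group_intensity = {}
    for t in temps:
        cols_t = list(matrix.samples.index[matrix.samples["temperature"] == t])
        group_intensity[float(t)] = float(
            2.0 ** _group_log2_mean(matrix.values, cols_t, cols_low)
        )
    report.step2_group_intensity = group_intensity

    curve, diag = fit_melting(list(group_intensity), list(group_intensity.values()))
    if curve is None:
        raise RuntimeError(
            f"global melting-curve fit failed ({diag.failure_reason}); "
            "data are not melting-shaped"
        )
    report.global_curve = curve

    values = matrix.values.copy()
    for t, i_t in group_intensity.items():
        c_t = float(curve.predict(t)) / i_t
        report.step2_constants[t] = c_t
        cols = list(matrix.samples.index[matrix.samples["temperature"] == t])
        values[cols] = values[cols] * c_t
    return IntensityMatrix(values, matrix.samples)


# ---------------------------------------------------------------------------
# Step 3 — per-protein labeling-set leveling

def quality_filter(
    matrix: IntensityMatrix, min_valid_fraction: float
) -> tuple[list, dict]:
    """Retain proteins quantified in >= ``min_valid_fraction`` of the
    channels of *every* labeling set; report exclusions with reasons."""
    kept, excluded = [], {}
    set_cols = {
        s: list(ann.index) for s, ann in matrix.samples.groupby("labeling_set")
    }
    present = matrix.values.notna()
    for pid in matrix.protein_ids:
        bad = None
        for set_id, cols in set_cols.items():
            frac = present.loc[pid, cols].mean()
            if frac < min_valid_fraction:
                bad = (set_id, frac)
                break
        if bad is None:
            kept.append(pid)
        else:
            excluded[pid] = (
                f"quantified in {bad[1]:.0%} of channels in labeling set "
                f"{bad[0]} (< {min_valid_fraction:.0%})"
            )
    return kept, excluded


def level_labeling_sets(
    matrix: IntensityMatrix,
    config: Optional[RunConfig] = None,
    report: Optional[NormalizationReport] = None,
    n_iterations: int = 3,
) -> IntensityMatrix:
    """Level each protein's labeling sets onto a common melting curve.

    Per protein: (a) each labeling set is multiplied by the ratio of the
    protein's maximum intensity across sets to its maximum in that set;
    (b) the melting sigmoid is fitted to the combined data of all sets
    (four parameters, three-parameter ``I_min = 0`` fallback); (c) with the
    fitted curve frozen, a scale factor per set is fitted (closed form) and
    divided out.  (b)-(c) run three times in total; an iteration whose
    scale factors are all within ``sf_convergence_tol`` of 1 stops early.
    Proteins failing the quality filter or whose curve cannot be fitted are
    excluded with a reason, never an error.
    """
    config = config or RunConfig()
    report = report if report is not None else NormalizationReport()

    kept, excluded = quality_filter(matrix, config.min_valid_fraction)
    report.excluded.update(excluded)

    set_cols = {
        s: list(ann.index) for s, ann in matrix.samples.groupby("labeling_set")
    }
    temps_by_set = {
        s: matrix.samples.loc[cols, "temperature"].to_numpy(float)
        for s, cols in set_cols.items()
    }
    all_temps = matrix.samples["temperature"].to_numpy(float)

    values = matrix.values.loc[kept].copy()
    sf_records = []
    param_rows = []
    final_kept = []
    for pid in kept:
        row = values.loc[pid].to_numpy(dtype=float)

        # (a) rough leveling by per-set maxima
        col_pos = {c: k for k, c in enumerate(values.columns)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            global_max = np.nanmax(row)
        if not np.isfinite(global_max) or global_max <= 0:
            report.excluded[pid] = "no positive intensities"
            continue
        for s, cols in set_cols.items():
            idx = [col_pos[c] for c in cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                set_max = np.nanmax(row[idx])
            if np.isfinite(set_max) and set_max > 0:
                row[idx] *= global_max / set_max

        # (b)/(c) iterated combined fit + per-set scale
        params = None
        failed = None
        for it in range(n_iterations):
            params, diag = fit_melting(all_temps, row, xtol=config.fit_xtol)
            if params is None:
                failed = f"melting-curve fit failed: {diag.failure_reason}"
                break
            sfs = {}
            for s, cols in set_cols.items():
                idx = [col_pos[c] for c in cols]
                try:
                    sf = fit_scaling_factor(row[idx], temps_by_set[s], params)
                except ValueError:
                    sf = np.nan
                sfs[s] = sf
                if np.isfinite(sf) and sf > 0:
                    row[idx] /= sf
                sf_records.append(
                    {"protein_id": pid, "labeling_set": s, "iteration": it + 1,
                     "sf": sf}
                )
            finite = [v for v in sfs.values() if np.isfinite(v)]
            if finite and max(abs(v - 1.0) for v in finite) < config.sf_convergence_tol:
                report.messages.append(
                    f"{pid}: scale factors converged after iteration {it + 1}"
                )
                break
        if failed is not None:
            report.excluded[pid] = failed
            continue

        values.loc[pid] = row
        final_kept.append(pid)
        param_rows.append({
            "protein_id": pid, "i_min": params.i_min, "i_max": params.i_max,
            "tm": params.tm, "s": params.s, "n_params": diag.n_params,
            "rss": diag.rss,
        })

    report.sf_table = pd.DataFrame(
        sf_records, columns=["protein_id", "labeling_set", "iteration", "sf"]
    )
    report.protein_params = (
        pd.DataFrame(param_rows).set_index("protein_id")
        if param_rows else pd.DataFrame(
            columns=["i_min", "i_max", "tm", "s", "n_params", "rss"]
        )
    )
    return IntensityMatrix(values.loc[final_kept], matrix.samples)


def normalize_tr(
    matrix: IntensityMatrix, config: Optional[RunConfig] = None
) -> tuple[IntensityMatrix, NormalizationReport]:
    """Run the full three-step temperature-range normalization."""
    config = config or RunConfig()
    report = NormalizationReport()
    step1 = normalize_tr_step1(matrix, report)
    step2 = normalize_to_global_curve(step1, report)
    step3 = level_labeling_sets(step2, config, report)
    return step3, report


# ---------------------------------------------------------------------------
# Concentration-range normalization

def normalize_ccr(matrix: IntensityMatrix) -> IntensityMatrix:
    """Normalize a concentration-range matrix to the vehicle channel.

    Within each labeling set, every sample is scaled so its median log2
    fold change against the set's vehicle (0 nM) channel is zero; each
    protein's intensities are then expressed relative to the mean of its
    vehicle-channel values at the same assay temperature.
    """
    if matrix.samples["concentration"].isna().any():
        raise ValueError("concentration annotations required for CCR normalization")
    values = matrix.values.copy()

    vehicle_cols_all = []
    for set_id, ann in matrix.samples.groupby("labeling_set"):
        veh = ann.index[ann["concentration"] == 0]
        if len(veh) != 1:
            raise ValueError(
                f"labeling set {set_id} must contain exactly one vehicle "
                f"(0 nM) channel, found {len(veh)}"
            )
        veh_col = veh[0]
        vehicle_cols_all.append(veh_col)
        log_veh = np.log2(values[veh_col].to_numpy(dtype=float))
        for col in ann.index:
            if col == veh_col:
                continue
            diff = log_veh - np.log2(values[col].to_numpy(dtype=float))
            shared = np.isfinite(diff)
            if not shared.any():
                raise ValueError(
                    f"sample {col!r} shares no proteins with vehicle channel"
                )
            values[col] = values[col] * float(2.0 ** np.median(diff[shared]))

    veh_ann = matrix.samples.loc[vehicle_cols_all]
    for assay_t, ann in veh_ann.groupby("assay_temperature"):
        cols_t = list(
            matrix.samples.index[matrix.samples["assay_temperature"] == assay_t]
        )
        ref = values[list(ann.index)].mean(axis=1)
        values[cols_t] = values[cols_t].div(ref, axis=0)
    return IntensityMatrix(values, matrix.samples)
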