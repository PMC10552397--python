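"""Per-protein differential analysis of compound vs vehicle arms.

For every protein the paired design yields, per replicate, a compound and a
vehicle melting curve over the full temperature grid.  The analysis
separates two kinds of treatment effect:

* a *thermal-stability* effect — the melting point of the compound arm is
  shifted against the vehicle arm (mean per-replicate ``delta T_m`` with a
  one-sample t-test), and
* an *abundance* effect — a log2 intensity ratio at the lowest heat-
  challenge temperature, where essentially no melting has occurred.

Per-temperature log2 ratios with paired t-tests localize where along the
curve the arms differ.  A signed distance score collates the effect over
the significant temperatures (the signed Euclidean norm of their log2
ratios), and a protein-level significance flag combines the per-temperature
p-values by Fisher's method with Benjamini-Hochberg control across
proteins.  The distance score and collation ratio here are this package's
own scoring of the paired design and are the single place to swap in an
alternative definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .curves import _fit_mode, fit_melting
from .io import IntensityMatrix, RunConfig

#: p-value reported for a zero-variance nonzero effect (flagged downstream).
MIN_P = float(np.finfo(float).tiny)


@dataclass
class DifferentialResult:
    """All per-protein differential statistics."""

    protein_id: str
    delta_tm: float = float("nan")       # mean compound - vehicle T_m, deg C
    stab_p: float = float("nan")
    stab_t: float = float("nan")
    n_delta_tm: int = 0
    abundance_log2fc: float = float("nan")  # at the lowest temperature
    abund_p: float = float("nan")
    abund_t: float = float("nan")
    per_temperature: pd.DataFrame = field(default_factory=pd.DataFrame)
    collation_ratio: float = float("nan")
    distance_score: float = 0.0
    fisher_p: float = float("nan")
    padj: float = float("nan")
    significant: bool = False
    effect_class: str = "none"
    zero_variance: bool = False


def _one_sample_test(values: np.ndarray) -> tuple[float, float, float, bool]:
    """Mean, two-sided one-sample t-test p vs 0, t statistic, degenerate flag.

    Zero-variance input is degenerate: p is 1 for an all-zero effect and
    the minimal representable p for a nonzero one (flagged).
    """
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, float("nan"), float("nan"), False
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        if mean == 0:
            return mean, 1.0, 0.0, True
        return mean, MIN_P, math.copysign(math.inf, mean), True
    t = mean / (sd / math.sqrt(len(values)))
    p = float(2.0 * stats.t.sf(abs(t), df=len(values) - 1))
    return mean, p, t, False


# ---------------------------------------------------------------------------
# Extraction of per-protein series from the matrix

def _ratio_table(row: pd.Series, samples: pd.DataFrame) -> dict:
    """Per-temperature per-replicate log2(compound/vehicle) ratios."""
    out: dict = {}
    for (temp, rep), ann in samples.groupby(["temperature", "replicate"]):
        comp = ann.index[ann["treatment"] == "compound"]
        veh = ann.index[ann["treatment"] == "vehicle"]
        if len(comp) != 1 or len(veh) != 1:
            raise ValueError(
                f"expected one compound and one vehicle sample at "
                f"(T={temp}, replicate {rep})"
            )
        c, v = row[comp[0]], row[veh[0]]
        if np.isfinite(c) and np.isfinite(v) and c > 0 and v > 0:
            out.setdefault(float(temp), {})[int(rep)] = float(np.log2(c / v))
    return out


def _arm_series(row: pd.Series, samples: pd.DataFrame) -> dict:
    """(treatment, replicate) -> (temperatures, intensities) arrays."""
    out = {}
    for (treatment, rep), ann in samples.groupby(["treatment", "replicate"]):
        t = ann["temperature"].to_numpy(float)
        y = row[ann.index].to_numpy(float)
        keep = np.isfinite(y)
        out[(treatment, int(rep))] = (t[keep], y[keep])
    return out


# ---------------------------------------------------------------------------
# Per-protein statistics

def per_temperature_tests(
    row: pd.Series, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-temperature mean log2(compound/vehicle) ratio and paired t-test.

    The paired test is a one-sample two-sided t-test of the per-replicate
    log2 ratios against zero; with fewer than two pairs the ratio is still
    reported but the p-value is absent.
    """
    ratios = _ratio_table(row, samples)
    records = []
    for temp in sorted(ratios):
        vals = np.array(list(ratios[temp].values()))
        mean, p, t, degen = _one_sample_test(vals)
        records.append({
            "temperature": temp, "log2_ratio": mean, "p": p,
            "n_pairs": len(vals), "zero_variance": degen,
        })
    return pd.DataFrame(
        records, columns=["temperature", "log2_ratio", "p", "n_pairs",
                          "zero_variance"]
    )


def compute_delta_tm(
    row: pd.Series, samples: pd.DataFrame, xtol: float = 1e-8
) -> tuple[float, float, float, int]:
    """Mean per-replicate melting-point shift and its one-sample t-test.

    Each arm of each replicate is fitted separately; replicates where
    either arm fails to fit are dropped.  Returns (mean delta T_m, p,
    t statistic, surviving replicates); the estimate is absent with fewer
    than two survivors.
    """
    series = _arm_series(row, samples)
    reps = sorted({rep for (_, rep) in series})
    shifts = []
    for rep in reps:
        tms = {}
        for arm in ("compound", "vehicle"):
            t, y = series.get((arm, rep), (np.array([]), np.array([])))
            if len(np.unique(t)) < 4:
                break
            params, _ = fit_melting(t, y, xtol=xtol)
            if params is None:
                break
            tms[arm] = params.tm
        if len(tms) == 2:
            shifts.append(tms["compound"] - tms["vehicle"])
    if len(shifts) < 2:
        return float("nan"), float("nan"), float("nan"), len(shifts)
    mean, p, t, _ = _one_sample_test(np.array(shifts))
    return mean, p, t, len(shifts)


def abundance_change(
    row: pd.Series, samples: pd.DataFrame
) -> tuple[float, float, float]:
    """Mean log2(compound/vehicle) at the lowest temperature, with t-test."""
    t_low = float(samples["temperature"].min())
    ratios = _ratio_table(row, samples).get(t_low, {})
    if not ratios:
        return float("nan"), float("nan"), float("nan")
    mean, p, t, _ = _one_sample_test(np.array(list(ratios.values())))
    return mean, p, t


def distance_score(
    per_temp: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float]:
    """Signed collated effect size over the significant temperatures.

    score = sign(mean log2 ratio over significant temperatures) x
    sqrt(sum of squared log2 ratios over those temperatures); zero when no
    temperature is significant.  The collation ratio is 2**(mean log2
    ratio over the significant temperatures).
    """
    if per_temp.empty:
        return 0.0, float("nan")
    sig = per_temp[(per_temp["p"].notna()) & (per_temp["p"] < alpha)]
    if sig.empty:
        return 0.0, float("nan")
    ratios = sig["log2_ratio"].to_numpy(float)
    mean = float(ratios.mean())
    score = math.copysign(float(np.sqrt(np.sum(ratios**2))), mean) if mean != 0 else 0.0
    return score, float(2.0**mean)


def classify_protein(
    delta_tm: float, stab_p: float, stab_t: float,
    abund_lfc: float, abund_p: float, abund_t: float,
    alpha: float = 0.05,
) -> str:
    """Dominant-effect class from the stability and abundance statistics.

    Each effect counts when its own p-value is below ``alpha``; when both
    do, the one with the larger standardized effect (|t|) is primary.
    """
    stab_sig = np.isfinite(stab_p) and stab_p < alpha and np.isfinite(delta_tm)
    abund_sig = np.isfinite(abund_p) and abund_p < alpha and np.isfinite(abund_lfc)
    if not stab_sig and not abund_sig:
        return "none"
    if stab_sig and abund_sig:
        stab_primary = abs(stab_t) >= abs(abund_t)
    else:
        stab_primary = stab_sig
    if stab_primary:
        return "stabilized" if delta_tm > 0 else "destabilized"
    return "abundance_up" if abund_lfc > 0 else "abundance_down"


# ---------------------------------------------------------------------------
# Cohort-level analysis

def analyze_protein(
    row: pd.Series, samples: pd.DataFrame, config: RunConfig
) -> DifferentialResult:
    """All per-protein statistics except the cross-protein adjustment."""
    res = DifferentialResult(protein_id=str(row.name))
    res.per_temperature = per_temperature_tests(row, samples)
    res.zero_variance = bool(res.per_temperature["zero_variance"].any()) \
        if not res.per_temperature.empty else False
    res.delta_tm, res.stab_p, res.stab_t, res.n_delta_tm = compute_delta_tm(
        row, samples, xtol=config.fit_xtol
    )
    res.abundance_log2fc, res.abund_p, res.abund_t = abundance_change(row, samples)
    res.distance_score, res.collation_ratio = distance_score(
        res.per_temperature, alpha=config.per_temperature_alpha
    )
    ps = res.per_temperature["p"].dropna()
    if len(ps):
        _, res.fisher_p = stats.combine_pvalues(
            np.clip(ps.to_numpy(float), MIN_P, 1.0), method="fisher"
        )
    res.effect_class = classify_protein(
        res.delta_tm, res.stab_p, res.stab_t,
        res.abundance_log2fc, res.abund_p, res.abund_t,
        alpha=config.significance_alpha,
    )
    return res


def analyze_tr(
    matrix: IntensityMatrix, config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Differential analysis of a normalized temperature-range matrix.

    Returns one row per protein with the thermal-shift, abundance,
    per-temperature and collated statistics.  The ``significant`` flag is
    Benjamini-Hochberg-adjusted Fisher-combined evidence below
    ``significance_alpha``.
    """
    config = config or RunConfig()
    results = [
        analyze_protein(matrix.values.loc[pid], matrix.samples, config)
        for pid in matrix.protein_ids
    ]

    fisher = np.array([r.fisher_p for r in results], dtype=float)
    ok = np.isfinite(fisher)
    padj = np.full(len(results), np.nan)
    if ok.any():
        _, padj[ok], _, _ = multipletests(fisher[ok], method="fdr_bh")
    for r, adj in zip(results, padj):
        r.padj = float(adj)
        r.significant = bool(np.isfinite(adj) and adj < config.significance_alpha)

    return results_to_frame(results, matrix.samples)


def results_to_frame(results, samples: pd.DataFrame) -> pd.DataFrame:
    temps = sorted(samples["temperature"].unique())
    rows = []
    for r in results:
        rec = {
            "protein_id": r.protein_id,
            "delta_tm": r.delta_tm,
            "stab_p": r.stab_p,
            "n_delta_tm": r.n_delta_tm,
            "abundance_log2fc": r.abundance_log2fc,
            "abund_p": r.abund_p,
            "collation_ratio": r.collation_ratio,
            "distance_score": r.distance_score,
            "fisher_p": r.fisher_p,
            "padj": r.padj,
            "significant": r.significant,
            "effect_class": r.effect_class,
            "zero_variance": r.zero_variance,
        }
        pt = r.per_temperature.set_index("temperature") if not r.per_temperature.empty \
            else pd.DataFrame()
        for t in temps:
            rec[f"log2_ratio_{t:g}C"] = (
                float(pt.loc[t, "log2_ratio"]) if t in pt.index else np.nan
            )
            rec[f"p_{t:g}C"] = float(pt.loc[t, "p"]) if t in pt.index else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("protein_id")


# ---------------------------------------------------------------------------
# CETSA immunoblot path

def analyze_cetsa(
    series: pd.DataFrame, config: Optional[RunConfig] = None
) -> DifferentialResult:
    """Differential melting analysis of single-protein immunoblot data.

    ``series`` is a long table with columns ``treatment``, ``replicate``,
    ``temperature`` and ``intensity`` (band densitometry, one protein).
    Each (treatment, replicate) series is normalized by the fitted
    ``I_max`` of its own three-parameter (``I_min = 0``) melting fit, which
    makes the analysis invariant to arbitrary positive rescaling of any
    series; series whose fit fails are excluded with a warning.  The
    normalized data then run through the standard thermal-shift and
    per-temperature statistics.
    """
    config = config or RunConfig(mode="CETSA")
    required = {"treatment", "replicate", "temperature", "intensity"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series table lacks columns {sorted(missing)}")
    if (series["intensity"].dropna() < 0).any():
        raise ValueError("band intensities must be nonnegative")

    # normalize each arm x replicate series by its fitted plateau
    rows = []
    for (arm, rep), grp in series.groupby(["treatment", "replicate"]):
        t = grp["temperature"].to_numpy(float)
        y = grp["intensity"].to_numpy(float)
        keep = np.isfinite(y)
        params = None
        if len(np.unique(t[keep])) >= 3:
            params, _ = _fit_mode(t[keep], y[keep], n_params=3,
                                  xtol=config.fit_xtol)
        if params is None:
            warnings.warn(
                f"CETSA series (treatment={arm}, replicate={rep}) could not "
                "be fitted and is excluded", stacklevel=2,
            )
            continue
        norm = grp.copy()
        norm["intensity"] = norm["intensity"] / params.i_max
        rows.append(norm)
    if not rows:
        raise ValueError("no CETSA series could be fitted")
    normalized = pd.concat(rows, ignore_index=True)

    # repackage as a one-protein matrix row + annotation table
    ann = normalized[["treatment", "replicate", "temperature"]].copy()
    ann["sample_id"] = [
        f"cetsa:{a}:{r}:{t:g}" for a, r, t in
        zip(ann["treatment"], ann["replicate"], ann["temperature"])
    ]
    ann = ann.set_index("sample_id", drop=False)
    row = pd.Series(normalized["intensity"].to_numpy(float),
                    index=ann.index, name="cetsa_protein")

    res = DifferentialResult(protein_id="cetsa_protein")
    res.per_temperature = per_temperature_tests(row, ann)
    res.delta_tm, res.stab_p, res.stab_t, res.n_delta_tm = compute_delta_tm(
        row, ann, xtol=config.fit_xtol
    )
    res.abundance_log2fc, res.abund_p, res.abund_t = abundance_change(row, ann)
    res.distance_score, res.collation_ratio = distance_score(
        res.per_temperature, alpha=config.per_temperature_alpha
    )
    res.effect_class = classify_protein(
        res.delta_tm, res.stab_p, res.stab_t,
        res.abundance_log2fc, res.abund_p, res.abund_t,
        alpha=config.significance_alpha,
    )
    return res
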