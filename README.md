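# tppmelt

Thermal proteome profiling (TPP) analysis for paired-TMT designs:
melting-curve normalization, thermal-shift vs abundance statistics, and
sigmoidal dose-response fitting — with a synthetic-data generator that
provides ground truth for every stage.

## What problem this solves

TPP measures, proteome-wide, how much of each protein stays soluble after a
brief heat challenge. A small molecule that binds a protein usually shifts
that protein's melting behavior, so comparing compound-treated and
vehicle-treated cells across a temperature gradient reveals drug targets
without labeling or immobilizing anything. In the paired-TMT variant
implemented here, the compound and vehicle sample of each temperature share
one TMT 10plex labeling set (five temperatures per set, two sets per
replicate), which makes the within-set compound/vehicle ratios directly
interpretable and lets the same experiment separate two effects:

* **thermal stability** — a shift ΔT<sub>m</sub> of the melting point,
* **abundance** — an intensity change already present at the lowest
  temperature (36.5 °C), where no melting has occurred.

The package is aimed at computational proteomics users who want a tested,
scriptable implementation of this analysis plus simulations to validate it.

## The model

The soluble fraction follows a four-parameter sigmoid in temperature
(Celsius),

```
I(T) = I_min + (I_max − I_min) / (1 + exp[(T_m/T − 1) · s · T_m])
```

with plateaus `I_min`, `I_max`, melting point `T_m` and slope `s` (< 0 for
melters). An equivalent shape parameterization uses `(a, b)` via
`exp[−(a/T − b)]` with `T_m = a/b`, `s = −b²/a`.

Before fitting, reporter intensities pass a three-step normalization:

1. **within each temperature** — the six samples (2 arms × 3 replicates)
   are aligned so each sample's median log2 fold change against a selected
   reference sample is zero (absorbs pipetting/cell-count errors);
2. **between temperatures** — a per-temperature summary intensity is fitted
   with the melting sigmoid and each temperature group is shifted onto the
   fitted global curve;
3. **per protein** — each protein's six labeling sets are leveled onto a
   common per-protein curve by three iterated fit/scale rounds.

Steps 2–3 multiply whole groups by shared constants, so the paired
compound/vehicle ratios survive normalization untouched.

Dose-response (compound-concentration-range, "CCR") experiments at a fixed
50 °C heat challenge are fitted with the standard four-parameter
log-logistic curve in log10 dose (parameters pEC50, Hill slope H, two
plateaus); fits are rated by pseudo-R² = 1 − RSS/TSS, responders need
pseudo-R² ≥ 0.8, and a 37 °C control arm separates stability from
abundance effects.

## Worked example

```python
import tppmelt as tp

# simulate a 60-sample paired TR experiment: 100 proteins, 15% thermally
# stabilized by +2 °C, realistic noise
spec = tp.TruthSpec(proportions={"unaffected": 0.85, "stabilized": 0.15})
noise = tp.NoiseModel(cv=0.1, sample_scale_sd=0.1, missing_rate=0.02)
matrix, truths = tp.simulate_tr_experiment(100, spec, noise, seed=7)

results, report, manifest = tp.run_tr_pipeline(matrix)
hits = results[results["significant"]]
print(len(results), "proteins analyzed,", len(hits), "significant")
print(hits[["delta_tm", "abundance_log2fc", "distance_score",
            "effect_class"]].round(2).head())
```

prints

```
99 proteins analyzed, 3 significant
            delta_tm  abundance_log2fc  distance_score effect_class
protein_id
P00006          2.46              0.11            1.00         none
P00078          2.20             -0.05            1.37   stabilized
P00095          1.65              0.08            0.64   stabilized
```

All three flagged proteins are true stabilized proteins (estimated
melting-point shifts `delta_tm` of 1.6–2.5 °C around the simulated
+2.0 °C; abundance log2 ratios at 36.5 °C near the true 0). One protein
failed the labeling-set quality filter, and the protein-level flag is
deliberately conservative (Benjamini–Hochberg on Fisher-combined
per-temperature p-values), so a +2 °C shift at this noise level is only
detected for a fraction of the 17 simulated stabilized proteins — ranking
by |distance score| is the more sensitive view. The same workflow is
available from the shell:

```
tppmelt simulate-tr -n 100 --stabilized 0.15 --seed 7 -o scratch/sim
tppmelt analyze-tr -i scratch/sim_intensities.tsv \
                   -a scratch/sim_annotation.tsv -o scratch/run --plots
tppmelt report -r scratch/run_results.tsv
```

Dose-response analysis works analogously with `simulate-ccr` /
`analyze-ccr`, and `analyze-cetsa` handles single-protein immunoblot
(CETSA) band series.

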