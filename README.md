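# ricewash

Targeted LC-MS/MS residue analysis for pesticides in rice: MRM
identification criteria, matrix-matched internal-standard quantification
with LOQ censoring, SANTE-style method-validation metrics, and a
washing-effect analysis based on processing factors.

The package is aimed at residue analysts and food-safety researchers who
have per-injection peak tables (quantifier/qualifier transition areas,
internal-standard area, retention time) and want a reproducible, tested
pipeline from those areas to validated concentrations and
washing-decontamination summaries. Because raw residue datasets are rarely
shareable, a first-class synthetic-data generator reproduces the study
designs (10-level matrix-matched calibration at 5–100 μg/kg, spike
recoveries at 5/10/50 μg/kg with n = 5 over three days, washing experiments
at 20 and 50 μg/kg with n = 3) with known ground truth, so every stage has
a parameter-recovery test surface.

## The statistics at the core

* **Identification** — a detection is positive only if both
  |ΔRT| = |RT_sample − RT_mean,calib| < 0.1 min and
  |ΔIR| = |IR_sample − IR_mean,calib|/IR_mean,calib × 100 < 30 %, with the
  ion ratio IR = (lower MRM transition area / higher) × 100.
* **Quantification** — OLS of the response ratio (analyte area / internal
  standard area) on concentration over matrix-matched standards;
  back-calculated concentrations below the analyte's LOQ are censored
  ("< LOQ").
* **Validation** — recovery (70–120 % window), repeatability RSDr and
  pooled within-lab reproducibility RSDR (≤ 20 %), expanded uncertainty
  U = 2·sqrt(RSDR² + bias²).
* **Washing** — processing factor PF = C_washed/C_unprocessed (ratio of
  group means), reduction %Re = 100·(1 − PF); when the washed group is
  censored the reduction is reported as the minimal bound
  "> 100·(1 − LOQ/C_unprocessed)"; significance by pooled Student's t
  (p < 0.05) after Shapiro–Wilk and Levene pre-checks.

A registry transcribing the validated 120-pesticide method (LOQ, linear
range, matrix r², recovery, RSDs) and the published washing-study summary
tables at 20 and 50 μg/kg are bundled as CSV.

## Worked example

Processing factors from the bundled 50 μg/kg washing table:

```python
import ricewash as rw
from ricewash.processing_factors import pf_results_to_frame, summarize_reductions

registry = rw.default_registry()
results = rw.pf_table_from_summaries(rw.load_washing_table(50), registry)
frame = pf_results_to_frame(results).set_index("analyte")
print(frame.loc[["Pirimiphos-methyl", "Cadusafos", "Fludioxonil", "EPN", "Carboxin"],
                ["cb_mean", "ca_mean", "pf_label", "reduction_label", "p_value"]])
```

```
                   cb_mean  ca_mean pf_label reduction_label   p_value
analyte
Pirimiphos-methyl     32.9     8.86     0.27            73.1  0.001884
Cadusafos             34.5    11.80     0.34            65.8  0.003490
Fludioxonil           24.1    24.10     1.00               0  1.000000
EPN                   21.5      NaN        –          > 53.5       NaN
Carboxin               NaN      NaN        –               –       NaN
```

Pirimiphos-methyl drops from 32.9 to 8.86 μg/kg (PF 0.27, a 73 %
reduction, significant at p < 0.05); fludioxonil is untouched by washing
(PF 1.00); EPN's washed replicates fall below its 10 μg/kg LOQ, so only the
minimal bound "> 53.5 %" is known; carboxin is censored in both groups and
stays undefined. Binning the 80 numeric reductions:

```python
s = summarize_reductions(results)
print(dict(zip(s.labels, s.fractions)))
```

```
{'< 20': 0.0875, '20–40': 0.3625, '40–60': 0.4375, '> 60': 0.1125}
```

— about 44 % of quantifiable pesticides lose 40–60 % of their residue in a
single wash and 11 % lose more than 60 %.

The same operations run from the shell:

```sh
ricewash all --seed 7 --analytes all --out run/       # synthetic end-to-end
ricewash pf --bundled-level 50 --out pf_report.csv    # published-table analysis
```

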