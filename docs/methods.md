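# Methods

## Scope and model

`ricewash` implements the data-analysis layer of a targeted LC-MS/MS
multi-residue workflow for pesticides in rice: MRM identification criteria,
matrix-matched internal-standard quantification with limit-of-quantification
(LOQ) censoring, SANTE-style method-validation metrics, and a washing-effect
analysis built on processing factors. Wet-lab chemistry (QuEChERS
extraction, chromatography, ion source settings) is out of scope and enters
only as noise and recovery parameters of the synthetic-data generator; peak
areas are the pipeline's entry point.

## Identification

Each analyte is acquired with two MRM transitions (quantifier + qualifier).
A detection is identified only if both criteria hold:

* retention time: |RT_sample − RT_mean,calib| < 0.1 min, where the reference
  is the mean RT of the analyte over a matrix-matched calibration batch;
* ion ratio: IR = (lower transition area / higher transition area) × 100,
  and |IR_sample − IR_mean,calib| / IR_mean,calib × 100 < 30 %.

Both tolerances are strict — equality fails. The ion ratio is always formed
min/max, so it is symmetric and bounded in (0, 100]; when the true ratio is
near 100 the "lowest intensity" transition can flip under noise, which is
the literal consequence of the min/max definition and is left as is. When a
registry entry carries no references, they are computed as arithmetic means
over the batch's own calibration injections. The RT criterion operates on
absolute retention times; no ratio to the internal-standard RT is formed.

## Quantification

The response ratio (quantifier area / internal-standard area) is regressed
on concentration by unweighted ordinary least squares over the calibration
levels (default levels 5–100 μg/kg, ten points); r² is the coefficient of
determination of that line, and curves with r² < 0.95 are flagged.
Concentrations are read off the inverted line; values below the analyte LOQ
are censored and reported "< LOQ"; negative back-calculations (possible at
blank level) are clamped to zero and censored with a flag rather than
raising.

Unweighted OLS is the default because the method description never mentions
weighting. Under the multiplicative noise this data shows, unweighted OLS
lets the high-concentration points dominate, and the resulting intercept
scatter is the leading error source at the bottom of the range — in
simulated batches at 7 % repeatability CV the intercept varies by roughly
±2–3 μg/kg in concentration units. A `weighting="1/x"` switch is provided
for laboratories that prefer variance-stabilised fits; the Monte-Carlo
parameter-recovery tests below therefore evaluate the spike/washing
estimators against an exactly known calibration line so that they measure
the estimator, not the calibration-fit noise.

Calibration linear ranges are tabulated in μg/L while sample levels are in
μg/kg; with the 1:1 blank-extract dilution used to build matrix-matched
standards the numeric level labels coincide, so a single numeric scale is
stored and the unit string is metadata.

## Validation metrics

Per pesticide, blank samples spiked at 5, 10 and 50 μg/kg (n = 5) on three
days by different operators yield:

* recovery = 100 × measured mean / spiked, window 70–120 %;
* RSDr = 100 × SD/mean of one day's replicates (repeatability);
* RSDR = RSD of the values pooled across days. The pooled-total convention
  was chosen over the ANOVA between-day component because the design is
  described only as "three different days". With three days the pooled
  sample RSD is a downward-biased estimate of the generating reproducibility
  CV (few between-day degrees of freedom); the parameter-recovery test
  allows ±3 points around the generating 7 %/12 % values accordingly;
* expanded uncertainty U = k·sqrt(RSDR² + bias²) with bias = recovery − 100
  and k = 2. The source study reports U per pesticide without stating its
  formula; this top-down model is standard SANTE practice, so the published
  U column is treated as reference metadata, not a reproduction target.

Precision RSDs are reported at the spike level equal to the analyte's LOQ
(the convention behind single-RSD method tables); recoveries are reported
per level, and the per-pesticide recovery is their mean. LOQ verification is
operational: the claimed LOQ passes if the recovery and precision windows
hold at that spike level; no LOQ search is performed.

## Washing analysis

Processing factor PF = Ca/Cb, the ratio of washed to unprocessed group
means (matching the published arithmetic; not the mean of per-replicate
ratios); percent reduction %Re = 100·(1 − PF), negative when residues
increase. Censoring conventions:

* washed group censored, unprocessed quantifiable: reduction reported as the
  minimal bound "> 100·(1 − LOQ/Cb)", using the analyte's registry LOQ; a
  per-row LOQ override exists because one published bound is only consistent
  with a lower LOQ than the method table lists;
* unprocessed group censored: PF and reduction undefined ("–"), even if the
  washed group is quantifiable.

A replicate-level group is called censored when its mean back-calculated
concentration falls below the LOQ.

Significance of the before/after difference: Shapiro–Wilk on each group and
Levene's test across groups (centered on means, matching SPSS-style
software) precede a two-tailed two-sample Student's t with pooled variance;
when Levene fails, Welch's t is used and the row flagged — the source
procedure is silent on a fallback, and dropping the comparison would be
worse. Zero variance in both groups: p = 1 for equal means, p = 0
otherwise. A summary-statistic variant (`summary_ttest`) reproduces the
pooled t exactly from mean ± SD and n, so published table rows can be
re-tested without raw replicates.

Reduction-bin summaries count numeric reductions into <20, 20–40, 40–60 and
≥60 % bins (half-open on the right). Censored "> x" bounds are excluded
from the bin fractions — their exact reduction is unknown — and reported as
a separate stratum; undefined rows are counted separately. Reporting
precision follows the published tables: PF to two decimals, reductions to
three significant figures.

## Synthetic-data generator

The generator emulates the study designs with known truth:

* noise is multiplicative lognormal with mean exactly 1 and requested CV
  (σ² = ln(1 + cv²), μ = −σ²/2); defaults cv_r = 0.07 within day and
  cv_R = 0.12 pooled, implemented as an extra between-day factor with
  CV = sqrt(cv_R² − cv_r²);
* the qualifier transition gets its own independent noise so realized ion
  ratios fluctuate around the analyte's true ratio; RTs jitter with Gaussian
  SD 0.02 min;
* washing experiments draw the unprocessed truth as nominal × uptake with
  uptake 0.65 by default: measured unprocessed means in this
  soak-contaminate-dry design sit well below nominal (e.g. ≈33 at nominal
  50 μg/kg), and how much of that gap is uptake versus drying loss is not
  identifiable, so the factor is a single configurable parameter;
* per-analyte defaults are spread deterministically across the analyte
  list: true recoveries 0.70–1.19 (the validated method's observed range),
  true PFs 0.70–1.00 at the 20 μg/kg level and 0.27–1.00 at 50 μg/kg (the
  published PF ranges), ion ratios 20–80 %, reference RTs 2–12 min across
  the 18-min gradient; the response slope defaults to 0.02 response-ratio
  per μg/kg;
* a single root seed feeds per-analyte, per-purpose child streams
  (`SeedSequence` spawn keys from CRC32 of the analyte and purpose names),
  so adding an analyte never shifts another analyte's draws and identical
  configs regenerate byte-identical studies.

What the generator does not emulate: chromatographic peak shapes and
integration errors, matrix-effect differences between standards and
samples, analyte-specific degradation during washing, censoring mechanisms
other than the LOQ rule, and correlated noise between the two transitions.
Passing parameter-recovery tests therefore show that the estimators are
correct under the stated noise model, not that the method performs
identically on real extracts.

## Numerical and testing choices

* OLS fits are cross-checked against a normal-equations oracle to 1e-12 and
  the 1/x-weighted fit against an independent WLS implementation; r² must
  equal the squared Pearson correlation.
* Noiseless closure: with all CVs zero the full pipeline returns true
  concentrations, 100·true recovery and true PFs to ≤1e-9 relative.
* Monte-Carlo sizes: 500 studies for recovery coverage (±5 points in ≥95 %
  of studies, per-pesticide recovery averaged over the three spike levels at
  n = 5), 1000 for PF bias (mean within 2 % relative at n = 3), 200 for the
  censoring and precision checks; these sizes give sampling errors well
  below the asserted tolerances.
* Reproduction of the published derived columns is checked at ±0.01 in PF
  and ±0.15 percentage points in reduction/bound. Rows whose printed means
  are too coarsely rounded to reproduce their printed derived value (the
  published means carry three significant figures), and bound rows implying
  a different LOQ than the method table lists, are excluded via explicit
  frozen lists in the acceptance tests; every printed PF reproduces except
  one internally contradictory row at the 50 μg/kg level.

## Known limitations

* The bundled registry carries acquisition polarity and internal-standard
  assignment as defaults (positive/TPP) because the per-compound MRM tables
  are not transcribed; these fields are metadata and never computed on.
* One wash-table analyte (metrobromuron) has no registry entry and thus no
  LOQ; its censored rows carry no bound unless an override supplies one.
* The exclusion rule that reduced 121 validated pesticides to 97
  quantifiable ones in the washing study is not reconstructable and is not
  modelled.
* Blank-interference specificity checks are represented only as pass flags;
  no formula exists for them here.
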