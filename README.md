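# mrpath

Two-sample and multivariable Mendelian randomisation (MR) for summary-level
GWAS data, with mediation decomposition, a full pleiotropy-sensitivity suite
and analytic power calculations.

The package grew out of analyses asking whether physical activity (PA)
protects against colorectal cancer directly or through body fatness: genetic
variants associated with self-reported moderate-to-vigorous PA (MVPA),
accelerometer-measured PA (AMPA) or sedentary time serve as instrumental
variables, the outcome is colorectal-cancer case–control GWAS summary data on
the log-odds scale, and adiposity traits (BMI, body-fat percentage, waist
circumference, segmental fat ratios) enter as mediators. Everything is
testable end-to-end without any data download through a synthetic
summary-statistics generator with known causal structure.

## The statistics

For variant *j*, let β̂<sub>Xj</sub> (SD units) and β̂<sub>Yj</sub> (log-OR)
be its estimated effects on exposure and outcome with standard errors
σ<sub>Xj</sub>, σ<sub>Yj</sub>.

- **IVW**: weighted regression of β̂<sub>Yj</sub> on β̂<sub>Xj</sub> through
  the origin with weights 1/σ<sub>Yj</sub>²; the multiplicative
  random-effects variant scales the SE by max(1, √(Q/(J−1))), with Q the
  Cochran heterogeneity statistic (flagged at *P* < 0.10). With correlated
  instruments the fit is generalised least squares with covariance
  Σ<sub>jk</sub> = σ<sub>Yj</sub>σ<sub>Yk</sub>r<sub>jk</sub> from an LD
  correlation matrix.
- **MR-Egger**: the same regression with an intercept after orienting rows to
  positive exposure effects; a nonzero intercept indicates directional
  pleiotropy or an InSIDE violation.
- **Weighted median / mode-based / MR-Robust**: a weighted median of the
  per-variant Wald ratios β̂<sub>Yj</sub>/β̂<sub>Xj</sub> (valid with up to
  50% invalid weight), the mode of their smoothed density (modified-Silverman
  bandwidth), and Tukey-bisquare MM regression; bootstrap SEs are seeded.
- **MR-PRESSO**: residual-sum-of-squares global pleiotropy test by parametric
  simulation, per-variant outlier tests (Bonferroni-adjusted) and a
  distortion test; the main-analysis rule removes a variant only when both
  MR-PRESSO and the leave-one-out influence screen flag it.
- **Multivariable MR**: weighted regression of β̂<sub>Yj</sub> on several
  exposures' beta columns jointly, giving each exposure's direct effect with
  the others held constant (IVW and Egger variants).
- **Mediation**: proportion mediated = 100 × (1 − direct/total) on the
  log-OR scale (difference method) or 100 × (κ̂·θ̂<sub>M</sub>)/total
  (product / two-step network method), with Monte-Carlo uncertainty
  intervals truncated to [0, 100]%.
- **Instrument strength and power**: per-variant R² = 2·EAF(1−EAF)β²,
  F = R²(N−2)/(1−R²) (F < 10 flags a weak instrument), and
  non-centrality-parameter power for a binary outcome,
  NCP = N·R²·φ(1−φ)·b² with case fraction φ.

## Worked example

```python
import numpy as np
from mrpath import MRModel, generate, study_scenario, mr_power

truth = study_scenario("ampa", seed=7)   # 5 SNPs, R²=0.002, N=91,105
data = generate(truth)
model = MRModel.from_tables(data.exposure_instruments(), data.outcome_table)
print(model.fit("ivw_random").summary())
print(model.fit("egger").summary())
power = mr_power(r2=0.002, n_outcome=92967, case_fraction=31197/92967,
                 effect=np.log(0.6))
print(f"power at OR 0.60: {power.power:.3f}")
```

prints

```
MR estimate [ivw_random] AMPA -> outcome
  n_snps = 5
  beta (log-OR/SD) = -0.4207  se = 0.1560  p = 0.007
  OR = 0.657 (95% CI 0.484, 0.891)
  Cochran Q = 4.431 (df 4, p = 0.351)
MR estimate [egger] AMPA -> outcome
  n_snps = 5
  beta (log-OR/SD) = -0.5110  se = 0.2967  p = 0.085
  OR = 0.600 (95% CI 0.335, 1.073)
  Cochran Q = 4.229 (df 3, p = 0.238)
  Egger intercept = 0.003738 (se 0.009886, p = 0.705)
power at OR 0.60: 0.908
```

The scenario's generating total effect is ln(0.60); this replicate's IVW
estimate, OR 0.657 (0.484, 0.891), is one draw around it. The Egger
intercept (p = 0.71) shows no directional pleiotropy — as it should, since
none was simulated — and Cochran's Q (p = 0.35) shows no excess
heterogeneity. A 5-SNP instrument explaining 0.2% of exposure variance
against 31,197 cases gives 91% power to detect an OR of 0.60 per SD.

The same analysis runs from the shell:

```sh
mrpath simulate --scenario ampa --seed 7 --out sim/
mrpath mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv --method ivw_random
mrpath run --config analysis.yaml        # full multi-stage pipeline
```

`mrpath run` executes read → harmonise → instrument selection → univariable
MR with all sensitivity methods → MR-PRESSO/leave-one-out with the joint
outlier rule → multivariable models → mediation → power, and writes TSV
tables plus a deterministic JSON report.

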