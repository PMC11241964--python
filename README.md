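# pvsignal

Case/non-case disproportionality analysis for pharmacovigilance
databases, built around the study design used to probe the association
between antidepressant classes and delirium reporting in older adults —
with a synthetic report generator so the whole pipeline is testable
without access to a proprietary database.

**Who it is for:** pharmacoepidemiologists and pharmacovigilance analysts
who work with ICSR line listings (reports, drugs, events) and want
reproducible, configurable signal-detection analyses; and methodologists
who want a ground-truth simulator for benchmarking disproportionality
methods.

## The statistic

Within a reporting database, *cases* are reports of the event of interest
(here: a composite delirium outcome over the preferred terms Delirium,
Confusional state, Disorientation) and *non-cases* are all other reports.
For exposure counts a, b, c, d (exposed/unexposed × case/non-case), the
crude **reporting odds ratio** is

    r-OR = (a·d) / (b·c),   95% CI = exp(log r-OR ± 1.96·√(1/a+1/b+1/c+1/d))

Adjusted r-ORs are exp(β) from a logistic regression of case status on
exposure and confounders (age band, sex, region, co-prescriptions matched
by ATC prefix, predisposing illnesses matched as preferred terms), with
Wald CIs. An exposure is a **signal** when the lower 95% bound exceeds 1;
r-ORs below 1 are never read as protective. Positive (opium alkaloids,
ATC N02AA) and negative (bisphosphonates, M05BA) control exposures
validate each run, and collinearity is checked with variance-inflation
factors.

## Worked example

`examples/02_crude_vs_adjusted.py` runs the `confounded` scenario: the
generator gives amitriptyline **no** direct effect on delirium reporting
(true OR = 1) but makes dementia both triple the odds of a delirium
report and triple the odds of amitriptyline exposure:

```
n = 20000, true OR for amitriptyline = 1.0
2x2 table: a=612 b=1820 c=3655 d=13913
crude r-OR:    1.28 [1.16-1.41]  -> signal
adjusted r-OR: 0.94 [0.85-1.05]  -> no_signal
```

The crude r-OR flags a spurious signal; adjusting for the dementia
covariate recovers the null. `examples/03_full_study.py` runs the full
class-level analysis plus control validation:

```
primary analysis (adjusted r-OR per antidepressant class):
  NSMRI   a=112  crude 1.89 [1.53-2.33]  adjusted 1.84 [1.49-2.28]  signal
  SSRI    a=179  crude 1.20 [1.02-1.41]  adjusted 1.16 [0.98-1.37]  no_signal
  ...
controls: positive (opium alkaloids) 3.00 [2.71-3.33] -> signal;
          negative (bisphosphonates) 1.05 [0.88-1.24] -> no_signal; passed=True
```

Each `a` is the number of exposed cases; `signal` means the adjusted
lower bound exceeds 1. The other examples cover simulation
(`01_simulate_reports.py`), sensitivity/age-subgroup/concomitant analyses
(`04_sensitivity_and_subgroups.py`), and YAML configuration
(`05_custom_config.py`).

A thin CLI wraps the same functions:

```bash
pvsignal simulate --preset study_like --n 20000 --seed 3 --out data/
pvsignal run --reports data/ --out results/ --analyses primary,sensitivity,controls
pvsignal controls --reports data/ --strict
```

`run` writes `results.csv`, `forest.tsv` (forest-plot data),
`results.md`, `exclusions.csv`, `vif.csv`, and `run_manifest.json`
(seed, config hash, exclusion accounting, test count).

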