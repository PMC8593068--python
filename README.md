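# clinnet

Simulation and trial-level analysis of clinician peer-network experiments on
treatment-recommendation bias.

The package models a three-round study in which practicing clinicians watch a
standardized chest-pain case (one of two patient-actor arms), give a 0–100
probability estimate of a 30-day adverse cardiac event, and choose one of four
treatment options (A: unsafe undertreatment, B: undertreatment, C:
guideline-recommended care, D: overtreatment). Clinicians in *network*
conditions sit on a connected degree-4 egalitarian graph and see the average
estimate of their four contacts between rounds; *control* clinicians revise
independently. Analysis runs at the trial level: control cells are
bootstrapped into groups matching the network cell size, each (trial,
condition, arm) cell becomes one observation, and contrasts use exact /
tie-corrected Wilcoxon tests plus trial-clustered logistic models.

## Modules

| Module | What it does |
| --- | --- |
| `clinnet.clinical` | Risk-score arithmetic (4–6 band → 16%), treatment options, correctness rules |
| `clinnet.topology` | Connected k-regular networks by degree-preserving double-edge swaps; neighbor means |
| `clinnet.simulate` | Agent-based generator: truncated-normal estimates, categorical choices, error-weighted DeGroot-style revision, control drift, attrition |
| `clinnet.metrics` | Normalized diagnostic accuracy, option rates (trial-then-grand), inequity in percentage points, A-vs-C odds, revision coefficient with clustered SE |
| `clinnet.analysis` | Bootstrap control groups, trial observations, rank-sum / signed-rank tests (exact enumeration on small n), clustered logistic OR contracts, sensitivity re-analysis |
| `clinnet.io`, `clinnet.config`, `clinnet.cli` | CSV/JSON schemas with validation, reference configuration, CLI |

## CLI

```sh
# generate a synthetic study (7 trials, 840 clinicians) with the reference config
clinnet simulate --out data.csv --seed 1 [--config config.json] [--topology-out edges.txt]

# trial-level analysis: observations.csv, tests.csv, summary.json, report.txt
clinnet analyze --data data.csv --out results/ [--config config.json] [--sensitivity bc]

# re-render the plain-text report
clinnet report --results results/ --out report.txt
```

`--sensitivity bc` re-runs everything accepting options B and C as correct.
All randomness flows from the single master seed; runs with the same seed are
byte-identical. The resolved configuration is logged to stderr. A config JSON
can be produced with `clinnet.config.save_study_config(reference_study_config(), path)`
and edited; unknown keys are rejected.

## Python API sketch

```python
from clinnet import (reference_generator, simulate_study, run_analysis,
                     revision_coefficient)

cfg = reference_generator(master_seed=1)
records = simulate_study(cfg)            # tidy table, one row per clinician-round
result = run_analysis(records)           # 28 trial-level observations + test battery
print(result.summary["inequity_initial_pp"])
```
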