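# pmcrt

Cluster-level analysis of pair-matched community randomized trials with
binary survey outcomes — from item-level questionnaire responses to crude
and covariate-adjusted cluster-level risk ratios, with an exposure-matched
secondary analysis, between-cluster variation estimation, design-stage
precision tools and a synthetic trial generator so the whole pipeline is
testable end to end.

## What's inside

| module | purpose |
|---|---|
| `pmcrt.trial_data` | domain types, validation, CSV/config I/O |
| `pmcrt.outcomes` | six built-in composite indicators + exposure classification |
| `pmcrt.cluster_analysis` | site summaries, weights, crude and adjusted (observed/expected) weighted pair+arm ANOVA, unpaired t-test sensitivity analysis, between-cluster coefficient of variation `k` |
| `pmcrt.propensity` | exposure propensity model, optimal 1:1 matching, matched re-analysis |
| `pmcrt.design_tools` | pair randomization, `k`-based precision estimates |
| `pmcrt.synthetic_cohort` | logit-normal cluster model, full synthetic trials, replication driver |
| `pmcrt.cli` / `pmcrt.report` | `pmcrt` command-line interface and report tables |

## Quick start (Python)

```python
import pmcrt

cfg = pmcrt.SimulationConfig()           # 4 pairs, 150/sex/site at follow-up
ds = pmcrt.simulate_trial(cfg, seed=1)   # baseline + follow-up rounds

spec = pmcrt.BUILTIN_SPECS["physical_ipv"]
summaries = pmcrt.summarize_sites(ds, spec, "followup")
print(pmcrt.crude_effect(summaries))     # prevalence ratio + 95% CI, df = P-1

bprev = pmcrt.baseline_ea_prevalence(ds, spec)
model = pmcrt.fit_control_model(ds, spec, bprev)
print(pmcrt.adjusted_effect(ds, spec, model=model))
```

## Command line

```bash
pmcrt simulate --seed 1 --out trial.csv
pmcrt analyze --data trial.csv --report out/ --seed 1
pmcrt replicate --reps 100 --outcome physical_ipv --seed 1 --out recovery.csv
pmcrt match --data trial.csv --report out/
pmcrt design precision --grid grid.yaml --out precision.csv
pmcrt design randomize --pairs pairs.csv --seed 1
```

`analyze` writes an effects table (one row per indicator, attitude outcomes
split by sex; pooled n/N per arm and round; crude and adjusted risk ratios
with 95% CIs), descriptive tables, a validation log and a run log that
records continuity corrections and model fallbacks.

## Statistical notes

- Crude effects: weighted least squares of site log prevalence on arm +
  matched-pair terms; CI from the t distribution on `2P - P - 1` residual
  degrees of freedom.
- Adjusted effects: a logistic model (age, marital status, baseline
  enumeration-area prevalence) fitted to control-arm follow-up respondents
  predicts each site's expected count; site log observed/expected ratios
  enter the same weighted ANOVA.
- Weights are inverse delta-method variances of the log-scale measure with
  the prevalence pooled across sites (`n * p̄ / (1 - p̄)`; expected counts for
  O/E), so a site's weight does not depend on its own sampling noise.
- A zero numerator gets 0.5 added (numerator only) so the log measure exists.
- `k` is estimated by subtracting the binomial sampling contribution from the
  empirical variance of site prevalences, truncated at zero.
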