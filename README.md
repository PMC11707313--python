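# quitcost

Trial-based economic evaluation of an emergency-department (ED) smoking
cessation intervention — provision of an e-cigarette starter kit plus brief
advice, compared with signposting to local stop-smoking services — from the
health-and-social-care payer perspective, with a lifetime Markov projection.

The package is written for health economists and trial statisticians who
need a reusable, tested pipeline for this class of two-arm cost-utility
analysis (CUA). Because individual-level trial data of this kind are rarely
redistributable, a synthetic-trial generator with known ground truth is a
first-class component: every downstream stage can be exercised and validated
end to end without any real participant data.

## What it computes

**Micro-costing.** The per-participant intervention cost is built up from
staff training (trainer and trainee opportunity costs), carbon-monoxide
monitor depreciation, e-cigarette starter kits, printed materials and
brief-advice staff time. Self-reported resource use (pharmacotherapies,
cessation advice contacts, primary/secondary healthcare) is valued against a
unit-cost schedule (GBP 2021/22).

**Outcomes.** Utilities come from EQ-5D-5L descriptors via a pluggable value
set (official tariffs are licensed, so the packaged default is a labelled
synthetic linear set). QALYs over the 6-month trial window are the
trapezoidal area under the utility curve,
`QALY = h · (u₀ + u₆)/2` with `h = 0.5` years.

**Missing data.** Missing cessation outcomes count as not abstinent;
missing baseline covariates take the full-sample mean; missing follow-up
variables are multiply imputed by chained equations with predictive mean
matching (PMM, 10 donors), separately by arm and stratified by site, with
estimates pooled by Rubin's rules. Pattern-mixture MNAR scenarios scale
only the imputed cost and utility cells.

**Incremental analysis.** Adjusted incremental costs (gamma GLM, log link,
average marginal effect of arm) and QALYs (linear model with a site
intercept) give the incremental cost-effectiveness ratio
`ICER = Δcost / ΔQALY`, with cost-effectiveness-plane dominance handling.
Uncertainty comes from bootstrap-then-impute resampling: B paired
(Δcost, ΔQALY) draws yield percentile confidence intervals and the
cost-effectiveness acceptability curve,
`CEAC(λ) = P(λ·ΔQALY − Δcost > 0)`.

**Lifetime projection.** A three-state (smoker / ex-smoker / dead) annual
cohort model runs a cohort of 1000 from the trial mean age to age 90, with
sex-specific mortality (smokers at a relative risk), natural quitting,
relapse, smoking-attributable costs and status-specific utility weights,
discounted at 3.5%/year, plus Monte-Carlo probabilistic sensitivity
analysis. The packaged parameter schedules are clearly-labelled synthetic
placeholders; substantive use requires supplying real tables.

## Worked example

```python
import quitcost as qc

total, comp = qc.intervention_cost_per_participant(qc.default_intervention_spec())
for k, v in comp.items():
    print(f"{k:>12}: £{v:.2f}")
print(f"{'total':>12}: £{total:.2f}")
```

prints the per-participant intervention cost build-up:

```
    training: £13.82
   equipment: £0.57
 starter_kit: £23.10
     leaflet: £0.39
    tote_bag: £1.47
brief_advice: £8.16
       total: £47.52
```

i.e. about £48 per participant, dominated by the starter kit (£23.10) and
training (£13.82), against £0.20 per control participant (an information
card). Dividing arm cost by abstainers gives the cessation cost per
CO-validated sustained abstainer, and `qc.icer(31.0, 0.004)` renders the
headline ratio as `£7,750 per QALY gained`.

A full synthetic run from the shell:

```bash
quitcost simulate --seed 1 --out trial.csv
quitcost cua --data trial.csv --seed 1 --m 10 --bootstrap 200 --out cua.json
quitcost report --seed 1 --out results/
```

`report` executes the whole sequence (simulate → cost → impute → CUA with
complete-case, MNAR-grid and broader-sample variants → Markov → figures)
and writes a results bundle with a run manifest; re-running with the same
seed reproduces `results.json` byte for byte.

## Layout

| module | contents |
| --- | --- |
| `quitcost.trialgen` | synthetic-trial configuration and generator |
| `quitcost.costing` | intervention cost build-up, unit-cost valuation |
| `quitcost.qaly` | value sets, utility lookup, QALY area under the curve |
| `quitcost.imputation` | outcome rule, mean imputation, MICE-PMM, Rubin pooling, MNAR |
| `quitcost.cua` | abstinence statistics, adjusted incrementals, ICER, bootstrap, CEAC |
| `quitcost.markov` | lifetime cohort model, smoking-attributable fraction, PSA |
| `quitcost.pipeline` / `quitcost.cli` | orchestration, results bundle, `quitcost` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
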