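# metacheck

Simulation and inference toolkit for uncertainty-guided checking behavior and
metacognitive sensitivity.

The package provides a tested pipeline that:

1. **simulates** cohorts of metacognitive 2AFC observers — either mechanistic
   signal-detection observers with a noisy second-order confidence readout, or
   "GLMM-mode" trial tables whose generative truth is exactly the statistical
   models below (`metacheck.synthetic_cohort`);
2. **calibrates** stimulus difficulty per subject with an adaptive
   (information-maximizing grid-posterior) psychometric procedure, and applies
   group-level outlier-exclusion rules (`metacheck.psychometrics`);
3. **estimates** explicit metacognitive efficiency (meta-d′ / M-ratio from 1–6
   confidence ratings) and implicit sensitivity (CMI, the normalized
   psychometric-slope difference between chosen and discarded trials in a
   confidence forced-choice task) (`metacheck.metacognition`);
4. **fits** the two mixed-effects models of checking behavior — a Poisson GLMM
   of per-trial check counts with a subject random intercept and an
   observation-level random effect (OLRE), and a logistic GLMM of trial
   accuracy — via a Laplace-approximation ML fitter with Wald tables,
   equality-constrained likelihood-ratio tests, VIF diagnostics, parametric
   bootstrap CIs, and exact / normal-approximation Wilcoxon signed-rank and
   Pearson correlation tests (`metacheck.inference`);
5. **orchestrates** the whole analysis with seeded reproducibility, tercile
   descriptives and CSV/JSON artifacts (`metacheck.pipeline`, CLI `metacheck`).

## CLI

```bash
# synthetic cohort CSV (+ JSON config sidecar); glmm mode = exact model truth
metacheck simulate --seed 1 --out cohort.csv --mode glmm

# adaptive calibration demo on simulated observers
metacheck calibrate --seed 1 --n-trials 120 --out fits.csv

# per-subject M-ratio / CMI from a cohort CSV
metacheck metacog --data cohort.csv --out measures.csv

# mixed-model coefficient tables
metacheck fit-m1 --data cohort.csv --out m1.csv   # Poisson checks model
metacheck fit-m2 --data cohort.csv --out m2.csv   # logistic accuracy model

# tercile descriptives
metacheck report --data cohort.csv --out report/

# full pipeline: simulate -> calibrate -> exclude -> estimate -> fit -> report
metacheck run-all --seed 1 --out artifacts/
```

`metacheck import-osf` is a documented stub printing the trial/subject schema
an external behavioral dataset must be mapped to.

## Layout

```
src/metacheck/
  synthetic_cohort.py   observers, checking policy, questionnaires, cohort I/O
  psychometrics.py      psychometric MLE, adaptive calibration, exclusions
  metacognition.py      rating tables, meta-d'/M-ratio, type-2 ROC, CMI
  inference/
    glmm.py             Laplace GLMM (subject intercept + OLRE), LRT, bootstrap
    stattests.py        exact/normal Wilcoxon signed-rank, Pearson tests
    diagnostics.py      standardization, VIF
  pipeline.py           orchestration, tercile descriptives, provenance log
  cli.py                click CLI
tests/                  unit + property tests, tests/test_acceptance.py
scripts/acceptance.py   acceptance report
```

## Notes

- Psychometric curves use `P(correct) = F(slope·(coherence − inflexion))`
  (logit or probit `F`); `predict(..., folded=True)` reports accuracy folded
  at chance. The inflexion is the chance point, so a probit observer with
  accuracy `Φ(k·c)` maps to `(slope, inflexion) = (k, 0)`.
- The GLMM fitter maximizes the Laplace-approximate marginal likelihood; the
  per-subject arrowhead structure of the (subject intercept, OLRE) Hessian
  makes each iteration O(n). With both variance components absent it reduces
  exactly to the plain GLM.
- Every stochastic entry point takes a seed or `numpy.random.Generator`;
  fixed seeds give byte-identical outputs.
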