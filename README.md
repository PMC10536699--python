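# anchorinv

Anchoring-vignette adjustment and measurement-invariance analysis for
cross-group ordinal survey data.

## The problem

When two language or cultural groups answer the same rating-scale
questionnaire, apparent group differences can be artefacts of *how* each
group uses the response scale rather than of the construct being measured
(response-category differential item functioning, RC-DIF).  The standard
audit is multi-group confirmatory factor analysis (MGCFA): the one-factor
measurement model

```
Y_ij = tau_j + Lambda_j * eta_ij + e_ij
```

is fitted simultaneously in the groups *j*, and increasingly strict
cross-group equality constraints are tested — *configural* (same model
shape), *metric* (equal loadings, `Lambda_j = Lambda`), *scalar*
(additionally equal intercepts, `tau_j = tau`).  Only under scalar
invariance are latent-mean comparisons meaningful.

Anchoring vignettes — short fixed scenarios pinned to scale levels that
every respondent rates alongside their self-reports — offer two repairs
when invariance fails:

* **non-parametric rescaling**: each self-report `y` is re-expressed
  relative to the respondent's anchor ratings `z_1 <= ... <= z_J`,
  giving the rescaled category `C` on `1..2J+1` (`C = 1` if `y < z_1`,
  `2` if `y = z_1`, `3` if `z_1 < y < z_2`, ..., `2J+1` if `y > z_J`).
  Tied or misordered anchors make `C` an integer interval `[Cs, Ce]`;
* **parametric modelling (CHOPIT)**: a compound hierarchical ordered
  probit with covariate-driven response thresholds
  (`tau^1 = gamma^1 V`, `tau^k = tau^{k-1} + exp(gamma^k V)`) estimated
  jointly from self-reports and vignette ratings; the predicted
  respondent-specific thresholds then enter the MGCFA as manifest
  covariates.

The package implements the full pipeline — a synthetic vignette-survey
generator (the reference survey data are not public), the rescaling rules
with their interval semantics, per-indicator CHOPIT estimation by
Gauss–Hermite quadrature, and a multi-group ML CFA engine with fit
indices (CFI, RMSEA, sample-size-adjusted BIC), chi-square difference
tests, score-test modification indices, and the configural/metric/scalar
decision rules (`CFI >= 0.95`, `RMSEA <= 0.08`; rejection on significant
delta-chi-square, `dCFI >= 0.005` or `dRMSEA >= 0.010`).

## Worked example

```python
from anchorinv import (
    PopulationSpec, VignetteDesign, simulate_survey,
    pooled_anchor_means, rescale_one, ordering_accuracy,
)
from anchorinv.pipeline import WorkflowConfig, run_workflow
from anchorinv.io import render_report

data = simulate_survey(PopulationSpec.default(), VignetteDesign.default(),
                       (145, 91), seed=7)
print(ordering_accuracy(data).per_group)
# {'english': 0.7709750566893424, 'arabic': 0.7730496453900709}

print(rescale_one(3, [3, 3]))         # tied anchors -> interval
# CInterval(cs=2, ce=4, j=2)

report = run_workflow(WorkflowConfig(workflow="rescaled_lowest", seed=7))
print(render_report(report))
```

The rendered report is a compact invariance table:

```
workflow: rescaled_lowest
retained n: english=145, arabic=91
model                         chi2(df)    dchi2(ddf)   RMSEA  dRMSEA     CFI    dCFI      aBIC  decision
configural                 32.87(28)             -   0.038       -   0.987       -   5033.40  supported
metric                     39.91(35)       7.03(7)   0.034  -0.004   0.987  +0.000   5024.43  supported
scalar                     43.32(42)       3.41(7)   0.016  -0.018   0.996  -0.010   5011.81  supported
```

Each row is one constraint level: its chi-square and degrees of freedom,
the change against the previous level, the fit indices, and the decision
the rule engine derives from them.  Here the generating population is
invariant, so all three levels are supported; injecting non-invariance
with `inject_noninvariance` (loading, intercept or threshold shifts)
makes the corresponding level fail.

A thin CLI mirrors the library: `anchorinv simulate | rescale | chopit |
invariance | run | report` (all accept `--seed`; see `--help`).

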