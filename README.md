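# tdm1pk

Population pharmacokinetics of trastuzumab emtansine (T-DM1), the
HER2-targeted antibody–drug conjugate, as a tested, reusable Python
package: the two-compartment covariate model of the conjugate's serum
kinetics, forward simulation of virtual trials, nonlinear mixed-effects
(FOCE-I/Laplace) estimation with stepwise covariate selection, the usual
validation machinery (VPC, NPC, bootstrap, shrinkage, prediction-error
statistics), and covariate sensitivity / subgroup exposure analyses.

It is aimed at pharmacometricians and methodologists who want to exercise
a realistic antibody–drug-conjugate PopPK analysis end to end — simulate,
fit, diagnose, interpret — without access to the original clinical trial
data, which are not public. A synthetic-cohort generator stands in for
them, reproducing the analysis-relevant structure: 3.6 mg/kg every-3-week
IV dosing, sparse-to-rich sampling over multiple cycles, log-normal
covariate distributions anchored at published percentiles, ~31.6%
proportional residual error, and omission of samples below the assay's
minimum quantifiable concentration.

## The model

Subject *i*'s clearance and central volume follow

```
CL_i = exp( θ1 + θ6·ln(WT/70) + θ7·ln(ECD/25) + θ8·ln(ALBU/41)
            + θ9·ln(TMBD/9) + θ10·TBL + θ11·ln(AST/27) + η_CL )
Vc_i = exp( θ2 + θ5·ln(WT/70) + η_Vc )
```

inside a linear two-compartment disposition model with first-order
elimination and zero-order infusion input (Q, Vp with their own log-normal
random effects; strictly proportional residual error). The shipped default
parameter file carries the published estimates — typical CL 0.676 L/day,
Vc 3.127 L, terminal half-life 3.94 days — and the package reproduces the
published covariate-effect table and steady-state exposure sensitivity
bounds from them analytically.

## Worked example

```python
import numpy as np
from tdm1pk import *

theta, omega, sigma = published_model()
ref = REFERENCE_COVARIATES                     # 70 kg, ECD 25, ALBU 41, ...
ind = individual_parameters(theta, ref, np.zeros(4))
print(f"typical CL   {ind.cl:.3f} L/day")
print(f"typical Vc   {ind.vc:.3f} L")
print(f"half-life    {terminal_half_life(ind):.2f} days")
ex = steady_state_exposure(ind, dose=3.6 * ref.weight, tau=21.0)
print(f"steady state: AUC {ex.auc_ss:.1f} ug*day/mL, "
      f"Cmax {ex.cmax_ss:.1f} ug/mL, Ctrough {ex.ctrough_ss:.2f} ug/mL")

heavy = ref.replace(weight=98.0)
print(f"CL at 98 kg  {typical_clearance(theta, heavy):.3f} L/day "
      f"({100*(typical_clearance(theta, heavy)/ind.cl - 1):+.1f}%)")

design = TrialDesign(n_subjects=40, sampling="sparse")
trial = simulate_trial(design, theta, omega, sigma, seed=7)
trial, bql = apply_mqc_censoring(trial, design.mqc)
print(f"simulated trial: {trial.n_subjects} subjects, "
      f"{trial.n_observations} samples, {100*bql:.1f}% below MQC")
```

prints

```
typical CL   0.676 L/day
typical Vc   3.127 L
half-life    3.94 days
steady state: AUC 372.8 ug*day/mL, Cmax 81.6 ug/mL, Ctrough 1.65 ug/mL
CL at 98 kg  0.797 L/day (+17.9%)
simulated trial: 40 subjects, 702 samples, 7.6% below MQC
```

A typical 70-kg patient on 3.6 mg/kg q3w reaches a steady-state AUC of
~373 µg·day/mL over one cycle with peaks near 82 µg/mL and troughs near
1.7 µg/mL; a 95th-percentile-weight patient clears ~18% faster (and, under
per-kg dosing, receives ~40% more drug, which is why weight dominates the
exposure sensitivity). The simulated sparse trial loses ~8% of its samples
to the assay's quantification limit, concentrated at pre-dose and washout
times.

Model estimation composes with scikit-learn conventions
(`PopPKEstimator().fit(dataset)` with fitted attributes `theta_`,
`omega_`, `sigma_`, `ofv_`, `etas_`), with functional wrappers
(`fit_population`, `map_individual`, `stepwise_selection`, ...) for
script use, and a `tdm1pk` command-line interface (`simulate`, `fit`,
`select`, `vpc`, `npc`, `bootstrap`, `validate`, `covtable`,
`sensitivity`, `subgroups`, `pipeline`) over CSV/YAML files.

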