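# Methods

`tdm1pk` models the serum kinetics of the antibody–drug conjugate
trastuzumab emtansine (T-DM1) at the population level, provides virtual
trials with the statistical structure such analyses assume, and estimates
the model from data by approximate maximum marginal likelihood. This note
records the model, the numerical choices, and the limits of what the
synthetic experiments can demonstrate.

## Structural and covariate model

Disposition is a linear two-compartment model with first-order elimination
from the central compartment and zero-order (infusion) input. Internally
time is in days, amounts in mg, volumes in L and concentrations in mg/L
(numerically µg/mL), so the shipped parameter set is directly usable.

Subject-level clearance and central volume carry covariate effects and
log-normal inter-individual variability (IIV):

    CL_i = exp( θ1 + θ6 ln(WT/70) + θ7 ln(ECD/25) + θ8 ln(ALBU/41)
                + θ9 ln(TMBD/9) + θ10·TBL + θ11 ln(AST/27) + η_CL )
    Vc_i = exp( θ2 + θ5 ln(WT/70) + η_Vc )
    Q_i  = exp( θ3 + η_Q ),    Vp_i = exp( θ4 + η_Vp )

with body weight WT (kg), shed HER2 extracellular domain ECD (ng/mL),
albumin (g/L), tumour burden TMBD (cm), residual baseline trastuzumab TBL
(µg/mL — the one linear, un-normalised term) and AST (IU/L). η ~ N(0, Ω)
with a free CL–Vc covariance; the residual error is strictly proportional,
DV = F·(1+ε), ε ~ N(0, σ²).

The shipped defaults (`final_model.yaml`) are the published final-model
estimates: typical CL 0.676 L/day, Vc 3.127 L, Q 1.534 L/day, Vp 0.66 L;
weight exponents 0.49 (CL) and 0.596 (Vc); IIV 19.11/11.66/180.8/74.5 %
for CL/Vc/Q/Vp with cov(η_CL, η_Vc) = 0.011; proportional CV 31.56%.
Two documented irregularities of the printed table are preserved rather
than patched: the TBL rows of the covariate-effect table are not
reproducible from the rounded coefficient −0.002/µg/mL (it yields
0.607 L/day at TBL 54, not the printed 0.615 — the unrounded estimate was
evidently ≈ −0.0018), and the printed Vc percent-change column is
inconsistent with its own estimate column, so the estimates are treated as
authoritative.

Reported "IIV %" is read as 100·ω (the SD of the log-scale η), the common
convention for exponential IIV; `OmegaMatrix.from_iiv_percent(...,
convention="cv")` provides the 100·√(exp(ω²)−1) reading. The choice does
not affect any covariate-table or exposure arithmetic, only the width of
simulated parameter distributions.

Kinetics are evaluated in closed form (bi-exponential infusion solution,
superposition over doses). Two implementations exist deliberately:
`model.concentration` (vectorised closed form, the reference) and the
estimation kernel in `_kernel.py`, which propagates the two exponential
modes sequentially through each subject's merged event list —
algebraically identical but O(doses+times) instead of O(doses×times)
exponentials, numba-compiled when available. Tests pin them together to
~1e-12 and against adaptive ODE integration to <0.1%. Steady-state AUC is
dose/CL exactly; Cmax/Ctrough come from the geometric-series steady-state
profile (grid search over one interval, 4001 points). Infusion duration
defaults to 30 min (0.0208 d), configurable per dose; a zero duration is
treated as a 1e-9-day infusion, numerically a bolus.

## Virtual cohorts

Because the underlying clinical datasets are not public, the cohort
generator emulates their structure:

- Covariates are sampled independently from log-normals anchored at the
  published 5th/50th/95th percentiles (log-mean = ln p50; log-SD averages
  the two one-sided tail fits). TBL is a mixture: a point mass at zero
  (probability 0.3, representing washout of prior trastuzumab) and a
  log-normal with median 10 µg/mL whose overall 95th percentile is the
  published 54 µg/mL. The point-mass probability and nonzero median are
  generator choices — the source percentiles (p5 = 0, p95 = 54) do not
  identify them. No covariate correlations are imposed (none are
  published).
- Dosing is 3.6 mg/kg every 3 weeks (weekly optional), 30-min infusions,
  8 cycles by default; flat dosing is available for policy comparisons.
- The rich design samples full profiles in the first and last cycle
  (pre-dose, end of infusion, 0.25, 1, 3, 7, 14 d), troughs in between,
  and washout samples 28 and 42 d after the last dose; the sparse design
  keeps end-of-infusion + trough per cycle. Real per-study schedules are
  unpublished; these are declared assumptions of the generator.
- Observations below the assay's minimum quantifiable concentration
  (MQC, 0.04 µg/mL by default) are *omitted*, mirroring the source
  analysis. Under the default rich design this removes ≈5–7% of records —
  the pre-first-dose zero, deep washout samples and occasional extreme
  troughs — the same qualitative structure as the reported assay dropout.
- Proportional Gaussian noise can produce non-positive concentrations
  (P ≈ 0.08% per record at 31.6% CV); these are floored at 1e-6 µg/mL and
  invariably removed by the MQC rule.

What passing tests on such cohorts do *not* show: robustness to covariate
correlation, time-varying covariates, model misspecification, assay error
that is not proportional-Gaussian, or dropout that is informative beyond
the left-censoring rule.

## Estimation

The marginal likelihood is approximated per subject by Laplace's method at
the conditional mode of η, with the residual variance evaluated at the
individual prediction (the "FOCE with interaction" family):

    OFV_i = ℓ_i(η̂) + ln det Ω + ln det H_i,
    ℓ_i(η) = Σ_t [ (y−f)²/(σ²f²) + ln 2πσ²f² ] + ηᵀΩ⁻¹η

Two curvatures H are available: the Gauss–Newton linearisation
JᵀV⁻¹J + Ω⁻¹ (used inside the optimiser; cheap and smooth) and the exact
Hessian of ℓ/2 by differentiating the analytic inner gradient (default for
reported objective values; matches adaptive quadrature to <0.5% on
single-η problems, ~1% better than Gauss–Newton there).

Numerical choices that matter:

- **Inner problem.** Batched damped Gauss–Newton over all subjects with an
  active set; central-difference Jacobians (h = 1e-4). With ω above ~0.5
  (Q: 1.8, Vp: 0.75) the conditional objective can be multimodal — some
  subjects' data genuinely prefer a collapsed (Q→0) or instant-equilibrium
  profile — so a second Newton polish is seeded from a coarse ±3 SD grid
  (plus a joint grid over wide pairs) and the best polished mode per
  subject is kept. A random-restart audit puts remaining mode misses at
  ~2% of subjects with ≤1 unit of −2logL.
- **Outer problem.** L-BFGS-B on transformed parameters (log typicals,
  log-Cholesky Ω with one free covariance, log σ), bounds ±25,
  convergence tolerance 1e-6 (relative OFV), 300 iteration cap. Gradients
  are explicit central differences computed with the conditional-mode
  warm-start cache frozen, so inner-solve noise cancels between paired
  evaluations. Parameters are preconditioned twice: linear covariate
  coefficients by the data span of their column, then all parameters by
  √|g| at the start, which prevents the first line search from
  overshooting a single steep direction (a freshly added covariate
  coefficient, typically) and stalling.
- **Observations at or before the first dose** predict exactly zero, where
  a proportional-error likelihood is undefined; they are excluded from
  estimation (they carry no information). Subjects left without usable
  observations are dropped with a warning.
- Stepwise covariate selection uses forward addition at p < 0.01 and
  backward deletion at p < 0.001, one degree of freedom per term, each
  step warm-started from the incumbent fit.
- Asymptotic SEs (optional) come from a central finite-difference Hessian
  of OFV/2.

### Known limitation: the wide-ω ridge

With the shipped 180.8% IIV on Q, the exact marginal likelihood of a
300-subject rich q3w trial is nearly flat along a ridge that trades
typical Q, ω_Q and typical Vc (≈12 units of −2logL across a 40% shift in
typical Q). Two consequences, established by simulation and by exact
quadrature/importance-sampling cross-checks: (i) *any* estimator has
limited precision for Vc at this design (SE ≈ 1.4%), and (ii)
conditional-mode approximations tilt systematically along the ridge —
refits of simulated trials recover CL within ~1% but Vc ≈ +4% high with
typical Q low. The covariate coefficients, σ, and ω_CL/ω_Vc are recovered
essentially unbiased. An importance-sampling refinement reduces but does
not remove the tilt at substantial cost, and is not included. Consumers
who need unbiased Q/Vc at such variance magnitudes should enrich the
design in the distribution phase or fix the poorly identified components,
as the bootstrap tests here do for trough-only designs.

## Diagnostics

Prediction errors follow the external-validation convention
Pe = (PRED−DV)/DV·100% (positive = over-prediction), averaged to MPE with
a 1,000-resample percentile-bootstrap 95% CI; the per-subject CL/Vc
versions compare covariate predictions to MAP empirical-Bayes estimates.
Note that dividing by a noisy DV inflates the *mean* concentration Pe
upward under 31.6% proportional error even for the generating model
(E[1/(1+ε)] > 1); the parameter-level MPEs are centred on zero and the
noise-free concentration MPE is exactly zero, which is what the tests
assert.

The VPC simulates the dataset's own design (doses, times, covariates)
under the model, applies the same MQC-omission rule, and compares observed
5/50/95th percentiles per time bin with across-replicate 95% bands; bins
default to the exact nominal times (synthetic designs are not ragged) and
bins with <5 observations are flagged. The NPC reports outside-fractions
of simulated prediction intervals. Shrinkage uses the SD conventions
η-shr = 100(1−SD(η̂)/ω) and ε-shr = 100(1−SD(IWRES)). The bootstrap
resamples subjects with replacement, refits (warm-started), and reports
2.5/50/97.5 percentiles, counting and excluding non-converged replicates
(flagged above 20%).

## Covariate analyses

The effect table evaluates typical CL (and Vc for weight) with one
covariate at its published 5th/95th percentile and the rest at reference
(70 kg, ECD 25, ALBU 41, TMBD 9, TBL 0, AST 27). Exposure sensitivity
computes steady-state AUC, Cmax and Ctrough for the same perturbations
under 3.6 mg/kg q3w; a weight perturbation rescales the dose as well as
the parameters (per-kg dosing), with a flag to isolate the pure
disposition effect — both variants matter for the trough metric, whose
bound is sensitive to that convention. For a non-weight covariate the AUC
change reduces exactly to 100(CL_typ/CL_new − 1). Subgroup summaries
(mean and 5th–95th percentile of AUC/Cmax/Ctrough per label) work from
individual parameters, per-kg or flat dosing.

## Problem sizes

Defaults were chosen so the full experiment battery runs comfortably on a
single core: recovery experiments use 300-subject rich q3w trials
(~21 quantifiable samples/subject), predictive-check calibration uses
80-subject cohorts with 150–200 replicates, stepwise-selection simulations
use 120 subjects with two candidate terms, and bootstrap demonstrations
use 40 subjects × 50 replicates with the under-identified Q/Vp held fixed.
The desk-scale bootstrap count (50) stands in for the 1,000 used in
full-scale analyses; the machinery is identical.
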