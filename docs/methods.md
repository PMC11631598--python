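# Methods

## Structural and statistical model

Ceftazidime kinetics are described by a one-compartment model with linear
elimination, parameterized by clearance CL (L/h) and volume of distribution
V (L); the elimination rate constant k = CL/V is always derived, never
stored. Doses are constant-rate IV infusions with an explicit duration —
there is no bolus, lag time or bioavailability term. For a single infusion
of amount D over T_inf hours,

    C(t) = (R0/CL)(1 − e^(−kt)),                 0 ≤ t ≤ T_inf,  R0 = D/T_inf
    C(t) = C(T_inf) · e^(−k(t − T_inf)),         t > T_inf,

multi-dose profiles are superpositions (linear kinetics), and the
steady-state profile adds the geometric tail sum e^(−kτ)/(1 − e^(−kτ)) of
all earlier doses. Times are hours since first dose; observation times in a
steady-state interval use the half-open convention [0, τ).

Fixed effects follow a power covariate model normalized to a 70 kg,
eGFR 116.93 mL/min/1.73 m² reference:

    CL_i = tvCL · (WT_i/70)^θ2 · (eGFR_i/116.93)^θ3 · exp(η_CL,i)
    V_i  = tvV  · (WT_i/70)^θ1 · exp(η_V,i)

Inter-individual variability is log-normal with diagonal covariance
(ω²_CL, ω²_V). Residual error is additive (σ, mg/L) by default;
proportional and combined models are available, in their standard forms
Y = F(1+ε) and Y = F(1+ε₁)+ε₂. The reference estimates used as generating
truth throughout the tests are tvV 27.83 L, tvCL 7.76 L/h, θ1 = 1,
θ2 = 0.90, θ3 = 0.38, ω²_CL 0.06, ω²_V 0.04, σ 1.20 mg/L.

## Estimation

The marginal likelihood integrates the per-subject random effects out of
the joint density. Each subject's integral is evaluated by **adaptive
Gauss–Hermite quadrature** (default 5 nodes per η dimension) centered at
the conditional mode and scaled by the Gauss–Newton Hessian
J'V⁻¹J + Ω⁻¹. With a single node the expression reduces exactly to the
Laplace/FOCE objective; because the residual variance is evaluated at the
conditional mode, proportional and combined error models get
FOCE-with-interaction behavior. The default of 5 nodes was chosen because
plain Laplace leaves an approximation error of up to ~0.15 OFV points on
sparse (1–3 observation) subjects at the ω² magnitudes of this problem,
whereas 5-node quadrature agrees with dense brute-force integration to
better than ~0.03; model-comparison decisions at ΔOFV thresholds of 3.84
and 6.635 deserve that margin.

Conditional modes are found by a damped Gauss–Newton iteration (finite-
difference Jacobians, step-halving line search, tolerance 1e−9, NaN-safe),
always started from η = 0 so that the outer objective is a deterministic
function of the parameters rather than of the optimizer's history; when a
caller supplies starting etas (the diagnostics path), that descent is raced
against the cold start and the better per-subject mode kept.

The outer problem is parameterized with log transforms on all
positivity-constrained parameters (tvV, tvCL, ω², σ) and solved in two
stages: a pooled (η = 0) nonlinear least-squares pre-fit supplies starting
values for the structural fixed effects; a bounded Nelder–Mead pre-search
then rides out the likelihood cliffs far from the optimum; and L-BFGS-B
with numeric gradients polishes to ftol 1e−11 / gtol 1e−5. The best point
seen anywhere in the search is retained. Standard errors come from the
inverse numeric Hessian of the OFV (covariance 2H⁻¹), delta-method
transformed to the natural scale; RSE% = 100·SE/|estimate|. Non-convergence
is flagged with partial estimates retained, and any estimate at a transform
bound (including ω² → 0) raises a boundary flag.

Empirical Bayes estimates are the conditional modes; a subject without
observations gets the prior mode (0, 0). CWRES are first-order-conditional
residuals: the observation vector is centered at F(η̂) − Jη̂ and whitened by
the Cholesky factor of JΩJ' + residual covariance. PRED is the prediction
at η = 0, IPRED at η̂.

## Covariate selection

Candidates are WT, AGE, HT, BSA, BMI, SCR, BUN, CysC, UA, ALT, AST, TBIL
and eGFR (continuous; power relation on the covariate normalized by the
cohort median, except WT by 70 kg and eGFR by 116.93 to match the reference
parameterization) and sex (proportional shift). BMI is computed as
WT/(HT/100)². The prescreen tests the empirical-Bayes individual clearance
against each covariate — Spearman rank correlation for continuous,
Wilcoxon rank-sum for binary — and retains p < 0.05. Forward selection adds
the candidate with the largest OFV drop while the drop exceeds 3.84;
backward elimination removes, cheapest first, any covariate whose removal
costs less than 6.635. Candidate fits are warm-started from the current
model's estimates. Every evaluation is logged in a step record
(action, covariate, OFV before/after, decision, threshold), so the path is
fully auditable. Ties on OFV prefer fewer parameters.

The five clearance–weight descriptions compared on the full model are
(I) fixed 3/4 allometry; (II) a single estimated exponent; (III) 3/4
allometry times a sigmoidal age-maturation factor AGE^γ/(AGE50^γ + AGE^γ);
(IV) a weight-dependent exponent k(WT) = k0 − kmax·WT^γ/(WT50^γ + WT^γ);
and (V) the same sigmoidal exponent driven by age. The exact functional
forms of III–V are standard pharmacometric choices; only the model family
names are fixed by convention, so these formulas are a documented
assumption. A model is excluded as unstable when any estimated parameter
has RSE > 50%, a standard error cannot be computed, an estimate sits at a
bound, or the fit fails; remaining models are ranked by OFV.

## Validation

The nonparametric bootstrap resamples **whole subjects** with replacement
to the original subject count (the exchangeable unit in sparse PK data),
refits each replicate starting from the original estimates, and reports
per-parameter medians, 2.5/97.5 percentiles and
bias% = 100·(median − estimate)/estimate. Non-converged replicates are
dropped and counted; more than 20% failures flags the result unreliable.

NPDE simulates K (default 1000) replicate datasets at the observed design,
decorrelates observed and simulated vectors within each subject by the
Cholesky factor of the simulation covariance, ranks each observation among
its simulations (ranks truncated to [1/(2K), 1 − 1/(2K)]), and transforms
through the standard-normal quantile. Reported tests: one-sample t-test of
mean 0, a two-sided χ² test of variance 1, Shapiro–Wilk normality, and a
Bonferroni global test (3 × the minimum p, capped at 1). Subjects with a
singular simulation covariance are excluded with a warning; if all subjects
are degenerate (e.g. noise-free data) the input is rejected.

## Monte Carlo PTA and dose optimization

The pharmacodynamic target is **70% fT>MIC**: the free concentration
(fixed free fraction 0.9 of total) must exceed the MIC for at least 70% of
the steady-state dosing interval. Virtual subjects draw weight and eGFR
uniformly and independently within their subgroup bin (the <10 kg bin
starts at the cohort minimum 2.8 kg) and η ~ N(0, ω²); residual (assay)
error is excluded because the target concerns true concentrations, not
measurements. The steady-state profile rises monotonically during the
infusion and decays mono-exponentially afterwards, so both MIC crossings
are inverted in closed form (each segment is a single exponential); a
0.001-h grid scan in the test suite confirms the inversion to 2e−3 of the
interval. PTA is the fraction of n = 1000 virtual subjects with
fT>MIC ≥ 0.70, with its binomial Monte Carlo SE attached.

Dose optimization evaluates a 2.5 mg/kg grid (default 2.5–60 mg/kg per
dose; the grid step is read off the spacing of the published dose table)
across q12h/q8h/q6h with a per-cell deterministic sub-seed, then applies
the clinical priority rules: among regimens with PTA > 90%, the one with
the fewest doses per day wins if its daily dose is ≤ 100 mg/kg/day
(tie-break: lower per-dose amount); otherwise the lowest daily dose wins.
If no grid regimen qualifies, a no-solution marker is returned. The full
search log reconstructs every PTA evaluated.

Key unstated-by-necessity assumptions, all configurable: infusion duration
0.5 h (common pediatric short-infusion practice), uniform covariate
sampling within bins, and steady-state evaluation. Published dose-table
cells that sit near the PTA = 90% boundary are sensitive to these choices
and to Monte Carlo noise at n = 1000; reproduction of dose-valued cells is
therefore judged to within one 2.5 mg/kg grid step, and one cell
(the cheapest q6h daily dose at MIC 16 for 30–50 kg children with
augmented renal clearance) lands one further step higher under these
assumptions (180 rather than 160 mg/kg/day, with PTA at the printed dose
measuring ≈87%).

## Synthetic cohort generator

The generator emulates the study population rather than any particular
anthropometric standard; its defaults are the study conditions. Age is
drawn from a normal distribution with the cohort's mean 5.43 y and SD
4.10 y, truncated to 0.03–15 y (a log-uniform draw over that range would
put the median at 0.67 y, contradicting the cohort's median of 5.17 y).
Height follows a two-piece linear growth curve (50 cm at birth, 75 cm at
1 y, 6.5 cm/y thereafter) with 4% log-normal noise; weight is a
BMI-like curve (13.6 + 0.2·age) times height squared with 12% noise; both
are truncated to the cohort ranges (50–172 cm, 2.8–95 kg). Serum
creatinine follows an age-dependent reference curve (23 + 2.1·age µmol/L —
anchored so the cohort-median height/SCR pair reproduces the cohort-median
eGFR) with log-SD 0.28, truncated to 15.9–66.2 µmol/L; the log-SD is set
so the cohort eGFR SD ≈ 30 matches the study's 31.35. Each subject is
first assigned a renal-function bin with the study prevalence (5/9/31/43
of 88 across eGFR 30–60/60–90/90–120/120–200), and creatinine is redrawn
until the **computed** Schwartz eGFR = 0.413·height/SCR(mg/dL) lands in
the bin (SCR is simulated in µmol/L and converted with 88.4 µmol/L per
mg/dL — the cohort medians confirm the formula expects mg/dL). eGFR and
BSA (Mosteller) are always computed from the generated height/weight/SCR,
never drawn independently, so the age–size–renal-function correlation
structure arises mechanically. Bins unreachable within the creatinine
range for a given height (a tall child cannot have eGFR 40 with
SCR ≤ 66.2) fall back to the nearest reachable bin. BUN, CysC, UA, ALT,
AST and TBIL have no mechanistic role and are drawn log-normally around
the cohort medians, truncated to the cohort ranges.

Dosing assigns each subject a uniform 21.05–76 mg/kg per-dose amount,
q8h or q12h with equal probability, 3–6 doses, 0.5-h infusions. Sampling
is opportunistic: 1–3 observation times per subject drawn uniformly over
the dosed span, with probabilities (0.88, 0.10, 0.02) for 1/2/3 samples so
the expected total is ≈100 samples per 88 subjects, as in the study.
Concentrations are the subject's model prediction plus residual noise;
values below the 0.025 mg/L quantification limit are dropped, and a
subject left without a quantifiable sample has its sampling redrawn (a
mild conditioning the recovery tests tolerate). Every synthetic dataset
embeds its generating parameters; recovery tests never read them during
fitting.

What the generator does **not** emulate: real anthropometric growth-chart
joint distributions, disease covariates (ventilation, fluid resuscitation,
comorbidity), within-subject creatinine dynamics, dose adjustment over
time, or informative (sickness-driven) sampling. Passing recovery and
calibration tests on these cohorts therefore demonstrates correctness of
the estimation and validation machinery under the study's design, not
clinical validity on real PICU data.

## Numerical choices and problem sizes

Chi-square thresholds 3.84 (p < 0.05, add) and 6.635 (p < 0.01, remove) for
1 df; inner mode tolerance 1e−9 with at most 60 Gauss–Newton iterations;
finite-difference step 1e−5 on η; outer Hessian step 1e−4. All random
draws flow from explicit integer seeds (numpy Generator); pipeline stages
derive named sub-seeds from the master seed by hashing, and every
stochastic result records its seed. The test suite scales Monte Carlo
studies to sizes chosen for thorough-but-practical coverage: 20 replicates
for parameter recovery at the full study design, 10 replicates each for
the covariate-selection power and null operating characteristics,
200 replicates for NPDE calibration (K = 1000), and 8 outer replicates ×
B = 30 for bootstrap coverage on a reduced 30-subject design.

## Known limitations

* Two-compartment and saturable-elimination structures are out of scope;
  only the selected one-compartment linear model is implemented.
* ω is diagonal; no CL–V correlation, no inter-occasion variability.
* The bootstrap does not re-run covariate selection per replicate
  (estimates-given-structure, the common practice).
* NPDE decorrelation uses the empirical simulation covariance; with very
  small K it is noisy, hence the K ≥ 100 floor.
* Extended/continuous-infusion schedules are supported only through the
  configurable infusion duration, not as a search dimension.
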