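# Methods

This note documents the models implemented in `tcequant`, their
assumptions, the defaults and why they were chosen, and what the synthetic
data used in the test suite does and does not establish about real assays.

## Data model and preprocessing

The canonical container is a tidy long table with one row per
(readout, concentration, time, replicate) observation. Concentrations are
held in pM throughout — every potency parameter downstream is molar — and
readers convert from nM/µM directly or from mass units (ng/mL, µg/mL)
using the compound's molecular weight. Replicates are kept raw at ingest;
reduction is explicit and ordered:

1. **½-LLOQ substitution.** Any value strictly below its readout's lower
   limit of quantification is replaced by LLOQ/2, the standard
   bioanalytical reporting convention. This happens *before* replicate
   aggregation, mirroring how assay software exports reported values. The
   operation is idempotent, and substitution counts are logged.
2. **Replicate aggregation.** Median by default (robust for triplicate
   wells); mean available.
3. **Normalization to control.** Cytotoxicity readouts are expressed
   relative to the *time-matched* drug-free control — the control
   population grows over the multi-day assay, so a fixed baseline would
   conflate growth with drug effect. Two conventions are offered: percent
   viability `100·v(c,t)/v(0,t)` and drug-related kill
   `100·(1 − v(c,t)/v(0,t))`. Negative kill (growth beyond control) is
   deliberately preserved so the AUCE can distinguish stimulation from no
   effect. Whether published "drug-related cytotoxicity" traces are
   time-matched or baseline normalized is ambiguous in the field;
   time-matched is this package's documented choice.

## Time-independent effect metrics (AUCE)

For each concentration the effect time course is reduced to the
trapezoidal area under the curve over the observed window, plus the
maximum response `R_max` and its time `T_max` (ties resolve to the
earliest time, for determinism). No baseline point at t = 0 is imputed:
typical first observations are 18–24 h into the assay, and inventing
unobserved early kinetics would bias cytokine AUCEs with fast peaks. AUCE
therefore means "area from first to last observation" — a reporting
convention, stated here once, applied everywhere.

## Dose–response models

**Sigmoid (Hill / Emax).** `E = E0 + Emax·C^γ/(EC50^γ + C^γ)` with signed
`Emax` (negative for inhibitory responses such as falling viability).
Fitted by bounded nonlinear least squares under additive error, with EC50
and γ log-transformed internally. Multi-start: EC50 initialized at the
geometric mean of the positive concentrations and at the concentration
nearest the half-maximal response; γ at 1. Bounds: γ ∈ [0.05, 20], EC50 ∈
[min positive conc/1000, max conc·1000]. The zero-concentration control
point is included through the model's exact C = 0 limit (E = E0), so no
log-concentration dodge is needed. Standard errors come from the
Gauss–Newton covariance `s²(JᵀJ)⁻¹` with the analytic Jacobian in the
natural parameterization; %RSE is `100·SE/|estimate|`. A fit reports
`converged=False` (never raises) when optimization fails or the EC50
leaves the tested concentration range by more than 100-fold. The response
direction (`auto`) is decided by the sign of the Spearman rank correlation
of response versus concentration — deterministic and scale-free.

**Hockey-stick (segmented threshold).**
`E = E0 + S·(C − C_thr)·[C > C_thr]`, used when no sigmoid can be
established; it estimates the lowest concentration with effect above
baseline. The threshold is profiled: on a grid over [0, C_max] (grid nodes
plus the observed concentrations) the two linear parameters are solved in
closed form, and the grid optimum seeds a bounded scalar refinement.
Identifiability is decided by an F-test of the hinge against a flat
mean-only fit at α = 0.05, plus the requirement that the threshold is
interior to the dose range; pure baseline noise is flagged
unidentifiable rather than reported as a threshold.

**Derived potencies.** `PA_x = EC50·(x/(100−x))^{1/γ}` (identical algebra
for ECx/ICx). `PA_50` is exactly the EC50. The inverse chain (an ECx
back-calculated to a PA at another level under an assumed Hill
coefficient) is provided for translating historically reported potencies;
note that a published value of "80 ng/mL" against the closed form's
78.9 ng/mL reflects rounding of unprinted intermediates — the package
reports full precision.

**Static analysis.** The same sigmoid fitted to a single time point's
dose–response slice, provided for comparison with the AUCE analysis; the
contrast between the two is the package's central subject.

## Delayed tumor-kill model (mechanistic reference)

The reference potency comes from a transit-compartment tumor-kill model:

    k_el      = Emax·TCB/(EC50 + TCB)
    dk_i/dt   = (k_{i−1} − k_i)/τ        (i = 1..3, k_0 ≡ k_el, k_i(0)=0)
    dTumor/dt = k_g·(1 − Tumor/K) − k_3·Tumor

Assumptions: constant drug concentration (in vitro medium, no PK, no
ligand depletion), three transit steps producing the observed delay
between exposure and kill, and a growth *input* term `k_g(1 − Tumor/K)`
— this exact form, not the classical logistic `k_g·Tumor·(1 − Tumor/K)`,
is implemented as the primary model; a `logistic_growth=True` switch is
available for sensitivity analysis. Consequences of the printed form: the
no-drug fixed point is `Tumor = K`, and under constant drug the count
approaches the closed-form steady state `k_g/(k_g/K + k_el)`, which the
test suite uses as an oracle.

For constant drug the transit chain is linear with the exact solution
`k_3(t) = k_el·(1 − e^{−x}(1 + x + x²/2))`, `x = t/τ`, so only the scalar
tumor equation is integrated numerically (LSODA, rtol 1e-8, vectorized
across doses). An independent fixed-step RK4 integration of the full
four-state system serves as the cross-check in the tests.

**Fitting** is pooled fixed-effect nonlinear least squares: all doses
simultaneously, shared parameters, log-transformed for positivity, three
EC50 multi-starts around the geometric-mean dose. Error models: additive;
proportional; combined `sd = a + b·prediction` (default), implemented as
one reweighting pass — a first unweighted fit, (a, b) estimated from the
absolute residuals versus predictions, then a weighted refit. Population
random-effects machinery is intentionally out of scope; pooled fitting is
appropriate for the single-donor designs the package targets. Parameter
SEs use the weighted Jacobian with the delta method back to the natural
scale. Datasets with drug-free wells only still yield growth parameters
(k_g, K, Tumor₀) with the drug parameters flagged unidentifiable; a
missing control series produces a warning, not an error.

## Ternary (trimeric) complex model

Quasi-equilibrium mass action for drug C bridging tumor antigen R and
CD3 S: `dimer_TA = C·R/Kd_TA`, `dimer_CD3 = C·S/Kd_CD3`,
`trimer = α·C·R·S/(Kd_TA·Kd_CD3)`, plus three conservation laws. The
cooperativity factor α (default 1) absorbs any membrane avidity gain; the
bivalent tumor-antigen arm is folded into a single measured avidity KD
rather than modeled with explicit bivalent states. Surface copy numbers
convert to concentrations via `copies × cell density / N_A`.

The solver brackets free drug on [0, C_tot] (Brent); at fixed free drug
the CD3 balance reduces to a quadratic in free CD3 solved in a
numerically stable form, and free TA follows linearly. Every solution is
verified against the conservation laws to 1e-6 relative before being
returned. Characteristic predictions: unimodality of trimer versus dose
(the hook effect: at high dose binary dimers outcompete the trimer),
monotonicity in α and receptor totals, scale equivariance, and — at equal
sub-saturating doses — more trimer for a higher-affinity tumor-antigen
arm.

## MABEL dose

The MABEL dose is defined as the dose whose initial Cmax equals the
chosen minimally active concentration under instantaneous distribution
into plasma: `dose [µg] = potency [ng/mL] × V_plasma [mL] / 1000`, with
V_plasma defaulting to 3000 mL (typical adult plasma volume),
overridable. No absorption, clearance or allometric scaling — this is
deliberately the most conservative exposure assumption for a first dose.

## Synthetic data: what it emulates and what it does not

`generate_tdcc` simulates tumor counts from the kill model on standard
plate designs (`CIBISATAMAB_DESIGN`: 0–100,000 pM in 8 steps at
24–168 h; `INCUCYTE_DESIGN`: 0–50,000 pM in 7 steps at 18–94 h; both
triplicate) with combined replicate noise `sd = additive + CV·value`,
floored at zero. `generate_cytokine` builds cytokine release as a
*separable* product of a Hill dose amplitude and a pulse time profile
(linear rise to the peak, exponential decay). The separability is the
point: time factors out of the AUCE integral, so the noiseless AUCE
dose–response carries exactly the generating EC50 and Hill coefficient,
giving the pipeline an analytic ground truth. Both generators are pure
functions of (design, truth, noise, seed).

Real assays are messier in ways these generators do not emulate: donor-
to-donor PBMC variability, effector-cell dynamics, plate-position
effects, cytokine kinetics coupled to T-cell activation rather than
separable in time, and drug depletion. Passing tests therefore establish
the correctness and statistical behavior of the *analysis*, not the
biological fidelity of the generators.

## Study conditions used in the tests

Chosen once as representative of the assays the package targets, and used
for all simulation-based checks:

* **Recovery study**: truth k_g = 1000 cells/h, K = 1e5 cells,
  Emax = 0.08 /h, EC50 = 20 pM, τ = 30 h, Tumor₀ = 3e4 cells; 8 doses ×
  5 times × 3 replicates; 10% CV + 50-cell additive noise; 100 seeds.
  Observed: ≥90% of fits recover EC50 within ±25%.
* **Slow-kill (time-bias) contrast**: Emax = 0.03 /h, τ = 40 h, other
  parameters as above; 5% CV + 20-cell additive noise. In this regime the
  kill effect does not saturate across the dose range within the
  observation window, so the AUCE-based EC50 tracks the generating value
  (within 2-fold) while early-time static estimates are biased by orders
  of magnitude. When the kill rate is large enough to flatten the
  dose–response at the AUCE level (strong saturation over a long window),
  the AUCE estimate itself shifts left — a real limitation of any
  cumulative metric, documented here rather than hidden.
* Problem sizes throughout (100 recovery fits, 200×200 oracle grids,
  3-seed property checks) were picked as the smallest sizes that make the
  statistical statements meaningful.

## Numerical choices and degenerate inputs

* Optimizer tolerances 1e-10…1e-15 (xtol/ftol/gtol) so noiseless
  recovery reaches ~1e-6 relative or better.
* Trapezoidal AUCE rejects <2 points and duplicate times; ties in T_max
  go to the earliest time.
* Sigmoid fitting refuses <4 distinct concentrations and exactly flat
  responses (degenerate); the pipeline catches the latter and falls back
  to the hockey-stick path, whose F-test then typically reports
  "unidentifiable" — the honest answer for a flat readout.
* The trimer solver special-cases C_tot = 0 and α·C underflow (reduces to
  the 1:1 isotherm), and raises with diagnostics if a solution violates
  conservation.
* All multi-start grids are fixed, so the whole pipeline is deterministic
  for a given input and seed.

## Known limitations

* Pooled (fixed-effect) fitting understates uncertainty relative to a
  population analysis when replicates are correlated within donor.
* The combined error model uses a single reweighting pass, not full joint
  ML over (a, b) and the structural parameters.
* AUCE potencies inherit the assay window: changing the observation
  period changes the metric (by design, but worth remembering when
  comparing across experiments).
* The trimer model has no kinetics, internalization or synapse geometry;
  α is phenomenological.
* MABEL arithmetic ignores PK beyond the instantaneous-distribution
  assumption.
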