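# Methods

## Model structure and assumptions

The package implements a target-mediated disposition model of an
antibody–drug conjugate (gemtuzumab ozogamicin, GO) interacting with
CD33-bearing AML blasts. Binding of free drug to surface CD33 is
reversible (association `k_b`, dissociation `k_u`); free CD33 is produced
at a constant per-cell rate `R_p` and internalized at rate `k_e`;
drug–CD33 complexes internalize at rate `k_i`, feeding an intracellular
pool `S` that is cleared by P-glycoprotein efflux at rate `k_d`.
Structural assumptions worth making explicit:

* Free drug is lost only through net binding (`k_b·A·R − k_u·B`) and, in
  vivo, nonspecific first-order clearance `k`; internalized drug leaves the
  system through the bound pool, and effluxed intracellular drug is
  eliminated rather than recycled to blood.
* Receptor dynamics are written per cell; the drug equation couples to the
  whole population through `N/(n_A·v)` (well) or `N(t)/(n_A·V)` (body).
* The blast count is an exogenous forcing: constant until 6 h after the
  first infusion starts, then exponential decay at rate `α`. The decay
  onset is tied to the first infusion only; by a second infusion two weeks
  later the blast contribution is negligible, which is exactly the
  assumption under which the one-compartment clearance parameters are
  estimated.
* No bone-marrow compartment, no plasma-protein binding, and no
  intracellular payload release/DNA-damage model: `S` stops at
  internalized-conjugate content, and I-AUC = ∫S dt is the response
  surrogate.

## Parameters

| symbol | meaning | cell line | patient mean (CV%) |
|---|---|---|---|
| `R_p` | CD33 production, molecules·cell⁻¹·h⁻¹ | 2047 | 279 (109.6) |
| `k_e` | free CD33 internalization, h⁻¹ | 0.12 | 0.213 (65.7) |
| `k_i` | complex internalization, h⁻¹ | 0.4 | 0.66 (50) |
| `k_d` | efflux, h⁻¹ | — | 0.34 (64.7) |
| `k_b` | association, M⁻¹·h⁻¹ | 1.1×10¹² | (cell-line value reused) |
| `k_u` | dissociation, h⁻¹ | 397.1 | (cell-line value reused) |
| `k` | nonspecific clearance, h⁻¹ | — | 0.01919 |
| `V` | distribution volume, L | — | 6.2 |
| `N_0` | initial blast burden, cells | — | 2.47×10¹² |
| `α` | blast elimination, h⁻¹ | — | 0.104 |

Doses are prescribed in mg/m² and converted to moles with a body surface
area of 1.8 m² and a conjugate molar mass of 1.515×10⁵ g/mol (an IgG4 plus
payload); both are configurable on `SystemicParams`, and neither is pinned
by the source estimates, which is the main reason absolute I-AUC values
carry a few-percent ambiguity. Infusions default to 2 h. In vitro wells
default to 10⁶ cells in 1 mL; the saturating assay uses 5 µg/mL
(≈ 3.3×10⁻⁸ M) sampled at 0/1/3/6 h, the non-saturating assay 0.1–0.5
µg/mL for 15 minutes.

## Numerics

Both ODE systems are integrated with `scipy.integrate.solve_ivp` using the
implicit BDF method and an analytic Jacobian, rtol 10⁻⁸ and per-state
absolute tolerances scaled to typical magnitudes (drug ~10⁻⁸ M, receptors
~10³ molecules/cell). The binding kinetics are stiff across the whole
plausible parameter range (`k_b·A` reaches 10⁶ h⁻¹ in sweep corners);
LSODA was abandoned after it showed a fragile stiffness-switching mode —
millions of right-hand-side evaluations on particular sweep combinations —
while BDF handles the worst corner in under a second. Integration is
restarted at every infusion start/stop and at the blast-decay onset so the
discontinuous forcing never crosses a solver step, and observation times
can be injected into the output grid exactly, which keeps fitting free of
interpolation error. Trajectory states are clipped of sub-tolerance
negative round-off. I-AUC integrates `S` by the trapezoid rule on a ~300
points/segment grid (stable to 4 significant digits against 10× denser
grids); the default horizon is 28 days after the first dose, and extending
it to 35 days changes mean-parameter I-AUC by < 0.01%.

## Estimation cascade

All positive parameters are fitted in log₁₀ space with
`scipy.optimize.least_squares` (trust-region reflective) under bounds of
±6 decades around each parameter's natural scale (`k_b`: 10⁶–10¹⁸ M⁻¹h⁻¹;
`N_0`: 1–10¹⁴ cells), from one data-driven heuristic start plus seeded
Latin-hypercube restarts (default 10). The objective is unweighted least
squares on raw counts/concentrations. Step-specific choices:

* **Saturating fit** uses the closed-form reduced model
  `T(t) = R_p/k_i + (R_p/k_e − R_p/k_i)·e^(−k_i·t)` against total-CD33
  records; bound-CD33 records serve as a fallback (B ≈ T under saturation)
  with the t = 0 point dropped, since `B(0) = 0` is outside the reduced
  model. At least three distinct times are required for identifiability.
* **Non-saturating fit** simulates the full well system per dose at 15
  minutes. Binding is essentially equilibrated there, so the data pin the
  effective dissociation constant `(k_u + k_i)/k_b` sharply while the
  individual rates sit in a shallow residual valley whose floor is set by
  small off-equilibrium lag terms (~10⁻⁵ relative). The fit therefore runs
  the solver at rtol 10⁻¹² (LSODA, cheap and reliable on this benign
  15-minute horizon) with finite-difference steps of 10⁻⁵ log-units; at
  zero noise this recovers the individual rates, but users should expect
  only the ratio to be robust once realistic noise is present.
* **Blood-PK fits** use the closed-form one-compartment infusion solution
  (blast-free case) and the full in vivo simulation (blast-burden case).
  The ODE-backed objective cannot be resolved below the solver tolerance,
  so the blast-burden fit uses rtol 10⁻⁶ with matched optimizer tolerances
  and 10⁻³ finite-difference steps.
* The efflux rate is the closed inversion `k_d = ln(ratio)/Δt`, Δt = 1.5 h.

Fits are deterministic given (data, seed) and report residual norm,
convergence flag and starts used.

## Synthetic data

The generators emulate the study's assays: flow-cytometry-style total and
bound CD33 at the saturating condition, a 15-minute dose–response, blood
concentration curves for arbitrary schedules (a blast-free mode emulates
second-infusion conditions), dye-retention ratios, and a virtual cohort.
Measurement noise is multiplicative log-normal with unit mean (default CV
10%, a flow-cytometry-scale error). Inter-patient variability is
independent log-normal per parameter matching the reported arithmetic
means and CVs (R_p 109.6%, k_e 65.7%, k_i 50%, k_d 64.7%); binding
constants are shared across patients, mirroring how they were measured
once in a cell line. What the generators deliberately do not reproduce:
inter-parameter correlations (unreported), assay-specific error structure
beyond a single CV, raw fluorescence channels, and any bone-marrow
compartment — so passing round-trip tests demonstrates internal
consistency of model + estimator under the stated noise model, not
performance on real clinical data.

Noisy-recovery envelopes are frozen from seeded studies run once: with 10%
noise the 4-point saturating design leaves the asymptote `R_p/k_i` weakly
determined (median relative errors ≈ 0.44/0.41/0.31 for `R_p`/`k_e`/`k_i`
over the study seeds), while the blast-burden fit recovers `N_0` with
median error ≈ 0.15 over 10 replicates. The suite re-runs scaled-down
versions of the same seeded studies (40 saturating seeds, 10 blood-PK
seeds) against those frozen bounds.

## Simulation studies

Sensitivity sweeps scale one quantity (a rate constant, the blast burden
or every dose in the schedule) by 25 log-spaced factors in [0.1, 10] and
report I-AUC normalized to the all-means baseline — a single 9 mg/m² 2-h
infusion unless a schedule is given. The blast-burden grids cross 10
log-spaced burdens in [10¹¹, 5×10¹²] with production or dose factors. The
correlation scan runs the full 3⁶ factorial of {0.1×, 1×, 10×} over
(N_0, dose, k_b, R_p, k_e, k_i) and reports Pearson and Spearman
coefficients between blood AUC and I-AUC; "no correlation" is
operationalized as |r| < 0.5, and the computed values (factorial r = 0.28;
cohort expression-vs-I-AUC r = 0.18 at n = 100) are pinned as regressions.
Day numbering for schedules puts day n at (n−1)·24 h.

## Known limitations

* Absolute I-AUC values depend on the mg/m²→molar conversion constants and
  the integration horizon; with the defaults the two AML19 schedule values
  land within ~2.5% of the published figures, and their ordering is robust
  to solver tolerance across rtol 10⁻⁶–10⁻¹⁰.
* The model's dose–response above 3 mg/m² is steeper at the 28-day horizon
  than the published dose-insensitivity statements (which are consistent
  with a ~1-week exposure window); at blast burdens ≳10¹² a 4 mg/m² dose is
  largely consumed by blast-mediated clearance and intracellular exposure
  collapses. See the test suite for the exact measured ratios.
* Individual `k_b` and `k_u` are near-unidentifiable from the 15-minute
  equilibrated design; only their ratio is robust.
* The blast-decay onset (6 h) and the exponential-decay form are taken as
  given; nothing in the estimation cascade re-identifies the onset.
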