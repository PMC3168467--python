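# gopk — mechanism-based pharmacokinetics of gemtuzumab ozogamicin

Gemtuzumab ozogamicin (GO) is an anti-CD33 IgG4 antibody conjugated to a
calicheamicin derivative, used in acute myeloid leukemia (AML). The drug is
active only after CD33-mediated internalization, and the leukemic blast
population itself is a major clearance route (target-mediated drug
disposition), so blood concentrations say little about how much drug ends up
inside blasts. `gopk` implements a mechanism-based model of GO–blast
interaction for pharmacometricians and modelers studying antibody–drug
conjugate dosing: it simulates binding, internalization and efflux kinetics
in vitro and in vivo, estimates the rate constants from the assays used in
practice, and computes the intracellular exposure metric that serves as the
model's surrogate for response.

## The model

Free drug `A` (molar), free and drug-bound surface CD33 per cell (`R`, `B`),
intracellular drug per cell (`S`) and blast count `N(t)` evolve as

```
dA/dt = In(t)/V − k·A − (N(t)/(n_A·V))·(k_b·A·R − k_u·B)
dR/dt = R_p − k_e·R − k_b·A·R + k_u·B
dB/dt = k_b·A·R − k_u·B − k_i·B
dS/dt = k_i·B − k_d·S
N(t)  = N_0                      for t ≤ 6 h
      = N_0·exp(−α·(t − 6))      afterwards
```

with `In(t)` the infusion rate (mg/m² doses converted to moles via body
surface area and conjugate molar mass), `k` nonspecific clearance, `V` the
distribution volume, `R_p` CD33 production, `k_e`/`k_i` free/bound CD33
internalization, `k_b`/`k_u` association/dissociation and `k_d`
P-glycoprotein efflux. The in vitro variant replaces infusion and clearance
with a closed well (`N` cells in volume `v`). Under saturating drug the
total surface CD33 `T = R + B` reduces to `dT/dt = R_p − k_i·T` with
`T(0) = R_p/k_e`, which is what the saturating flow-cytometry time course
identifies. The surrogate efficacy metric is the intracellular AUC,
`I-AUC = ∫ S dt` (molecules·day/cell), integrated over 28 days by default.

Estimation follows the multi-step cascade used with the real assays:
saturating time course → (`R_p`, `k_e`, `k_i`); 15-minute sub-saturating
dose–response with those rates fixed → (`k_b`, `k_u`); dye-efflux ratio →
`k_d = ln(ratio)/1.5 h`; blast-free (second-infusion) blood PK →
(`k`, `V`); first-infusion blood PK with everything else fixed →
(`N_0`, `α`). The fitters are scikit-learn-style estimators
(`fit`/`predict`, fitted attributes with trailing underscores) over bounded
log-space least squares with seeded Latin-hypercube multi-start.

## Worked example

```python
from gopk import (Baseline, DoseSchedule, intracellular_auc)

base = Baseline()  # population-mean parameters, 28-day horizon
for label, sched in {
    "6 mg/m2 d1 + 3 mg/m2 d8": DoseSchedule.aml19_nonfractionated(),
    "3 mg/m2 d1,3,5": DoseSchedule.aml19_fractionated(),
}.items():
    iauc = intracellular_auc(base.simulate(schedule=sched))
    print(f"{label}: I-AUC = {iauc:.1f} mol*day/cell")
```

prints

```
6 mg/m2 d1 + 3 mg/m2 d8: I-AUC = 12317.3 mol*day/cell
3 mg/m2 d1,3,5: I-AUC = 10798.2 mol*day/cell
```

— the non-fractionated arm delivers more intracellular drug despite the
identical 9 mg/m² total dose, because intracellular levels plateau for about
a week after a dose (internalization is saturated), so the day-3/day-5
fractions add little while the day-8 dose lands after the plateau has
decayed.

The same operations are available from the shell:

```sh
gopk simulate --config config.yaml --out out/     # trajectory CSV + summary
gopk fit --measurements assay.csv --out out/      # estimation cascade
gopk sweep --parameter k_d --out out/             # I-AUC sensitivity
gopk reproduce fig4 fig6 aml19 --out out/         # simulation studies
```

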