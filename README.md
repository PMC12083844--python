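# casevac

Robust location–allocation planning for post-earthquake casualty evacuation.

After a major earthquake, triaged casualties must be moved through a
three-tier rescue chain: disaster areas → temporary field hospitals (by road
vehicle) → general hospitals (by helicopter). `casevac` chooses which
candidate hospitals to open and how to route casualties and vehicles so that
the total urgency-weighted deterioration score accrued in transit is
minimal, for planners and researchers in emergency-medical logistics.

## The model

Casualties come in two triage classes `s ∈ {serious, moderate}` with urgency
weights `ω_s` (2 / 1) and hourly deterioration rates `p_s` (0.8 / 0.2).  A
casualty moved over a road arc with one-way time `t_ij` accrues
`2·t_ij·p_s` score points; after first treatment the rate drops to 20%, so
the air leg accrues `2·t_jk·0.2·p_s`.  The deterministic problem is a
mixed-integer program over opening decisions `U_j, V_k`, integer flows and
vehicle counts:

    min  F1 + F2
    F1 = Σ_{ijs} 2 t_ij p_s ω_s x_ijs        (road leg, pre-treatment)
    F2 = Σ_{jks} 2 t_jk (0.2 p_s) ω_s y_jks  (air leg, post-treatment)

subject to demand coverage, temporary capacity `C` (head-count, both
classes), per-class general capacities `Q_ks`, per-vehicle seat limits, and
fleet sizes.  Casualty counts are uncertain: with nominal count `q̄`,
deviation `q̂ = δ·q̄` and per-area budget `Γ ∈ [0,1]`, the
budget-of-uncertainty robust counterpart inflates each coverage constraint
to `Σ_j x ≥ q̄ + ⌈q̂·Γ⌉`.  A multi-period extension lets tools return after
one period and adds waiting penalties `p_s((t−1)Δt + 2t)`, solvable
monolithically or by a generalized Benders decomposition.

The 2013 Lushan earthquake case (9 areas, 5 temporary and 3 general
hospital candidates, 985 casualties) is embedded as `lushan_instance()`.

## Worked example

```python
import casevac as cv

inst = cv.lushan_instance()
det = cv.solve_static(inst)
print(det.objective, det.F1, det.F2, sorted(det.temp_open), sorted(det.general_open))
rob = cv.solve_robust(inst, cv.UncertaintySpec(variability=0.20, budget=1.0))
print(rob.objective, sorted(rob.temp_open), sorted(rob.general_open))
```

prints

```
1283.4464 1149.96 133.4864 ['J2', 'J5'] ['K1', 'K3']
1563.1116000000002 ['J2', 'J4', 'J5'] ['K1', 'K2', 'K3']
```

At nominal demand the optimal plan opens temporary hospitals J2 and J5 and
general hospitals K1 and K3, with a total weighted score of 1283.4 (1150.0
accrued on the road leg, 133.5 on the air leg).  Hedging against the
worst-case demand (`Γ=1`, 20% variability) costs 280 extra score points and
opens a third temporary hospital (J4) and all three general hospitals.

The same workflows are available from a shell:

```bash
casevac solve-static --instance lushan --out solution.json
casevac solve-robust --instance lushan --gamma 0.6 --variability 0.20
casevac sweep --instance lushan --out sweep.csv
casevac solve-dynamic --instance lushan --periods 2 --method gbd
casevac generate-instance --size 12x7x6 --seed 1 --out big.json
```

## Layout

- `casevac.instance` — data model, validation, JSON/CSV serialization, embedded case
- `casevac.rates` — deterioration-rate formulas and objective coefficients
- `casevac.model` — MILP container, HiGHS backend, static model (aggregated and per-vehicle formulations), LP export
- `casevac.robust` — demand inflation, robust counterpart, worst-case oracle
- `casevac.dynamic` — multi-period model with fleet-return recursion
- `casevac.gbd` — generalized Benders decomposition with iteration trace
- `casevac.generate` — seeded synthetic instances and demand realizations
- `casevac.experiments` — sensitivity sweeps, feasibility stress tests, capacity curves
- `casevac.cli` — the `casevac` command

See `docs/methods.md` for modelling assumptions, numerical choices and known
limitations.
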