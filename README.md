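# erysim

Patient-individualized modeling of erythropoiesis for hemodialysis anemia
management.

Anemia in end-stage renal disease is treated with erythropoiesis-stimulating
agents (ESAs), but the response is delayed by weeks, nonlinear, and highly
variable between patients, so hemoglobin (Hgb) frequently overshoots targets or
cycles. `erysim` implements a physiology-based route to individualized
forecasting: an age-structured cell population model of red blood cell
production is fitted to a patient's per-treatment Hgb series (as produced by
optical in-line monitors) and the fitted model is then run forward to predict
Hgb under any dosing scenario. The fitted parameters — RBC lifespan, endogenous
erythropoietin level, ESA half-life, and two bone-marrow response slopes — are
quantities that are clinically meaningful but nearly impossible to measure
directly.

Because per-treatment clinical Hgb records are not publicly available, the
package ships a synthetic-cohort generator that emulates the relevant study
conditions (thrice-weekly dialysis, ~53±7 usable measurements per 150-day
adaptation period, multiplicative monitor noise, guideline-band ESA titration,
occasional bleeds and transfusions), so the whole pipeline is testable end to
end.

## Model

Five maturity-structured classes — BFU-E, CFU-E, erythroblasts, marrow
reticulocytes, circulating erythrocytes — each obey a transport equation in
maturity μ:

    ∂u/∂t + v(E) ∂u/∂μ = (β(E) − α(E, μ)) u,      v(E) u(t, 0) = f(t)

where `u(t, μ)` is the cell density, `β` and `α` are proliferation and
apoptosis rates, `v` the maturation velocity, and the boundary influx `f` is
the outflux of the preceding class (stem-cell commitment `S0` feeds BFU-E).
Erythropoietin `E(t) = E_endo + Σ (Dᵢ/V_d)·2^(−(t−tᵢ)·24/t_half)` (constant
endogenous release plus first-order elimination of intravenous boluses) drives
the system at three points:

* CFU-E survival: `α = α_min + (α_max − α_min)·exp(−s_α E)`;
* reticulocyte maturation speed: `v = min(v_max, v_min + s_v E)`;
* neocytolysis: cells younger than μ_neo die at rate
  `α_neo·max(0, (E_neo − E)/E_neo)` when EPO is suppressed.

Cells reaching maturity `T_RBC` are cleared, so the lifespan is literally a
model parameter. The observable is Hgb via the Nadler blood volume and MCH;
measured pre/post-dialysis pairs convert simulated post-dialysis values to
pre-dialysis ones algebraically. Five parameters
`(T_RBC, E_endo, t_half, s_α, s_v)` are estimated per patient by multi-start
Nelder-Mead (log-space, with ±10% restarts) on the sum of squared post-dialysis
Hgb residuals over a 150-day adaptation window; `S0` follows from a
steady-state calibration against the first measurement. Accuracy is reported
as MAPE (adaptation fit, and per 30-day prediction window with frozen
parameters); parameter distributions are compared with the Kantorovich
(Wasserstein-1) distance.

## Worked example

```python
import numpy as np
from erysim import CohortConfig, EstimationConfig, estimate, generate_patient

patient = generate_patient(seed=42, config=CohortConfig(noise_cv=0.03))
result = estimate(patient.records, patient.profile, EstimationConfig(seed=0))
```

With seed 42 the generator draws a female patient (165 cm, 98 kg, total blood
volume 5.01 l) and produces 103 dialysis sessions of which 83 carry a
measurement; the fit recovers the generating parameters from the noisy series:

```
parameter                         true   estimated
t_rbc                            83.71       83.95     # RBC lifespan, days
e_endo                           4.207       4.161     # endogenous EPO, U/l
t_half                           11.45        11.9     # ESA half-life, hours
s_alpha                        0.01073      0.0103     # CFU-E survival slope
s_v                            0.05644     0.05352     # maturation-velocity slope
adaptation MAPE: 1.77%  (cost 4.11 (g/dl)^2, 6593 evaluations)
```

The 1.77% adaptation MAPE sits at the noise floor implied by the 3%
multiplicative measurement noise (E|ε| ≈ 2.4%), i.e. the model explains the
deterministic part of the Hgb trajectory essentially completely.

The same workflow is available from the shell:

```
erysim synth --n 5 --seed 1 --out data/
erysim fit --records data/records.csv --profiles data/profiles.csv --out fit/ --seed 2
erysim predict --records data/records.csv --profiles data/profiles.csv \
               --fits fit/fits.json --out pred/
erysim evaluate --records data/records.csv --predictions pred/predictions.csv --out eval/
erysim simulate --sex male --height 175 --weight 80 --params-file params.json \
                --bleed 85:200:5 --transfusion 91:2 --t-end 150 --out scenario.csv
```

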