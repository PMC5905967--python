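# Methods

## Population model

Erythropoiesis is modeled as five maturity-structured population classes in
series — BFU-E, CFU-E, erythroblasts, marrow reticulocytes, and circulating
erythrocytes (blood reticulocytes are counted with the erythrocytes).  Each
class carries a density `u(t, μ)` (cells per maturity-day) obeying

    ∂u/∂t + v(E) ∂u/∂μ = (β(E) − α(E, μ)) u,   v(E) u(t, 0) = f(t),

with the boundary influx `f` given by the upstream class's outflux
`v·u(t, μ_max)` and by the stem-cell commitment `S0` for BFU-E.  The model is
linear in the densities; all nonlinearity enters through the EPO forcing.

EPO couples to the cascade in three places:

* **CFU-E survival.**  `α_CFU-E(E) = α_min + (α_max − α_min) exp(−s_α E)` — a
  monotone decreasing form with a single slope parameter.  The functional form
  is a design choice (only the slope is a published quantity; the healthy
  reference value is s_α = 0.02 l/U).
* **Reticulocyte maturation velocity.**  `v(E) = min(v_max, v_min + s_v E)`,
  linear with a cap; healthy reference slope s_v = 0.08.
* **Neocytolysis.**  Cells of age μ ≤ μ_neo in the circulating class die at
  `α_neo · max(0, (E_neo − E)/E_neo)`: suppressed EPO selectively removes the
  youngest erythrocytes, which matters for dialysis patients whose endogenous
  EPO may sit below the threshold between doses.

Erythrocytes are removed when their age reaches `T_RBC` (absorbing right
boundary) — there is no additional random senescence term, so the estimated
lifespan is literally the age at clearance.  Proliferation rates are constant
per class: EPO acts through survival and velocity only, and BFU-E dynamics are
EPO-independent (held constant, as nothing firmer is published).

**EPO pharmacokinetics.**  Endogenous release is constant per patient (the
renal feedback loop is destroyed in CKD-5), and intravenous ESA boluses decay
with first-order elimination, so total EPO has the closed form
`E(t) = E_endo + Σ_{tᵢ≤t} (Dᵢ/V_d)·2^(−(t−tᵢ)·24/t_half)` with `t_half` in
hours and `V_d = 0.055 l/kg` body weight.  One unit of exogenous ESA is
treated as equipotent with one unit of endogenous EPO.

**Blood events.**  A bleed multiplies the circulating density by
`1 − volume/TBV`; a transfused unit adds `473 ml × 5·10⁹ cells/ml =
23.65·10¹¹ cells`, spread uniformly over `[0, T_RBC]` (the age distribution of
banked blood is unknown; uniform is the least-informative choice).  Marrow
classes are untouched by either.

## Default constants

| constant | value | meaning |
|---|---|---|
| maturity spans | 7 / 6 / 5 / 3 d | BFU-E, CFU-E, erythroblast, marrow retic |
| β | 0.5 / 0.5 / 0.7 / 0 / 0 /day | proliferation per class |
| α (constant classes) | 0.02 / — / 0.02 / 0 /day | baseline apoptosis |
| α_min, α_max | 0.01, 0.25 /day | CFU-E survival range |
| v_min, v_max | 0.1, 2.5 | reticulocyte velocity range |
| E_neo, μ_neo, α_neo | 5 U/l, 14 d, 0.4 /day | neocytolysis |
| MCH | 29 pg/cell | count → Hgb conversion |
| V_d | 0.055 l/kg | ESA distribution volume |

All constants live in one overridable table (`ModelConstants`).  The CFU-E
ceiling `α_max` was calibrated once against the clinical dosing scale: with a
large survival range (e.g. α_max ≥ 1/day) a single ESA bolus transiently
boosts marrow output by two orders of magnitude, so a simulated clinic would
hold hemoglobin with ~2 U/kg/treatment and any realistic titration loop
overshoots violently; at α_max = 0.25/day sustaining the 10–11.5 g/dl band
requires on the order of 10–20 U/kg/treatment, matching reported dialysis
practice, and closed-loop trajectories stay in the 8–16 g/dl range.  `S0` is
never a free constant: it is recalibrated per patient (see below), so the
model's absolute production scale always matches the observed hemoglobin.

## Numerical scheme

First-order upwind in maturity, explicit Euler in time:

    u[j] ← u[j] − (v·dt/Δμ)(u[j] − u[j−1]) + dt·(β − α_j)·u[j],

boundary node set to `f/v` after each step.  Default resolution Δμ = 0.25
maturity-days (1 d for the long erythrocyte class, whose spacing divides
`T_RBC` exactly); `dt = 0.8 × min_k(Δμ_k / v_k^max)` uses the capped
reticulocyte velocity, so one fixed step is CFL-stable for any EPO trajectory
and, importantly, is identical across candidate parameter vectors — which
makes fits of data generated by the same scheme exactly self-consistent.  A
`coarse()` preset (Δμ = 0.5/2) halves the work where throughput matters.
Doses and blood events are snapped to the time grid; the EPO forcing is
evaluated by the exact one-step recursion of the elimination ODE (algebraically
equal to the closed form at grid points).  The inner loop is JIT-compiled with
numba; a 150-day simulation costs well under a millisecond, which is what makes
multi-start estimation over whole cohorts cheap.

Two steady-state constructions support the solver.  The analytic profile
`u(μ) = (f/v)·exp(((β−α)/v)μ)` (piecewise over the neocytolysis window) is the
convergence oracle: the scheme's error against it is O(Δμ)·(β−α)², so the
1%-at-Δμ=0.25 convergence check is run on a moderate-rate configuration
(|β−α| ≤ 0.05/day); with the stiff default CFU-E rates the discrete profile
deviates from the continuum one by several percent, which is immaterial for
estimation because generator and fitter share the discretization.  The
*discrete* steady state — the exact fixed point
`u[j] = u[j−1]/(1 − (β−α_j)Δμ/v)` of the update, independent of `dt` — is used
as the initial condition and for calibration, so a resting patient holds its
hemoglobin to rounding rather than to truncation error.

## Observation model

Post-dialytic total blood volume comes from the Nadler regression (sex, height,
weight); Hgb = count·MCH/(TBV·10).  Simulated pre-dialysis values are obtained
from the measured pre/post pair: `preTBV = postHgb·postTBV/preHgb` and
`preHgb_sim = postHgb_sim·postTBV/preTBV`, which reduces to rescaling by the
measured ratio.  Intradialytic fluid dynamics are deliberately not modeled.

## Parameter estimation

Five parameters per patient: `T_RBC`, `E_endo`, `t_half`, `s_α`, `s_v`.  `S0`
is fixed by linearity: one reference steady profile at `S0 = 1` gives the
influx that reproduces the first observed post-dialysis Hgb exactly.  The cost
is the unweighted SSE of post-dialysis Hgb at measured sessions, with doses and
events replayed from the records; simulation failures map to a large finite
penalty so the simplex can continue.

The search runs in log-parameter space (the optimizer itself is unconstrained,
but negative lifespans are meaningless): 32 Latin-hypercube candidates over
the physiological starting ranges (T_RBC 35–135 d, E_endo 2–20 U/l, t_half
4–12 h, s_α 0.001–0.03, s_v 0.001–0.2) are screened by a single cost
evaluation; the best 4 seed Nelder-Mead runs (max 600 iterations, xatol 1e-3
in log space); the incumbent is then restarted with ±10% multiplicative
perturbations until two consecutive restarts improve by <0.1% (≤10 restarts);
an optional coordinate-wise refinement pass exists for stubborn patients.
Everything is deterministic given the seed.  The adaptation window is the
half-open 150 days from the first record; estimates far outside the starting
ranges warn rather than fail.

## Synthetic cohort

The generator emulates the study conditions the estimator assumes, as a pure
function of (seed, config): Mon/Wed/Fri sessions over 150 adaptation + 90
prediction days; anthropometrics from dialysis-population statistics (52% male,
height 166.5±9.7 cm, weight 78.6±19.7 kg minus 2.56 kg interdialytic gain);
true parameters drawn from reported cohort distributions — T_RBC ~
N(73, 20²) truncated to [33, 137] d, t_half log-normal with median 6.3 h
truncated to [3.8, 13.6], E_endo ~ N(8, 3²) truncated ≥1 U/l (CKD-5 scale),
and both slopes log-uniform over their reported ranges (0.0013–0.0208 and
0.0007–0.1864).

Patients start at the un-dosed steady state of their own parameters, with Hgb
drawn around 8.75 g/dl — untreated renal anemia — so sustained ESA therapy is
required to reach the target band.  Dosing is produced by a titration
controller (the real records contain prescriptions but no algorithm): per-kg
dose starts at 18 U/kg, steps ±25% at most every 14 days when the trailing
two-week mean of *measured* Hgb leaves the 10–11.5 g/dl band, is clipped to
[0, 100] U/kg, rounded to 100 U — and is withheld entirely while the trailing
mean is above the band, mirroring clinical hold rules (without the hold, the
marrow pipeline plus the long RBC lifespan make overshoots persist for months).
The resulting trajectories show the slow Hgb cycling familiar from dialysis
practice.

Measurements get multiplicative noise `(1 + cv·N(0,1))` (default cv = 3%; no
monitor noise magnitude is published, and the acceptance harness exercises 0%
and 3%); the pre-dialysis value divides out an independent fluid-shift ratio
~ U(1.02, 1.12); sessions after the first are dropped i.i.d. with probability
0.18, reproducing the ~53±7 usable measurements per adaptation window.  The
first session is always recorded because it anchors the steady-state initial
condition.  Dropped sessions keep their row with Hgb "NA" and the dose intact
(doses come from pharmacy records, not the bedside monitor).  Bleed/transfusion
scenarios insert a multi-day bleed followed by packed red cells and appear as
measurement-free event rows.

The generator advances the same solver session by session, so with noise
switched off the recorded series is *exactly* reproducible by replaying the
recorded doses at the true parameters: the cost at the truth is numerically
zero and parameter-recovery experiments measure the estimator, not scheme
mismatch.

What the generator does not emulate: iron dynamics and hepcidin,
inflammation, structured hospitalization gaps, monitor drift or optical-sensor
physics, and any real between-session correlation of fluid status.  Passing
recovery tests therefore demonstrate identifiability and correctness of the
pipeline under the model's own assumptions, not clinical validity on real
monitors.

## Evaluation

Adaptation quality is the MAPE `100/N·Σ|y−g|/|y|` on post-dialysis Hgb (the
fitted quantity).  Prediction quality is reported on pre-dialysis Hgb — the
clinically customary presentation — in half-open 30-day windows after the
adaptation period, with parameters frozen; patients contribute only to windows
their follow-up reaches, so the cohort N shrinks with horizon.  Parameter
distributions are compared with the Kantorovich (Wasserstein-1) distance,
computed from the empirical CDFs via `scipy.stats.wasserstein_distance` and
cross-checked in the tests against the sorted-pairing coupling.

## Problem sizes and determinism

The validation suite fits 20 noise-free and 6 noisy virtual patients at the
default resolution (a few seconds per fit); `scripts/acceptance.py` uses 8
noise-free and 4 noisy patients, all freshly generated from the command-line
seed.  Every random draw in the package flows from an explicit seed: cohort
generation, measurement noise, start sampling and restart perturbations, so
repeated runs are bit-identical.

## Known limitations

* The estimator assumes the patient starts at steady state at the first
  measurement; a patient mid-transient (e.g. shortly after a transfusion) will
  bias `S0` and, through it, the early fit.
* `E_endo` and `s_α` are partially confounded when dosing varies little — the
  eligibility rule (≥2 administrations) is a weak floor; variable dosing is
  what makes the five parameters jointly identifiable.
* Cost discontinuities of order the discretization error exist where the
  erythrocyte node count changes with candidate `T_RBC`; Nelder-Mead tolerates
  them, but gradient-based optimizers would not without smoothing.
* MCH is a population constant (29 pg); per-patient MCV/MCH data would shift
  absolute counts but not Hgb fits.
* The titration controller is a stand-in for prescriber behavior; estimates on
  real records should replay the recorded doses, which the fitting path
  already does.
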