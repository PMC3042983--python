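# Methods

## The model

Intracranial pressure (ICP) `p(t)` during a constant-rate infusion study
is driven by a volume balance: fluid enters the cerebrospinal space at
rate `I` (external infusion plus CSF formation, mL/min), is stored
against the compliance `C(p) = 1/(E·p)` (elastance `E`, mL⁻¹; reference
pressure fixed at 0), and is reabsorbed into the sagittal sinuses at
rate `(p − p_b)/R` (outflow resistance `R`, mmHg·mL⁻¹·min; baseline
pressure `p_b`, mmHg).  Perturbing the inflow rate with white noise of
intensity `σ` (mL/min) and passing to the Ito differential gives

    dp = (E·I·p − E·p·(p − p_b)/R) dt + σ·E·p dW
       = (α·p − β·p²) dt + a·p dW,

with `α = E(I + p_b/R)` (min⁻¹), `β = E/R` (mmHg⁻¹·min⁻¹) and
`a = σE` (min⁻¹) — a stochastic logistic (Verhulst) process.  The Ito
convention is fixed; there is no Stratonovich mode.  The nonzero
reference-pressure variant is out of scope (no closed-form solution is
known); the `p0_ref` field exists only to keep serialised configurations
forward-compatible.

Units are minutes, mmHg and mL throughout, with no conversion layer.

### Reference parameters

| symbol | default | unit | meaning |
|--------|---------|------|---------|
| E      | 0.15    | mL⁻¹ | cerebral elastance (infusion-study estimates) |
| R      | 7       | mmHg·mL⁻¹·min | CSF outflow resistance (typical range 6–10) |
| p_b    | 8       | mmHg | baseline pressure |
| I      | 1.5     | mL/min | constant infusion rate of the clinical protocol |
| σ      | 0.5     | mL/min | inflow-noise intensity, `round(0.33·I, 1)` |

`σ` is calibrated as one third of the inflow rate — the fluctuations in
CSF formation are poorly observable, so this is a deliberate
order-of-magnitude choice; the risk analyses therefore sweep
σ = 0.4–1.3 mL/min rather than rely on the point value.  The
deterministic equilibrium is `R·I + p_b = 18.5` mmHg (the Davson
relation).

## Closed-form pathwise solution

With `g(t) = (α − a²/2)t + a·W(t)`,

    p(t) = exp(g(t)) / ( 1/p₀ + β·∫₀ᵗ exp(g(s)) ds ).

Substituting via Ito's formula reproduces the SDE exactly, which also
pins the denominator coefficient as `β = E/R` (dimensional analysis
agrees: (mmHg⁻¹ min⁻¹)·min = mmHg⁻¹, matching `1/p₀`).  Two numerical
choices matter:

* **Log-space evaluation.**  `g` reaches magnitudes of order 10³ at
  physiological parameters over long horizons, so the numerator,
  integrand and denominator are manipulated as logarithms
  (`logaddexp.accumulate` for the running integral).
* **Exponential quadrature.**  The integral of `exp(g)` over one step is
  computed assuming `g` piecewise linear:
  `Δt·(e^{g₁} − e^{g₀})/(g₁ − g₀)`, in log space with a series fallback
  for small increments.  This is the natural interpolation of the
  sampled Brownian path and — unlike the plain trapezoid rule, which is
  only O(Δt²) accurate — it is *exact* when σ = 0, so the noise-free
  reduction to the deterministic logistic solution holds to machine
  precision on any grid.

## Discretisation schemes

* `euler-maruyama`: the literal discretisation
  `p_{k+1} = p_k + (αp_k − βp_k²)Δt + a·p_k·ΔW_k`.  It can cross zero;
  that is signalled as a `PositivityBreachError` with the step index,
  never hidden.  It anchors the strong-convergence study (empirical
  endpoint order ≈ 0.5 against the closed form on a common path).
* `log-euler` (default): Euler on `y = ln p` after Ito transformation,
  `y_{k+1} = y_k + (α − a²/2 − β·e^{y_k})Δt + a·ΔW_k`.  Positive by
  construction, as the exact solution says the process must be.
* Default step `dt = 1e-3` min for single trajectories; both schemes
  consume the identical Brownian increments for a given seed, so they
  are pathwise comparable.

Ensembles derive per-path seeds from the master seed by a counter rule
(`SeedSequence(master, spawn_key=(i,))`), making path *i* independent of
the ensemble size, and are integrated in path chunks to bound memory.

## Stationary analysis

The zero-flux stationary Fokker–Planck solution,
`f ∝ exp(∫2·drift/diff²)/diff² ∝ p^{shape−1} e^{−rate·p}`, is a gamma
law with

    shape = 2(R·I + p_b)/(R·E·σ²) − 1,   rate = 2/(R·E·σ²),

proper iff `σ² < 2(R·I + p_b)/(R·E)` (strict).  Two independent anchors
pin the derivation and are asserted numerically over random parameter
draws at 1e-10 relative tolerance: the mean `shape/rate` must equal
`(R·I + p_b) − R·E·σ²/2`, and `shape > 0` must coincide with the
existence condition.  Consequences tested: the mean *decreases* with
σ², and `∂μ/∂R = I − σ²E/2`, so inflow noise dampens the influence of
outflow resistance on the average ICP.  At σ = 0 the stationary law
degenerates to a point mass and the constructor signals, pointing to
the deterministic equilibrium instead.

## First-passage probabilities

The risk quantity is the two-barrier probability `u(x)` of reaching a
critical level `b` (default 40 mmHg) before a lower level `a`, from the
current ICP `x`.  It is computed through the scale function:
`u = (S(x) − S(a))/(S(b) − S(a))` with `S' = s` and

    log s(p) = −(2/(σ²E))·[(I + p_b/R)·ln p − p/R],

the elementary antiderivative of `−2·drift/diff²` (minimised exactly at
the deterministic equilibrium).  `∫s` is evaluated by composite 16-node
Gauss–Legendre quadrature on the *log* integrand with log-sum-exp,
panel-doubling until the log-integral changes by < 1e-8; linear-space
evaluation is never used, because at σ = 0.5 the integrand spans > 500
natural-log units across (0.1, 40) mmHg.  `log_hitting_probability`
stays finite even when `u` itself underflows.

**Lower boundary.**  The textbook formulation imposes `u(0) = 0`, but
0 is an entrance boundary whenever the stationary law exists (the scale
integral diverges there), so the exact `a → 0` limit is `u ≡ 1` — the
boundary condition is degenerate.  The library therefore exposes a
clinically meaningful positive lower level (default `a = 30` mmHg for
the 35 → 40 mmHg scenarios: "drops 5 before rising 5"), and keeps
`paper_bvp_probability` as an explicit replication mode that solves the
singular two-point boundary-value problem

    (σ²E²x²/2)·u'' + (αx − βx²)·u' = 0,  u(ε) = 0, u(b) = 1,

by central finite differences on `[ε, b]`; it matches the scale-function
route with `a = ε` to 1e-6 and exhibits the `ε → 0` degeneracy
explicitly.  A consequence worth stating plainly: the near-zero plateau
and the convex, thresholded rise of the risk curves are properties of
the well-posed two-barrier question, while "probabilities approach one"
is a property of the singular `u(0) = 0` formulation; on the standard
grids (σ ≤ 1.3, R ≤ 12) the two-barrier corner probability is ≈ 0.30
and its large-R limit at σ = 1.3 is ≈ 0.85, not 1.  No particular
threshold location (e.g. σ = 1.1 or R = 10) is treated as exact.

**Monte-Carlo cross-validation.**  An independent estimator simulates
log-Euler paths (default n = 20 000, dt = 5e-4 min, horizon 60 min) and
counts which barrier is crossed first, detecting crossings by level
comparison at grid times (no Brownian-bridge correction — an O(√dt)
bias, covered by a 0.005 allowance in comparisons, larger for starts
adjacent to a barrier).  Censored paths are reported, and > 1%
censoring signals an error rather than biasing the estimate.

## Synthetic infusion recordings

`synth_infusion_recording` emulates a two-phase clinical trace: a
baseline phase with `I = 0` (pressure settling near `p_b`) followed by
constant infusion at 1.5 mL/min, one continuous Brownian realisation
across both phases, log-Euler at an internal step ≤ 1e-2 min, resampled
at the protocol interval (default 0.1 min; defaults 10 min baseline +
45 min infusion).  It reproduces the gross features of a noisy bedside
recording — logistic rise, stationary fluctuations of sd ≈ 1.55 mmHg at
σ = 0.5 — but *not* pulsatile cardiac/respiratory waveform components,
measurement-device artifacts, or slow parameter drift; tests passing on
it validate the solver and the statistical machinery, not the clinical
realism of any individual waveform.

## Problem sizes and numerical checks

The validation suite uses: stationary recovery from a single
T = 5000 min path (dt = 1e-2, 500 min burn-in, 1-min thinning, ~4500
samples; batch-means SE over 30 batches; KS distance < 0.03 against the
derived gamma); a 200-path strong-convergence study over T = 5 min
(dt ∈ {1e-2, 5e-3, 2.5e-3} vs a 1e-4 reference); and 20 000 Monte-Carlo
paths for the hitting-probability cross-check at σ = 1.2, where the
analytic value is ≈ 0.0385.  Degenerate inputs are signalled, not
coerced: σ = 0 in any stochastic-only operation, non-positive pressures
in compliance/scale computations, `ε ≤ 0` in the BVP, and Euler
positivity breaches all raise typed exceptions.

## Known limitations

* No parameter estimation from patient recordings; parameters are
  inputs.
* No nonzero reference pressure, no jump noise, no Stratonovich mode,
  no time-resolved first-passage densities or expected hitting times.
* The Monte-Carlo estimator's crossing detection is first-order in
  √dt; for barrier-adjacent starts reduce dt accordingly.
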