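# Methods

This note documents the models, statistics and numerical choices behind
`cvcalib`: what is computed, under which assumptions, and which knobs
matter.

## The forward model

The circulation is a closed-loop lumped-parameter (0D) model: 21 ODEs in
compartment *stressed* volumes (volume above the unstressed vessel
volume), with pressures obtained from volume through compliances.
Internal units are SI-derived throughout: m³ for volume, MPa for
pressure, s for time, so resistances are MPa·s/m³ and compliances
m³/MPa; reported pressures are converted to kPa (and mmHg via
0.133322 kPa/mmHg).

Module realizations:

* **Heart chambers** (RA, RV, LA, LV) — time-varying elastance,
  p = E(t)·q, with E(t) = (E_A − E_B)·e(t) + E_B and e(t) a raised
  cosine of width 0.3 s (ventricles) or 0.15 s (atria, onset 0.8 s so
  atrial systole immediately precedes the ventricular beat at a heart
  period of 1 s).  E_A is the chamber's maximum elastance — the free
  contractility parameters E_LVa, E_RVa — and E_B its diastolic
  baseline stiffness.
* **Valves** — ideal diodes in series with a small resistance.
  max(Δp, 0) is smoothed as (Δp + √(Δp² + ε²))/2 with ε = 10 Pa, which
  is C∞, strictly positive (no reverse leak of negative sign), and
  cheap to evaluate inside the integrator.
* **Vessel segments** — linear compliances joined by resistances
  (RC π-elements without inertances; terminal compliance and inertance
  identification is out of scope and those elements are held fixed).
* **Terminal beds** — a lumped terminal resistance R_x_T feeding a
  terminal compliance, drained through a fixed venous-return
  resistance.  The seven beds (leg LE, brachial BR, anterior/middle/
  posterior cerebral AC/MC/PC, external carotid EC, trunk TR) hang off
  a reduced arterial tree: aortic root → upper-body branch → (brachial
  artery; cerebral branch → middle cerebral artery) and aortic root →
  descending aorta.
* **Veins** — upper- and lower-body compliances sharing the single
  venous compliance parameter C_V (45% / 55% split), returning to the
  right atrium through vena-cava resistances.

The middle cerebral artery pressure p_MC — the *core prediction* — is
the pressure of a dedicated MCA compartment between the cerebral branch
and the middle cerebral terminal bed, so it responds directly to
R_MC_T.

**Conservation.** Every flow appears with opposite signs in exactly two
volume derivatives, so total stressed volume is conserved analytically;
fixed-step RK4 preserves this to rounding (observed drift ~1e-18 m³,
against a tolerance-based ceiling of 1e-10).

**Nominal parameters.** The twelve calibration candidates (stressed
blood volume q_sbv, ventricular maximum elastances, pulmonary
resistance, seven terminal resistances, venous compliance) take typical
adult values consistent with published lumped-model estimates; the
fixed plumbing (baseline elastances, segment R/C, venous return
resistances, unstressed-volume reporting offsets) was chosen once so
that the nominal model is physiologically plausible: brachial pressure
≈ 134/98 mmHg, MCA mean flow ≈ 177 ml/min, left-ventricular volumes
83–115 ml, atrial volumes 47–72 ml.  Because the arterial tree carries
one representative branch per territory (not bilateral duplicates),
total model flow is correspondingly low (≈1.9 l/min through the seven
beds); all calibration experiments are self-consistent with respect to
this design.  Physiological bounds span roughly ×/÷3 around nominal.

**Initial condition.** q_sbv is distributed across compartments with
weights compliance × reference filling pressure (13 kPa arterial,
1.4 kPa pulmonary-venous, 0.9 kPa venous, chamber baselines), then the
loop is integrated over repeated cardiac cycles until the cycle-start
state changes by less than the periodicity tolerance (relative L∞).
The converged cycle does not depend on the initial distribution; the
reference-pressure weighting only shortens the run-in.

## Solver

A fixed-step classical RK4 integrator, numba-compiled, with reciprocal
conductances precomputed per solve.  Two standard configurations:

| setting | reference | pipeline |
|---|---|---|
| step dt | 0.5 ms | 1 ms |
| periodicity tolerance | 1e-6 | 1e-4 |
| max cycles | 60 | 60 |
| output sampling | 500 Hz | 500 Hz |

The stability bound is set by peak systolic elastance against the
aortic valve resistance (λ ≈ E_LVa/R_aov ≤ ~1700 s⁻¹ at the E_LVa upper
bound), safely inside the RK4 region at dt = 1 ms.  Against a dt =
0.5 ms, tol = 1e-7 reference, the pipeline configuration reproduces all
fifteen observables to ≤ 7e-4 relative — at least 20× below the
smallest measurement CV (1.5%) — at ~8 ms per solve, which is what
makes ~10⁵ forward solves per calibration affordable.  Integrator
failure (non-finite or runaway state) is reported as `solver_ok=False`
and treated by every caller as candidate rejection, never as an
exception.

During MCMC the likelihood warm-starts each solve from the previous
successful periodic state (proposals are local, so the previous orbit
is a good initial guess; the periodicity criterion keeps the result
init-independent to within its tolerance).  This makes the likelihood
closure stateful, so it is used only inside the sequential sampler —
population (GA) evaluation stays pure.

## Measurements and objective

A patient is a set of named scalar observables: chamber-volume extrema,
brachial-pressure extrema and mean, and mean terminal flows.  Each
carries either a standard deviation σ or a coefficient of variation
CV = σ/ẑ (equivalently CV = RC%/2.77 for a repeatability coefficient).
The packaged CV table uses echocardiographic inter-observer CVs for the
volumes (10–23.5%), 24-h cuff repeatabilities for the pressures (1.5%
systolic, 4% diastolic, 2.25% mean — the mean-pressure value is the
estimate its source derived from the extrema repeatabilities), 8% for
the cerebral terminal flows, and deliberately large CVs (30–50%) for
the non-crucial leg/arm/trunk flows so they only weakly constrain the
fit.  Missing measurements are simply absent rows — no imputation.

The objective is the weighted sum of squares
cost(θ) = Σᵢ ((fᵢ(θ) − ẑᵢ)/σᵢ)², and the MCMC log-likelihood is
−0.5·cost (independent Gaussian errors, no correlation structure).

## Synthetic patients

The generator simulates the model at a known parameter vector and
applies multiplicative Gaussian noise, ẑ = f_true·(1 + CV·ξ),
resampling ξ (not clipping) if a value would go non-positive.  The CV
table doubles as the noise law and the weighting; `noise_scale=0`
yields a noise-free patient that keeps realistic σ.  Three presets
mirror typical data availability: the full set, a missing atrial
minimum, and missing ventricular volumes.

What the generator does *not* emulate: acquisition artifacts of the
modalities, correlated errors between observables traced from the same
image, and any model mismatch — the synthetic patient is drawn from the
same model family that is fitted, so passing tests demonstrate the
pipeline's internal consistency (parameter recovery, honest interval
coverage), not robustness to structural error on real patients.

## Identifiability reduction

At a fit point θ* the normalized sensitivity matrix is computed by
first-order forward differences, S_kl = ∂f_k/∂θ_l · θ*_l/σ_k, with
relative step 1e-3 (stepping backwards at the upper bound, halving the
step on solver failure).  Sensitivity runs use an exact cycle count
(45 cycles, periodicity stop disabled) so the finite differences see a
deterministic solver rather than a cycle-count discontinuity.

Parameter importance is the column RMS δ_l = √(Σ_k S_kl²/n_z);
pairwise collinearity normalizes each column to unit norm (divide by
δ_l√n_z) and takes γ_ij = 1/√μ_min of the 2×2 Gram matrix, equal to
1/√(1 − |cos∠|) in closed form.  γ is capped at 1e12 for serialization
(proportional columns).  Thresholds: importance t_i = 0.1, collinearity
t_c = 10 (the classical critical range is 5–20; |cos| = 0.99
corresponds exactly to γ = 10).

Each iteration of the reduction loop refits the current free set with
the genetic algorithm, then fixes **at most one** parameter: the
lower-importance member of the worst above-threshold collinear pair
(ties break to the name that sorts later), else the least important
below-threshold parameter.  Refitting after every single fixation
avoids cascading removals from one stale linearization.  Fixed
parameters are held at their nominal table values (their approximate
physiological values), not at the fitted values.  Before fixing, the
same quantities computed against the core predictions
(δᵖ, γᵖ, normalized by the prediction magnitudes, since predictions
carry no measurement σ) must show the candidate is *safe*: it either
barely moves the predictions (δᵖ < t_i) or is prediction-collinear
with a retained parameter (γᵖ ≥ t_c), whose freedom then expresses the
candidate's influence.  An unsafe candidate is retained and the next
pair considered.  The loop terminates when an iteration fixes nothing.

On the packaged model with the full measurement set the loop fixes C_V
(collinear with q_sbv — both control venous filling pressure), R_par
(collinear with E_RVa — right-heart strength versus pulmonary
afterload) and, depending on the noise realization, E_RVa itself
(which, once R_par is pinned, can become collinear with q_sbv at the
refit point), leaving 9–10 identifiable parameters; the prediction-
uncertainty threshold t_u is only ever reported, never used as a gate,
because acceptability of a prediction interval is a task- and
clinician-specific judgement.

## Genetic algorithm

Real-coded, box-bounded: tournament selection (size 3), BLX-α blend
crossover (α = 0.5, rate 0.9), per-gene Gaussian mutation (rate 0.2,
SD 5% of box width), elitism 2, clip-to-box.  Defaults are population
100 × 300 generations with a 50-generation stall stop; the desk-scale
pipeline uses 32 × 40 (stall 15), which reliably reaches the cost basin
that seeds the sampler.  Candidates whose forward solve fails receive
infinite cost and cannot be selected.  Identical seed and configuration
reproduce the trajectory bit for bit.

## Ensemble MCMC

The affine-invariant stretch move: a walker x_j proposes
y = x_k + z(x_j − x_k) with partner x_k drawn from the complementary
half-ensemble and z ~ g(z) ∝ 1/√z on [1/a, a], a = 2; acceptance
min(1, z^{d−1} e^{Δlog π}).  Priors are uniform on the physiological
box, so the log-posterior is −0.5·cost inside and −∞ outside (or on
solver failure).  Walkers (32, matching the full-scale setting even
when 2d < 32) start at the GA optimum perturbed per coordinate by
N(0, (0.01·θ*)²), redrawn until inside the support.

Full-scale chains are 5,000 steps with burn-in 2,500.  The desk-scale
runs in this repository use 3,000 steps with burn-in 1,500 — the same
50% burn-in proportion — because the tiny initialization ball makes
the ensemble expand slowly into the flattest posterior directions
(practically weakly-identified parameters such as E_RVa), and shorter
chains demonstrably fail the convergence diagnostic.

## Geweke convergence diagnostic

For a single series, the classical construction: compare the means of
the first 10% and last 50% with a Z-score whose segment variances are
spectral-density-at-zero estimates (Tukey–Hanning lag window over the
first 4% of lags); two-sided normal p-value; p > 0.05 for every
parameter passes.

For the ensemble chains the per-segment spectral estimate is invalid at
desk scale: a 10% segment of the kept chain holds only a couple of
ensemble autocorrelation times, and the resulting Z-scores are badly
anti-conservative (measured ~30% false-failure rate on an exactly
converged Gaussian target).  The chain-level score therefore
standardizes the same segment-mean difference by the **sum of two
complementary variance components**: the between-walker variance of
the paired differences d_w = mean(early_w) − mean(late_w) over W (the
walker-idiosyncratic part, in which any common-mode shift cancels),
plus var·τ·(1/n_a + 1/n_b) of the per-step ensemble-mean series with τ
estimated by automatic Sokal windowing over the whole kept chain (the
collective-wander part, into which idiosyncratic noise enters only at
1/W).  Their sum bounds the total variance, making the per-parameter
p-values deliberately conservative — which is the only way the "all
p > 0.05" family rule can work with ~10 parameters, since an exactly
calibrated per-parameter test would fail that rule on ~40% of
perfectly converged runs.  Measured behaviour on dimension-matched
Gaussian-target ensembles: ~5% false-failure rate, while cold-started
(unconverged) ensembles are rejected at p ≲ 1e-2.  A Geweke failure
aborts the pipeline with exit code 3 *after* persisting chains and
diagnostics.

## Core-prediction uncertainty

100 parameter vectors are drawn uniformly **without replacement** from
the flattened post-burn-in samples (far fewer than available, avoids
duplicate domination); each is simulated and the p_MC waveform kept,
aligned at cycle start.  Reported quantities: pointwise mean/SD and
equal-tailed 95% percentile band over the cycle, and per-sample
max/min/mean pressures with their medians and equal-tailed 95%
percentile intervals (linear-interpolation percentiles).  Both the
posterior-sample median and the best-fit value are available; the
median is the headline central value.  Interval half-widths are
reported in kPa and mmHg; the optional threshold t_u yields a pass/fail
annotation only.  Failed draws are redrawn and counted; more than ~50%
failures aborts (the posterior mass sits on a solver-failure region).

## Seeds and reproducibility

One global seed fans out through a seed sequence to the four stochastic
stages (reduction/GA, MCMC, prediction draws, synthetic noise); each
stage uses its own generator, so reruns reproduce every artifact bit
for bit, and stages can be rerun independently from their upstream
files.

## Problem sizes in the reproduction script

`scripts/acceptance.py` runs the desk-scale configuration: one
synthetic patient (full 15-observable set, table CVs), GA 32 × 40 per
reduction iteration, ensemble 32 × 3,000 steps (burn-in 1,500), 100
prediction samples — about 10⁵ forward solves in total.

## Known limitations

* Identifiability is *local* (finite differences at θ*); a different
  basin could have a different collinearity structure.
* The uncertainty band reflects parameter uncertainty only; with no
  model-mismatch term it is a lower bound on real predictive
  uncertainty.
* The reduced single-branch arterial tree carries less total flow than
  a bilateral anatomy; absolute flows are per-territory
  representatives.
* The Gaussian independent-noise likelihood ignores correlations
  between observables derived from the same acquisition.
* Heart period is fixed per patient (1 s default), not calibrated.
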