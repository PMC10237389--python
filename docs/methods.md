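# Methods

## The model

`nfkbid` implements a six-variable, non-dimensional ODE model of the
canonical NF-κB signaling pathway with its two NF-κB-induced negative
feedback loops: IκBα, which binds NF-κB and holds it in the cytoplasm, and
A20, which inactivates the active IκB kinase (IKKa) and thereby protects
IκBα from IKK-driven degradation. The state is

| variable | meaning |
|----------|---------|
| `IKKn`   | neutral IκB kinase (fraction of total IKK) |
| `IKKa`   | active IκB kinase |
| `NFkBn`  | free nuclear NF-κB; total NF-κB is conserved, so the cytoplasmic (IκBα-bound) pool is 1 − NFκBn |
| `A20`    | A20 protein |
| `IkBa`   | free cytoplasmic IκBα protein |
| `IkBat`  | IκBα transcript |

TNF stimulation is a binary input T_R ∈ {0, 1} that switches the
IKKn → IKKa activation term. The equations (rates per second):

```
IKKn'  = k_deg − k_deg·IKKn − T_R·k1·IKKn
IKKa'  = T_R·k1·IKKn − (k3 + k_deg + T_R·k2·A20)·IKKa
NFkBn' = a3·IKKa·(1−NFkBn)·δ/(IkBa+δ) − i1a·IkBa·NFkBn/(NFkBn+ε)
A20'   = c_deg·NFkBn − c_deg·A20
IkBa'  = c4a·IkBat − c5a·IkBa − a2·IKKa·IkBa
         − a3·IKKa·(1−NFkBn)·IkBa/(IkBa+δ) − i1a·IkBa·NFkBn/(NFkBn+ε)
IkBat' = c3a·NFkBn − c3a·IkBat
```

The two Michaelis-type constants δ and ε arise from the elimination of
fast binding steps; the release fraction δ/(IkBa+δ) in the NFκBn equation
and the consumption fraction IkBa/(IkBa+δ) in the IκBα equation sum to
one, so the a3-driven flux out of the cytoplasmic complexes is conserved.
With TNF off, the system has the exact resting state (1, 0, 0, 0, 0, 0),
which is the default initial condition everywhere.

Two named parameter presets are built in: `pre-fitted` (values produced by
the reduction itself) and `fitted` (values refitted against the parent
15-variable mechanistic model; the nominal set). The parent model is not
re-implemented here — reference trajectories from it, or from any other
source, enter as measurement CSV files.

The A20 knock-out genotype zeroes the A20 synthesis term (the knocked-out
protein never appears, A20 ≡ 0 from A20(0) = 0). For every other variable
this is equivalent to setting k2 = 0, which the test suite checks; A20 is
never part of knock-out measurement schedules.

## Numerics

Integration runs in seconds (rate constants are s⁻¹) with LSODA, analytic
Jacobian, rtol 1e-8 and atol 1e-10; the public time coordinate is minutes.
Because the TNF input is discontinuous, the integrator is restarted at
every ON/OFF switch rather than stepping across it; a measurement at a
switch time reads the (continuous) state at that instant. Trajectory
values are clamped to zero only for excursions above −1e-7, which is the
solver-tolerance scale on this positivity-preserving system. Halving the
tolerances moves trajectory values by less than 1e-6 (tested).

The stimulated (T_R = 1) fixed point is found by a damped Newton root
search seeded with the time average of the tail of a 200-hour tonic
simulation — on a limit cycle that average lies in the interior near the
unstable fixed point. Convergence requires a residual ∞-norm below 1e-12;
stability is read off the analytic Jacobian's eigenvalues with a margin of
1e-9 s⁻¹ on the leading real part.

## Protocols and measurements

A protocol couples contiguous TNF segments (minutes) with per-genotype,
per-observable measurement times for the five observables IKKa, NFκBn,
total IκBα (IκBα* = IκBα + 1 − NFκBn), A20 and IκBα mRNA. The built-in
on–off protocol (TNF ON 0–120 min, OFF 120–720 min; 50 measurements in 9
series) is the reference identification experiment; tonic and pulsatile
stimulus shapes are available as builders, and user protocols load from a
validated YAML/JSON schema (a commented template ships with the package).

Measurements mimic data in arbitrary units. Each series x is shifted by
x′ = x + ρ·max(x) with ρ = 0.03 — values below ~3% of the series maximum
are experimentally indistinguishable from background — and divided by its
geometric mean, leaving n − 1 independent numbers per n-point series. The
independent-point count dim = N − n_series (41 for the on–off protocol) is
the scaling basis of all identifiability measures. Measurement noise is
multiplicative lognormal with median at the true value and geometric SD
σ_data ≥ 1, applied to raw values before the ρ-shift (the shift then uses
the noisy series' own maximum, as an experimenter would); each Monte Carlo
replicate r draws from an RNG seeded base_seed + r.

## Fitting

The objective is J(θ) = Σ (ln y_model − ln y_ref)² over all N matched
normalized measurements; goodness of fit is reported as the Average
Multiplicative Distance AMD = exp(√(J/N)) — the mean multiplicative factor
by which two trajectories disagree (1 = identical, 2 = average two-fold
discrepancy). `PathwayFit.fit` searches log-parameter space, where all 13
rates are positive and errors are multiplicative:

* `method="de"` — differential evolution (population 15×13 by default,
  Latin-hypercube initialisation inside fold-range bounds, default
  100-fold either side of the start, capped at 2×10⁵ model evaluations,
  followed by a local polish). Seed-deterministic.
* `method="local"` — bounded trust-region least squares from a starting
  point, for refits known to lie near the start.

## Linear identifiability analysis

The sensitivity matrix S has one row per normalized measurement and one
column per parameter, s_ij = ∂ln y_i/∂ln θ_j, by central finite
differences with a 1% increase/decrease of each parameter (step-halving
changes entries by < 1%, tested). Geometric-mean normalization makes the
per-series column sums vanish, which is why a series only carries n − 1
independent values. Singular values, column norms ‖S_j‖ and perpendicular
components ‖S_j⊥‖ are divided by √dim, making them invariant under
repetition of an experiment (tested by stacking). The error-amplification
ratios R_j = ln σ_linear,j / ln σ_data are the row norms of the
pseudo-inverse (SᵀS)⁻¹Sᵀ, computed through the QR factorisation of S
(row norms of R_a⁻¹), which agrees with the dense pseudo-inverse to 1e-8
on random matrices but is numerically stabler. R_j is reported both raw
(used for σ_linear,j = σ_data^R_j) and ×√dim for cross-protocol
comparison, since either scaling convention is defensible. Confidence
ellipses in log-parameter planes come from the 2×2 marginals of
ln(σ_data)²·(SᵀS)⁻¹ scaled by the χ²₂ quantile.

On the on–off protocol at the fitted parameters this implementation gives
a smallest scaled singular value of ≈ 0.025 (all 13 above 1e-3: the model
is structurally identifiable there) and a largest R_j of ≈ 5 (for ε,
with δ a close second), i.e. max σ_linear(σ_data = 1.3) ≈ 3.8.

## Monte Carlo practical identifiability

For each noise level σ_data, k perturbed copies of the on–off measurements
are drawn and all 13 parameters refitted to each; the geometric SD of the
estimates, σ_carlo,j = exp(SD(ln θ_j,k)), measures practical
identifiability. Two design choices matter:

* **Refit strategy.** A full population-based global search per replicate
  costs ~10⁵ ODE solves and is not what σ_carlo needs. The noisy
  log-objective is, however, multimodal — descents from jittered starts
  sometimes reach lower J at parameters farther from the truth — so a
  single local descent from the truth underestimates the spread of a
  global fitter. Each replicate therefore runs three trust-region
  descents (one from the nominal parameters, two from starts jittered by
  a lognormal factor of geometric SD 3) and keeps the lowest J: a
  budget-limited emulation of a stochastic global fit. With this scheme
  max_j σ_carlo,j at σ_data = 1.3 lands near 3, against a linear-analysis
  prediction of 3.8.
* **Common random numbers.** Replicate seeds do not depend on the noise
  level, so the σ_data levels share underlying noise draws; level-to-level
  comparisons (σ_carlo growing with σ_data) are then sharp already at
  k = 20, the scaled-down replicate count used by the test suite
  (k = 50 with the full global fitter is an hours-scale computation).
  At σ_data = 1 the perturbation is the identity and the deterministic
  refit is computed once.

## Response-regime classification

`classify_response` simulates tonic TNF (default onset 1 h, horizon 48 h,
0.5-min grid — peak times are absolute, so the first response peak sits
just after 1 h), detects NFκBn peaks (prominence ≥ 1% of the signal range,
quadratic sub-grid refinement) and assigns one of five labels from
recorded metrics:

* late-window (last 25% of the horizon) amplitude ≥ 1% of the first-peak
  amplitude → **sustained**; of these, a late-window floor below 0.05 of
  the total NF-κB pool → **spiky** (relaxation-like: the orbit has a slow
  segment with NFκBn ≈ 0 and a fast spike away from it). The floor
  criterion replaces a duty-cycle rule because the decaying tail of a
  relaxation spike keeps NFκBn above 10% of its maximum for well over
  half the cycle, which a duty-cycle threshold misreads as smooth;
* otherwise, adaptation index (final NFκBn / first peak) < 0.1 with a
  pronounced first peak → **near-perfect adaptation**;
* otherwise ≥ 2 peaks → **damped**; else **no oscillation**.

Labels whose deciding metric lies within 25% of its threshold carry a
low-confidence flag. With the nominal parameters the response is damped
with the second NFκBn peak near 3.4 h; weakening IκBα degradation
(a2 = 0.02, c5a = 1e-5, i1a = 1e-4) destabilises the stimulated fixed
point and gives a limit cycle with the second peak near 4.7 h; a2 = 0.01
gives relaxation-like spikes; k2 = 0 (no A20 feedback) gives a single
overshoot to a high plateau; k2 = 3.57 with i1a = 0.01 gives near-perfect
adaptation.

## What the synthetic data does and does not emulate

The in-silico measurements reproduce the structure of population-level
time-course data: arbitrary units (hence geometric-mean normalization),
multiplicative errors, sparse per-variable schedules, and genotype panels
(WT and A20-KO). They do not emulate single-cell heterogeneity or
stochastic transcriptional bursting, correlated (batch) errors, or
background thresholds beyond the ρ-shift; passing tests therefore
demonstrate correctness of the identifiability machinery under the stated
noise model, not robustness of parameter estimation to un-modelled error
structure.

## Known limitations

* The parent 15-variable model and the published pulsatile measurement
  schedules are not bundled; cross-model distances (AMD to the parent
  model) and combination-experiment quantities require user-supplied
  reference tables and protocol configs.
* Identifiability analyses are local to the nominal parameter point.
* A small number of published landmark values resist exact reproduction
  from the printed information alone (the scaled c5a sensitivity norm and
  the identity of the largest-R_j parameter on the on–off protocol);
  the package reports its own computed values, whose companion landmarks
  (smallest scaled singular value, max σ_linear) do agree.
* No bifurcation continuation or entrainment analysis; regime labels are
  trajectory-metric based.
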