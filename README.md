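# nfkbid

A reduced, identifiable ODE model of the canonical NF-κB signaling pathway,
together with the analysis workbench needed to ask — and answer — the
question: *can all of its parameters be determined from a realistic
experiment?*

NF-κB is a central transcription factor of innate immunity. Its activity
under TNF stimulation is shaped by two NF-κB-induced negative feedback
loops: IκBα, which re-sequesters NF-κB in the cytoplasm, and A20, which
inactivates the IκB kinase. Detailed mechanistic models of this pathway
reproduce experiments but are non-identifiable — their parameters cannot
be pinned down by data. This package implements a deliberately small,
non-dimensional model (6 variables, 13 rate constants) that keeps both
feedback loops and the delayed IκBα transcription step, and the full
identifiability toolchain around it:

* stiff ODE simulation under piecewise-constant TNF protocols, for wild
  type and A20 knock-out cells (`simulate`, `stimulated_fixed_point`);
* in-silico measurements of the five observables (IKKa, nuclear NF-κB,
  total IκBα, A20, IκBα mRNA) with geometric-mean normalization and
  multiplicative lognormal noise (`simulate_measurements`, `normalize`,
  `add_lognormal_noise`);
* log-least-squares fitting with the Average Multiplicative Distance
  AMD = exp(√(J/N)) as goodness-of-fit (`PathwayFit` → `PathwayFitResults`);
* linear identifiability analysis: the log-log sensitivity matrix
  s_ij = ∂ln y_i/∂ln θ_j, its √dim-scaled SVD spectrum, column and
  perpendicular-component norms, QR-based error-amplification ratios
  R_j = ln σ_linear,j / ln σ_data, and confidence ellipses
  (`LinearAnalysis` → `LinearReport`);
* Monte Carlo practical identifiability: repeated refits to
  noise-perturbed data, σ_carlo,j = exp(SD(ln θ_j,k))
  (`run_monte_carlo` → `MCResult`);
* classification of the qualitative response to tonic TNF — damped,
  sustained or spiky oscillations, no oscillation, near-perfect
  adaptation (`classify_response`).

The model, units, normalization and every analysis convention are
documented in [docs/methods.md](docs/methods.md).

## Worked example

The central experiment is the built-in **on–off protocol**: 2 h of TNF
followed by a 10 h washout, with 50 sparse measurements of the five
observables in wild type and A20 knock-out cells (9 series, hence
50 − 9 = 41 independent data points after per-series normalization).

```python
>>> import nfkbid as nk
>>> protocol = nk.make_on_off()
>>> protocol.n_measurements, protocol.n_series, protocol.dim
(50, 9, 41)
>>> report = nk.LinearAnalysis(nk.FITTED, protocol).run()
>>> print(report.summary())
Linear identifiability analysis
============================================================
measurements: 50   dim: 41
scaled singular values (desc): largest 0.9369, smallest 0.02469
structurally identifiable (all > 1e-3): True
least identifiable parameter (max R_j): epsilon
------------------------------------------------------------
parameter    |S_j|/√dim   |S_j⊥|/√dim       R_j    R_j·√dim
k_deg            0.4814         0.056     2.789       17.86
k1               0.2353       0.08213     1.902       12.18
...
epsilon         0.06345        0.0308      5.07       32.46
...
```

The smallest √dim-scaled singular value, ≈ 0.025, is well above the
10⁻³ structural-identifiability floor: with this single, simple protocol
every one of the 13 parameters is determinable in principle. The largest
error-amplification ratio R_j ≈ 5 belongs to the Michaelis constant ε,
so data with geometric error σ_data = 1.3 determine even the worst
parameter to within a geometric SD of about 1.3⁵ ≈ 3.8 — and the Monte
Carlo analysis (`nk.run_monte_carlo(nk.FITTED, protocol, k=50)`) confirms
a practical spread of max σ_carlo ≈ 3 at that noise level.

Qualitative dynamics under tonic TNF:

```python
>>> reg = nk.classify_response(nk.FITTED)   # TNF switched on at t = 1 h
>>> reg.label, round(reg.peaks.times_h[1], 2)
('damped_oscillations', 3.36)
>>> weak = nk.FITTED.with_updates(a2=0.02, c5a=1e-5, i1a=1e-4)
>>> reg = nk.classify_response(weak)
>>> reg.label, round(reg.peaks.times_h[1], 2)
('sustained_oscillations', 4.69)
```

Weakening IκBα degradation destabilises the stimulated steady state and
turns the damped response (second nuclear NF-κB peak near 3 h) into a
limit cycle (second peak near 5 h).

Command-line equivalent:

```sh
nfkbid identify-linear --params fitted --protocol on_off --out results/
nfkbid classify --set a2=0.02 --set c5a=1e-5 --set i1a=1e-4 --out results/
```

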