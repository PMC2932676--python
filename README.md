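# cardioreg

Constraining free parameters in cardiac myocyte models from their
measurable phenotype, by population regression and Bayesian
conditioning.

## The problem

Ionic models of the cardiac action potential contain many maximal
conductances and transport rates (G_Na, G_CaL, G_Kr, K_NCX, ...) that
are hard to measure directly. Very different parameter combinations can
produce nearly identical action potentials, so matching a single output
such as APD cannot identify them. But a myocyte's *panel* of routine
electrophysiological measurements — AP morphology, Ca²⁺ transient
amplitude and kinetics, stimulation threshold, restitution, alternans
onset, responses to pauses and to altered extracellular K⁺ — carries
far more information. `cardioreg` formalizes this: if enough linearly
independent outputs are measured, the map from parameters to outputs
can be inverted and the parameters read off.

## The method

1. **Population**: randomize the p scalable parameters of a cell model
   multiplicatively (lognormal factors, median 1, log-SD σ = ln 1.2),
   run the full protocol suite on each of n = 300 variants, and collect
   the log scale factors as **X** (n×p) and the outputs as **Y** (n×m).
2. **Forward regression**: after Z-scoring every column, fit **B**
   (p×m) such that **Ŷ** = **XB** ≈ **Y**.
3. **Reverse regression / inversion**: fit **B′** (m×p) with
   **YB′** ≈ **X**; or reduce the outputs to a square, linearly
   independent set of p by greedy backward elimination (repeatedly
   dropping the output whose removal least degrades the prediction of
   **X**, measured by mean per-parameter R²) and invert: **X** ≈
   **YB⁻¹**. Per-column R² of the recovered parameters quantifies how
   well each conductance is constrained.
4. **Bayesian conditioning**: estimate P(parameter ∈ range | outputs ∈
   windows) empirically — condition the ensemble on successive output
   windows centred on the best-reproduced trial and watch the parameter
   histograms narrow.

Three ventricular myocyte models are built in behind one interface:
ten Tusscher et al. 2004 human epicardial (`tnnp`, 16 parameters,
32 outputs), Luo–Rudy 1991 (`lr1`, 6 parameters) and a reduced
six-variable Bernus-type human model (`bernus`, 8 parameters). A
numba-compiled adaptive Rush–Larsen integrator runs a full 300-variant
population suite in about a minute per model on one core.

## Worked example

```bash
python examples/simulate_single_cell.py
```

prints (baseline epicardial cell, 1 Hz):

```
resting potential :    -85.3 mV
peak voltage      :     34.8 mV
max upstroke      :      357 mV/ms
APD90             :    307.2 ms
notch / dome      :   13.4 / 25.1 mV
Ca amplitude      :     1.06 uM
Ca decay constant :      132 ms
```

— the per-trial outputs that, across a randomized population, feed the
regression. `examples/population_regression.py` then builds a small
Luo–Rudy population and prints per-conductance reverse-regression R²
(G_Na 0.98, G_K1 1.00, ... at n = 80); `examples/invert_regression_matrix.py`
shows output elimination plus matrix inversion recovering known inputs;
`examples/bayesian_constraint.py` shows the surviving-subset sizes and
parameter-SD narrowing under sequential output windows; and
`examples/condition_reconstruction.py` recovers imposed "remodelling"
fold-changes from the phenotype alone.

A thin CLI mirrors the library (`cardioreg simulate-population`,
`fit-forward`, `fit-reverse`, `eliminate-outputs`, `invert`, `predict`,
`reconstruct-condition`, `bayes`, `fixture`, `run-all`); see
`cardioreg --help`.

## Layout

- `src/cardioreg/models/` — cell models and the shared integrator
- `src/cardioreg/protocols.py` — pacing, pause, quiescence, threshold
  bisection, alternans scan, S1S2 restitution
- `src/cardioreg/features.py` — output extraction from traces
- `src/cardioreg/population.py` — randomization, trial suites, X/Y
  assembly, synthetic linear fixture
- `src/cardioreg/regression.py` — standardization, forward/reverse
  fits, inversion, elimination, condition reconstruction
- `src/cardioreg/bayes.py` — sequential conditional analysis
- `docs/methods.md` — modelling and numerical details
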