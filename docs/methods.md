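# Methods

## Cell models

Three ventricular myocyte models sit behind a uniform interface
(ordered state vector, ordered scalable-parameter vector, published
initial conditions, default extracellular K⁺):

- **`tnnp`** — ten Tusscher–Noble–Noble–Panfilov 2004 human ventricular
  model, epicardial subtype (spike-and-dome morphology; the epicardial
  variant is the conventional single-cell reference). 17 states, 16
  scalable parameters: ten maximal conductances (G_Na, G_CaL, G_to,
  G_Kr, G_Ks, G_K1, G_pK, G_bNa, G_bCa in nS/pF), the sarcolemmal Ca²⁺
  pump (K_pCa), Na⁺/K⁺ pump (K_NaK) and Na⁺/Ca²⁺ exchanger (K_NCX)
  maximal currents, SERCA uptake rate (K_up), SR leak rate (K_leak) and
  the two SR release parameters (K_rel1 = a_rel, K_rel2 = c_rel). This
  is the complete set of maximal rates in the source model. State units
  follow the source verbatim ([Ca] in mM, V in mV, t in ms). Note the
  published Ca-dependent L-type inactivation gate fCa has a diastolic
  steady state of (1+0.1+0.2+0.23)/1.46 ≈ 1.048, so it rests slightly
  above 1; this is a property of the source formulation, kept as is.
- **`lr1`** — Luo–Rudy 1991 "phase 1" model: 8 states, 6 conductances
  (G_Na, G_si, G_K, G_K1, G_Kp, G_b). The K⁺ conductances scale with
  √([K⁺]ₒ/5.4) and the K⁺ reversal potentials follow Nernst, so the
  hypo-/hyperkalemia protocols act through the published mechanism.
- **`bernus`** — a reduced six-variable human ventricular model with
  the Bernus et al. 2002 current roster (I_Na with a single combined
  slow-inactivation gate, I_Ca with instantaneous activation, I_to,
  I_K, I_K1, I_NaK, I_NaCa, linear background; fixed intracellular
  concentrations, hence no Ca²⁺ transient) and 8 scalable parameters.
  The original publication's refitted rate expressions are not
  reproduced here; gating kinetics are adapted from the Luo–Rudy and
  ten Tusscher formulations and were tuned **once** to the published
  AP characteristics (rest ≈ −90 mV, APD90 ≈ 285 ms at 1 Hz,
  [K⁺]ₒ = 4 mM default) and then frozen. Its baseline values are this
  package's baselines.

## Integration

All models share one numba-compiled integrator. Hodgkin–Huxley gates
advance by the exact exponential (Rush–Larsen) update, which is
unconditionally stable and respects the gates' [0, 1] range whenever
their steady states do; voltage and concentrations advance by forward
Euler. The step size is proportional control on the projected per-step
changes: |ΔV| ≤ 0.15 mV and |Δ[Ca]ᵢ| ≤ 6·10⁻⁶ mM per step (0.8 safety
factor), bounded to [0.002, 2] ms ([0.002, 5] ms in quiescence). These
bounds were set so that the baseline APD moves by less than 0.1 ms when
both are halved (tested); the remaining APD bias against a 4× tighter
run is ≈ 0.15 ms, i.e. ≲ 0.05 % of APD and identical in structure
across trials, which is what matters for a regression over a
population. Traces are sampled on a fixed 0.5 ms grid by linear
interpolation; the true maximum of dV/dt within each sample interval is
tracked inside the stepper so upstroke velocity is not limited by the
output grid. Every protocol — paced train, pause, quiescence, S1S2 —
reduces to a list of stimulus onset times handed to the same kernel,
and stimulus onsets/offsets are exact step boundaries.

An integration producing a non-finite voltage marks the trial failed;
failed trials are logged, their output rows masked, and a population
aborts if more than 20 % of its trials fail (that indicates a broken
configuration, not bad luck).

## Protocols and outputs

Per-trial sequencing: the stimulation threshold (1 ms rectangular
pulse; capture = V crosses 0 mV within 50 ms; bisection to 0.1 pA/pF)
is measured first, and all subsequent pacing uses 1.5× that trial's
threshold, so capture is guaranteed across the randomized population.
Excitability shifts with [K⁺]ₒ, so the threshold is re-measured at each
potassium level before the hypo-/hyperkalemia runs. A 40-beat train at
BCL 1000 ms from the published quiescent state then provides the core
morphology outputs and the launch state for the rate- and
potassium-change protocols. Forty beats leave the baseline beat-to-beat
APD change far below 0.1 % (tested); longer pre-pacing changes the
slow Na⁺/K⁺ drift but not the regression structure.

The full (`tnnp`) suite produces 32 outputs: APD90 (from the
maximal-upstroke time to 90 % repolarisation toward the pre-stimulus
diastolic voltage), resting and peak voltage, maximal upstroke
velocity, Ca²⁺ transient amplitude, the three spike-and-dome shape
parameters (phase-1 notch voltage, dome voltage, dome time − upstroke
time; when no notch/dome exists the fallbacks V(+20 ms), V(+50 ms),
50 ms are used and flagged), alternans threshold BCL_alt (descending
scan 350→150 ms in 5 ms steps, 10 beats per cycle length with the
state carried over; alternans = all three final beat-to-beat APD
differences > 1 ms with alternating sign; sentinel 145 ms when absent
or when 1:1 capture is lost), stimulation threshold, maximum S1S2
restitution slope (centered differences over a 14-point diastolic
interval grid; S2 failures are dropped, < 3 valid points masks the
output), Ca²⁺ time-to-peak and single-exponential decay constant
(fit from 20 ms after the peak to the end of the beat), the post-pause
beat's APD/ΔCa/shape parameters (5 s pause after the steady train),
first-vs-last-beat APD and ΔCa differences of the pacing train,
APD and shape parameters under hypokalemia (3 mM) and hyperkalemia
(8 mM), intracellular Ca²⁺/Na⁺/K⁺ after 60 s of quiescence, and
frequency adaptation (steady APD at BCL 2000 ms ÷ steady APD at BCL
500 ms). Sub-sample (parabolic/linear-interpolation) refinement is
applied to the smooth time-of-extremum features; the phase-0 peak is a
cusp and is read directly from the grid.

The reduced suites for `lr1` (24 outputs) and `bernus` (22 outputs)
drop the Ca-handling outputs the models lack and instead add plateau
probes (APD50, V at +50/+100 ms) and resting/peak voltages at each
[K⁺]ₒ — informative, cheaply available outputs that separate the
pump/background currents these simpler models express only weakly.
The condition-reconstruction suite is the core per-beat output set
evaluated at [K⁺]ₒ = normal/3/8 mM (33 outputs for `tnnp`; outputs
that do not vary in a restricted population, e.g. a shape parameter
pinned at its fallback, are dropped before fitting).

## Population and randomization

Scale factors are i.i.d. lognormal with median 1; each trial draws
from substream `seed XOR trial-index`, so any single trial is
reproducible in isolation and X is bitwise-reproducible from
(seed, n, p, σ). The default spread is **σ = ln 1.2 ≈ 0.182** (log-SD;
one-sigma variation ×1.2/÷1.2). This is the spread convention of the
regression-based sensitivity approach this package extends, and it is
the calibration at which the linearity assumption demonstrably holds
for these models: at σ = 0.30 the parameter-to-output maps of all
three models are visibly nonlinear in log-factors (forward R² of
smooth outputs drops by 0.1–0.5) and the method's headline accuracy
statements stop holding, which is a property of the models, not of the
fitting code. σ is a single argument everywhere.

Default population size n = 300 (32, 24 or 22 outputs per trial).
Masked output entries are mean-imputed — equivalently set to 0 in
Z-space — keeping n fixed while contributing no signal.

## Regression

Both matrices are Z-scored column-wise (constant columns are an error
at the API level: they carry no information and make the Z-score
undefined). The default fit is full-rank, where partial least squares
coincides with ordinary least squares on standardized data, and the
coefficients are computed directly by least squares; a reduced
component count (scikit-learn PLS) is available for under-determined
cases. Per-column R² = 1 − SSE/SST.

Greedy backward elimination drops, at each step, the output whose
removal least reduces the mean per-parameter R² of the reverse
regression (a per-parameter-minimum criterion is available); ties
break toward the lowest column index. Inversion of the square retained
forward matrix requires reciprocal condition number ≥ 1e-10 — a
near-singular system raises rather than silently pseudo-inverting,
because near-singularity means the retained outputs are not linearly
independent.

When comparing the predictive value of output *sets of different
size* (all m outputs vs the retained p vs the rejected m−p), in-sample
R² is biased by the predictor count (more columns always fit better),
so those comparisons use 5-fold cross-validated mean per-parameter R².
Single-set R² values are reported in-sample, as is conventional.

Condition reconstruction builds a population randomizing only the k
condition parameters, fits the reverse regression from the condition
suite, simulates the "condition" cell with the imposed fold-changes,
and maps its outputs through the fitted model; predictions are
exponentiated de-standardized log factors. Fold-changes far outside
the training spread extrapolate and are systematically over- or
under-estimated — a documented limitation of any local linear model.

## Bayesian conditioning

Windows are centred on the *best trial* — the row whose outputs the
forward regression reproduces with the smallest Z-space squared
residual — in one of two modes: a percentile window covering a fixed
fraction of the samples (default 10 %), or ± a fixed relative
deviation (default 5 %) of the best-trial value. Constraints intersect
sequentially, so the surviving subsets are nested (and never empty:
the best trial satisfies every window centred on itself). Histograms
use 20 fixed bins per parameter spanning the marginal range, shared
across stages so narrowing is directly comparable, and each histogram
is normalized to its subset size. "The conditional probability reaches
unity" corresponds to all survivors falling in a single bin; this
depends on n and the window widths and is reported, not asserted.

The analytic check conditions a linear-Gaussian ensemble
(X ~ N(0, I), Y = XB + ε) on a window box and compares empirical
conditional variances with multivariate-normal theory: Var(X|Y∈R) =
Var(X|Y=y) + bᵀCov(Y_S|Y_S∈R)b, with the truncated-box moments
evaluated by dense quadrature. The test uses 20 %-windows so the
surviving subset is large enough that the empirical variance estimate
itself is not the limiting error.

## Synthetic fixture

`synthetic_linear_fixture` generates X standard normal and
Y = X·B_true + ε with B_true's singular values log-spaced up to a
requested condition number. It emulates exactly the structure the
regression stages assume — standardized inputs, linear map, additive
noise — and therefore provides exact oracles for them. It deliberately
does *not* emulate what real (or simulated-myocyte) data add:
nonlinearity in the parameter–output map, heteroscedastic and
discretized outputs (threshold grids, alternans sentinels), missing
values, or correlated failures. Passing the fixture tests shows the
machinery is correct; the model-population tests show the method still
works under those realistic distortions.

## Problem sizes and runtimes

The test suite and the acceptance script both use the full study
conditions: n = 300 populations for all three models, n = 20 000 for
the Gaussian-conditioning check, n = 150 (of 7 parameters) for
condition reconstruction. On one core the whole test suite runs in
about 5 minutes and the acceptance script in about 3 minutes; the
integrator's speed (a 300-variant TNNP population in ~75 s) is what
makes desk-scale reproduction of the full pipeline possible.

## Known limitations

- The method is local: it linearizes around the baseline model, and
  accuracy degrades for spreads much beyond σ ≈ 0.2 (by design of the
  underlying approach, not of this implementation).
- BCL_alt is intrinsically discrete (5 ms grid with a no-alternans
  sentinel) and t_minmax under hyperkalemia mixes detected domes with
  fallback values; both are poorly captured by a linear model and are
  reliably rejected by the elimination step — consistent with their
  low standalone informativeness.
- The Bernus-type model's kinetics are an adaptation, not a
  transcription; analyses that depend on that model's exact published
  rate functions should not rely on it.
- Fixed-concentration models (`bernus`) cannot express Ca²⁺-handling
  outputs at all; their parameter constraint rests entirely on
  voltage-derived outputs.
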