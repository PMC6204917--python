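# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Models

**Hill–Langmuir.** Y(C) = C^h/(IC50^h + C^h), Y the fraction of
current inhibited, C in μM. The package treats the steep slopes seen
for lipophilic channel blockers (h ≈ 2–4) purely as a descriptive
property of the pooled curve; no multi-site binding scheme is implied,
and the state-dependence analysis operates on apparent IC50s, not on a
cooperative mechanism.

**Boltzmann gating.** Both conductance activation and availability
(SSFI) curves are two-parameter Boltzmanns. A single printed form with
k > 0 cannot be monotone in the right direction for both curve types,
so a `polarity` flag selects the exponent sign — (V½ − V)/k for
activation, (V − V½)/k for availability — keeping fitted slope factors
positive and directly comparable between conventions. With equal
(V½, k) the two polarities are exact complements:
act(V) + avail(V) = 1.

**Exponential kinetics.** Recovery from inactivation is biexponential
with spans defined as fractions of Y0 − Plateau, so span conservation
holds identically for any percent-fast. Components are labelled by
rate after fitting (k_fast ≥ k_slow); a fit whose minor span falls
below 1% of the total is flagged "effectively monoexponential" rather
than reported as a genuine two-component result. Block onset uses the
single exponential Y = (Y0 − Plateau)e^(−Kt) + Plateau with
τ_obs = 1/K.

**Two-state block model.** Channels distribute between resting and
fast-inactivated states per the availability Boltzmann h∞(V); the
blocker has dissociation constants K_rest and K_inact for the two
states. The apparent dissociation constant obeys
1/K_app(V) = h∞(V)/K_rest + (1 − h∞(V))/K_inact, which is linear in
the inverse potencies, so the fit is a non-negative linear least
squares in 1/IC50 space — no iteration, no initialization, and the
positivity of both K values is structural. The model accepts any
availability curve as input; it does not hard-code a channel subtype,
because the appropriate h∞ depends on the preparation and equilibration
time of the experiment being analysed.

**Neuron model.** Single compartment, C_m dV/dt = I_inj − g_Na m³h
(V − E_Na) − g_K n⁴(V − E_K) − g_leak(V − E_leak). Gating steady
states are Boltzmann functions so that voltage-clamp-fitted midpoints
and slopes are usable without conversion; the defaults use the fitted
Na activation (−41.9 mV, 3.6 mV) and availability (−69.7 mV, 5.0 mV)
curves and a delayed-rectifier K gate at (−35 mV, 9 mV). Time
constants use a Gaussian bell τ(V) = base + amp·exp(−((V −
V_peak)/width)²), a standard reduced form when rate constants are not
measured separately; the defaults (τ_m ≲ 0.12 ms, τ_h ≤ 6.5 ms,
τ_n ≤ 3.5 ms) were chosen once to give regular, non-adapting
cortical-like firing across the default 2–10 μA/cm² step family and
were then left alone. Conductance densities (g_Na = 56, g_K = 6,
g_leak = 0.0205 mS/cm²) follow single-compartment cortical pyramidal
models. No adaptation (M-type) conductance is included: the modelled
cell fires tonically through each 100-ms step. A drug condition is the
triple (Na-block fraction, K-block fraction, inactivation-midpoint
shift); the default drug comparison is 50%/50%/−8.1 mV.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| Hill slope bound | – | fitted free, or fixed by caller | fixed-slope refits mirror temperature-series practice |
| QC gates | MΩ, MΩ, pA | 500, 10, 500 | standard plate filters for seal quality and signal size |
| persistent-current window | fraction of step | last 10% (10 ms of a 100-ms step) | the window is not standardized; stated explicitly for reproducibility |
| baseline aggregation | sweeps | mean of last 5 pre-addition | timing of baselining is protocol-defined; aggregation is ours |
| vehicle correction | – | multiplicative, linear interpolation between vehicle time points | the correction's existence is protocol-defined, its form is ours |
| integrator step dt | ms | 0.01 (cap 0.025) | resolves τ_m by an order of magnitude; halving dt moves spike times <0.1 ms |
| spike criteria | mV, mV/ms | threshold 0, dV/dt 20, refractory 1 ms | conventional current-clamp readouts |

## Synthetic data: what it emulates, what it does not

Emulated: single-exposure plate design (one concentration per cell)
with vehicle wells; monoexponential rundown (default 2%/min);
monoexponential approach of block to its Hill-predicted equilibrium
within the drug epoch (default τ = 40 s); a full-block epoch leaving a
2% residual; lognormal cell-size scatter (σ_log = 0.2) on raw
amplitudes; additive Gaussian noise (σ = 0.03) on normalized peaks; a
QC-failure fraction (10%) split between leaky seals, high series
resistance, and small currents. The noise defaults were chosen to
reproduce standard errors of roughly 10% of the mean at 3–15 cells per
condition, the range typical of plate experiments of this kind.

Not emulated: within-sweep kinetics of drug binding (no Markov-state
trace simulation), capacitive/leak artifacts, series-resistance and
liquid-junction-potential errors, voltage-escape at large currents,
cell-to-cell gating-parameter heterogeneity. Passing round-trip tests
therefore demonstrates that the pipeline and fitters are unbiased and
correctly plumbed under the assumed noise structure — not that they
are robust to every artifact of real recordings.

Percent-fast fractions for the recovery defaults (70% vehicle, 50%
drug at the 10-s prepulse) are assumptions: the reference measurements
constrain them only graphically, and they are labelled as such in
`defaults.py`.

## Numerical choices

* All nonlinear fits run Levenberg–Marquardt (lmfit) from
  deterministic, data-derived starts: IC50 from log-interpolated 50%
  crossing, Boltzmann midpoint from the half-crossing and k from the
  10–90% width (k·ln 81), exponential rates from log-linear tail
  regression. Identical inputs give bit-identical results.
* Strictly positive parameters (IC50, h, k, rates) are optimized in
  log space, so the optimizer is unconstrained and cannot stick at a
  boundary.
* Loss is unweighted least squares on the pooled per-concentration
  means by default (per-cell points are retained and can be fitted
  instead); pooled fits carry no analytic standard errors, and a
  seeded case-resampling bootstrap is provided instead.
* Degenerate inputs (flat curves, no concentration dependence,
  constant signals, identical availabilities) return
  `converged=False` with a named diagnostic or raise, never silent
  parameter garbage.
* The pipeline pools unclipped per-cell inhibition values so that
  drug-free wells average to zero (clipping a zero-mean quantity at
  zero would bias it upward); values entering the Hill fit are clipped
  to [0, 1] since the estimand is a fraction.
* Biexponential identifiability requires separated time constants;
  the generator-facing tests draw τ ratios ≥ 8.
* Fixed-step classic RK4 for the neuron; an adaptive-solver
  cross-check (0.5 mV RMS agreement over the full default scenario) is
  part of the test suite.

## Design decisions that were genuinely open

* Whether pooled Hill fits should use per-concentration means or all
  per-cell points: both are supported; means are the default.
* The drug condition's voltage-threshold readout ("threshold of the
  first action potential") is ambiguous between voltage threshold and
  rheobase; the simulator reports per-spike dV/dt-criterion thresholds
  and per-step counts and asserts neither direction.
* The K-current block fraction in the drug condition defaults to the
  same 50% as Na but is independently configurable.
* Equilibrium block from pulse trains is taken from the plateau of a
  monoexponential fit to the per-pulse relaxation rather than the raw
  final pulse, making the apparent-IC50 estimates insensitive to
  truncated equilibration.

## Known limitations

* The two-state model assumes equilibrium occupancy at each holding
  potential; slow inactivated states reached during minutes-long holds
  are outside the model, so fitted K_rest/K_inact ratios from real
  trains are approximate.
* The neuron model is a point cell with three currents: it predicts
  direction and ordering of excitability changes, not absolute firing
  rates of any particular cortical cell.
* Temperature enters only through lookup tables of measured τ_obs and
  IC50; no Arrhenius/Eyring rate theory is attempted.
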