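# Methods

## The model

`somnet` implements a deliberately minimal network model of the mammalian
sleep–wake cycle: three neural populations — Wake-promoting (W),
NREM-promoting (N) and REM-promoting (R) — coupled by six directed synaptic
pathways and driven by a single slow homeostatic sleep drive. Each
population is a firing-rate unit: its activity `F_X(t)` (Hz) relaxes toward
a sigmoidal steady state of its summed synaptic input,

    dF_X/dt = (F_X∞(I_X) − F_X) / τ_X
    F_W∞ = W_max · ½(1 + tanh[(I_W − β_W)/α_W])
    F_R∞ = R_max · ½(1 + tanh[(I_R − β_R)/α_R])
    F_N∞ = N_max · ½(1 + tanh[(I_N − k_N·H)/α_N])

Populations communicate through released transmitter concentrations, one per
source population, normalised to [0, 1]:

    dC_Y/dt = (tanh(F_Y/γ_Y) − C_Y) / τ_C_Y

and the inputs are weighted sums of those concentrations plus a weak
additive Gaussian noise ξ (mean 0.01 Hz, s.d. 0.005 Hz, one independent draw
per population per step):

    I_W = g_NWi·C_N + g_RWe·C_R + ξ
    I_N = g_WNi·C_W + ξ
    I_R = g_WRi·C_W + g_NRi·C_N + g_RRe·C_R + ξ

The homeostatic drive H builds toward `H_max` whenever the Wake rate is at
the detection threshold `θ_W` or above, and decays otherwise:

    dH/dt = (H_max − H)/τ_hw · step(F_W − θ_W) − H/τ_hs · step(θ_W − F_W)

with the right-continuous step convention (`step(0) = 1`; both terms are
therefore active at `F_W = θ_W` exactly, a measure-zero coincidence in
practice). H has no fixed threshold of its own: it enters the NREM
activation threshold as `k_N·H`. **`k_N` is negative in this
parameterisation**, so rising sleep pressure lowers the NREM population's
effective threshold and promotes sleep onset; this sign is the only way the
printed form `(I_N − k_N·H)` produces homeostatic sleep with the package's
sign conventions, and it is validated (a positive `k_N` is accepted by the
container but breaks the cycling battery below).

Architectural assumptions: W and N are mutually inhibitory (the flip-flop
switch for wake/NREM transitions); R has a recurrent excitatory connection
(RRe) and excites W (RWe); R receives inhibition from both W (WRi) and N
(NRi). There is no circadian drive, no REM-sleep homeostasis and no
plasticity — those are outside the model's scope.

### State classification

A stored sample is scored **Wake** if `F_W > 2 Hz`; otherwise **REM** if
`F_R > 2 Hz`; otherwise **NREM**. Both comparisons are strict, so a rate of
exactly 2 Hz falls through (2, 2) → NREM. No smoothing or minimum episode
duration is applied by default (`Hypnogram.filtered` exists but is off).

## Parameters

Synaptic weights (control condition) are fixed by the perturbation table,
whose eighth/quarter/half/double/quadruple/octuple columns are exact
multiples of a single control column:

| pathway | g (control) | sign |
|---|---|---|
| RRe | 1.6 | excitatory |
| RWe | 1.0 | excitatory |
| WNi | −2.0 | inhibitory |
| WRi | −4.0 | inhibitory |
| NRi | −1.3 | inhibitory |
| NWi | −1.68 | inhibitory |

The remaining constants are the package's own calibrated reference
configuration (`somnet/defaults.yaml`). They were chosen once so that the
noise-free day reproduces the qualitative behaviour expected of the model —
wake onset at t = 0, homeostatic build-up terminating wakefulness, NREM/REM
alternation within sleep, spontaneous awakening, stable periodicity — and
then frozen; `scripts/calibrate_defaults.py` re-runs that battery verbatim.

| parameter | value | units | role |
|---|---|---|---|
| W_max, N_max, R_max | 5 | Hz | population rate ceilings |
| α_W, α_N, α_R | 0.3, 0.2, 0.3 | a.u. | activation slopes |
| β_W, β_R | −0.8, −1.3 | a.u. | activation thresholds (negative: self-sustaining wake; REM excitable during sleep) |
| k_N | −2.5 | a.u./H | homeostatic gating of NREM threshold |
| τ_W, τ_N, τ_R | 25, 10, 15 | s | membrane time constants |
| H_max | 1 | a.u. | homeostat ceiling |
| θ_W | 2 | Hz | homeostat wake-detection threshold (equals the scoring threshold, so H and the hypnogram agree) |
| τ_hw, τ_hs | 6000, 3000 | s | sleep-pressure build-up / decay |
| τ_C_W/N/R | 2 | s | transmitter decay |
| γ_C_W/N/R | 2 | Hz | transmitter release half-saturation |
| noise mean, sd | 0.01, 0.005 | Hz | additive input noise |
| dt, duration | 0.001, 86400 | s | integration grid |

`τ_C` and `γ_C` are deliberately separate parameters that default to equal
numbers: the single-symbol form `C∞ = tanh(F/τ)` is recovered literally,
while decay time and release scale remain independently configurable.

With these values the noise-free day gives ≈76% wake / 19% NREM / 5% REM,
NREM bouts of ≈1.3 min, REM bouts of ≈0.3 min, a sleep-onset (NREM) latency
of ≈124 min and a sleep–wake cycle period of 83.5 min after the first cycle
— a rodent-like, strongly polyphasic architecture. (These numbers are
recomputed, not asserted, by `scripts/acceptance.py`.)

## Integration

Classical fixed-step RK4 at dt = 1 ms. Noise is frozen within a step: one
draw per population is made before the step and used identically in all four
stages, which preserves classical RK4 semantics (the model treats ξ as a
piecewise-constant input, not an Itô/Stratonovich SDE — the discretisation
convention is part of the model definition here). Draw order is W, N, R per
step from a seeded `numpy.random.Generator` (PCG64), consumed row-major, so
a (parameters, seed) pair fully determines a trajectory and the sequence is
independent of internal chunking. `seed=None` selects ξ ≡ 0.

The state box `[0, X_max]³ × [0, 1]³ × [0, H_max]` is forward invariant for
the continuous flow (every component of the vector field points inward on
the boundary; the test suite asserts this by property sampling). The
discrete stepper clips truncation-level overshoot back onto the box and
treats any excursion larger than `BOX_TOL = 1e-9` as an integration failure,
reported with the offending step index and component. The production path
is a numba-compiled kernel; a pure-Python RK4 (`rk4_step`) defines the
reference semantics and the tests assert step-for-step agreement between the
two at 1e-12 relative tolerance, plus empirical convergence order ≥ 3.5 on a
closed-form relaxation problem.

Storage: integrating 24 h at 1 ms produces 86.4 M samples; storing all seven
state variables at every step would need ≈4.8 GB. `run_simulation` therefore
accepts a `store_stride`; integration always happens on the dt grid and only
storage is decimated. The pipeline and CLI default to stride 100 (one stored
sample per 0.1 s), which is recorded in the hypnogram metadata; sleep
episodes in this model last tens of seconds to minutes, so scoring on the
0.1 s grid is unaffected in practice. One consequence is quantified rather
than ignored: when checking that H only rises while wake-scored and only
falls while sleep-scored, a threshold crossing inside a stored interval can
contribute drift in the "wrong" direction of at most
`stride·dt·H_max/min(τ_hw, τ_hs)` ≈ 3.3e-5, which is the tolerance the
acceptance check uses.

## Perturbation experiments

Each pathway is scaled by {0, ⅛, ¼, ½, 1, 2, 4, 8} of its control weight
(0 = lesion), 48 single-pathway conditions in all; joint sweeps scale the
two output pathways of one population over the same (configurable) grid.
Every condition runs n replicate simulations (default 8) with seeds
`base_seed + replicate`, identical across conditions: conditions differ
only in weights, never in noise, which maximises contrast sensitivity.
Failed replicates are recorded with their error and do not abort a sweep.
Results are written long-format (condition, pathway, scale, replicate,
metric, value).

Reduced-scale trend checks (used by the tests and the acceptance script)
run 6 simulated hours with 4 replicates: long enough for two to four full
sleep–wake cycles under the reference configuration, which is what the
directional comparisons need.

## Statistics

Per metric, a classical one-way ANOVA across scale conditions
(`F = MS_between/MS_within`, df `k−1, N−k`; F and p via
`scipy.stats.f_oneway`) followed by Tukey HSD comparisons of every condition
against the control, using the Tukey–Kramer standard error so unbalanced
groups are handled, with p-values from `scipy.stats.studentized_range` and
significance flagged at p < 0.05. Degenerate inputs (zero variance) are
rejected rather than returning 0/0. The suite calibrates the layer against
independent routes: from-scratch sums of squares, the F = t² identity,
`scipy.stats.tukey_hsd`, `statsmodels` `pairwise_tukeyhsd`, and an empirical
type-I error of 0.05 ± 0.02 under the null over 2,000 resampled datasets.
No linear-trend contrast or family-wise correction beyond Tukey is applied.

## Synthetic fixtures

`somnet.fixtures` makes the scoring and statistics layers testable without
the ODE core. Synthetic hypnograms come either from explicit episode lists
(realised exactly) or from a seeded first-order Markov chain over episodes
with geometric dwell times at the sample resolution — the simplest process
consistent with a per-sample chain, used purely as a test device; real sleep
bout-length distributions are heavier-tailed and history-dependent, so
passing these tests validates the bookkeeping (run-length encoding,
transition counting, latency rules), not any biological claim. Piecewise-
constant rate trajectories exercise the classifier, including exact-
threshold samples. `brute_force_metrics_oracle` recomputes every metric by a
naive per-sample scan sharing no code with the production implementation;
the two must agree exactly on 1,000 random hypnograms.

## Numerical choices and edge cases

- Latencies: NREM latency is the onset of the first NREM episode from t = 0
  (0 if the run starts in NREM); REM latency is the first REM onset at or
  after the first NREM onset minus that onset. REM occurring before any
  NREM is ignored for the latency but still counted in the metrics. A
  latency whose defining state never occurs is NaN, a value, not an error.
- Classification thresholds are strict (`>`), and the homeostat step is
  right-continuous (`≥`); both conventions are fixed and tested.
- Weight-scale resolution is exact in floating point: scales are powers of
  two, so `control × scale` reproduces every table entry bit-exactly.
- Trajectory TSV round-trips bit-exactly (`%.17g`); result bundles are
  byte-deterministic except for the manifest timestamp.

## Known limitations

- The parameter set is a calibrated reference configuration, not a fit to
  recordings; absolute percentages and latencies should be read as
  model-scale quantities.
- REM bouts terminate through transient Wake-population activation, so very
  strong WRi scaling can suppress awakening entirely after sleep onset —
  a real (and reported) behaviour of this model class, but one that makes
  per-state statistics degenerate in extreme conditions.
- Strong RRe scaling produces a locked wake-with-high-REM-activity state;
  under the activity-based scoring rule this counts as Wake, which is
  exactly why the scoring layer deliberately stays separate from any notion
  of "true" underlying state.
- The frozen-noise RK4 convention is not an SDE integrator; results at
  noise amplitudes much larger than the default would depend on it.
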