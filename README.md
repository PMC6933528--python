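# somnet

A three-population firing-rate model of the sleep–wake cycle, with the full
perturbation pipeline around it: reproducible stochastic simulation,
hypnogram scoring, sleep-architecture metrics, systematic synaptic-weight
sweeps and lesions, and post-hoc statistics.

The package is for computational neuroscientists and sleep researchers who
want to ask *pathway-level* questions in silico: which synaptic connection
in a wake/NREM/REM circuit controls which feature of sleep architecture —
time in state, episode counts, fragmentation, sleep latencies — and how
those features respond when a single pathway is weakened, strengthened or
lesioned.

## The model

Three neural populations — Wake-, NREM- and REM-promoting — are firing-rate
units coupled by six directed pathways (RRe, RWe excitatory; WNi, WRi, NRi,
NWi inhibitory; named source → target) and driven by a homeostatic sleep
drive H:

    dF_X/dt = (F_X∞(I_X) − F_X) / τ_X,   F_X∞(I) = X_max · ½(1 + tanh[(I − β_X)/α_X])
    dC_Y/dt = (tanh(F_Y/γ_Y) − C_Y) / τ_C_Y
    dH/dt   = (H_max − H)/τ_hw · ℋ(F_W − θ_W) − H/τ_hs · ℋ(θ_W − F_W)

The NREM unit has no fixed threshold: its activation threshold is `k_N·H`
(k_N < 0), so accumulating sleep pressure gates NREM onset. Inputs `I_X` are
weighted sums of the transmitter concentrations plus weak Gaussian noise.
The system is integrated with fixed-step RK4 at dt = 1 ms (a compiled
kernel; 24 h in ~40 s), and each sample is scored **Wake** if `F_W > 2 Hz`,
else **REM** if `F_R > 2 Hz`, else **NREM**.

Perturbation experiments scale any pathway weight by
{0, ⅛, ¼, ½, 1, 2, 4, 8} of its control value (0 = lesion) and run seeded
replicate simulations per condition; a one-way ANOVA across conditions with
Tukey HSD comparisons against control sits on top. See `docs/methods.md`
for the full model description, parameter table and design rationale.

## Worked example

```python
from somnet import ModelParameters, run_simulation, build_hypnogram, compute_metrics

params = ModelParameters()                               # packaged reference configuration
ts = run_simulation(params, seed=None, store_stride=100) # noise-free 24 h day
m = compute_metrics(build_hypnogram(ts))

for state in ("WAKE", "NREM", "REM"):
    print(f"{state:<4}  {m.percent[state]:5.1f}%  "
          f"{m.episode_count[state]:3d} episodes  "
          f"{m.duration_s[state] / 3600:5.2f} h")
print(f"NREM latency: {m.nrem_latency_s / 60:.1f} min")
print(f"REM latency:  {m.rem_latency_s / 60:.1f} min")
print(f"transitions NREM->REM: {m.transition_count[('NREM', 'REM')]}")
```

prints

```
WAKE   76.2%   17 episodes  18.28 h
NREM   19.3%  224 episodes   4.62 h
REM     4.6%  208 episodes   1.10 h
NREM latency: 124.2 min
REM latency:  1.2 min
transitions NREM->REM: 208
```

i.e. the network wakes up at t = 0, stays awake for ~2 h while sleep
pressure builds (the NREM latency), then settles into a polyphasic
sleep–wake rhythm: within each sleep bout, NREM and REM alternate on a
minutes timescale (224 NREM and 208 REM episodes), and every REM episode is
entered from NREM. Percentages sum to 100 and transitions = episodes − 1 by
construction.

The same run from the shell, plus a weight sweep and its statistics:

```
somnet simulate --noise-free --out runs/control
somnet sweep --pathway WNi --replicates 8 --seed 0 --out runs/wni
somnet stats --results runs/wni/sweep_results.csv --out runs/wni_stats
somnet joint-sweep --population R --replicates 8 --seed 0 --out runs/joint_r
```

Every run directory contains a `manifest.json` with the resolved-parameter
digest, seeds and RNG algorithm; trajectories are TSV, hypnograms run-length
CSV, metrics and stats plain CSV.

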