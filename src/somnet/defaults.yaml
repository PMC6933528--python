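# somnet reference configuration (calibrated defaults; see docs/methods.md).
# Flat key: value pairs, one per model parameter.  Units: rates/thresholds in
# Hz, time constants in seconds, weights/concentrations/drive dimensionless.

# population activation
W_max: 5.0
N_max: 5.0
R_max: 5.0
alpha_W: 0.3
alpha_N: 0.2
alpha_R: 0.3
beta_W: -0.8
beta_R: -1.3
# homeostatic coupling of the NREM threshold: negative so rising sleep
# pressure promotes NREM onset
k_N: -2.5

# membrane time constants (s)
tau_W: 25.0
tau_N: 10.0
tau_R: 15.0

# homeostatic sleep drive
H_max: 1.0
theta_W: 2.0
tau_hw: 6000.0
tau_hs: 3000.0

# transmitter kinetics: decay time constants (s) and release scales (Hz)
tau_C_W: 2.0
tau_C_N: 2.0
tau_C_R: 2.0
gamma_C_W: 2.0
gamma_C_N: 2.0
gamma_C_R: 2.0

# control synaptic weights (back-derived from the perturbation table)
g_RRe: 1.6
g_RWe: 1.0
g_WNi: -2.0
g_WRi: -4.0
g_NRi: -1.3
g_NWi: -1.68

# additive Gaussian input noise (Hz)
noise_mean: 0.01
noise_sd: 0.005

# integration grid (s)
dt: 0.001
duration: 86400.0
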