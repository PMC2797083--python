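# Model and experiment presets: the single source of truth for every
# numeric condition the packaged experiments use.
#
# Model constants are the canonical published values for each oscillator
# family: the FitzHugh (1961) Bonhoeffer-van der Pol constants for the
# FitzHugh-Nagumo unit and the Hindmarsh & Rose (1984) constants for the
# three-dimensional bursting unit. Network sizes, coupling strengths,
# noise intensities and horizons are this package's own working defaults,
# chosen so each experiment runs in minutes on one CPU while exhibiting
# the regime it studies (strong coupling, significant noise); every one
# of them can be overridden per run.

models:
  fitzhugh_nagumo:
    state_dim: 2
    params: {a: 0.7, b: 0.8, c: 3.0, I: -0.4}
    noise_mask: [true, false]
    coupling_mask: [true, false]
    input_mask: [true, false]
    sigma: 0.5
  hindmarsh_rose:
    state_dim: 3
    params: {a: 1.0, b: 3.0, c: 1.0, d: 5.0, r: 0.006, s: 4.0, x_rest: -1.6, I: 3.0}
    noise_mask: [true, false, false]
    coupling_mask: [true, false, false]
    input_mask: [true, false, false]
    sigma: 0.5

experiments:
  fig1_protection:
    n: 50
    k: 1.0
    sigma: 0.5
    dt: 0.005
    t_end: 600.0
    transient: 100.0     # ~9 periods of the noise-free cycle (period ~11.2)
    n_harmonics: 3
  fig2_spatial_mean:
    n: 50
    k: 1.0
    sigma: 0.5
    dt: 0.005
    t_end: 600.0
    transient: 100.0
    n_harmonics: 3
  fig3a_bound_sweep:
    n_grid: [4, 8]
    k_grid: [8.0, 16.0, 32.0]
    sigma: 0.3
    dt: 0.002
    t_end: 200.0
    transient: 50.0
  fig3b_observer_sweep:
    n: 8
    k_grid: [4.0, 8.0, 16.0, 32.0]
    sigma: 0.3
    dt: 0.002
    t_end: 200.0
    transient: 50.0
    observer_gain: 30.0
  fig4_probabilistic:
    n: 60
    p: 0.3
    k: 1.0
    sigma: 0.5
    dt: 0.005
    t_end: 600.0
    transient: 100.0
    n_harmonics: 3
  fig5_hindmarsh_rose:
    n: 20
    k: 0.5
    sigma: 0.5
    dt: 0.01
    t_end: 1200.0
    baseline_current: 1.4
    input: {kind: step, params: {t0: 400.0, t1: 800.0, level: 1.8, baseline: 0.0}}
    segments: [[100.0, 400.0], [450.0, 800.0], [850.0, 1200.0]]
    spike_threshold: 0.8
  linear_sqrtN:
    decay: 1.0           # OU relaxation rate a in dx = -a x dt + sigma dW
    sigma: 1.0
    n_grid: [1, 4, 16, 64]
    n_reference: 10
    dt: 0.01
    t_end: 2000.0
    transient: 20.0
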