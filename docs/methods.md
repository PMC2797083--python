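# Methods

## The model

`syncnoise` studies diffusive networks of N identical noisy nonlinear
units

    dx_i = [ f(x_i, t) + Σ_j W_ij (x_j − x_i) + u(t) e_in ] dt + σ dW_i ,

with `f` the single-unit drift, `W_ij ≥ 0` the weight of the connection
from unit j into unit i (zero diagonal), `u(t)` a scalar input common to
all units, and independent standard Wiener processes `W_i` scaled by a
constant intrinsic noise intensity σ on the noise-masked components.
Coupling, noise and input act on the voltage-like first component by
default (gap-junction-style coupling); all three channels are
configurable per model through boolean masks.

Built-in units:

* **FitzHugh–Nagumo** (Bonhoeffer–van der Pol form, FitzHugh 1961):
  `dv/dt = c(v + w − v³/3 + I) + u`, `dw/dt = −(v − a + bw)/c`, with the
  canonical constants a=0.7, b=0.8, c=3, I=−0.4 (stable limit cycle of
  period ≈ 11.2 time units, |v| ≲ 2).
* **Hindmarsh–Rose** (1984): the standard three-dimensional burster with
  constants a=1, b=3, c=1, d=5, r=0.006, s=4, x_rest=−1.6; the baseline
  current I sets the firing regime.
* **Time-varying linear systems** `dx/dt = A(t)x + b(t)`, used for the
  Ornstein–Uhlenbeck baselines.

All constants live in `presets.yaml`; nothing numeric is hard-coded in
the experiment drivers.

## Integration

Plain Euler–Maruyama: deterministic step `dt`, noise increment
`σ √dt 𝒩(0,1)` per masked component, independent across units and steps.
No adaptive stepping (pathwise step control is ill-defined for SDEs) and
no higher-order schemes: the weak error of the plain scheme is linear in
`dt`, which the suite verifies on the OU closed form (the
stationary-variance error falls by ≈ 2 when `dt` halves; the exact Euler
stationary variance is σ²/(2a − a²dt), relative bias ≈ a·dt/2). Default
`dt` values per experiment keep the fastest rate (per-pair coupling
rate N·k) well inside the stability region N·k·dt < 2. A divergence
guard aborts when any |state| exceeds 10⁶ (cubic drifts explode under
too-large steps) and reports the step and unit.

Reproducibility: the tuple (seed, config, model, graph, input) fully
determines a trajectory bitwise. Noise comes from numpy's seeded
generators; per-unit substreams are spawned seed sequences
(statistically independent, cross-correlation < 0.01 at 10⁵ samples).
The quorum-star equivalence check drives two network formulations with
the *same* generator to compare them pathwise.

## Theoretical quantities

All bound algebra is documented in `syncnoise/bounds.py`; in brief, for
all-to-all FitzHugh–Nagumo networks with per-link strength k the
difference of any pair obeys a linear time-varying SDE whose voltage
damping is at least ρ = N·k − c (the cubic contributes a nonnegative
curvature term (v_i² + v_iv_j + v_j²)/3), while the recovery difference
is an exponentially stable filter of gain 1/b driven by the voltage
difference. Stochastic contraction per (mutually uncoupled) pair gives

    E‖x_i − x_j‖² ≤ σ²(1 + 1/b²)/ρ ,

hence, summed over the N(N−1) ordered pairs,

    C(N, k, σ) = N(N−1) σ²(1 + 1/b²) / (N·k − c) ,

proportional to σ², strictly decreasing in k, ~ 1/k for large k and → 0
as k → ∞ (noise-free networks synchronize completely). The bound applies
after exponential transients at rate min(2(N·k − c), 2b/c). The
**convention** throughout package and tests: the synchronization error is
the ordered-pair sum, identically equal to 2N·Σ_i‖x_i − x̄‖².

The **mean-impact bound** `Q·C/(4N²) + σ/√N` combines the Taylor
(integral-remainder) bound on the drift mismatch sustained by residual
desynchronization — `Q` being the uniform spectral-norm bound on the
drift's per-component Hessians over the operating ball, 2cR for
FitzHugh–Nagumo at radius R, exactly 0 for linear systems — with the
intensity of the averaged noise. With Q = 0 it reduces to the classical
1/√N averaging law, recovered by simulation to slope −0.5 ± 0.05.

The bound validity precondition is strong coupling; the package warns
(does not error) when k is below 10× the largest model parameter.
Empirically the bound dominates the ergodic estimate with roughly a 2×
margin over the packaged (n, k) grid, including points below the warning
threshold.

## The observer

A copy of the deterministic unit dynamics with voltage output injection
`gain·(v_meas − v̂)` (gain default 10c; contraction in the metric
diag(1, c) needs gain > c), zero-order hold of the measured signal over
each step. On noise-free input the squared error decays log-linearly at
a rate set by the slow recovery mode (≥ 2b/c ≈ 0.53), independent of the
observer's initial condition. On noisy input the post-transient
time-average of the squared distance measures how far the measured unit
is from noise-free behavior; it drops by orders of magnitude when the
unit is strongly coupled.

## Spectral diagnostics

One-sided FFT power spectra after mean removal, Parseval-consistent
(rectangular window by default; an optional variance-normalised Hann
taper trades that for reduced leakage). Dominant peaks are refined by
quadratic interpolation of log-power. Harmonic clarity is measured
*locally*: for each expected harmonic h·f₀ the peak within ±15% is
compared against the median power of that band; a harmonic is "clear"
when it rises ≥ 10 dB above this background, and the clarity score is
the mean prominence over fundamental plus harmonics. A global noise
floor was rejected during design: with long windows most bins are
background, so even a phase-diffused oscillator clears a global-median
threshold, whereas local prominence separates the regimes robustly.
Both the band width and the threshold are arguments.

Trajectory-to-reference comparisons between noisy and noise-free
oscillators are made at the spectrum level by default: slow phase
diffusion dominates raw state-space distances even for well-protected
units, so raw time-averaged squared distances are reported where grids
match but not used as the protection criterion.

## Study conditions of the packaged experiments

Chosen once, recorded in `presets.yaml`, and scaled to minutes on one
CPU (manifests carry `scale: scaled_down`):

* Protection contrast (fig1/fig2 presets): N=50, k=1 (per link; network
  rate N·k=50), σ=0.5, dt=5·10⁻³, horizon 600 with 100 discarded (≈ 9
  noise-free periods). At these conditions the uncoupled unit's
  harmonics sink below the 10 dB criterion while the synchronized unit
  keeps the noise-free fundamental within ~1%.
* Bound sweep (fig3a): n ∈ {4, 8}, k ∈ {8, 16, 32}, σ=0.3, horizon 200
  with 50 discarded.
* Observer sweep (fig3b): n=8, k ∈ {4,…,32}, gain 30, plus an uncoupled
  baseline.
* Probabilistic network (fig4): N=60, p=0.3, k=1; symmetric by
  construction, connectivity not enforced (a disconnected draw is
  logged, since disconnected components cannot synchronize globally).
* Hindmarsh–Rose input tracking (fig5): N=20, k=0.5, σ=0.5, baseline
  I=1.4 with a +1.8 step on t ∈ [400, 800); readout is the spike count
  (upward crossings of 0.8) of the spatial mean per input segment. The
  synchronized mean multiplies its rate during the step; the uncoupled
  mean's amplitude collapses and shows no spikes at all.
* Linear baseline (linear_sqrtN): OU rate a=1, σ=1, N ∈ {1,4,16,64},
  horizon 2000; the N=10 variance check averages 20 disjoint replicate
  groups to keep the estimator's sampling error well under the 5%
  tolerance.

Initial conditions default to uniform draws from a half-width-0.5 box
around a reference state (seeded and recorded in provenance); the law is
an implementation choice, and transients are always discarded before
statistics.

## What the synthetic data does and does not show

Everything here is self-generated: the "data" are SDE sample paths of
the stated models. Passing tests therefore demonstrate the mathematical
mechanism — balanced diffusive coupling cancels in the population sum,
contraction bounds hold, protection appears in the simulated regimes —
under idealised conditions: identical units, constant σ, additive
voltage noise, white noise, instantaneous symmetric coupling. They say
nothing about heterogeneous populations, conduction delays, correlated
or state-dependent noise, or conductance-based membrane dynamics, all of
which are out of scope.

## Known limitations

* The curvature inequality is guaranteed per drift component; for
  multi-component nonlinearities the Euclidean-norm mismatch can exceed
  the single-component bound by up to √dim. For FitzHugh–Nagumo (one
  nonlinear component) the packaged inequality is exact and is checked
  sample-wise.
* The pair bound requires 2k > c (network form N·k > c); below that the
  contraction argument fails and the functions raise rather than
  extrapolate.
* Hindmarsh–Rose networks are simulated and analysed spectrally only; no
  synchronization bound is claimed for them.
* `eigenmode_transform` uses the frozen-curvature evolution matrix;
  outside the strong-coupling regime the modes become complex and the
  transform reports degeneracy instead of returning real modal rates.
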