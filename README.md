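# syncnoise

**How synchronization protects coupled oscillators from intrinsic noise.**

Individually, a noisy nonlinear oscillator — a FitzHugh–Nagumo neuron,
say — loses its temporal and spectral identity once the noise is large:
the trajectory jitters, the phase diffuses, the harmonic structure of its
spectrum washes out. Averaging many *independent* noisy units does not
help: because the dynamics are nonlinear, the population mean is smooth
but nearly information-free. Mutual diffusive (gap-junction-like)
coupling changes the picture completely: once the units synchronize, each
one — and their spatial mean — behaves like a *noise-free* oscillator,
even at noise intensities that destroy an uncoupled unit. This
"collective enhancement of precision" is what this package simulates,
quantifies and bounds.

`syncnoise` is a Python library (with a thin CLI) for:

* **Simulating** networks `dxᵢ = [f(xᵢ,t) + Σⱼ Wᵢⱼ(xⱼ − xᵢ) + u(t)] dt + σ dWᵢ`
  with Euler–Maruyama, for FitzHugh–Nagumo, Hindmarsh–Rose, linear units
  or user-supplied drifts, over all-to-all, probabilistic symmetric or
  arbitrary balanced topologies — fully reproducible from a seed.
* **Bounding** the synchronization error. For all-to-all FitzHugh–Nagumo
  networks the stochastic-contraction argument gives, in stationary
  state (ordered-pair sum convention, Σ_{i≠j} E‖xᵢ−xⱼ‖² = 2N Σᵢ E‖xᵢ−x̄‖²):

      C(N, k, σ) = N(N−1) σ²(1 + 1/b²) / (Nk − c)

  — proportional to σ², decaying as 1/k, zero in the noise-free limit —
  together with the pair bound, the curvature (Taylor) inequality
  `‖mean drift − drift at mean‖ ≤ (Q/2)·mean‖xᵢ−x̄‖²`, and the
  mean-impact bound `Q·C/(4N²) + σ/√N`, which collapses to the classical
  1/√N averaging law for linear dynamics.
* **Diagnosing** protection: ergodic synchronization statistics, power
  spectra with harmonic-clarity scoring, and a contracting model-based
  observer whose time-averaged squared distance certifies how close a
  noisy unit is to noise-free behavior.
* **Reproducing** the packaged experiment presets (`fig1_protection`,
  `fig2_spatial_mean`, `fig3a_bound_sweep`, `fig3b_observer_sweep`,
  `fig4_probabilistic`, `fig5_hindmarsh_rose`, `linear_sqrtN`), each a
  one-call, seed-deterministic pipeline with CSV/JSON outputs and a
  reproducibility manifest.

See `docs/methods.md` for the model, the bound derivations, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from syncnoise import (fitzhugh_nagumo, NoiseSpec, SimConfig, build_all_to_all,
                       euler_maruyama, simulate_noise_free, power_spectrum,
                       harmonic_match)
from syncnoise.simulate import default_initial_conditions

model = fitzhugh_nagumo()                      # a=0.7, b=0.8, c=3, I=-0.4
n, k, sigma, tr = 50, 1.0, 0.5, 100.0
cfg = SimConfig(dt=0.005, t_end=600.0, seed=11, transient=tr)

ref = simulate_noise_free(model, None, np.array([0.0, 0.0]), cfg)
x0  = default_initial_conditions(model, n, seed=12)
unc = euler_maruyama(model, None,                 NoiseSpec(sigma), None, x0, cfg)
syn = euler_maruyama(model, build_all_to_all(n, k), NoiseSpec(sigma), None, x0, cfg)

spec = lambda t: power_spectrum(t.after(tr).states[:, 0, 0], t.dt)
for label, traj in [("synchronized", syn), ("uncoupled", unc)]:
    rep = harmonic_match(spec(ref), spec(traj), n_harmonics=3)
    print(label, rep.dominant_rel_diff, rep.clarity_b, rep.clear_harmonics_b)
```

Running this (it is `examples/01_protected_oscillator.py`) prints:

```
synchronized: dominant 0.0901 cycles/unit (noise-free 0.0892, off by 1.00%), clarity 18.0 dB, clear harmonics: True
   uncoupled: dominant 0.0999 cycles/unit (noise-free 0.0892, off by 11.91%), clarity 8.8 dB, clear harmonics: False
```

The synchronized unit, despite carrying the same σ = 0.5 noise, keeps the
noise-free fundamental within 1% and ≥ 10 dB harmonic prominence; the
uncoupled unit's frequency drifts by 12% and its harmonics sink into the
phase-diffusion background. Comparing the bound with simulation
(`examples/02_bound_vs_simulation.py`):

```
  n     k  empirical      bound  ratio
  4     8    0.03303    0.09543   0.35
  4    32    0.00951    0.02214   0.43
  8     8    0.08293    0.21172   0.39
  8    32    0.02640    0.05105   0.52
```

the ergodic synchronization error sits below `C(n, k, σ)` at every grid
point and both fall as coupling grows. The remaining examples cover the
observer diagnostic and the linear 1/√N baseline versus the nonlinear
population mean.

Each script in `examples/` is a short, self-contained narrative: it
builds its inputs, runs one capability, and prints what the numbers mean.

## CLI

```bash
syncnoise simulate --model fn --topology all-to-all --n 50 --k 1 --sigma 0.5 \
    --dt 0.005 --t-end 600 --seed 42 --out traj.h5
syncnoise observe --traj traj.h5 --oscillator 0 --transient 100 --out dist.csv
syncnoise bounds-sweep --n-grid 4,8 --k-grid 8,16,32 --sigma 0.3 --out sweep.csv
syncnoise experiment fig3a_bound_sweep --seed 7 --out results/fig3a
```

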