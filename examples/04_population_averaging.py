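"""Why averaging alone fails for nonlinear units, and the linear baseline.

Part 1: for linear Ornstein-Uhlenbeck units, averaging N independent
units shrinks the noise impact on the mean as 1/sqrt(N) — the classical
law, recovered here from simulation.

Part 2: for nonlinear FitzHugh-Nagumo units the spatial mean of an
*uncoupled* noisy ensemble is clean but nearly information-free, while
the mean of a *synchronized* ensemble reproduces the noise-free waveform:
coupling, not averaging, is what preserves the signal.
"""

import numpy as np

from syncnoise import (
    NoiseSpec,
    SimConfig,
    build_all_to_all,
    euler_maruyama,
    fitzhugh_nagumo,
    harmonic_match,
    linear_model,
    power_spectrum,
    simulate_noise_free,
    spatial_mean_series,
)
from syncnoise.simulate import default_initial_conditions

# --- linear units: inverse-square-root law -----------------------------
ou = linear_model(np.array([[-1.0]]))
print("OU units: RMS of ensemble mean vs. N (expect halving per 4x N)")
for i, n in enumerate([1, 4, 16, 64]):
    cfg = SimConfig(dt=0.01, t_end=2000.0, seed=30 + i, transient=20.0)
    traj = euler_maruyama(ou, None, NoiseSpec(1.0), None, np.zeros((n, 1)), cfg)
    rms = np.sqrt(np.mean(spatial_mean_series(traj.after(20.0)) ** 2))
    print(f"  N={n:>3}: RMS = {rms:.4f}   (1/sqrt(2N) = {1 / np.sqrt(2 * n):.4f})")

# --- nonlinear units: the mean needs synchronization -------------------
model = fitzhugh_nagumo()
n, k, sigma, transient = 50, 1.0, 0.5, 100.0
cfg = SimConfig(dt=0.005, t_end=600.0, seed=41, transient=transient)
ref = simulate_noise_free(model, None, np.array([0.0, 0.0]), cfg)
x0 = default_initial_conditions(model, n, seed=42)
unc = euler_maruyama(model, None, NoiseSpec(sigma), None, x0, cfg)
syn = euler_maruyama(model, build_all_to_all(n, k), NoiseSpec(sigma), None, x0, cfg)

spec_ref = power_spectrum(ref.after(transient).states[:, 0, 0], ref.dt)
for label, traj in [("synchronized", syn), ("uncoupled", unc)]:
    spec = power_spectrum(spatial_mean_series(traj.after(transient)), traj.dt)
    rep = harmonic_match(spec_ref, spec, n_harmonics=3)
    print(
        f"{label:>12} mean: clarity {rep.clarity_b:.1f} dB "
        f"(noise-free reference {rep.clarity_a:.1f} dB)"
    )
# The synchronized mean keeps sharp harmonics; the uncoupled mean's
# spectral peaks collapse toward the background even though the series
# itself looks "smooth" — averaging removed the signal with the noise.
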