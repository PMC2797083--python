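"""A synchronized noisy oscillator keeps the noise-free spectrum.

Simulates three FitzHugh-Nagumo conditions — noise-free, noisy uncoupled,
and noisy inside a strongly coupled all-to-all network — and compares the
dominant frequency and harmonic clarity of one oscillator's voltage
spectrum in each. Coupling restores the noise-free spectral signature
that noise alone destroys.
"""

import numpy as np

from syncnoise import (
    NoiseSpec,
    SimConfig,
    build_all_to_all,
    euler_maruyama,
    fitzhugh_nagumo,
    harmonic_match,
    power_spectrum,
    simulate_noise_free,
)
from syncnoise.simulate import default_initial_conditions

model = fitzhugh_nagumo()
n, k, sigma, transient = 50, 1.0, 0.5, 100.0
cfg = SimConfig(dt=0.005, t_end=600.0, seed=11, transient=transient)

reference = simulate_noise_free(model, None, np.array([0.0, 0.0]), cfg)
x0 = default_initial_conditions(model, n, seed=12)
uncoupled = euler_maruyama(model, None, NoiseSpec(sigma), None, x0, cfg)
network = euler_maruyama(model, build_all_to_all(n, k), NoiseSpec(sigma), None, x0, cfg)


def spectrum(traj):
    sub = traj.after(transient)
    return power_spectrum(sub.states[:, 0, 0], sub.dt)


spec_ref = spectrum(reference)
for label, traj in [("synchronized", network), ("uncoupled", uncoupled)]:
    rep = harmonic_match(spec_ref, spectrum(traj), n_harmonics=3)
    print(
        f"{label:>12}: dominant {rep.dominant_b:.4f} cycles/unit "
        f"(noise-free {rep.dominant_a:.4f}, off by {100 * rep.dominant_rel_diff:.2f}%), "
        f"clarity {rep.clarity_b:.1f} dB, clear harmonics: {rep.clear_harmonics_b}"
    )
# The synchronized unit sits within a fraction of a percent of the
# noise-free fundamental with sharp harmonics; the uncoupled unit's
# harmonics sink toward the phase-diffusion background.
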