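"""Statistics quantifying protection from noise.

Three families of diagnostics:

* synchronization statistics — the ergodic estimate of the expected
  (ordered-pair) sum of squared distances between unit states, the centre
  of mass and the exact rearrangement identity linking the two;
* spectral diagnostics — one-sided power spectra, dominant-frequency and
  harmonic comparison with a peak-prominence clarity score (the spectrum
  of a protected oscillator keeps the noise-free fundamental and its
  harmonics, a phase-diffused one does not);
* trajectory distances — time-averaged squared distances between
  trajectories on a common grid.

All ergodic averages are single-run time averages after an explicit
transient window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .models import InvalidInputError
from .simulate import EnsembleTrajectory

__all__ = [
    "SyncStats",
    "Spectrum",
    "HarmonicReport",
    "center_of_mass",
    "sync_error",
    "spatial_mean_series",
    "power_spectrum",
    "harmonic_match",
    "trajectory_distance",
]

# a harmonic counts as "clear" when its peak rises at least this much
# above the local spectral background (median power in the search band)
CLARITY_THRESHOLD_DB = 10.0
HARMONIC_BAND = 0.15  # search half-width around h*f0, relative


@dataclass
class SyncStats:
    """Ergodic synchronization-error estimate and supporting series."""

    sync_error: float
    center_of_mass: np.ndarray  # (T, dim)
    pairwise_mean_sq: np.ndarray  # (T,) ordered-pair sum per time point
    window: tuple[float, float]
    convention: str = "sum"

    def __post_init__(self) -> None:
        if self.sync_error < 0:
            raise InvalidInputError("sync_error must be nonnegative")


@dataclass
class Spectrum:
    """One-sided power spectrum; sum of ``power`` equals the series variance."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        if np.any(self.power < -1e-300):
            raise InvalidInputError("power must be nonnegative")


def center_of_mass(states: np.ndarray | EnsembleTrajectory) -> np.ndarray:
    """Arithmetic mean over oscillators, per component (and time point)."""
    arr = states.states if isinstance(states, EnsembleTrajectory) else np.asarray(states, float)
    if arr.ndim == 2:  # (N, dim) single time point
        if arr.shape[0] < 1:
            raise InvalidInputError("empty ensemble")
        return arr.mean(axis=0)
    if arr.ndim == 3:
        if arr.shape[1] < 1:
            raise InvalidInputError("empty ensemble")
        return arr.mean(axis=1)
    raise InvalidInputError("states must be (N, dim) or (T, N, dim)")


def _pairwise_sum_sq(states: np.ndarray) -> np.ndarray:
    """Ordered-pair sum of squared distances per time point, via the exact
    identity with distances to the centre of mass."""
    com = states.mean(axis=1, keepdims=True)
    n = states.shape[1]
    return 2.0 * n * np.sum((states - com) ** 2, axis=(1, 2))


def sync_error(
    traj: EnsembleTrajectory,
    transient: float = 0.0,
    convention: Literal["sum", "average"] = "sum",
) -> SyncStats:
    """Ergodic estimate of the synchronization error.

    The per-time quantity is the sum over ordered pairs (i, j), i != j, of
    ``|x_i - x_j|^2`` (``convention="average"`` divides by n (n-1)); the
    statistic is its time average over the post-transient window. The
    computation cross-checks the direct pairwise sum against the exact
    rearrangement ``2 n sum_i |x_i - mean|^2`` and fails loudly if they
    disagree beyond round-off, since every bound in
    :mod:`syncnoise.bounds` relies on that identity.
    """
    if convention not in ("sum", "average"):
        raise InvalidInputError("convention must be 'sum' or 'average'")
    sub = traj.after(transient)
    states = sub.states
    n = states.shape[1]
    series = _pairwise_sum_sq(states)
    # independent direct evaluation on a probe of time points
    probe = states[:: max(1, states.shape[0] // 16)]
    diff = probe[:, :, None, :] - probe[:, None, :, :]
    direct = np.sum(diff**2, axis=(1, 2, 3))
    ref = series[:: max(1, states.shape[0] // 16)][: direct.shape[0]]
    scale = np.maximum(np.abs(direct), 1e-30)
    if np.max(np.abs(direct - ref) / scale) > 1e-9:
        raise AssertionError("pairwise/centre-of-mass identity violated beyond round-off")
    denom = n * (n - 1) if convention == "average" and n > 1 else 1
    return SyncStats(
        sync_error=float(series.mean() / denom),
        center_of_mass=center_of_mass(sub),
        pairwise_mean_sq=series / denom,
        window=(float(sub.times[0]), float(sub.times[-1])),
        convention=convention,
    )


def spatial_mean_series(traj: EnsembleTrajectory, component: int = 0) -> np.ndarray:
    """Population readout: per-time mean of one component across oscillators."""
    if not 0 <= component < traj.state_dim:
        raise InvalidInputError(
            f"component {component} out of range for state_dim {traj.state_dim}"
        )
    return traj.states[:, :, component].mean(axis=1)


def power_spectrum(
    series: np.ndarray,
    dt: float,
    window: Literal["none", "taper"] = "none",
) -> Spectrum:
    """One-sided power spectrum after mean removal.

    With no taper the spectrum is Parseval-consistent: the power summed
    over bins equals the series variance. ``window="taper"`` applies a
    Hann window (variance-normalised) to reduce leakage at the cost of
    exact Parseval consistency.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 16:
        raise InvalidInputError("need a 1-d series of at least 16 samples")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    x = series - series.mean()
    m = x.size
    if window == "taper":
        w = np.hanning(m)
        x = x * w / np.sqrt(np.mean(w**2))
    elif window != "none":
        raise InvalidInputError("window must be 'none' or 'taper'")
    X = np.fft.rfft(x)
    power = np.abs(X) ** 2 / m**2
    if m % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(m, dt)
    return Spectrum(frequencies=freqs, power=power, resolution=float(freqs[1]))


def _interp_peak(freqs: np.ndarray, power: np.ndarray, i: int) -> float:
    """Sub-bin peak location by quadratic interpolation of log-power."""
    if 0 < i < power.size - 1 and power[i - 1] > 0 and power[i + 1] > 0 and power[i] > 0:
        l, c, r = np.log(power[i - 1]), np.log(power[i]), np.log(power[i + 1])
        denom = l - 2 * c + r
        if denom < 0:
            return float(freqs[i] + 0.5 * (l - r) / denom * (freqs[1] - freqs[0]))
    return float(freqs[i])


@dataclass
class HarmonicPeak:
    frequency: float | None
    prominence_db: float
    clear: bool


@dataclass
class HarmonicReport:
    """Comparison of dominant frequency and harmonics of two spectra."""

    dominant_a: float | None
    dominant_b: float | None
    dominant_rel_diff: float | None
    harmonics_a: list = field(default_factory=list)
    harmonics_b: list = field(default_factory=list)
    harmonic_rel_diffs: list = field(default_factory=list)
    clarity_a: float = 0.0  # mean prominence (dB) over fundamental + harmonics
    clarity_b: float = 0.0
    clear_harmonics_a: bool = False
    clear_harmonics_b: bool = False

    def to_dict(self) -> dict:
        return {
            "dominant_a": self.dominant_a,
            "dominant_b": self.dominant_b,
            "dominant_rel_diff": self.dominant_rel_diff,
            "harmonic_rel_diffs": self.harmonic_rel_diffs,
            "clarity_a": self.clarity_a,
            "clarity_b": self.clarity_b,
            "clear_harmonics_a": self.clear_harmonics_a,
            "clear_harmonics_b": self.clear_harmonics_b,
        }


def _extract_harmonics(
    spec: Spectrum, n_harmonics: int, threshold_db: float
) -> tuple[float | None, list[HarmonicPeak]]:
    power = spec.power[1:]  # drop DC
    freqs = spec.frequencies[1:]
    if power.size == 0 or np.max(power) <= 0:
        return None, []
    i0 = int(np.argmax(power))
    f0 = _interp_peak(freqs, power, i0)
    peaks: list[HarmonicPeak] = []
    for h in range(1, n_harmonics + 1):
        lo, hi = h * f0 * (1 - HARMONIC_BAND), h * f0 * (1 + HARMONIC_BAND)
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            peaks.append(HarmonicPeak(None, -np.inf, False))
            continue
        band = power[sel]
        fband = freqs[sel]
        ip = int(np.argmax(band))
        background = float(np.median(band))
        if background <= 0:
            prom = np.inf if band[ip] > 0 else -np.inf
        else:
            prom = 10.0 * np.log10(band[ip] / background)
        peaks.append(
            HarmonicPeak(_interp_peak(fband, band, ip), float(prom), prom >= threshold_db)
        )
    return f0, peaks


def harmonic_match(
    spec_a: Spectrum,
    spec_b: Spectrum,
    n_harmonics: int = 3,
    threshold_db: float = CLARITY_THRESHOLD_DB,
) -> HarmonicReport:
    """Compare dominant frequency and first harmonics of two spectra.

    The clarity score of a spectrum is the mean prominence (in dB above
    the local background) of the fundamental and its harmonics; a
    spectrum "has clear harmonics" when every one of them rises at least
    ``threshold_db`` above background. A no-peak spectrum is reported
    (dominant ``None``), not raised.
    """
    if n_harmonics < 1:
        raise InvalidInputError("need n_harmonics >= 1")
    f0a, peaks_a = _extract_harmonics(spec_a, n_harmonics, threshold_db)
    f0b, peaks_b = _extract_harmonics(spec_b, n_harmonics, threshold_db)
    rel = None
    if f0a and f0b:
        rel = abs(f0b - f0a) / f0a
    harm_rel = []
    for pa, pb in zip(peaks_a, peaks_b):
        if pa.frequency and pb.frequency:
            harm_rel.append(abs(pb.frequency - pa.frequency) / pa.frequency)
        else:
            harm_rel.append(None)

    def _clarity(peaks: list[HarmonicPeak]) -> float:
        finite = [p.prominence_db for p in peaks if np.isfinite(p.prominence_db)]
        return float(np.mean(finite)) if finite else 0.0

    return HarmonicReport(
        dominant_a=f0a,
        dominant_b=f0b,
        dominant_rel_diff=rel,
        harmonics_a=peaks_a,
        harmonics_b=peaks_b,
        harmonic_rel_diffs=harm_rel,
        clarity_a=_clarity(peaks_a),
        clarity_b=_clarity(peaks_b),
        clear_harmonics_a=bool(peaks_a) and all(p.clear for p in peaks_a),
        clear_harmonics_b=bool(peaks_b) and all(p.clear for p in peaks_b),
    )


def trajectory_distance(
    a: EnsembleTrajectory,
    b: EnsembleTrajectory,
    transient: float = 0.0,
) -> float:
    """Time-averaged squared distance between two single-unit trajectories
    on a common grid after the transient."""
    sa, sb = a.after(transient), b.after(transient)
    m = min(sa.times.size, sb.times.size)
    if not np.allclose(sa.times[:m], sb.times[:m], rtol=1e-9, atol=1e-9):
        raise InvalidInputError("trajectories are not on a common time grid")
    xa = sa.states[:m, 0, :] if sa.n_oscillators == 1 else sa.states[:m].mean(axis=1)
    xb = sb.states[:m, 0, :] if sb.n_oscillators == 1 else sb.states[:m].mean(axis=1)
    return float(np.mean(np.sum((xa - xb) ** 2, axis=1)))
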