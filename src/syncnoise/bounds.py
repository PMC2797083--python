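"""Theoretical bounds from the stochastic-contraction analysis.

Setting and notation
--------------------
For an all-to-all network of N FitzHugh-Nagumo units with per-link
strength k and voltage noise intensity sigma, the difference
``(dv, dw) = x_i - x_j`` of any pair obeys a linear time-varying SDE
whose voltage equation carries the damping

    -[N k - c (1 - q(t))] dv,   q(t) = (v_i^2 + v_i v_j + v_j^2) / 3 >= 0,

(the cubic contributes the nonnegative q, so the contraction rate of the
fast mode is at least ``rho = N k - c``) while the recovery equation is an
exponentially stable filter of gain 1/b driven by dv. Each pair is
uncoupled from the other pairs in the auxiliary-system (virtual system)
decomposition, so stochastic contraction applies pairwise:

    E|dv|^2 <= (sqrt(2) sigma)^2 / (2 rho) = sigma^2 / rho
    E|dw|^2 <= E|dv|^2 / b^2

giving the per-pair bound ``sigma^2 (1 + 1/b^2) / (N k - c)`` and, summed
over the N (N - 1) ordered pairs, the synchronization bound

    C(N, k, sigma) = N (N - 1) sigma^2 (1 + 1/b^2) / (N k - c).

C is proportional to sigma^2, strictly decreasing in k, and behaves as
``N (N - 1) sigma^2 (1 + 1/b^2) / (N k)`` for large k, vanishing as
k -> infinity: noise-free networks synchronize completely, and strong
coupling recovers that limit at any noise intensity. The bound applies
after exponential transients at the slower of the two modal rates
(``2 (N k - c)`` for the voltage difference, ``2 b / c`` for the
recovery difference).

The *sum convention*: the synchronization error is the expected sum of
squared distances over ordered pairs (i, j), i != j, equal to
``2 N sum_i |x_i - mean|^2``; every statistic in :mod:`syncnoise.analysis`
uses the same convention so bounds and estimates are directly comparable.

Mean-trajectory impact
----------------------
Writing the population mean's SDE and Taylor-expanding each unit's drift
around the mean, the drift mismatch is controlled by the curvature
constant Q (see :func:`syncnoise.models.hessian_bound`) and the
synchronization error, while the averaged noise has intensity
sigma / sqrt(N); the impact of noise on the mean trajectory is of order

    Q C / (4 N^2) + sigma / sqrt(N),

which reduces to the classical inverse-square-root averaging law for
linear dynamics (Q = 0) and vanishes when N grows and C shrinks jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .models import FN_DEFAULT_PARAMS, InvalidInputError, OscillatorModel

__all__ = [
    "BoundReport",
    "LargeCouplingWarning",
    "DegenerateTransformError",
    "EigenmodeTransform",
    "sync_bound_all_to_all",
    "pair_bound",
    "eigenmode_transform",
    "taylor_mismatch",
    "mean_impact_bound",
]


class LargeCouplingWarning(UserWarning):
    """The coupling is not clearly in the strong-coupling regime the
    pairwise contraction argument assumes."""


class DegenerateTransformError(ValueError):
    """The modal change of variables is (numerically) singular."""


@dataclass(frozen=True)
class BoundReport:
    """A theoretical bound value plus everything that produced it."""

    bound_value: float
    transient_rate: float
    inputs: Mapping[str, float]
    kind: str
    asymptotic_value: float | None = None

    def __post_init__(self) -> None:
        if self.bound_value < 0:
            raise InvalidInputError("bound_value must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "bound_value": self.bound_value,
            "transient_rate": self.transient_rate,
            "asymptotic_value": self.asymptotic_value,
            "inputs": dict(self.inputs),
        }


def _check_fn_params(params: Mapping[str, float] | None) -> dict[str, float]:
    params = dict(FN_DEFAULT_PARAMS if params is None else params)
    for name in ("a", "b", "c"):
        if name not in params:
            raise InvalidInputError(f"missing FitzHugh-Nagumo parameter {name!r}")
    return params


def _warn_if_weak(k: float, params: Mapping[str, float]) -> None:
    largest = max(abs(params["a"]), abs(params["b"]), abs(params["c"]))
    if k < 10.0 * largest:
        warnings.warn(
            f"coupling k={k:g} is below 10x the largest model parameter "
            f"({largest:g}); the strong-coupling bound may be loose or invalid",
            LargeCouplingWarning,
            stacklevel=3,
        )


def _pair_mean_sq_bound(rho: float, sigma: float, b: float) -> float:
    """Expected squared pair distance under fast contraction rate rho > 0."""
    if rho <= 0:
        raise InvalidInputError(
            "coupling too weak: the pairwise contraction rate N*k - c must be positive"
        )
    return sigma**2 * (1.0 + 1.0 / b**2) / rho


def sync_bound_all_to_all(
    n: int,
    k: float,
    sigma: float,
    params: Mapping[str, float] | None = None,
) -> BoundReport:
    """Synchronization bound C for an all-to-all FitzHugh-Nagumo network.

    Returns the bound on the stationary expected *ordered-pair sum* of
    squared distances between unit states. See the module docstring for
    the derivation and conventions.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2 oscillators")
    if k <= 0:
        raise InvalidInputError("coupling strength k must be positive")
    if sigma < 0:
        raise InvalidInputError("sigma must be nonnegative")
    params = _check_fn_params(params)
    _warn_if_weak(k, params)
    b, c = params["b"], params["c"]
    rho = n * k - c
    value = n * (n - 1) * _pair_mean_sq_bound(rho, sigma, b)
    asymptotic = n * (n - 1) * sigma**2 * (1.0 + 1.0 / b**2) / (n * k)
    rate = min(2.0 * rho, 2.0 * b / c)
    return BoundReport(
        bound_value=value,
        transient_rate=rate,
        inputs={"n": n, "k": k, "sigma": sigma, **params},
        kind="A4_all_to_all",
        asymptotic_value=asymptotic,
    )


def pair_bound(
    k: float,
    sigma: float,
    params: Mapping[str, float] | None = None,
) -> BoundReport:
    """Bound on E|x_1 - x_2|^2 for two coupled FitzHugh-Nagumo units.

    This is the single-pair quantity; the all-to-all bound at n = 2 counts
    the pair in both orders and therefore equals exactly twice this value.
    """
    if k <= 0:
        raise InvalidInputError("coupling strength k must be positive")
    if sigma < 0:
        raise InvalidInputError("sigma must be nonnegative")
    params = _check_fn_params(params)
    _warn_if_weak(k, params)
    b, c = params["b"], params["c"]
    rho = 2.0 * k - c
    value = _pair_mean_sq_bound(rho, sigma, b)
    return BoundReport(
        bound_value=value,
        transient_rate=min(2.0 * rho, 2.0 * b / c),
        inputs={"k": k, "sigma": sigma, **params},
        kind="pair",
    )


def _pair_evolution_matrix(params: Mapping[str, float], k: float, q: float) -> np.ndarray:
    b, c = params["b"], params["c"]
    return np.array(
        [
            [c * (1.0 - q) - 2.0 * k, c],
            [-1.0 / c, -b / c],
        ]
    )


@dataclass(frozen=True)
class EigenmodeTransform:
    """Modal coordinates of the two-oscillator difference system."""

    modes: np.ndarray  # transformed difference coordinates (2,)
    eigenvalues: np.ndarray  # (2,) decay rates (negative reals)
    eigenvectors: np.ndarray = field(repr=False)  # columns
    difference: np.ndarray = field(repr=False)

    def inverse(self) -> np.ndarray:
        """Map the modal coordinates back to the (dv, dw) difference."""
        return self.eigenvectors @ self.modes


def eigenmode_transform(
    pair_states: np.ndarray,
    params: Mapping[str, float] | None = None,
    k: float = 10.0,
    q: float = 0.0,
) -> EigenmodeTransform:
    """Change of variables decoupling the pair-difference modes.

    Diagonalises the evolution matrix of the auxiliary (virtual) system of
    a coupled pair at frozen curvature level ``q``; in the strong-coupling
    regime the two modes are a fast voltage-difference mode with rate
    close to 2k and a slow recovery mode with rate close to b/c, and they
    relax independently. The transform is exactly invertible
    (``inverse()`` reproduces the difference to machine precision).
    """
    params = _check_fn_params(params)
    pair_states = np.asarray(pair_states, dtype=float)
    if pair_states.shape != (2, 2):
        raise InvalidInputError("pair_states must be a 2x2 array (two FN states)")
    A = _pair_evolution_matrix(params, k, q)
    eigvals, eigvecs = np.linalg.eig(A)
    if np.iscomplexobj(eigvals) and np.max(np.abs(eigvals.imag)) > 1e-12 * np.max(
        np.abs(eigvals.real)
    ):
        raise DegenerateTransformError(
            "pair evolution matrix has complex modes; k is outside the "
            "strong-coupling validity regime"
        )
    eigvals = eigvals.real
    eigvecs = eigvecs.real
    cond = np.linalg.cond(eigvecs)
    if not np.isfinite(cond) or cond > 1e8:
        raise DegenerateTransformError(
            f"modal matrix is numerically singular (cond={cond:.2e})"
        )
    order = np.argsort(eigvals)  # fast (most negative) first
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    diff = pair_states[0] - pair_states[1]
    modes = np.linalg.solve(eigvecs, diff)
    return EigenmodeTransform(
        modes=modes, eigenvalues=eigvals, eigenvectors=eigvecs, difference=diff
    )


def taylor_mismatch(
    model: OscillatorModel,
    states: np.ndarray,
    Q: float,
    radius: float | None = None,
) -> tuple[float, float]:
    """Drift-mean mismatch and its curvature bound at one time point.

    Returns ``(mismatch, bound)`` where ``mismatch`` is the Euclidean norm
    of (mean over units of the drift) - (drift at the centre of mass) and
    ``bound = (Q / 2) * mean_i |x_i - mean|^2``. By Taylor's formula with
    integral remainder the mismatch is guaranteed to satisfy
    ``mismatch <= bound`` whenever Q bounds the drift's Hessians over a
    region containing the states; linear dynamics (Q = 0) contribute no
    mismatch at all.
    """
    if Q < 0:
        raise InvalidInputError("Q must be nonnegative")
    states = np.asarray(states, dtype=float)
    if states.ndim != 2:
        raise InvalidInputError("states must be (N, dim)")
    if radius is not None:
        cmask = model.mask_array("coupling")
        if np.max(np.abs(states[:, cmask])) > radius + 1e-12:
            raise InvalidInputError(
                "a state lies outside the ball on which Q was computed"
            )
    com = states.mean(axis=0)
    drift_mean = model.drift(states, 0.0).mean(axis=0)
    drift_at_com = model.drift(com, 0.0)
    mismatch = float(np.linalg.norm(drift_mean - drift_at_com))
    msd = float(np.mean(np.sum((states - com) ** 2, axis=1)))
    return mismatch, 0.5 * Q * msd


def mean_impact_bound(Q: float, C: float, sigma: float, n: int) -> float:
    """Bound-scale of the noise impact on the population-mean trajectory.

    ``Q C / (4 n^2) + sigma / sqrt(n)`` with C in the ordered-pair sum
    convention: the first term is the nonlinear drift mismatch sustained by
    residual desynchronization, the second the intensity of the averaged
    intrinsic noise. With Q = 0 (linear dynamics) only the
    inverse-square-root averaging term remains.
    """
    if Q < 0 or C < 0 or sigma < 0:
        raise InvalidInputError("Q, C and sigma must be nonnegative")
    if n < 1:
        raise InvalidInputError("need n >= 1")
    return Q * C / (4.0 * n**2) + sigma / np.sqrt(n)
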