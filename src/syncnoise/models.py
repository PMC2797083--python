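"""Oscillator models and their differential structure.

The package works with networks of identical units

    dx_i = [ f(x_i, t) + coupling_i + u(t) e_in ] dt + sigma dW_i,

where ``f`` is the drift of a single unit, ``u`` a common scalar input
injected on the input-masked components, and ``sigma`` the intensity of the
additive white noise applied to the noise-masked components (independent
across units).

Built-in drifts
---------------
* FitzHugh-Nagumo (Bonhoeffer-van der Pol form, FitzHugh 1961)::

      dv/dt = c (v + w - v^3/3 + I) + u(t)
      dw/dt = -(v - a + b w) / c

* Hindmarsh-Rose (Hindmarsh & Rose 1984)::

      dx/dt = y - a x^3 + b x^2 - z + I + u(t)
      dy/dt = c - d x^2 - y
      dz/dt = r (s (x - x_rest) - z)

* Time-varying linear systems ``dx/dt = A(t) x + b(t)``.

Besides the drift itself, each model exposes the pieces of differential
structure the theoretical machinery needs: a uniform bound ``Q`` on the
spectral norm of the per-component Hessians over a ball (the curvature
constant quantifying the nonlinearity), and the operating radius ``R``
extracted from simulated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "OscillatorModel",
    "NoiseSpec",
    "InvalidInputError",
    "UnsupportedModelError",
    "fn_drift",
    "hr_drift",
    "linear_drift",
    "fitzhugh_nagumo",
    "hindmarsh_rose",
    "linear_model",
    "hessian_bound",
    "trajectory_radius",
]


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


class UnsupportedModelError(TypeError):
    """Raised when an operation needs structure a model does not provide."""


FN_DEFAULT_PARAMS: dict[str, float] = {"a": 0.7, "b": 0.8, "c": 3.0, "I": -0.4}
HR_DEFAULT_PARAMS: dict[str, float] = {
    "a": 1.0,
    "b": 3.0,
    "c": 1.0,
    "d": 5.0,
    "r": 0.006,
    "s": 4.0,
    "x_rest": -1.6,
    "I": 3.0,
}


def _require_params(params: Mapping[str, float], names: tuple[str, ...]) -> None:
    for name in names:
        if name not in params:
            raise InvalidInputError(f"missing model parameter {name!r}")


def _check_state(state: np.ndarray, dim: int) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != dim:
        raise InvalidInputError(
            f"state has trailing dimension {state.shape[-1]}, expected {dim}"
        )
    if not np.all(np.isfinite(state)):
        raise InvalidInputError("non-finite state")
    return state


def fn_drift(
    state: np.ndarray,
    t: float,
    input: float = 0.0,
    params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """FitzHugh-Nagumo drift for one state ``(v, w)`` or a batch ``(N, 2)``.

    The external input ``u`` enters the voltage equation with unit
    coefficient, separately from the intrinsic bias current ``I`` that sits
    inside the fast subsystem.
    """
    params = FN_DEFAULT_PARAMS if params is None else params
    _require_params(params, ("a", "b", "c", "I"))
    state = _check_state(state, 2)
    a, b, c, bias = params["a"], params["b"], params["c"], params["I"]
    v = state[..., 0]
    w = state[..., 1]
    dv = c * (v + w - v**3 / 3.0 + bias) + input
    dw = -(v - a + b * w) / c
    return np.stack([dv, dw], axis=-1)


def hr_drift(
    state: np.ndarray,
    t: float,
    input: float = 0.0,
    params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Hindmarsh-Rose drift for one state ``(x, y, z)`` or a batch ``(N, 3)``.

    ``x`` is the membrane potential, ``y`` the fast recovery current and
    ``z`` the slow adaptation current; the common input adds to dx/dt.
    """
    params = HR_DEFAULT_PARAMS if params is None else params
    _require_params(params, ("a", "b", "c", "d", "r", "s", "x_rest", "I"))
    state = _check_state(state, 3)
    a, b, c, d = params["a"], params["b"], params["c"], params["d"]
    r, s, x_rest, bias = params["r"], params["s"], params["x_rest"], params["I"]
    x = state[..., 0]
    y = state[..., 1]
    z = state[..., 2]
    dx = y - a * x**3 + b * x**2 - z + bias + input
    dy = c - d * x**2 - y
    dz = r * (s * (x - x_rest) - z)
    return np.stack([dx, dy, dz], axis=-1)


def linear_drift(
    state: np.ndarray,
    t: float,
    A: np.ndarray | Callable[[float], np.ndarray],
    b: np.ndarray | Callable[[float], np.ndarray] | None = None,
) -> np.ndarray:
    """Affine drift ``A(t) x + b(t)``; ``A``/``b`` may be constants or callables."""
    At = np.asarray(A(t) if callable(A) else A, dtype=float)
    if At.ndim != 2 or At.shape[0] != At.shape[1]:
        raise InvalidInputError("A(t) must be a square matrix")
    if not np.all(np.isfinite(At)):
        raise InvalidInputError("non-finite A(t)")
    n = At.shape[0]
    state = _check_state(state, n)
    out = state @ At.T
    if b is not None:
        bt = np.asarray(b(t) if callable(b) else b, dtype=float)
        if bt.shape != (n,):
            raise InvalidInputError(f"b(t) has shape {bt.shape}, expected ({n},)")
        out = out + bt
    return out


@dataclass(frozen=True)
class NoiseSpec:
    """Intensity of the intrinsic additive white noise.

    ``sigma`` is constant in time and state; each oscillator receives an
    independent Wiener process (independence is what makes the population
    mean average the noise down).
    """

    sigma: float
    per_oscillator_independent: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("sigma must be nonnegative")
        if not self.per_oscillator_independent:
            raise InvalidInputError("only independent per-oscillator noise is supported")


@dataclass(frozen=True)
class OscillatorModel:
    """A single-unit drift plus the channel masks the network machinery uses.

    Parameters
    ----------
    name:
        Identifier recorded in trajectory provenance.
    state_dim:
        Dimension of one unit's state.
    params:
        Named real parameters of the drift.
    noise_mask, coupling_mask, input_mask:
        Per-component booleans selecting which components receive additive
        noise, diffusive coupling, and the common input. The default for
        the neuron models is voltage-only (gap junctions couple membrane
        potentials).
    drift_fn:
        ``drift_fn(states, t, u, params) -> derivative``, vectorised over a
        leading batch axis.
    hessian_norm_fn:
        Optional ``(radius, params) -> Q`` giving a uniform bound on the
        spectral norms of the per-component Hessians of the drift over the
        centred ball of that radius. ``None`` means unknown (finite
        differences are then used as a fallback).
    """

    name: str
    state_dim: int
    params: Mapping[str, float]
    noise_mask: tuple[bool, ...]
    coupling_mask: tuple[bool, ...]
    input_mask: tuple[bool, ...]
    drift_fn: Callable[..., np.ndarray] = field(repr=False)
    hessian_norm_fn: Callable[[float, Mapping[str, float]], float] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if self.state_dim < 1:
            raise InvalidInputError("state_dim must be >= 1")
        for mask_name in ("noise_mask", "coupling_mask", "input_mask"):
            mask = getattr(self, mask_name)
            if len(mask) != self.state_dim:
                raise InvalidInputError(f"{mask_name} must have length {self.state_dim}")

    def drift(self, states: np.ndarray, t: float, input: float = 0.0) -> np.ndarray:
        """Evaluate the uncoupled drift; deterministic in (state, t, input)."""
        return self.drift_fn(states, t, input, self.params)

    def mask_array(self, which: str) -> np.ndarray:
        return np.asarray(getattr(self, which + "_mask"), dtype=bool)


def _fn_hessian_norm(radius: float, params: Mapping[str, float]) -> float:
    # only the voltage equation is nonlinear: d2(dv/dt)/dv2 = -2 c v
    return 2.0 * params["c"] * radius


def _hr_hessian_norm(radius: float, params: Mapping[str, float]) -> float:
    # x-equation: d2/dx2 = -6 a x + 2 b; y-equation: d2/dx2 = -2 d
    a, b, d = params["a"], params["b"], params["d"]
    return max(6.0 * a * radius + 2.0 * b, 2.0 * d)


def fitzhugh_nagumo(
    params: Mapping[str, float] | None = None,
    *,
    noise_mask: tuple[bool, ...] = (True, False),
    coupling_mask: tuple[bool, ...] = (True, False),
    input_mask: tuple[bool, ...] = (True, False),
) -> OscillatorModel:
    """FitzHugh-Nagumo unit with voltage-only noise, coupling and input."""
    merged = dict(FN_DEFAULT_PARAMS)
    if params:
        merged.update(params)
    return OscillatorModel(
        name="fitzhugh_nagumo",
        state_dim=2,
        params=merged,
        noise_mask=noise_mask,
        coupling_mask=coupling_mask,
        input_mask=input_mask,
        drift_fn=lambda x, t, u, p: fn_drift(x, t, u, p),
        hessian_norm_fn=_fn_hessian_norm,
    )


def hindmarsh_rose(
    params: Mapping[str, float] | None = None,
    *,
    noise_mask: tuple[bool, ...] = (True, False, False),
    coupling_mask: tuple[bool, ...] = (True, False, False),
    input_mask: tuple[bool, ...] = (True, False, False),
) -> OscillatorModel:
    """Hindmarsh-Rose unit with membrane-potential noise, coupling and input."""
    merged = dict(HR_DEFAULT_PARAMS)
    if params:
        merged.update(params)
    return OscillatorModel(
        name="hindmarsh_rose",
        state_dim=3,
        params=merged,
        noise_mask=noise_mask,
        coupling_mask=coupling_mask,
        input_mask=input_mask,
        drift_fn=lambda x, t, u, p: hr_drift(x, t, u, p),
        hessian_norm_fn=_hr_hessian_norm,
    )


def linear_model(
    A: np.ndarray | Callable[[float], np.ndarray],
    b: np.ndarray | Callable[[float], np.ndarray] | None = None,
    *,
    state_dim: int | None = None,
    noise_mask: tuple[bool, ...] | None = None,
    coupling_mask: tuple[bool, ...] | None = None,
    input_mask: tuple[bool, ...] | None = None,
) -> OscillatorModel:
    """Time-varying linear unit ``dx/dt = A(t) x + b(t)``; curvature Q is 0."""
    if state_dim is None:
        A0 = np.asarray(A(0.0) if callable(A) else A, dtype=float)
        state_dim = A0.shape[0]
    all_on = tuple([True] * state_dim)
    return OscillatorModel(
        name="linear",
        state_dim=state_dim,
        params={},
        noise_mask=all_on if noise_mask is None else noise_mask,
        coupling_mask=all_on if coupling_mask is None else coupling_mask,
        input_mask=(
            tuple([True] + [False] * (state_dim - 1)) if input_mask is None else input_mask
        ),
        drift_fn=lambda x, t, u, p, _A=A, _b=b: linear_drift(x, t, _A, _b)
        + u * np.asarray([1.0] + [0.0] * (x.shape[-1] - 1)),
        hessian_norm_fn=lambda radius, p: 0.0,
    )


def _finite_difference_hessian_norm(
    model: OscillatorModel, radius: float, n_grid: int = 7
) -> float:
    """Brute-force fallback: largest per-component Hessian spectral norm over
    a grid in the centred ball, by central differences with step
    ``1e-6 * (1 + |x|)``."""
    dim = model.state_dim
    if dim > 3:
        raise UnsupportedModelError(
            "finite-difference Hessian fallback supports state_dim <= 3"
        )
    axes = [np.linspace(-radius, radius, n_grid) for _ in range(dim)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, dim)
    grid = grid[np.linalg.norm(grid, axis=1) <= radius + 1e-12]
    if grid.size == 0:
        grid = np.zeros((1, dim))
    worst = 0.0
    for x in grid:
        h = 1e-6 * (1.0 + np.abs(x))
        hess = np.empty((dim, dim, dim))  # component, i, j
        f0 = model.drift(x, 0.0)
        for i in range(dim):
            for j in range(i, dim):
                ei = np.zeros(dim)
                ej = np.zeros(dim)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    fpp = model.drift(x + ei, 0.0)
                    fmm = model.drift(x - ei, 0.0)
                    second = (fpp - 2 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = model.drift(x + ei + ej, 0.0)
                    fpm = model.drift(x + ei - ej, 0.0)
                    fmp = model.drift(x - ei + ej, 0.0)
                    fmm = model.drift(x - ei - ej, 0.0)
                    second = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
                hess[:, i, j] = second
                hess[:, j, i] = second
        for comp in range(dim):
            worst = max(worst, float(np.linalg.norm(hess[comp], 2)))
    return worst


def hessian_bound(model: OscillatorModel, radius: float) -> float:
    """Curvature constant Q of the drift over the ball of the given radius.

    Q uniformly bounds the spectral norm of every component's Hessian on
    that ball; it is exactly 0 for linear systems (the no-nonlinearity
    extreme) and ``2 c R`` for FitzHugh-Nagumo, whose only curvature comes
    from the cubic voltage term.
    """
    if radius < 0:
        raise InvalidInputError("radius must be nonnegative")
    if model.hessian_norm_fn is not None:
        return float(model.hessian_norm_fn(radius, model.params))
    return _finite_difference_hessian_norm(model, radius)


def trajectory_radius(traj, components: np.ndarray | None = None) -> float:
    """Operating radius R: max absolute state value over time and oscillators.

    By default only the coupled (voltage-like) components recorded in the
    trajectory's provenance are scanned, since those are the components the
    curvature bound of the neuron models depends on; pass ``components`` to
    override.
    """
    states = np.asarray(traj.states if hasattr(traj, "states") else traj, dtype=float)
    if states.size == 0:
        raise InvalidInputError("empty trajectory")
    if components is None and hasattr(traj, "provenance"):
        mask = traj.provenance.get("coupling_mask")
        if mask is not None:
            components = np.flatnonzero(np.asarray(mask, dtype=bool))
    if components is not None:
        states = states[..., np.asarray(components, dtype=int)]
    return float(np.max(np.abs(states)))
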