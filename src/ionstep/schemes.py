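"""Per-step update operators: forward Euler, Rush-Larsen, GRL1.

All operators act block-wide on a :class:`~ionstep.layouts.StateBlock`,
reading only the pre-step state (Jacobi-style) and mutating the block in
place.  Forward Euler is

    s(t + dt) = s(t) + dt * f(t, s(t)).

Rush-Larsen freezes the gate input over one step, which makes each gating
equation dw/dt = (w_inf - w)/tau a linear scalar ODE with the exact update

    w(t + dt) = a w(t) + b,   a = exp(-dt/tau),  b = -w_inf (exp(-dt/tau) - 1),

and applies FE to all other states.  GRL1 extends the same exponential
update to every state via the diagonal linearisation lambda_j = df_j/ds_j:

    s_j(t + dt) = s_j + f_j dt phi(lambda_j dt),   phi(x) = (e^x - 1)/x,

which reduces to FE where lambda_j = 0 and to the exact gate update on
quasi-linear gates when the analytic diagonal is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._math import em1, phi
from .errors import InvalidArgumentError, NumericalFailure
from .layouts import StateBlock
from .models import CellModel

__all__ = [
    "RLCoefficients",
    "fe_step",
    "rl_coefficients",
    "rl_step",
    "grl1_step",
    "diagonal_linearisation",
    "STEPPERS",
]


@dataclass(frozen=True)
class RLCoefficients:
    """Rush-Larsen update coefficients ``w <- a w + b`` for one gate,
    stamped with the time step they were built for."""

    a: np.ndarray
    b: np.ndarray
    dt_stamp: float


def _check_finite(d: np.ndarray, block: StateBlock, *, step: int | None = None) -> None:
    live = d[:, : block.n_cells] if d.ndim == 2 else d
    if np.all(np.isfinite(live)):
        return
    bad = np.argwhere(~np.isfinite(live))
    j, c = (int(bad[0][0]), int(bad[0][1])) if live.ndim == 2 else (int(bad[0][0]), 0)
    name = block.state_names[j] if block.state_names else f"state[{j}]"
    raise NumericalFailure(
        f"non-finite derivative for {name} in cell {c}"
        + (f" at step {step}" if step is not None else ""),
        step=step, cell=c, state=name)


def fe_step(model: CellModel, block: StateBlock, t: float, dt: float,
            params=None, *, step_index: int | None = None) -> StateBlock:
    """One forward-Euler step, in place; returns the block."""
    if dt < 0:
        raise InvalidArgumentError("dt must be >= 0")
    params = model.parameters if params is None else params
    s = block.active_view()
    d = model.rhs(t, s, params)
    _check_finite(d, block, step=step_index)
    s[...] = s + dt * d
    return block


def rl_coefficients(winf, tau, dt: float, use_expm1: bool = True):
    """Rush-Larsen coefficients ``(a, b)`` for gate(s) with the given
    steady state and time constant.

    ``a = exp(-dt/tau)`` and ``b = -w_inf (exp(-dt/tau) - 1)``; the
    ``e^x - 1`` factor goes through the expm1 toggle.  ``dt = 0`` yields
    ``(1, 0)`` exactly.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise InvalidArgumentError("tau must be strictly positive")
    if np.any(np.asarray(dt) < 0):
        raise InvalidArgumentError("dt must be >= 0")
    x = -dt / tau
    a = np.exp(x)
    b = -np.asarray(winf, dtype=float) * em1(x, use_expm1)
    return a, b


def rl_step(model: CellModel, block: StateBlock, t: float, dt: float,
            params=None, *, use_expm1: bool = True,
            step_index: int | None = None) -> StateBlock:
    """One Rush-Larsen step, in place; returns the block.

    Gates get the exact frozen-input exponential update from the pre-step
    value of their input variable; every other state gets forward Euler.
    All reads are from the pre-step state.
    """
    if dt < 0:
        raise InvalidArgumentError("dt must be >= 0")
    params = model.parameters if params is None else params
    s = block.active_view()
    d = model.rhs(t, s, params)
    _check_finite(d, block, step=step_index)
    gate_new = []
    for g in model.gates:
        x = s[model.state_index(g.input_variable)]
        a, b = rl_coefficients(g.winf(x), g.tau(x), dt, use_expm1)
        gate_new.append((g.state_index, a * s[g.state_index] + b))
    s[...] = s + dt * d
    for j, w_new in gate_new:
        s[j] = w_new
    return block


def diagonal_linearisation(model: CellModel, t: float, s: np.ndarray,
                           params) -> np.ndarray:
    """Per-state diagonal Jacobian lambda_j = df_j/ds_j at the given state.

    Uses the model's analytic diagonal when declared; otherwise a central
    finite difference with step h = sqrt(eps_mach) * max(1, |s_j|).
    """
    if model.diag is not None:
        return np.asarray(model.diag(t, s, params), dtype=float)
    lam = np.empty_like(np.asarray(s, dtype=float))
    h0 = np.sqrt(np.finfo(float).eps)
    for j in range(model.n_states):
        h = h0 * np.maximum(1.0, np.abs(s[j]))
        sp = np.array(s, dtype=float)
        sm = np.array(s, dtype=float)
        sp[j] = s[j] + h
        sm[j] = s[j] - h
        fp = model.rhs(t, sp, params)[j]
        fm = model.rhs(t, sm, params)[j]
        lam[j] = (fp - fm) / (sp[j] - sm[j])
    return lam


def grl1_step(model: CellModel, block: StateBlock, t: float, dt: float,
              params=None, *, use_expm1: bool = True,
              step_index: int | None = None) -> StateBlock:
    """One first-order generalised Rush-Larsen step, in place.

    Where the diagonal vanishes the update is bit-for-bit forward Euler
    (phi(0) = 1); on a scalar linear ODE it reproduces the exact solution.
    """
    if dt < 0:
        raise InvalidArgumentError("dt must be >= 0")
    params = model.parameters if params is None else params
    s = block.active_view()
    d = model.rhs(t, s, params)
    _check_finite(d, block, step=step_index)
    lam = diagonal_linearisation(model, t, s, params)
    s[...] = s + dt * d * phi(lam * dt, use_expm1)
    return block


STEPPERS = {"fe": fe_step, "rl": rl_step, "grl1": grl1_step}
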