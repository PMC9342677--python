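"""Cell-model abstraction and built-in models.

A cardiac ionic cell model is a system of N nonlinear ODEs
``ds/dt = f(t, s)`` whose state vector holds the transmembrane potential v,
ionic concentrations, and gating variables.  Gating variables obey the
quasi-linear form ``dw/dt = (w_inf(x) - w)/tau_w(x)`` where the driver x is
usually v; declaring them as :class:`GateSpec` entries lets the Rush-Larsen
and lookup-table machinery treat them specially.

The right-hand side contract is "Jacobi-style": all derivative components
are functions of the state at the current step only, with no in-place
sequential dependence, so a block of cells can be updated by uniform
array-wide arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from ._math import pulse_current
from .errors import InvalidArgumentError, UnsupportedModelError

__all__ = [
    "GateSpec",
    "AuxExpr",
    "CellModel",
    "fhn_model",
    "synthetic_gate_model",
    "load_tp06",
    "read_parameter_csv",
    "MODEL_BUILDERS",
]


@dataclass(frozen=True)
class GateSpec:
    """Declaration of one gating variable.

    ``winf`` and ``tau`` are scalar functions of the single input variable
    (vectorised over numpy arrays); ``tau`` must be strictly positive on the
    tabulation range the model declares for that input.
    """

    state_index: int
    input_variable: str
    winf: Callable[[np.ndarray], np.ndarray]
    tau: Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class AuxExpr:
    """A non-gate expression of a single state variable, eligible for
    tabulation alongside the gate coefficients of the same input."""

    name: str
    input_variable: str
    fn: Callable[[np.ndarray], np.ndarray]


@dataclass
class CellModel:
    """A cell model: state metadata, parameters, and evaluators.

    Attributes
    ----------
    rhs : callable
        ``rhs(t, states, params, aux=None) -> derivatives``; ``states`` has
        shape ``(N,)`` (single cell) or ``(N, C)`` (block), and the result
        matches its shape.  ``params`` maps parameter names to scalars or
        length-C arrays.  ``aux``, when given, maps declared auxiliary
        expression names to pre-evaluated (possibly interpolated) values.
    diag : callable or None
        Analytic diagonal of the Jacobian, ``diag(t, states, params)`` with
        the same shape contract as ``rhs``; used by the GRL1 scheme.  When
        absent a finite-difference fallback is applied.
    """

    name: str
    state_names: tuple[str, ...]
    default_initial_state: np.ndarray
    parameters: dict[str, float]
    rhs: Callable
    gates: tuple[GateSpec, ...] = ()
    lut_inputs: tuple[str, ...] = ()
    auxiliary_lut_expressions: tuple[AuxExpr, ...] = ()
    diag: Callable | None = None
    time_unit: str = "ms"

    def __post_init__(self):
        self.default_initial_state = np.asarray(self.default_initial_state, dtype=float)
        if self.default_initial_state.shape != (self.n_states,):
            raise InvalidArgumentError(
                f"initial state has shape {self.default_initial_state.shape}, "
                f"expected ({self.n_states},)")
        idx = [g.state_index for g in self.gates]
        if len(set(idx)) != len(idx):
            raise InvalidArgumentError("gate state indices must be distinct")
        for g in self.gates:
            if not 0 <= g.state_index < self.n_states:
                raise InvalidArgumentError(
                    f"gate index {g.state_index} out of range for N={self.n_states}")
            if g.input_variable not in self.state_names:
                raise InvalidArgumentError(
                    f"gate input {g.input_variable!r} is not a state variable")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise InvalidArgumentError(f"unknown state variable {name!r}") from None

    @property
    def gate_indices(self) -> np.ndarray:
        return np.array([g.state_index for g in self.gates], dtype=int)

    @property
    def non_gate_indices(self) -> np.ndarray:
        gset = set(int(i) for i in self.gate_indices)
        return np.array([i for i in range(self.n_states) if i not in gset], dtype=int)

    def with_parameters(self, **overrides: float) -> "CellModel":
        """Return a copy with some parameter defaults replaced."""
        unknown = set(overrides) - set(self.parameters)
        if unknown:
            raise InvalidArgumentError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(overrides)
        return replace(self, parameters=params)


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo


def fhn_model(alpha: float = 0.13, eps: float = 0.01, gamma: float = 1.0) -> CellModel:
    """The two-variable FitzHugh-Nagumo model.

        dv/dt = v (v - alpha) (1 - v) - w + I_stim(t)
        dw/dt = eps (v - gamma w)

    with a single stimulus pulse I_stim = -8 on t in [0, 0.5].  The model
    has no quasi-linear gate, so it exercises the FE and GRL1 paths.

    alpha, eps and gamma default to repository choices (0.13, 0.01, 1.0);
    they are ordinary overridable parameters, as are the stimulus settings.
    Time is the model's own dimensionless unit.
    """

    def rhs(t, states, params, aux=None):
        v, w = states[0], states[1]
        a = params["alpha"]
        e = params["eps"]
        g = params["gamma"]
        istim = pulse_current(t, params["stim_amplitude"], params["stim_start"],
                              params["stim_duration"], params["stim_period"])
        d = np.empty_like(np.asarray(states, dtype=float))
        d[0] = v * (v - a) * (1.0 - v) - w + istim
        d[1] = e * (v - g * w)
        return d

    def diag(t, states, params):
        v = states[0]
        a = params["alpha"]
        e = params["eps"]
        g = params["gamma"]
        d = np.empty_like(np.asarray(states, dtype=float))
        # d/dv of the cubic v(v-a)(1-v) = -v^3 + (1+a)v^2 - a v
        d[0] = -3.0 * v * v + 2.0 * (1.0 + a) * v - a
        d[1] = (-e * g) * np.ones_like(np.asarray(v, dtype=float))
        return d

    return CellModel(
        name="fhn",
        state_names=("v", "w"),
        default_initial_state=np.array([0.0, 0.0]),
        parameters={
            "alpha": alpha, "eps": eps, "gamma": gamma,
            "stim_amplitude": -8.0, "stim_start": 0.0,
            "stim_duration": 0.5, "stim_period": np.inf,
        },
        rhs=rhs,
        diag=diag,
        lut_inputs=("v",),
        time_unit="dimensionless",
    )


# ---------------------------------------------------------------------------
# Seeded synthetic gate model


def synthetic_gate_model(n_gates: int, seed: int) -> CellModel:
    """Generate a reproducible membrane-like model with ``n_gates`` gates.

    The model emulates the structure of biophysical cell models without
    transcribing any particular one: a voltage-like driver v with a leak
    toward rest, gated conductances, and 1 Hz pulse pacing, plus ``n_gates``
    gating variables obeying ``dw/dt = (w_inf(v) - w)/tau_w(v)``.  Each
    ``w_inf`` is a logistic sigmoid (hence in [0, 1]) and each ``tau_w`` a
    Gaussian bump on a positive offset (hence strictly positive everywhere).
    Shape constants are drawn from ``numpy.random.default_rng(seed)``, so
    the same ``(n_gates, seed)`` pair always yields the identical model.
    Time is in milliseconds; v in mV.
    """
    if n_gates < 1:
        raise InvalidArgumentError("n_gates must be >= 1")
    rng = np.random.default_rng(seed)

    centers = rng.uniform(-60.0, -10.0, n_gates)
    slopes = rng.uniform(4.0, 10.0, n_gates) * rng.choice([-1.0, 1.0], n_gates)
    tau0 = rng.uniform(1.0, 10.0, n_gates)
    tau_amp = rng.uniform(5.0, 50.0, n_gates)
    tau_mu = rng.uniform(-70.0, 0.0, n_gates)
    tau_sigma = rng.uniform(10.0, 30.0, n_gates)
    reversal = rng.uniform(-90.0, 50.0, n_gates)
    conductance = rng.uniform(0.02, 0.2, n_gates)

    def make_winf(c, s):
        def winf(v):
            return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - c) / s))
        return winf

    def make_tau(t0, amp, mu, sig):
        def tau(v):
            z = (np.asarray(v, dtype=float) - mu) / sig
            return t0 + amp * np.exp(-z * z)
        return tau

    gates = tuple(
        GateSpec(state_index=1 + k, input_variable="v",
                 winf=make_winf(centers[k], slopes[k]),
                 tau=make_tau(tau0[k], tau_amp[k], tau_mu[k], tau_sigma[k]))
        for k in range(n_gates)
    )

    v_rest = -85.0
    tau_v = 20.0
    g_names = tuple(f"g{k}" for k in range(n_gates))

    def rhs(t, states, params, aux=None):
        states = np.asarray(states, dtype=float)
        v = states[0]
        d = np.empty_like(states)
        istim = pulse_current(t, params["stim_amplitude"], params["stim_start"],
                              params["stim_duration"], params["stim_period"])
        total = (params["v_rest"] - v) / params["tau_v"] + istim
        for k in range(n_gates):
            w = states[1 + k]
            total = total - params[g_names[k]] * w * (v - reversal[k])
            d[1 + k] = (gates[k].winf(v) - w) / gates[k].tau(v)
        d[0] = total
        return d

    def diag(t, states, params):
        states = np.asarray(states, dtype=float)
        v = states[0]
        d = np.empty_like(states)
        lam_v = -1.0 / params["tau_v"] * np.ones_like(v)
        for k in range(n_gates):
            lam_v = lam_v - params[g_names[k]] * states[1 + k]
            d[1 + k] = -1.0 / gates[k].tau(v)
        d[0] = lam_v
        return d

    params = {name: float(conductance[k]) for k, name in enumerate(g_names)}
    params.update({
        "v_rest": v_rest, "tau_v": tau_v,
        "stim_amplitude": 8.0, "stim_start": 10.0,
        "stim_duration": 2.0, "stim_period": 1000.0,
    })

    init = np.empty(1 + n_gates)
    init[0] = v_rest
    for k in range(n_gates):
        init[1 + k] = gates[k].winf(v_rest)

    return CellModel(
        name=f"synthetic{n_gates}_s{seed}",
        state_names=("v",) + tuple(f"w{k}" for k in range(n_gates)),
        default_initial_state=init,
        parameters=params,
        rhs=rhs,
        gates=gates,
        diag=diag,
        lut_inputs=("v",),
        time_unit="ms",
    )


def load_tp06() -> CellModel:
    """ten Tusscher-Panfilov (2006) ventricular model (19 states, 12 gates).

    The full equation set must be transcribed from its source publication or
    the CellML repository; no transcription ships with this build, so this
    always raises :class:`UnsupportedModelError`.
    """
    raise UnsupportedModelError(
        "the TP06 transcription is not present in this build; "
        "available models: fhn, synthetic")


# ---------------------------------------------------------------------------
# Registry and CSV overrides

MODEL_BUILDERS: dict[str, Callable[..., CellModel]] = {
    "fhn": fhn_model,
    "synthetic": synthetic_gate_model,
    "tp06": load_tp06,
}


def read_parameter_csv(path) -> dict[str, float]:
    """Read parameter or initial-state overrides from a two-column CSV
    (``name,value``)."""
    df = pd.read_csv(path)
    if not {"name", "value"} <= set(df.columns):
        raise InvalidArgumentError("override CSV needs columns 'name' and 'value'")
    return {str(r["name"]): float(r["value"]) for _, r in df.iterrows()}
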