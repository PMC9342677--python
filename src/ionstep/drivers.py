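"""Run orchestration: simulation and ensemble scenarios.

The simulation scenario advances one population of cells with shared
parameters (outer loop over time).  The ensemble scenario solves one cell
model instance per parameter-table row, under any of three loop nestings:

* ``CELL_TIME``  - outer loop over cells, inner over time;
* ``TIME_CELL``  - outer loop over time, inner (array-wide) over cells;
* ``CELL_TIME_CELL`` - outer loop over batches of B cells, middle over
  time, inner over the lanes of the batch.

All three produce the same trajectories; they differ only in traversal
order (on compiled SIMD hardware they differ greatly in speed, which is
why the distinction exists).  Pacing is a periodic stimulus pulse, and
steady state is declared when the last two pacing periods of the recorded
transmembrane potential agree in the relative root-mean-square sense.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._math import pulse_current, rrms_core
from .errors import InvalidArgumentError
from .layouts import Layout, StateBlock, pack
from .lut import build_rl_tables, lut_rl_step, partitioned_step
from .models import CellModel
from .schemes import fe_step, grl1_step, rl_step

__all__ = [
    "LoopStructure",
    "StimulusProtocol",
    "RunPlan",
    "Trace",
    "run_simulation",
    "run_ensemble",
    "steady_state_check",
    "parameter_grid",
]


class LoopStructure(str, enum.Enum):
    CELL_TIME = "cell-time"
    TIME_CELL = "time-cell"
    CELL_TIME_CELL = "cell-time-cell"


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic rectangular stimulus.

    The stimulus equals ``amplitude`` whenever ``(t - start_time) mod period``
    lies in ``[0, pulse_duration]``; ``period = inf`` encodes a single pulse.
    """

    amplitude: float
    pulse_duration: float
    period: float = np.inf
    start_time: float = 0.0

    def __post_init__(self):
        if not self.pulse_duration < self.period:
            raise InvalidArgumentError("pulse_duration must be < period")

    def current(self, t):
        return pulse_current(t, self.amplitude, self.start_time,
                             self.pulse_duration, self.period)

    def as_parameters(self) -> dict[str, float]:
        """Parameter overrides for models that read their stimulus from the
        standard ``stim_*`` parameter names."""
        return {
            "stim_amplitude": self.amplitude,
            "stim_duration": self.pulse_duration,
            "stim_period": self.period,
            "stim_start": self.start_time,
        }


@dataclass
class RunPlan:
    """Everything needed to reproduce a run."""

    dt: float
    n_steps: int
    scheme: str = "fe"
    t0: float = 0.0
    loop_structure: LoopStructure = LoopStructure.TIME_CELL
    batch_size: int = 32
    record_stride: int = 1
    record_vars: tuple[str, ...] | None = None
    lut: bool = False
    lut_partitioned: bool = False
    lut_v_min: float = -100.0
    lut_v_max: float = 50.0
    lut_v_step: float = 0.05
    lut_policy: str = "clamp"
    use_expm1: bool = True
    layout: Layout = Layout.SOA
    lane_width: int = 8
    seed: int | None = None

    def __post_init__(self):
        self.layout = Layout(self.layout)
        self.loop_structure = LoopStructure(self.loop_structure)
        if self.dt < 0:
            raise InvalidArgumentError("dt must be >= 0")
        if self.n_steps < 0:
            raise InvalidArgumentError("n_steps must be >= 0")
        if self.record_stride < 1:
            raise InvalidArgumentError("record_stride must be >= 1")
        if self.batch_size < 1 or self.batch_size % self.lane_width:
            raise InvalidArgumentError(
                "batch_size must be a positive multiple of lane_width")
        if self.scheme not in ("fe", "rl", "grl1"):
            raise InvalidArgumentError(f"unknown scheme {self.scheme!r}")
        if self.lut and self.scheme != "rl":
            raise InvalidArgumentError("lookup tables apply to the rl scheme")
        if self.record_vars is not None:
            self.record_vars = tuple(self.record_vars)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"] = self.layout.value
        d["loop_structure"] = self.loop_structure.value
        if d["record_vars"] is not None:
            d["record_vars"] = list(d["record_vars"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunPlan":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunPlan":
        path = str(path)
        if path.endswith(".toml"):
            import tomllib
            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Trace:
    """Recorded time series for the live cells of a run."""

    times: np.ndarray
    data: dict[str, np.ndarray]  # var -> (n_recorded, C)
    plan: RunPlan

    @property
    def n_cells(self) -> int:
        return next(iter(self.data.values())).shape[1]

    def series(self, var: str, cell: int = 0) -> np.ndarray:
        return self.data[var][:, cell]

    def to_dataframe(self, cell: int | None = None) -> pd.DataFrame:
        """Wide table: first column time, then one column per recorded
        variable (and per cell when ``cell`` is None and C > 1)."""
        cols = {"t": self.times}
        for var, arr in self.data.items():
            if cell is not None:
                cols[var] = arr[:, cell]
            elif arr.shape[1] == 1:
                cols[var] = arr[:, 0]
            else:
                for c in range(arr.shape[1]):
                    cols[f"{var}[{c}]"] = arr[:, c]
        return pd.DataFrame(cols)

    def write_csv(self, path, cell: int | None = None) -> None:
        self.to_dataframe(cell).to_csv(path, index=False)


def _make_stepper(model: CellModel, plan: RunPlan):
    """Bind the plan's scheme (and tables, if any) into a step callable
    ``step(block, t, params, step_index)``."""
    if plan.lut:
        tables = build_rl_tables(model, plan.dt, v_min=plan.lut_v_min,
                                 v_max=plan.lut_v_max, v_step=plan.lut_v_step,
                                 use_expm1=plan.use_expm1)
        if plan.lut_partitioned:
            def step(block, t, params, step_index):
                return partitioned_step(model, block, t, plan.dt, tables,
                                        params, policy=plan.lut_policy,
                                        batch_size=plan.batch_size,
                                        step_index=step_index)
        else:
            def step(block, t, params, step_index):
                return lut_rl_step(model, block, t, plan.dt, tables, params,
                                   policy=plan.lut_policy,
                                   step_index=step_index)
        return step
    if plan.scheme == "fe":
        return lambda block, t, params, step_index: fe_step(
            model, block, t, plan.dt, params, step_index=step_index)
    if plan.scheme == "rl":
        return lambda block, t, params, step_index: rl_step(
            model, block, t, plan.dt, params, use_expm1=plan.use_expm1,
            step_index=step_index)
    return lambda block, t, params, step_index: grl1_step(
        model, block, t, plan.dt, params, use_expm1=plan.use_expm1,
        step_index=step_index)


def _recorded_vars(model: CellModel, plan: RunPlan) -> tuple[str, ...]:
    if plan.record_vars is None:
        return model.state_names
    for v in plan.record_vars:
        model.state_index(v)  # validates
    return plan.record_vars


def _time_loop(model, block, plan, params, step, record_into, cells):
    """Advance ``block`` for plan.n_steps, recording the live cells into the
    given trace columns.  ``t_l = t0 + l*dt`` is formed by multiplication so
    it cannot drift over millions of steps."""
    var_idx = {v: model.state_index(v) for v in record_into}
    live = block.live_view()

    def record(r):
        for v, arr in record_into.items():
            arr[r, cells] = live[var_idx[v]]

    record(0)
    r = 1
    for l in range(plan.n_steps):
        t = plan.t0 + l * plan.dt
        step(block, t, params, l)
        if (l + 1) % plan.record_stride == 0:
            record(r)
            r += 1


def _trace_arrays(model, plan, n_cells):
    n_rec = plan.n_steps // plan.record_stride + 1
    return {v: np.empty((n_rec, n_cells)) for v in _recorded_vars(model, plan)}


def _trace(model, plan, arrays) -> Trace:
    n_rec = next(iter(arrays.values())).shape[0]
    times = plan.t0 + np.arange(n_rec) * (plan.record_stride * plan.dt)
    return Trace(times, arrays, plan)


def run_simulation(model: CellModel, block: StateBlock, plan: RunPlan,
                   params=None) -> tuple[StateBlock, Trace]:
    """Simulation scenario: one outer loop over time, shared parameters.

    Mutates ``block`` in place and returns it together with the recorded
    :class:`Trace` (padded lanes are never recorded).
    """
    params = model.parameters if params is None else params
    arrays = _trace_arrays(model, plan, block.n_cells)
    step = _make_stepper(model, plan)
    _time_loop(model, block, plan, params, step, arrays, slice(None))
    return block, _trace(model, plan, arrays)


def _param_columns(model: CellModel, table) -> dict[str, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        table = {c: table[c].to_numpy(dtype=float) for c in table.columns}
    out = {}
    for name, col in table.items():
        if name not in model.parameters:
            raise InvalidArgumentError(f"unknown parameter {name!r}")
        out[name] = np.asarray(col, dtype=float)
    return out


def _pad_params(base: dict, columns: dict, lo: int, hi: int, width: int):
    """Per-cell parameter slice [lo, hi) padded (by replicating the last
    live value) to the active lane count."""
    params = dict(base)
    for name, col in columns.items():
        sl = col[lo:hi]
        if width > sl.size:
            sl = np.concatenate([sl, np.full(width - sl.size, sl[-1])])
        params[name] = sl
    return params


def run_ensemble(model: CellModel, param_table, initial_states,
                 plan: RunPlan) -> tuple[StateBlock, Trace]:
    """Ensemble scenario: one model instance per parameter-table row.

    ``param_table`` is a DataFrame (or mapping of columns) with one row per
    cell; ``initial_states`` is a ``(C, N)`` table or None for the model
    default.  The three loop structures produce identical trajectories.
    """
    columns = _param_columns(model, param_table)
    n_cells = len(next(iter(columns.values()))) if columns else None
    if initial_states is None:
        if n_cells is None:
            raise InvalidArgumentError("need a parameter table or initial states")
        initial_states = np.tile(model.default_initial_state, (n_cells, 1))
    initial_states = np.asarray(initial_states, dtype=float)
    if n_cells is None:
        n_cells = initial_states.shape[0]
    if initial_states.shape != (n_cells, model.n_states):
        raise InvalidArgumentError(
            f"initial states shape {initial_states.shape} does not match "
            f"{n_cells} parameter rows x {model.n_states} states")
    for name, col in columns.items():
        if col.size != n_cells:
            raise InvalidArgumentError(
                f"parameter column {name!r} has {col.size} rows, expected {n_cells}")

    base = dict(model.parameters)
    arrays = _trace_arrays(model, plan, n_cells)
    step = _make_stepper(model, plan)

    if plan.loop_structure is LoopStructure.TIME_CELL:
        block = pack(initial_states, plan.layout, plan.lane_width, model.state_names)
        width = block.active_view().shape[1]
        params = _pad_params(base, columns, 0, n_cells, width)
        _time_loop(model, block, plan, params, step, arrays, slice(None))
        return block, _trace(model, plan, arrays)

    if plan.loop_structure is LoopStructure.CELL_TIME:
        final = np.empty_like(initial_states)
        for c in range(n_cells):
            sub = pack(initial_states[c:c + 1], plan.layout, plan.lane_width,
                       model.state_names)
            width = sub.active_view().shape[1]
            params = _pad_params(base, columns, c, c + 1, width)
            _time_loop(model, sub, plan, params, step, arrays, slice(c, c + 1))
            final[c] = sub.unpack()[0]
        return (pack(final, plan.layout, plan.lane_width, model.state_names),
                _trace(model, plan, arrays))

    # CELL_TIME_CELL: batches of B cells; the last partial batch is padded by
    # replicating its final live row
    b = plan.batch_size
    final = np.empty_like(initial_states)
    for lo in range(0, n_cells, b):
        hi = min(lo + b, n_cells)
        rows = initial_states[lo:hi]
        if hi - lo < b:
            rows = np.concatenate(
                [rows, np.tile(rows[-1], (b - (hi - lo), 1))])
        sub = pack(rows, plan.layout, plan.lane_width, model.state_names)
        width = sub.active_view().shape[1]
        params = _pad_params(base, columns, lo, hi, width)
        sub_arrays = {v: np.empty((arr.shape[0], b)) for v, arr in arrays.items()}
        _time_loop(model, sub, plan, params, step, sub_arrays, slice(None))
        for v in arrays:
            arrays[v][:, lo:hi] = sub_arrays[v][:, : hi - lo]
        final[lo:hi] = sub.unpack()[: hi - lo]
    return (pack(final, plan.layout, plan.lane_width, model.state_names),
            _trace(model, plan, arrays))


def steady_state_check(trace: Trace, period: float, tolerance: float,
                       var: str = "v") -> tuple[bool, float]:
    """Compare the last two pacing periods of the recorded signal.

    ``deviation`` is the relative root-mean-square difference between the
    final period's samples and the preceding period's (the reference); for
    multi-cell traces it is the worst cell.  Steady state holds when the
    deviation is at most ``tolerance``.  The pacing period must be an
    integer multiple of the recording interval and the trace must span at
    least two periods.
    """
    if trace.times.size < 2:
        raise InvalidArgumentError("trace too short for a steady-state check")
    dt_rec = trace.times[1] - trace.times[0]
    ratio = period / dt_rec
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, abs(ratio)):
        raise InvalidArgumentError(
            "pacing period must be an integer multiple of the recording interval")
    n = int(round(ratio))
    if n < 1 or trace.times.size < 2 * n:
        raise InvalidArgumentError("trace must cover at least two pacing periods")
    sig = trace.data[var]
    last = sig[-n:]
    prev = sig[-2 * n:-n]
    dev = 0.0
    for c in range(sig.shape[1]):
        dev = max(dev, rrms_core(last[:, c], prev[:, c]))
    return dev <= tolerance, dev


def parameter_grid(grid: dict[str, list]) -> pd.DataFrame:
    """Cartesian product of per-parameter value lists.

    Row count is the product of the list lengths; the last parameter varies
    fastest, so the row order is deterministic.
    """
    names = list(grid)
    values = [list(v) for v in grid.values()]
    if not names or any(len(v) == 0 for v in values):
        raise InvalidArgumentError("every parameter needs at least one value")
    rows = list(itertools.product(*values))
    return pd.DataFrame(rows, columns=names, dtype=float)
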