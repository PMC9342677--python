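"""Multi-expression lookup tables and the partitioned LUT solver.

Expressions of a single state variable (typically the transmembrane
potential v) are pre-evaluated at S equally spaced nodes and stored as an
S x M row-major grid, so the two rows a query needs are contiguous in
memory.  Queries use two-point linear interpolation with one weight pair
shared by all M expressions:

    w_a = (v_b - v)/v_step,  w_b = 1 - w_a,  f(v) ~ w_a f(v_a) + w_b f(v_b).

For Rush-Larsen stepping, the per-gate coefficients a(v) and b(v) are
tabulated for a specific dt (the table carries a dt stamp and is rejected
for any other step size).  One LUT-based gate update then costs eight
floating-point operations: three per interpolated coefficient and two for
the a*w + b recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (ConstructionFailure, InvalidArgumentError, RangeError,
                     StaleTableError)
from .layouts import StateBlock, iter_batches
from .models import CellModel
from .schemes import _check_finite, rl_coefficients

__all__ = [
    "LookupTable",
    "InterpWeights",
    "LutFlopCount",
    "build_table",
    "weights",
    "interp",
    "build_rl_tables",
    "lut_rl_step",
    "partitioned_step",
    "gate_update_flops",
    "dump_table",
    "load_table",
]


def _grid(v_min: float, v_max: float, v_step: float) -> np.ndarray:
    if not (v_min < v_max):
        raise InvalidArgumentError("v_min must be < v_max")
    if not (v_step > 0):
        raise InvalidArgumentError("v_step must be > 0")
    ratio = (v_max - v_min) / v_step
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidArgumentError(
            f"range [{v_min}, {v_max}] is not commensurate with step {v_step}")
    s = int(round(ratio)) + 1
    nodes = v_min + np.arange(s) * v_step
    if abs(v_max - nodes[-1]) > 1e-9 * v_step:
        raise InvalidArgumentError("grid does not reach v_max within tolerance")
    return nodes


@dataclass
class LookupTable:
    """S x M row-major grid of expression values over one input variable."""

    input_name: str
    v_min: float
    v_max: float
    v_step: float
    nodes: np.ndarray
    values: np.ndarray
    column_labels: tuple[str, ...]
    dt_stamp: float | None = None
    out_of_range_count: int = field(default=0, compare=False)

    @property
    def S(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class InterpWeights:
    """Lower node index and the shared weight pair for one query."""

    lower_index: int
    w_a: float
    w_b: float


def build_table(exprs, v_min: float, v_max: float, v_step: float, *,
                input_name: str = "v", column_labels=None,
                dt_stamp: float | None = None) -> LookupTable:
    """Tabulate scalar expressions at equally spaced nodes.

    ``exprs`` is a sequence of vectorised scalar functions of the input.
    Raises :class:`ConstructionFailure` if any tabulated value is non-finite,
    naming the expression and node.
    """
    nodes = _grid(v_min, v_max, v_step)
    exprs = list(exprs)
    if not exprs:
        raise InvalidArgumentError("need at least one expression")
    if column_labels is None:
        column_labels = tuple(f"f{m}" for m in range(len(exprs)))
    column_labels = tuple(column_labels)
    if len(column_labels) != len(exprs):
        raise InvalidArgumentError("column_labels length must match exprs")
    values = np.empty((nodes.size, len(exprs)), dtype=float)
    for m, f in enumerate(exprs):
        col = np.asarray(f(nodes), dtype=float)
        col = np.broadcast_to(col, nodes.shape)
        if not np.all(np.isfinite(col)):
            bad = int(np.argwhere(~np.isfinite(col))[0][0])
            raise ConstructionFailure(
                f"expression {column_labels[m]!r} is non-finite at node "
                f"{nodes[bad]!r}", expression=column_labels[m],
                node=float(nodes[bad]))
        values[:, m] = col
    return LookupTable(input_name, float(v_min), float(v_max), float(v_step),
                       nodes, values, column_labels, dt_stamp)


def _weights_arrays(table: LookupTable, v, policy: str = "clamp"):
    """Vectorised (index, w_a, w_b) for queries ``v``; clamps or raises on
    out-of-range values depending on policy."""
    v = np.asarray(v, dtype=float)
    below = v < table.v_min
    above = v > table.v_max
    n_out = int(np.count_nonzero(below) + np.count_nonzero(above))
    if n_out:
        if policy == "strict":
            bad = float(v[below | above].flat[0])
            raise RangeError(
                f"query {bad} outside table range [{table.v_min}, {table.v_max}]",
                value=bad, bounds=(table.v_min, table.v_max))
        table.out_of_range_count += n_out
    vq = np.clip(v, table.v_min, table.v_max)
    i = np.floor((vq - table.v_min) / table.v_step).astype(int)
    i = np.clip(i, 0, table.S - 2)
    w_a = (table.nodes[i + 1] - vq) / table.v_step
    # snap exact node hits so sample-point queries return stored rows
    # bit-identically regardless of rounding in the index arithmetic
    w_a = np.where(vq == table.nodes[i], 1.0, w_a)
    w_a = np.where(vq == table.nodes[i + 1], 0.0, w_a)
    w_a = np.clip(w_a, 0.0, 1.0)
    return i, w_a, 1.0 - w_a


def weights(table: LookupTable, v: float, policy: str = "clamp") -> InterpWeights:
    """Interpolation weights for a single query value."""
    i, w_a, w_b = _weights_arrays(table, float(v), policy)
    return InterpWeights(int(i), float(w_a), float(w_b))


def interp(table: LookupTable, v, policy: str = "clamp") -> np.ndarray:
    """Interpolate all M expressions at ``v``.

    Returns shape ``(M,)`` for a scalar query or ``(n, M)`` for a vector of
    queries; one shared weight pair per query.
    """
    v = np.asarray(v, dtype=float)
    i, w_a, w_b = _weights_arrays(table, v, policy)
    rows_a = table.values[i]
    rows_b = table.values[i + 1]
    return w_a[..., None] * rows_a + w_b[..., None] * rows_b


DEFAULT_V_RANGE = (-100.0, 50.0)
DEFAULT_V_STEP = 0.05


def _gates_by_input(model: CellModel):
    out: dict[str, list] = {}
    for g in model.gates:
        out.setdefault(g.input_variable, []).append(g)
    return out


def build_rl_tables(model: CellModel, dt: float, *,
                    v_min: float = DEFAULT_V_RANGE[0],
                    v_max: float = DEFAULT_V_RANGE[1],
                    v_step: float = DEFAULT_V_STEP,
                    ranges: dict | None = None,
                    use_expm1: bool = True) -> dict[str, LookupTable]:
    """Build one dt-stamped table per tabulated input variable.

    Each table's columns are the Rush-Larsen ``(a, b)`` pair for every gate
    driven by that input (in gate order), followed by the model's auxiliary
    expressions of the same input.  The v default range is [-100, 50] with
    step 0.05; ``ranges`` maps an input name to a ``(v_min, v_max, v_step)``
    override (required for non-voltage inputs such as a calcium
    concentration, whose physiological range is different).
    """
    if not model.gates:
        raise InvalidArgumentError("model declares no gates")
    if dt < 0:
        raise InvalidArgumentError("dt must be >= 0")
    by_input = _gates_by_input(model)
    aux_by_input: dict[str, list] = {}
    for ax in model.auxiliary_lut_expressions:
        aux_by_input.setdefault(ax.input_variable, []).append(ax)
    tables: dict[str, LookupTable] = {}
    for input_name in model.lut_inputs:
        gates = by_input.get(input_name, [])
        auxes = aux_by_input.get(input_name, [])
        if not gates and not auxes:
            continue
        lo, hi, step = (ranges or {}).get(input_name, (v_min, v_max, v_step))
        nodes = _grid(lo, hi, step)
        for g in gates:
            tau = np.asarray(g.tau(nodes), dtype=float)
            if np.any(tau <= 0) or not np.all(np.isfinite(tau)):
                bad = int(np.argwhere((tau <= 0) | ~np.isfinite(tau))[0][0])
                raise ConstructionFailure(
                    f"tau for gate {model.state_names[g.state_index]!r} is "
                    f"not positive at node {nodes[bad]!r}",
                    expression=f"tau:{model.state_names[g.state_index]}",
                    node=float(nodes[bad]))
        exprs, labels = [], []
        for g in gates:
            wname = model.state_names[g.state_index]
            exprs.append(lambda x, g=g: rl_coefficients(g.winf(x), g.tau(x), dt, use_expm1)[0])
            labels.append(f"a:{wname}")
            exprs.append(lambda x, g=g: rl_coefficients(g.winf(x), g.tau(x), dt, use_expm1)[1])
            labels.append(f"b:{wname}")
        for ax in auxes:
            exprs.append(ax.fn)
            labels.append(f"aux:{ax.name}")
        tables[input_name] = build_table(exprs, lo, hi, step,
                                         input_name=input_name,
                                         column_labels=labels, dt_stamp=dt)
    return tables


def _check_stamps(tables, dt: float) -> None:
    for name, tab in tables.items():
        if tab.dt_stamp is not None and tab.dt_stamp != dt:
            raise StaleTableError(
                f"table for {name!r} was built for dt={tab.dt_stamp}, "
                f"step uses dt={dt}")


def _interp_tables(model: CellModel, s: np.ndarray, tables, policy: str):
    """Interpolate every table at the current input values.

    Returns (gate coefficient updates, auxiliary value dict).  Gate entries
    are ``(state_index, a, b)`` arrays over all lanes.
    """
    by_input = _gates_by_input(model)
    gate_coeffs = []
    aux_values: dict[str, np.ndarray] = {}
    for input_name, tab in tables.items():
        x = s[model.state_index(input_name)]
        vals = interp(tab, x, policy)  # (lanes, M)
        gates = by_input.get(input_name, [])
        for k, g in enumerate(gates):
            gate_coeffs.append((g.state_index, vals[..., 2 * k], vals[..., 2 * k + 1]))
        for m in range(2 * len(gates), tab.M):
            label = tab.column_labels[m]
            aux_values[label.removeprefix("aux:")] = vals[..., m]
    return gate_coeffs, aux_values


def lut_rl_step(model: CellModel, block: StateBlock, t: float, dt: float,
                tables: dict, params=None, *, policy: str = "clamp",
                step_index: int | None = None) -> StateBlock:
    """One Rush-Larsen step with table-interpolated gate coefficients.

    Gates update as ``w <- a w + b`` with (a, b) read from the dt-stamped
    tables; non-gate states use the FE rule on exact (non-tabulated)
    expressions.  A dt-stamp mismatch is rejected before any mutation.
    """
    if dt < 0:
        raise InvalidArgumentError("dt must be >= 0")
    _check_stamps(tables, dt)
    params = model.parameters if params is None else params
    s = block.active_view()
    gate_coeffs, aux_values = _interp_tables(model, s, tables, policy)
    d = model.rhs(t, s, params, aux=aux_values or None)
    _check_finite(d, block, step=step_index)
    gate_new = [(j, a * s[j] + b) for j, a, b in gate_coeffs]
    s[...] = s + dt * d
    for j, w_new in gate_new:
        s[j] = w_new
    return block


def partitioned_step(model: CellModel, block: StateBlock, t: float, dt: float,
                     tables: dict, params=None, *, policy: str = "clamp",
                     batch_size: int | None = None,
                     step_index: int | None = None) -> StateBlock:
    """LUT Rush-Larsen step organised as two passes over the cells.

    Pass one updates all non-gate states array-wide (the vectorisable part);
    pass two walks the cells in batches performing the table lookups for the
    gate states.  The arithmetic per element is identical to
    :func:`lut_rl_step`, only the traversal differs.
    """
    if dt < 0:
        raise InvalidArgumentError("dt must be >= 0")
    _check_stamps(tables, dt)
    params = model.parameters if params is None else params
    if batch_size is None:
        batch_size = max(32, block.lane_width)
        batch_size -= batch_size % block.lane_width
    s = block.active_view()

    # pass 1: array-wide non-gate computation (needs tabulated auxiliaries)
    _, aux_values = _interp_tables(model, s, tables, policy)
    d = model.rhs(t, s, params, aux=aux_values or None)
    _check_finite(d, block, step=step_index)
    pre_gate = {int(j): np.array(s[j]) for j in model.gate_indices}
    pre_input = {name: np.array(s[model.state_index(name)]) for name in tables}
    s[...] = s + dt * d
    by_input = _gates_by_input(model)

    # pass 2: batched table lookups for the gate states, all reads from the
    # captured pre-step values
    for batch in iter_batches(block, batch_size):
        lanes = slice(batch.start, batch.start + batch.live_lanes)
        for input_name, tab in tables.items():
            gates = by_input.get(input_name, [])
            if not gates:
                continue
            vals = interp(tab, pre_input[input_name][lanes], policy)
            for k, g in enumerate(gates):
                a = vals[..., 2 * k]
                b = vals[..., 2 * k + 1]
                s[g.state_index, lanes] = a * pre_gate[g.state_index][lanes] + b
    return block


@dataclass(frozen=True)
class LutFlopCount:
    """Analytic arithmetic cost of one LUT-based gate update."""

    per_interpolation: int = 3
    recurrence: int = 2
    coefficients_per_gate: int = 2

    @property
    def total(self) -> int:
        return self.coefficients_per_gate * self.per_interpolation + self.recurrence


def gate_update_flops() -> LutFlopCount:
    """Operation count of one lookup-table gate update.

    Two interpolations (a and b) at three floating-point operations each,
    plus two for the ``a w + b`` recurrence: eight in total.
    """
    return LutFlopCount()


# ---------------------------------------------------------------------------
# Text serialisation (lossless at 17 significant digits)


def dump_table(table: LookupTable, path) -> None:
    """Write a table as plain text: header lines then S whitespace-delimited
    rows; round-trips losslessly."""
    with open(path, "w") as fh:
        fh.write(f"input_name {table.input_name}\n")
        fh.write(f"v_min {table.v_min!r}\n")
        fh.write(f"v_max {table.v_max!r}\n")
        fh.write(f"v_step {table.v_step!r}\n")
        fh.write(f"dt_stamp {table.dt_stamp!r}\n")
        fh.write("columns " + " ".join(table.column_labels) + "\n")
        for row in table.values:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def load_table(path) -> LookupTable:
    with open(path) as fh:
        header = {}
        for _ in range(5):
            key, _, val = fh.readline().strip().partition(" ")
            header[key] = val
        cols = tuple(fh.readline().split()[1:])
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    dt_stamp = None if header["dt_stamp"] == "None" else float(header["dt_stamp"])
    v_min = float(header["v_min"])
    v_step = float(header["v_step"])
    nodes = v_min + np.arange(values.shape[0]) * v_step
    return LookupTable(header["input_name"], v_min, float(header["v_max"]),
                       v_step, nodes, values, cols, dt_stamp)
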