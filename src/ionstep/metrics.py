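"""Evaluation metrics and paired experiments.

Throughput is measured in cell steps per second,

    cell steps per second = (number of cells x number of time steps)
                            / solution time in seconds,

which makes runs of different sizes directly comparable.  Accuracy between
two solver configurations is the relative root-mean-square (RRMS) norm of
the recorded transmembrane potential against the reference arm,

    e_RRMS = sqrt(sum_i (v_i - v_i_ref)^2) / sqrt(sum_i (v_i_ref)^2),

summed over the recorded time steps.  Throughput numbers are reported, never
asserted against published figures: they are hardware-dependent by design.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np

from ._math import rrms_core
from .drivers import RunPlan, run_simulation
from .errors import InvalidArgumentError
from .layouts import StateBlock
from .models import CellModel

__all__ = [
    "SCHEMA_VERSION",
    "ThroughputReport",
    "AccuracyReport",
    "throughput",
    "rrms",
    "accuracy_experiment",
    "bench",
]

SCHEMA_VERSION = 1


def throughput(n_cells: int, n_steps: int, wall_seconds: float) -> float:
    """Cell steps per second."""
    if n_cells <= 0 or n_steps <= 0:
        raise InvalidArgumentError("n_cells and n_steps must be positive")
    if wall_seconds <= 0:
        raise InvalidArgumentError("wall_seconds must be positive")
    return n_cells * n_steps / wall_seconds


def rrms(v, v_ref) -> float:
    """Relative root-mean-square norm of ``v`` against the reference."""
    v = np.asarray(v, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v.shape != v_ref.shape or v.size == 0:
        raise InvalidArgumentError("series must have equal nonzero length")
    try:
        return rrms_core(v, v_ref)
    except ValueError as exc:
        raise InvalidArgumentError(str(exc)) from None


@dataclass
class ThroughputReport:
    n_cells: int
    n_steps: int
    wall_seconds: float
    cell_steps_per_second: float
    scheme: str
    layout: str
    loop_structure: str
    lut: bool
    repeats: int = 1
    schema_version: int = SCHEMA_VERSION

    def to_json(self, **kw) -> str:
        return json.dumps(self.__dict__, **kw)


@dataclass
class AccuracyReport:
    rrms_v: float
    max_abs_dev_v: float
    v_unit: str
    per_variable_rrms: dict[str, float]
    config_a: dict
    config_b: dict
    schema_version: int = SCHEMA_VERSION

    def to_json(self, **kw) -> str:
        return json.dumps(self.__dict__, **kw)


_ARM_KEYS = ("dt", "n_steps", "t0", "record_stride")


def accuracy_experiment(model: CellModel, block: StateBlock, plan_a: RunPlan,
                        plan_b: RunPlan, params=None,
                        var: str = "v") -> AccuracyReport:
    """Run two solver configurations from the same initial block and report
    the deviation of arm A from arm B (the reference).

    The two plans must share time stepping and recording (same dt, step
    count, start time and stride) so the traces align sample-for-sample; no
    resampling is performed.
    """
    for key in _ARM_KEYS:
        if getattr(plan_a, key) != getattr(plan_b, key):
            raise InvalidArgumentError(
                f"plans must agree on {key} for an aligned comparison")
    _, trace_a = run_simulation(model, block.copy(), plan_a, params)
    _, trace_b = run_simulation(model, block.copy(), plan_b, params)
    per_var = {}
    for name in trace_a.data:
        if name in trace_b.data:
            try:
                per_var[name] = rrms(trace_a.data[name].ravel(),
                                     trace_b.data[name].ravel())
            except InvalidArgumentError:
                per_var[name] = float("nan")
    va = trace_a.data[var]
    vb = trace_b.data[var]
    unit = "mV" if model.time_unit == "ms" else "model units"
    return AccuracyReport(
        rrms_v=rrms(va.ravel(), vb.ravel()),
        max_abs_dev_v=float(np.max(np.abs(va - vb))),
        v_unit=unit,
        per_variable_rrms=per_var,
        config_a=plan_a.to_dict(),
        config_b=plan_b.to_dict(),
    )


def bench(model: CellModel, block: StateBlock, plan: RunPlan, repeats: int = 3,
          params=None) -> ThroughputReport:
    """Time repeated identical runs and report best-of-repeats throughput.

    One warm-up run is excluded from timing; the timed runs all start from
    the same initial block and must produce bit-identical final states.
    """
    if repeats < 1:
        raise InvalidArgumentError("repeats must be >= 1")
    run_simulation(model, block.copy(), plan, params)  # warm-up
    best = np.inf
    reference = None
    for _ in range(repeats):
        work = block.copy()
        start = time.perf_counter()
        run_simulation(model, work, plan, params)
        elapsed = time.perf_counter() - start
        best = min(best, elapsed)
        final = work.unpack()
        if reference is None:
            reference = final
        elif not np.array_equal(reference, final):
            raise AssertionError("repeated runs were not bit-identical")
    return ThroughputReport(
        n_cells=block.n_cells,
        n_steps=plan.n_steps,
        wall_seconds=best,
        cell_steps_per_second=throughput(block.n_cells, max(plan.n_steps, 1), best),
        scheme=plan.scheme,
        layout=plan.layout.value,
        loop_structure=plan.loop_structure.value,
        lut=plan.lut,
        repeats=repeats,
    )
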