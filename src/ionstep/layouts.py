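"""State storage layouts for blocks of cells.

The natural "array of structs" (AoS) layout keeps the N state variables of
one cell contiguous; the vectorisation-friendly "struct of arrays" (SoA)
layout keeps one state variable of all C cells contiguous, padding each
per-state run to a multiple of the lane width L so every run starts aligned.
Padded lanes replicate the last live cell so they stay finite under any
model arithmetic, and they never contribute to reported output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "Layout",
    "StateBlock",
    "BatchView",
    "padded_width",
    "pack",
    "convert",
    "iter_batches",
    "read_states_csv",
    "write_states_csv",
]


class Layout(str, enum.Enum):
    AOS = "aos"
    SOA = "soa"


def padded_width(n_cells: int, lane_width: int) -> int:
    """Smallest multiple of ``lane_width`` that is >= ``n_cells``.

    The count of padded lanes is ``(L - C mod L) mod L``; a cell count that
    is already a multiple of L gets no padding.
    """
    if n_cells < 1 or lane_width < 1:
        raise InvalidArgumentError("n_cells and lane_width must be positive")
    return n_cells + (lane_width - n_cells % lane_width) % lane_width


@dataclass
class StateBlock:
    """Padded storage for N state variables of C cells.

    ``storage`` is one contiguous 1D float64 buffer: for SoA, N runs of
    ``padded_cells`` values (one per state variable); for AoS, C runs of N
    values (one per cell, no padding).
    """

    layout: Layout
    n_cells: int
    n_states: int
    lane_width: int
    padded_cells: int
    storage: np.ndarray
    state_names: tuple[str, ...] | None = None

    def active_view(self) -> np.ndarray:
        """Writable ``(N, lanes)`` view the steppers operate on.

        For SoA this includes the padded lanes (they are computed along with
        the live cells, exactly as an array-wide kernel would); for AoS it is
        the transposed ``(N, C)`` view of the cell-major buffer.
        """
        if self.layout is Layout.SOA:
            return self.storage.reshape(self.n_states, self.padded_cells)
        return self.storage.reshape(self.n_cells, self.n_states).T

    def live_view(self) -> np.ndarray:
        """Writable ``(N, C)`` view of the live cells only."""
        return self.active_view()[:, : self.n_cells]

    def unpack(self) -> np.ndarray:
        """Return the live cells as a fresh ``(C, N)`` table."""
        return np.array(self.live_view().T, dtype=float)

    def copy(self) -> "StateBlock":
        return StateBlock(self.layout, self.n_cells, self.n_states,
                          self.lane_width, self.padded_cells,
                          self.storage.copy(), self.state_names)


@dataclass(frozen=True)
class BatchView:
    """One tile of ``batch_size`` consecutive cells of a parent block."""

    parent: StateBlock
    batch_index: int
    batch_size: int
    start: int
    live_lanes: int


def pack(table: np.ndarray, layout: Layout | str = Layout.SOA,
         lane_width: int = 8, state_names: tuple[str, ...] | None = None) -> StateBlock:
    """Pack a ``(C, N)`` per-cell state table into a :class:`StateBlock`.

    SoA padded lanes replicate the last live cell's values so padding is
    safe to evaluate; AoS has no padding.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise InvalidArgumentError("state table must be a non-empty (C, N) array")
    layout = Layout(layout)
    n_cells, n_states = table.shape
    if layout is Layout.SOA:
        c_pad = padded_width(n_cells, lane_width)
        arr = np.empty((n_states, c_pad), dtype=float)
        arr[:, :n_cells] = table.T
        if c_pad > n_cells:
            arr[:, n_cells:] = table.T[:, -1:]
        storage = arr.reshape(-1)
    else:
        c_pad = n_cells
        storage = np.array(table, dtype=float).reshape(-1)
    return StateBlock(layout, n_cells, n_states, lane_width, c_pad,
                      storage, state_names)


def convert(block: StateBlock, target: Layout | str) -> StateBlock:
    """Re-pack a block into the target layout; live cells are preserved
    bit-identically."""
    target = Layout(target)
    return pack(block.unpack(), target, block.lane_width, block.state_names)


def iter_batches(block: StateBlock, batch_size: int):
    """Tile ``[0, C)`` into :class:`BatchView` tiles of ``batch_size`` cells.

    ``batch_size`` must be a multiple of the lane width; the final tile may
    have fewer live lanes than its width.
    """
    if batch_size < 1 or batch_size % block.lane_width != 0:
        raise InvalidArgumentError(
            f"batch size {batch_size} must be a positive multiple of the "
            f"lane width {block.lane_width}")
    n_batches = -(-block.n_cells // batch_size)
    for b in range(n_batches):
        start = b * batch_size
        live = min(batch_size, block.n_cells - start)
        yield BatchView(block, b, batch_size, start, live)


def read_states_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a per-cell state table (one row per cell, one column per state)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_states_csv(path, table: np.ndarray, state_names) -> None:
    pd.DataFrame(np.asarray(table, dtype=float), columns=list(state_names)).to_csv(
        path, index=False, float_format="%.17g")
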