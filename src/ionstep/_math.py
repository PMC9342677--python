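"""Shared numerical kernels.

Every occurrence of ``e^x - 1`` in the package is routed through :func:`em1`
so that a single flag switches between ``expm1(x)`` (accurate near zero) and
the literal ``exp(x) - 1`` (the form produced when only a plain vectorised
``exp`` is available).  The default is the accurate path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["em1", "phi", "pulse_current", "rrms_core"]


def rrms_core(v, v_ref):
    """Relative root-mean-square deviation of ``v`` from ``v_ref``:
    ``sqrt(sum((v - v_ref)^2)) / sqrt(sum(v_ref^2))``."""
    v = np.asarray(v, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    denom = np.sqrt(np.sum(v_ref * v_ref))
    if denom == 0.0:
        raise ValueError("reference series is identically zero")
    return float(np.sqrt(np.sum((v - v_ref) ** 2)) / denom)


def em1(x, use_expm1: bool = True):
    """Evaluate ``e^x - 1`` elementwise.

    Parameters
    ----------
    x : array_like
        Exponent(s).
    use_expm1 : bool
        If True (default) use ``numpy.expm1``; otherwise compute the
        cancellation-prone ``exp(x) - 1`` literally.
    """
    if use_expm1:
        return np.expm1(x)
    return np.exp(x) - 1.0


def phi(x, use_expm1: bool = True):
    """The exponential-integrator weight ``(e^x - 1)/x`` with ``phi(0) = 1``.

    Exact zeros map to exactly 1.0 so that a zero diagonal reduces the GRL1
    update to forward Euler bit-for-bit.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    if np.any(nz):
        xv = x[nz]
        out[nz] = em1(xv, use_expm1) / xv
    return out


def pulse_current(t, amplitude, start, duration, period):
    """Rectangular stimulus pulse train.

    Returns ``amplitude`` when ``(t - start) mod period`` lies in
    ``[0, duration]`` (closed interval, and only for ``t >= start``), else 0.
    ``period = inf`` encodes a single pulse.
    """
    t = np.asarray(t, dtype=float)
    rel = t - start
    finite = np.isfinite(period) if np.ndim(period) == 0 else np.isfinite(period)
    if np.ndim(period) == 0:
        tm = np.mod(rel, period) if finite else rel
    else:
        tm = np.where(np.isfinite(period), np.mod(rel, np.where(np.isfinite(period), period, 1.0)), rel)
    on = (rel >= 0.0) & (tm >= 0.0) & (tm <= duration)
    return np.where(on, amplitude, 0.0)
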