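"""Multiple-testing adjustment shared by the methylation and expression stages.

A single Benjamini-Hochberg implementation is used everywhere a false
discovery rate is controlled, so the two omics stages are guaranteed to
apply the identical procedure.  ``NaN`` p-values (untestable features,
e.g. all-zero genes) are excluded from the adjustment and propagate as
``NaN`` adjusted values.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["bh_adjust", "register_qvalue_method", "adjust_pvalues"]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Equivalent to the textbook definition ``q_(i) = min_{j >= i} m * p_(j) / j``
    on the sorted p-values, clipped at 1.  The number of tests ``m`` counts
    only the non-NaN entries.

    Parameters
    ----------
    pvalues:
        1-D array of raw p-values in [0, 1]; NaN allowed.

    Returns
    -------
    numpy.ndarray
        Adjusted values, same shape, NaN where the input was NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D p-value vector")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    ps = p[mask]
    if ps.size == 0:
        return out
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


_QVALUE_METHODS: dict[str, Callable[[np.ndarray], np.ndarray]] = {"bh": bh_adjust}


def register_qvalue_method(name: str, func: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an alternative q-value procedure under ``name``.

    The per-site methylation test exposes a hook so users preferring a
    different q-value estimator (e.g. a SLIM-style sliding linear model)
    can plug one in without touching the testing code.
    """
    _QVALUE_METHODS[name] = func


def adjust_pvalues(pvalues: np.ndarray, method: str = "bh") -> np.ndarray:
    """Dispatch to a registered q-value method (default Benjamini-Hochberg)."""
    try:
        func = _QVALUE_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown q-value method {method!r}; registered: {sorted(_QVALUE_METHODS)}"
        ) from None
    return func(np.asarray(pvalues, dtype=float))
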