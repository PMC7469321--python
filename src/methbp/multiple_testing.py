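"""Benjamini-Hochberg false-discovery-rate adjustment."""

from __future__ import annotations

import numpy as np


def bh_qvalues(p) -> np.ndarray:
    """Step-up BH q-values for a family of p-values.

    With the p-values sorted ascending, ``q(i) = min_{j >= i} p(j) * m / j``,
    mapped back to the input order (stable sort for ties). Values are
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
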