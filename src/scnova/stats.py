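"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values).

    NaN entries are ignored for ranking and returned as NaN. Implements
    q_(i) = min_{j>=i} p_(j) * m / j over the m non-missing p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def activity_score(log2fc, pvalues) -> np.ndarray:
    """Differential gene activity score: sign(FC) * (-log10 p)."""
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sign(fc) * (-np.log10(p))
    return s
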