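"""Small shared numerics: reporting-grade rounding and BH-FDR."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from statsmodels.stats.multitest import multipletests


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tables in the dairy literature do.

    Python's builtin round() is banker's rounding; reported means/CVs use
    half-up.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, q >= p elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def as_1d_float(x, name: str = "values") -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return a
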