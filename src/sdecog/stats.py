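"""Contingency-table inference for prevalence comparisons.

Both tests are written out explicitly (Pearson statistic; exact two-sided
hypergeometric summation) so their behaviour is fully specified; the test
suite cross-checks them against an independent statistics library and a
brute-force enumeration oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .simulate import ParameterError

__all__ = ["chi_squared_2x2", "fisher_exact_2x2"]

_REL_TIE = 1.0 + 1e-9  # tolerance for "probability <= observed" ties


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ParameterError("table entries must be non-negative integers")
    return t.astype(np.int64)


def chi_squared_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table.

    Returns (statistic, upper-tail p) with df = 1. Yates continuity
    correction is off by default and available via ``correction=True``.
    Requires every expected count > 0 (i.e. no zero margin).
    """
    t = _validate_table(table)
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if n == 0 or np.any(row == 0) or np.any(col == 0):
        raise ParameterError("zero margin: expected counts must all be > 0")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sstats.chi2.sf(stat, df=1))
    return stat, p


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's. Degenerate tables
    (a zero margin) carry no information and return p = 1.
    """
    t = _validate_table(table)
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    dist = sstats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * _REL_TIE].sum())
    return min(p, 1.0)
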