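"""Small statistical helpers shared across modules."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = ["fisher_exact_2x2"]

_LGFACT = gammaln(np.arange(256) + 1.0)  # log k! lookup, grown on demand


def _logfact(n: int) -> np.ndarray:
    global _LGFACT
    if n >= _LGFACT.size:
        _LGFACT = gammaln(np.arange(2 * n) + 1.0)
    return _LGFACT


def _canonical(a: int, b: int, c: int, d: int) -> tuple[int, int, int, int]:
    """Lexicographically smallest table under row swap / column swap /
    transpose — all of which leave the two-sided Fisher p unchanged."""
    forms = []
    for t in ((a, b, c, d), (a, c, b, d)):          # identity, transpose
        x, y, z, w = t
        for r in ((x, y, z, w), (z, w, x, y)):      # row swap
            p, q, r2, s = r
            forms.append((p, q, r2, s))
            forms.append((q, p, s, r2))             # column swap
    return min(forms)


@lru_cache(maxsize=1 << 20)
def _p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided hypergeometric p: sum of outcome probabilities not
    exceeding the observed one. Ties (e.g. the mirror outcome of a
    symmetric table) are recognized with a 1e-11 relative tolerance,
    wide enough to absorb log-gamma rounding in the pmf and far below
    any genuine probability gap at these table sizes."""
    n1, n2, n = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or n == 0 or b + d == 0:
        return 1.0
    lg = _logfact(n1 + n2)

    def log_comb(m, k):
        return lg[m] - lg[k] - lg[m - k]

    lo, hi = max(0, n - n2), min(n, n1)
    k = np.arange(lo, hi + 1)
    logpmf = log_comb(n1, k) + log_comb(n2, n - k) - log_comb(n1 + n2, n)
    observed = logpmf[a - lo]
    p = float(np.exp(logpmf[logpmf <= observed + 1e-11]).sum())
    return min(p, 1.0)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (sample odds ratio, p). The p-value is computed on the
    symmetry-canonicalized table and cached, so permuted tables give
    bitwise-identical p and repeated calls are cheap.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in contingency table")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = _p_two_sided(*_canonical(int(a), int(b), int(c), int(d)))
    return float(odds), p
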