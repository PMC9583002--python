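"""Correlation statistics for affinity analyses.

Pearson correlation (scipy) and the Dunn & Clark (1969) z-test for
comparing two *dependent, overlapping* correlations r12 and r13 sharing
variable 1, measured on the same n subjects.  The test Fisher-transforms
both correlations and accounts for their covariance, which depends on
the intercorrelation r23 of the two non-shared variables:

    c = [ r23 (1 − r12² − r13²) − ½ r12 r13 (1 − r12² − r13² − r23²) ]
        / [ (1 − r12²)(1 − r13²) ]
    z = (atanh(r12) − atanh(r13)) · sqrt( (n − 3) / (2 − 2c) )

with a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "pearson", "dunn_clark_test"]


@dataclass
class CorrelationResult:
    rho: float | None
    p_value: float
    n: int
    z: float | None = None


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(rho=float(r), p_value=float(p), n=len(x))


def dunn_clark_test(
    r12: float, r13: float, r23: float, n: int
) -> CorrelationResult:
    """Dunn–Clark z for H0: ρ12 = ρ13 with a shared variable.

    ``r12`` and ``r13`` are the two correlations being compared (both
    involving variable 1); ``r23`` is the correlation between variables
    2 and 3 on the same ``n`` subjects.  The z sign follows r12 − r13.
    """
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(r12) == 1.0 or abs(r13) == 1.0:
        raise ValueError("degenerate correlation |r| = 1")
    if n < 4:
        raise ValueError("need n ≥ 4")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    num = r23 * (1 - r12**2 - r13**2) - 0.5 * r12 * r13 * (
        1 - r12**2 - r13**2 - r23**2
    )
    c = num / ((1 - r12**2) * (1 - r13**2))
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationResult(rho=None, p_value=float(p), n=n, z=float(z))
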