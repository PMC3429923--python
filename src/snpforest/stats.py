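"""Small statistical primitives shared by the epistasis and LD stages.

Two tools live here: a one-sample Student t-test with explicit conventions
for degenerate inputs, and Storey's q-value transform with a fixed-lambda
pi0 estimator. Both are deliberately self-contained so that the multiple
testing behaviour of the pipeline is pinned to one definition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["one_sample_t", "storey_qvalue", "QValueResult"]


def one_sample_t(x) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean(x) == 0.

    Returns ``(t, p)`` with ``t = mean / (sd / sqrt(n))`` (sd uses the n-1
    denominator) and p from the t distribution with n-1 degrees of freedom.

    Degenerate samples follow a fixed convention: zero spread around a zero
    mean gives (0, 1); zero spread around a nonzero mean gives a signed
    infinite t with p = 0 (logged, since it usually signals an upstream
    problem such as identical replicate fits).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one_sample_t needs a 1-d sample of length >= 2")
    n = x.size
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0
        logger.warning("one_sample_t: zero variance around nonzero mean %g", m)
        return math.copysign(math.inf, m), 0.0
    t = m / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return t, float(min(p, 1.0))


@dataclass(frozen=True)
class QValueResult:
    """Storey q-values for a family of p-values.

    pi0 is the estimated proportion of true nulls; q_values align with the
    input order; lam is the tuning constant used for the pi0 estimate.
    """

    pi0: float
    q_values: np.ndarray
    lam: float


def storey_qvalue(pvals, lam: float = 0.5, pi0: float | None = None) -> QValueResult:
    """Storey q-values with the fixed-lambda pi0 estimator.

    pi0 is estimated as ``#{p > lam} / ((1 - lam) * m)``, clipped to
    ``[1/m, 1]`` (an estimate of exactly zero nulls is not usable in the
    q-value recursion and cannot be distinguished from noise at these family
    sizes). Pass ``pi0=1.0`` to reproduce Benjamini-Hochberg adjusted
    p-values exactly.

    The q-value of the i-th smallest p is ``min(pi0 * m * p_(i) / i,
    q_(i+1))``: the familiar step-up transform scaled by pi0.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("storey_qvalue needs a non-empty 1-d vector")
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly in (0, 1)")
    m = p.size
    if pi0 is None:
        pi0 = float(np.sum(p > lam)) / ((1.0 - lam) * m)
        pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    elif not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.empty(m, dtype=float)
    q_sorted[m - 1] = min(pi0 * ps[m - 1], 1.0)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(pi0 * m * ps[i] / (i + 1), q_sorted[i + 1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return QValueResult(pi0=pi0, q_values=q, lam=lam)
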