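"""Random-effects meta-analysis primitives.

Standardized mean differences (Hedges' g), DerSimonian–Laird pooling with
Cochran's Q and I² heterogeneity, Fisher-z pooling of correlation
coefficients, and Benjamini–Hochberg FDR adjustment.  These are the atoms
every multi-cohort stage of the pipeline (diversity, ordination axes,
interkingdom correlations) feeds into.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StudyEffect",
    "RandomEffectsResult",
    "hedges_g",
    "dl_pool",
    "fisher_z_effect",
    "pool_correlation",
    "bh_adjust",
]


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate with its sampling variance.

    ``estimate`` is on whatever scale the effect lives on (Hedges' g for
    standardized mean differences, atanh(r) for correlations); ``variance``
    is the squared standard error of that estimate.
    """

    estimate: float
    variance: float
    n1: int = 0
    n2: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise ValueError("effect estimate must be finite")
        if not (self.variance > 0):
            raise ValueError(f"sampling variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class RandomEffectsResult:
    """DerSimonian–Laird pooled effect with heterogeneity statistics."""

    mu_hat: float
    se: float
    ci95: tuple[float, float]
    z: float
    p: float
    tau2: float
    q: float
    df: int
    q_p: float
    i2: float
    k: int
    weights: tuple[float, ...] = field(default=(), repr=False)


def hedges_g(control: Sequence[float], case: Sequence[float],
             correct: bool = True, label: str = "") -> StudyEffect:
    """Standardized mean difference of case vs control (positive = higher in cases).

    g = J * (mean_case - mean_control) / s_pooled with the small-sample
    correction J = 1 - 3/(4*nu - 1), nu = n1 + n2 - 2.  Sampling variance
    v = (n1 + n2)/(n1*n2) + g^2 / (2*(n1 + n2)).

    Set ``correct=False`` for Cohen's d (no bias correction).
    """
    x = np.asarray(control, dtype=float)
    y = np.asarray(case, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both arms need at least 2 observations")
    nu = n1 + n2 - 2
    s2_pooled = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / nu
    if s2_pooled <= 0:
        raise ValueError("pooled variance is zero; SMD undefined")
    d = (y.mean() - x.mean()) / math.sqrt(s2_pooled)
    j = 1.0 - 3.0 / (4.0 * nu - 1.0) if correct else 1.0
    g = j * d
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return StudyEffect(estimate=g, variance=v, n1=n1, n2=n2, label=label)


def dl_pool(effects: Sequence[StudyEffect]) -> RandomEffectsResult:
    """DerSimonian–Laird random-effects pooling.

    Method-of-moments between-study variance:
        Q   = sum w_i (y_i - ybar_w)^2           with fixed weights w_i = 1/v_i
        tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))
    then random-effects weights w*_i = 1/(v_i + tau2),
    mu_hat = sum(w* y)/sum(w*), se = 1/sqrt(sum w*), and
    I^2 = max(0, (Q - df)/Q) * 100.
    """
    if len(effects) < 2:
        raise ValueError("need at least 2 studies to pool")
    y = np.array([e.estimate for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = len(effects) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    mu_hat = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = mu_hat / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q_p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return RandomEffectsResult(
        mu_hat=mu_hat,
        se=se,
        ci95=(mu_hat - 1.96 * se, mu_hat + 1.96 * se),
        z=z,
        p=p,
        tau2=tau2,
        q=q,
        df=df,
        q_p=q_p,
        i2=i2,
        k=len(effects),
        weights=tuple(float(x) for x in w_star),
    )


def fisher_z_effect(r: float, n: int, label: str = "") -> StudyEffect:
    """Fisher z-transformed correlation: y = atanh(r), v = 1/(n - 3)."""
    if not abs(r) < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    if n <= 3:
        raise ValueError(f"need n >= 4 for a Fisher-z variance, got n={n}")
    return StudyEffect(estimate=math.atanh(r), variance=1.0 / (n - 3),
                       n1=n, n2=0, label=label)


def pool_correlation(effects: Sequence[StudyEffect]) -> tuple[float, float, RandomEffectsResult]:
    """Pool Fisher-z correlation effects; back-transform the mean via tanh.

    Returns (pooled r, p-value of the z-scale test of zero correlation,
    full z-scale RandomEffectsResult).
    """
    res = dl_pool(effects)
    return math.tanh(res.mu_hat), res.p, res


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
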