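"""Alpha-diversity statistics and per-study disease association.

Shannon index (nats), Heip evenness, Chao1 richness, the two-tailed
Wilcoxon rank-sum test used for per-study case-control comparison, and
naive / covariate-adjusted linear models of log-transformed diversity on
disease status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "shannon",
    "heip_evenness",
    "chao1",
    "observed_richness",
    "diversity_table",
    "wilcoxon_rank_sum",
    "disease_lm",
    "DiseaseAssociation",
]

#: additive guard inside the log transform of diversity values, so samples
#: with zero diversity stay in the linear models
LOG_EPS = 1e-6


def _positive(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if not (x > 0).any():
        raise ValueError("all-zero abundance vector")
    return x


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i in nats, over positive entries."""
    x = _positive(counts)
    p = x[x > 0] / x.sum()
    return float(-np.sum(p * np.log(p)))


def observed_richness(counts) -> int:
    """Number of taxa with a positive count."""
    return int(np.count_nonzero(_positive(counts) > 0))


def heip_evenness(counts) -> float:
    """Heip evenness (e^H - 1)/(S - 1); equals 1 for a uniform community.

    Defined as 0 when only a single taxon is present (the S = 1 case is
    degenerate; a one-taxon community carries no evenness information).
    """
    x = _positive(counts)
    s = observed_richness(x)
    if s == 1:
        return 0.0
    return float((math.exp(shannon(x)) - 1.0) / (s - 1))


def chao1(counts) -> float:
    """Chao1 richness from singleton (f1) and doubleton (f2) counts.

    S + f1^2/(2 f2) when doubletons exist, otherwise the bias-corrected
    form S + f1 (f1 - 1) / (2 (f2 + 1)).  Requires integer counts.
    """
    x = _positive(counts)
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 requires integer counts")
    s = observed_richness(x)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f2 > 0:
        return float(s + f1 * f1 / (2.0 * f2))
    return float(s + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity of a taxa x samples count matrix."""
    rows = {}
    for sample in counts.columns:
        v = counts[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(v),
            "heip_evenness": heip_evenness(v),
            "chao1": chao1(v),
            "richness": observed_richness(v),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for combined n <= 12 without ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass(frozen=True)
class DiseaseAssociation:
    """Disease-term coefficient from a linear model of log diversity."""

    coefficient: float
    p_value: float
    se: float
    model: str  # "naive" or "adjusted"
    n: int


def disease_lm(diversity, metadata: pd.DataFrame, adjusted: bool = False) -> DiseaseAssociation:
    """OLS of Y = ln(diversity + eps) on disease (plus age/gender/BMI if adjusted).

    ``metadata`` needs a ``group`` column with exactly two levels, coded so
    that "CRC" (or alphabetically the later level) is 1; adjusted mode also
    needs ``age``, ``gender`` and ``bmi`` columns.  Returns the disease-term
    coefficient and its two-sided t-test p-value.
    """
    d = np.asarray(diversity, dtype=float)
    if len(d) != len(metadata):
        raise ValueError("diversity and metadata lengths differ")
    y = np.log(d + LOG_EPS)
    groups = metadata["group"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    # disease = 1 for the case level; 'CRC' beats 'control' both by convention
    # and alphabetically (uppercase sorts first), so pin the case level explicitly
    case_level = "CRC" if "CRC" in levels else levels[1]
    disease = (groups == case_level).astype(float).to_numpy()
    cols = {"disease": disease}
    if adjusted:
        missing = [c for c in ("age", "gender", "bmi") if c not in metadata.columns]
        if missing:
            raise ValueError(f"adjusted model needs covariates: {missing}")
        cols["age"] = metadata["age"].astype(float).to_numpy()
        gender = metadata["gender"]
        if gender.dtype == object:
            gender = (gender.astype(str).str.lower().isin(["male", "m", "1"])).astype(float)
        cols["gender"] = np.asarray(gender, dtype=float)
        cols["bmi"] = metadata["bmi"].astype(float).to_numpy()
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix (columns: {list(X.columns)})")
    fit = sm.OLS(y, X).fit()
    return DiseaseAssociation(
        coefficient=float(fit.params["disease"]),
        p_value=float(fit.pvalues["disease"]),
        se=float(fit.bse["disease"]),
        model="adjusted" if adjusted else "naive",
        n=len(y),
    )
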