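"""Two-group negative-binomial differential abundance testing.

A deliberately transparent stand-in for the count-model testing packages
used in RNA-seq-style microbiome analysis: median-of-ratios size factors,
per-taxon method-of-moments dispersion on the scaled counts, and a hybrid
test — an exact conditional negative-binomial test on the group sums when
the total count is small, a Wald test on the log-mean difference
otherwise — followed by Benjamini–Hochberg adjustment.  Outputs are meant
to be consumed qualitatively (ranked taxa, q < 0.05 sets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_adjust

__all__ = ["size_factors", "nb_test", "intersect_significant"]

#: dispersion floor; below this the Poisson limit is used in the exact test
MIN_DISPERSION = 1e-8
#: exact conditional test used when the (scaled, rounded) total is at most this
EXACT_TOTAL_MAX = 1000
#: pseudo-count guarding the log2 fold change against zero group means
LFC_PSEUDO = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean pseudo-reference).

    For each sample, the factor is the median over taxa of
    count / geometric-mean-across-samples, taken over taxa with no zero
    count in any sample (so the geometric mean is well defined).
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no taxon is positive in every sample; median-of-ratios undefined "
            "(consider a pseudo-reference or stronger prevalence filtering)"
        )
    ref = x[all_positive]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(scaled: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha with var = m + alpha m^2."""
    m = scaled.mean()
    v = scaled.var(ddof=1)
    if m <= 0:
        return MIN_DISPERSION
    return max(MIN_DISPERSION, (v - m) / (m * m))


def _exact_conditional_p(s_obs: int, total: int, n1: int, n2: int,
                         mu: float, alpha: float) -> float:
    """Two-sided exact NB test of equal group means, conditional on the total.

    Group sums of n i.i.d. NB(mu, alpha) counts are NB with size n/alpha.
    The p-value sums, over all splits s + (total - s) = total, the
    probabilities no larger than that of the observed split (the
    "doubletail by probability mass" convention).  In the small-dispersion
    limit the conditional law is Binomial(total, n1/(n1+n2)).
    """
    s = np.arange(total + 1)
    if alpha < 1e-4:
        # Poisson limit: conditional distribution is exactly binomial
        logp = stats.binom.logpmf(s, total, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / alpha, n2 / alpha
        p_nb = 1.0 / (1.0 + alpha * mu)  # per-unit success prob, shared by both groups
        logp = stats.nbinom.logpmf(s, r1, p_nb) + stats.nbinom.logpmf(total - s, r2, p_nb)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(min(1.0, prob[prob <= prob[s_obs] * (1 + 1e-12)].sum()))


def _wald_p(scaled1: np.ndarray, scaled2: np.ndarray, alpha: float) -> float:
    """Wald test of equal means on the log scale, delta-method variance."""
    n1, n2 = scaled1.size, scaled2.size
    m1 = scaled1.mean() + LFC_PSEUDO
    m2 = scaled2.mean() + LFC_PSEUDO
    # var(log mean_g) ~= (m + alpha m^2) / (n m^2)
    v1 = (m1 + alpha * m1 * m1) / (n1 * m1 * m1)
    v2 = (m2 + alpha * m2 * m2) / (n2 * m2 * m2)
    z = (np.log(m2) - np.log(m1)) / np.sqrt(v1 + v2)
    # t reference with n1+n2-2 df rather than normal: guards small-sample
    # anticonservatism of the plug-in dispersion
    return float(2.0 * stats.t.sf(abs(z), n1 + n2 - 2))


def nb_test(counts: pd.DataFrame, groups, sf: pd.Series | None = None,
            case_level: str | None = None) -> pd.DataFrame:
    """Per-taxon two-group differential abundance test.

    Returns a DataFrame indexed by taxon with base_mean, log2_fc
    (case vs control), p, q (BH) and the test used per taxon.  Exactly two
    groups are required; ``case_level`` names the case group (default:
    "CRC" if present, else the alphabetically later level).
    """
    groups = pd.Series(np.asarray(groups).astype(str), index=counts.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if case_level is None:
        case_level = "CRC" if "CRC" in levels else levels[1]
    elif case_level not in levels:
        raise ValueError(f"case level {case_level!r} not among {levels}")
    control_level = next(l for l in levels if l != case_level)
    if (groups == case_level).sum() < 2 or (groups == control_level).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if sf is None:
        sf = size_factors(counts)
    sf = sf.reindex(counts.columns)
    x = counts.to_numpy(dtype=float)
    scaled = x / sf.to_numpy()
    is_case = (groups == case_level).to_numpy()
    # group-balance recentering: under the usual assumption that most taxa are
    # not differentially abundant, the median per-taxon log-ratio of group
    # means should be zero; one-directional planted effects otherwise leak a
    # small systematic shift into every null taxon through the size factors.
    # The split (case / 2^(m/2), control * 2^(m/2)) makes the adjusted matrix
    # identical under a group-label swap, so log2FC negates and p is preserved
    # exactly.
    med_lfc = np.median(np.log2(
        (scaled[:, is_case].mean(axis=1) + LFC_PSEUDO)
        / (scaled[:, ~is_case].mean(axis=1) + LFC_PSEUDO)))
    adj = scaled.copy()
    adj[:, is_case] /= 2.0 ** (med_lfc / 2.0)
    adj[:, ~is_case] *= 2.0 ** (med_lfc / 2.0)

    rows = []
    for t in range(scaled.shape[0]):
        s_case = adj[t, is_case]
        s_ctrl = adj[t, ~is_case]
        base_mean = scaled[t].mean()
        lfc = float(np.log2((s_case.mean() + LFC_PSEUDO) / (s_ctrl.mean() + LFC_PSEUDO)))
        if scaled[t].max() == scaled[t].min():
            # constant taxon: no information against equal means
            rows.append((base_mean, lfc, 1.0, "constant"))
            continue
        if scaled[t].sum() <= EXACT_TOTAL_MAX:
            # exact branch conditions on (rounded) size-factor-scaled sums
            # without recentering, as a conditional test needs integer counts
            alpha = _mom_dispersion(scaled[t])
            s1 = int(round(scaled[t, ~is_case].sum()))
            s2 = int(round(scaled[t, is_case].sum()))
            total = s1 + s2
            if total == 0:
                rows.append((base_mean, lfc, 1.0, "exact"))
                continue
            mu = total / scaled.shape[1]
            p = _exact_conditional_p(s1, total, int((~is_case).sum()),
                                     int(is_case.sum()), mu, alpha)
            rows.append((base_mean, lfc, p, "exact"))
        else:
            rows.append((base_mean, lfc, _wald_p(s_ctrl, s_case, _mom_dispersion(adj[t])),
                         "wald"))

    out = pd.DataFrame(
        rows, index=counts.index,
        columns=["base_mean", "log2_fc", "p", "test"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["base_mean", "log2_fc", "p", "q", "test"]]


def intersect_significant(per_study: dict[str, pd.DataFrame], q_max: float = 0.05) -> pd.DataFrame:
    """Count, per taxon, in how many studies it is significant (q < q_max).

    Mirrors intersecting per-dataset significant sets: the output has one
    row per taxon significant anywhere, with the number of supporting
    studies and the study list.
    """
    hits: dict[str, list[str]] = {}
    for study, table in per_study.items():
        for taxon in table.index[table["q"] < q_max]:
            hits.setdefault(taxon, []).append(study)
    rows = [
        {"taxon": taxon, "n_studies": len(studies), "studies": ",".join(sorted(studies))}
        for taxon, studies in hits.items()
    ]
    out = pd.DataFrame(rows, columns=["taxon", "n_studies", "studies"])
    if not out.empty:
        out = out.sort_values(["n_studies", "taxon"], ascending=[False, True]).reset_index(drop=True)
    return out
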