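"""Taxon filtering and TMM (trimmed mean of M-values) normalization.

Count matrices are pandas DataFrames with taxa as rows and samples as
columns.  Filtering removes low-variance and low-prevalence taxa before
normalization; TMM estimates per-sample scaling factors from doubly
trimmed log-ratios against a reference sample, and normalized abundances
are counts-per-million on the effective (factor-adjusted) library size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["filter_taxa", "tmm_factors", "tmm_normalize", "EmptyFilterError"]


class EmptyFilterError(ValueError):
    """Raised when every taxon is removed by the filtering rules."""


def _as_count_frame(counts: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(counts, pd.DataFrame):
        raise TypeError("counts must be a taxa x samples DataFrame")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate taxon or sample identifiers")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def filter_taxa(counts: pd.DataFrame, prevalence_min: float = 0.10,
                variance_frac: float = 0.5) -> pd.DataFrame:
    """Remove low-variance and low-prevalence taxa.

    A taxon is dropped when its across-sample variance is below
    ``variance_frac`` times the median of all taxon variances, or when it
    is non-zero in fewer than ``prevalence_min`` of the samples.  Both
    rules are evaluated against the original matrix in a single pass (the
    median is not recomputed after removals).
    """
    counts = _as_count_frame(counts)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to filter on variance")
    x = counts.to_numpy(dtype=float)
    variances = x.var(axis=1, ddof=1)
    med = np.median(variances)
    prevalence = (x > 0).mean(axis=1)
    keep = (variances >= variance_frac * med) & (prevalence >= prevalence_min)
    if not keep.any():
        raise EmptyFilterError("all taxa removed by variance/prevalence filter")
    return counts.loc[keep]


def _tmm_reference_column(frac: np.ndarray) -> int:
    """Column whose upper-quartile count fraction is closest to the mean of those."""
    uq = np.quantile(frac, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_factor_one(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                    trim_m: float, trim_a: float) -> float:
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise ValueError("sample shares no positive taxon with the reference")
    o = obs[shared] / lib_obs
    r = ref[shared] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic inverse variance of M (delta method on binomial counts)
    w = (lib_obs - obs[shared]) / (lib_obs * obs[shared]) + \
        (lib_ref - ref[shared]) / (lib_ref * ref[shared])
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = np.argsort(np.argsort(m, kind="mergesort"), kind="mergesort") + 1
    rank_a = np.argsort(np.argsort(a, kind="mergesort"), kind="mergesort") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    return float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the column whose 75th-percentile count
    fraction is closest to the mean of those fractions across samples.
    For every other sample, M (log2 ratio) and A (mean log2 abundance)
    values are computed over taxa positive in both sample and reference;
    the most extreme ``trim_m`` of M values and ``trim_a`` of A values
    are trimmed from each tail, and the factor is 2 raised to the
    precision-weighted mean of the surviving M values.
    """
    counts = _as_count_frame(counts)
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    ref_idx = _tmm_reference_column(x / lib)
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        try:
            factors[j] = _tmm_factor_one(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                                         trim_m, trim_a)
        except ValueError as err:
            raise ValueError(f"sample {counts.columns[j]!r}: {err}") from None
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million on the effective library: count / (lib * factor) * 1e6."""
    counts = _as_count_frame(counts)
    if factors is None:
        factors = tmm_factors(counts)
    if set(factors.index) != set(counts.columns):
        raise ValueError("factor and count sample sets differ")
    factors = factors.reindex(counts.columns)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    return counts / (lib * factors) * 1e6
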