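"""Virus-bacterium association analysis.

Per-study Spearman correlations between viral-family and
bacterial-species abundances, computed within one disease group at a
time, pooled across studies on the Fisher-z scale with DerSimonian–Laird
random effects, and filtered by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_adjust, fisher_z_effect, pool_correlation

__all__ = ["spearman", "study_grid", "pooled_grid", "StudyGrid", "CorrelationGrid"]

#: minimum paired observations for a correlation cell
MIN_N = 4


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < MIN_N:
        raise ValueError(f"need at least {MIN_N} observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass(frozen=True)
class StudyGrid:
    """One study's correlation matrix (families x species) with sample count."""

    study_id: str
    r: pd.DataFrame     # NaN marks missing cells (constant taxon or too few samples)
    n: int


@dataclass(frozen=True)
class CorrelationGrid:
    """Pooled grid: per-cell random-effects r, q-value, and study support."""

    pooled_r: pd.DataFrame
    q: pd.DataFrame
    k_studies: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at the q threshold


def study_grid(viral_family_abund: pd.DataFrame, bacterial_species_abund: pd.DataFrame,
               study_id: str = "") -> StudyGrid:
    """Spearman grid between two features x samples matrices on shared samples.

    Rows of the result are viral families, columns bacterial species.
    Cells with fewer than 4 shared samples or a constant vector are NaN.
    """
    shared = viral_family_abund.columns.intersection(bacterial_species_abund.columns)
    v = viral_family_abund[shared]
    b = bacterial_species_abund[shared]
    out = pd.DataFrame(np.nan, index=v.index, columns=b.index)
    if len(shared) >= MIN_N:
        vr = stats.rankdata(v.to_numpy(dtype=float), axis=1)
        br = stats.rankdata(b.to_numpy(dtype=float), axis=1)
        vr_c = vr - vr.mean(axis=1, keepdims=True)
        br_c = br - br.mean(axis=1, keepdims=True)
        v_sd = np.sqrt((vr_c**2).sum(axis=1))
        b_sd = np.sqrt((br_c**2).sum(axis=1))
        num = vr_c @ br_c.T
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / np.outer(v_sd, b_sd)
        r[v_sd == 0, :] = np.nan
        r[:, b_sd == 0] = np.nan
        out.iloc[:, :] = r
    return StudyGrid(study_id=study_id, r=out, n=len(shared))


def pooled_grid(grids: list[StudyGrid], q_max: float = 0.05,
                min_studies: int = 2) -> CorrelationGrid:
    """Pool per-study Spearman grids by Fisher-z random effects + BH.

    Cells observed in fewer than ``min_studies`` studies are excluded from
    pooling and from the BH denominator; significance is q < ``q_max``.
    """
    if not grids:
        raise ValueError("no study grids to pool")
    families = grids[0].r.index
    species = grids[0].r.columns
    pooled = pd.DataFrame(np.nan, index=families, columns=species)
    pvals = pd.DataFrame(np.nan, index=families, columns=species)
    kmat = pd.DataFrame(0, index=families, columns=species, dtype=int)
    for fam in families:
        for sp in species:
            effects = []
            for g in grids:
                r = g.r.at[fam, sp]
                # clamp |r| = 1 cells (possible at tiny n) just inside the domain
                if not np.isnan(r) and g.n >= MIN_N:
                    effects.append(fisher_z_effect(float(np.clip(r, -0.999999, 0.999999)), g.n))
            kmat.at[fam, sp] = len(effects)
            if len(effects) >= min_studies:
                r_pool, p, _ = pool_correlation(effects)
                pooled.at[fam, sp] = r_pool
                pvals.at[fam, sp] = p
    flat_p = pvals.to_numpy().ravel()
    tested = ~np.isnan(flat_p)
    qs = np.full(flat_p.shape, np.nan)
    if tested.any():
        qs[tested] = bh_adjust(flat_p[tested])
    qmat = pd.DataFrame(qs.reshape(pvals.shape), index=families, columns=species)
    return CorrelationGrid(
        pooled_r=pooled,
        q=qmat,
        k_studies=kmat,
        significant=qmat < q_max,
    )


def grid_to_long(grid: CorrelationGrid, group: str = "") -> pd.DataFrame:
    """Long-format table (family, species, group, pooled_r, q, k_studies)."""
    rows = []
    for fam in grid.pooled_r.index:
        for sp in grid.pooled_r.columns:
            rows.append({
                "family": fam,
                "species": sp,
                "group": group,
                "pooled_r": grid.pooled_r.at[fam, sp],
                "q": grid.q.at[fam, sp],
                "k_studies": grid.k_studies.at[fam, sp],
            })
    return pd.DataFrame(rows)
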