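"""Synthetic multi-study virome + bacteriome cohorts with known ground truth.

The generator emulates the structure of multi-cohort fecal shotgun
case-control studies so every downstream stage (normalization, diversity
meta-analysis, ordination, differential abundance, interkingdom
correlation, prediction) can be tested against planted parameters.

Latent model
------------
Each taxon t has a global base log-mean ``b_t ~ Normal(2, 1.5)`` shared
across studies (the common biology that cross-study classifiers exploit),
plus a per-study, per-taxon batch offset ``o_t ~ Normal(0, batch_shift_sd)``
(sequencing platform / protocol differences).  For a sample s the latent
log-mean is

    l_ts = center + (b_t + o_t - center) * exp(-eps_g)     (evenness dial)
           + [case] * lfc_t * ln 2                         (planted DA taxa)
           + sigma_c * z_cs                                (copula factors)

where ``eps_g`` is 0 for controls and a per-study calibrated value for
cases that realizes the planted standardized mean difference theta_i of
Shannon diversity; ``z_cs`` are per-sample standard-normal factors shared
(with latent correlation 2 sin(pi rho / 6), the Gaussian-copula value
mapping to Spearman rho) between a planted viral family and bacterial
species.  The relative profile ``softmax(l)`` is scaled to a per-sample
library size drawn around ``depth_mean`` and counts are negative-binomial
draws with dispersion alpha (variance m + alpha m^2).

Per-study effects theta_i are drawn Normal(diversity_smd_mu,
diversity_smd_tau2).  The evenness dial is solved from the *expected*
profile (deterministic root-finding on the Shannon index of the mean
profile) against a pilot estimate of the per-sample diversity standard
deviation, so a zero planted effect yields a byte-identical null.

Seeding: one global seed expands into independent child streams via
``numpy.random.SeedSequence(seed).spawn`` — one stream for global taxon
parameters, one for the per-study effect draws, then one per study, in
the order the studies are listed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diversity import shannon

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "MetadataModel",
    "XkCorrelation",
    "CohortTruth",
    "StudyData",
    "generate_cohort_set",
    "generate_summary_effects",
    "generate_orf_hits",
]

#: latent scale of the shared copula factors for planted correlations
COPULA_SIGMA = 0.8
#: per-sample jitter of the evenness dial (both groups): subjects differ in
#: community evenness far more than sequencing noise alone would suggest, so
#: planted diversity shifts overlap between groups the way real cohorts do
EVENNESS_JITTER_SD = 0.25
#: log-normal sd of per-sample sequencing depth around depth_mean; modest, so
#: realized library means stay within a few percent of depth_mean at n >= 50
#: (negative-binomial dispersion already adds per-sample column-sum noise)
DEPTH_LOG_SD = 0.15
#: base log-mean distribution of taxon abundances (log-normal community)
BASE_LOC, BASE_SCALE = 2.0, 1.5


@dataclass(frozen=True)
class CohortSpec:
    """Shape and noise parameters of one synthetic study."""

    study_id: str
    n_control: int = 50
    n_case: int = 50
    n_viral_taxa: int = 300
    n_bacterial_taxa: int = 200
    depth_mean: float = 1e6
    batch_shift_sd: float = 0.5
    dispersion: float = 0.3

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("each arm needs at least 2 samples")
        if self.n_viral_taxa < 1 or self.n_bacterial_taxa < 1:
            raise ValueError("need at least one taxon per kingdom")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass(frozen=True)
class MetadataModel:
    age_mean: float = 60.0
    age_sd: float = 10.0
    bmi_mean: float = 25.0
    bmi_sd: float = 4.0
    gender_p_male: float = 0.5
    #: when True, cases are systematically older / heavier — exercises the
    #: covariate-adjusted linear model
    confounded: bool = False
    confound_age_shift: float = 6.0
    confound_bmi_shift: float = 2.0


@dataclass(frozen=True)
class XkCorrelation:
    """Planted Spearman correlation between a viral family and a bacterial species."""

    family: str
    species: str
    rho_control: float
    rho_case: float

    def __post_init__(self) -> None:
        for rho in (self.rho_control, self.rho_case):
            if not abs(rho) < 1:
                raise ValueError(f"planted |rho| must be < 1, got {rho}")


@dataclass(frozen=True)
class EffectSpec:
    """Planted case-control structure shared by all studies."""

    diversity_smd_mu: float = 0.0
    diversity_smd_tau2: float = 0.0
    da_taxa: tuple[tuple[str, float], ...] = ()          # (taxon id, log2 FC case/control)
    xk_correlations: tuple[XkCorrelation, ...] = ()
    metadata_model: MetadataModel = field(default_factory=MetadataModel)

    def __post_init__(self) -> None:
        if self.diversity_smd_tau2 < 0:
            raise ValueError("between-study variance tau2 must be non-negative")


@dataclass
class CohortTruth:
    """Record of everything the generator planted, for recovery tests."""

    seed: int
    theta_by_study: dict[str, float]
    da_taxa: dict[str, float]
    correlations: list[dict]
    viral_family_map: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class StudyData:
    study_id: str
    viral: pd.DataFrame       # taxa x samples counts
    bacterial: pd.DataFrame   # taxa x samples counts


def _spearman_to_latent(rho: float) -> float:
    """Gaussian-copula latent correlation giving Spearman rho."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def _profile(latent: np.ndarray) -> np.ndarray:
    """Softmax over taxa (columns are samples when 2-D)."""
    z = latent - latent.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def _even_latent(base: np.ndarray, eps: float) -> np.ndarray:
    center = base.mean()
    return center + (base - center) * math.exp(-eps)


#: pilot samples per condition when calibrating the evenness dial
N_PILOT = 600


def _calibrate_evenness_profile(base: np.ndarray, da_shift: np.ndarray, theta: float,
                                sigma_h: float) -> float:
    """Deterministic first guess for the case evenness dial.

    Delta(eps) = H(softmax(even(base, eps) + da_shift)) - H(softmax(base))
    is computed on expected profiles; the root of Delta(eps) = theta * sigma_h
    is found by bisection.  Finite sequencing depth biases realized
    (count-level) Shannon values relative to the profile-level value, so this
    guess is refined against pilot counts by `_calibrate_evenness`.
    """
    h_control = shannon(_profile(base[:, None])[:, 0])

    def delta(eps: float) -> float:
        lat = _even_latent(base, eps) + da_shift
        return shannon(_profile(lat[:, None])[:, 0]) - h_control

    target = theta * sigma_h
    lo, hi = -5.0, 5.0
    if delta(lo) > target:
        return lo
    if delta(hi) < target:
        return hi
    return float(brentq(lambda e: delta(e) - target, lo, hi, xtol=1e-8))


def _pilot_mean_h(rng: np.random.Generator, base: np.ndarray, eps: float,
                  da_shift: np.ndarray, depth_mean: float, alpha: float,
                  n_pilot: int = N_PILOT) -> tuple[float, float]:
    """Mean and sd of count-level Shannon diversity for one model condition."""
    eps_s = eps + rng.normal(0.0, EVENNESS_JITTER_SD, n_pilot)
    lat = np.stack([_even_latent(base, e) for e in eps_s], axis=1) + da_shift[:, None]
    p = _profile(lat)
    depth = depth_mean * np.exp(rng.normal(-DEPTH_LOG_SD**2 / 2, DEPTH_LOG_SD, n_pilot))
    counts = _nb_draw(rng, p * depth[None, :], alpha)
    ok = counts.sum(axis=0) > 0
    hs = np.array([shannon(counts[:, j]) for j in np.flatnonzero(ok)])
    return float(hs.mean()), float(hs.std(ddof=1))


def _calibrate_evenness(rng: np.random.Generator, base: np.ndarray,
                        da_shift: np.ndarray, theta: float, depth_mean: float,
                        alpha: float) -> float:
    """Case evenness dial realizing a count-level Shannon SMD of theta.

    A deterministic guess from expected profiles is refined by one secant
    step on pilot count simulations, which capture the depth- and
    dispersion-dependent bias of realized diversity.
    """
    zeros = np.zeros_like(base)
    h_ctrl, sd_ctrl = _pilot_mean_h(rng, base, 0.0, zeros, depth_mean, alpha)
    target = theta * sd_ctrl
    guess = _calibrate_evenness_profile(base, da_shift, theta, sd_ctrl)

    # affine correction of the deterministic profile response: the count-level
    # group difference g(eps) is modeled as c0 + c1 * delta_profile(eps), with
    # the two coefficients estimated from pilots at eps = 0 and a wide probe
    # (wide, so pilot noise enters the slope with a large denominator)
    h_profile_ctrl = shannon(_profile(base[:, None])[:, 0])

    def delta_profile(eps: float) -> float:
        lat = _even_latent(base, eps) + da_shift
        return shannon(_profile(lat[:, None])[:, 0]) - h_profile_ctrl

    probe = math.copysign(max(2.0 * abs(guess), 0.6),
                          guess if guess else (theta if theta else 1.0))
    g0 = _pilot_mean_h(rng, base, 0.0, da_shift, depth_mean, alpha)[0] - h_ctrl
    g1 = _pilot_mean_h(rng, base, probe, da_shift, depth_mean, alpha)[0] - h_ctrl
    dp0, dp1 = delta_profile(0.0), delta_profile(probe)
    if abs(dp1 - dp0) < 1e-12:
        return float(np.clip(guess, -5.0, 5.0))
    c1 = (g1 - g0) / (dp1 - dp0)
    c0 = g0 - c1 * dp0
    if c1 <= 0:
        return float(np.clip(guess, -5.0, 5.0))

    def f(eps: float) -> float:
        return c0 + c1 * delta_profile(eps) - target

    lo, hi = -5.0, 5.0
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-6))


def generate_cohort_set(specs: Sequence[CohortSpec], effects: EffectSpec, seed: int,
                        n_viral_families: int = 24,
                        ) -> tuple[list[StudyData], pd.DataFrame, CohortTruth]:
    """Generate per-study viral + bacterial count matrices, metadata and truth.

    All studies share taxon identifiers and base abundances; study-specific
    batch offsets, planted effects and sampling noise are layered on top as
    described in the module docstring.  Identical (specs, effects, seed)
    reproduce identical outputs.
    """
    if not specs:
        raise ValueError("need at least one cohort spec")
    ids = [s.study_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study ids")
    n_v = max(s.n_viral_taxa for s in specs)
    n_b = max(s.n_bacterial_taxa for s in specs)
    if any(s.n_viral_taxa != n_v or s.n_bacterial_taxa != n_b for s in specs):
        raise ValueError("all studies must share one taxon space")

    ss = np.random.SeedSequence(seed)
    global_ss, theta_ss, *study_ss = ss.spawn(2 + len(specs))
    g_rng = np.random.default_rng(global_ss)
    theta_rng = np.random.default_rng(theta_ss)

    viral_taxa = [f"vOTU_{i:04d}" for i in range(n_v)]
    bact_taxa = [f"BS_{i:04d}" for i in range(n_b)]
    family_map = {t: f"VF_{i % n_viral_families:02d}" for i, t in enumerate(viral_taxa)}

    base_v = g_rng.normal(BASE_LOC, BASE_SCALE, n_v)
    base_b = g_rng.normal(BASE_LOC, BASE_SCALE, n_b)

    da = dict(effects.da_taxa)
    unknown = set(da) - set(viral_taxa) - set(bact_taxa)
    if unknown:
        raise ValueError(f"planted DA taxa not in the taxon space: {sorted(unknown)}")
    # planted effects live on well-observed taxa, so recovery tests measure the
    # downstream statistics rather than detection limits of rare taxa
    planted_ids = set(da) | {xk.species for xk in effects.xk_correlations}
    for i, t in enumerate(viral_taxa):
        if t in planted_ids:
            base_v[i] = max(base_v[i], BASE_LOC + 1.0)
    for i, t in enumerate(bact_taxa):
        if t in planted_ids:
            base_b[i] = max(base_b[i], BASE_LOC + 1.0)
    da_shift_v = np.array([da.get(t, 0.0) for t in viral_taxa]) * math.log(2.0)
    da_shift_b = np.array([da.get(t, 0.0) for t in bact_taxa]) * math.log(2.0)

    for xk in effects.xk_correlations:
        if xk.family not in set(family_map.values()):
            raise ValueError(f"planted family {xk.family!r} not in the family space")
        if xk.species not in bact_taxa:
            raise ValueError(f"planted species {xk.species!r} not in the taxon space")

    if effects.diversity_smd_tau2 > 0:
        thetas = theta_rng.normal(effects.diversity_smd_mu,
                                  math.sqrt(effects.diversity_smd_tau2), len(specs))
    else:
        thetas = np.full(len(specs), effects.diversity_smd_mu)

    mm = effects.metadata_model
    studies: list[StudyData] = []
    meta_rows: list[dict] = []
    fam_arr = np.array([family_map[t] for t in viral_taxa])
    vf_members = {fam: fam_arr == fam for fam in set(family_map.values())}
    bs_index = {t: i for i, t in enumerate(bact_taxa)}

    for spec, theta, child in zip(specs, thetas, study_ss):
        rng = np.random.default_rng(child)
        off_v = rng.normal(0.0, spec.batch_shift_sd, n_v)
        off_b = rng.normal(0.0, spec.batch_shift_sd, n_b)
        base_study_v = base_v + off_v
        base_study_b = base_b + off_b

        pure_null = theta == 0.0 and not da
        if pure_null:
            eps_case = 0.0
        else:
            eps_case = _calibrate_evenness(rng, base_study_v, da_shift_v, theta,
                                           spec.depth_mean, spec.dispersion)

        n = spec.n_control + spec.n_case
        is_case = np.zeros(n, dtype=bool)
        is_case[spec.n_control:] = True
        samples = [f"{spec.study_id}_S{j:03d}" for j in range(n)]

        eps_jitter = rng.normal(0.0, EVENNESS_JITTER_SD, n)
        lat_v = np.empty((n_v, n))
        lat_b = np.empty((n_b, n))
        for j in range(n):
            eps_j = (eps_case if is_case[j] else 0.0) + eps_jitter[j]
            lat_v[:, j] = _even_latent(base_study_v, eps_j)
            if is_case[j]:
                lat_v[:, j] += da_shift_v
                lat_b[:, j] = base_study_b + da_shift_b
            else:
                lat_b[:, j] = base_study_b

        for xk in effects.xk_correlations:
            members = vf_members[xk.family]
            sp_idx = bs_index[xk.species]
            for j in range(n):
                rho = xk.rho_case if is_case[j] else xk.rho_control
                lam = _spearman_to_latent(rho)
                z_v = rng.standard_normal()
                z_b = lam * z_v + math.sqrt(max(0.0, 1 - lam * lam)) * rng.standard_normal()
                lat_v[members, j] += COPULA_SIGMA * z_v
                lat_b[sp_idx, j] += COPULA_SIGMA * z_b

        depth = spec.depth_mean * np.exp(
            rng.normal(-DEPTH_LOG_SD**2 / 2, DEPTH_LOG_SD, n))
        mean_v = _profile(lat_v) * depth
        mean_b = _profile(lat_b) * depth
        counts_v = _nb_draw(rng, mean_v, spec.dispersion)
        counts_b = _nb_draw(rng, mean_b, spec.dispersion)

        studies.append(StudyData(
            study_id=spec.study_id,
            viral=pd.DataFrame(counts_v, index=viral_taxa, columns=samples),
            bacterial=pd.DataFrame(counts_b, index=bact_taxa, columns=samples),
        ))

        age_shift = mm.confound_age_shift if mm.confounded else 0.0
        bmi_shift = mm.confound_bmi_shift if mm.confounded else 0.0
        for j, sample in enumerate(samples):
            case = bool(is_case[j])
            meta_rows.append({
                "sample_id": sample,
                "study": spec.study_id,
                "group": "CRC" if case else "control",
                "age": rng.normal(mm.age_mean + (age_shift if case else 0.0), mm.age_sd),
                "gender": "male" if rng.random() < mm.gender_p_male else "female",
                "bmi": rng.normal(mm.bmi_mean + (bmi_shift if case else 0.0), mm.bmi_sd),
            })

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = CohortTruth(
        seed=seed,
        theta_by_study={s.study_id: float(t) for s, t in zip(specs, thetas)},
        da_taxa={t: float(l) for t, l in effects.da_taxa},
        correlations=[asdict(xk) for xk in effects.xk_correlations],
        viral_family_map=family_map,
    )
    return studies, metadata, truth


def family_abundance(viral_counts: pd.DataFrame, family_map: dict[str, str]) -> pd.DataFrame:
    """Aggregate taxon-level viral counts to family level (sum of members)."""
    fam = pd.Series({t: family_map.get(t, "UNCLASSIFIED") for t in viral_counts.index})
    return viral_counts.groupby(fam).sum()


def generate_summary_effects(mu: float, tau2: float, k: int, n_per_arm: int,
                             seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-study (control, case) value arrays for meta-analysis recovery tests.

    Study i draws a true effect theta_i ~ Normal(mu, tau2); its case values
    are Normal(theta_i, 1) and control values Normal(0, 1), n_per_arm each.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if k < 2:
        raise ValueError("need at least 2 studies")
    if n_per_arm < 3:
        raise ValueError("need at least 3 values per arm")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(k):
        theta = rng.normal(mu, math.sqrt(tau2)) if tau2 > 0 else mu
        control = rng.normal(0.0, 1.0, n_per_arm)
        case = rng.normal(theta, 1.0, n_per_arm)
        out.append((control, case))
    return out


def generate_orf_hits(genome_plan: Sequence[tuple[str, Sequence[Sequence[tuple]]]],
                      seed: int = 0) -> pd.DataFrame:
    """Build an ORF hit table with controlled best-hit structure.

    ``genome_plan`` lists (genome_id, orfs); each ORF is a list of candidate
    hits ``(lineage, bit_score, e_value)`` or ``(lineage, bit_score,
    e_value, protein_id)`` — lineage is a rank->taxon mapping.  Protein ids
    are auto-numbered when absent.  Output rows are shuffled with the seed
    (annotation must be order-invariant) and columns match the hit-table
    TSV schema: genome_id, orf_id, protein_id, bit_score, e_value, family,
    genus, species.
    """
    if not genome_plan:
        raise ValueError("empty genome plan")
    rows = []
    counter = 0
    seen = set()
    for genome_id, orfs in genome_plan:
        for o, candidates in enumerate(orfs):
            orf_id = f"{genome_id}_ORF{o + 1:03d}"
            for cand in candidates:
                if len(cand) == 4:
                    lineage, bit, ev, protein_id = cand
                else:
                    lineage, bit, ev = cand
                    protein_id = f"P{counter:05d}"
                    counter += 1
                key = (genome_id, orf_id, protein_id)
                if key in seen:
                    raise ValueError(f"duplicate hit row {key}")
                seen.add(key)
                rows.append({
                    "genome_id": genome_id,
                    "orf_id": orf_id,
                    "protein_id": protein_id,
                    "bit_score": float(bit),
                    "e_value": float(ev),
                    "family": lineage.get("family", ""),
                    "genus": lineage.get("genus", ""),
                    "species": lineage.get("species", ""),
                })
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)
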