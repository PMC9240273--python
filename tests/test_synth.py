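"""Synthetic cohort generator: determinism, planted structure, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from virome_meta import (
    CohortSpec,
    EffectSpec,
    XkCorrelation,
    dl_pool,
    family_abundance,
    generate_cohort_set,
    generate_summary_effects,
    hedges_g,
)
from virome_meta.diversity import shannon
from virome_meta.synth import COPULA_SIGMA, DEPTH_LOG_SD, _spearman_to_latent


def _specs(k=2, **kw):
    defaults = dict(n_control=30, n_case=30, n_viral_taxa=120,
                    n_bacterial_taxa=80, depth_mean=3e4)
    defaults.update(kw)
    return [CohortSpec(study_id=f"S{i}", **defaults) for i in range(k)]


class TestDeterminismAndShape:
    def test_same_seed_identical_outputs(self):
        specs, eff = _specs(), EffectSpec(diversity_smd_mu=0.3)
        a = generate_cohort_set(specs, eff, seed=11)
        b = generate_cohort_set(specs, eff, seed=11)
        for sa, sb in zip(a[0], b[0]):
            pd.testing.assert_frame_equal(sa.viral, sb.viral)
            pd.testing.assert_frame_equal(sa.bacterial, sb.bacterial)
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2].theta_by_study == b[2].theta_by_study

    def test_different_seed_different_counts(self):
        specs, eff = _specs(), EffectSpec()
        a = generate_cohort_set(specs, eff, seed=1)
        b = generate_cohort_set(specs, eff, seed=2)
        assert not a[0][0].viral.equals(b[0][0].viral)

    def test_metadata_schema_and_groups(self):
        studies, md, _ = generate_cohort_set(_specs(), EffectSpec(), seed=3)
        assert set(md.columns) == {"study", "group", "age", "gender", "bmi"}
        assert set(md["group"]) == {"control", "CRC"}
        counts = md.groupby(["study", "group"]).size()
        assert (counts == 30).all()

    def test_zero_arm_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(study_id="X", n_control=1, n_case=5)
        with pytest.raises(ValueError):
            CohortSpec(study_id="X", n_viral_taxa=0)

    def test_library_size_tracks_depth_mean(self):
        studies, _, _ = generate_cohort_set(
            _specs(k=1, n_control=100, n_case=100, depth_mean=5e4), EffectSpec(), seed=4)
        libs = studies[0].viral.sum(axis=0)
        assert abs(libs.mean() / 5e4 - 1) < 0.05


class TestNullCalibration:
    def test_null_two_group_t_pvalues_uniform(self):
        specs = _specs(k=1, n_viral_taxa=2000, n_bacterial_taxa=10,
                       n_control=40, n_case=40, depth_mean=2e5)
        studies, md, _ = generate_cohort_set(specs, EffectSpec(), seed=5)
        counts = studies[0].viral.to_numpy(dtype=float)
        grp = (md.loc[studies[0].viral.columns, "group"] == "CRC").to_numpy()
        logc = np.log(counts + 1)
        keep = counts.var(axis=1) > 0
        t = stats.ttest_ind(logc[keep][:, grp], logc[keep][:, ~grp], axis=1)
        ks = stats.kstest(t.pvalue, "uniform")
        assert ks.pvalue > 0.01


class TestEffectRealization:
    def test_realized_smd_matches_planted_theta(self):
        specs = _specs(k=3, n_control=150, n_case=150)
        studies, md, truth = generate_cohort_set(
            specs, EffectSpec(diversity_smd_mu=0.5, diversity_smd_tau2=0.04), seed=6)
        for st in studies:
            theta = truth.theta_by_study[st.study_id]
            grp = md.loc[st.viral.columns, "group"]
            h = np.array([shannon(st.viral[c]) for c in st.viral.columns])
            eff = hedges_g(h[(grp == "control").to_numpy()],
                           h[(grp == "CRC").to_numpy()])
            # within ~3 standard errors of the planted per-study effect
            assert abs(eff.estimate - theta) < 3 * math.sqrt(eff.variance) + 0.05

    def test_tau2_zero_means_identical_thetas(self):
        _, _, truth = generate_cohort_set(
            _specs(k=3), EffectSpec(diversity_smd_mu=0.26, diversity_smd_tau2=0.0),
            seed=7)
        assert set(truth.theta_by_study.values()) == {0.26}

    def test_planted_da_taxa_shift_case_means(self):
        da = tuple((f"vOTU_{i:04d}", 2.0) for i in range(5))
        specs = _specs(k=1, n_control=60, n_case=60)
        studies, md, truth = generate_cohort_set(specs, EffectSpec(da_taxa=da), seed=8)
        st = studies[0]
        grp = md.loc[st.viral.columns, "group"]
        rel = st.viral / st.viral.sum(axis=0)
        lfc = np.log2((rel.loc[:, (grp == "CRC").to_numpy()].mean(axis=1) + 1e-9)
                      / (rel.loc[:, (grp == "control").to_numpy()].mean(axis=1) + 1e-9))
        planted = [t for t, _ in da]
        assert lfc.loc[planted].min() > 1.0
        assert np.abs(lfc.drop(planted)).median() < 0.5


class TestPlantedCorrelation:
    def _oracle(self, rho, seed, n=100_000, m_members=7, n_v=150, n_b=100,
                alpha=0.3, depth=5e4):
        """Direct Monte-Carlo of the documented latent model."""
        rng = np.random.default_rng(seed)
        base_v = rng.normal(2.0, 1.5, n_v)
        base_b = rng.normal(2.0, 1.5, n_b)
        base_b[0] = max(base_b[0], 3.0)  # planted species is well observed
        lam = _spearman_to_latent(rho)
        zv = rng.standard_normal(n)
        zb = lam * zv + math.sqrt(1 - lam * lam) * rng.standard_normal(n)
        lat_v = np.tile(base_v[:, None], (1, n))
        lat_v[:m_members] += COPULA_SIGMA * zv
        lat_b = np.tile(base_b[:, None], (1, n))
        lat_b[0] += COPULA_SIGMA * zb

        def prof(latent):
            e = np.exp(latent - latent.max(axis=0))
            return e / e.sum(axis=0)

        d = depth * np.exp(rng.normal(-DEPTH_LOG_SD**2 / 2, DEPTH_LOG_SD, n))
        r = 1 / alpha
        mv = prof(lat_v) * d
        mb = prof(lat_b) * d
        fam = rng.negative_binomial(r, r / (r + mv[:m_members])).sum(axis=0)
        sp = rng.negative_binomial(r, r / (r + mb[0]))
        return stats.spearmanr(fam, sp).statistic

    def test_sample_spearman_matches_copula_oracle(self):
        # both sides are Monte-Carlo estimates of the same latent model; the
        # generator side averages groups/seeds so base-draw noise does not
        # swamp the comparison at the n=200-per-group scale
        rho = 0.8
        specs = _specs(k=1, n_control=200, n_case=200, n_viral_taxa=150,
                       n_bacterial_taxa=100, depth_mean=5e4)
        eff = EffectSpec(xk_correlations=(XkCorrelation("VF_00", "BS_0000", rho, rho),))
        rs = []
        for seed in (9, 10):
            studies, md, truth = generate_cohort_set(specs, eff, seed=seed)
            st = studies[0]
            fam = family_abundance(st.viral, truth.viral_family_map)
            grp = md.loc[st.viral.columns, "group"]
            for level in ("control", "CRC"):
                sel = (grp == level).to_numpy()
                rs.append(stats.spearmanr(fam.loc["VF_00", sel],
                                          st.bacterial.loc["BS_0000", sel]).statistic)
        r_oracle = np.mean([self._oracle(rho, seed=s, n=30_000) for s in range(3)])
        assert abs(np.mean(rs) - r_oracle) < 0.1

    def test_group_specific_correlations(self):
        eff = EffectSpec(xk_correlations=(XkCorrelation("VF_00", "BS_0000", 0.7, -0.7),))
        specs = _specs(k=1, n_control=150, n_case=150, n_viral_taxa=150,
                       n_bacterial_taxa=100, depth_mean=5e4)
        studies, md, truth = generate_cohort_set(specs, eff, seed=10)
        st = studies[0]
        fam = family_abundance(st.viral, truth.viral_family_map)
        grp = md.loc[st.viral.columns, "group"]
        r_ctrl = stats.spearmanr(fam.loc["VF_00", (grp == "control").to_numpy()],
                                 st.bacterial.loc["BS_0000", (grp == "control").to_numpy()]).statistic
        r_case = stats.spearmanr(fam.loc["VF_00", (grp == "CRC").to_numpy()],
                                 st.bacterial.loc["BS_0000", (grp == "CRC").to_numpy()]).statistic
        assert r_ctrl > 0.3
        assert r_case < -0.3


class TestSummaryEffects:
    def test_structure_and_domain_errors(self):
        data = generate_summary_effects(0.3, 0.0, k=5, n_per_arm=10, seed=0)
        assert len(data) == 5
        assert all(len(c) == 10 and len(x) == 10 for c, x in data)
        with pytest.raises(ValueError):
            generate_summary_effects(0.3, -0.1, k=5, n_per_arm=10, seed=0)

    def test_null_pooled_effect_near_zero(self):
        data = generate_summary_effects(0.0, 0.0, k=30, n_per_arm=50, seed=1)
        res = dl_pool([hedges_g(c, x) for c, x in data])
        assert abs(res.mu_hat) < 3 * res.se

    def test_mean_recovery_small_scale(self):
        mus = []
        for seed in range(30):
            data = generate_summary_effects(0.3, 0.0, k=20, n_per_arm=60, seed=seed)
            mus.append(dl_pool([hedges_g(c, x) for c, x in data]).mu_hat)
        assert np.mean(mus) == pytest.approx(0.3, abs=0.03)

    def test_tau2_recovery_small_scale(self):
        tau2s = []
        for seed in range(40):
            data = generate_summary_effects(0.0, 0.25, k=100, n_per_arm=50, seed=seed)
            tau2s.append(dl_pool([hedges_g(c, x) for c, x in data]).tau2)
        assert np.mean(tau2s) == pytest.approx(0.25, abs=0.05)
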