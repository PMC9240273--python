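"""End-to-end orchestration of the multi-cohort virome analysis.

A single config (YAML-friendly dict or :class:`PipelineConfig`) drives:
synthetic cohort generation (or TSV loading), taxon filtering + TMM
normalization, per-study alpha-diversity disease associations pooled by
random-effects meta-analysis, Bray-Curtis PCoA + PERMANOVA (study and
disease), per-study negative-binomial differential abundance with
cross-study intersection, interkingdom correlation grids, and the
within / cross-study / LODO prediction harness.  Every stage is a pure
function of (inputs, config, seed); outputs are TSV tables plus one JSON
summary.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffabund, diversity, interkingdom, meta, norm, ordination, predict, synth

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("virome_meta")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; one global seed."""

    seed: int = 1
    out_dir: str = "pipeline_out"
    # synthetic-data block (used when counts_paths is empty)
    synth_specs: list[synth.CohortSpec] = field(default_factory=list)
    synth_effects: synth.EffectSpec = field(default_factory=synth.EffectSpec)
    # thresholds and protocol sizes
    q_max: float = 0.05
    prevalence_min: float = 0.10
    n_permutations: int = 999
    n_folds: int = 10
    cv_repeats: int = 20
    transfer_repeats: int = 20
    n_trees: int = 1000
    # stage toggles
    run_diversity: bool = True
    run_ordination: bool = True
    run_diffabund: bool = True
    run_interkingdom: bool = True
    run_predict: bool = True


def load_config(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON mapping."""
    data = dict(data)
    synth_block = data.pop("synth", None)
    cfg = PipelineConfig(**{k: v for k, v in data.items()
                            if k in PipelineConfig.__dataclass_fields__})
    if synth_block:
        cfg.synth_specs = [synth.CohortSpec(**s) for s in synth_block.get("studies", [])]
        eff = dict(synth_block.get("effects", {}))
        if "xk_correlations" in eff:
            eff["xk_correlations"] = tuple(
                synth.XkCorrelation(**x) for x in eff["xk_correlations"])
        if "da_taxa" in eff:
            eff["da_taxa"] = tuple((t, float(l)) for t, l in eff["da_taxa"])
        if "metadata_model" in eff:
            eff["metadata_model"] = synth.MetadataModel(**eff["metadata_model"])
        cfg.synth_effects = synth.EffectSpec(**eff)
    return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _pool_effects(effects: list[meta.StudyEffect]) -> dict:
    res = meta.dl_pool(effects)
    return {
        "mu_hat": res.mu_hat, "se": res.se, "ci95": list(res.ci95), "p": res.p,
        "tau2": res.tau2, "q": res.q, "q_p": res.q_p, "i2": res.i2, "k": res.k,
    }


@_stage("diversity")
def _diversity_stage(studies, metadata, cfg):
    """Per-study diversity, group tests, linear models, pooled SMD."""
    tables = {}
    per_study = []
    smd_shannon, smd_heip, smd_chao1 = [], [], []
    for st in studies:
        div = diversity.diversity_table(st.viral)
        div["study"] = st.study_id
        tables[st.study_id] = div
        md = metadata.loc[div.index]
        ctrl = div.loc[md["group"] == "control"]
        case = div.loc[md["group"] == "CRC"]
        naive = diversity.disease_lm(div["shannon"], md, adjusted=False)
        adjusted = diversity.disease_lm(div["shannon"], md, adjusted=True)
        per_study.append({
            "study": st.study_id,
            "wilcoxon_p_shannon": diversity.wilcoxon_rank_sum(
                ctrl["shannon"], case["shannon"]),
            "naive_coef": naive.coefficient, "naive_p": naive.p_value,
            "adjusted_coef": adjusted.coefficient, "adjusted_p": adjusted.p_value,
        })
        smd_shannon.append(meta.hedges_g(ctrl["shannon"], case["shannon"], label=st.study_id))
        smd_heip.append(meta.hedges_g(ctrl["heip_evenness"], case["heip_evenness"], label=st.study_id))
        smd_chao1.append(meta.hedges_g(ctrl["chao1"], case["chao1"], label=st.study_id))
    per_study = pd.DataFrame(per_study)
    per_study["wilcoxon_p_shannon_bh"] = meta.bh_adjust(per_study["wilcoxon_p_shannon"])
    return {
        "tables": tables,
        "per_study": per_study,
        "per_study_smd_shannon": [(e.label, e.estimate, e.variance) for e in smd_shannon],
        "pooled": {
            "shannon": _pool_effects(smd_shannon),
            "heip_evenness": _pool_effects(smd_heip),
            "chao1": _pool_effects(smd_chao1),
        },
    }


@_stage("ordination")
def _ordination_stage(abund_by_study, metadata, cfg):
    """Combined-sample Bray-Curtis PCoA; PERMANOVA by study and by disease."""
    combined = pd.concat(abund_by_study.values(), axis=1)
    dmat = ordination.bray_curtis(combined.T)
    md = metadata.loc[combined.columns]
    pc = ordination.pcoa(dmat, k=2)
    by_study = ordination.permanova(dmat, md["study"].to_numpy(),
                                    n_perm=cfg.n_permutations, seed=cfg.seed)
    by_disease = ordination.permanova(dmat, md["group"].to_numpy(),
                                      n_perm=cfg.n_permutations, seed=cfg.seed + 1)
    # per-study SMD meta-analysis of the principal coordinates
    pooled_axes = {}
    for axis in pc.coordinates.columns:
        effs = []
        for study in md["study"].unique():
            sel = md["study"] == study
            ctrl = pc.coordinates.loc[sel & (md["group"] == "control"), axis]
            case = pc.coordinates.loc[sel & (md["group"] == "CRC"), axis]
            effs.append(meta.hedges_g(ctrl, case, label=study))
        pooled_axes[axis] = _pool_effects(effs)
    return {
        "coordinates": pc.coordinates.join(md[["study", "group"]]),
        "proportion_explained": pc.proportion_explained.tolist(),
        "permanova_study": vars(by_study) | {"labels": "study"},
        "permanova_disease": vars(by_disease) | {"labels": "group"},
        "pooled_axes": pooled_axes,
    }


@_stage("diffabund")
def _diffabund_stage(studies, metadata, cfg, kingdom="viral"):
    per_study = {}
    for st in studies:
        counts = getattr(st, kingdom)
        counts = norm.filter_taxa(counts, prevalence_min=cfg.prevalence_min)
        groups = metadata.loc[counts.columns, "group"]
        per_study[st.study_id] = diffabund.nb_test(counts, groups)
    intersection = diffabund.intersect_significant(per_study, q_max=cfg.q_max)
    counts_by_n = (intersection["n_studies"].value_counts().sort_index().to_dict()
                   if not intersection.empty else {})
    return {"per_study": per_study, "intersection": intersection,
            "intersection_counts": {int(k): int(v) for k, v in counts_by_n.items()}}


@_stage("interkingdom")
def _interkingdom_stage(studies, metadata, family_map, species_list, cfg):
    grids = {}
    for group in ("control", "CRC"):
        study_grids = []
        for st in studies:
            viral_tmm = norm.tmm_normalize(st.viral, norm.tmm_factors(st.viral))
            vf = synth.family_abundance(viral_tmm, family_map)
            bs = norm.tmm_normalize(st.bacterial, norm.tmm_factors(st.bacterial))
            bs = bs.loc[[s for s in species_list if s in bs.index]]
            keep = metadata.loc[vf.columns, "group"] == group
            sg = interkingdom.study_grid(vf.loc[:, keep.to_numpy()],
                                         bs.loc[:, keep.to_numpy()], study_id=st.study_id)
            study_grids.append(sg)
        grids[group] = interkingdom.pooled_grid(study_grids, q_max=cfg.q_max)
    return grids


@_stage("predict")
def _predict_stage(abund_by_study, metadata, cfg):
    clf = predict.ClassifierSpec(n_estimators=cfg.n_trees)
    datasets = {}
    for study, ab in abund_by_study.items():
        feats = np.log10(ab.T + 1.0)
        labels = (metadata.loc[feats.index, "group"] == "CRC").astype(int).to_numpy()
        datasets[study] = (feats, labels)
    ids = sorted(datasets)
    rng = np.random.default_rng(cfg.seed)
    within = {}
    for sid in ids:
        f, y = datasets[sid]
        within[sid] = predict.within_study_cv(
            f, y, clf, n_folds=cfg.n_folds, n_repeats=cfg.cv_repeats,
            seed=int(rng.integers(2**31 - 1)), study_id=sid).mean_auroc
    cross = pd.DataFrame(np.nan, index=ids, columns=ids)
    for tr in ids:
        for te in ids:
            if tr == te:
                cross.loc[tr, te] = within[tr]
                continue
            cross.loc[tr, te] = predict.cross_study(
                datasets[tr], datasets[te], clf, n_repeats=cfg.transfer_repeats,
                seed=int(rng.integers(2**31 - 1)), train_id=tr, test_id=te).mean_auroc
    lodo = {}
    for sid in ids:
        lodo[sid] = predict.lodo(datasets, sid, clf, n_repeats=cfg.transfer_repeats,
                                 seed=int(rng.integers(2**31 - 1))).mean_auroc
    return {"within": within, "cross_matrix": cross, "lodo": lodo}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; write TSV outputs and a JSON summary to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": cfg.seed}

    if not cfg.synth_specs:
        raise RuntimeError("stage 'data' failed: no synthetic study specs configured "
                           "(external count loading requires per-study TSVs)")
    studies, metadata, truth = synth.generate_cohort_set(
        cfg.synth_specs, cfg.synth_effects, cfg.seed)
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    (out / "truth.json").write_text(truth.to_json())
    for st in studies:
        st.viral.to_csv(out / f"counts_viral_{st.study_id}.tsv", sep="\t")
        st.bacterial.to_csv(out / f"counts_bacterial_{st.study_id}.tsv", sep="\t")

    # normalization (per study, viral)
    abund_by_study = {}
    for st in studies:
        filtered = norm.filter_taxa(st.viral, prevalence_min=cfg.prevalence_min)
        abund_by_study[st.study_id] = norm.tmm_normalize(filtered, norm.tmm_factors(filtered))
    # shared taxon space for combined / cross-study stages
    common = None
    for ab in abund_by_study.values():
        common = ab.index if common is None else common.intersection(ab.index)
    abund_by_study = {k: v.loc[common] for k, v in abund_by_study.items()}
    log.info("normalized: %d shared taxa across %d studies", len(common), len(studies))

    if cfg.run_diversity:
        div = _diversity_stage(studies, metadata, cfg)
        pd.concat(div["tables"].values()).to_csv(out / "diversity.tsv", sep="\t")
        div["per_study"].to_csv(out / "diversity_associations.tsv", sep="\t", index=False)
        summary["diversity"] = {
            "pooled": div["pooled"],
            "per_study": div["per_study"].to_dict(orient="records"),
        }
        if truth is not None:
            est = {label: (g, v) for label, g, v in div["per_study_smd_shannon"]}
            summary["recovery"] = {
                "per_study_smd": [
                    {"study": s, "planted_theta": truth.theta_by_study[s],
                     "estimated_g": est[s][0], "variance": est[s][1]}
                    for s in truth.theta_by_study
                ],
            }

    if cfg.run_ordination:
        ordn = _ordination_stage(abund_by_study, metadata, cfg)
        ordn["coordinates"].to_csv(out / "pcoa.tsv", sep="\t")
        summary["ordination"] = {
            "proportion_explained": ordn["proportion_explained"],
            "permanova_study": ordn["permanova_study"],
            "permanova_disease": ordn["permanova_disease"],
            "pooled_axes": ordn["pooled_axes"],
        }

    if cfg.run_diffabund:
        da = _diffabund_stage(studies, metadata, cfg)
        for study, table in da["per_study"].items():
            table.sort_values("q").to_csv(out / f"diffabund_{study}.tsv", sep="\t")
        da["intersection"].to_csv(out / "diffabund_intersection.tsv", sep="\t", index=False)
        summary["diffabund"] = {"intersection_counts": da["intersection_counts"]}
        if truth is not None and truth.da_taxa:
            planted = set(truth.da_taxa)
            n_studies = len(studies)
            everywhere = set(da["intersection"].loc[
                da["intersection"]["n_studies"] == n_studies, "taxon"]) \
                if not da["intersection"].empty else set()
            summary.setdefault("recovery", {})["da"] = {
                "planted": len(planted),
                "recovered_in_all_studies": len(planted & everywhere),
                "false_in_all_studies": len(everywhere - planted),
            }

    if cfg.run_interkingdom:
        species = sorted({xk["species"] for xk in truth.correlations}) if truth.correlations else []
        # species panel: differentially abundant bacteria across studies, or the
        # most abundant species when the intersection is empty
        da_b = _diffabund_stage(studies, metadata, cfg, kingdom="bacterial")
        if not da_b["intersection"].empty:
            species = sorted(set(species) | set(
                da_b["intersection"].loc[da_b["intersection"]["n_studies"] >= 2, "taxon"]))
        if not species:
            mean_ab = sum(st.bacterial.mean(axis=1) for st in studies)
            species = sorted(mean_ab.nlargest(27).index)
        grids = _interkingdom_stage(studies, metadata, truth.viral_family_map, species, cfg)
        long = pd.concat([interkingdom.grid_to_long(g, group) for group, g in grids.items()])
        long.to_csv(out / "interkingdom.tsv", sep="\t", index=False)
        summary["interkingdom"] = {
            group: {"n_significant": int(g.significant.to_numpy().sum()),
                    "n_tested": int((~np.isnan(g.q.to_numpy())).sum())}
            for group, g in grids.items()
        }
        if truth.correlations:
            rec = []
            for xk in truth.correlations:
                for group, key in (("control", "rho_control"), ("CRC", "rho_case")):
                    g = grids[group]
                    rec.append({
                        "family": xk["family"], "species": xk["species"], "group": group,
                        "planted_rho": xk[key],
                        "pooled_r": float(g.pooled_r.at[xk["family"], xk["species"]]),
                        "q": float(g.q.at[xk["family"], xk["species"]]),
                    })
            summary.setdefault("recovery", {})["correlations"] = rec

    if cfg.run_predict:
        pred = _predict_stage(abund_by_study, metadata, cfg)
        pred["cross_matrix"].to_csv(out / "auroc_matrix.tsv", sep="\t")
        summary["predict"] = {
            "within": pred["within"],
            "lodo": pred["lodo"],
            "cross_mean_offdiag": float(np.nanmean(
                pred["cross_matrix"].to_numpy()[~np.eye(len(pred["within"]), dtype=bool)])),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    log.info("pipeline complete; summary at %s", out / "summary.json")
    return summary
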