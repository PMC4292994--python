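"""End-to-end pipeline stages driven by a YAML config.

Each stage reads its inputs from the run directory (or the configured
paths), writes versioned TSV outputs plus a log of parameters and dropped
items, and never mutates its inputs, so any stage can be re-run from saved
intermediates.  All randomness is seeded explicitly from the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, concordance, enrichment, hostfactors, preprocess
from . import synthdata
from .io import (GenotypeTable, MetadataTable, read_genotypes,
                 read_gmt, read_metadata, read_taxa_table)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "depth": 2000,
    "maf": 0.1,
    "callrate": 0.95,
    "prevalence": 0.75,
    "collapse_r": 0.95,
    "alpha": 0.05,
    "concordance_fdr": 0.25,
    "network_fdr": 0.05,
    "n_null": 100_000,
    "min_pairs": 3,
}


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; round-trips through YAML."""

    run_dir: str = "runs/default"
    seed: int = 0
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        t = dict(DEFAULT_THRESHOLDS)
        t.update(self.thresholds or {})
        self.thresholds = t
        if not 0 < t["prevalence"] <= 1:
            raise ValueError("prevalence threshold must lie in (0, 1]")
        if not 0 <= t["maf"] < 0.5:
            raise ValueError("MAF floor must lie in [0, 0.5)")
        if not 0 < t["callrate"] <= 1:
            raise ValueError("call-rate threshold must lie in (0, 1]")
        if not 0 < t["alpha"] < 1:
            raise ValueError("nominal alpha must lie in (0, 1)")
        if not 0 < t["concordance_fdr"] < 1:
            raise ValueError("concordance FDR must lie in (0, 1)")
        if not 0 < t["network_fdr"] < 1:
            raise ValueError("network FDR must lie in (0, 1)")
        if t["depth"] <= 0 or t["n_null"] <= 0:
            raise ValueError("depth and n_null must be positive")
        if not 0 < t["collapse_r"] <= 1:
            raise ValueError("collapse r threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"run_dir": self.run_dir, "seed": self.seed,
                            "thresholds": self.thresholds,
                            "simulate": self.simulate,
                            "inputs": self.inputs}, fh, sort_keys=True)


def _rundir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.run_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _log_stage(rundir: Path, stage: str, payload: dict) -> None:
    logpath = rundir / f"{stage}.log.json"
    with open(logpath, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def _default_effects(cfg: PipelineConfig):
    effects = [synthdata.PlantedEffect(e["snp"], e["taxon"], float(e["beta"]),
                                       tuple(e.get("conserved_in", ())))
               for e in cfg.simulate.get("planted", [])]
    return effects


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate the multi-cohort fixture and write it under the run dir."""
    rundir = _rundir(cfg)
    sim = cfg.simulate
    seed = int(sim.get("seed", cfg.seed))
    overrides = {k: sim[k] for k in ("n_risk_snps", "n_null_snps", "n_taxa",
                                     "n_rare_taxa", "dispersion")
                 if k in sim}
    specs = synthdata.study_specs(seed=seed, **overrides)
    if "cohorts" in sim:
        specs = [synthdata.CohortSpec(c["id"], n_subjects=c["n"], seed=seed
                                      + i, **overrides)
                 for i, c in enumerate(sim["cohorts"])]
    effects = _default_effects(cfg)
    locus = synthdata.nod2_like_locus() if sim.get("aggregate_locus", True) \
        else None
    study = synthdata.simulate_study(
        specs, effects=effects, aggregate_locus=locus,
        cohort_offset_sd=float(sim.get("cohort_offset_sd", 0.1)), seed=seed)
    newick = synthdata.random_bifurcating_tree(specs[0].taxon_ids, seed=seed)
    manifest = {"seed": seed, "cohorts": [s.cohort_id for s in specs],
                "n_subjects": [s.n_subjects for s in specs]}
    for cid, (g, m, t) in study.items():
        synthdata.write_cohort(rundir / "fixtures", cid, g, m, t,
                               effects=effects, newick=newick,
                               manifest=manifest)
    _log_stage(rundir, "simulate", manifest)
    return {"cohorts": list(study)}


def _load_cohort(cfg: PipelineConfig, cid: str):
    rundir = Path(cfg.run_dir)
    fx = rundir / "fixtures"
    g = read_genotypes(fx / f"{cid}_genotypes.tsv",
                       fx / f"{cid}_snp_annotations.tsv")
    m = read_metadata(fx / f"{cid}_metadata.tsv")
    t = read_taxa_table(fx / f"{cid}_taxa.tsv", format="tsv")
    return g, m, t


def _cohort_ids(cfg: PipelineConfig) -> list:
    rundir = Path(cfg.run_dir)
    manifest = rundir / "fixtures" / "manifest.yaml"
    if manifest.exists():
        with open(manifest, encoding="utf-8") as fh:
            return yaml.safe_load(fh)["cohorts"]
    raise FileNotFoundError("no fixture manifest; run the simulate stage "
                            "or configure input paths")


def stage_preprocess(cfg: PipelineConfig) -> dict:
    """Rarefy, filter SNPs, collapse redundant taxa, split by prevalence."""
    rundir = _rundir(cfg)
    t_cfg = cfg.thresholds
    outdir = rundir / "processed"
    outdir.mkdir(exist_ok=True)
    summary = {}
    for cid in _cohort_ids(cfg):
        g, m, taxa = _load_cohort(cfg, cid)
        rarefied = preprocess.rarefy(taxa, depth=int(t_cfg["depth"]),
                                     seed=cfg.seed)
        g2 = preprocess.callrate_filter(
            preprocess.maf_filter(g, floor=t_cfg["maf"]),
            min_callrate=t_cfg["callrate"])
        collapsed, cmap = preprocess.collapse_correlated(
            rarefied, r_threshold=t_cfg["collapse_r"])
        split = preprocess.prevalence_split(collapsed,
                                            threshold=t_cfg["prevalence"])
        collapsed.to_tsv(outdir / f"{cid}_taxa.tsv")
        g2.to_tsv(outdir / f"{cid}_genotypes.tsv",
                  outdir / f"{cid}_snp_annotations.tsv")
        m.to_tsv(outdir / f"{cid}_metadata.tsv")
        cmap.to_frame().to_csv(outdir / f"{cid}_collapse_map.tsv", sep="\t",
                               index=False)
        pd.Series(split.prevalence, name="prevalence").to_csv(
            outdir / f"{cid}_prevalence.tsv", sep="\t",
            index_label="feature")
        summary[cid] = {
            "samples_kept": int(collapsed.data.shape[0]),
            "samples_dropped": int(taxa.data.shape[0]
                                   - collapsed.data.shape[0]),
            "snps_kept": int(g2.data.shape[1]),
            "snps_dropped": int(g.data.shape[1] - g2.data.shape[1]),
            "linear_features": len(split.linear_features),
            "logistic_features": len(split.logistic_features),
        }
    _log_stage(rundir, "preprocess", {"thresholds": t_cfg, **summary})
    return summary


def stage_associate(cfg: PipelineConfig) -> dict:
    """Per-cohort covariate-adjusted SNP-taxon tests (linear + logistic)."""
    rundir = _rundir(cfg)
    outdir = rundir / "associations"
    outdir.mkdir(exist_ok=True)
    t_cfg = cfg.thresholds
    procdir = rundir / "processed"
    summary = {}
    for cid in _cohort_ids(cfg):
        g = read_genotypes(procdir / f"{cid}_genotypes.tsv",
                           procdir / f"{cid}_snp_annotations.tsv")
        m = read_metadata(procdir / f"{cid}_metadata.tsv")
        taxa = read_taxa_table(procdir / f"{cid}_taxa.tsv")
        pcs = preprocess.genotype_pcs(g, k=3)
        X = association.build_design(m, pcs)
        rel = taxa.relative_abundance()
        split = preprocess.prevalence_split(taxa,
                                            threshold=t_cfg["prevalence"])
        transformed = pd.DataFrame(
            preprocess.transform_arcsine_sqrt(
                rel[split.linear_features].to_numpy()),
            index=rel.index, columns=split.linear_features)
        res = association.association_screen(g, transformed, X,
                                             cohort_id=cid)
        logi_rows = []
        for feat in split.logistic_features:
            presence = (taxa.data[feat] > 0).astype(float)
            dosages = g.data.astype(float)
            dosages = dosages.fillna(dosages.mean(axis=0))
            for snp in g.snp_ids:
                Xd = X.copy()
                Xd[association.DOSAGE_COLUMN] = dosages[snp]
                r = association.logistic_test(presence, Xd, snp_id=snp,
                                              taxon_id=feat, cohort_id=cid)
                logi_rows.append(r.__dict__)
        if logi_rows:
            res = pd.concat([res, pd.DataFrame(logi_rows)],
                            ignore_index=True)
        res["q"] = association.bh_fdr(res["p"].to_numpy())
        res.to_csv(outdir / f"{cid}_associations.tsv", sep="\t", index=False)
        summary[cid] = {"n_tests": int(len(res)),
                        "n_linear": int((res["family"] == "linear").sum()),
                        "n_logistic": int((res["family"] == "logistic").sum())}
    _log_stage(rundir, "associate", summary)
    return summary


def stage_concord(cfg: PipelineConfig) -> pd.DataFrame:
    """Cross-cohort MCC sign-concordance screen."""
    rundir = _rundir(cfg)
    t_cfg = cfg.thresholds
    results = {}
    gene_map = {}
    for cid in _cohort_ids(cfg):
        res = pd.read_csv(rundir / "associations" /
                          f"{cid}_associations.tsv", sep="\t")
        results[cid] = res
        ann = pd.read_csv(rundir / "processed" /
                          f"{cid}_snp_annotations.tsv", sep="\t",
                          index_col=0)
        gene_map.update(ann["gene"].to_dict())
    screen = concordance.concordance_screen(
        results, alpha=t_cfg["alpha"], fdr=t_cfg["concordance_fdr"],
        min_pairs=int(t_cfg["min_pairs"]), gene_map=gene_map, seed=cfg.seed)
    screen.to_csv(rundir / "concordance.tsv", sep="\t", index=False)
    _log_stage(rundir, "concord", {
        "n_tests": int(len(screen)),
        "n_significant": int(screen["significant"].sum())
        if len(screen) else 0})
    return screen


def stage_enrich(cfg: PipelineConfig) -> pd.DataFrame:
    """Rank-product pathway enrichment against size-matched null sets."""
    rundir = _rundir(cfg)
    t_cfg = cfg.thresholds
    gmt_path = cfg.inputs.get("pathways")
    if gmt_path is None:
        raise FileNotFoundError("config inputs.pathways (GMT) is required "
                                "for the enrich stage")
    sets = enrichment.bin_pathways(read_gmt(gmt_path))
    frames, gene_map, status = [], {}, {}
    for cid in _cohort_ids(cfg):
        res = pd.read_csv(rundir / "associations" /
                          f"{cid}_associations.tsv", sep="\t")
        frames.append(res)
        ann = pd.read_csv(rundir / "processed" /
                          f"{cid}_snp_annotations.tsv", sep="\t",
                          index_col=0)
        gene_map.update(ann["gene"].to_dict())
        status.update(ann["status"].to_dict())
    allres = pd.concat(frames, ignore_index=True)
    allres["gene"] = allres["snp_id"].map(gene_map)
    null_pool = {gene_map[s] for s, st in status.items() if st == "null"}
    screen = enrichment.rank_product_screen(
        sets, allres[["gene", "p"]], null_pool,
        n_null=int(t_cfg["n_null"]), seed=cfg.seed)
    screen.to_csv(rundir / "enrichment.tsv", sep="\t", index=False)
    _log_stage(rundir, "enrich", {"n_pathways": int(len(screen))})
    return screen


def _pooled_tables(cfg: PipelineConfig):
    gs, ms, ts = [], [], []
    for cid in _cohort_ids(cfg):
        g, m, t = (read_genotypes(Path(cfg.run_dir) / "processed" /
                                  f"{cid}_genotypes.tsv",
                                  Path(cfg.run_dir) / "processed" /
                                  f"{cid}_snp_annotations.tsv"),
                   read_metadata(Path(cfg.run_dir) / "processed" /
                                 f"{cid}_metadata.tsv"),
                   read_taxa_table(Path(cfg.run_dir) / "processed" /
                                   f"{cid}_taxa.tsv"))
        gs.append(g)
        ms.append(m)
        ts.append(t)
    shared_snps = sorted(set.intersection(*(set(g.snp_ids) for g in gs)))
    shared_taxa = sorted(set.intersection(*(set(t.feature_ids) for t in ts)))
    g_all = GenotypeTable(pd.concat([g.data[shared_snps] for g in gs]),
                          gs[0].annotations.loc[shared_snps])
    m_all = MetadataTable(pd.concat([m.data for m in ms]))
    t_all = ts[0].with_data(pd.concat([t.data[shared_taxa] for t in ts]))
    return g_all, m_all, t_all


def _locus_dosage(cfg, g_all):
    locus_variants = [s for s in g_all.snp_ids
                      if g_all.annotations.loc[s, "locus"]]
    if locus_variants:
        return association.aggregate_dosage(g_all, locus_variants)
    return None


def stage_hostnet(cfg: PipelineConfig) -> pd.DataFrame:
    """Host-factor to taxon association network."""
    rundir = _rundir(cfg)
    g_all, m_all, t_all = _pooled_tables(cfg)
    dosage = _locus_dosage(cfg, g_all)
    extra = pd.DataFrame({"locus_dosage": dosage}) if dosage is not None \
        else None
    edges = hostfactors.host_network(
        t_all, m_all, extra_factors=extra,
        fdr=cfg.thresholds["network_fdr"],
        min_per_taxon=int(cfg.thresholds.get("min_per_taxon", 4)))
    frame = hostfactors.edges_to_frame(edges)
    frame.to_csv(rundir / "host_network.tsv", sep="\t", index=False)
    _log_stage(rundir, "hostnet", {"n_edges": int(len(frame))})
    return frame


def stage_mdi(cfg: PipelineConfig) -> dict:
    """MDI per subject and the antibiotics association test."""
    rundir = _rundir(cfg)
    g_all, m_all, t_all = _pooled_tables(cfg)
    spec = hostfactors.load_default_mdi_spec()
    binned = preprocess.bin_taxonomy(t_all)
    scores = hostfactors.mdi_score(binned.relative_abundance(), spec)
    scores.rename("mdi").to_csv(rundir / "mdi_scores.tsv", sep="\t",
                                index_label="subject")
    dosage = _locus_dosage(cfg, g_all)
    abx = m_all.data["antibiotics"]
    try:
        beta, p = hostfactors.mdi_antibiotics_test(scores, abx, dosage)
        out = {"beta": float(beta), "p": float(p)}
    except ValueError as exc:
        out = {"error": str(exc)}
    _log_stage(rundir, "mdi", out)
    return out


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "associate": stage_associate,
    "concord": stage_concord,
    "enrich": stage_enrich,
    "hostnet": stage_hostnet,
    "mdi": stage_mdi,
}

#: enrich requires a pathway GMT input; `all` runs every other stage and
#: includes enrich only when configured.
ALL_ORDER = ("simulate", "preprocess", "associate", "concord", "enrich",
             "hostnet", "mdi")


def run(stage: str, cfg: PipelineConfig) -> dict:
    if stage == "all":
        out = {}
        for name in ALL_ORDER:
            if name == "enrich" and "pathways" not in cfg.inputs:
                logger.info("run all: skipping enrich (no pathway GMT "
                            "configured)")
                continue
            out[name] = STAGES[name](cfg)
        return out
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return {stage: STAGES[stage](cfg)}
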