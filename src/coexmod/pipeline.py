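"""End-to-end orchestration of the synthetic study.

``run_all`` simulates the case single-cell dataset, the healthy reference,
the bulk cohort and the candidate list; preprocesses and clusters the cells;
discovers consensus co-expression modules per annotated cell type; tests
module preservation in the reference; projects module activity into the bulk
samples and associates it with histology grades; and maps candidate genes and
gene-set collections onto the modules.  All outputs are plain-text
(MTX/TSV/JSON/GMT) and byte-identical across runs with the same configs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import enrichment as enr
from . import network as net
from . import preprocess as pp
from .io import ExpressionMatrix, PipelineConfig, write_gmt, write_mtx_triplet, \
    write_sample_metadata
from .simulate import (SimConfig, simulate_bulk_dataset, simulate_candidate_genes,
                       simulate_geneset_collection, simulate_reference_dataset,
                       simulate_sc_dataset)

logger = logging.getLogger("coexmod")

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def simulate_all(sim_cfg: SimConfig, out_dir: Path) -> dict:
    """Generate all synthetic inputs and write them via the standard formats."""
    data_dir = Path(out_dir) / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    sc, truth = simulate_sc_dataset(sim_cfg)
    ref = simulate_reference_dataset(sim_cfg, truth)
    bulk, bulk_meta = simulate_bulk_dataset(sim_cfg, truth)
    target = f"M-{truth.cell_types[0]}-1"
    candidates = simulate_candidate_genes(
        truth, n_total=20, planted_per_module={target: 8}, seed=sim_cfg.seed,
    )
    genesets = simulate_geneset_collection(truth, seed=sim_cfg.seed)

    write_mtx_triplet(sc, data_dir / "sc_counts")
    sc.obs_meta.to_csv(data_dir / "sc_cellmeta.tsv", sep="\t",
                       index_label="obs_id")
    write_mtx_triplet(ref, data_dir / "ref_counts")
    ref.obs_meta.to_csv(data_dir / "ref_cellmeta.tsv", sep="\t",
                        index_label="obs_id")
    bulk_df = pd.DataFrame(bulk.dense().astype(int), index=bulk.gene_ids,
                           columns=bulk.obs_ids)
    bulk_df.to_csv(data_dir / "bulk_counts.tsv", sep="\t", index_label="gene")
    write_sample_metadata(bulk_meta, data_dir / "bulk_metadata.tsv")
    (data_dir / "candidate_genes.txt").write_text(
        "".join(g + "\n" for g in candidates))
    write_gmt(genesets, data_dir / "gene_sets.gmt")
    truth.to_json(data_dir / "ground_truth.json")
    sim_cfg.to_yaml(data_dir / "sim_config.yaml")
    return {
        "sc": sc, "truth": truth, "ref": ref, "bulk": bulk,
        "bulk_meta": bulk_meta, "candidates": candidates, "genesets": genesets,
    }


def run_all(cfg: PipelineConfig, sim_cfg: SimConfig, out_dir) -> dict:
    """Run the whole pipeline on freshly simulated data; returns key objects."""
    out_dir = Path(out_dir)
    res_dir = out_dir / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    cfg.log_resolved()
    cfg.to_yaml(res_dir / "config_resolved.yaml")

    data = simulate_all(sim_cfg, out_dir)
    sc, truth, ref = data["sc"], data["truth"], data["ref"]

    # --- single-cell preprocessing, clustering, annotation -----------------
    sc_qc = pp.qc_filter_cells(sc, cfg.min_genes, cfg.max_genes,
                               cfg.max_mito_frac, cfg.mito_prefix)
    sc_log = pp.normalize_log(sc_qc)
    donors = sc_log.obs_meta["donor"].to_numpy()
    clusters = pp.cluster_pipeline(sc_log, donors, cfg.n_hvgs, cfg.n_pcs,
                                   cfg.k_neighbors, cfg.resolution,
                                   cfg.seed_cluster)
    ref_log = pp.normalize_log(ref)
    centroids = pp.build_reference_centroids(ref_log)
    annotation = pp.annotate_nearest_centroid(sc_log, clusters, centroids,
                                              cfg.min_corr)
    labels = clusters.as_series(sc_log.obs_ids)
    cell_types = labels.map(annotation)
    lab_df = pd.DataFrame({"cluster": labels, "cell_type": cell_types})
    lab_df.to_csv(res_dir / "clusters.tsv", sep="\t", index_label="obs_id")

    # --- consensus module discovery per annotated cell type ----------------
    module_sets: dict[str, net.ModuleSet] = {}
    for ct in sorted(set(cell_types) - {"Unknown"}):
        mask = (cell_types == ct).to_numpy()
        if mask.sum() < max(cfg.min_cells_per_type, 100):
            logger.info("skipping %s: only %d cells", ct, int(mask.sum()))
            continue
        sub = sc_log.subset_obs(mask)
        scaled = pp.scale_within_batch(sub, sub.obs_meta["donor"].to_numpy())
        mset = net.consensus_modules(scaled, cfg, cell_type=ct)
        if mset.modules:
            module_sets[ct] = mset
            mset.to_json(res_dir / f"modules_{ct}.json")
    all_modules = [m for ms in module_sets.values() for m in ms.modules]
    if all_modules:
        gmt = {m.module_id: (f"cell type {m.cell_type}", m.genes)
               for m in all_modules}
        from .io import GeneSetCollection
        write_gmt(GeneSetCollection(gmt), res_dir / "modules.gmt")

    # --- preservation in the healthy reference -----------------------------
    pres_frames = []
    for ct, mset in module_sets.items():
        mask = (ref_log.obs_meta["cell_type"] == ct).to_numpy()
        if mask.sum() < 50:
            logger.info("preservation skipped for %s: %d reference cells",
                        ct, int(mask.sum()))
            continue
        ref_sub = ref_log.subset_obs(mask)
        pres_frames.append(assoc.preservation_table(
            mset.modules, ref_sub, cfg.m_perm, cfg.seed_perm))
    preservation = pd.concat(pres_frames) if pres_frames else pd.DataFrame()
    if len(preservation):
        tested = ~preservation["skipped"]
        preservation.loc[tested, "p_adj"] = assoc.bh_adjust(
            preservation.loc[tested, "p"].to_numpy())
        _write_tsv(preservation, res_dir / "preservation.tsv")

    # --- bulk projection and phenotype association -------------------------
    association = pd.DataFrame()
    if all_modules:
        bulk_norm, size_factors = pp.normalize_median_of_ratios(data["bulk"])
        bulk_log = ExpressionMatrix(np.log1p(bulk_norm.dense()),
                                    bulk_norm.gene_ids, bulk_norm.obs_ids,
                                    bulk_norm.obs_meta, "lognorm")
        activity = assoc.module_activity(bulk_log, all_modules)
        _write_tsv(activity.standardized, res_dir / "activity_bulk.tsv")
        association = assoc.associate_modules(
            activity, data["bulk_meta"], cfg.phenotypes, cfg.covariates,
            cfg.b_assoc, cfg.seed_assoc,
        )
        _write_tsv(association, res_dir / "association.tsv")

        # module activity per single-cell cluster
        sc_scaled = pp.scale_within_batch(sc_log, donors)
        sc_act = assoc.module_activity(sc_scaled, all_modules)
        by_cluster = assoc.activity_by_cluster(
            sc_act, cell_types.to_dict())
        _write_tsv(by_cluster, res_dir / "activity_by_cluster.tsv")

    # --- enrichment and overlap structure ----------------------------------
    if all_modules:
        cand = enr.enrich_candidates(list(module_sets.values()),
                                     data["candidates"])
        _write_tsv(cand, res_dir / "enrichment_candidates.tsv")
        universe = set()
        for ms in module_sets.values():
            universe.update(ms.all_genes)
        geneset_frames = []
        for mod in all_modules:
            tbl = enr.enrich_genesets(mod, data["genesets"], universe,
                                      cfg.min_set, cfg.max_set)
            tbl = tbl.assign(module_id=mod.module_id)
            geneset_frames.append(tbl.reset_index())
        if geneset_frames:
            gs = pd.concat(geneset_frames, ignore_index=True)
            gs = gs.set_index(["module_id", "set_name"])
            _write_tsv(gs, res_dir / "enrichment_gene_sets.tsv")
    if len(all_modules) >= 2:
        overlap = enr.module_overlap_matrix(list(module_sets.values()))
        _write_tsv(overlap.values, res_dir / "overlap_matrix.tsv")

    summary = {
        "n_cells_post_qc": sc_qc.n_obs,
        "n_clusters": len(set(labels)),
        "cell_types_analysed": sorted(module_sets),
        "n_modules": len(all_modules),
        "n_significant_associations": int(association["significant"].sum())
        if len(association) else 0,
    }
    with open(res_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {
        "truth": truth, "clusters": clusters, "annotation": annotation,
        "module_sets": module_sets, "preservation": preservation,
        "association": association, "summary": summary,
    }
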