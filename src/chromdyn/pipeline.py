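"""End-to-end orchestration of the synthetic or file-based analysis.

Stages run in dependency order (atlas -> dynamics -> footprint ->
single_cell -> integrate); every output file lands in the configured
output directory and is listed in a manifest with a SHA-256 content hash,
so a rerun with the same configuration and seed reproduces the hashes of
all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics as dyn
from . import footprinting as fp
from . import integration as integ
from . import peak_atlas as atlas_mod
from . import single_cell as sc
from .genomic_io import write_bed, write_count_table, write_gene_models
from .synthetic import (
    SimulationConfig,
    gene_models_from_universe,
    simulate_accessibility,
    simulate_cut_profiles,
    simulate_gene_universe,
    simulate_knockdown,
    simulate_single_cells,
)

logger = logging.getLogger("chromdyn.pipeline")

STAGE_ORDER = ("atlas", "dynamics", "footprint", "single_cell", "integrate")
STAGE_DEPS = {
    "atlas": (),
    "dynamics": ("atlas",),
    "footprint": (),
    "single_cell": (),
    "integrate": ("dynamics", "single_cell"),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "chromdyn_out"
    stages: dict = field(
        default_factory=lambda: {name: True for name in STAGE_ORDER}
    )
    simulation: dict = field(default_factory=dict)
    # thresholds, defaulting to the values used throughout the package
    merge_gap: int = 100
    min_frac: float = 0.5
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    min_cpm: float = 4.0
    min_fold_promoter: float = 2.0
    min_fold_distal: float = 2.5
    alpha: float = 0.05
    n_fuzzy_clusters: int = 12
    n_merged_clusters: int = 4
    fuzzifier: float = 2.0
    fence_factor: float = 3.0
    qc_n_mads: float = 3.0
    gene_min_mean: float = 0.05
    hvg_fdr: float = 0.05
    auc_top_fraction: float = 0.05
    pseudobulk_min_cpm: float = 2.0
    pseudobulk_min_fold: float = 1.5
    de_min_fold: float = 1.2
    bins_kb: tuple = integ.DEFAULT_BINS_KB

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        if "stages" in raw:
            stages = {name: True for name in STAGE_ORDER}
            stages.update(raw["stages"])
            config.stages = stages
        return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages on a seeded synthetic study; return the manifest."""
    for stage, deps in STAGE_DEPS.items():
        if config.stages.get(stage, True):
            for dep in deps:
                if not config.stages.get(dep, True):
                    raise ValueError(
                        f"stage {stage!r} requires stage {dep!r}, which is disabled"
                    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}

    def _save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        written.append(path)

    t0 = time.time()
    sim_config = SimulationConfig(seed=config.seed, **config.simulation)
    universe = simulate_gene_universe(sim_config)
    genes = gene_models_from_universe(universe)
    write_gene_models(genes, outdir / "genes.tsv")
    written.append(outdir / "genes.tsv")
    logger.info("simulated gene universe: %d genes", len(genes))

    merged_sets: dict = {}
    if config.stages.get("atlas", True):
        t = time.time()
        peaks, counts, peak_truth, _ = simulate_accessibility(sim_config, universe)
        peak_atlas = atlas_mod.build_atlas(
            [peaks],
            genes,
            counts=counts,
            max_gap=config.merge_gap,
            promoter_window=(config.promoter_upstream, config.promoter_downstream),
            condition_names=["union"],
        )
        write_bed(peaks, outdir / "atlas_peaks.bed")
        written.append(outdir / "atlas_peaks.bed")
        write_count_table(counts, outdir / "atlas_counts.tsv")
        written.append(outdir / "atlas_counts.tsv")
        _save(
            peak_atlas.partition.to_frame().join(peak_atlas.nearest_gene, how="left"),
            "atlas_annotation.tsv",
        )
        results["atlas"] = {
            "n_peaks": len(peaks),
            "partition_counts": peak_atlas.partition.value_counts().to_dict(),
        }
        results["_atlas_objects"] = (peaks, counts, peak_truth)
        logger.info("atlas stage done in %.1fs", time.time() - t)

    if config.stages.get("dynamics", True):
        t = time.time()
        peaks, counts, peak_truth = results["_atlas_objects"]
        diff = dyn.differential_features(
            counts,
            min_cpm=config.min_cpm,
            min_fold=config.min_fold_distal,
            alpha=config.alpha,
        )
        _save(diff, "differential_accessibility.tsv")
        norm = dyn.cpm_normalize(counts)
        z = dyn.zscore_profiles(norm)
        clustering = dyn.fuzzy_cmeans(
            z,
            c=config.n_fuzzy_clusters,
            m=config.fuzzifier,
            seed=config.seed,
        )
        clustering = dyn.merge_clusters(clustering, target_K=config.n_merged_clusters)
        _save(clustering.membership, "fuzzy_membership.tsv")
        _save(
            pd.DataFrame(
                {
                    "hard_label": clustering.hard_label,
                    "merged_label": clustering.merged_label,
                }
            ),
            "cluster_labels.tsv",
        )
        peak_by_name = {p.name: p for p in peaks}
        for label, grp in clustering.merged_label.groupby(clustering.merged_label):
            merged_sets[int(label)] = [peak_by_name[n] for n in grp.index]
        results["dynamics"] = {
            "n_differential": int(diff["passes"].sum()),
            "cluster_sizes": clustering.merged_label.value_counts().to_dict(),
        }
        results["_clustering"] = clustering
        logger.info("dynamics stage done in %.1fs", time.time() - t)

    if config.stages.get("footprint", True):
        t = time.time()
        cuts = simulate_cut_profiles(sim_config)
        cond_a, cond_b = sim_config.condition_names[:2]
        prof_a = fp.aggregate_cuts(
            cuts.occurrences,
            cuts.cut_counts[cond_a],
            cond_a,
            cuts.libsizes[cond_a],
            cuts.motif_width,
            cuts.window_halfwidth,
        )
        prof_b = fp.aggregate_cuts(
            cuts.occurrences,
            cuts.cut_counts[cond_b],
            cond_b,
            cuts.libsizes[cond_b],
            cuts.motif_width,
            cuts.window_halfwidth,
        )
        table, bag = fp.footprint_table(
            prof_a, prof_b, fence_factor=config.fence_factor
        )
        _save(table, "footprint_stats.tsv")
        polygons = {
            "bag": None if bag.bag_polygon is None else bag.bag_polygon.tolist(),
            "fence": None if bag.fence_polygon is None else bag.fence_polygon.tolist(),
            "depth_median": bag.depth_median.tolist(),
        }
        with open(outdir / "footprint_polygons.json", "w") as fh:
            json.dump(polygons, fh, indent=2)
        written.append(outdir / "footprint_polygons.json")
        results["footprint"] = {
            "n_motifs": len(table),
            "n_outliers": int((table["classification"] == "outlier").sum()),
        }
        logger.info("footprint stage done in %.1fs", time.time() - t)

    if config.stages.get("single_cell", True):
        t = time.time()
        cells = simulate_single_cells(sim_config, universe)
        qc = sc.qc_cells(cells.counts, n_mads=config.qc_n_mads)
        kept_genes = sc.filter_genes(cells.counts, qc, min_mean=config.gene_min_mean)
        sf, cpm = sc.normalize_cells(cells.counts[kept_genes], qc)
        hvgs, hvg_table = sc.hvg_select(cpm, fdr=config.hvg_fdr)
        condition = cells.cells["condition"].loc[cpm.index]
        pseudotime = sc.pseudotime_rank(cpm, list(hvgs), condition=condition)

        regulon_genes = [
            g
            for g in universe.index[
                (universe["regulon"] == 0) & ~universe["is_driver"]
            ]
            if g in cpm.columns
        ]
        binary = (cells.counts.loc[cpm.index, kept_genes] > 0).astype(np.int8)
        z, cond_summary = sc.coexpression_score(binary, regulon_genes, condition)
        auc = sc.regulon_auc(
            cpm, regulon_genes, top_fraction=config.auc_top_fraction, seed=config.seed
        )
        bulk = sc.pseudobulk(cells.counts[kept_genes], cells.cells["condition"], qc)
        _save(
            pd.DataFrame(
                {
                    "condition": cells.cells["condition"],
                    "qc_pass": qc,
                    "library_size": cells.counts.sum(axis=1),
                }
            ),
            "cell_qc.tsv",
        )
        _save(hvg_table, "hvg_decomposition.tsv")
        _save(
            pd.DataFrame(
                {"pseudotime": pseudotime, "coexpression_z": z, "regulon_auc": auc["auc"]}
            ),
            "cell_scores.tsv",
        )
        write_count_table(bulk, outdir / "pseudobulk_counts.tsv")
        written.append(outdir / "pseudobulk_counts.tsv")
        results["single_cell"] = {
            "n_cells": int(len(qc)),
            "n_qc_pass": int(qc.sum()),
            "n_genes_kept": int(len(kept_genes)),
            "n_hvgs": int(len(hvgs)),
        }
        results["_sc_objects"] = (cells, bulk)
        logger.info("single_cell stage done in %.1fs", time.time() - t)

    if config.stages.get("integrate", True):
        t = time.time()
        cells, bulk = results["_sc_objects"]
        # expression clusters: pseudobulk filter then fuzzy clustering
        bulk_diff = dyn.differential_features(
            bulk,
            min_cpm=config.pseudobulk_min_cpm,
            min_fold=config.pseudobulk_min_fold,
            alpha=config.alpha,
        )
        dyn_genes = bulk_diff.index[bulk_diff["passes"]]
        if len(dyn_genes) < 2 * config.n_merged_clusters:
            # small studies can starve the q-filter; fall back to the
            # CPM + fold candidate set so clustering stays meaningful
            candidates = (bulk_diff["max_cpm"] >= config.pseudobulk_min_cpm) & (
                bulk_diff["max_pairwise_fold"] > config.pseudobulk_min_fold
            )
            dyn_genes = bulk_diff.index[candidates]
        if len(dyn_genes) < 2 * config.n_merged_clusters:
            raise ValueError("too few dynamic genes for expression clustering")
        norm = dyn.cpm_normalize(bulk.subset_rows(list(dyn_genes)))
        z = dyn.zscore_profiles(norm)
        rna_clustering = dyn.merge_clusters(
            dyn.fuzzy_cmeans(
                z,
                c=min(config.n_fuzzy_clusters, max(2, len(dyn_genes) - 1)),
                m=config.fuzzifier,
                seed=config.seed,
            ),
            target_K=config.n_merged_clusters,
        )
        rna_clusters = {
            int(label): list(grp.index)
            for label, grp in rna_clustering.merged_label.groupby(
                rna_clustering.merged_label
            )
        }
        genes_list = gene_models_from_universe(universe)
        grid = integ.distance_binned_enrichment(
            merged_sets,
            rna_clusters,
            genes_list,
            bins_kb=config.bins_kb,
        )
        _save(grid.set_index(["atac_cluster", "rna_cluster", "bin_kb"]), "concordance_grid.tsv")

        kd = simulate_knockdown(sim_config, universe)
        de = dyn.differential_expression(
            kd.counts, kd.pairs, min_fold=config.de_min_fold, alpha=config.alpha
        )
        _save(de, "knockdown_de.tsv")
        bound = list(kd.truth.index[kd.truth["bound"]])
        targets, summary = integ.call_direct_targets(bound, de)
        _save(targets, "direct_targets.tsv")
        results["integrate"] = {
            "n_rna_cluster_genes": int(len(dyn_genes)),
            "max_neg_log10_p": float(grid["neg_log10_p"].max()),
            "n_direct_targets": summary.n_direct,
            "percent_activated": summary.percent_activated,
        }
        logger.info("integrate stage done in %.1fs", time.time() - t)

    manifest = {
        "seed": config.seed,
        "stages": {s: bool(config.stages.get(s, True)) for s in STAGE_ORDER},
        "elapsed_s": round(time.time() - t0, 2),
        "results": {k: v for k, v in results.items() if not k.startswith("_")},
        "files": {str(p.name): _sha256(p) for p in sorted(set(written))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
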