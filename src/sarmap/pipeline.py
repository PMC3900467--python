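"""Two-stage end-to-end analysis of a bioactivity panel.

Stage 1 runs on the full panel: binarize, build enrichment profiles and both
bioactivity distance matrices, neighbor-joining trees, the SAC/outlier
analysis under each metric (outlier group 1 = enrichment metric, group 2 =
Tanimoto metric), and the Hamming-distance MDS diagnostic.  Stage 2 drops
targets with too few shared activities (single pass on the stage-1 panel) and
rebuilds everything — including the feature vocabulary — from the kept panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chem_features import FeatureTable, build_vocabulary, read_feature_table
from .core_data import (BioactivityMatrix, binarize, panel_summary,
                        read_activity_matrix)
from .distances import (enrichment_distance_matrix, hamming_distance_matrix,
                        tanimoto_distance_matrix)
from .embedding import mds_embed
from .enrichment import enrichment_matrix
from .phylo import neighbor_joining, write_newick
from .sac import (DEFAULT_EXCLUSION_THRESHOLD, exclusion_filter,
                  run_sac_analysis, shared_activity_stats)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "run_full_from_paths"]


@dataclass
class RunConfig:
    activity_path: str | Path | None = None
    features_path: str | Path | None = None
    activity_threshold: float = 50.0
    sac_mode: str = "variable"
    exclusion_threshold: int = DEFAULT_EXCLUSION_THRESHOLD
    mds_dims: int = 2
    mds_min_stress_change: float = 0.00005
    mds_max_steps: int = 5000
    seed: int = 0
    outdir: str | Path | None = None
    extra: dict = field(default_factory=dict)


def _analyse_stage(matrix: BioactivityMatrix, features: FeatureTable,
                   config: RunConfig, stage: str, outdir: Path | None) -> dict:
    calls = binarize(matrix, config.activity_threshold)
    summary = panel_summary(matrix, calls)
    vocab = build_vocabulary(
        FeatureTable({i.compound_id: features.get(i.compound_id)
                      for i in matrix.instances})
    )
    profiles = enrichment_matrix(calls, features, vocab)
    d_enrich = enrichment_distance_matrix(profiles)
    d_tanimoto = tanimoto_distance_matrix(calls)
    d_hamming = hamming_distance_matrix(calls)

    artifacts: dict[str, str] = {}
    trees = {}
    for name, dm in (("enrichment", d_enrich), ("tanimoto", d_tanimoto)):
        trees[name] = neighbor_joining(dm)
        if outdir is not None:
            path = outdir / f"{stage}_tree_{name}.nwk"
            write_newick(trees[name], path)
            artifacts[f"tree_{name}"] = str(path)

    sac_enrich = run_sac_analysis(calls, d_enrich, config.sac_mode)
    sac_tanimoto = run_sac_analysis(calls, d_tanimoto, config.sac_mode)
    group1, group2 = set(sac_enrich.outliers), set(sac_tanimoto.outliers)

    mds = mds_embed(d_hamming, dims=config.mds_dims,
                    min_stress_change=config.mds_min_stress_change,
                    max_steps=config.mds_max_steps, seed=config.seed)
    if outdir is not None:
        for name, dm in (("enrichment", d_enrich), ("tanimoto", d_tanimoto),
                         ("hamming", d_hamming)):
            path = outdir / f"{stage}_dist_{name}.tsv"
            dm.write_tsv(path)
            artifacts[f"dist_{name}"] = str(path)
        path = outdir / f"{stage}_sac_calls.tsv"
        sac_enrich.calls_table.to_csv(path, sep="\t", index=False)
        artifacts["sac_calls"] = str(path)
        path = outdir / f"{stage}_mds.tsv"
        labels = {t: ("outlier group 1" if t in group1 - group2 else
                      "outlier group 1+2" if t in group1 & group2 else
                      "outlier group 2" if t in group2 - group1 else
                      "non-outlier")
                  for t in matrix.target_ids}
        mds.write_tsv(path, class_labels=labels)
        artifacts["mds"] = str(path)

    return {
        "n_targets": len(matrix.target_ids),
        "n_instances": len(matrix.instances),
        "fraction_active": summary.fraction_active,
        "fraction_midband": summary.fraction_midband,
        "promiscuous_instances": summary.promiscuous_instances,
        "n_features": len(vocab),
        "sac": {
            "enrichment": {
                "neighborhood_fraction": sac_enrich.neighborhood_fraction,
                "n_series": sac_enrich.n_series,
                "outliers": sorted(group1),
            },
            "tanimoto": {
                "neighborhood_fraction": sac_tanimoto.neighborhood_fraction,
                "n_series": sac_tanimoto.n_series,
                "outliers": sorted(group2),
            },
        },
        "outlier_group1": sorted(group1),
        "outlier_group2": sorted(group2),
        "outlier_intersection": sorted(group1 & group2),
        "zero_active_targets": sac_enrich.zero_active,
        "mds_final_stress": mds.final_stress,
        "mds_converged": mds.converged,
        "artifacts": artifacts,
        "_calls": calls,  # stripped before serialization
    }


def run_full(matrix: BioactivityMatrix, features: FeatureTable,
             config: RunConfig | None = None) -> dict:
    """Run both stages and return a JSON-serializable report."""
    config = config or RunConfig()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage 1: %d targets x %d instances, threshold %.1f%%",
                len(matrix.target_ids), len(matrix.instances),
                config.activity_threshold)
    try:
        stage1 = _analyse_stage(matrix, features, config, "stage1", outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 1 failed: {exc}") from exc

    calls = stage1.pop("_calls")
    stats = shared_activity_stats(calls)
    kept, excluded = exclusion_filter(stats, config.exclusion_threshold)
    logger.info("exclusion at <= %d shared activities: %d kept, %d excluded",
                config.exclusion_threshold, len(kept), len(excluded))
    try:
        stage2 = _analyse_stage(matrix.subset_targets(kept), features, config,
                                "stage2", outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 2 failed: {exc}") from exc
    stage2.pop("_calls")

    report = {
        "parameters": {
            "activity_threshold": config.activity_threshold,
            "sac_mode": config.sac_mode,
            "exclusion_threshold": config.exclusion_threshold,
            "mds_dims": config.mds_dims,
            "mds_min_stress_change": config.mds_min_stress_change,
            "mds_max_steps": config.mds_max_steps,
            "seed": config.seed,
        },
        "stage1": stage1,
        "excluded_targets": excluded,
        "stage2": stage2,
    }
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_full_from_paths(config: RunConfig) -> dict:
    if config.activity_path is None or config.features_path is None:
        raise ValueError("activity_path and features_path are required")
    matrix = read_activity_matrix(config.activity_path)
    features = read_feature_table(config.features_path)
    return run_full(matrix, features, config)
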