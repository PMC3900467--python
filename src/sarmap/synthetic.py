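"""Synthetic bioactivity panels with ground truth.

The generator emulates the statistical structure of a full-matrix kinase
inhibition screen: clustered targets inhibited by cluster-matched chemotypes,
a handful of promiscuous pan-inhibitors, targets with deliberately few shared
activities, one target inhibited by nothing, two assay concentrations per
compound with low-concentration actives nested inside high-concentration
actives, roughly 16% active cells at the 50% threshold, and only ~2% of
values in the ambiguous 40–60% band.

Chemotype feature signatures are disjoint between clusters by default; an
overlap parameter plants cross-reactive chemotypes.  All randomness flows
from one seeded generator, so panels are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chem_features import FeatureTable, write_feature_table
from .core_data import BioactivityMatrix, CompoundInstance, write_activity_matrix

__all__ = ["SyntheticConfig", "SyntheticPanel", "generate_panel", "write_fixtures"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic screen (defaults mirror a mid-size panel:
    6 × 8 clustered targets + 3 sparse + 1 zero-active, 150 compounds at
    1 and 10 µM)."""

    n_clusters: int = 6
    targets_per_cluster: int = 8
    n_compounds: int = 150
    concentrations: tuple[float, ...] = (1.0, 10.0)
    chemotype_features_per_cluster: int = 12
    chemotype_overlap: int = 0          # signature features shared with next cluster
    background_features_per_compound: int = 8
    background_feature_pool: int = 300
    p_within: float = 0.8               # cluster-matched activity at the top conc.
    p_background: float = 0.02          # off-cluster activity per instance
    cluster_decay: float = 0.45         # activity decay per unit of cluster separation
    cluster_positions: tuple[float, ...] | None = None  # relatedness-axis layout
    target_rate_range: tuple[float, float] = (0.6, 1.0)  # per-target rate multiplier
    low_conc_factor: float = 0.6        # P(active at low conc | active at high)
    n_pan_inhibitors: int = 4
    pan_activity_prob: float = 0.9
    n_sparse_targets: int = 3
    sparse_max_shared: int = 16         # planted shared_total ceiling
    include_zero_active_target: bool = True
    active_value_range: tuple[float, float] = (60.0, 100.0)
    inactive_value_range: tuple[float, float] = (0.0, 40.0)
    midband_prob: float = 0.02          # chance of a value in [40, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        for name in ("p_within", "p_background", "low_conc_factor",
                     "pan_activity_prob", "midband_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.active_value_range[0] < self.active_value_range[1] <= 100
                and self.active_value_range[0] >= 50):
            raise ValueError("active_value_range must lie within [50, 100]")
        if not (0 <= self.inactive_value_range[0] < self.inactive_value_range[1] <= 50):
            raise ValueError("inactive_value_range must lie within [0, 50]")
        if self.n_pan_inhibitors >= self.n_compounds:
            raise ValueError("n_pan_inhibitors must be smaller than n_compounds")


@dataclass
class SyntheticPanel:
    matrix: BioactivityMatrix
    features: FeatureTable
    truth: dict = field(default_factory=dict)


def _draw_values(rng, active: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Percent-inhibition values consistent with the planted calls.

    Mid-band contamination is drawn on the correct side of the 50% threshold
    ([50, 60) for actives, [40, 50) for inactives) so the planted truth is
    exactly recoverable by binarization at 50.
    """
    shape = active.shape
    vals = np.where(
        active,
        rng.uniform(*cfg.active_value_range, size=shape),
        rng.uniform(*cfg.inactive_value_range, size=shape),
    )
    mid = rng.random(shape) < cfg.midband_prob
    mid_vals = np.where(
        active,
        rng.uniform(50.0, 60.0, size=shape),
        rng.uniform(40.0, 50.0, size=shape),
    )
    return np.where(mid, mid_vals, vals)


def generate_panel(cfg: SyntheticConfig | None = None) -> SyntheticPanel:
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- compounds and chemotype features ------------------------------------
    compound_ids = [f"C{i + 1:03d}" for i in range(cfg.n_compounds)]
    pan_ids = compound_ids[: cfg.n_pan_inhibitors]
    regular = compound_ids[cfg.n_pan_inhibitors :]
    compound_cluster = {cid: i % cfg.n_clusters for i, cid in enumerate(regular)}

    signatures: dict[int, list[str]] = {
        k: [f"F{k}_{i:02d}" for i in range(cfg.chemotype_features_per_cluster)]
        for k in range(cfg.n_clusters)
    }
    if cfg.chemotype_overlap:
        for k in range(cfg.n_clusters):
            nxt = (k + 1) % cfg.n_clusters
            signatures[k] = (signatures[k][: -cfg.chemotype_overlap]
                             + signatures[nxt][: cfg.chemotype_overlap])
    pool = [f"B{i:03d}" for i in range(cfg.background_feature_pool)]

    features: dict[str, frozenset[str]] = {}
    for cid in compound_ids:
        bg = rng.choice(pool, size=cfg.background_features_per_compound,
                        replace=False)
        if cid in pan_ids:
            # pan-inhibitors straddle chemotypes: a slice of every signature
            sig = [f for k in range(cfg.n_clusters) for f in signatures[k][:2]]
        else:
            sig = signatures[compound_cluster[cid]]
        features[cid] = frozenset(sig) | frozenset(bg.tolist())

    # --- targets --------------------------------------------------------------
    target_ids, target_cluster = [], {}
    for k in range(cfg.n_clusters):
        for j in range(cfg.targets_per_cluster):
            t = f"K{k}_{j:02d}"
            target_ids.append(t)
            target_cluster[t] = k
    sparse_targets = []
    for s in range(cfg.n_sparse_targets):
        t = f"KS{s}"
        target_ids.append(t)
        target_cluster[t] = s % cfg.n_clusters
        sparse_targets.append(t)
    zero_target = None
    if cfg.include_zero_active_target:
        zero_target = "KNULL"
        target_ids.append(zero_target)
        target_cluster[zero_target] = None

    instances = [
        CompoundInstance(cid, conc)
        for cid in compound_ids
        for conc in sorted(cfg.concentrations)
    ]
    n_t, n_c = len(target_ids), len(compound_ids)

    # --- activity calls at compound level, then per concentration -------------
    # Clusters sit on a relatedness axis: a compound's activity on a target
    # decays geometrically with the separation of their cluster positions.
    # The default layout places most clusters in a related core with a few
    # remote ones, mimicking the right-skewed inter-target distance
    # distribution of real panels (many moderately related pairs, a long tail
    # of distant ones).  A per-target rate multiplier models heterogeneous
    # target sensitivity.
    positions = cfg.cluster_positions
    if positions is None:
        n_core = max(2, (2 * cfg.n_clusters + 2) // 3)
        core = [0.7 * i for i in range(n_core)]
        remote = [core[-1] + 2.5 * (i + 1) for i in range(cfg.n_clusters - n_core)]
        positions = tuple(core + remote)
    if len(positions) != cfg.n_clusters:
        raise ValueError("cluster_positions length must equal n_clusters")
    target_rate = rng.uniform(*cfg.target_rate_range, size=n_t)
    p = np.full((n_t, n_c), cfg.p_background)
    for ti, t in enumerate(target_ids):
        kt = target_cluster[t]
        for ci, cid in enumerate(compound_ids):
            if cid in pan_ids:
                p[ti, ci] = cfg.pan_activity_prob
            elif kt is not None:
                sep = abs(positions[compound_cluster[cid]] - positions[kt])
                p[ti, ci] = max(
                    cfg.p_background,
                    cfg.p_within * target_rate[ti] * cfg.cluster_decay ** sep,
                )
    if zero_target is not None:
        p[target_ids.index(zero_target), :] = 0.0

    high = rng.random((n_t, n_c)) < p
    low = high & (rng.random((n_t, n_c)) < cfg.low_conc_factor)

    # --- thin sparse targets until shared_total <= sparse_max_shared ----------
    # shared instances of t = active instances also active on >= 1 other target
    for t in sparse_targets:
        ti = target_ids.index(t)
        while True:
            inst_active = np.concatenate([low, high], axis=1)  # (targets, 2*compounds)
            col_sums = inst_active.sum(axis=0)
            shared = inst_active[ti] & (col_sums >= 2)
            excess = int(shared.sum()) - cfg.sparse_max_shared
            if excess <= 0:
                break
            # deactivate whole compounds (both concentrations) to keep nesting
            shared_compounds = sorted({k % n_c for k in np.flatnonzero(shared)})
            drop = rng.choice(shared_compounds,
                              size=min(len(shared_compounds),
                                       max(1, excess // 2 + 1)),
                              replace=False)
            high[ti, drop] = False
            low[ti, drop] = False

    # --- assemble percent-inhibition values -----------------------------------
    active = np.empty((n_t, len(instances)), dtype=bool)
    concs = sorted(cfg.concentrations)
    for ci in range(n_c):
        for k, conc in enumerate(concs):
            col = ci * len(concs) + k
            active[:, col] = high[:, ci] if conc == concs[-1] else low[:, ci]
    values = _draw_values(rng, active, cfg)

    matrix = BioactivityMatrix(list(target_ids), instances, values)
    truth = {
        "clusters": {t: target_cluster[t] for t in target_ids},
        "sparse_targets": sparse_targets,
        "zero_active_target": zero_target,
        "pan_inhibitors": pan_ids,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    return SyntheticPanel(matrix, FeatureTable(features), truth)


def write_fixtures(panel: SyntheticPanel, directory) -> dict[str, Path]:
    """Emit activity TSV, feature TSV and truth JSON in the pipeline's formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "activity": directory / "activity.tsv",
        "features": directory / "features.tsv",
        "truth": directory / "truth.json",
    }
    write_activity_matrix(panel.matrix, paths["activity"])
    write_feature_table(panel.features, paths["features"])
    paths["truth"].write_text(json.dumps(panel.truth, indent=2))
    return paths
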