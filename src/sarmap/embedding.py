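"""Stress-minimizing 2D embedding of targets from bioactivity distances.

SMACOF majorization: from a seeded random start, each Guttman-transform step
provably does not increase the raw stress, so the recorded stress trace is
non-increasing.  The reported stress is the normalized form

    stress = sqrt( sum_{i<j} (d_ij - delta_ij)^2 / sum_{i<j} delta_ij^2 )

with delta the input distances and d the embedded Euclidean distances.
Iteration stops when the per-step change in normalized stress falls below
``min_stress_change`` or after ``max_steps`` Guttman updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix

__all__ = ["EmbeddingResult", "mds_embed"]


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame   # index = target ids, columns x, y, ...
    stress_trace: list[float]
    final_stress: float
    converged: bool
    seed: int | None

    def write_tsv(self, path, class_labels=None) -> None:
        df = self.coordinates.copy()
        if class_labels is not None:
            df["class"] = [class_labels.get(t, "non-outlier") for t in df.index]
        df.to_csv(path, sep="\t", index_label="target")


def mds_embed(
    distances: DistanceMatrix,
    dims: int = 2,
    min_stress_change: float = 0.00005,
    max_steps: int = 5000,
    seed: int | None = None,
    n_init: int = 4,
) -> EmbeddingResult:
    """Embed a distance matrix by SMACOF, keeping the best of ``n_init``
    seeded random starts (majorization can stall in local optima from an
    unlucky initialization)."""
    if len(distances) < 3:
        raise ValueError("embedding needs at least 3 labels")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    delta = distances.values
    n = len(distances)
    cols = ["x", "y", "z"][:dims] if dims <= 3 else [f"d{i}" for i in range(dims)]
    condensed = squareform(delta, checks=False)
    denom = float((condensed ** 2).sum())
    if denom == 0.0:
        coords = pd.DataFrame(np.zeros((n, dims)), index=list(distances.labels),
                              columns=cols)
        return EmbeddingResult(coords, [0.0], 0.0, True, seed)

    def norm_stress(pts: np.ndarray) -> float:
        return float(np.sqrt(((pdist(pts) - condensed) ** 2).sum() / denom))

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for _ in range(n_init):
        x = rng.standard_normal((n, dims))
        trace = [norm_stress(x)]
        converged = False
        for _ in range(max_steps):
            d = squareform(pdist(x))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, delta / np.where(d > 0, d, 1.0), 0.0)
            b = -ratio
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = b @ x / n
            trace.append(norm_stress(x))
            if trace[-2] - trace[-1] < min_stress_change:
                converged = True
                break
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], x, trace, converged)
    final_stress, x, trace, converged = best
    coords = pd.DataFrame(x, index=list(distances.labels), columns=cols)
    return EmbeddingResult(coords, trace, final_stress, converged, seed)
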