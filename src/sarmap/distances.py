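"""Inter-target distance metrics and the labeled distance-matrix container.

Two families of bioactivity distance are supported:

* dimension-normalized Manhattan distance between fingerprint enrichment
  profiles (chemistry-aware), and
* distances on binary bioactivity fingerprints — one bit per compound
  instance, set when the instance is active on the target: Tanimoto distance
  D = 1 - T_C, and the Hamming distance (raw disagreement count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import ActivityCalls
from .enrichment import EnrichmentProfile

__all__ = [
    "DistanceMatrix",
    "manhattan_enrichment_distance",
    "tanimoto_distance",
    "hamming_distance",
    "build_distance_matrix",
    "enrichment_distance_matrix",
    "tanimoto_distance_matrix",
    "hamming_distance_matrix",
    "bioactivity_bitstrings",
    "read_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric labeled inter-target distances under a named metric."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distance entries")
        if (self.values < 0).any():
            raise ValueError("negative distance entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("non-zero diagonal")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def subset(self, keep: Iterable[str]) -> "DistanceMatrix":
        keep = set(keep)
        idx = [i for i, t in enumerate(self.labels) if t in keep]
        labels = tuple(self.labels[i] for i in idx)
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.metric_name)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        return squareform(self.values, checks=False)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="target",
                               float_format="%.17g")

    def write_phylip(self, path) -> None:
        """Square PHYLIP distance format (name-padded, for tree-program interop)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for lab, row in zip(self.labels, self.values):
                name = lab[:10].ljust(10)
                fh.write(name + " ".join(f"{v:.6f}" for v in row) + "\n")

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=list(self.labels))


def read_distance_matrix(source, metric_name: str = "", sep: str = "\t") -> DistanceMatrix:
    df = pd.read_csv(source, sep=sep, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels differ")
    return DistanceMatrix(tuple(str(t) for t in df.index),
                          df.to_numpy(dtype=float), metric_name)


def manhattan_enrichment_distance(p: EnrichmentProfile, q: EnrichmentProfile) -> float:
    """Manhattan distance between enrichment vectors, normalized by dimension."""
    if p.vocabulary.feature_ids != q.vocabulary.feature_ids:
        raise ValueError("profiles built on different vocabularies")
    n = len(p.vocabulary)
    if n == 0:
        raise ValueError("empty vocabulary")
    return float(np.abs(p.values - q.values).sum() / n)


def _as_bits(a) -> np.ndarray:
    return np.asarray(a, dtype=bool)


def tanimoto_distance(a, b) -> float:
    """D = 1 - T_C on binary bioactivity fingerprints.

    T_C = c / (n_a + n_b - c) with c shared on-bits.  Two all-zero strings are
    defined maximally similar (D = 0) with a warning; in-pipeline the case is
    prevented by excluding zero-active targets upstream.
    """
    a, b = _as_bits(a), _as_bits(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    c = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("Tanimoto of two empty bitstrings defined as distance 0",
                      stacklevel=2)
        return 0.0
    return 1.0 - c / (na + nb - c)


def hamming_distance(a, b, normalized: bool = False) -> float:
    """Number of disagreeing positions (raw count; optionally length-normalized)."""
    a, b = _as_bits(a), _as_bits(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = int((a ^ b).sum())
    return d / a.size if normalized else float(d)


def build_distance_matrix(
    items: Sequence[tuple[str, object]],
    metric: Callable[[object, object], float],
    metric_name: str = "",
) -> DistanceMatrix:
    """Symmetric matrix from per-pair metric calls (each unordered pair once)."""
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    labels = tuple(lab for lab, _ in items)
    n = len(items)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = metric(items[i][1], items[j][1])
            except Exception as exc:
                raise RuntimeError(
                    f"metric failed on pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, metric_name)


def enrichment_distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Dimension-normalized Manhattan distances from a targets × features frame."""
    n_features = profiles.shape[1]
    if n_features == 0:
        raise ValueError("no features in profile matrix")
    condensed = pdist(profiles.to_numpy(), metric="cityblock") / n_features
    return DistanceMatrix(tuple(profiles.index), squareform(condensed),
                          "manhattan_enrichment")


def bioactivity_bitstrings(calls: ActivityCalls) -> pd.DataFrame:
    """Per-target binary bioactivity fingerprints (targets × instances)."""
    return calls.to_frame()


def tanimoto_distance_matrix(calls: ActivityCalls) -> DistanceMatrix:
    a = calls.values.astype(np.int64)
    on = a.sum(axis=1)
    c = a @ a.T
    union = on[:, None] + on[None, :] - c
    if (on == 0).any():
        warnings.warn("zero-active target(s) present; Tanimoto with another "
                      "empty fingerprint is defined as distance 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = np.where(union > 0, c / np.where(union > 0, union, 1), 1.0)
    d = 1.0 - tc
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(calls.target_ids), d, "tanimoto")


def hamming_distance_matrix(calls: ActivityCalls, normalized: bool = False) -> DistanceMatrix:
    a = calls.values.astype(np.int64)
    b = 1 - a
    d = (a @ b.T + b @ a.T).astype(float)  # exact integer disagreement counts
    if normalized:
        d = d / a.shape[1]
    return DistanceMatrix(tuple(calls.target_ids), d,
                          "hamming_normalized" if normalized else "hamming")
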