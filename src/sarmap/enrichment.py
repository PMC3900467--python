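"""Per-target bioactivity-based fingerprint enrichment profiles.

For each target, compound instances are split into an active and an inactive
set by the activity calls.  For each substructure feature i, f_A is the number
of active instances whose compound contains the feature, f_I the analogous
count on the inactive set, and the enrichment is

    E_i = f_A / f_I,                 if f_A > 0 and f_I > 0
    E_i = (f_A + 1) / (f_I + 2),     if either count is zero (Laplacian
                                     correction against zero counts)

Instances of the same compound at different concentrations are counted
separately, so features of strong inhibitors (active at both concentrations)
weigh twice.  The frequencies are raw counts, not proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_features import FeatureTable, FeatureVocabulary
from .core_data import ActivityCalls

__all__ = [
    "feature_enrichment",
    "EnrichmentProfile",
    "build_profile",
    "enrichment_matrix",
]


def feature_enrichment(f_a: int, f_i: int, always_correct: bool = False) -> float:
    """Enrichment of one feature from its active/inactive counts.

    ``always_correct=True`` applies the Laplacian correction to every pair,
    not only at zero counts (sensitivity-analysis variant).
    """
    if f_a < 0 or f_i < 0:
        raise ValueError(f"counts must be non-negative, got ({f_a}, {f_i})")
    if not always_correct and f_a > 0 and f_i > 0:
        return f_a / f_i
    return (f_a + 1) / (f_i + 2)


@dataclass
class EnrichmentProfile:
    """One target's enrichment vector over a shared feature vocabulary."""

    target_id: str
    vocabulary: FeatureVocabulary
    values: np.ndarray
    f_active: np.ndarray
    f_inactive: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.vocabulary)
        if not (len(self.values) == len(self.f_active) == len(self.f_inactive) == n):
            raise ValueError("profile length does not match vocabulary size")
        if (self.values <= 0).any():
            raise ValueError("enrichment values must be strictly positive")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.vocabulary.feature_ids),
                         name=self.target_id)


def _instance_feature_matrix(
    calls: ActivityCalls, table: FeatureTable, vocab: FeatureVocabulary
) -> np.ndarray:
    """Binary instances × features membership (instances share their compound's set)."""
    index = vocab.index
    m = np.zeros((len(calls.instances), len(vocab)), dtype=np.int64)
    for j, inst in enumerate(calls.instances):
        if inst.compound_id not in table:
            raise KeyError(f"compound {inst.compound_id!r} missing from feature table")
        for fid in table[inst.compound_id]:
            m[j, index[fid]] = 1
    return m


def build_profile(
    target_id: str,
    calls: ActivityCalls,
    table: FeatureTable,
    vocab: FeatureVocabulary,
    always_correct: bool = False,
) -> EnrichmentProfile:
    if target_id not in calls.target_ids:
        raise KeyError(f"unknown target {target_id!r}")
    row = calls.values[calls.target_ids.index(target_id)]
    m = _instance_feature_matrix(calls, table, vocab)
    f_a = row.astype(np.int64) @ m
    f_i = (~row).astype(np.int64) @ m
    return EnrichmentProfile(
        target_id, vocab, _enrich_vec(f_a, f_i, always_correct), f_a, f_i
    )


def _enrich_vec(f_a: np.ndarray, f_i: np.ndarray, always_correct: bool) -> np.ndarray:
    corrected = (f_a + 1) / (f_i + 2)
    if always_correct:
        return corrected
    with np.errstate(divide="ignore", invalid="ignore"):
        plain = f_a / np.where(f_i > 0, f_i, 1) * (f_i > 0)
    return np.where((f_a > 0) & (f_i > 0), plain, corrected)


def enrichment_matrix(
    calls: ActivityCalls,
    table: FeatureTable,
    vocab: FeatureVocabulary | None = None,
    always_correct: bool = False,
) -> pd.DataFrame:
    """All per-target profiles stacked as a targets × features frame.

    The whole panel shares one vocabulary, so features absent from a target's
    compounds still appear with the zero-count corrected value 0.5.
    """
    if vocab is None:
        from .chem_features import build_vocabulary

        vocab = build_vocabulary(table)
    m = _instance_feature_matrix(calls, table, vocab)
    active = calls.values.astype(np.int64)
    f_a = active @ m               # targets × features
    f_i = (1 - active) @ m
    values = _enrich_vec(f_a, f_i, always_correct)
    return pd.DataFrame(values, index=list(calls.target_ids),
                        columns=list(vocab.feature_ids))
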