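"""Cross-panel diagnostics: sequence vs bioactivity distance, gatekeeper bins.

Two checks of whether the ligand-based classification carries information the
sequence-based one does not:

* for target pairs hit by the same inhibitor, how often the pair is distant in
  sequence space (default window 0.6–0.8 on the 0–1 patristic scale) yet close
  in bioactivity space (default 0–0.4), and
* whether target pairs sharing the same gatekeeper residue concentrate in the
  low bioactivity-distance bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["cross_density", "gatekeeper_bins", "CrossDensityResult",
           "GatekeeperBinsResult"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class CrossDensityResult:
    fraction: float
    rows: pd.DataFrame  # inhibitor, target_a, target_b, seq_distance, bio_distance, in_window
    n_skipped: int


def cross_density(
    seq_distances: DistanceMatrix,
    bio_distances: DistanceMatrix,
    inhibitor_targets: Mapping[str, set[str] | list[str]],
    seq_window: tuple[float, float] = (0.6, 0.8),
    bio_window: tuple[float, float] = (0.0, 0.4),
    dedup_pairs: bool = False,
) -> CrossDensityResult:
    """Scatter of (sequence, bioactivity) distances over inhibitor-linked pairs.

    Every unordered pair of targets hit by the same inhibitor contributes one
    row; the fraction counts rows inside the closed seq × bio window.  Pairs
    with a target missing from either matrix are skipped with a warning.
    With ``dedup_pairs`` each unordered target pair is counted once even when
    several inhibitors link it.
    """
    sidx, bidx = seq_distances.index, bio_distances.index
    rows, skipped, seen = [], 0, set()
    for inhibitor in sorted(inhibitor_targets):
        targets = sorted(set(inhibitor_targets[inhibitor]))
        for i in range(len(targets)):
            for j in range(i + 1, len(targets)):
                a, b = targets[i], targets[j]
                if a not in sidx or b not in sidx or a not in bidx or b not in bidx:
                    skipped += 1
                    continue
                if dedup_pairs:
                    if (a, b) in seen:
                        continue
                    seen.add((a, b))
                sd = seq_distances.loc(a, b)
                bd = bio_distances.loc(a, b)
                in_window = (seq_window[0] <= sd <= seq_window[1]
                             and bio_window[0] <= bd <= bio_window[1])
                rows.append((inhibitor, a, b, sd, bd, in_window))
    if skipped:
        warnings.warn(f"skipped {skipped} pair(s) with targets missing from a "
                      "distance matrix", stacklevel=2)
    df = pd.DataFrame(rows, columns=["inhibitor", "target_a", "target_b",
                                     "seq_distance", "bio_distance", "in_window"])
    fraction = float(df["in_window"].mean()) if len(df) else 0.0
    return CrossDensityResult(fraction, df, skipped)


@dataclass
class GatekeeperBinsResult:
    bins: pd.DataFrame       # bin_lo, bin_hi, n_pairs, n_same, fraction_same (NaN if empty)
    head_average: float      # mean over bins covering [0, 0.5)
    tail_average: float      # mean over the 5 highest non-empty bins
    above_half_average: float  # mean over all non-empty bins with bin_lo >= 0.5


def gatekeeper_bins(
    bio_distances: DistanceMatrix,
    gatekeepers: Mapping[str, str],
    bin_width: float = 0.1,
) -> GatekeeperBinsResult:
    """Fraction of same-gatekeeper pairs per bioactivity-distance bin.

    Pairs of annotated targets are binned into half-open intervals
    [k·w, (k+1)·w).  Empty bins have an undefined (NaN) fraction and are
    ignored by the unweighted head/tail averages.
    """
    annotated = []
    for t in bio_distances.labels:
        res = gatekeepers.get(t)
        if res is None:
            warnings.warn(f"target {t!r} lacks a gatekeeper annotation; skipped",
                          stacklevel=2)
            continue
        res = res.upper()
        if res not in AMINO_ACIDS:
            raise ValueError(f"invalid residue code {res!r} for target {t!r}")
        annotated.append(t)
    if len(annotated) < 2:
        raise ValueError("need at least 2 annotated targets")

    dists, same = [], []
    for i in range(len(annotated)):
        for j in range(i + 1, len(annotated)):
            a, b = annotated[i], annotated[j]
            dists.append(bio_distances.loc(a, b))
            same.append(gatekeepers[a].upper() == gatekeepers[b].upper())
    dists, same = np.asarray(dists), np.asarray(same)
    n_bins = int(np.floor(dists.max() / bin_width)) + 1
    rows = []
    for k in range(n_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        mask = (dists >= lo) & (dists < hi)
        n = int(mask.sum())
        n_same = int(same[mask].sum())
        rows.append((lo, hi, n, n_same, n_same / n if n else np.nan))
    bins = pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_pairs", "n_same",
                                       "fraction_same"])
    head = bins[(bins["bin_lo"] < 0.5) & bins["fraction_same"].notna()]
    nonempty = bins[bins["fraction_same"].notna()]
    tail5 = nonempty.nlargest(min(5, len(nonempty)), "bin_lo")
    above = nonempty[nonempty["bin_lo"] >= 0.5]
    return GatekeeperBinsResult(
        bins=bins,
        head_average=float(head["fraction_same"].mean()) if len(head) else np.nan,
        tail_average=float(tail5["fraction_same"].mean()) if len(tail5) else np.nan,
        above_half_average=(float(above["fraction_same"].mean())
                            if len(above) else np.nan),
    )
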