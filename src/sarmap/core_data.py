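"""Data model and I/O for bioactivity panels.

A panel is a complete percent-inhibition matrix: one row per target (e.g. a
kinase), one column per *compound instance* — the same compound screened at
two assay concentrations counts as two instances, because a strong inhibitor
(active at both concentrations) carries more evidence than a weak one.

Raw values are percent inhibition relative to native activity and may fall
outside [0, 100] due to assay noise; they are binarized at a configurable
threshold (default: inhibition of 50% or more is "active").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundInstance",
    "BioactivityMatrix",
    "ActivityCalls",
    "PanelSummary",
    "parse_instance_label",
    "read_activity_matrix",
    "write_activity_matrix",
    "binarize",
    "panel_summary",
]

#: separator between compound id and concentration in instance labels
INSTANCE_SEP = "@"


@dataclass(frozen=True)
class CompoundInstance:
    """A compound screened at one concentration (µM)."""

    compound_id: str
    concentration: float

    def __post_init__(self) -> None:
        if INSTANCE_SEP in self.compound_id:
            raise ValueError(
                f"compound id {self.compound_id!r} may not contain {INSTANCE_SEP!r}"
            )
        if not (self.concentration > 0):
            raise ValueError(
                f"concentration must be positive, got {self.concentration!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.compound_id}{INSTANCE_SEP}{self.concentration:g}"


def parse_instance_label(label: str) -> CompoundInstance:
    """Parse ``"<compound_id>@<concentration>"`` into a :class:`CompoundInstance`."""
    cid, sep, conc = label.rpartition(INSTANCE_SEP)
    if not sep or not cid:
        raise ValueError(
            f"instance label {label!r} does not match '<id>{INSTANCE_SEP}<conc>'"
        )
    try:
        concentration = float(conc)
    except ValueError as exc:
        raise ValueError(
            f"instance label {label!r}: unparseable concentration {conc!r}"
        ) from exc
    return CompoundInstance(cid, concentration)


def _check_unique(labels: Sequence, kind: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {kind} label: {lab!r}")
        seen.add(lab)


@dataclass
class BioactivityMatrix:
    """Complete targets × compound-instances percent-inhibition grid."""

    target_ids: list[str]
    instances: list[CompoundInstance]
    values: np.ndarray  # shape (n_targets, n_instances), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.target_ids), len(self.instances)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.target_ids)} targets x {len(self.instances)} instances"
            )
        _check_unique(self.target_ids, "target")
        _check_unique([i.label for i in self.instances], "instance")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                "missing/non-finite cell at target "
                f"{self.target_ids[r]!r}, instance {self.instances[c].label!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def instance_labels(self) -> list[str]:
        return [i.label for i in self.instances]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.target_ids, columns=self.instance_labels
        )

    def subset_targets(self, keep: Iterable[str]) -> "BioactivityMatrix":
        """Row-subset the panel, preserving the original target order."""
        keep = set(keep)
        missing = keep - set(self.target_ids)
        if missing:
            raise KeyError(f"targets not in panel: {sorted(missing)}")
        idx = [i for i, t in enumerate(self.target_ids) if t in keep]
        return BioactivityMatrix(
            [self.target_ids[i] for i in idx],
            list(self.instances),
            self.values[idx],
        )


@dataclass
class ActivityCalls:
    """Boolean active/inactive calls: cell is True iff inhibition >= threshold."""

    target_ids: list[str]
    instances: list[CompoundInstance]
    values: np.ndarray  # bool
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.target_ids), len(self.instances)):
            raise ValueError("calls shape does not match axes")

    @property
    def instance_labels(self) -> list[str]:
        return [i.label for i in self.instances]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.target_ids, columns=self.instance_labels
        )

    def subset_targets(self, keep: Iterable[str]) -> "ActivityCalls":
        keep = set(keep)
        idx = [i for i, t in enumerate(self.target_ids) if t in keep]
        return ActivityCalls(
            [self.target_ids[i] for i in idx],
            list(self.instances),
            self.values[idx],
            self.threshold,
        )


def _read_table(source, sep: str | None):
    path = Path(source) if isinstance(source, (str, Path)) else None
    if sep is None:
        sep = "," if (path is not None and path.suffix.lower() == ".csv") else "\t"
    return pd.read_csv(source, sep=sep, index_col=0, header=0,
                       float_precision="round_trip"), sep


def read_activity_matrix(
    source,
    orientation: str = "rows-are-targets",
    sep: str | None = None,
) -> BioactivityMatrix:
    """Read a labeled percent-inhibition table (TSV by default, CSV by suffix).

    Instance labels must encode compound and concentration as ``"<id>@<conc>"``.
    ``orientation="rows-are-instances"`` reads the transposed layout.
    """
    if orientation not in ("rows-are-targets", "rows-are-instances"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df, _ = _read_table(source, sep)
    if orientation == "rows-are-instances":
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate target label: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate instance label: {dup!r}")
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        c = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(f"missing cell near target {r!r}, instance {c!r}")
    instances = [parse_instance_label(str(c)) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in activity table: {exc}") from exc
    return BioactivityMatrix([str(t) for t in df.index], instances, values)


def write_activity_matrix(matrix: BioactivityMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="target")


def binarize(matrix: BioactivityMatrix, threshold: float = 50.0) -> ActivityCalls:
    """Call a cell active iff inhibition >= ``threshold`` (boundary inclusive)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out_of_range = (matrix.values < 0) | (matrix.values > 100)
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} cell(s) outside [0, 100] "
            "(assay noise); binarized by the same rule",
            stacklevel=2,
        )
    return ActivityCalls(
        list(matrix.target_ids),
        list(matrix.instances),
        matrix.values >= threshold,
        float(threshold),
    )


@dataclass
class PanelSummary:
    """Descriptive statistics of a binarized panel.

    ``promiscuous_instances`` are instances hitting more targets than the
    panel mean + 3 population SD of per-instance target counts.
    """

    per_instance_counts: pd.Series
    per_target_counts: pd.Series
    fraction_active: float
    fraction_midband: float
    midband: tuple[float, float]
    promiscuity_cutoff: float
    promiscuous_instances: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fraction_active": self.fraction_active,
            "fraction_midband": self.fraction_midband,
            "midband": list(self.midband),
            "promiscuity_cutoff": self.promiscuity_cutoff,
            "promiscuous_instances": list(self.promiscuous_instances),
            "per_instance_counts": self.per_instance_counts.to_dict(),
            "per_target_counts": self.per_target_counts.to_dict(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def panel_summary(
    matrix: BioactivityMatrix,
    calls: ActivityCalls,
    midband: tuple[float, float] = (40.0, 60.0),
) -> PanelSummary:
    """Summarise a panel: active/mid-band fractions, promiscuity counts and flags.

    The mid-band fraction counts raw values in the half-open interval
    ``[midband[0], midband[1])`` — borderline responses near the activity
    threshold.  The promiscuity flag uses mean + 3·SD (population SD) of the
    per-instance target counts.
    """
    if (
        matrix.target_ids != calls.target_ids
        or matrix.instance_labels != calls.instance_labels
    ):
        raise ValueError("matrix and calls do not share axes")
    lo, hi = midband
    n_cells = matrix.values.size
    per_instance = calls.values.sum(axis=0)
    per_target = calls.values.sum(axis=1)
    counts = pd.Series(per_instance, index=matrix.instance_labels, name="n_targets")
    cutoff = float(per_instance.mean() + 3.0 * per_instance.std(ddof=0))
    flagged = counts.index[per_instance > cutoff].tolist()
    in_band = (matrix.values >= lo) & (matrix.values < hi)
    return PanelSummary(
        per_instance_counts=counts,
        per_target_counts=pd.Series(
            per_target, index=matrix.target_ids, name="n_inhibitors"
        ),
        fraction_active=float(calls.values.sum()) / n_cells,
        fraction_midband=float(in_band.sum()) / n_cells,
        midband=(float(lo), float(hi)),
        promiscuity_cutoff=cutoff,
        promiscuous_instances=flagged,
    )
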