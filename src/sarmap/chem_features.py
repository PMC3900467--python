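"""Per-compound circular substructure features.

Feature sets are binary per compound (presence/absence): a feature is counted
once per compound however often the substructure occurs within it.  Features
can be computed from SMILES with a Morgan/ECFP-style backend (RDKit) or read
from a precomputed long-format table, so the chemistry backend is optional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FeatureTable",
    "FeatureVocabulary",
    "extract_features",
    "read_smiles_records",
    "read_feature_table",
    "write_feature_table",
    "build_vocabulary",
]


@dataclass
class FeatureTable:
    """Mapping compound_id -> set of feature ids (opaque strings)."""

    features: dict[str, frozenset[str]]

    def __getitem__(self, compound_id: str) -> frozenset[str]:
        return self.features[compound_id]

    def get(self, compound_id: str, default=frozenset()) -> frozenset[str]:
        return self.features.get(compound_id, default)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.features

    @property
    def compound_ids(self) -> list[str]:
        return list(self.features)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class FeatureVocabulary:
    """Lexicographically ordered distinct feature ids over a whole panel."""

    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.feature_ids) != sorted(set(self.feature_ids)):
            raise ValueError("vocabulary must be sorted and duplicate-free")

    @property
    def index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def __len__(self) -> int:
        return len(self.feature_ids)


def extract_features(
    records: Iterable[tuple[str, str]],
    diameter: int = 4,
    on_error: str = "raise",
) -> FeatureTable:
    """Compute circular substructure feature sets from SMILES.

    Parameters
    ----------
    records
        Iterable of ``(smiles, compound_id)`` pairs.
    diameter
        Even substructure diameter in bonds; radius = diameter // 2
        (diameter 4 = the classic ECFP_4 setting).
    on_error
        ``"raise"`` fails fast listing all unparseable records; ``"skip"``
        drops them with a warning.

    Feature ids are the backend's stable hashed atom-environment identifiers
    rendered as strings; identical input yields identical ids across runs.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if diameter < 0 or diameter % 2:
        raise ValueError(f"diameter must be a non-negative even integer, got {diameter}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    gen = AllChem.GetMorganGenerator(radius=diameter // 2)
    table: dict[str, frozenset[str]] = {}
    bad: list[str] = []
    for smiles, cid in records:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            bad.append(f"{cid}: {smiles!r}")
            continue
        fp = gen.GetSparseCountFingerprint(mol)
        table[cid] = frozenset(str(k) for k in fp.GetNonzeroElements())
    if bad:
        if on_error == "raise":
            raise ValueError("unparseable SMILES records: " + "; ".join(bad))
        warnings.warn(f"skipped {len(bad)} unparseable SMILES record(s)", stacklevel=2)
    return FeatureTable(table)


def read_smiles_records(source) -> list[tuple[str, str]]:
    """Read ``SMILES<TAB>compound_id`` records, one per line."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'SMILES<TAB>id', got {line!r}")
        records.append((parts[0], parts[1]))
    return records


def read_feature_table(source, sep: str = "\t") -> FeatureTable:
    """Read a long-format (compound_id, feature_id) table; duplicates collapse."""
    df = pd.read_csv(source, sep=sep, header=None, names=["compound_id", "feature_id"],
                     dtype=str, comment="#", skip_blank_lines=True)
    if df.empty:
        warnings.warn("empty feature table", stacklevel=2)
        return FeatureTable({})
    table: dict[str, set[str]] = {}
    for cid, fid in zip(df["compound_id"], df["feature_id"]):
        table.setdefault(str(cid), set()).add(str(fid))
    return FeatureTable({c: frozenset(f) for c, f in table.items()})


def write_feature_table(table: FeatureTable | Mapping, path, sep: str = "\t") -> None:
    mapping = table.features if isinstance(table, FeatureTable) else table
    with open(path, "w") as fh:
        for cid in mapping:
            for fid in sorted(mapping[cid]):
                fh.write(f"{cid}{sep}{fid}\n")


def build_vocabulary(table: FeatureTable) -> FeatureVocabulary:
    """Union of all feature sets, lexicographically ordered."""
    all_features: set[str] = set()
    for fs in table.features.values():
        all_features |= fs
    return FeatureVocabulary(tuple(sorted(all_features)))
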