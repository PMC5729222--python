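"""Labeled count tables: the native TSV format and the mothur ``.shared`` dialect.

Native format (UTF-8, tab-separated)::

    sample_id<TAB>label<TAB><taxon1><TAB><taxon2>...

one row per sample, non-negative integer read counts, exactly two distinct
class labels.  The mothur ``.shared`` dialect (columns ``label``, ``Group``,
``numOtus``, then one column per OTU) is accepted with class labels supplied
in a separate two-column file mapping sample id to class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledTable", "read_table", "write_table", "read_label_file"]


@dataclass(frozen=True)
class LabeledTable:
    """Samples x taxa read counts with one binary class label per sample."""

    sample_ids: list[str]
    labels: np.ndarray  # class name per sample
    taxa: list[str]
    counts: np.ndarray  # (n_samples, n_taxa) int64

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", [str(s) for s in self.sample_ids])
        object.__setattr__(self, "taxa", [str(t) for t in self.taxa])
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {', '.join(dupes)}")
        if counts.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError("counts shape must be (n_samples, n_taxa)")
        if not np.issubdtype(counts.dtype, np.integer):
            bad = np.argwhere(counts != np.rint(counts))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, taxon {self.taxa[j]!r}"
                )
            counts = np.rint(counts).astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, taxon {self.taxa[j]!r}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if np.any(counts.sum(axis=1) == 0):
            i = int(np.argwhere(counts.sum(axis=1) == 0)[0][0])
            raise ValueError(f"sample {self.sample_ids[i]!r} has zero total reads")
        n_classes = len(set(labels.tolist()))
        if n_classes != 2:
            raise ValueError(
                f"exactly 2 class labels required (binary classification only), got {n_classes}"
            )

    @property
    def classes(self) -> list[str]:
        """The two class names in sorted order."""
        return sorted(set(self.labels.tolist()))

    def positive_label(self, requested: str | None = None) -> str:
        """The diseased/positive class: ``requested`` if given, else the
        lexicographically second label."""
        if requested is None:
            return self.classes[1]
        if requested not in self.classes:
            raise ValueError(f"positive label {requested!r} not among classes {self.classes}")
        return requested

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.taxa)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def with_counts(self, counts: np.ndarray, taxa: list[str]) -> "LabeledTable":
        return replace(self, counts=counts, taxa=taxa)


def read_label_file(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping sample id -> class label (no header)."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields, got {len(parts)}")
        mapping[parts[0]] = parts[1]
    if not mapping:
        raise ValueError(f"label file {path} is empty")
    return mapping


def read_table(
    path: str | Path,
    format: str = "tsv",
    label_column: str = "label",
    label_file: str | Path | None = None,
    transpose: bool = False,
) -> LabeledTable:
    """Read a labeled count table.

    ``format="tsv"`` expects the native layout (sample_id, label, taxa...);
    ``format="shared"`` the mothur dialect, which carries no class labels, so
    ``label_file`` is required.  ``transpose`` accepts taxa-as-rows exports
    (native format only).
    """
    path = Path(path)
    if format == "shared":
        if label_file is None:
            raise ValueError("the .shared dialect carries no class labels; pass label_file")
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"label", "Group", "numOtus"}
        if not required <= set(df.columns):
            raise ValueError(f".shared file must have columns {sorted(required)}")
        taxa = [c for c in df.columns if c not in required]
        sample_ids = df["Group"].tolist()
        mapping = read_label_file(label_file)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples missing from label file: {', '.join(missing[:5])}")
        labels = np.array([mapping[s] for s in sample_ids], dtype=object)
        counts = _parse_counts(df[taxa], sample_ids, taxa)
        return LabeledTable(sample_ids=sample_ids, labels=labels, taxa=taxa, counts=counts)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'shared'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names="sample_id")
    if "sample_id" not in df.columns:
        raise ValueError("native table must have a 'sample_id' column")
    sample_ids = df["sample_id"].tolist()
    if label_file is not None:
        mapping = read_label_file(label_file)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples missing from label file: {', '.join(missing[:5])}")
        labels = np.array([mapping[s] for s in sample_ids], dtype=object)
        taxa = [c for c in df.columns if c not in ("sample_id", label_column)]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        labels = df[label_column].to_numpy(dtype=object)
        taxa = [c for c in df.columns if c not in ("sample_id", label_column)]
    counts = _parse_counts(df[taxa], sample_ids, taxa)
    return LabeledTable(sample_ids=sample_ids, labels=labels, taxa=taxa, counts=counts)


def _parse_counts(block: pd.DataFrame, sample_ids: list[str], taxa: list[str]) -> np.ndarray:
    values = block.to_numpy(dtype=object)
    counts = np.empty(values.shape, dtype=np.int64)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            raw = values[i, j]
            try:
                x = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count {raw!r} at sample {sample_ids[i]!r}, taxon {taxa[j]!r}"
                ) from None
            if x != int(x):
                raise ValueError(
                    f"non-integer count {raw!r} at sample {sample_ids[i]!r}, taxon {taxa[j]!r} "
                    "(relative-abundance tables are not accepted; the DM fit needs raw reads)"
                )
            if x < 0:
                raise ValueError(
                    f"negative count {raw!r} at sample {sample_ids[i]!r}, taxon {taxa[j]!r}"
                )
            counts[i, j] = int(x)
    return counts


def write_table(table: LabeledTable, path: str | Path) -> None:
    """Write the native TSV layout; round-trips through :func:`read_table`."""
    table.to_frame().to_csv(path, sep="\t", index=False)
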