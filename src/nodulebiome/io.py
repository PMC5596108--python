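"""Readers and writers for OTU tables and sample metadata.

Two TSV dialects are supported for count tables:

``wide-tsv``
    First column ``otu_id``, one column per sample, optional trailing
    ``taxonomy`` column with a semicolon-ranked lineage string.
``biom-tsv``
    The classic BIOM-style TSV export: an optional ``# Constructed from
    biom file`` comment line, then a header line starting ``#OTU ID``,
    with an optional trailing ``taxonomy`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, SampleFrame, ValidationError

TAXONOMY_COLUMN = "taxonomy"
DIALECTS = ("wide-tsv", "biom-tsv")


def read_count_table(path: str | Path, dialect: str = "wide-tsv") -> CountTable:
    """Read a count table from TSV.

    Raises :class:`ValidationError` on duplicate ids, negative or
    non-integer counts, or ragged rows.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    skiprows = 0
    if dialect == "biom-tsv":
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and not first.startswith("#OTU ID"):
            skiprows = 1
    # validate header duplicates before pandas mangles them
    with open(path) as fh:
        for _ in range(skiprows):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
        ncols = len(header)
        dup = [h for h in set(header) if header.count(h) > 1]
        if dup:
            raise ValidationError(f"duplicate sample ids in header: {sorted(dup)}")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncols:
                raise ValidationError(f"ragged row at line {lineno + skiprows}")
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate OTU ids: {dups}")
    taxonomy = None
    if TAXONOMY_COLUMN in df.columns:
        taxonomy = df.pop(TAXONOMY_COLUMN).fillna("")
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
    arr = counts.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError("non-integer counts in table")
    if (arr < 0).any():
        raise ValidationError("negative counts in table")
    return CountTable(counts.astype(np.int64), taxonomy)


def write_count_table(table: CountTable, path: str | Path, dialect: str = "wide-tsv") -> None:
    path = Path(path)
    df = table.counts.copy()
    df[TAXONOMY_COLUMN] = table.taxonomy
    with open(path, "w") as fh:
        if dialect == "biom-tsv":
            fh.write("# Constructed from biom file\n")
            fh.write("#OTU ID\t" + "\t".join(df.columns) + "\n")
            df.to_csv(fh, sep="\t", header=False)
        else:
            df.index.name = "otu_id"
            df.to_csv(fh, sep="\t")


def read_sample_frame(path: str | Path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise ValidationError("sample frame TSV requires a sample_id column")
    df = df.set_index("sample_id")
    if "depth" in df.columns:
        df["depth"] = pd.to_numeric(df["depth"], errors="coerce")
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path: str | Path) -> None:
    df = frame.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
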