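"""OTU-table preprocessing: decoy-lineage removal, blank subtraction,
relative-abundance normalisation, and rarefaction.

The preprocessing mirrors standard amplicon practice for surveys that carry
an extraction blank: any OTU whose lineage matches a decoy pattern
(chloroplast 16S, archaeal reads amplified by bacterial primers) is dropped,
and any OTU detected in the blank control is treated as a contaminant and
removed wherever it occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, RelAbundTable, SampleFrame, ValidationError

DEFAULT_EXCLUDE_PATTERNS = ("Chloroplast", "Archaea")


@dataclass
class FilterReport:
    """What filter_table removed and why."""

    lineage_removed: list[str] = field(default_factory=list)
    blank_removed: list[str] = field(default_factory=list)
    control_samples_dropped: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_lineage_removed": len(self.lineage_removed),
            "n_blank_removed": len(self.blank_removed),
            "control_samples_dropped": self.control_samples_dropped,
        }


def filter_table(
    table: CountTable,
    frame: SampleFrame,
    exclude_lineage_patterns: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS,
    subtract_counts: bool = False,
    return_report: bool = False,
):
    """Remove decoy lineages and blank-control contaminants.

    Lineage matching is case-insensitive substring on the full semicolon
    lineage. Blank subtraction removes the entire OTU row for every OTU with
    at least one read in any control sample (``subtract_counts=True``
    instead subtracts the per-OTU maximum blank count from every sample, a
    sensitivity-analysis mode). Control samples are dropped from the output.
    """
    missing = set(table.sample_ids) - set(frame.sample_ids)
    if missing:
        raise ValidationError(f"sample frame missing samples: {sorted(missing)}")
    report = FilterReport()

    counts = table.counts
    taxonomy = table.taxonomy
    # lineage filter first; order is irrelevant under row removal
    if exclude_lineage_patterns:
        lineage_lc = taxonomy.str.lower()
        mask = pd.Series(False, index=counts.index)
        for pat in exclude_lineage_patterns:
            mask |= lineage_lc.str.contains(pat.lower(), regex=False)
        report.lineage_removed = counts.index[mask].tolist()
        counts = counts.loc[~mask]
        taxonomy = taxonomy.loc[~mask]

    controls = [s for s in frame.control_samples() if s in counts.columns]
    if controls:
        blank_counts = counts[controls]
        in_blank = blank_counts.sum(axis=1) >= 1
        if subtract_counts:
            sub = blank_counts.max(axis=1)
            counts = counts.sub(sub, axis=0).clip(lower=0)
            report.blank_removed = counts.index[in_blank & (counts.sum(axis=1) == 0)].tolist()
            keep = counts.sum(axis=1) > 0
            counts = counts.loc[keep]
            taxonomy = taxonomy.loc[keep]
        else:
            report.blank_removed = counts.index[in_blank].tolist()
            counts = counts.loc[~in_blank]
            taxonomy = taxonomy.loc[~in_blank]
        report.control_samples_dropped = controls
        counts = counts.drop(columns=controls)

    out = CountTable(counts.copy(), taxonomy.copy())
    if return_report:
        return out, report
    return out


def to_relative(table: CountTable) -> RelAbundTable:
    """Normalise each sample column to relative abundances.

    Raises on all-zero sample columns: an empty sample must be dropped by
    the caller, not silently normalised.
    """
    sums = table.counts.sum(axis=0)
    empty = sums.index[sums == 0].tolist()
    if empty:
        raise ValidationError(f"all-zero sample columns: {empty}")
    fractions = table.counts.div(sums, axis=1)
    return RelAbundTable(fractions, table.taxonomy.copy())


@dataclass
class RarefactionReport:
    depth: int
    seed: int
    dropped_samples: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"depth": self.depth, "seed": self.seed, "dropped_samples": self.dropped_samples}


def rarefy(
    table: CountTable, depth: int, seed: int, return_report: bool = False
):
    """Subsample every sample column to exactly ``depth`` reads without
    replacement (multivariate hypergeometric, one draw per sample).

    Samples with fewer than ``depth`` total reads are dropped and listed in
    the report. Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    report = RarefactionReport(depth=int(depth), seed=int(seed))
    sums = table.counts.sum(axis=0)
    cols: dict[str, np.ndarray] = {}
    for sample in table.sample_ids:
        total = int(sums[sample])
        if total < depth:
            report.dropped_samples.append(sample)
            continue
        colors = table.counts[sample].to_numpy(dtype=np.int64)
        if total == depth:
            cols[sample] = colors
        else:
            cols[sample] = rng.multivariate_hypergeometric(colors, depth)
    counts = pd.DataFrame(cols, index=table.counts.index, dtype=np.int64)
    if counts.empty:
        counts = pd.DataFrame(index=table.counts.index)
    out = CountTable(counts, table.taxonomy.copy())
    if return_report:
        return out, report
    return out
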