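"""Alpha diversity on rarefied counts: observed richness, Shannon, Chao-1."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable, SampleFrame
from .preprocess import rarefy


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over OTUs with p_i > 0.

    Natural log by default; pass ``base`` for another log base.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao-1 richness estimate from singleton and doubleton counts.

    Bias-corrected form S_obs + F1(F1-1) / (2(F2+1)) by default; the
    classical form S_obs + F1^2 / (2 F2) is available (undefined when
    F2 = 0 and F1 > 0, in which case the corrected form is used anyway).
    """
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("Chao-1 requires integer counts")
    c = c.astype(np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


@dataclass
class AlphaResult:
    """Per-sample alpha metrics at a common rarefaction depth, with
    per-(habitat, stratum, area) means and standard errors."""

    per_sample: pd.DataFrame  # columns: observed_otus, shannon, chao1 + metadata
    per_group: pd.DataFrame  # index (habitat, stratum, area); mean/se per metric
    rarefaction_depth: int
    seed: int
    dropped_samples: list[str] = field(default_factory=list)
    empty_groups: list[tuple] = field(default_factory=list)


METRICS = ("observed_otus", "shannon", "chao1")


def alpha_summary(
    table: CountTable,
    frame: SampleFrame,
    depth: int = 5000,
    seed: int = 0,
    group_cols: tuple[str, ...] = ("habitat", "stratum", "area"),
) -> AlphaResult:
    """Rarefy once per sample, compute the three alpha metrics, and
    aggregate by group. Samples below ``depth`` are dropped and reported;
    groups left with zero samples are reported, not silently omitted."""
    rare, report = rarefy(table, depth, seed, return_report=True)
    records = []
    for sample in rare.sample_ids:
        c = rare.counts[sample].to_numpy()
        rec = {
            "sample_id": sample,
            "observed_otus": int((c > 0).sum()),
            "shannon": shannon(c),
            "chao1": chao1(c),
        }
        for col in group_cols:
            rec[col] = frame.data.loc[sample, col]
        records.append(rec)
    per_sample = (
        pd.DataFrame.from_records(records).set_index("sample_id")
        if records
        else pd.DataFrame(columns=["sample_id", *METRICS, *group_cols]).set_index("sample_id")
    )

    all_groups = set(
        map(tuple, frame.data.loc[frame.noncontrol_samples(), list(group_cols)].to_numpy())
    )
    if len(per_sample):
        g = per_sample.groupby(list(group_cols))
        per_group = g[list(METRICS)].agg(["mean", "sem", "count"])
        per_group.columns = [f"{m}_{s}" for m, s in per_group.columns]
        # SEM of a single observation is NaN; report 0 spread is not claimed
        surviving = set(per_group.index if len(group_cols) > 1 else [(i,) for i in per_group.index])
    else:
        per_group = pd.DataFrame()
        surviving = set()
    empty = sorted(all_groups - surviving)
    return AlphaResult(
        per_sample=per_sample,
        per_group=per_group,
        rarefaction_depth=int(depth),
        seed=int(seed),
        dropped_samples=report.dropped_samples,
        empty_groups=empty,
    )
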