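"""Cross-habitat abundance coupling: stratum-pair regressions of OTU mean
relative abundances, taxon-group habitat fractions, and abundant-OTU flow
tables (which abundant source-stratum OTUs reappear in which destination
strata)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountTable, RelAbundTable, SampleFrame, StratumScheme, ValidationError


def stratum_mean_abundance(
    rel: RelAbundTable, frame: SampleFrame, scheme: StratumScheme
) -> pd.DataFrame:
    """Mean relative abundance of every OTU in every stratum (mean over
    samples, not pooled counts)."""
    cols = {}
    for st in scheme.labels:
        samples = [s for s in frame.samples_in_stratum(st) if s in rel.fractions.columns]
        cols[st] = rel.fractions[samples].mean(axis=1) if samples else np.nan
    return pd.DataFrame(cols)


@dataclass
class PairRegression:
    stratum_a: str
    stratum_b: str
    n_shared: int
    slope: float
    intercept: float
    r2: float
    p_value: float
    estimable: bool


@dataclass
class CouplingResult:
    regressions: list[PairRegression]
    mean_abundance: pd.DataFrame  # OTU x stratum

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.regressions])


def habitat_abundance_regression(
    rel: RelAbundTable,
    frame: SampleFrame,
    scheme: StratumScheme,
    pairs: list[tuple[str, str]],
) -> CouplingResult:
    """OLS of log10 mean abundance in stratum B on log10 mean abundance in
    stratum A, over OTUs detected (mean > 0) in both strata.

    Pairs with fewer than 3 jointly detected OTUs are flagged not-estimable
    rather than raised.
    """
    means = stratum_mean_abundance(rel, frame, scheme)
    for a, b in pairs:
        for st in (a, b):
            if st not in means.columns or means[st].isna().all():
                raise ValidationError(f"stratum {st!r} has no samples")
    out = []
    for a, b in pairs:
        xa, xb = means[a], means[b]
        joint = (xa > 0) & (xb > 0)
        n = int(joint.sum())
        if n < 3:
            out.append(PairRegression(a, b, n, np.nan, np.nan, np.nan, np.nan, False))
            continue
        lx = np.log10(xa[joint].to_numpy())
        ly = np.log10(xb[joint].to_numpy())
        res = stats.linregress(lx, ly)
        out.append(
            PairRegression(
                a, b, n, float(res.slope), float(res.intercept),
                float(res.rvalue**2), float(res.pvalue), True,
            )
        )
    return CouplingResult(regressions=out, mean_abundance=means)


def taxon_habitat_fractions(
    table: CountTable,
    frame: SampleFrame,
    lineage_pattern: str,
    habitats: tuple[str, ...] = ("water", "sediment", "nodule"),
    by: str = "habitat",
) -> pd.Series:
    """Fraction of a taxon group's total sequences found in each habitat
    (or stratum, with ``by="stratum"``). Matching is case-insensitive
    substring on the lineage. Fractions over the full partition sum to 1."""
    mask = table.taxonomy.str.lower().str.contains(lineage_pattern.lower(), regex=False)
    if not mask.any():
        raise ValidationError(f"lineage pattern {lineage_pattern!r} matches no OTU")
    samples = [s for s in frame.noncontrol_samples() if s in table.counts.columns]
    group_counts = table.counts.loc[mask, samples].sum(axis=0)
    key = frame.data.loc[samples, by]
    per = group_counts.groupby(key).sum()
    total = per.sum()
    if total == 0:
        raise ValidationError(f"group {lineage_pattern!r} has zero sequences")
    frac = per / total
    if by == "habitat":
        frac = frac.reindex(list(habitats), fill_value=0.0)
    return frac


@dataclass
class FlowTable:
    """Abundant source-stratum OTUs and where else they occur."""

    source_stratum: str
    threshold: float
    mean_abundance: pd.DataFrame  # abundant OTUs x all strata
    detected: pd.DataFrame  # same shape, bool


def abundant_flow(
    rel: RelAbundTable,
    frame: SampleFrame,
    scheme: StratumScheme,
    source_stratum: str,
    threshold: float = 0.01,
) -> FlowTable:
    """OTUs whose mean relative abundance in the source stratum exceeds the
    threshold (default 1%), with their mean abundance and a detection flag
    in every other stratum."""
    means = stratum_mean_abundance(rel, frame, scheme)
    if source_stratum not in means.columns or means[source_stratum].isna().all():
        raise ValidationError(f"source stratum {source_stratum!r} has no samples")
    abundant = means.index[means[source_stratum] > threshold]
    sub = means.loc[abundant]
    return FlowTable(
        source_stratum=source_stratum,
        threshold=threshold,
        mean_abundance=sub,
        detected=sub > 0,
    )
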