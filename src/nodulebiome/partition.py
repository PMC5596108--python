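"""Habitat partitioning of OTUs: presence/absence by stratum, three-habitat
Venn partition, and the specialist / moderate-generalist / generalist
classification with occupancy and per-class sequence contributions.

Classification rules (presence/absence over strata):

* **specialist** — detected in exactly one stratum;
* **generalist** — detected in every stratum of a core set spanning all
  three habitats (``rule_set="strict"``: every stratum of the scheme;
  ``rule_set="operative"``: all water zones, the nodules, and the
  sediment layers above 6 cm — the operative rule, since surveys of this
  kind find no OTU spanning the deepest sediment layers);
* **moderate_generalist** — detected in at least two habitats but not a
  generalist;
* **unclassified** — detected in several strata of a single habitat
  (a pattern the three rules above do not cover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CountTable,
    SampleFrame,
    StratumScheme,
    ValidationError,
    operative_core_set,
)

RULE_SETS = ("strict", "operative")
LABELS = ("specialist", "moderate_generalist", "generalist", "unclassified")


@dataclass
class PresenceMatrix:
    """OTU x stratum detection booleans.

    OTUs detected nowhere under the detection rule are dropped and listed in
    ``dropped_otus``.
    """

    detected: pd.DataFrame  # bool, index otu_id, columns stratum labels
    min_count: int
    min_samples: int
    dropped_otus: list[str] = field(default_factory=list)
    empty_strata: list[str] = field(default_factory=list)


def presence_matrix(
    table: CountTable,
    frame: SampleFrame,
    scheme: StratumScheme,
    min_count: int = 1,
    min_samples: int = 1,
) -> PresenceMatrix:
    """detected(otu, stratum) iff the OTU has >= min_count reads in >=
    min_samples samples of that stratum."""
    missing = set(table.sample_ids) - set(frame.sample_ids)
    if missing:
        raise ValidationError(f"sample frame missing samples: {sorted(missing)}")
    cols = {}
    empty_strata = []
    for st in scheme.labels:
        samples = [s for s in frame.samples_in_stratum(st) if s in table.counts.columns]
        if not samples:
            empty_strata.append(st)
            cols[st] = pd.Series(False, index=table.counts.index)
            continue
        hits = (table.counts[samples] >= min_count).sum(axis=1)
        cols[st] = hits >= min_samples
    det = pd.DataFrame(cols)[scheme.labels]
    nowhere = det.index[~det.any(axis=1)].tolist()
    det = det.loc[det.any(axis=1)]
    return PresenceMatrix(
        detected=det,
        min_count=min_count,
        min_samples=min_samples,
        dropped_otus=nowhere,
        empty_strata=empty_strata,
    )


@dataclass
class VennPartition:
    """Counts of OTUs in the 7 regions of the water/sediment/nodule Venn
    diagram, plus habitat totals and pairwise shared counts."""

    region_counts: dict[str, int]  # keys like "water", "water&sediment", ...
    habitat_totals: dict[str, int]
    pairwise_shared: dict[str, int]
    n_otus: int

    def as_dict(self) -> dict:
        return {
            "region_counts": self.region_counts,
            "habitat_totals": self.habitat_totals,
            "pairwise_shared": self.pairwise_shared,
            "n_otus": self.n_otus,
        }


_HABS = ("water", "sediment", "nodule")


def venn_partition(presence: PresenceMatrix, scheme: StratumScheme) -> VennPartition:
    """Partition OTUs over the three habitats by inclusion-exclusion.

    Habitat-level presence is the OR over that habitat's strata.
    """
    hab_presence = {}
    for hab in _HABS:
        strata = [s for s in scheme.strata_of(hab) if s in presence.detected.columns]
        hab_presence[hab] = (
            presence.detected[strata].any(axis=1)
            if strata
            else pd.Series(False, index=presence.detected.index)
        )
    hp = pd.DataFrame(hab_presence)
    region_counts: dict[str, int] = {}
    for mask in range(1, 8):
        members = [h for i, h in enumerate(_HABS) if mask >> i & 1]
        sel = pd.Series(True, index=hp.index)
        for h in _HABS:
            sel &= hp[h] if h in members else ~hp[h]
        region_counts["&".join(members)] = int(sel.sum())
    habitat_totals = {h: int(hp[h].sum()) for h in _HABS}
    pairwise = {}
    for i, h1 in enumerate(_HABS):
        for h2 in _HABS[i + 1 :]:
            pairwise[f"{h1}&{h2}"] = int((hp[h1] & hp[h2]).sum())
    return VennPartition(
        region_counts=region_counts,
        habitat_totals=habitat_totals,
        pairwise_shared=pairwise,
        n_otus=len(hp),
    )


def shared_among(presence: PresenceMatrix, strata: list[str], absent_from: list[str] | None = None) -> int:
    """Number of OTUs detected in every listed stratum (and, optionally,
    in none of ``absent_from``)."""
    det = presence.detected
    sel = det[strata].all(axis=1)
    if absent_from:
        sel &= ~det[absent_from].any(axis=1)
    return int(sel.sum())


@dataclass
class HabitatClassification:
    labels: pd.Series  # otu_id -> label
    specialist_stratum: pd.Series  # otu_id -> stratum (specialists only)
    specialist_habitat: pd.Series
    occupancy: pd.Series  # otu_id -> fraction of non-control samples detected
    rule_set: str
    core_set: list[str]


def classify_otus(
    presence: PresenceMatrix,
    scheme: StratumScheme,
    rule_set: str = "operative",
    occupancy_table: CountTable | None = None,
    frame: SampleFrame | None = None,
    min_count: int | None = None,
) -> HabitatClassification:
    """Assign every OTU exactly one habitat-breadth label (see module
    docstring for the rules). Occupancy — the fraction of non-control
    samples in which an OTU is detected — is computed when a count table and
    sample frame are supplied."""
    if rule_set not in RULE_SETS:
        raise ValueError(f"unknown rule_set {rule_set!r}; expected one of {RULE_SETS}")
    det = presence.detected
    if det.empty:
        raise ValidationError("presence matrix is empty")
    core = (
        list(scheme.labels) if rule_set == "strict" else operative_core_set(scheme)
    )
    unknown = set(core) - set(det.columns)
    if unknown:
        raise ValidationError(f"core set references unknown strata: {sorted(unknown)}")

    habitat_of = {s: scheme.habitat_of(s) for s in det.columns}
    n_strata = det.sum(axis=1)
    hab_df = pd.DataFrame(
        {
            hab: det[[s for s in det.columns if habitat_of[s] == hab]].any(axis=1)
            for hab in _HABS
        }
    )
    n_habitats = hab_df.sum(axis=1)
    is_generalist = det[core].all(axis=1)

    labels = pd.Series("unclassified", index=det.index)
    labels[n_habitats >= 2] = "moderate_generalist"
    labels[is_generalist] = "generalist"
    labels[n_strata == 1] = "specialist"

    spec = labels.index[labels == "specialist"]
    spec_stratum = pd.Series(
        det.loc[spec].idxmax(axis=1) if len(spec) else pd.Series(dtype=object), index=spec
    )
    spec_habitat = spec_stratum.map(habitat_of)

    occupancy = pd.Series(np.nan, index=det.index)
    if occupancy_table is not None and frame is not None:
        mc = min_count if min_count is not None else presence.min_count
        samples = [
            s for s in frame.noncontrol_samples() if s in occupancy_table.counts.columns
        ]
        detected = (occupancy_table.counts[samples] >= mc).sum(axis=1) / len(samples)
        occupancy = detected.reindex(det.index)

    return HabitatClassification(
        labels=labels,
        specialist_stratum=spec_stratum,
        specialist_habitat=spec_habitat,
        occupancy=occupancy,
        rule_set=rule_set,
        core_set=core,
    )


@dataclass
class ClassSummary:
    per_class: pd.DataFrame  # n_otus, pct_sequences per label
    per_class_stratum: pd.DataFrame  # specialist counts and pct per stratum
    top_occupancy: pd.DataFrame  # widest-distribution OTUs per class


def class_summary(
    classification: HabitatClassification,
    table: CountTable,
    frame: SampleFrame,
    top_n: int = 20,
) -> ClassSummary:
    """Per-class OTU counts and percent-of-total-sequence contributions,
    specialist breakdown per stratum, and the top-N widest-distribution OTUs
    per class (ranked by occupancy, ties by total count then OTU id)."""
    samples = [s for s in frame.noncontrol_samples() if s in table.counts.columns]
    counts = table.counts[samples]
    shared = classification.labels.index.intersection(counts.index)
    if len(shared) == 0:
        raise ValidationError("classification and table share no OTU ids")
    total_seqs = counts.sum().sum()
    totals = counts.loc[shared].sum(axis=1)
    labels = classification.labels.loc[shared]

    per_class = pd.DataFrame(
        {
            "n_otus": labels.value_counts().reindex(LABELS, fill_value=0),
            "pct_sequences": totals.groupby(labels).sum().reindex(LABELS, fill_value=0)
            / total_seqs
            * 100.0,
        }
    )

    spec_ids = labels.index[labels == "specialist"]
    strat = classification.specialist_stratum.loc[spec_ids]
    per_cs = pd.DataFrame(
        {
            "n_otus": strat.value_counts(),
            "pct_sequences": totals.loc[spec_ids].groupby(strat).sum() / total_seqs * 100.0,
        }
    ).fillna(0)

    occ = classification.occupancy.loc[shared]
    rank_df = pd.DataFrame(
        {"label": labels, "occupancy": occ, "total_count": totals}
    ).reset_index(names="otu_id")
    rank_df = rank_df.sort_values(
        ["label", "occupancy", "total_count", "otu_id"],
        ascending=[True, False, False, True],
    )
    top = rank_df.groupby("label", group_keys=False).head(top_n)
    return ClassSummary(per_class=per_class, per_class_stratum=per_cs, top_occupancy=top)
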