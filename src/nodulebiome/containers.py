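"""Core in-memory containers for OTU-table analyses.

The package works on three aligned objects: a :class:`CountTable` (integer
OTU x sample matrix with a taxonomy lineage per OTU), a :class:`SampleFrame`
mapping samples to habitat/stratum/area/depth, and a :class:`StratumScheme`
giving the ordered vertical strata (water-column zones, sediment layers,
nodules) that the survey design distinguishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HABITATS = ("water", "sediment", "nodule")
CONTROL = "control"


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass(frozen=True)
class Stratum:
    """One vertical stratum: a label, its habitat, and optional depth bounds.

    Depth bounds are metres for water strata and centimetres below the
    sediment surface for sediment strata; nodules carry no bounds.
    """

    label: str
    habitat: str
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"stratum {self.label!r}: habitat {self.habitat!r} not in {HABITATS}"
            )


@dataclass(frozen=True)
class StratumScheme:
    """Ordered stratum definitions for one survey design."""

    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ValidationError("stratum labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strata]

    def habitat_of(self, label: str) -> str:
        for s in self.strata:
            if s.label == label:
                return s.habitat
        raise KeyError(f"unknown stratum {label!r}")

    def strata_of(self, habitat: str) -> list[str]:
        return [s.label for s in self.strata if s.habitat == habitat]

    def __contains__(self, label: object) -> bool:
        return any(s.label == label for s in self.strata)

    def __len__(self) -> int:
        return len(self.strata)


def default_scheme() -> StratumScheme:
    """The CCZ survey scheme: four water-column zones, five sediment layers
    (cm below surface), and the nodule habitat.

    Water-zone bounds follow the oceanographic convention (epipelagic
    0-200 m, mesopelagic 200-1,000 m, bathypelagic 1,000-3,000 m,
    abyssopelagic below 3,000 m).
    """
    return StratumScheme(
        (
            Stratum("epipelagic", "water", 0, 200),
            Stratum("mesopelagic", "water", 200, 1000),
            Stratum("bathypelagic", "water", 1000, 3000),
            Stratum("abyssopelagic", "water", 3000, None),
            Stratum("sed_0_5", "sediment", 0, 5),
            Stratum("sed_5_6", "sediment", 5, 6),
            Stratum("sed_6_8", "sediment", 6, 8),
            Stratum("sed_8_10", "sediment", 8, 10),
            Stratum("sed_15_18", "sediment", 15, 18),
            Stratum("nodule", "nodule", None, None),
        )
    )


# core set used by the operative generalist rule: every water zone, the
# nodules, and the sediment layers whose upper bound is at most 6 cm.
def operative_core_set(scheme: StratumScheme) -> list[str]:
    core: list[str] = []
    for s in scheme.strata:
        if s.habitat in ("water", "nodule"):
            core.append(s.label)
        elif s.habitat == "sediment" and s.upper is not None and s.upper <= 6:
            core.append(s.label)
    return core


@dataclass
class CountTable:
    """Integer OTU x sample count matrix with per-OTU taxonomy lineages.

    ``counts`` is a pandas DataFrame indexed by OTU id with one column per
    sample; ``taxonomy`` is a Series over the same index holding
    semicolon-ranked lineage strings (``d__...;p__...;...``), possibly empty.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if arr.size and (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.counts.index, dtype=str)
        else:
            self.taxonomy = self.taxonomy.reindex(self.counts.index).fillna("").astype(str)

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[:, list(sample_ids)].copy(), self.taxonomy.copy())

    def subset_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        keep = list(otu_ids)
        return CountTable(self.counts.loc[keep].copy(), self.taxonomy.loc[keep].copy())

    def equals(self, other: "CountTable") -> bool:
        return self.counts.equals(other.counts) and self.taxonomy.equals(other.taxonomy)


@dataclass
class RelAbundTable:
    """Relative-abundance table: every sample column sums to 1."""

    fractions: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy(dtype=float)
        if arr.size:
            if (arr < 0).any() or (arr > 1 + 1e-12).any():
                raise ValidationError("fractions must lie in [0, 1]")
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.fractions.columns[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise ValidationError(f"sample columns do not sum to 1: {bad}")
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.fractions.index, dtype=str)
        else:
            self.taxonomy = self.taxonomy.reindex(self.fractions.index).fillna("").astype(str)

    @property
    def otu_ids(self) -> list[str]:
        return self.fractions.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.fractions.columns.tolist()


REQUIRED_FRAME_COLUMNS = ("habitat", "stratum", "area")


@dataclass
class SampleFrame:
    """Sample metadata: habitat, stratum, study area, and depth per sample.

    ``data`` is indexed by sample id with columns habitat, stratum, area and
    (optionally) depth. Control (blank) samples carry habitat ``"control"``
    and an empty stratum.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_FRAME_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample frame missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sample frame")
        bad = set(self.data["habitat"]) - set(HABITATS) - {CONTROL}
        if bad:
            raise ValidationError(f"unknown habitats: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def control_samples(self) -> list[str]:
        return self.data.index[self.data["habitat"] == CONTROL].tolist()

    def noncontrol_samples(self) -> list[str]:
        return self.data.index[self.data["habitat"] != CONTROL].tolist()

    def samples_in_stratum(self, stratum: str) -> list[str]:
        return self.data.index[self.data["stratum"] == stratum].tolist()

    def validate_against(self, scheme: StratumScheme) -> None:
        noncontrol = self.data[self.data["habitat"] != CONTROL]
        unknown = set(noncontrol["stratum"]) - set(scheme.labels)
        if unknown:
            raise ValidationError(f"strata not in scheme: {sorted(unknown)}")
        for sid, row in noncontrol.iterrows():
            if scheme.habitat_of(row["stratum"]) != row["habitat"]:
                raise ValidationError(
                    f"sample {sid!r}: habitat {row['habitat']!r} disagrees with "
                    f"stratum {row['stratum']!r}"
                )

    def subset(self, sample_ids: Iterable[str]) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)].copy())


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]
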