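"""Synthetic OTU-table generator with planted ground truth.

Emulates the post-clustering artefacts of a deep-sea nodule-field 16S
survey: a count table over water-column zones, sediment layers, and nodule
samples across several study areas, with

* planted habitat-preference classes (specialists confined to one stratum,
  moderate generalists spanning two or more habitats, generalists covering
  a core stratum set that spans all three habitats),
* an extraction-blank control carrying kit-contaminant OTUs that also
  bleed into real samples,
* decoy lineages (chloroplast 16S, archaeal reads) that preprocessing must
  remove,
* export-coupled epipelagic OTUs co-seeded onto nodules but never into
  sediments (the phytodetritus-export signature), and
* an optional paired eukaryote (18S) table with planted cross-domain
  abundance-coupled OTU pairs.

The model: each OTU draws a log-normal base abundance; within a sample the
latent abundance is base x ``preference_multiplier`` in preferred strata and
base x ``off_habitat_epsilon`` elsewhere, times a per-OTU-per-sample
log-normal fluctuation (``sample_sigma``). Realised counts are a single
multinomial draw per sample at a Normal(depth_mean, depth_sd) sequencing
depth (rounded, truncated at 1); a Dirichlet-multinomial option adds
overdispersion. Identical parameters (including the seed) give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    CountTable,
    SampleFrame,
    StratumScheme,
    default_scheme,
    operative_core_set,
)

SPECIALIST = "specialist"
MODERATE = "moderate_generalist"
GENERALIST = "generalist"
CONTAMINANT = "contaminant"
DECOY = "decoy"

_AREA_NAMES = ("UK1-A", "UK1-B", "OMS-A", "APEI-6")

_LINEAGES = {
    "epipelagic": "d__Bacteria;p__Cyanobacteria;c__Cyanobacteriia;o__Synechococcales;f__Cyanobiaceae;g__Prochlorococcus",
    "water": "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__SAR11_clade;f__Clade_I;g__Clade_Ia",
    "sediment": "d__Bacteria;p__Planctomycetes;c__Planctomycetia;o__Pirellulales;f__Pirellulaceae;g__",
    "sediment2": "d__Bacteria;p__Chloroflexi;c__Anaerolineae;o__Anaerolineales;f__Anaerolineaceae;g__",
    "nodule": "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Steroidobacterales;f__Woeseiaceae;g__JTB255",
    "nodule2": "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhizobiales;f__Rhodobiaceae;g__",
    MODERATE: "d__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__SAR324_clade;f__;g__",
    GENERALIST: "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;o__Rhodospirillales;f__Rhodospirillaceae;g__",
    CONTAMINANT: "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Moraxellaceae;g__Acinetobacter",
    "decoy_plastid": "d__Bacteria;p__Cyanobacteria;c__Chloroplast;o__;f__;g__",
    "decoy_archaea": "d__Archaea;p__Thaumarchaeota;c__Nitrososphaeria;o__Nitrosopumilales;f__Nitrosopumilaceae;g__",
    "euk": "d__Eukaryota;p__Retaria;c__Foraminifera;o__Rotaliida;f__;g__",
    "euk2": "d__Eukaryota;p__Ochrophyta;c__Bacillariophyceae;o__;f__;g__",
}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the community simulator.

    ``n_specialist_otus_per_stratum`` may be a single count applied to every
    stratum or a mapping from stratum label to count (to plant, e.g., a
    sediment-heavy diversity gradient).
    """

    n_areas: int = 4
    strata: StratumScheme = field(default_factory=default_scheme)
    samples_per_stratum_per_area: int = 11
    n_specialist_otus_per_stratum: int | Mapping[str, int] = 30
    n_moderate_otus: int = 150
    n_generalist_otus: int = 30
    n_contaminant_otus: int = 10
    n_decoy_otus: int = 10
    abund_mu: float = 0.0
    abund_sigma: float = 1.0
    sample_sigma: float = 0.8
    preference_multiplier: float = 1000.0
    off_habitat_epsilon: float = 0.01
    export_fraction: float = 0.3
    export_scale: float = 0.1
    export_to_nearbottom: bool = False
    overdispersion: float = 0.0
    depth_mean: float = 9694.7
    depth_sd: float = 892.7
    n_euk_otus: int = 100
    n_planted_pairs: int = 20
    pair_noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_areas,
            self.samples_per_stratum_per_area,
            self.n_moderate_otus,
            self.n_generalist_otus,
            self.n_contaminant_otus,
            self.n_decoy_otus,
            self.n_euk_otus,
            self.n_planted_pairs,
        ]
        if isinstance(self.n_specialist_otus_per_stratum, int):
            counts.append(self.n_specialist_otus_per_stratum)
        else:
            counts.extend(self.n_specialist_otus_per_stratum.values())
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.abund_sigma <= 0 or self.pair_noise_sigma <= 0:
            raise ValueError("abund_sigma and pair_noise_sigma must be > 0")
        if self.sample_sigma < 0:
            raise ValueError("sample_sigma must be >= 0")
        if not (0.0 <= self.export_fraction <= 1.0):
            raise ValueError("export_fraction must lie in [0, 1]")
        if self.export_scale <= 0:
            raise ValueError("export_scale must be > 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.preference_multiplier < 1:
            raise ValueError("preference_multiplier must be >= 1")
        if self.off_habitat_epsilon < 0:
            raise ValueError("off_habitat_epsilon must be >= 0")

    def specialists_in(self, stratum: str) -> int:
        if isinstance(self.n_specialist_otus_per_stratum, int):
            return self.n_specialist_otus_per_stratum
        return int(self.n_specialist_otus_per_stratum.get(stratum, 0))


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-OTU class and preferred strata, export
    flags, and (after the eukaryote table is generated) planted 16S-18S
    pairs."""

    planted_class: dict[str, str]
    preferred_strata: dict[str, list[str]]
    exported: dict[str, bool]
    planted_pairs: list[tuple[str, str]]
    seed: int
    # per-sample latent abundances, kept so a paired eukaryote table can
    # share them; not part of the serialised record
    latent: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "planted_class": self.planted_class,
            "preferred_strata": self.preferred_strata,
            "exported": self.exported,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "seed": self.seed,
        }


def _draw_depths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    d = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.maximum(d, 1)


def _sample_counts(
    rng: np.random.Generator, latent: np.ndarray, depth: int, overdispersion: float
) -> np.ndarray:
    total = latent.sum()
    if total <= 0:
        raise ValueError("sample with all-zero latent abundance")
    p = latent / total
    if overdispersion > 0:
        alpha = np.where(p > 0, p / overdispersion, 0.0)
        mask = alpha > 0
        q = np.zeros_like(p)
        q[mask] = rng.dirichlet(alpha[mask])
        p = q
    return rng.multinomial(depth, p)


def generate_community(
    params: SimParams,
) -> tuple[CountTable, SampleFrame, SyntheticTruth]:
    """Generate a bacterial count table, its sample metadata (including one
    blank control), and the planted-truth record."""
    scheme = params.strata
    habitats = {s.habitat for s in scheme.strata}
    if params.export_fraction > 0 and not {"water", "sediment", "nodule"} <= habitats:
        raise ValueError(
            "export_fraction > 0 requires water, sediment, and nodule strata"
        )
    rng = np.random.default_rng(params.seed)

    # --- samples -----------------------------------------------------------
    areas = [
        _AREA_NAMES[i] if i < len(_AREA_NAMES) else f"AREA-{i + 1}"
        for i in range(params.n_areas)
    ]
    rows = []
    for area in areas:
        for st in scheme.strata:
            mid = None
            if st.lower is not None:
                mid = st.lower if st.upper is None else (st.lower + st.upper) / 2
            for rep in range(params.samples_per_stratum_per_area):
                rows.append(
                    {
                        "sample_id": f"{area}.{st.label}.{rep + 1}",
                        "habitat": st.habitat,
                        "stratum": st.label,
                        "area": area,
                        "depth": mid,
                    }
                )
    rows.append(
        {"sample_id": "blank_1", "habitat": CONTROL, "stratum": "", "area": "", "depth": None}
    )
    frame_df = pd.DataFrame(rows).set_index("sample_id")
    frame = SampleFrame(frame_df)
    real_samples = frame.noncontrol_samples()
    sample_strata = frame_df.loc[real_samples, "stratum"].to_numpy()

    # --- OTUs and planted classes -----------------------------------------
    otu_ids: list[str] = []
    classes: dict[str, str] = {}
    preferred: dict[str, list[str]] = {}
    lineages: dict[str, str] = {}
    exported: dict[str, bool] = {}

    sed_toggle = 0
    nod_toggle = 0
    epipelagic_specialists: list[str] = []
    for st in scheme.strata:
        for i in range(params.specialists_in(st.label)):
            oid = f"OTU_sp_{st.label}_{i + 1}"
            otu_ids.append(oid)
            classes[oid] = SPECIALIST
            preferred[oid] = [st.label]
            if st.label == "epipelagic":
                lineages[oid] = _LINEAGES["epipelagic"]
                epipelagic_specialists.append(oid)
            elif st.habitat == "water":
                lineages[oid] = _LINEAGES["water"]
            elif st.habitat == "sediment":
                lineages[oid] = _LINEAGES["sediment" if sed_toggle % 2 == 0 else "sediment2"]
                sed_toggle += 1
            else:
                lineages[oid] = _LINEAGES["nodule" if nod_toggle % 2 == 0 else "nodule2"]
                nod_toggle += 1

    core = set(operative_core_set(scheme))
    habitat_list = sorted(habitats)
    for i in range(params.n_moderate_otus):
        oid = f"OTU_mg_{i + 1}"
        n_hab = 2 if (len(habitat_list) < 3 or rng.random() < 0.7) else 3
        habs = list(rng.choice(habitat_list, size=min(n_hab, len(habitat_list)), replace=False))
        pref: list[str] = []
        for hab in habs:
            strata = scheme.strata_of(hab)
            k = int(rng.integers(1, len(strata) + 1))
            pref.extend(rng.choice(strata, size=k, replace=False))
        pref = sorted(set(pref), key=scheme.labels.index)
        # a moderate generalist must not cover the generalist core set
        if core <= set(pref):
            drop = [p for p in pref if p in core]
            pref.remove(drop[int(rng.integers(len(drop)))])
        otu_ids.append(oid)
        classes[oid] = MODERATE
        preferred[oid] = pref
        lineages[oid] = _LINEAGES[MODERATE]

    core_ordered = [s for s in scheme.labels if s in core]
    for i in range(params.n_generalist_otus):
        oid = f"OTU_gen_{i + 1}"
        otu_ids.append(oid)
        classes[oid] = GENERALIST
        preferred[oid] = core_ordered
        lineages[oid] = _LINEAGES[GENERALIST]

    for i in range(params.n_contaminant_otus):
        oid = f"OTU_contam_{i + 1}"
        otu_ids.append(oid)
        classes[oid] = CONTAMINANT
        preferred[oid] = []
        lineages[oid] = _LINEAGES[CONTAMINANT]

    for i in range(params.n_decoy_otus):
        oid = f"OTU_decoy_{i + 1}"
        otu_ids.append(oid)
        classes[oid] = DECOY
        preferred[oid] = list(scheme.labels)
        lineages[oid] = _LINEAGES["decoy_plastid" if i % 2 == 0 else "decoy_archaea"]

    # export-coupled epipelagic specialists: co-seeded onto nodules, never
    # into sediments
    n_export = int(round(params.export_fraction * len(epipelagic_specialists)))
    export_ids = set()
    if n_export:
        export_ids = set(
            rng.choice(epipelagic_specialists, size=n_export, replace=False)
        )
    for oid in otu_ids:
        exported[oid] = oid in export_ids

    # --- latent abundances -------------------------------------------------
    n_otus = len(otu_ids)
    base = rng.lognormal(params.abund_mu, params.abund_sigma, size=n_otus)
    otu_index = {oid: k for k, oid in enumerate(otu_ids)}

    nodule_strata = set(scheme.strata_of("nodule"))
    water_strata = scheme.strata_of("water")
    nearbottom = {water_strata[-1]} if (params.export_to_nearbottom and water_strata) else set()

    mult = np.full((n_otus, len(real_samples)), params.off_habitat_epsilon)
    stratum_cols: dict[str, np.ndarray] = {
        st: np.flatnonzero(sample_strata == st) for st in scheme.labels
    }
    for oid in otu_ids:
        k = otu_index[oid]
        cls = classes[oid]
        if cls == CONTAMINANT:
            mult[k, :] = 1.0  # kit contamination bleeds evenly into samples
            continue
        if cls == DECOY:
            mult[k, :] = 1.0
            continue
        for st in preferred[oid]:
            mult[k, stratum_cols[st]] = params.preference_multiplier
        if exported[oid]:
            # exported abundance = attenuated copy of the source-water
            # (boosted) abundance, seeded onto nodules only
            exported_mult = params.export_scale * params.preference_multiplier
            for st in nodule_strata | nearbottom:
                cols = stratum_cols[st]
                mult[k, cols] = np.maximum(mult[k, cols], exported_mult)

    latent = base[:, None] * mult
    if params.sample_sigma > 0:
        latent = latent * np.exp(
            rng.normal(0.0, params.sample_sigma, size=latent.shape)
        )

    # --- realised counts ---------------------------------------------------
    depths = _draw_depths(rng, len(real_samples), params.depth_mean, params.depth_sd)
    counts = np.zeros((n_otus, len(real_samples)), dtype=np.int64)
    for j in range(len(real_samples)):
        counts[:, j] = _sample_counts(rng, latent[:, j], int(depths[j]), params.overdispersion)

    # blank control: contaminant OTUs only
    blank = np.zeros(n_otus, dtype=np.int64)
    contam_idx = [otu_index[o] for o in otu_ids if classes[o] == CONTAMINANT]
    if contam_idx:
        blank_depth = int(_draw_depths(rng, 1, params.depth_mean, params.depth_sd)[0])
        blank_lat = base[contam_idx]
        blank[contam_idx] = _sample_counts(rng, blank_lat, blank_depth, params.overdispersion)

    count_df = pd.DataFrame(counts, index=otu_ids, columns=real_samples)
    count_df["blank_1"] = blank
    count_df = count_df[frame.sample_ids]
    table = CountTable(count_df, pd.Series(lineages).reindex(otu_ids))

    truth = SyntheticTruth(
        planted_class=classes,
        preferred_strata=preferred,
        exported=exported,
        planted_pairs=[],
        seed=params.seed,
        latent=pd.DataFrame(latent, index=otu_ids, columns=real_samples),
    )
    return table, frame, truth


def generate_paired_euk_table(
    params: SimParams, truth: SyntheticTruth, frame: SampleFrame
) -> tuple[CountTable, SyntheticTruth]:
    """Generate a eukaryote (18S) table over the same non-control samples.

    ``n_planted_pairs`` eukaryote OTUs share their paired bacterial OTU's
    per-sample latent log-abundance plus Normal(0, pair_noise_sigma) noise;
    the remaining eukaryote OTUs have sample-independent latents.
    """
    if truth.latent is None:
        raise ValueError("truth must come from generate_community (latent record missing)")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 18]))
    samples = [s for s in frame.noncontrol_samples() if s in truth.latent.columns]

    candidates = [
        o
        for o in truth.latent.index
        if truth.planted_class[o] in (GENERALIST, MODERATE, SPECIALIST)
    ]
    if params.n_planted_pairs > len(candidates):
        raise ValueError(
            f"n_planted_pairs={params.n_planted_pairs} exceeds available bacterial OTUs "
            f"({len(candidates)})"
        )
    if params.n_planted_pairs > params.n_euk_otus:
        raise ValueError("n_planted_pairs exceeds n_euk_otus")
    paired_bact = (
        [str(o) for o in rng.choice(candidates, size=params.n_planted_pairs, replace=False)]
        if params.n_planted_pairs
        else []
    )

    euk_ids = [f"EUK_{i + 1}" for i in range(params.n_euk_otus)]
    latent = np.empty((params.n_euk_otus, len(samples)))
    base = rng.lognormal(params.abund_mu, params.abund_sigma, size=params.n_euk_otus)
    pairs: list[tuple[str, str]] = []
    for i, eid in enumerate(euk_ids):
        if i < len(paired_bact):
            b = paired_bact[i]
            shared = truth.latent.loc[b, samples].to_numpy(dtype=float)
            # share the latent's per-sample variation at the eukaryote's own
            # abundance scale (a constant log offset leaves coupling intact)
            scale = shared[shared > 0].mean() if (shared > 0).any() else 1.0
            noise = np.exp(rng.normal(0.0, params.pair_noise_sigma, size=len(samples)))
            latent[i] = base[i] * (shared / scale) * noise
            pairs.append((b, eid))
        else:
            # independent OTUs fluctuate too; without this, the paired OTUs
            # would dominate the compositional denominator and induce
            # spurious cross-table correlations
            jitter = np.exp(rng.normal(0.0, params.sample_sigma, size=len(samples)))
            latent[i] = base[i] * jitter

    depths = _draw_depths(rng, len(samples), params.depth_mean, params.depth_sd)
    counts = np.zeros((params.n_euk_otus, len(samples)), dtype=np.int64)
    for j in range(len(samples)):
        counts[:, j] = _sample_counts(rng, latent[:, j], int(depths[j]), params.overdispersion)

    lineage = pd.Series(
        [_LINEAGES["euk" if i % 2 == 0 else "euk2"] for i in range(params.n_euk_otus)],
        index=euk_ids,
    )
    table = CountTable(pd.DataFrame(counts, index=euk_ids, columns=samples), lineage)
    new_truth = replace(truth, planted_pairs=list(pairs))
    return table, new_truth
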