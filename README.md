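# nodulebiome

Community-level analysis of 16S rRNA amplicon surveys of deep-sea
polymetallic-nodule fields — the abyssal Pacific habitats where
manganese-nodule mining is planned and where bacterial communities span
three very different habitats: the overlying water column, the sediment,
and the nodules themselves.

The package is aimed at microbial ecologists working with OTU count tables
from such surveys (or any multi-habitat amplicon design). It provides, as a
tested library with a CLI:

* **Preprocessing** — decoy-lineage removal (chloroplast 16S, archaeal
  reads), blank-control contaminant subtraction, relative-abundance
  normalisation, and seeded rarefaction (multivariate hypergeometric).
* **Alpha diversity** — observed OTUs, Shannon H = −Σ pᵢ ln pᵢ, and
  bias-corrected Chao-1 Ŝ = S_obs + F₁(F₁−1)/(2(F₂+1)), with per-group
  summaries.
* **Beta diversity** — Bray-Curtis d = 1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ),
  non-metric multidimensional scaling minimising Kruskal stress-1 with
  isotonic regression, one-way PERMANOVA (pseudo-F with permutation p, and
  exact small-sample enumeration), and two-way ANOVA with Tukey HSD for
  between-area diversity comparisons.
* **Habitat specialization** — presence/absence by stratum, the
  three-habitat Venn partition, and the specialist / moderate-generalist /
  generalist occupancy classification with per-class sequence
  contributions.
* **Export coupling** — cross-stratum log-log abundance regressions,
  taxon-group habitat fractions, and abundant-OTU flow tables that trace
  surface (e.g. cyanobacterial) populations onto nodules.
* **Co-occurrence networks** — cross-domain (16S–18S) Spearman edges with
  permutation p-values and Benjamini–Hochberg FDR control.
* **A synthetic-community generator** with planted ground truth (habitat
  preference classes, export-coupled OTUs, contaminants, decoy lineages,
  coupled 16S–18S pairs) used throughout the test suite for
  parameter-recovery validation.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

```python
from nodulebiome import (
    SimParams, generate_community, filter_table, to_relative, alpha_summary,
    bray_curtis, permanova, nmds, presence_matrix, classify_otus,
    class_summary, venn_partition,
)

params = SimParams(
    n_areas=2, samples_per_stratum_per_area=3,
    n_specialist_otus_per_stratum=30, n_moderate_otus=150,
    n_generalist_otus=30, n_contaminant_otus=10, n_decoy_otus=10, seed=42,
)
table, frame, truth = generate_community(params)
filtered = filter_table(table, frame)          # drops decoys + blank hits
frame_nc = frame.subset(frame.noncontrol_samples())
print(f"{table.shape[0]} OTUs -> {filtered.shape[0]} after filtering")

rel = to_relative(filtered)
dist = bray_curtis(rel)
res = permanova(dist, frame_nc.data.loc[dist.sample_ids, "habitat"],
                n_permutations=999, seed=42)
print(f"PERMANOVA: pseudo-F={res.pseudo_F:.1f}, R2={res.R2:.2f}, p={res.p_value:.3f}")

pres = presence_matrix(filtered, frame_nc, params.strata)
cls = classify_otus(pres, params.strata, occupancy_table=filtered, frame=frame_nc)
print(class_summary(cls, filtered, frame_nc).per_class.round(2))
```

Output:

```
500 OTUs -> 480 after filtering
PERMANOVA: pseudo-F=10.1, R2=0.26, p=0.001
                     n_otus  pct_sequences
specialist              280          22.01
moderate_generalist     168          59.11
generalist               30          18.55
unclassified              2           0.33
```

The 500 simulated OTUs lose the 10 chloroplast/archaeal decoys and the 10
blank-control contaminants in filtering. PERMANOVA rejects homogeneity
across the three habitats at the minimum attainable p (1/1000 with 999
permutations) — the planted habitat preferences separate the communities.
The classification recovers the planted design: 30 specialists in each of
the 10 strata, 30 generalists covering the core stratum set, and the
moderate generalists in between; 2 OTUs fall into the unclassified pattern
(several strata of a single habitat) once sampling noise is layered on the
preferences. Sequence percentages are shares of the filtered table's total
read count.

The same pipeline runs end-to-end from a config file:

```bash
nodulebiome all --config examples/demo.yaml --out runs/demo --seed 11
```

which writes per-stage TSV/JSON artifacts and a `report.json` whose
artifact checksums are bit-identical across reruns with the same seed.

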