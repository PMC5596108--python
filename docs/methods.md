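# Methods

`nodulebiome` re-implements, as a tested library, the community-level
analyses used in 16S amplicon surveys of abyssal polymetallic-nodule fields:
OTU-table preprocessing, alpha and beta diversity with permutation
inference, an occupancy-based habitat-specialization classification,
cross-habitat abundance coupling, and a bacterial–eukaryote co-occurrence
network. Because such surveys' headline numbers depend on the raw reads and
on upstream clustering (OTU tables are pipeline-version-dependent), the
package is validated on synthetic communities with planted ground truth
rather than on any particular deposited dataset. This note documents the
models, the defaults, and the design choices.

## Survey design and stratum scheme

Samples are assigned to one of three habitats — water column, sediment,
nodule — and, within habitat, to an ordered stratum. The default scheme
follows standard oceanographic zonation for the water column (epipelagic
0–200 m, mesopelagic 200–1,000 m, bathypelagic 1,000–3,000 m, abyssopelagic
below 3,000 m) and five sediment layers (0–5, 5–6, 6–8, 8–10, 15–18 cm),
plus the nodule habitat: ten strata in total. Water-zone bounds are
configurable because survey literature also uses a 0–300 m epipelagic
convention; the package defaults to the 0–200 m scheme. One extraction-blank
sample carries habitat `control` so preprocessing can find it by role rather
than by name.

## Preprocessing

* **Decoy-lineage removal.** OTUs whose SILVA-style lineage contains
  `Chloroplast` or `Archaea` (case-insensitive substring on the full
  semicolon lineage) are removed — chloroplast 16S and archaeal amplicons
  are artefacts of bacterial-primer surveys.
* **Blank subtraction.** Any OTU with at least one read in a control sample
  is removed entirely, everywhere. We read "subtracting all hits of OTUs
  found in the blank" as row removal, not per-count subtraction, because the
  unit being subtracted is the OTU, not the read; a per-count mode
  (`subtract_counts=True`) exists for sensitivity analysis. Under row
  removal the order of the two filters is irrelevant; the lineage filter
  runs first and the order is recorded in the run report.
* **Normalisation** divides each sample column by its total
  (relative abundances); **rarefaction** draws a single without-replacement
  subsample (multivariate hypergeometric) per sample at a common depth,
  default 5,000 reads, with a required, logged seed. Samples below the depth
  are dropped and reported, not padded.

## Alpha diversity

Observed richness, Shannon H = −Σ p ln p (natural log by default; the
`base` argument changes it), and Chao-1 in the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)), which stays finite when doubletons are absent
(the classical F1²/2F2 form is available). Metrics are computed on one
rarefied draw per sample, as is conventional for these surveys; an averaging
mode over draws is deliberately out of scope for the default path.
Group summaries report mean and standard error per (habitat, stratum, area),
and groups that lose all samples to rarefaction are reported rather than
silently omitted.

## Beta diversity and inference

* **Bray-Curtis** d(x,y) = 1 − 2 Σ min(xᵢ,yᵢ) / Σ (xᵢ+yᵢ) on relative
  abundances.
* **nMDS** minimises Kruskal stress-1,
  √(Σ(d̂ᵢⱼ − Dᵢⱼ)² / ΣDᵢⱼ²), where D are configuration distances and d̂ are
  disparities from isotonic (pooled-adjacent-violators) regression of D on
  the observed dissimilarity order. Ties are handled by the primary (weak)
  approach: within a tie block, configuration distances order themselves.
  Each restart (default 20) starts from a random Gaussian configuration and
  alternates isotonic regression with a Guttman-transform update; an uphill
  step ends the restart, so accepted stress is monotone, and the best
  restart is returned. Non-convergence is flagged, never raised. Defaults:
  tol 1e-6, max 300 iterations.
* **PERMANOVA** is the one-way pseudo-F on squared dissimilarities:
  SS_total = (1/N)Σ_{i<j} d²ᵢⱼ, SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ,
  F = (SS_between/(a−1))/(SS_within/(N−a)). The p-value permutes group
  labels with the +1 convention in numerator and denominator (so p > 0);
  `exact=True` enumerates every distinct relabeling (small N only) and
  reports the exact tail fraction. Multi-factor designs are analysed one
  factor at a time.
* **Two-way ANOVA + Tukey HSD** on per-sample Shannon values uses Type II
  sums of squares (suited to unbalanced surveys) via statsmodels, with
  Tukey's studentized-range adjustment on the first factor's marginal
  means. This is an ordinary linear-model fit, so it is delegated to
  statsmodels rather than re-derived; a hand-computed balanced-design
  oracle cross-checks it in the test suite.

## Habitat classification

Presence is ≥ `min_count` reads (default 1) in ≥ `min_samples` samples
(default 1) of a stratum; both thresholds are exposed because detection
limits are a known sensitivity of occupancy analyses. Habitat-level
presence is the OR over the habitat's strata; the three-habitat Venn
partition is computed by inclusion–exclusion. Labels:

* **specialist** — detected in exactly one stratum (its habitat and stratum
  are recorded);
* **generalist** — detected in every stratum of a core set spanning all
  three habitats. The default `operative` core set is all water zones,
  the nodules, and the sediment layers above 6 cm: deep sediment layers
  share essentially no OTUs with nodules in surveys of this kind, so the
  strict all-strata rule classifies nothing and is kept only as an option;
* **moderate generalist** — detected in ≥ 2 habitats but not a generalist;
* **unclassified** — multiple strata of a single habitat; this pattern fits
  none of the three rules above and is reported separately rather than
  forced into a class.

Occupancy is the fraction of non-control samples in which an OTU is
detected. Class summaries report OTU counts and percent-of-total-sequence
contributions (these sum to 100% by construction), and the top-N
widest-distribution OTUs per class, ranked by occupancy with ties broken by
total count then OTU id.

## Cross-habitat coupling and the co-occurrence network

Per-stratum mean relative abundance averages over samples (not pooled
counts), matching the per-sample normalisation applied first. Stratum-pair
regressions fit ordinary least squares of log10 mean abundance in stratum B
on stratum A over OTUs detected in both strata — restricting to jointly
detected OTUs avoids pseudocounts; a pseudocount mode exists for users who
want zeros included. Pairs with fewer than 3 shared OTUs are flagged
not-estimable. The flow table lists OTUs above a mean-abundance threshold
(default 1%) in a source stratum together with their abundance and
detection elsewhere.

The 16S–18S network computes Spearman rho for every cross-table OTU pair
over shared samples (≥ 8 required), after excluding OTUs below a prevalence
floor (default 0.2 — double-zero inflation is a known hazard of
compositional data). Significance comes from a permutation null: one
table's sample labels are shuffled, the same permutation applied to all of
its OTUs, so each permuted statistic matrix is one draw from the pairwise
null; p uses the +1 convention, Benjamini–Hochberg q controls the edge set
at `fdr_alpha`, and an optional |rho| floor prunes weak edges. The survey
literature does not specify a network method; Spearman + permutation + BH
is the minimal defensible concretization, and every threshold is surfaced
in the output metadata. Note a resolution constraint: with m tested pairs,
BH at level α can only retain edges whose p can reach ≈ αk/m, so
`n_permutations` must be of order m/α for small edge sets — the recovery
analyses use 19,999 permutations for 10,000 candidate pairs.

## Synthetic communities

The generator emulates post-clustering artefacts of a nodule-field survey —
not reads, chimeras, or clustering. Each OTU draws a log-normal base
abundance (abund_mu 0, abund_sigma 1). Its latent abundance in a sample is
the base times `preference_multiplier` (default 1000) in its preferred
strata and times `off_habitat_epsilon` (default 0.01) elsewhere, times a
per-OTU-per-sample log-normal fluctuation exp(N(0, `sample_sigma`))
(default 0.8). The defaults encode a view of habitat specialization in
which a specialist is ~10⁵-fold enriched in its home stratum relative to
the cross-talk floor, consistent with the near-total absence of specialists
outside their stratum seen in such surveys; `sample_sigma` models
taxon-level abundance fluctuation between replicate samples and is what
makes abundance co-variation (and hence the planted 16S–18S coupling)
observable at all — without it, latents would be constant within a stratum.
Realised counts are one multinomial draw per sample at depth
round(N(`depth_mean`, `depth_sd`)) truncated at 1, defaults 9694.7 ± 892.7
reads, the published scale for this survey type; a Dirichlet-multinomial
option (`overdispersion`) is off by default. Planted classes:

* per-stratum **specialists** (a scalar or per-stratum mapping), epipelagic
  specialists carrying cyanobacterial lineages;
* **moderate generalists** preferring strata from two (70%) or three (30%)
  habitats, never covering the generalist core set;
* **generalists** preferring exactly the operative core set;
* **contaminants** at uniform low level in all samples and alone in the
  blank control;
* **decoys** with chloroplast/archaeal lineages everywhere.

A fraction `export_fraction` (default 0.3) of epipelagic specialists is
additionally seeded into nodule samples — never sediments — at
`export_scale` (default 0.1) times their *water-column* (boosted)
abundance: the exported pool is an attenuated copy of the surface
population delivered by sinking phytodetritus, and attenuating the boosted
abundance (rather than the raw base) keeps exported OTUs at the low but
detectable relative abundances (~10⁻⁴–10⁻³) at which surveys actually
retrieve them. An option seeds near-bottom water as well.

The paired eukaryote table spans the same non-control samples. Each planted
pair's eukaryote OTU shares its partner's per-sample latent variation —
rescaled to the eukaryote's own log-normal base, since a constant log
offset leaves rank coupling intact while keeping 18S abundances at a
realistic scale — times exp(N(0, `pair_noise_sigma`)) noise (default 0.2).
Unpaired eukaryote OTUs fluctuate independently with the same
per-OTU-per-sample log-normal jitter; if they were held constant instead,
the paired OTUs would dominate the eukaryote table's compositional
denominator and induce spurious cross-table correlations. The truth record
carries every OTU's class, preferred strata, export flag, and the planted
pairs, plus (in memory only) the latent matrix the pairing uses.

What the generator does **not** emulate: taxonomic correlation structure
within habitats, distance decay between areas, sequencing-error singletons,
and compositional interactions beyond closure. Passing recovery tests
therefore demonstrates that the analysis chain is correct under its own
assumptions, not that those assumptions exhaust real nodule-field data.

## Numerical and testing choices

Determinism is part of every contract: all stochastic operations take a
seed, and a pipeline rerun from the same config is bit-identical (artifact
checksums are recorded in the run report; wall-time recording is off by
default so the report itself reproduces). Problem sizes in the validation
suite are chosen to make each statistical check sharp at interactive cost:
formula oracles use ≥ 1,000 random small inputs at 1e-9 tolerance;
PERMANOVA exactness uses N = 6 with full relabeling enumeration; type-I
calibration uses 1,000 null simulations of 20 exchangeable samples at 199
permutations (nominal level 10/200 = 0.05 exactly, by the discreteness of
the permutation test); power uses 100 simulations at preference multiplier
5; classification recovery uses a 60-sample, 480-OTU community, noise-free
and at 1% leakage over 10 seeds; network recovery uses 100×100 OTUs over 40
samples with 20 planted pairs over 10 seeds; rarefaction is checked by
chi-square against the exact hypergeometric marginal over 10,000 draws with
sparse tail bins pooled (expected ≥ 5 per bin).

Known limitations: the nMDS optimiser is a local method — restarts mitigate
but do not eliminate local minima; PERMANOVA is one-way only (no
interactions, no PERMDISP companion test, so dispersion and location
effects are confounded as in any pseudo-F test); the network makes no
compositional correction (no SparCC/SPIEC-EASI); and blank subtraction by
row removal is conservative — a genuinely abundant OTU that bleeds into the
blank is lost.
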