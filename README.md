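# radsym

Marker-based microbiome profiling and downstream statistics for insect
symbiont ecology, built around the 2bRAD-M idea: a type IIB restriction
enzyme (BcgI by default) excises uniform-length tags from genomic DNA,
and tags that are unique to a single species act as that species'
markers. Counting sample reads against a species-specific marker
database yields species-level relative abundances even from low-biomass
samples — the setting in which heritable endosymbionts such as
*Wolbachia* and *Cardinium* are studied across host populations.

The package implements the full analysis chain as a library plus a
`radsym` command line:

1. **Marker database** — in-silico digestion of labelled reference
   genomes; a canonical tag becomes a marker for species *i* iff it is
   single-copy in every genome of species *i* where it occurs and
   absent from all other species. `T_i` is the species' marker count.
2. **Profiling** — reads are matched to markers by exact
   strand-canonical identity. Per species, `S_i` (assigned reads) and
   `t_i` (distinct markers seen) give a confidence score
   `G_i = sqrt(S_i * t_i)`; species with `G_i < 5` are discarded as
   false positives. Relative abundance is marker-normalised,
   `RA_i = (S_i/T_i) / Σ_j (S_j/T_j)`, and species with
   `RA < 10⁻⁴` are flagged as below the detection threshold.
3. **Diversity** — Shannon (nats), Gini–Simpson, Chao1 on read counts,
   Bray–Curtis distances, principal-coordinates ordination (PCoA), and
   UPGMA clustering with ultrametric newick output.
4. **Gated group statistics** — per variable, every group is screened
   by a Lilliefors-corrected Kolmogorov–Smirnov normality test and
   Levene's homogeneity test; passing variables get one-way ANOVA with
   Tukey HSD, failing ones Kruskal–Wallis with Dunn's test and
   Bonferroni correction. Pairwise outcomes are summarised as compact
   letter displays. Pearson screens relate symbiont abundances,
   diversity indices and environmental covariates.
5. **Path analysis (SEM)** — recursive observed-variable models
   `Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ` fitted by maximum likelihood, with the
   Satorra–Bentler scaled chi-square `T_SB = T_ML / c` (c from
   empirical fourth-order moments), sandwich standard errors,
   CFI against the independence baseline, `AIC = T_ML + 2q`, backward
   AIC pruning of redundant paths, and standardized coefficients.
   Models are accepted when `p(T_SB) > 0.05` and `CFI > 0.95`.
6. **Synthetic data** — generators for planted-site genomes (with a
   ground-truth tag registry), mock-community reads with per-base
   errors, and population tables whose environmental covariates drive
   symbiont abundance through known linear paths. These make every
   stage testable without external downloads.

## Worked example

```python
from radsym import (BCGI, CommunitySpec, build_marker_db,
                    generate_genomes, profile_sample, shannon,
                    simulate_reads)

genomes, registry = generate_genomes(n_species=3, genome_len=3000,
                                     sites_per_genome=8, seed=11)
db = build_marker_db(genomes, BCGI)
print("T_i:", db.theoretical_count)

community = CommunitySpec(species=tuple(sorted(registry)),
                          proportions=(0.6, 0.3, 0.1),
                          depth=50_000, seed=7)
profile = profile_sample(simulate_reads(registry, community), db)
for sp, ra in sorted(profile.abundances().items()):
    print(f"{sp}: RA = {ra:.4f}")
print(f"Shannon = {shannon(list(profile.abundances().values())):.4f}")
```

prints

```
T_i: {'sp000': 8, 'sp001': 8, 'sp002': 8}
sp000: RA = 0.5970
sp001: RA = 0.3013
sp002: RA = 0.1017
Shannon = 0.9018
```

i.e. each species' planted marker count is recovered exactly, the
profiled abundances sit within half a percent of the true (0.6, 0.3,
0.1) composition at 50,000 reads, and the community's Shannon entropy
is 0.90 nats.

Path models are specified as plain-text edge lists and fitted in the
statsmodels style — a model object whose `fit()` returns a results
object with `summary()`:

```python
model = PathModel.from_spec("""
temperature -> Wolbachia
precipitation_log -> Wolbachia
latitude -> Wolbachia
""")
fit = model.fit(table)        # table: one row per population
print(fit.summary())          # estimates, robust SEs, T_SB, CFI, AIC
```

On data simulated with slopes (0.3, 0.4, −0.2) and n = 500 this prints
estimates (0.326, 0.358, −0.227) with robust z-statistics near ±10 and
a saturated-model fit (`T_ML = 0`, `CFI = 1`).

The same stages are available from the shell:

```sh
radsym simulate genomes --n-species 3 --sites 8 --out sim/
radsym build-db --genomes sim/genomes.fasta --labels sim/labels.tsv --out db/
radsym profile --db db/ --reads sample1.fastq --gscore 5 --min-ra 1e-4 --out profiles/
radsym diversity --abundance profiles/abundance.tsv --out div/
radsym sem --model model.txt --data merged.tsv --out sem/
```

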