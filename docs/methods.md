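# Methods

## Marker model

A type IIB enzyme is described by its IUPAC recognition pattern and the
number of nucleotides excised on each side (`EnzymeSpec`). The shipped
default is BcgI: recognition `CGANNNNNNTGC`, 12-nt flanks, 36-nt tags.
Other enzymes are plain records the user can construct; no catalogue is
hard-coded. Digestion reports every recognition-site occurrence on
either strand whose flanks fit inside the sequence, in forward
coordinates (0-based internally, 1-based only in human-readable
reports); windows containing N are dropped, and overlapping sites each
yield their own tag. Tag identity is strand-canonical: the
lexicographically smaller of tag and reverse complement.

"Species-specific" is interpreted as the conjunction of two conditions:
single-copy within every genome of the species in which the tag occurs,
and absence from every genome of every other species. A marker need not
occur in *all* genomes of its species (any-genome semantics): requiring
core presence would silently shrink `T_i` for species represented by
several divergent assemblies, and the profiler's normalisation only
needs `T_i` to count tags the species *can* produce. Species whose
marker set is empty are excluded from the database and listed in a
diagnostics field.

## Profiling model

Reads are matched to markers by exact canonical-form equality — no
mismatch tolerance, because markers are short (36 nt) and the
database's contract is uniqueness; a single mismatch tolerance would
reintroduce cross-species ambiguity. The per-species confidence score
is the geometric mean `G = sqrt(S · t)` of assigned reads and distinct
markers observed, with the exponent exposed as a parameter. The default
threshold `G ≥ 5` (so 5 reads over 5 distinct markers is the smallest
passing evidence) controls false positives from sporadic matches.
Relative abundance normalises read counts by marker counts,
`RA_i = (S_i/T_i) / Σ_j (S_j/T_j)`, over the species passing the G
filter; the detection threshold (default 10⁻⁴) only flags species as
below-detection — it does not remove them or trigger renormalisation,
so abundances always sum to 1 over G-passing species. Reads whose
length differs from the tag length are skipped with a warning; if more
than half of a sample mismatches, the run aborts on the suspicion that
the wrong enzyme was configured.

## Diversity

Shannon entropy uses natural logarithms; Simpson is reported as
Gini–Simpson `1 − Σp²` (an `inverse` variant is available). Chao1
requires integer counts; in pipeline use the per-species read count
`S_i` serves as the count proxy, it being the only integer per-species
signal the profile carries. Bray–Curtis is computed on the full
species-level profile. PCoA is classical scaling of `−½ J D² J`; axes
with negative eigenvalues (Bray–Curtis is non-Euclidean, so they occur)
are reported but dropped from the coordinates, and the triangle
inequality is deliberately not asserted anywhere. UPGMA uses
size-weighted average linkage with ties broken by the lexicographically
smallest pair of cluster representatives, making output deterministic;
node height is half the merge distance, so the tree is exactly
ultrametric.

## Gated univariate statistics

The gate runs a Lilliefors-corrected Kolmogorov–Smirnov test per group
(parameters estimated from the data; a naive KS variant is switchable)
and Levene's test with mean centring (median centring gives
Brown–Forsythe). Only if every group passes normality and the variances
are homogeneous at α does the variable take the parametric branch
(one-way ANOVA + Tukey HSD); otherwise Kruskal–Wallis with tie
correction and Dunn's pairwise z-tests under Bonferroni
(`m = k(k−1)/2`). Groups with fewer than 4 observations cannot be
normality-tested and are routed to the nonparametric branch. Note that
the gate compounds four α-level tests, so even exactly Gaussian data
take the parametric branch only ~76–81% of the time — an inherent
property of gated testing, not a defect. Compact letter displays are
built by insert-and-absorb on the significant-pair list, guaranteeing
that two groups share a letter iff their adjusted p ≥ α. Correlation
screens are plain Pearson tests with 0.05/0.01/0.001 stars and no
multiplicity adjustment; the intended unit of observation is the
population (one row per population, e.g. n = 18), though the functions
are agnostic.

## Path analysis

Models are recursive (acyclic) systems over observed variables only.
Free parameters are the edge coefficients, the full covariance matrix
of the exogenous block (optionally variances only, which makes the
empty model the independence baseline), residual variances of
endogenous variables, and named residual covariances — the latter is
how an undirected symbiont–symbiont association is expressed.
`F_ML = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p` is minimised by BFGS from a
least-squares start (per-equation OLS plus sample moments), which for
recursive models starts essentially at the optimum; up to 5 jittered
restarts guard against stalls, and convergence is accepted at gradient
norms attainable by finite-difference gradients (~1e-5 relative).
`S` uses the n−1 divisor and `T_ML = (n−1)·F_ML`.

Normal-theory standard errors come from `(ΔᵀWΔ)⁻¹/(n−1)` with
`W = ½Dᵀ(Σ̂⁻¹⊗Σ̂⁻¹)D` (D the duplication matrix) and Δ the numerical
Jacobian of vech Σ. The Satorra–Bentler scaling factor is
`c = tr(UΓ)/df` with `U = W − WΔ(ΔᵀWΔ)⁻¹ΔᵀW` and Γ the empirical
covariance of `vech(z zᵀ)`; `T_SB = T_ML/c`, with robust (sandwich)
standard errors from the same ingredients. With df = 0 the scaling is
undefined and `T_SB` is reported as 0 with a note. CFI is computed on
the scaled statistics against an independence baseline fitted in closed
form; `AIC = T_ML + 2q` is used purely ordinally, so the constant data
likelihood term is omitted. Backward pruning deletes the single edge
whose removal most lowers AIC (never orphaning an endogenous variable),
stops at the AIC minimum, and the result carries the acceptance flag
`p(T_SB) > 0.05 ∧ CFI > 0.95`. Standardized coefficients are
`b·sd(cause)/sd(effect)` with model-implied standard deviations; both
unstandardized and standardized values are always reported. A warning
is emitted when `n < 5q`, where population-level fits are fragile.

## Synthetic data

The genome generator plants a requested number of concrete recognition
sites with random flanks in site-free random background (uniform base
composition), rejection-sampling flanking tags until every planted
canonical tag is unique across all species, and rebuilding any genome
in which chunk junctions create accidental sites. The returned registry
is therefore the exact ground truth for the marker database. The read
generator samples species with probability ∝ `a_i·T_i` and markers
uniformly within species, so `E[S_i/T_i] ∝ a_i` and the profiler's
abundance estimator is unbiased for the community proportions; per-base
substitution errors at a configurable rate and random strand flips
emulate sequencing noise — there is no quality-score model and no PCR
duplication. The environment generator draws covariates from an
equicorrelated multivariate normal (means and sds set to plausible
South/Southeast-Asian ranges: temperature 22 ± 4 °C, log-precipitation
7 ± 0.4, latitude 20 ± 6°, longitude 105 ± 8°, altitude 400 ± 300 m)
and evaluates declared linear paths with Gaussian noise in topological
order. Abundance-type endogenous variables are squashed to (0, 1) by a
logistic link; the table carries both the link-scale and squashed
columns, and recovery tests operate on the link scale, where the linear
model is exact. Defaults describe 18 populations, matching the kind of
field design the pipeline targets.

What the generators do not emulate: real marker-count heterogeneity
across species (thousands of markers per bacterial genome rather than
~10), read-depth variation across samples, compositional coupling
between symbiont load and the rest of the community, and spatial
autocorrelation among populations. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not
robustness to those real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so the whole
chain exercises comfortably on one CPU: 3–10 species, ~10 planted sites
per genome, read depths of 10⁴–5·10⁴, 2,000-replicate null
calibrations, and 50–100-replicate SEM recovery/pruning studies at
n = 500 (n = 2,000 where asymptotic behaviour of the scaling factor is
the point). Floating-point tolerances follow the quantity: exact
closed forms at 1e-12, linear-algebra identities at 1e-8, optimizer
results at 1e-5–1e-6. All generators and studies are pure functions of
their seed.

## Known limitations

- Exact matching means sequencing errors only lose reads (no
  misassignment); error-tolerant matching is out of scope.
- Chao1 on `S_i` counts estimates richness of *marker-detected*
  species, which underestimates true richness at low depth.
- The SEM module handles complete cases only, no latent variables and
  no multi-group fits; with n as small as 18 populations, fits are
  reported but flagged as fragile.
- PCoA "classification probability" ellipses and rarefaction are not
  implemented; plotting is left to the user's tooling.
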