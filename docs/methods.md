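# Methods

## Scope and model

`cryoassembly` implements the null-model framework for partitioning microbial
community assembly into five ecological processes, the Mantel-correlogram
test of its phylogenetic-signal precondition, and the incubation CO₂ flux
arithmetic used alongside such analyses. The inference operates on a rooted
phylogeny with branch lengths, a rarefied sample × taxon count table whose
taxa are tree tips, and per-sample group labels and abiotic variables.

### βMNTD, tip-shuffle null, βNTI

For a sample pair, βMNTD is the mean patristic distance from each taxon in
one sample to its nearest relative in the other, weighted by relative
abundance (an unweighted 1/richness variant is available) and symmetrized.
Taxa present in both samples contribute zero, so βMNTD responds only to the
mismatched part of the two communities. The null model shuffles, once per
iteration (default 999), the assignment between the table's taxa and their
tip positions; the same permutation is shared across all pairs in that
iteration, matching within-run exchangeability and keeping 999 iterations
affordable. βNTI is the observed deviation in null standard deviations.
Patristic distances are computed once as a tip × tip matrix and permuted by
index; equality with direct traversal is covered by a test.

Degenerate nulls: when two samples have identical taxon support, βMNTD is
zero under every permutation. The `bnti` function raises an explicit
`DegenerateNullError` rather than returning ±∞; the pipeline-level
`assembly_analysis` treats the specific case obs = null exactly (identical
supports) as βNTI = 0 — the pair carries no phylogenetic information — and
lets the Raup–Crick test decide. This matters for homogenizing-dispersal
regimes, whose samples are near-copies.

### RC_bray

Each iteration reassembles both samples from the metacommunity (all samples
in the analyzed table): taxon identities are drawn without replacement with
probability proportional to occupancy, each drawn taxon receives one
individual, and the remaining individuals are allocated multinomially by
metacommunity relative abundance. Richness and total count of each sample are
preserved. Ties against the observed Bray–Curtis are counted half, with an
absolute tolerance of 1e−12. Per-pair RNG streams are derived from the sorted
sample names, so results are independent of pair iteration order and
RC(a, b) = RC(b, a) exactly.

A structural property worth knowing: RC_bray cannot exceed
1 − P(two null assemblies share no taxa). With few taxa or very low sample
richness this ceiling sits below +0.95, which makes dispersal limitation
undetectable regardless of how divergent the observed pair is. Sample
richness above roughly √(3 · n_taxa) keeps the ceiling out of the way.

### Classification and profiles

βNTI < −2 → homogeneous selection; βNTI > 2 → heterogeneous selection;
otherwise RC_bray < −0.95 → homogenizing dispersal, RC_bray > 0.95 →
dispersal limitation + drift, else drift alone. Values exactly at a threshold
fall to the stochastic/interior side (|βNTI| = 2 proceeds to the RC test;
|RC| = 0.95 is drift alone): a conservative-toward-stochasticity convention,
covered by tests. Process profiles are fractions of pairwise comparisons per
process, over all pairs or within-group subsets; empty subsets raise (a
group reduced to one sample cannot be compared).

### Phylogenetic signal

Niche optima are abundance-weighted means of each abiotic variable over the
samples where a taxon occurs — convex combinations, hence bounded by the
variable's observed range. Between-taxon optima distances are Manhattan
(absolute difference) per variable; the combined test takes the Euclidean
distance over log₁₀-transformed optima, shifting any variable with
nonpositive values to minimum + 1 unit first (the shift is recorded in the
run manifest). The Mantel correlogram bins patristic distances into fifty
equal-width classes over [0, max]; per class, the statistic is the Pearson
correlation between the ecological distances and the within-class indicator
over all off-diagonal pairs, negated so that positive r means "more similar
than expected". p-values come from 999 simultaneous row+column permutations
of the ecological matrix (two-sided, (1 + #{|r*| ≥ |r|})/(n+1)); class k is
Holm-corrected over classes 1..k (progressive), so p_corrected ≥ p_raw.
Classes with fewer than two pairs (or no indicator variance) are untestable
and excluded from the correction count. `short_distance_signal` summarizes a
correlogram as "signal present" if any testable class in the shortest quarter
of the distance range is significantly positive.

### Flux

rate [µg C-CO₂ g⁻¹ h⁻¹] = CO₂ppm · P·V/(R·T) · 12 / (g dry soil · t), with
R = 0.0821 L·atm·K⁻¹·mol⁻¹ (configurable). Rates below detection are flagged,
never imputed. Stabilized means average days 20–193 by default. Q₁₀ =
(k_high/k_low)^(10/(T_high−T_low)), exponent 10/11 for the 15 °C/4 °C pair.

### Rarefaction and pipeline

Rarefaction subsamples without replacement (multivariate hypergeometric) to a
fixed depth; samples below depth are dropped and listed in the manifest,
all-zero taxon columns are removed; with-replacement resampling is available
behind a flag. A single draw is used by default (multi-draw averaging was
considered and left out as an option for downstream variance analysis).
`run_pipeline` is deterministic given (inputs, config, seed) and writes a
machine-readable manifest recording seeds, dropped samples and conventions.
Count tables are plain TSV (samples as rows); trees are newick.

## The synthetic experiment

The generators realize the five verbal process definitions one-to-one, so
classifier recovery is interpretable. Defaults are the study conditions used
in validation; they were designed once, on the reasoning below, and the test
suite asserts recovery under them.

**Tree geometry.** Microbial 16S trees are strongly hierarchical: within-genus
distances are a few percent of between-phylum distances. `simulate_tree` is a
plain birth–death simulator (ultrametric; terminal edges extended by one
exponential waiting time so all branch lengths are positive; optional
lognormal jitter breaks ultrametricity for robustness checks).
`simulate_structured_tree` composes it into the two-level geometry: a
backbone whose splits are pushed toward the root (depth remap d → h·(d/h)^5)
carrying shallow radiations (height 2% of total, ~3 tips each). On a single
birth–death tree at 50 tips, nearest-neighbour distances are ~10% of typical
distances and trait windows select phylogenetically scattered taxa; the
two-level geometry restores the short-distance niche conservatism that the
βMNTD framework presupposes.

**Selection with lottery drift.** `assemble_selection` follows the classic
Gaussian-filter form (taxon weight ∝ exp(−(trait−env)²/2w²)) with an optional
Dirichlet perturbation. Pure multinomial sampling from shared weights makes
every sample hold the same dominant taxa; since shared taxa contribute
nothing to βMNTD, such communities are invisible to the inference — a
genuine property of the metric, not an implementation artifact. The
experiment therefore uses `assemble_guild_selection`: the environment offers
a fixed number of niches (default 6), filled by the guilds (patristic
clusters of close relatives) whose mean trait is closest; guild-level
abundances are set by the filter, while member identity within each guild is
a lottery (each member retained with probability 0.45, at least one
survives, the guild share split evenly). Selection between guilds, neutral
lottery within — repeated samples are phylogenetically clustered yet
compositionally distinct, which is exactly the homogeneous-selection
signature (βNTI ≪ −2). The two environments of the heterogeneous condition
are anchored in the two most guild-balanced deep halves of the tree: each
favours its half's most extreme-trait guilds. This encodes a real limitation
of the method — divergent selection is detectable by phylogenetic turnover
only when environmental divergence aligns with deep lineages.

**Stochastic regimes.** Drift alone draws Dirichlet-multinomial samples
(concentration 50) from a lognormal (σ = 1.5) metacommunity; a near-uniform
metacommunity would put every taxon in every sample and degenerate the null.
Homogenizing dispersal copies a single template (one multinomial draw from
the metacommunity) and resamples 2% of individuals per sample. Dispersal
limitation gives each sample its own random pool of 60% of the taxa with
strong local drift inside the pool (Dirichlet concentration 15; at
pool_fraction = 1 the generator reduces exactly to neutral drift from a
uniform metacommunity with the same concentration). The pool and drift
settings keep realized richness above the RC ceiling discussed above while
independent local dominance keeps observed dissimilarities in the null's
upper tail.

**Scale.** 50 taxa, 8 samples per regime, 200 individuals per sample. Two
hundred individuals over 50 taxa reproduces, in miniature, the
presence–absence sparsity of a rarefied amplicon table (most taxa absent
from most samples), which both βMNTD and RC need to be informative. All five
regimes are analyzed together as one combined table — the design of a real
survey, where a single rarefied table spanning the whole tree is analyzed at
once — so the tip-shuffle pool covers the full phylogeny.

**Respiration.** Paired 4 °C/15 °C series with the 15 °C rate equal to
base · Q₁₀^1.1 times mean-one lognormal noise of a given CV.

**What passing recovery does and does not show.** Recovery demonstrates that
the inference chain — rarefied counts → βMNTD → tip-shuffle null → βNTI →
RC_bray → classification — identifies each generating process under
conditions where the process leaves a detectable signature at desk scale. It
does not show that real communities at thousands of taxa behave like the
50-taxon miniature (real data have far larger effective mismatch counts, so
βNTI is better resolved there), nor does it validate the framework's
ecological assumptions (niche conservatism, meaningful metacommunity
delineation) on field data.

## Numerical choices

* Null iterations default to 999 for both βMNTD and RC_bray.
* RC tie tolerance 1e−12 (absolute, on Bray–Curtis values in [0, 1]).
* βNTI is exactly invariant under uniform branch-length rescaling when the
  same seed is used (permutations are identical; values scale linearly).
* Abundance weighting of βMNTD defaults to on, consistent with rarefied
  counts; the unweighted variant is one flag away.
* Equal-width distance classes for the correlogram (quantile binning was
  considered; equal-width is the common correlogram default and keeps class
  midpoints interpretable); far classes are not truncated by default.
* The Mantel permutation test adds one to numerator and denominator, so
  p ∈ (0, 1] and is never zero.
* Rarefaction, tree simulation, trait evolution and all generators take
  explicit seeds; per-pair RC streams are sub-seeded from sorted sample
  names.

## Known limitations

* βNTI at a few dozen taxa has a hard resolution limit: the null z-score of
  a pair is bounded by roughly √k·√((1−q)/q), where k is the number of
  effectively mismatched taxa and q the probability that a shuffled taxon
  lands near the other sample. Sparse pairs (k ≤ 2) cannot cross the −2
  threshold even when the observed βMNTD is below the null's first
  percentile.
* RC_bray's +1 side is capped by null-disjointness (see above); at small
  richness the dispersal-limitation class is systematically under-called.
* Heterogeneous selection is invisible when divergent environments select
  within the same deep lineages.
* The correlogram tests association, not a causal trait model; significant
  short-distance classes are consistent with, not proof of, niche
  conservatism.
* Flux math assumes complete headspace flushing between intervals
  (flush-to-flush accumulation) and a known headspace volume per jar.
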