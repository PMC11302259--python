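# Methods

This note records the models implemented by `ecoassembly`, the conventions
and defaults chosen where the literature leaves room, and what the synthetic
validation does and does not establish.

## Community data model

The unit of analysis is a taxa × samples table of nonnegative integer read
counts (OTUs or ASVs as rows — the common amplicon orientation; orientation
is a contract, never guessed), a rooted phylogeny with branch lengths whose
tips cover the table's taxa, and per-sample metadata (group label, latitude/
longitude in decimal degrees, numeric environmental covariates). Tree tips
absent from the table are pruned silently; table taxa absent from the tree
are a hard error — failing loud is preferred to silently dropping data.
Label matching is exact and case-sensitive. Samples with zero total reads
are rejected at construction.

## Rarefaction and diversity

Rarefaction draws each sample down to a common depth **without replacement**
(multivariate hypergeometric), one draw per sample at a logged seed; by
default the depth is the minimum sample total. A single draw (not an average
over draws) is the default because that is how surveys of this kind are
usually processed; averaging can be layered on top by the caller.

Alpha indices: Shannon entropy in nats; Gini–Simpson 1 − Σp²; Pielou
evenness H/ln S (undefined, reported NaN, for S = 1); **classic Chao1**
S + F₁²/(2F₂) with the F₂ = 0 fallback S + F₁(F₁−1)/2 (the bias-corrected
variant gives different values — e.g. 4.5 instead of 6 for counts 5,1,1,2 —
and is deliberately not the default); ACE with the standard rare/abundant
cutoff of 10; Faith PD as the total branch length of the subtree spanning
the observed taxa **including the path to the root** (the picante `pd`
convention; `include_root=False` restricts to branches below the MRCA).

Beta diversity is Bray–Curtis on counts. It is scale-invariant across
samples only at equal depth, so the intended input is the rarefied table.

Geographic distance is great-circle (haversine) on a 6371-km sphere — the
distance model is a package convention since field studies rarely state one.
Distance–decay correlates similarity (1 − Bray–Curtis) with distance by
Spearman rank over sample pairs, with a Mantel-style permutation p
(rows/columns permuted jointly; two-sided, since the sign is the question),
and reports the OLS slope of similarity on distance as the spatial turnover
rate.

## Assembly null models

**βMNTD.** For communities j, k with within-sample relative abundances f:

βMNTD(j,k) = ½ [ Σ_{i∈j} f_ij · min_{i′∈k} d(i,i′) + Σ_{i∈k} f_ik · min_{i′∈j} d(i,i′) ]

with d the patristic distance. Taxa shared by both samples contribute a
nearest-taxon distance of 0 (conspecifics included). The unweighted variant
replaces f by 1/S per community and averages the two community means
half-and-half; note picante's unweighted `comdistnt` instead pools all
S_j + S_k nearest-taxon distances, which differs when richness differs.
The abundance-weighted form (the default, and the one used for βNTI) is
identical to picante's.

**βNTI.** The null shuffles taxon labels across *all* tips of the pruned
phylogeny (the "taxa.labels" randomization of the framework this package
implements), equivalently a joint random permutation of the rows and columns
of the patristic matrix, recomputing βMNTD each iteration. One shuffle per
iteration is shared by all sample pairs — the standard scheme, and ~n_pairs
times cheaper than per-pair shuffle streams for no inferential gain. The
z-score uses the sample (ddof = 1) standard deviation of the null. Pairs
with zero null spread (identical samples; star phylogenies; two communities
that jointly span taxa symmetric under shuffling) are **undefined**: reported
as NaN, never ±∞ or 0, and excluded from process fractions with a separate
count. n_null defaults to 999, the field standard. βNTI is computed on the
rarefied table by default (switchable), matching the usual practice of
rarefying before diversity analysis.

**RC_bray.** For each sample pair and each of n_null iterations, both
communities are reassembled independently from the metacommunity (all
samples in the analysis — not per-group): the observed richness S is drawn
without replacement with probability proportional to occurrence frequency,
then the observed read total N is allocated by giving each drawn taxon one
read and distributing the remaining N − S reads multinomially in proportion
to metacommunity relative abundance. The index is
RC = 2·([#(null < obs) + ½·#(null = obs)]/n_null − ½) ∈ [−1, 1]
(ties get half weight; the [−1, 1] rescaling is on by default). Weighted
sampling without replacement uses Gumbel-top-k keys, which realizes exactly
the successive-sampling distribution. Each pair consumes an RNG stream
derived from (seed, pair index), so results are independent of iteration
order and would be unchanged under parallelization.

**Classification.** βNTI > 2 → heterogeneous selection; βNTI < −2 →
homogeneous selection; otherwise RC_bray > 0.95 → dispersal limitation;
RC_bray < −0.95 → homogenizing dispersal; otherwise undominated. All
comparisons are **strict**: a value exactly at a threshold falls to the less
extreme category (the two defining inequalities |βNTI| > 2 and
−2 < βNTI < 2 leave ±2 itself unassigned; this package assigns it to the
stochastic branch and documents that choice). Per-group process fractions
are computed over all within-group pairs, counting only classified pairs in
the denominator and reporting undefined pairs separately.

## Distance-matrix statistics

All permutation tests permute **whole samples** — a joint permutation of
rows and columns — never individual triangle elements, which would break
exchangeability and inflate type-I error. p-values use the add-one rule,
so p ≥ 1/(n_perm + 1), and fixed seeds make them bit-reproducible.

- **PERMANOVA** (one-way): SS_total = Σ_{i<j} d²_ij / N, SS_within sums each
  group's squared within-group distances over its size; pseudo-F compares
  between/within mean squares; R² = SS_between/SS_total. Zero within-group SS
  yields an infinite F with the p-value still from permutations.
- **SIMPER**: per between-group pair, taxon i contributes
  |x_ij − x_ik| / Σ_i(x_ij + x_ik); averaged over all between-group pairs the
  contributions sum exactly to the mean between-group Bray–Curtis. Output is
  sorted descending with cumulative percentages and group mean relative
  abundances in percent.
- **Mantel**: Spearman (default) correlation of the condensed vectors;
  one-sided "greater" by default (the ecological convention); the community
  response is taken as *dissimilarity*, so a positive Mantel r means
  environmentally distant pairs are compositionally distant.
- **Partial Mantel**: rank-transform all vectors, residualize response and
  focal predictor on the controls by least squares, correlate residuals;
  permutations re-residualize the permuted focal matrix. When the controls
  explain the response completely the statistic is defined as 0. Collinear
  controls are an error naming the offenders.
- **MRM**: OLS of the response triangle vector on explanatory triangle
  vectors plus intercept; R² p-value one-sided, per-coefficient p two-sided
  on the permutation distribution of each coefficient under response
  permutation. Stepwise reduction removes one variable per iteration (the
  largest p above alpha, ties broken by input order) and logs the removal
  order; an empty final model is allowed and flagged.
- Environmental "distances" are Euclidean on z-scored (ddof = 1) covariates,
  a convention this package fixes since field studies rarely state theirs.

## Synthetic data generator

The generator emulates a multi-island survey along a river: ~20–26 samples
in one or two regional groups, hundreds of taxa, per-sample read depth
16,817 (a typical rarefaction depth for such surveys), sites along a
~1,000–1,400 km transect emitted as lat/lon.

Components and defaults, chosen once as field-plausible and then left alone:

- **Phylogeny**: Yule pure-birth tree conditioned on n taxa (birth rate 1.0,
  time units arbitrary), ultrametric by construction. A pure-birth tree is
  sufficient to carry phylogenetic signal; birth–death realism adds nothing
  the analyses consume.
- **Niche optima**: Brownian motion along branches from a root value of 0
  with rate σ²_BM = 1 per unit branch length — close relatives get similar
  optima, the conservatism assumption that makes βNTI informative.
- **Metacommunity SAD**: lognormal(0, 1) relative abundances, the standard
  species-abundance choice.
- **Regimes** (per-site expected abundances, then one multinomial read draw
  per site):
  - *selection*: metacommunity × Gaussian niche kernel
    exp(−(E_s − μ_i)²/2σ²) with niche breadth σ = 0.5 against site
    environments spanning [−3, 3] in the steep-gradient preset — breadth is
    the knob that moves datasets from deterministic to stochastic signatures;
  - *dispersal_limited*: a neutral lottery with immigration weight
    metacommunity × exp(−|x_s − h_i|/λ), each taxon's home h_i uniform on
    the transect, λ = 60 km (about one inter-site spacing);
  - *mass_effects*: the same lottery with λ large (near-complete mixing);
  - *drift*: i.i.d. multinomial draws from the metacommunity.
- **Presets**: `mr_like` (selection, steep gradient) and `lr_like`
  (dispersal-limited, shallow gradient) reproduce the qualitative contrast
  of an upstream region dominated by heterogeneous selection versus a
  downstream region dominated by dispersal limitation;
  `riverine_island_dataset` combines both on one shared phylogeny and
  metacommunity (13 + 13 sites).

Everything is reproducible bit-for-bit from (scenario, seed); regime truth
and per-taxon optima are written to a sidecar JSON that the analysis modules
never read.

**What the generator does not emulate**: sequencing error and chimeras,
compositional artefacts of PCR, taxon-specific read-length/copy-number
biases, temporal dynamics, speciation during assembly, and spatially
autocorrelated environmental noise. Passing the recovery tests therefore
shows the estimators respond correctly to planted assembly signals of
realistic size and sparsity — not that any particular field dataset is free
of the confounders above.

## Problem sizes and numerical choices

The validation suite runs the full-scale recovery analysis on 20-sample,
300-taxon datasets with 999 null iterations (the package's standard
operating point); oracle-equivalence checks use hundreds of small random
instances (≤ 8 taxa, ≤ 6 samples) compared to brute-force reimplementations
at 1e-10; permutation-test calibration uses 1,000 structureless replicates
at 999 permutations. Ties in the RC null are detected at 1e-12 absolute;
null standard deviations below 1e-12 are treated as zero (undefined βNTI).
Degenerate inputs fail loud: empty samples, constant matrices in Mantel,
rank-deficient MRM designs, co-located samples in distance–decay.

## Known limitations

- βNTI is undefined (not ±∞) wherever the tip-shuffle null has zero spread;
  datasets in which every taxon occurs in every sample (deep sequencing of
  small, well-mixed taxon pools) classify almost entirely as undefined.
- The unweighted βMNTD convention differs from picante's (see above).
- The RC_bray metacommunity is the analyzed table itself; with few samples
  the occurrence-frequency weights are coarse.
- One-way PERMANOVA only; no strata/nested designs.
- The phylogeny is taken as given. How to build one from marker genes is out
  of scope, and βNTI inherits whatever error the tree carries.
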