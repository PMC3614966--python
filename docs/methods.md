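# Methods

This note documents the models and procedures implemented in thaumflow,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## Primer evaluation

A degenerate primer is an IUPAC string in 5′→3′ primer orientation. The
match rule at one position is the **subset rule**: template character *t*
matches primer character *p* iff expand(*t*) ⊆ expand(*p*). The
conservative direction matters for ambiguous template bases: an ambiguous
base only counts as covered if *every* base it could be is inside the
primer's degeneracy set. (How the original survey treated degenerate
template bases is not documented anywhere we know of; the subset rule is
this package's choice and is applied uniformly.)

`align_primer` is an exhaustive ungapped scan: forward primers along the
plus strand as given, reverse primers as their reverse complement along
the plus strand. The offset with the fewest mismatches wins; ties go to
the smallest plus-strand offset (determinism for golden tests). The
returned pattern is always in primer coordinates — token 1 is the primer
5′ end, and for reverse primers mismatch tokens are the complements of
the plus-strand bases, i.e. the template base as the primer "sees" it.
There is no indel model: published mismatch tables are positionally
aligned without gaps, and primer-template bulges are outside scope.

Pattern strings use the survey-table dialect: space-separated tokens,
`=` for match, the template base otherwise, and the literal text
`No mismatch` for a perfect site. `reconstruct_site` inverts a pattern
into a concrete binding site, emitting the alphabetically first base of
the primer's degeneracy set at match positions — any compatible base
would reproduce the mismatch count; a fixed rule makes fixtures
byte-stable. Reconstruction refuses tokens that the primer would in fact
tolerate (they would not be mismatches).

Group summaries report n, mean, sample SD (n−1 denominator, 0 for n=1 by
convention), SE = SD/√n and the fraction of perfect sequences. The
dispersion quoted alongside published per-clade means is the SE: the
printed shallow-cluster values (1 ± 0.45 over counts 0,0,3,1,1,1 and
1.5 ± 0.34 over 1,1,1,3,1,2) are reproduced exactly by SD/√6 and not by
the SD (1.10, 0.84). Both SD and SE are reported. Mismatches in the last
three primer positions (3′-terminal, most damaging to extension) are
flagged in reports but carry no extra weight in the count.

The **reference mismatch panel** encodes 23 published full- or nearly
full-length thaumarchaeal *accA* reference sequences (Sargasso Sea and
HOT/ALOHA metagenome contigs, Gulf of Maine scaffolds, cultured
*Nitrosopumilus*/*Nitrosoarchaeum*/*Nitrososphaera* strains and
*Cenarchaeum symbiosum*) with their printed mismatch patterns against
Cren529F/Cren981R, spanning five groups: shallow cluster (6), deep
cluster (4), Group 1.1a-associated (11), *Cenarchaeum* (1) and Group
1.1b (1). Binding sites are reconstructed from the patterns and embedded
between homopolymer spacers chosen to be maximally incompatible with the
primer; at load time every row is re-scanned and must reproduce its
printed count (46/46), so the panel is internally consistent by
construction.

## OTU clustering

Furthest-neighbor (complete-linkage) clustering merges clusters while
the smallest complete-linkage distance is ≤ the cutoff; consequently
every intra-OTU pairwise distance is ≤ the cutoff, which the tests
assert as a certificate on every output. The agglomeration is delegated
to scipy's complete-linkage implementation with a flat cut at the
cutoff; output is deterministic for fixed input, and for matrices with
distinct dissimilarities it coincides with the naive greedy
agglomeration oracle used in the tests. OTU labels are the
alphabetically first member id — stable and human-readable. Distances
are taken as given (PHYLIP square/lower-triangle or column format); a
p-distance helper for equal-length aligned sequences is provided for
synthetic work, but alignment and distance estimation from raw reads are
out of scope.

## Diversity

Per library: n, observed richness S_obs, Good's coverage C = 1 − F₁/n
(reported as a percentage with one decimal), Shannon H′ in natural log
(base selectable), and Chao1 in the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)). The bias-corrected variant is the default
because it is defined when F₂ = 0; the classic F₁²/(2F₂) form is
available by flag for comparison with software that uses it. Empty
libraries are skipped with a warning rather than raising — a report row
of undefined indices helps no one.

## Community comparison

Bray-Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on raw counts (undefined and rejected
for two empty samples). The abundance-based Sørensen similarity is
L_abd = 2UV/(U+V), where U is the proportion of sample-x individuals in
shared OTUs and V symmetrically; the corrected estimator (default) adds
the Chao unseen-shared term ((m−1)/m)·(f₊₁/(2f₊₂))·Σ_{shared, yᵢ=1} xᵢ/n
(and symmetrically), clamping U and V at 1. When f₊₂ = 0 the denominator
uses 2·max(f₊₂, 1), the EstimateS/vegan convention. The raw variant is
selectable; the correction only adds non-negative mass, so corrected ≥
raw before clamping. The ≥ 0.5 "substantial overlap" vocabulary is a
report annotation, never a filter.

Weighted UniFrac accumulates Σᵢ bᵢ|Aᵢ/A_T − Bᵢ/B_T| over all branches
(root length None contributes 0); the normalized variant divides by the
abundance-weighted tree depth Σᵢ bᵢ(Aᵢ/A_T + Bᵢ/B_T), bounding the
result in [0, 1]. Normalized is the default (dendrogram scale bars in
surveys imply bounded distances); both variants are exposed because
published usage rarely states which was used. Trees are consumed as
newick; tree inference is out of scope.

UPGMA dendrograms place each join at half the average-linkage distance,
so the output is ultrametric and cophenetic distances equal the linkage
heights; labels are sorted before clustering so ties break by label
order. Single and complete linkage are selectable.

## Ecological statistics

ANOSIM ranks the off-diagonal distances once and computes
R = (r̄_between − r̄_within)/(N(N−1)/4); the Mantel test correlates the
condensed vectors (Pearson default, Spearman by rank-transforming before
permutation — legitimate because a joint row/column permutation permutes
the condensed entries, commuting with the rank transform). Both tests
permute with a seeded generator, fully vectorized over permutations, and
report the one-sided upper-tail p = (1 + #{perm ≥ obs})/(perms + 1), so
p ≥ 1/(perms+1) always. 999 permutations is the default. Mann-Whitney is
two-sided and delegates to scipy's auto policy (exact enumeration for
small tie-free samples, tie-corrected normal approximation otherwise);
Spearman and OLS R² likewise wrap scipy.

Environmental distance is Euclidean on z-scored variables (sample SD,
ddof = 1): a single variable gives |Δz|, and the combined
temperature-salinity distance is the 2-D Euclidean on both standardized
variables — the natural construction in the PAST toolchain, flagged here
as an interpretation since published tables rarely define it. Geographic
distance is the haversine great-circle distance in km (R = 6371.0088).

## qPCR

Standard curves are least-squares fits of Ct on log₁₀(copies) over ≥ 3
distinct ten-fold dilution levels; efficiency is E = 10^(−1/slope) − 1
(intercept-invariant). Quantitation inverts the curve,
copies = 10^((Ct−intercept)/slope); a sample is *below detection* when a
replicate fails to amplify (NaN Ct) or its Ct reaches a configured
threshold (e.g. the lowest standard) — the criteria are explicit
configuration because published non-detections rarely state them.
Triplicates are summarized as mean ± SD after conversion to copies L⁻¹
via copies_per_rxn × (elution volume / template volume) / filtered
volume. The elution volume has no default: it is rarely published, so
conversions refuse to guess. Gene ratios (accA:16S × 100) are computed
per sample over paired detections, excluding and counting samples with
either gene below detection, and summarized as mean ± SE.

## Synthetic data

Generators define the study conditions the tests run under; all take a
mandatory seed through `SimConfig` and are byte-deterministic.

* **Clone libraries** — 19 libraries with the observed sizes 25–39
  (defaults sum to the printed per-library totals), 59 planted OTUs with
  geometric (default, shape 0.10) or log-series abundances; each library
  is a multinomial draw after round-robin placement of
  `seed_copies_per_otu` copies of every OTU (guaranteeing full OTU
  coverage; 2 copies per OTU forces a singleton-free design). Distances
  are planted at 0.02 within and 0.20 between OTUs, so furthest-neighbor
  clustering at 5% recovers the partition exactly. The generator does
  **not** emulate sequence evolution, chimeras, alignment error, or
  OTU-abundance distributions with realistic rare tails — a passing
  recovery test shows the clustering chain is correct, not that real
  libraries are this clean.
* **Templates** — one decoy-free binding site per record with an exact
  planted mismatch count (≤ primer length/3), placed between
  maximally-incompatible homopolymer spacers; decoy-freedom is asserted
  at generation time by re-scanning.
* **qPCR plates** — five-level ten-fold standards in triplicate plus
  20 autumn / 19 summer surface unknowns; each station has a latent
  abundance (autumn × 10 by default), 16S tracks it and accA carries
  16.3% of it with lognormal scatter (σ = 0.15), so the between-gene
  correlation and ratio of a real survey emerge. Ct noise is Gaussian
  (σ = 0.15 cycles) around a slope of −3.4746 (E ≈ 94%, mid-range of
  reported *accA* assay efficiencies of 90–98%), intercept 38.
* **Environment** — per-library season, depth, temperature and salinity
  from season-specific ranges (autumn 18–23 °C, summer 25–30 °C;
  salinity 31–34.5 vs 27–34.5) with shelf-like coordinates; a planted
  community-environment link of configurable strength mixes the scaled
  environmental distance with symmetric noise (strength 0 is the null
  used for type-I calibration; 0.6 is the effect size used for power
  checks, detected with power > 0.8 at n = 19 and 999 permutations).
  The fields are uniform draws, not an oceanographic model.

## Problem sizes and calibration checks

The test suite calibrates the permutation tests with 2000 simulated
nulls each (n = 12 samples, 99 permutations per replicate), requiring
the empirical type-I error at α = 0.05 to lie in [0.03, 0.07]; qPCR
efficiency recovery uses 500 noisy dilution-series replicates
(tolerance ±5 percentage points, required success ≥ 95%); survey-scale
OTU recovery regenerates 620 sequences in 19 libraries and requires the
59 planted OTUs exactly. Oracle tests compare the primer scanner against
exhaustive brute force on 200 random primer/template pairs, clustering
against naive agglomeration for n ≤ 8, and weighted UniFrac against an
independent per-branch accumulation on ≤ 10-tip trees (and scikit-bio's
implementation, which is never used as the implementation path).

## Known limitations

* No indel/thermodynamic model in primer evaluation; coverage is purely
  positional.
* The Mantel/ANOSIM implementations target survey-scale inputs (tens of
  samples); permutations are vectorized but the matrices are dense.
* Published whole-survey quantities that depend on the underlying
  620 real sequences (per-library H′/Chao1 values, the survey's Mantel
  coefficients, field abundances) are covered by property-based and
  scale-matched synthetic checks, not by re-deriving the unpublished raw
  data.
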