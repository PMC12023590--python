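# Methods

This note documents the models and procedures implemented in aquamob,
the defaults they ship with, the design choices made where the methods
literature leaves room, and what the synthetic-data tests do and do not
demonstrate about real data.

## Scope and shape

The package implements the post-prediction half of a groundwater
plasmidome survey. Upstream tools — assemblers, plasmid predictors,
viral predictors, gene callers and annotators, read mappers, CRISPR
array detectors, taxonomy classifiers — are out of scope; their outputs
(candidate contigs, annotation tables, viral-evidence flags, coverage
matrices, spacers, taxonomy) are the package's inputs. The repository is
organised as an analysis project: `src/aquamob` holds every computation,
the numbered scripts under `analysis/` narrate one full run, and
`scripts/acceptance.py` recomputes the headline numbers.

## Containment dereplication

Candidate MGE contigs (minimum length 1,000 bp) are compared pairwise.
An edge requires a local alignment — Smith–Waterman with match +1,
mismatch −1, linear gap −1, both orientations tried — whose identity
(matches / alignment columns, gap columns included) is ≥ `min_identity`
(default 0.90) and whose aligned span covers ≥ `min_cov_smaller`
(default 0.90) of the shorter sequence. Identity-on-columns is a
contract, not an implementation detail: the test suite pins it against
an independent aligner (Biopython's `PairwiseAligner` with the same
scoring) on randomized fixtures with planted duplicates, containments
and mutated copies.

Performance choices: pairs are only aligned when they share ≥ 2 exact
16-mers on either strand (a 90%-identity containment of ≥ 1 kb shares
hundreds, so the prescreen cannot lose qualifying pairs in practice),
and when the full dynamic programme would exceed ~3×10⁷ cells the
longer sequence is windowed around the shared-seed diagonals before
alignment. Clusters are connected components; the representative is the
member with the highest mean pairwise identity to the rest, ties broken
by length then id — "highest identity" alone is ambiguous for ties, so
the tie-break is fixed and tested. Raising the identity threshold can
only split clusters, never merge them; this monotonicity is asserted.

Circularity flags are carried as metadata only; completeness-aware
clustering is not replicated.

## Triage rules

Free-text functional annotations are tokenized case-insensitively;
tokens split on whitespace and punctuation but keep internal hyphens, so
"T4-like" and "toxin-antitoxin" are single tokens, and a term also
matches a longer hyphenated token of which it is a hyphen-boundary
prefix ("head" matches "head-tail" but never "overhead"). The decision
ladder is: external viral call ⇒ phage; phage term ⇒ phage; plasmid term
⇒ plasmid; mobility term ⇒ uMGE; default uMGE. Two deliberate choices:
phage terms outrank plasmid terms (mirroring the dedicated
phage-exclusion step that motivates the viral override), and
"mobilization", which appears in both the plasmid and uMGE vocabularies,
resolves to plasmid because plasmid rules are checked first. Unannotated
elements default to uMGE, the bucket for ambiguous classification.
Labels are order-invariant in the annotation table by construction
(set-based matching), which a property test verifies by permutation.
MOB/relaxase hits set `mobilizable` on plasmids only and never change a
label.

## Host linking

The k-mer screen sketches each MGE with a bottom-k MinHash: the 1,000
smallest 64-bit hash values over canonical 21-mers (canonical = the
lexicographically smaller of a k-mer and its reverse complement, on the
2-bit packing). The hash is a splitmix64 finalizer over the packed k-mer
XORed with a fixed constant — chosen so sketches are bit-identical
across runs and platforms, which matters more here than any particular
hash family. The MAG side uses its full canonical-k-mer hash set,
mirroring query-sketch-versus-target-pool screen semantics. With
containment c = shared/|sketch|, estimated nucleotide identity is
c^(1/k) (the standard containment-to-identity conversion; at c = 0.8097
and k = 21 it crosses the 0.99 threshold). A link requires shared ≥
800/1000 and identity ≥ 0.99. Because host-linked synthetic MGEs are
embedded verbatim in their MAG, the screen must return c = 1 exactly for
them; sampling accuracy on partial containments is tested against exact
k-mer-set arithmetic within 3σ binomial bounds.

Spacer matching is deliberately ungapped: on 26–45 bp spacers a
"100% alignment coverage" rule makes gapped alignment moot and would
make the mismatch count ambiguous. Spacers ≤ 25 bp are dropped before
searching. A hit is a full-length occurrence on either strand with ≤ 2
substitutions; the identity filter (L − mm)/L ≥ 0.90 is provably
redundant for L ≥ 26 at ≤ 2 mismatches ((L−2)/L ≥ 24/26 ≈ 0.923) and is
asserted as such. The scanner is pinned to a brute-force sliding-window
oracle on every fixture.

Per MGE only the best link per method survives (k-mer: highest estimated
identity, then shared hashes; spacer: fewest mismatches); ties across
methods are all retained with the method recorded. Whether "top hits"
should apply per method or across methods is genuinely open; per-method
is chosen so the two evidence types remain independently inspectable.
Per-phylum plasmid counts are normalized by the summed mean coverage of
that phylum's MAGs per sample — the denominator is a documented
interpretation, since "normalized for sequencing coverage depth" admits
several.

## Abundance, presence and core sets

Coverage depths (MetaBAT-style adjusted coverage, computed upstream) are
normalized by scaling factor mean(rpoB)/rpoB(s). The ratio structure is
the contract: multiplying all rpoB counts by a constant changes nothing,
which is the tested invariant standing in for an exact formula the
marker-gene normalization literature states only loosely.

Presence is strict: normalized depth > 1, with replicate rule "any" by
default ("all" is available). Core sets come in three scopes — per well
(present in both fractions), per fraction (present in that fraction in
every well that has it; wells lacking a fraction are excluded from that
fraction's denominator, the missing-filter case), and global. Nesting
(global ⊆ fraction cores) is property-tested on random presence
matrices.

Distances: Bray–Curtis on depths, Jaccard on presence. Two all-empty
samples are at distance 0 and an empty versus non-empty pair at 1 — a
documented convention, since 0/0 is otherwise undefined. PERMANOVA uses
the distance-based one-factor partition (SS_total = Σ d²/n within the
whole, SS_within per group), with pseudo-F = (SS_among/(a−1)) /
(SS_within/(N−a)); when a grouping is perfectly homogeneous within
groups (SS_within = 0, which Jaccard on well-structured presence can
produce) the statistic is reported as +∞ and permutations are compared
against it as such. Marginal multi-factor tests are out of scope; the
two factors (well, fraction) are tested separately, which is flagged
rather than silently treated as equivalent to a joint marginal test.
Procrustes/protest computes principal coordinates of each matrix (Gower
centering, positive eigenvalues), centers and unit-norms both
configurations, takes r = √(1 − m²₁₂) from the SVD of X᙮Y, and permutes
the row order of one configuration. Mantel correlates lower-triangle
distances by Spearman under joint row/column permutation. All three use
p = (1 + #{perm ≥ obs})/(1 + n_perm), bounded below by 1/(n_perm + 1),
with an explicit integer seed.

Calibration is part of the acceptance suite: over 1,000 null simulations
each (small lognormal communities, 199 permutations), the type-I error
of PERMANOVA, Mantel, Procrustes and the permutation-Spearman screen
must lie in [0.03, 0.07] at α = 0.05.

## Association networks

Prefilters run in a fixed order: entries < 2× become 0; entities with
post-zeroing total < 50× are dropped; entities non-zero in < 25% of
samples are dropped. Reading "coverage depth of less than 2× per
metagenome were filtered out" as value-zeroing rather than row deletion
is a documented choice — row deletion is already covered by the
prevalence rule, and the zeroing reading makes the three rules
non-redundant. The order matters (a row can pass the total rule only
before zeroing) and idempotence is tested.

Network inference is a compositional partial-correlation method, built
as a desk-scale stand-in for sparse inverse-covariance ecological
network estimation with the same conditional-dependence intent: CLR
transform per matrix (pseudocount = half the smallest non-zero value,
applied to zeros only), columns standardized so Ledoit–Wolf shrinkage
acts on the correlation scale, partial correlations off the precision
matrix, and a permutation null in which each node's raw depths are
permuted and the CLR re-applied — re-applying the transform keeps the
closure-induced baseline dependence of compositional data inside the
null, which is essential at small node counts where that baseline is
far from zero. Pairs are kept at Benjamini–Hochberg q ≤ 0.05 against the
pooled null. This is not a numerical replica of any published network
tool, and results should not be compared to one; its contract is the
tested one — ≥ 95% recovery of duplicated nodes over seeded runs and a
null false-edge rate at or below q.

## Functional profiling and environment screening

COG category profiles are relative abundances over categorized genes per
(sample, MGE type), with the uncategorized fraction reported separately
so gene totals are conserved. Between-type comparisons use the
two-sided rank-sum test — exact null for combined n ≤ 20 without ties,
normal approximation with tie and continuity correction otherwise, BH
across categories; the exact branch reproduces the enumerated p = 0.1
for the 3-vs-3 extreme arrangement, and exact and approximate branches
agree within |Δp| ≤ 0.02 at the crossover. Environmental screening
computes Spearman's rho of normalized depth against each measured
variable; significance permutes the environmental vector (equivalent to
permuting the depth vector under exchangeability, fixed for
reproducibility), two-sided on |rho|, p = (1 + count)/(1 + n_perm) with
999 permutations by default; an MGE is "strongly associated" when any
variable reaches p < α = 0.05. Transcript summaries scale TPM by the
rpoB factor, average per well (single-sample wells pass through
unaveraged), and report log2(mean + 1); the +1 pseudocount is a display
choice for zero handling. The heatmap-ready presence matrix orders rows
and columns by average-linkage hierarchical clustering on Euclidean
distance, matching common heatmap defaults.

## The synthetic community generator

The generator emulates a six-well, two-filter-fraction, triplicate
groundwater survey at desk scale, with every planted feature recorded in
a truth object. Defaults (chosen once, stated here as the package's
study conditions):

| parameter | default | rationale |
|---|---|---|
| wells × fractions × replicates | 6 × 2 × 3 (36 samples) | survey design of the motivating system |
| n_plasmid / n_phage / n_umge | 20 / 45 / 70 | preserves the ~14/33/52% type mix at desk scale |
| plasmid length | log-normal, median 4,100 bp, σ_log 0.45 | reported plasmid median ≈ 4.1 kb; only median/mean are reported, so log-normal is the model choice |
| phage / uMGE length medians | 6,500 / 3,000 bp | phages longer, mobile fragments shorter, at alignable scale |
| cross_well_sharing_rate | 0.10 | well-specific populations, < 15% shared across wells |
| n_mags / mag_length | 30 / 20 kb backbone | enough hosts for ~70 links at desk scale |
| host_link_rate | 0.5 | between the per-type association rates of the motivating survey (20–60%) |
| spacer_rate | 0.15 | spacer links are rare relative to k-mer links |
| term_planting_noise | 0.0 | no annotation-noise model is stated; the knob exists for robustness experiments |
| coverage_dispersion | 0.4 (σ of log-normal noise) | no coverage error model is stated; multiplicative noise is the simplest defensible choice |
| rpob_range | 50–200 per sample | order-of-magnitude spread that makes normalization consequential |
| n_core / n_env_correlated | 8 / 4 | small planted sets recoverable exactly |

Construction rules that make round trips exact: host-linked MGEs are
embedded verbatim (or with a controlled substitution rate) into their
MAG, with the MAG backbone cut once per insert so embedded elements stay
intact — k-mer containment of 1 then holds by construction; spacers are
exact or ≤ 2-mismatch substrings of their target; contained copies are
literal (sometimes reverse-complemented) substrings of their parent;
environment-tracking MGEs are a subset of the planted core with depths
monotone in a latent per-well gradient (environmental variables are
linear in the same gradient plus noise), so they are both always present
and strongly rank-correlated; raw emitted depths equal planted depths ×
rpoB(s)/mean(rpoB), so rpoB normalization recovers the planted matrix
exactly. MAGs occupy their home well plus up to two extra wells —
microbial populations broader than their MGEs — so part of the
community passes prevalence-style network prefilters, as real MAGs must
to appear in association networks at all.

What passing tests therefore show: the machinery is correct on data
whose generative process matches the method's assumptions (exact
containments, ungapped spacers, monotone environmental responses,
log-normal noise). What they do not show: robustness to chimeric
contigs, strain mixtures, mapping artefacts, gapped protospacers,
compositional effects of very uneven community sizes, or annotation
vocabularies outside the planted term lists. The published survey-scale
counts (thousands of MGEs over 32 real metagenomes) are not reproducible
from synthetic data; the acceptance layer treats the published
numerator/denominator pairs as inputs to the summarizers and verifies
the arithmetic, not the biology.

## Numerical and reproducibility notes

- All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical (seed, config) gives
  byte-identical generator output files.
- Percentages round half-up to two decimals everywhere (Decimal-based,
  not banker's rounding). One published trio (14.41/33.61/51.98) mixes
  conventions — 2396/4609 is 51.985% and rounds to 51.99; the package
  keeps its single convention.
- Problem sizes in the test and acceptance layers (communities of
  ~100–150 MGEs, 1,000-simulation calibrations at 199 permutations,
  100-seed network runs) were chosen so a full run stays comfortable on
  a single CPU; all thresholds are independent of these sizes.
- The alignment engine is numba-compiled on first use; the first call in
  a fresh environment pays a one-time compilation cost.
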