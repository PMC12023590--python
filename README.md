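# aquamob

Mobilome analysis for groundwater metagenomes: triage of candidate mobile
genetic elements (MGEs) into plasmids, phages and unassigned MGEs (uMGEs),
containment-based dereplication and similarity modules, host assignment by
k-mer containment and CRISPR spacers, rpoB-normalized community ecology,
and microbe–MGE association networks.

It is written for microbial ecologists who already have the upstream
products of a plasmid survey — candidate contigs from plasmid predictors,
per-gene annotations, viral-predictor calls, MAGs with taxonomy, CRISPR
spacers, coverage matrices — and want a tested, seeded, desk-scale
implementation of everything that happens after: classification,
clustering, host linking and statistics. A built-in synthetic community
generator with recorded ground truth makes every stage testable without
any external data.

## The methods at the core

* **Containment dereplication.** Two contigs are redundant when a local
  alignment reaches identity ≥ 0.90 (matches / alignment columns, both
  strands tried) covering ≥ 0.90 of the shorter sequence. Clusters are
  connected components of this containment graph; the representative
  maximizes mean pairwise identity (ties: longer, then lexicographic).
  The same graph over the non-redundant set yields similarity modules,
  whose type composition (plasmid-only / phage-only / uMGE-only / hybrid)
  is summarized for modules with ≥ 3 members.
* **Term-rule triage.** Precedence: external viral evidence ⇒ phage;
  else phage terms (capsid, tail, head, …) ⇒ phage; else plasmid terms
  (plasmid, conjugation, mobA–E, parA/parB, …) ⇒ plasmid; else
  mobility terms (transposase, integrase, toxin–antitoxin, …) ⇒ uMGE;
  else uMGE. Plasmids with a relaxase/MOB hit are flagged mobilizable.
* **Host linking.** A bottom-k MinHash sketch (k = 21, s = 1000 smallest
  64-bit hashes of canonical k-mers) per MGE is intersected with each
  MAG's full k-mer hash set; a link needs ≥ 800/1000 shared hashes and
  estimated identity c^(1/k) ≥ 0.99, where c is the containment. CRISPR
  spacers (> 25 bp) link their MAG of origin to any MGE with a
  full-length ungapped occurrence at ≤ 2 mismatches and identity
  (L − mm)/L ≥ 0.90.
* **Community statistics.** Depths are scaled by mean(rpoB)/rpoB(s);
  presence means normalized depth > 1. Bray–Curtis / Jaccard distances
  feed one-factor PERMANOVA (pseudo-F, Anderson partition), Procrustes
  superimposition of principal coordinates (r = √(1 − m²₁₂)) and Mantel
  tests (Spearman), all with seeded permutations and
  p = (1 + #{perm ≥ obs}) / (1 + n_perm).
* **Association networks.** After the prefilters (depth < 2× → 0; total
  < 50×, or prevalence < 25% → drop), depths are CLR-transformed and
  partial correlations estimated with Ledoit–Wolf shrinkage; edges are
  kept at BH q ≤ 0.05 against a permutation null that re-applies the CLR
  to permuted raw depths, so compositional artefacts stay in the null.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
default synthetic community (seed 42):

```bash
python analysis/01_simulate.py
python analysis/02_dereplicate.py
...
python analysis/07_functions.py
```

Selected output, as printed:

```
145 candidates -> 135 non-redundant MGEs (10 clusters absorbed a contained duplicate)
                 row  count  denominator  percent
                uMGE     70          135    51.85
               phage     45          135    33.33
             plasmid     20          135    14.81
mobilizable_plasmids      2           20    10.00
core MGEs: 8 global (['phg_0034', 'pls_0001', 'pls_0005', ...])
PERMANOVA bray_curtis by well: F=87.96 R2=0.936 p=0.0010
PERMANOVA bray_curtis by fraction: F=0.09 R2=0.002 p=0.9970
Procrustes MGE vs MAG: r=0.9720 p=0.0001
```

Reading: all ten planted contained copies collapse onto their parents;
the triage shares mirror the planted 14/33/52% type mix; the eight
planted core MGEs are recovered exactly; the sampling well explains most
of the MGE community variance (R² = 0.94, minimum attainable p at 999
permutations) while the filter fraction explains none, and the MGE
ordination is strongly concordant with the microbial one — the planted
well structure propagates through every stage.

A thin CLI wraps the same functions (`aquamob simulate`, `aquamob
dereplicate`, `aquamob triage`, `aquamob hostlink`, `aquamob abundance`,
`aquamob network`, `aquamob envcorr`).

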