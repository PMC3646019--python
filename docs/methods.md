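# Methods

This note records the models, conventions and defaults implemented in
`coremk`, the choices made where more than one convention is defensible,
and what the synthetic-data checks do and do not establish.

## MK counting model

The unit of counting is the codon column of a per-gene alignment
(ingroup strains + outgroup strains).

* A codon containing a gap, an ambiguity code, or a partial gap in **any**
  counted sequence removes that column from counting (conservative
  pairwise information is not rescued at the codon level). Ambiguous and
  partially gapped codons are masked to `---` on input; internal stop
  codons are an error by default (maskable with a flag).
* A column segregating within the ingroup contributes **only** to
  polymorphism, never to divergence, whatever the outgroup carries.
  Divergence is counted only at ingroup-monomorphic columns. This
  "polymorphism priority" is the standard MK bookkeeping; the alternative
  (counting divergence at polymorphic codons against the outgroup) mixes
  the two classes.
* Polymorphism within a codon: each distinct minor codon is connected to
  the ingroup **majority** codon (ties broken toward the alphabetically
  first codon). One contribution per distinct variant, not per strain, so
  allele frequencies do not inflate counts.
* Divergence uses an outgroup **representative**: the majority-rule
  consensus codon over clean outgroup codons (columns with no unique
  plurality winner are skipped); a `first`-strain mode is available. A
  single-strain outgroup is its own representative.
* Codons differing at 2–3 positions are resolved by averaging the
  synonymous/non-synonymous step classification over all orderings of the
  position changes whose intermediate codons are not stops (shortest
  stop-free pathways, Nei–Gojobori style). If every ordering passes
  through a stop, the average is over all orderings, keeping the total
  number of steps conserved. This pathway averaging is why counts are
  reals; they are rounded to integers only for the contingency test.
* Translation uses NCBI table 11 by default (internal codons identical to
  the standard code), configurable by table id.

This counting deliberately replaces a codon-model ML estimate of
divergence (e.g. `codeml`) with direct pathway counting: the contract of
the package is the aggregate MK statistics, not model-based substitution
estimates, and the counting path is fully checkable against an explicit
enumeration oracle.

## Per-gene statistics and undefined cases

* NI is computed in the cross-multiplied form `P_N·D_S / (P_S·D_N)` and is
  undefined exactly when `P_S == 0` or `D_N == 0`. With `D_S == 0` (and a
  non-zero denominator) the ratio-of-ratios limit is 0 and is reported as
  such rather than as undefined.
* DoS is undefined exactly when `P_N + P_S == 0` or `D_N + D_S == 0`.
* Integer-valued tables are evaluated in exact rational arithmetic
  (`fractions.Fraction`) before conversion to float, so algebraically
  equal forms are bit-identical.
* Significance: chi-squared without continuity correction on the rounded
  2×2 table; Fisher's exact test substitutes whenever any expected cell is
  below 5 (the table reports which test ran). All-zero tables have no
  p-value. Benjamini–Hochberg q-values are reported across genes; raw p is
  primary.

## Pooled statistic and its CI

`NI_TG = Σ D_S·P_N/(P_S+D_S) / Σ P_S·D_N/(P_S+D_S)` over genes with
`P_S + D_S > 0` (zero-weight genes are skipped and counted). The 95% CI is
a nonparametric bootstrap over genes (default 10,000 resamples, percentile
method, seeded); resamples with a zero denominator are dropped. The
bootstrap was chosen over a closed-form variance because it makes no
assumption about across-gene heterogeneity of NI and is exactly
reproducible under the run seed; an analytic CI could be added as an
alternative method without changing the interface.

## Alignment QC

"Alignment overlap" is the fraction of codon columns that are gap-free in
every genome; "indel length" is the longest run of codon columns
containing at least one gap, measured in codons (not nucleotides) to
respect frame semantics, after trimming. Trimming removes leading and
trailing codon columns containing any gap so retained flanks are clean;
interior columns are untouched. Defaults: minimum overlap 0.85, maximum
indel 15 codons — both user-set parameters with no canonical published
values; they are deliberately permissive and configurable.

## Trees, outgroup designation, congruency

Distances are JC69 with pairwise deletion (each pair is compared over the
columns where both carry an unambiguous base); a mismatch proportion
≥ 0.75 has no finite JC69 distance and is an error. JC69 was chosen over
richer models (F84/K80) because its closed form is directly testable; the
distance model is isolated behind one function and could be swapped.

UPGMA: average linkage, node height = half the merge distance, and ties
broken by merging the pair whose smallest member labels sort first — the
output is a deterministic, rooted, ultrametric tree. The first split (the
root bipartition of the concatemer tree) defines the candidate ingroup /
outgroup clades; each clade with ≥ 2 members is run as ingroup, producing
up to two output tables. Per-gene congruency compares only the gene tree's
first split with the reference split; full-topology matching would flag
genes for within-clade rearrangements that do not affect the MK contrast.
Incongruent genes are excluded from NI_TG by default (they remain in the
per-gene table, flagged).

## Diversity and spectra

π is the mean pairwise difference per comparable site (pairwise deletion);
θ_W = S/(a_{n−1}·L) over sites clean in all ingroup strains. Both are
per-site for cross-gene comparability. Triallelic sites count once in S
and in π but are excluded from the spectra. The unfolded SFS is polarized
by the outgroup representative allele; sites where the outgroup carries
neither ingroup allele enter only the folded spectrum. Synonymous /
non-synonymous split spectra classify the biallelic change in the ingroup
consensus codon background; changes involving a stop codon or unresolvable
context stay unclassified (combined spectra only).

## PHI recombination test

For two informative sites the refined incompatibility score is the cycle
rank (E − V + C) of the state-pair graph over rows clean at both sites —
0 iff the pair fits on one tree, and exactly the four-gamete test for
binary sites. The statistic is the mean score over informative-site pairs
within 100 nt of each other (1,000 permutations by default, seeded).
Because recombination specifically elevates incompatibility between
*distant* sites, the observed near-pair statistic is compared against
site-order permutations with a lower-tail p-value,
`p = (1 + #{perm ≤ obs}) / (n_perm + 1)`. Genes with fewer than two
informative sites (or no in-window pair) have no p-value and pass the
filter by default. PHI-flagged genes are flagged only, not excluded,
unless `--exclude-recombinants` is set. The companion NSS and max-χ²
statistics of the original test battery are not implemented.

## Synthetic data

The generator emulates: a stop-free random ancestral CDS per gene; fixed
differences accumulated on the outgroup lineage; theta-scaled segregating
mutations with derived-allele counts from either a star model (independent
1/k-weighted carrier subsets; analytic truth, but carrier patterns are not
tree-consistent) or a per-gene Kingman coalescent (tree-consistent,
homoplasy-free up to recurrent mutation — the correct null for PHI);
K80-like 2:1 transition bias; selection as acceptance/rejection of
non-synonymous proposals (probability `omega_divergence` on the divergence
lineage, `omega_polymorphism` within the ingroup; stops always rejected).
Recombinants are either `inter` (one ingroup strain's half-gene block
replaced by the outgroup-lineage sequence — moves the gene's first split;
the congruency filter's target) or `intra` (the two halves of the ingroup
evolve on independent coalescent genealogies — crossing splits; PHI's
target).

Default study conditions: 200 genes × 300 codons, 6 ingroup + 2 outgroup
strains, divergence 0.03 substitutions/site, θ = 0.01/site — typical of
within/between-species comparisons of related bacterial strains, and large
enough that per-gene MK tables are mostly non-degenerate.

What the simulation does **not** emulate: indel evolution (gaps are
injected post hoc only for QC tests), rate variation across sites and
genes, codon-usage bias, selection on synonymous sites, gene-specific
genealogies shared across genes (no linkage between genes), and
back-mutation-free infinite-sites behaviour. Two consequences worth
knowing: (i) at appreciable divergence, multiple hits make counted D
slightly undershoot the true number of substitution events (the MK ratios
are barely affected because both classes shrink together); (ii) the
sequential evolution of the divergence lineage lets codon composition
drift slightly away from the uniform ancestral state, which induces a
small (≪ the ±0.02 acceptance band) negative offset in mean DoS under
neutrality. Passing the neutral-recovery checks therefore shows the
statistics are calibrated under these idealized conditions; it does not
certify behaviour under strong rate heterogeneity or pervasive
recombination.

## Numerical and reproducibility conventions

* All randomness (simulation, bootstrap, PHI permutations) derives from
  one top-level seed via named substreams (stage and gene-id hashed into
  the seed), so results are independent of gene execution order and reruns
  are byte-identical.
* Ultrametricity of UPGMA output holds to 1e-9; permutation-test ties use
  a 1e-12 tolerance on "≤ observed".
* Degenerate inputs are values, not crashes, wherever the field treats
  them so: undefined NI/DoS/p are reported as `NA`; genes with no usable
  columns, saturated distance pairs, and directions with a zero pooled
  denominator are logged and skipped rather than fatal.
* Problem sizes in the validation suite (200 genes × 50 replicates for the
  neutral and selection recovery checks, 200/100 genes for PHI
  calibration/power, 500 random trees ≤ 16 leaves, 20,000 single-codon
  oracle cases) were chosen to make Monte-Carlo error comfortably smaller
  than the effect sizes being checked on a single CPU.

## Known limitations

* Divergence counting is parsimony-like; for deeply diverged pairs
  (roughly > 0.3 substitutions/site) multiple hits bias D downward and a
  model-based estimator would be preferable.
* The outgroup consensus skips codons without a plurality winner, which
  discards some divergence information for very diverse outgroups.
* The congruency filter inspects only the root bipartition; recombination
  that does not move a strain across the first split is invisible to it
  (by design — PHI covers the within-gene case).
* The analytic (variance-based) CI for NI_TG is not implemented; the
  bootstrap CI is the only interval offered.
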