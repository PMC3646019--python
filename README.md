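# coremk

Genome-wide McDonald–Kreitman (MK) analysis for prokaryote core genomes.

`coremk` takes per-gene in-frame codon alignments of single-copy orthologs
(a set of closely related strains plus an outgroup), counts synonymous and
non-synonymous polymorphism and divergence per gene, and summarizes the
strength and direction of selection both per gene and pooled over the whole
core genome. It is aimed at microbial comparative genomicists who already
have ortholog alignments (from any orthology/alignment pipeline) and want
the population-genetic stage: MK tables, neutrality statistics, site
frequency spectra, automatic outgroup designation, and recombination
filtering — reproducibly, from the command line or from Python.

## The statistics

For each gene the codon columns yield the 2×2 MK table
(P_N, P_S: non-synonymous / synonymous polymorphisms within the ingroup;
D_N, D_S: fixed differences to the outgroup; multi-step codon differences
are averaged over all shortest stop-free mutational pathways):

* **Neutrality index** NI = (P_N/P_S) / (D_N/D_S). NI = 1 under neutrality,
  NI < 1 indicates excess non-synonymous divergence (positive selection),
  NI > 1 an excess of non-synonymous polymorphism (segregating weakly
  deleterious variation). NI is undefined when P_S = 0 or D_N = 0.
* **Direction of selection** DoS = D_N/(D_N+D_S) − P_N/(P_N+P_S), defined
  for far more genes than NI; DoS > 0 points to adaptive divergence.
* **Core-genome neutrality index** pooling all genes with
  Mantel–Haenszel-style weights,

      NI_TG = Σᵢ [D_Sᵢ·P_Nᵢ/(P_Sᵢ+D_Sᵢ)] / Σᵢ [P_Sᵢ·D_Nᵢ/(P_Sᵢ+D_Sᵢ)],

  with a seeded bootstrap-over-genes 95% CI. Unlike summing counts or
  averaging per-gene NI, this weighted form is well behaved when NI varies
  across genes.
* Per-gene significance by a 2×2 chi-squared test (Fisher's exact test when
  expected cells are small), with Benjamini–Hochberg q-values across genes.
* Ingroup diversity per gene: segregating sites, π, Watterson's θ, and
  folded/unfolded (outgroup-polarized) site frequency spectra split into
  synonymous and non-synonymous classes.

The ingroup/outgroup split is designated automatically from the first split
of a UPGMA tree (JC69 distances) of the per-genome concatemer of all genes;
when both clades have ≥ 2 strains the analysis is run in both directions.
Genes whose own tree contradicts that split (inter-taxon recombinants) are
flagged by a congruency filter, and the pairwise homoplasy index (PHI) with
a site-order permutation test flags within-gene recombination.

A forward simulator (`coremk simulate`) generates ortholog sets with known
divergence, polymorphism, selection regime and recombinant fraction, so the
whole pipeline can be exercised and calibrated without any external data.

## Worked example

```bash
# simulate a 40-gene core genome with adaptive divergence
cat > sim.json <<'EOF'
{"n_genes": 40, "gene_length_codons": 200, "n_ingroup": 6, "n_outgroup": 2,
 "divergence_subs_per_site": 0.03, "polymorphism_theta": 0.01,
 "omega_divergence": 1.0, "omega_polymorphism": 0.2, "seed": 7}
EOF
coremk simulate --config sim.json --out genes/
coremk run-all --in genes/ --out run/ --seed 1
```

which prints

```
direction1: NI_TG=0.2340 [0.1648, 0.3271] over 40 genes
direction2: NI_TG=0.2920 [0.1785, 0.4701] over 40 genes
```

`direction1` treats the six-strain clade as the ingroup: NI_TG ≈ 0.23 with
a CI well below 1 correctly recovers the simulated regime, in which
non-synonymous changes fix between taxa five times more readily than they
segregate within them. `direction2` is the reverse test using the two
outgroup strains as the ingroup — possible, but with only two strains its
polymorphism counts (and hence its CI) are much weaker. Per-gene tables
(`run/summary_direction1.tsv`) carry each gene's MK table, NI, DoS, test
p/q-values, π, θ, the SFS, and the congruency/PHI flags; `run/qc_report.tsv`
and `run/concatemer.nwk` record the trimming statistics and the tree behind
the split.

Each stage is also a standalone subcommand (`trim`, `qc`, `tree`,
`filter-congruent`, `phi`, `mk`), so intermediates can be replaced by your
own alignments or trees.

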