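# mhdiv

Analysis toolkit for single-locus MH class II exon-2 allelic diversity.
Given a codon-frame alignment of alleles, a diploid genotype panel and
(optionally) family pedigrees, it computes:

- **diversity** — nucleotide diversity (π), segregating sites, variable
  amino-acid sites, synonymous substitution columns, observed
  heterozygosity;
- **selection_ng86** — pathway-counting dN/dS with Jukes–Cantor
  correction, partitioned into peptide-binding-site (PBS) vs non-PBS
  codons via homology mapping to packaged human β1 contact-site
  catalogs, plus a bootstrap Z-test of positive selection;
- **site_models** — GY94 codon site models: beta-distributed ω ("M7")
  vs beta + positive-selection class ("M8"), df = 2 likelihood-ratio
  test, empirical-Bayes per-site selection posteriors, and a matching
  GY94 simulator;
- **popgen** — exact Hardy–Weinberg testing (complete enumeration or
  seeded Monte Carlo), an allelic-combination permutation test with
  sequential-Bonferroni (Holm) correction, EM haplotype phasing of
  degenerate IUPAC consensus sequences, and Mendelian inheritance
  checking;
- **recombination** — minimal-cost mosaic scanning for intralocus
  recombinant alleles with column-permutation p-values and a
  switch-penalty (ρ) sweep;
- **network** — minimum-spanning haplotype networks with amino-acid
  edge labels, including rebuilds after pruning recombinants;
- **synthetic_data** — seeded generators of allele pools (with planted
  recombinants), genotype panels (HWE or biased pairing) and nuclear
  families, with truth records for recovery testing.

## CLI

```sh
mhdiv simulate --seed 1 --out demo/            # synthetic dataset
mhdiv diversity demo/alleles.fasta --trim-leading 0 --trim-trailing 0
mhdiv dnds ALIGNED.fasta                       # dN/dS + Z-tests (PBS split)
mhdiv sitemodels ALIGNED.fasta                 # M7 vs M8 LRT
mhdiv hwe GENOTYPES.tsv
mhdiv combos GENOTYPES.tsv
mhdiv mendel [FAMILIES.tsv]                    # defaults to packaged pedigree
mhdiv phase GENOTYPES.tsv
mhdiv recomb ALIGNED.fasta
mhdiv network ALIGNED.fasta GENOTYPES.tsv
mhdiv all --out run/                           # full pipeline (synthetic demo
                                               # dataset if no input given)
```

Exon alignments are trimmed `(2, 1)` by default (drop the first two and
the last nucleotide) to restore a complete reading frame; pass
`--trim-leading 0 --trim-trailing 0` for already in-frame input. Every
randomized stage takes an explicit `--seed`, and `mhdiv all` writes a
provenance log (versions, seeds, config hash) alongside its report
bundle.

## File formats

- alignments: FASTA (uppercase A/C/G/T, equal lengths, no gaps after
  trimming);
- genotypes: TSV `individual<TAB>alleleA/alleleB[<TAB>IUPAC consensus]`;
- pedigrees: TSV `family role a1 a2 a3 a4` — father pair in (a1, a2),
  mother pair in (a3, a4), each offspring row has exactly two non-empty
  allele cells;
- outputs: TSV/JSON summaries, GraphML/DOT networks, newick trees.

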