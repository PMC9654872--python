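# orgredit

Analysis of **C-to-U RNA editing** in plant organelle genomes, built
around the tea plant (*Camellia sinensis*) chloroplast and
mitochondrion. In plant plastids and mitochondria, specific transcript
cytidines are deaminated to uridine after transcription; an editing site
is a position where the DNA carries C but the RNA shows U/T. Most edits
hit codon position 1 or 2 and change the protein — including creating
new start (ACG→AUG) or stop (CGA→UGA) codons — and their loss is linked
to albino and etiolated leaf phenotypes. This package is for researchers
who want to call such sites from paired DNA/RNA evidence, annotate their
codon-level effects, profile their sequence context, quantify how
completely each site is edited, and predict which PLS-class
pentatricopeptide-repeat (PPR) editing factors recognise them.

## What it computes

* **Site calling** (`orgredit.edit_caller`) — from aligned gDNA/cDNA
  amplicon pairs, or from DNA/RNA pileups with threshold filters
  (coverage, DNA homozygosity for C, T-read support, editing frequency
  f = T/(T+C)), strand-aware on the transcript strand.
* **Effect annotation** (`orgredit.effect_annotator`) — maps a genome
  position onto spliced, stranded gene models, computes the transcript
  coordinate, codon position `((cds_pos−1) mod 3)+1`, the edited codon
  and the amino-acid change, classified as synonymous / missense /
  stop gain / start gain.
* **Sequence context** (`orgredit.context_profile`) — base frequencies
  at offsets −5..+5 around edited Cs and FASTA export of upstream-25 or
  centered-51 windows for motif tools.
* **Editing level** (`orgredit.editing_level`) — per site and sample,
  level = h_T/(h_T+h_C) from chromatogram peak heights, or
  n_T/(n_T+n_C) from read counts with a Wilson 95% interval.
* **PPR target prediction** (`orgredit.ppr_matcher`) — turns the 2nd,
  5th and last residues of each P/L/S motif into a base-preference PWM
  via a PPR code table, scans 51-nt windows centered on editing sites
  with summed log-odds scores, and converts scores to *exact* p-values
  by dynamic programming over a discretized score lattice.
* **Synthetic data** (`orgredit.synth_organelle`) — a seeded generator
  of organelle genomes, gene models, planted sites with known levels,
  pileups, peak tables and code-consistent PPR proteins, used as the
  ground truth for the test suite.

Two validated-site catalogs ship with the package — 38 chloroplast
sites over 22 genes and 139 mitochondrial sites over 22 genes —
loadable with `orgredit.load_table1()` / `load_table2()`.

## Worked example

Simulate a noise-free organelle dataset, call sites from the pileups,
annotate them and check against the simulator's truth:

```console
$ orgredit simulate --seed 1 --out-dir demo --n-sites 20 --error-rate 0
INFO simulated 20 sites in 12 genes (seed=1, config hash 1292d44b506f) -> demo
$ orgredit call --pileups demo/pileups_S1.tsv --out demo/calls.tsv
INFO 20 calls (20 C-to-U) from 6489 positions -> demo/calls.tsv
$ orgredit annotate --calls demo/calls.tsv --genome demo/genome.fasta \
    --gff demo/genes.gff3 --out demo/annotated.tsv --check demo/truth_sites.tsv
INFO 20 coding sites, 0 noncoding, 0 ambiguous -> demo/annotated.tsv
consistency: 20 match, 0 mismatch, 0 missing, 0 extra
$ head -4 demo/annotated.tsv
gene    genome_position edited_nucleotide       amino_acid_change       editing_type    position_in_codon       effect
g01     401     C299    P100→L100       C→T     2       missense
g02     2737    C151    L51→F51 C→T     1       missense
g02     2762    C126    F42→F42 C→T     3       synonymous
```

All 20 planted sites are recovered (the `consistency` line compares the
re-annotated calls with the simulator's truth row by row), and each call
carries its transcript coordinate (`C299` = edited C at spliced-CDS
position 299), amino-acid change and effect class.

The bundled catalogs reproduce their published summary statistics:

```pycon
>>> from orgredit import load_table1, load_table2
>>> from orgredit.effect_annotator import codon_position_partition, per_gene_counts
>>> t1, t2 = load_table1(), load_table2()
>>> len(t1), len(t2)
(38, 139)
>>> codon_position_partition(t1, t2)
{1: 57, 2: 116, 3: 4}
>>> per_gene_counts(t2).head(3).to_dict()
{'ccmB': 34, 'nad5': 17, 'cox2': 15}
```

That is: of the 177 validated sites, 57 sit at codon position 1, 116 at
position 2 and 4 at position 3, and the mitochondrial gene *ccmB*
carries the most sites (34).

See `docs/methods.md` for the models, parameter defaults, numerical
choices and known catalog inconsistencies.

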