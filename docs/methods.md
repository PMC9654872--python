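# Methods

## Scope and model

`orgredit` analyses cytidine→uridine (C-to-U) RNA editing in plant
organelle (chloroplast and mitochondrial) genomes. The package covers
five analysis steps and one data generator:

1. **Site calling** from paired DNA/RNA evidence (`edit_caller`),
2. **Codon-effect annotation** on stranded, possibly spliced gene models
   (`effect_annotator`),
3. **Flanking-base context** profiling and motif-window export
   (`context_profile`),
4. **Editing-level quantification** from chromatogram peaks or read
   counts (`editing_level`),
5. **PPR-code target prediction** by PWM scanning with exact p-values
   (`ppr_matcher`),
6. a **seeded simulator** of all of the above inputs (`synth_organelle`).

Two validated-site catalogs for the tea plant (*Camellia sinensis*) ship
with the package: 38 chloroplast sites over 22 genes and 139
mitochondrial sites over 22 genes. They are transcribed verbatim from
their printed source, including internally inconsistent rows (below).

## Coordinates and genetic code

Genome positions are 1-based inclusive (GFF3 convention). CDS positions
are 1-based on the spliced transcript, position 1 being the first base
of the start codon; a token like `C701` denotes an edited C at
transcript position 701. Codon position is `((cds_pos − 1) mod 3) + 1`
and the codon index is `(cds_pos − 1) div 3 + 1`. Translation uses the
standard code (table 1) for both organelles — plant plastids and
mitochondria do not deviate from it for these genes — with stop written
`X` to match the catalogs' `R→X` notation. Effects are classified as
synonymous, missense, stop gain (edit creates a stop), or start gain
(ACG→AUG at codon 1). Stop loss is representable but unreachable: no
stop codon contains a C, and a test asserts this.

## The pileup caller

The caller takes per-position base counts for one DNA and one RNA sample
(forward-strand counts plus the gene strand). Counts of − strand genes
are complement-folded (A↔T, C↔G) before any test; an unknown strand is
an error rather than a guess. A C-to-U call requires, on the transcript
strand:

* DNA coverage ≥ `min_dna_cov` (default 10) with C the majority base and
  a non-C fraction ≤ `max_dna_alt_fraction` (default 0.05) — the
  homozygosity guard against SNPs;
* RNA coverage ≥ `min_rna_cov` (default 10), T reads ≥
  `min_edited_reads` (default 3), and T/(T+C) ≥ `min_editing_freq`
  (default 0.05).

Defaults are deliberately conservative and fully overridable; raising
any threshold can only remove calls (a tested monotonicity property).
Non-C→T differences that pass the analogous filters are reported with
`is_c_to_u=False` rather than dropped, so contrary evidence stays
visible. Heteroplasmy cannot be distinguished from editing with this
evidence model; the DNA minor-allele fraction is carried on every call
so downstream users can judge. No read alignment, base-quality modelling
or statistical error model beyond these filters is attempted.

## Context windows

All windows are taken in transcript coordinates so splice junctions and
strand are resolved exactly once; the biological rationale is that
editing factors bind the transcript. The context matrix covers offsets
−5..−1 and +1..+5 (the edited base itself excluded); windows that cross
a transcript end contribute only their available offsets, and each
matrix column is normalised by its own truncation-aware denominator.
Exported FASTA windows are either the 25 bases 5′ of the site (motif
discovery input) or the 51 bases centered on it (scan targets);
truncated records are flagged in the FASTA description.

## Editing level

From peak heights, level = h_T / (h_T + h_C); the estimate is
scale-invariant, and raw trace base-calling is out of scope (peak
heights are taken as provided numbers). From read counts, level =
n_T / (n_T + n_C) with a Wilson 95% score interval (statsmodels).
Qualitative bins (<10%, ~30%, ~50%, >80%, ~100%) are narrative labels
only and never enter computation.

## PPR-code matching

A PLS-class PPR protein is reduced to its ordered motif codes — the
2nd, 5th and last residue of each motif. A code table maps these to base
preference vectors with triple → pair (5th, last) → single (last) →
background fallback. One PWM column per nucleotide-specifying (P/L/S
family) motif is emitted in N→C order, mapping onto the target 5′→3′;
E/E+/DYW motifs belong to the deaminase arm and contribute no column.
A pseudocount (default 0.01) is added and rows renormalised. No fixed
offset between the last motif and the edited C is imposed: the scan over
the 51-nt window discovers the alignment.

Scores are summed log-odds in bits against an i.i.d. background
(default uniform). The p-value of a score is the exact probability that
a background sequence of the PWM's length scores at least as high,
computed by dynamic programming over a discretized score lattice (the
classical exact-scan construction). The lattice step is the total
finite score range divided by 100 000; rounding is conservative (the
reported p never undercuts the exact tail) and the total slack is
exposed as `discretization_bound` (= step × L, typically ~1e-4 bits).
Tests sandwich the DP between full 4^L enumerations. Matrix entries
with probability zero (pseudocount 0) score −∞; such sequences are
counted below every finite score, which keeps one-hot p-values exactly
(1/4)^L under a uniform background.

Interaction prediction keeps, per (protein, site window), the best hit
if its raw p ≤ `threshold_p` (default 1e-4, the conventional scanner
default). Benjamini–Hochberg q-values over all scanned pairs are
attached as a column but never drive filtering, matching the common
practice of reporting raw scan p-values. The per-protein target counts
are summarised in bins {1, 2, 3, 4, ≥5}.

## The simulator

`synth_organelle` emulates the roles of real study inputs, not their
full complexity. A genome of i.i.d. bases (uniform by default;
`base_weights` allows AT-rich compositions) has ATG…stop frames carved
out, optionally split into two segments and placed on either strand.
Sites are planted on transcript-strand Cs honouring codon-position
weights (default 57:116:4, the second-position skew of the bundled
catalogs), at most one site per codon so each truth row's amino-acid
change is attributable to its single edit. Editing levels cycle a
ladder (0.2…1.0 by default) and six samples carry a two-high/two-mid/
two-low contrast echoing a green/etiolation/albino cultivar design
(labels are synthetic; no biological claims). Pileups are multinomial
draws at 100× default coverage with a uniform-error channel (default
rate 0.001); peaks are level·(1+ε) with multiplicative Gaussian noise
(CV 0.05), truncated at 0. PPR positives copy a 7–12-nt subwindow of a
planted site's window through the code table — 7 is the shortest
consensus whose best p-value (1/4)^w clears the 1e-4 threshold —
and decoys draw codes uniformly. All randomness flows from one seed via
numbered child streams; identical configs are byte-identical.

What the simulator does **not** model: read alignment artefacts, indels,
strand-biased coverage, base-quality structure, GC-content gradients,
heteroplasmy, or chromatogram trace shapes. Passing round-trip tests
therefore demonstrates internal correctness of the pipeline's logic,
not robustness to every real-data pathology.

## Known catalog inconsistencies

Recomputing the codon position from the edited-nucleotide coordinate
agrees with the printed column for all 177 rows, and the pooled
partition is 57 / 116 / 4 over codon positions 1 / 2 / 3. However,
eight printed amino-acid transitions are not achievable by a single
C→U at the stated position (64-codon brute force). Six of them come in
adjacent pairs sharing a codon (ccmB C475 with C476, ccmB C193 with
C194, ccmB C148 with C149, nad5 C361 with C362): the printed change is
the *joint* outcome of editing both Cs (CCx→UUx), which
`achievable_with_coedits` reproduces. The remaining two — atpF C92
(P→H at position 2) and ccmB C28 (S→L at position 1) — are not
achievable even jointly and appear to be misprints; they are preserved
verbatim, and the strict single-edit acceptance check is intentionally
left failing for these rows rather than silently corrected. Five rows
also print amino-acid indices that disagree with `(cds_pos−1)//3+1`
(nad6 C446, atp6 C37, orf115b C77, cob C568, cob C982); indices are
stored as printed and not cross-validated.

Per-gene strand is not stated in the catalogs. `infer_strands` infers
it from the sign of the genome-vs-transcript coordinate relation for
genes with ≥2 sites and reports `?` otherwise; this is metadata only.

## Problem sizes and numerical choices

Round-trip suites use 50 planted sites in 12 genes on a 30 kb genome at
100× coverage; level-recovery checks use coverage 1000 with 200–300
replicates per level; PWM enumeration oracles go up to L = 8 (65 536
sequences) and calibration uses ~2×10⁴ scanned offsets. These sizes give
binomial standard errors comfortably inside the asserted tolerances.
Ties in scan hits are broken by leftmost offset; degenerate inputs
(empty site sets, both peaks zero, windows shorter than the PWM) raise
`ValidationError` rather than returning sentinels.
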