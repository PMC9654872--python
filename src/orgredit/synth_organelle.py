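"""Seeded generator of synthetic organelle data.

Emulates the data roles of a real study: an organelle genome with genic
structure (ATG…stop reading frames, optionally split and on either
strand), planted C-to-U sites with known per-site editing levels, DNA
and RNA pileups sampled binomially with a sequencing-error model,
chromatogram-style peak tables with multiplicative noise, and PPR
proteins whose codes are consistent with a code table (positives built
to match planted target windows, decoys drawn at random).

Every draw flows from the single ``SimulationConfig.seed`` through
numbered child streams; identical configs give identical outputs.

Defaults represent the study conditions the package is exercised under:
the codon-position weights mirror the strong second-position skew of
validated organellar site catalogs (57:116:4), editing levels cycle a
ladder from 0.2 to 1.0, six samples carry a high/mid/low level contrast
(two of each, echoing a green/etiolation/albino cultivar design), and
coverage is 100x per sample.  Genome composition is uniform by default
for analytic tractability; ``base_weights`` lets AT-rich compositions
be simulated when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import effect_annotator
from .edit_caller import BASES, PileupPair
from .orgdata import (
    EditSite,
    GeneModel,
    GenomeRecord,
    SiteTable,
    ValidationError,
    reverse_complement,
    transcript_sequence,
    write_fasta,
    write_gff,
    write_site_table,
)
from .ppr_matcher import PprCodeTable, PprMotif, PprProtein

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_organelle",
    "simulate_pileups",
    "simulate_peaks",
    "simulate_ppr",
    "synthetic_code_table",
    "write_truth_set",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 30_000
    n_genes: int = 12
    segments_per_gene: int = 1  # 1 or 2
    strand_mix: float = 0.5  # fraction of genes on the − strand
    gene_length_range: tuple[int, int] = (100, 250)  # codons incl. start/stop
    n_sites: int = 50
    codon_position_weights: tuple[float, float, float] = (57 / 177, 116 / 177, 4 / 177)
    level_distribution: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    n_samples: int = 6
    sample_level_factors: tuple[float, ...] = (1.0, 1.0, 0.6, 0.6, 0.3, 0.3)
    dna_coverage: int = 100
    rna_coverage: int = 100
    sequencing_error_rate: float = 0.001
    peak_noise_cv: float = 0.05
    peak_scale: float = 1000.0
    n_ppr_positive: int = 10
    n_ppr_decoy: int = 10
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.segments_per_gene not in (1, 2):
            raise ValidationError("segments_per_gene must be 1 or 2")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValidationError("strand_mix outside [0, 1]")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValidationError("sequencing_error_rate outside [0, 1)")
        if len(self.sample_level_factors) != self.n_samples:
            raise ValidationError(
                "sample_level_factors length must equal n_samples"
            )
        if abs(sum(self.codon_position_weights) - 1.0) > 1e-9:
            raise ValidationError("codon_position_weights must sum to 1")
        if any(not 0.0 <= lv <= 1.0 for lv in self.level_distribution):
            raise ValidationError("levels must lie in [0, 1]")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_samples))


@dataclass
class TruthSet:
    """Everything the simulator knows: the ground truth for round trips."""

    genome: GenomeRecord
    genes: list[GeneModel]
    sites: SiteTable
    true_levels: pd.DataFrame  # index gene:cds_pos, columns sample ids
    config: SimulationConfig

    def site_level(self, site: EditSite, sample_id: str) -> float:
        return float(self.true_levels.loc[f"{site.gene_id}:{site.cds_pos}", sample_id])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_organelle(config: SimulationConfig) -> TruthSet:
    """Generate a genome with genes and planted C-to-U sites.

    The genome is i.i.d. over ``base_weights`` with ATG…stop frames
    carved out; sites are placed on C positions honouring
    ``codon_position_weights`` (one site per codon, so every truth row's
    amino-acid change is attributable to its single edit).
    """
    rng = _rng(config, 1)
    genome_arr = rng.choice(list("ACGT"), size=config.genome_length,
                            p=config.base_weights)

    lo, hi = config.gene_length_range
    slot = config.genome_length // config.n_genes
    max_footprint = hi * 3 + (250 if config.segments_per_gene == 2 else 0)
    if slot < max_footprint + 20:
        raise ValidationError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_genes} genes of up to {hi} codons"
        )

    genes: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    for i in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in body)
        cds += _STOPS[int(rng.integers(3))]
        strand = "-" if rng.random() < config.strand_mix else "+"
        slot_start = i * slot + 10  # 1-based genome coordinate

        if config.segments_per_gene == 1:
            chunks = [cds]
            gaps = []
        else:
            cut = int(rng.integers(30, len(cds) - 30))
            chunks = [cds[:cut], cds[cut:]]
            gaps = [int(rng.integers(50, 200))]

        # place chunks left-to-right along the genome; on the − strand the
        # transcriptionally-first chunk occupies the rightmost segment
        placed = chunks if strand == "+" else chunks[::-1]
        segments_ltr = []
        cursor = slot_start
        for k, chunk in enumerate(placed):
            seg = (cursor, cursor + len(chunk) - 1)
            segments_ltr.append(seg)
            seq = chunk if strand == "+" else reverse_complement(chunk)
            genome_arr[seg[0] - 1 : seg[1]] = list(seq)
            cursor = seg[1] + 1 + (gaps[k] if k < len(gaps) else 0)

        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:02d}",
                strand=strand,
                segments=tuple(segments_ltr),
                feature_class="CDS",
            )
        )
        transcripts[genes[-1].gene_id] = cds

    genome = GenomeRecord(
        id="synth_organelle", sequence="".join(genome_arr), organelle="chloroplast"
    )
    for gene in genes:  # placement sanity check
        assert transcript_sequence(genome, gene) == transcripts[gene.gene_id]

    # candidate C positions by codon position, excluding the start codon
    # (which contains no C anyway) and allowing one site per codon
    candidates: dict[int, list[tuple[str, int]]] = {1: [], 2: [], 3: []}
    for gene in genes:
        cds = transcripts[gene.gene_id]
        for pos in range(4, len(cds) + 1):  # skip codon 1
            if cds[pos - 1] == "C":
                candidates[(pos - 1) % 3 + 1].append((gene.gene_id, pos))
    total_available = sum(len(v) for v in candidates.values())
    if config.n_sites > total_available:
        raise ValidationError(
            f"cannot plant {config.n_sites} sites: only {total_available} "
            "editable C positions available"
        )
    for v in candidates.values():
        rng.shuffle(v)

    used_codons: set[tuple[str, int]] = set()
    chosen: list[tuple[str, int]] = []
    weights = np.asarray(config.codon_position_weights, dtype=float)
    while len(chosen) < config.n_sites:
        open_classes = [p for p in (1, 2, 3) if candidates[p]]
        if not open_classes:
            raise ValidationError(
                "ran out of editable C positions (one site per codon)"
            )
        w = np.array([weights[p - 1] for p in open_classes])
        if w.sum() == 0:
            w = np.ones_like(w)
        p_class = int(rng.choice(open_classes, p=w / w.sum()))
        gene_id, pos = candidates[p_class].pop()
        codon_key = (gene_id, (pos - 1) // 3)
        if codon_key in used_codons:
            continue
        used_codons.add(codon_key)
        chosen.append((gene_id, pos))

    gene_by_id = {g.gene_id: g for g in genes}
    rows: list[EditSite] = []
    levels = {}
    for k, (gene_id, cds_pos) in enumerate(
        sorted(chosen, key=lambda t: (t[0], t[1]))
    ):
        gene = gene_by_id[gene_id]
        cds = transcripts[gene_id]
        codon_index = (cds_pos - 1) // 3 + 1
        cpos = (cds_pos - 1) % 3 + 1
        ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]
        outcome = effect_annotator.apply_edit(ref_codon, cpos, codon_index)
        rows.append(
            EditSite(
                gene_id=gene_id,
                genome_pos=gene.genome_position(cds_pos),
                cds_pos=cds_pos,
                codon_index=codon_index,
                codon_position=cpos,
                ref_aa=outcome.ref_aa,
                alt_aa=outcome.alt_aa,
                effect=outcome.effect,
                organelle=genome.organelle,
                ref_codon=ref_codon,
                alt_codon=outcome.alt_codon,
            )
        )
        base_level = config.level_distribution[k % len(config.level_distribution)]
        levels[f"{gene_id}:{cds_pos}"] = [
            min(1.0, max(0.0, base_level * f))
            for f in config.sample_level_factors
        ]

    true_levels = pd.DataFrame.from_dict(
        levels, orient="index", columns=list(config.sample_ids)
    )
    return TruthSet(
        genome=genome,
        genes=genes,
        sites=SiteTable(rows=rows, provenance="simulated"),
        true_levels=true_levels,
        config=config,
    )


def _error_probs(true_base: str, error: float) -> np.ndarray:
    probs = np.full(4, error / 3)
    probs[BASES.index(true_base)] = 1.0 - error
    return probs


def simulate_pileups(
    truth: TruthSet, config: Optional[SimulationConfig] = None
) -> dict[str, list[PileupPair]]:
    """Sample DNA/RNA pileups for every genic position, per sample.

    DNA reads draw the true genome base with probability 1−e and a
    uniform wrong base otherwise.  RNA reads at a planted site draw the
    edited transcript base (T) with probability equal to that sample's
    true level, then pass through the same error channel; unedited
    positions mirror the genome.  Counts are recorded on the forward
    strand (a − strand gene's edited C therefore shows up as G→A until
    strand-folded by the caller).
    """
    if config is None:
        config = truth.config
    rng = _rng(config, 2)
    site_by_genome_pos = {s.genome_pos: s for s in truth.sites}
    error = config.sequencing_error_rate

    out: dict[str, list[PileupPair]] = {}
    for sample_index, sample_id in enumerate(config.sample_ids):
        pileups = []
        for gene in truth.genes:
            positions = sorted(
                pos for a, b in gene.segments for pos in range(a, b + 1)
            )
            for pos in positions:
                genome_base = truth.genome.base(pos)
                dna = rng.multinomial(
                    config.dna_coverage, _error_probs(genome_base, error)
                )
                site = site_by_genome_pos.get(pos)
                if site is not None and site.gene_id == gene.gene_id:
                    level = truth.site_level(site, sample_id)
                    # transcript-strand C edited to T with prob = level,
                    # mapped back to the forward strand for the pileup
                    edited_fwd = "T" if gene.strand == "+" else "A"
                    probs = level * _error_probs(edited_fwd, error) + (
                        1.0 - level
                    ) * _error_probs(genome_base, error)
                    rna = rng.multinomial(config.rna_coverage, probs)
                else:
                    rna = rng.multinomial(
                        config.rna_coverage, _error_probs(genome_base, error)
                    )
                pileups.append(
                    PileupPair(
                        genome_pos=pos,
                        dna_counts=dict(zip(BASES, dna.tolist())),
                        rna_counts=dict(zip(BASES, rna.tolist())),
                        strand_of_gene=gene.strand,
                    )
                )
        pileups.sort(key=lambda p: p.genome_pos)
        out[sample_id] = pileups
    return out


def simulate_peaks(
    truth: TruthSet, config: Optional[SimulationConfig] = None
) -> pd.DataFrame:
    """Chromatogram-style peak heights per site and sample.

    h_T = scale·level·(1+ε) and h_C = scale·(1−level)·(1+ε′) with ε
    multiplicative Gaussian noise of CV ``peak_noise_cv``, truncated at 0.
    """
    if config is None:
        config = truth.config
    rng = _rng(config, 3)
    rows = []
    for site in truth.sites:
        for sample_id in config.sample_ids:
            level = truth.site_level(site, sample_id)
            eps_t, eps_c = rng.normal(0.0, config.peak_noise_cv, size=2)
            h_t = max(0.0, config.peak_scale * level * (1.0 + eps_t))
            h_c = max(0.0, config.peak_scale * (1.0 - level) * (1.0 + eps_c))
            rows.append(
                {
                    "gene": site.gene_id,
                    "cds_pos": site.cds_pos,
                    "sample": sample_id,
                    "h_A": 0.0,
                    "h_C": round(h_c, 3),
                    "h_G": 0.0,
                    "h_T": round(h_t, 3),
                }
            )
    return pd.DataFrame(rows)


def synthetic_code_table() -> PprCodeTable:
    """A deterministic synthetic PPR code table for simulations and tests.

    For each base there are two triples preferring it at 0.91, one pair
    at 0.85 and one single at 0.70, so that every base is reachable with
    probability ≥ 0.9 through some triple (the invertibility the positive
    construction needs).  Content is invented, not a transcription of any
    published code dataset.
    """
    strong = {"A": "TN", "C": "SN", "G": "TD", "T": "ND"}  # (res5, res_last)
    single_keys = {"A": "E", "C": "Q", "G": "K", "T": "R"}
    triples = {}
    pairs = {}
    singles = {}
    for base, (r5, rl) in strong.items():
        vec = [0.03, 0.03, 0.03, 0.03]
        vec["ACGT".index(base)] = 0.91
        triples[("V", r5, rl)] = list(vec)
        triples[("I", r5, rl)] = list(vec)
        pvec = [0.05, 0.05, 0.05, 0.05]
        pvec["ACGT".index(base)] = 0.85
        pairs[(r5, rl)] = pvec
        svec = [0.10, 0.10, 0.10, 0.10]
        svec["ACGT".index(base)] = 0.70
        singles[single_keys[base]] = svec
    return PprCodeTable(
        triples=triples, pairs=pairs, singles=singles,
        background=[0.25, 0.25, 0.25, 0.25],
    )


_PLS_CYCLE = ("P", "L", "S")


def simulate_ppr(
    truth: TruthSet,
    code_table: PprCodeTable,
    config: Optional[SimulationConfig] = None,
) -> tuple[list[PprProtein], pd.DataFrame]:
    """Build PPR proteins: positives matching planted windows, plus decoys.

    Each positive picks a planted site whose 51-nt centered window is
    fully available, chooses a 7–12-nt subwindow (the consensus of a
    window shorter than 7 cannot reach p ≤ 1e-4 against a uniform
    background, since min p = (1/4)^w), and emits one
    nucleotide-specifying motif per base whose triple prefers that base
    at ≥ 0.9 in ``code_table`` (plus a trailing E and DYW motif, which
    contribute no PWM column).  Decoys draw triples uniformly from the
    table.  Returns the proteins and a table of intended
    (protein, target, offset) pairs (empty for decoys).
    """
    if config is None:
        config = truth.config
    rng = _rng(config, 4)

    # invert the table: strongest triple per base
    best: dict[str, tuple] = {}
    for key, vec in code_table.triples.items():
        b = "ACGT"[int(np.argmax(vec))]
        if max(vec) >= 0.9 and b not in best:
            best[b] = key
    missing = [b for b in "ACGT" if b not in best]
    if missing:
        raise ValidationError(
            f"code table has no >=0.9 triple for bases {missing}: "
            "cannot build guaranteed positives"
        )

    gene_by_id = {g.gene_id: g for g in truth.genes}
    eligible = []
    for site in truth.sites:
        gene = gene_by_id[site.gene_id]
        if site.cds_pos > 25 and site.cds_pos + 25 <= len(gene):
            eligible.append(site)
    if config.n_ppr_positive > 0 and not eligible:
        raise ValidationError("no site has a full 51-nt window for positives")

    proteins: list[PprProtein] = []
    intended = []
    all_triples = list(code_table.triples.keys())
    for i in range(config.n_ppr_positive):
        site = eligible[i % len(eligible)]
        gene = gene_by_id[site.gene_id]
        tx = transcript_sequence(truth.genome, gene)
        window = tx[site.cds_pos - 26 : site.cds_pos + 25]
        w = int(rng.integers(7, 13))
        offset = int(rng.integers(0, 52 - w))
        sub = window[offset : offset + w]
        motifs = [
            PprMotif(_PLS_CYCLE[j % 3], *best[base])
            for j, base in enumerate(sub)
        ]
        motifs.append(PprMotif("E", "V", "T", "D"))
        motifs.append(PprMotif("DYW", "V", "T", "D"))
        pid = f"PPR_pos{i + 1:02d}"
        proteins.append(PprProtein(protein_id=pid, motifs=tuple(motifs)))
        intended.append(
            {
                "protein_id": pid,
                "target_id": f"{site.gene_id}:{site.cds_pos}",
                "offset": offset,
                "length": w,
            }
        )
    for i in range(config.n_ppr_decoy):
        w = int(rng.integers(6, 13))
        motifs = [
            PprMotif(
                _PLS_CYCLE[j % 3],
                *all_triples[int(rng.integers(len(all_triples)))],
            )
            for j in range(w)
        ]
        motifs.append(PprMotif("E", "V", "T", "D"))
        proteins.append(
            PprProtein(protein_id=f"PPR_decoy{i + 1:02d}", motifs=tuple(motifs))
        )
    return proteins, pd.DataFrame(intended)


def write_truth_set(truth: TruthSet, out_dir) -> None:
    """Write a truth set in the same dialects the other modules read.

    genome.fasta, genes.gff3, truth_sites.tsv, true_levels.tsv and a
    manifest recording the config for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([truth.genome], out / "genome.fasta")
    write_gff(truth.genes, out / "genes.gff3")
    write_site_table(truth.sites, out / "truth_sites.tsv")
    truth.true_levels.to_csv(out / "true_levels.tsv", sep="\t", index_label="site")
    with open(out / "manifest.txt", "w") as fh:
        for key, value in vars(truth.config).items():
            fh.write(f"{key} = {value!r}\n")
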