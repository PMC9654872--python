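"""C-to-U editing-site calling from paired DNA/RNA evidence.

Two evidence models are supported.  ``call_from_pair`` compares an
aligned genomic-DNA amplicon against its cDNA counterpart base by base
(the Sanger-validation route).  ``call_from_pileups`` applies threshold
filters to per-position base counts from a DNA sample and an RNA sample
(the sequencing route): a site is called C-to-U when DNA coverage is
adequate and effectively homozygous C on the transcript strand, and the
RNA sample shows enough T evidence.

Only transcript-strand C→T differences are emitted as editing calls;
every other DNA/RNA difference that passes the same evidence filters is
retained with ``is_c_to_u=False`` so contrary evidence is never hidden.
Heteroplasmy cannot be distinguished from editing by this evidence model;
the DNA minor-allele fraction is carried on every call for downstream
judgement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .orgdata import OrgreditError, ParseError, ValidationError

__all__ = [
    "PileupPair",
    "CallerParams",
    "CandidateSite",
    "strand_fold",
    "call_from_pair",
    "call_from_pileups",
    "read_pileups",
    "write_pileups",
    "write_calls",
]

BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PileupPair:
    """Per-position base counts for a DNA sample and an RNA sample.

    Counts are on the forward (reference) strand; ``strand_of_gene``
    says how to fold them onto the transcript strand.
    """

    genome_pos: int
    dna_counts: dict
    rna_counts: dict
    strand_of_gene: str = "unknown"

    def __post_init__(self) -> None:
        for name, counts in (("dna", self.dna_counts), ("rna", self.rna_counts)):
            clean = {b: int(counts.get(b, 0)) for b in BASES}
            if any(v < 0 for v in clean.values()):
                raise ValidationError(
                    f"pos {self.genome_pos}: negative {name} counts"
                )
            object.__setattr__(self, f"{name}_counts", clean)
        if self.strand_of_gene not in ("+", "-", "unknown"):
            raise ValidationError(
                f"pos {self.genome_pos}: bad strand {self.strand_of_gene!r}"
            )


@dataclass(frozen=True)
class CallerParams:
    """Threshold filters for pileup-based calling.

    Defaults are conservative and fully overridable: 10x coverage on both
    samples, at least 3 edited reads, editing frequency at least 5%, and
    at most 5% non-reference DNA reads (the homozygosity guard against
    SNPs/heteroplasmy).
    """

    min_dna_cov: int = 10
    min_rna_cov: int = 10
    min_edited_reads: int = 3
    min_editing_freq: float = 0.05
    max_dna_alt_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_editing_freq <= 1.0:
            raise ValidationError("min_editing_freq outside [0, 1]")
        if not 0.0 <= self.max_dna_alt_fraction < 0.5:
            raise ValidationError("max_dna_alt_fraction outside [0, 0.5)")
        for name in ("min_dna_cov", "min_rna_cov", "min_edited_reads"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CandidateSite:
    """One DNA/RNA difference, on the transcript strand."""

    genome_pos: int
    ref_base: str
    alt_base: str
    editing_freq: float
    dna_cov: int
    rna_cov: int
    is_c_to_u: bool
    dna_alt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.editing_freq <= 1.0:
            raise ValidationError("editing_freq outside [0, 1]")


def strand_fold(counts: dict, strand: str) -> dict:
    """Map forward-strand counts onto the transcript strand.

    '+' returns the counts unchanged; '-' swaps A↔T and C↔G.  An unknown
    strand is an error: the C/T test must not guess orientation.
    """
    if strand == "+":
        return {b: counts.get(b, 0) for b in BASES}
    if strand == "-":
        return {b: counts.get(_COMP[b], 0) for b in BASES}
    raise ValidationError(f"cannot strand-fold counts with strand {strand!r}")


def call_from_pair(gdna_seq: str, cdna_seq: str) -> list[CandidateSite]:
    """Compare aligned gDNA/cDNA sequences on the transcript strand.

    Positions where gDNA has C and cDNA has T are C-to-U calls with
    editing frequency 1.0; all other mismatches are reported with
    ``is_c_to_u=False``; matching positions are omitted.  The sequences
    must be pre-aligned and gap-free.
    """
    gdna = gdna_seq.upper().replace("U", "T")
    cdna = cdna_seq.upper().replace("U", "T")
    if len(gdna) != len(cdna):
        raise ValidationError(
            f"length mismatch: gDNA {len(gdna)} vs cDNA {len(cdna)}"
        )
    if "-" in gdna or "-" in cdna:
        raise ValidationError(
            "gap characters found: align the amplicons first and pass "
            "gap-free matched regions"
        )
    for seq, name in ((gdna, "gDNA"), (cdna, "cDNA")):
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValidationError(f"{name} has invalid characters {sorted(bad)}")
    out = []
    for i, (g, c) in enumerate(zip(gdna, cdna), start=1):
        if g == c or "N" in (g, c):
            continue
        out.append(
            CandidateSite(
                genome_pos=i,
                ref_base=g,
                alt_base=c,
                editing_freq=1.0,
                dna_cov=1,
                rna_cov=1,
                is_c_to_u=(g == "C" and c == "T"),
            )
        )
    return out


def call_from_pileups(
    pileups: Sequence[PileupPair], params: Optional[CallerParams] = None
) -> list[CandidateSite]:
    """Call editing sites from sorted DNA/RNA pileup pairs.

    On the transcript strand (counts complement-folded for − strand
    genes), a C-to-U site requires: DNA coverage ≥ ``min_dna_cov`` with C
    the majority base and non-C fraction ≤ ``max_dna_alt_fraction``; RNA
    coverage ≥ ``min_rna_cov``; RNA T reads ≥ ``min_edited_reads``; and
    T/(T+C) ≥ ``min_editing_freq``.  Differences for other base pairs
    passing the analogous filters are returned with ``is_c_to_u=False``.
    """
    if params is None:
        params = CallerParams()
    last = None
    calls: list[CandidateSite] = []
    for pile in pileups:
        if last is not None and pile.genome_pos <= last:
            raise ValidationError(
                f"pileups not sorted: {pile.genome_pos} after {last}"
            )
        last = pile.genome_pos

        dna = strand_fold(pile.dna_counts, pile.strand_of_gene)
        rna = strand_fold(pile.rna_counts, pile.strand_of_gene)
        dna_cov = sum(dna.values())
        rna_cov = sum(rna.values())
        if dna_cov < params.min_dna_cov or rna_cov < params.min_rna_cov:
            continue
        ref = max(BASES, key=lambda b: dna[b])
        alt_fraction = 1.0 - dna[ref] / dna_cov
        if alt_fraction > params.max_dna_alt_fraction:
            continue
        for alt in BASES:
            if alt == ref:
                continue
            n_alt = rna[alt]
            denom = n_alt + rna[ref]
            # a "difference" needs at least one alt read regardless of params
            if n_alt == 0 or n_alt < params.min_edited_reads or denom == 0:
                continue
            freq = n_alt / denom
            if freq < params.min_editing_freq:
                continue
            calls.append(
                CandidateSite(
                    genome_pos=pile.genome_pos,
                    ref_base=ref,
                    alt_base=alt,
                    editing_freq=freq,
                    dna_cov=dna_cov,
                    rna_cov=rna_cov,
                    is_c_to_u=(ref == "C" and alt == "T"),
                    dna_alt_fraction=alt_fraction,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# pileup / call TSV I/O
# ---------------------------------------------------------------------------

_PILEUP_COLUMNS = ["pos", "dA", "dC", "dG", "dT", "rA", "rC", "rG", "rT", "strand"]


def read_pileups(path) -> list[PileupPair]:
    """Read the pileup TSV dialect (pos, dA..dT, rA..rT, strand)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                PileupPair(
                    genome_pos=int(row.pos),
                    dna_counts={b: int(getattr(row, "d" + b)) for b in BASES},
                    rna_counts={b: int(getattr(row, "r" + b)) for b in BASES},
                    strand_of_gene=str(row.strand),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def write_pileups(pileups: Iterable[PileupPair], path) -> None:
    rows = []
    for p in pileups:
        row = {"pos": p.genome_pos}
        row.update({"d" + b: p.dna_counts[b] for b in BASES})
        row.update({"r" + b: p.rna_counts[b] for b in BASES})
        row["strand"] = p.strand_of_gene
        rows.append(row)
    pd.DataFrame(rows, columns=_PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def write_calls(calls: Iterable[CandidateSite], path) -> None:
    """Write calls with their evidence columns as TSV."""
    pd.DataFrame(
        [
            {
                "pos": c.genome_pos,
                "ref_base": c.ref_base,
                "alt_base": c.alt_base,
                "is_c_to_u": c.is_c_to_u,
                "editing_freq": round(c.editing_freq, 6),
                "dna_cov": c.dna_cov,
                "rna_cov": c.rna_cov,
                "dna_alt_fraction": round(c.dna_alt_fraction, 6),
            }
            for c in calls
        ],
        columns=[
            "pos",
            "ref_base",
            "alt_base",
            "is_c_to_u",
            "editing_freq",
            "dna_cov",
            "rna_cov",
            "dna_alt_fraction",
        ],
    ).to_csv(path, sep="\t", index=False)
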