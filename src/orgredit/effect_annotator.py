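"""Codon-level annotation of C-to-U editing sites.

Maps genome positions onto gene models (spliced, strand-aware), applies
the C→U edit to the affected codon, classifies the effect (synonymous /
missense / stop gain / start gain) and checks annotated tables against a
reference catalog.  Also provides the summary tallies used throughout:
per-gene site counts, the codon-position partition and amino-acid
transition spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import pandas as pd

from .orgdata import (
    EditSite,
    GeneModel,
    GenomeRecord,
    SiteTable,
    ValidationError,
    classify_effect,
    transcript_sequence,
    translate_codon,
)

__all__ = [
    "Location",
    "AnnotationResult",
    "locate",
    "codon_position",
    "apply_edit",
    "annotate_sites",
    "check_against_table",
    "codon_position_partition",
    "per_gene_counts",
    "aa_transition_counts",
    "achievable_codons",
    "achievable_with_coedits",
]

_BASES = "TCAG"


@dataclass(frozen=True)
class Location:
    """A genome position resolved to a feature-local transcript position."""

    gene: GeneModel
    position: int  # 1-based position on the spliced feature
    feature_class: str


def locate(genome_pos: int, genes: Sequence[GeneModel]) -> list[Location]:
    """All gene-model memberships of a genome position.

    Returns an empty list for intergenic positions and more than one
    entry when overlapping features claim the position — the caller must
    resolve ambiguity explicitly, no precedence is applied.
    """
    hits: list[Location] = []
    for gene in genes:
        tpos = gene.transcript_index(genome_pos)
        if tpos is not None:
            hits.append(Location(gene, tpos, gene.feature_class))
    return hits


def codon_position(cds_pos: int) -> int:
    """Position (1-3) within its codon of a 1-based spliced-CDS position."""
    if cds_pos < 1:
        raise ValidationError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) % 3 + 1


@dataclass(frozen=True)
class EditOutcome:
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str


def apply_edit(
    ref_codon: str, codon_pos: int, codon_index: Optional[int] = None
) -> EditOutcome:
    """Apply a single C→U edit at ``codon_pos`` (1-3) of ``ref_codon``.

    ``codon_index`` (the 1-based codon number in the CDS) is only needed
    to recognise start gain: an ACG→AUG conversion at codon 1 creates a
    new initiation codon.
    """
    ref_codon = ref_codon.upper().replace("U", "T")
    if codon_pos not in (1, 2, 3):
        raise ValidationError(f"codon position {codon_pos} outside 1..3")
    if len(ref_codon) != 3:
        raise ValidationError(f"not a codon: {ref_codon!r}")
    if ref_codon[codon_pos - 1] != "C":
        raise ValidationError(
            f"codon {ref_codon} has no C at position {codon_pos}: not editable"
        )
    alt_codon = ref_codon[: codon_pos - 1] + "T" + ref_codon[codon_pos:]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    effect = classify_effect(ref_aa, alt_aa, codon_index, alt_codon)
    return EditOutcome(alt_codon, ref_aa, alt_aa, effect)


@dataclass
class NoncodingSite:
    genome_pos: int
    feature_class: str  # 'tRNA', 'rRNA' or 'intergenic'
    gene_id: Optional[str] = None
    feature_pos: Optional[int] = None


@dataclass
class AnnotationResult:
    """Output of :func:`annotate_sites`: coding sites plus side reports."""

    sites: SiteTable
    noncoding: list[NoncodingSite] = field(default_factory=list)
    ambiguous: list[tuple[int, list[str]]] = field(default_factory=list)


def annotate_sites(
    candidates: Iterable,
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
) -> AnnotationResult:
    """Annotate called candidates (any objects with ``genome_pos``).

    Coding candidates become fully populated :class:`EditSite` rows;
    tRNA/rRNA and intergenic candidates are reported separately; a
    position claimed by two overlapping genes is reported as ambiguous
    listing all claimants, never silently resolved.  A candidate whose
    transcript-strand base is not C raises: its evidence contradicts the
    reference sequence.
    """
    coding: list[EditSite] = []
    noncoding: list[NoncodingSite] = []
    ambiguous: list[tuple[int, list[str]]] = []
    tx_cache: dict[str, str] = {}

    for cand in candidates:
        pos = cand.genome_pos
        hits = locate(pos, genes)
        if not hits:
            noncoding.append(NoncodingSite(pos, "intergenic"))
            continue
        if len(hits) > 1:
            ambiguous.append((pos, [h.gene.gene_id for h in hits]))
            continue
        loc = hits[0]
        if loc.feature_class != "CDS":
            noncoding.append(
                NoncodingSite(pos, loc.feature_class, loc.gene.gene_id, loc.position)
            )
            continue
        gene = loc.gene
        tx = tx_cache.get(gene.gene_id)
        if tx is None:
            tx = tx_cache[gene.gene_id] = transcript_sequence(genome, gene)
        cds_pos = loc.position
        if tx[cds_pos - 1] != "C":
            raise ValidationError(
                f"candidate at {pos} ({gene.gene_id} C{cds_pos}): reference "
                f"transcript base is {tx[cds_pos - 1]}, not C"
            )
        cpos = codon_position(cds_pos)
        codon_index = (cds_pos - 1) // 3 + 1
        start = (codon_index - 1) * 3
        ref_codon = tx[start : start + 3]
        outcome = apply_edit(ref_codon, cpos, codon_index)
        coding.append(
            EditSite(
                gene_id=gene.gene_id,
                genome_pos=pos,
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

    return AnnotationResult(
        sites=SiteTable(rows=coding, provenance="called"),
        noncoding=noncoding,
        ambiguous=ambiguous,
    )


@dataclass
class ConsistencyReport:
    per_row: pd.DataFrame
    n_match: int
    n_mismatch: int
    n_missing: int  # reference rows without an annotated counterpart
    n_extra: int  # annotated rows not in the reference

    @property
    def ok(self) -> bool:
        return self.n_mismatch == 0 and self.n_missing == 0 and self.n_extra == 0

    def summary(self) -> str:
        return (
            f"{self.n_match} match, {self.n_mismatch} mismatch, "
            f"{self.n_missing} missing, {self.n_extra} extra"
        )


def check_against_table(
    annotated: SiteTable, reference: SiteTable
) -> ConsistencyReport:
    """Row-by-row comparison of an annotated table against a reference.

    Rows are keyed by (gene, genome position); matched rows are compared
    on cds_pos, codon position and the amino-acid pair.
    """
    ref_by_key = {(s.gene_id, s.genome_pos): s for s in reference}
    ann_by_key = {(s.gene_id, s.genome_pos): s for s in annotated}
    records = []
    n_match = n_mismatch = 0
    for key, ref in ref_by_key.items():
        ann = ann_by_key.get(key)
        if ann is None:
            records.append(
                {"gene": key[0], "genome_position": key[1], "status": "missing"}
            )
            continue
        fields = {
            "cds_pos": (ann.cds_pos, ref.cds_pos),
            "codon_position": (ann.codon_position, ref.codon_position),
            "aa_change": ((ann.ref_aa, ann.alt_aa), (ref.ref_aa, ref.alt_aa)),
        }
        diffs = [name for name, (a, r) in fields.items() if a != r]
        if diffs:
            n_mismatch += 1
            records.append(
                {
                    "gene": key[0],
                    "genome_position": key[1],
                    "status": "mismatch:" + ",".join(diffs),
                }
            )
        else:
            n_match += 1
            records.append(
                {"gene": key[0], "genome_position": key[1], "status": "match"}
            )
    extra = [k for k in ann_by_key if k not in ref_by_key]
    for key in extra:
        records.append(
            {"gene": key[0], "genome_position": key[1], "status": "extra"}
        )
    n_missing = sum(1 for r in records if r["status"] == "missing")
    return ConsistencyReport(
        per_row=pd.DataFrame.from_records(records),
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_missing=n_missing,
        n_extra=len(extra),
    )


# ---------------------------------------------------------------------------
# summary tallies
# ---------------------------------------------------------------------------

def codon_position_partition(*tables: SiteTable) -> dict[int, int]:
    """Counts of sites at codon positions 1/2/3, pooled over tables."""
    out = {1: 0, 2: 0, 3: 0}
    for table in tables:
        for site in table:
            out[codon_position(site.cds_pos)] += 1
    return out


def per_gene_counts(table: SiteTable) -> pd.Series:
    """Number of sites per gene, descending."""
    counts = pd.Series([s.gene_id for s in table]).value_counts()
    counts.name = "n_sites"
    return counts


def aa_transition_counts(
    table: SiteTable, include_synonymous: bool = True
) -> pd.Series:
    """Counts of amino-acid transition types (e.g. ``S→L``).

    Both flavours are offered because the published per-organelle counts
    of transition types do not state whether synonymous rows were
    included; downstream reports print both and take no side.
    """
    labels = [
        f"{s.ref_aa}→{s.alt_aa}"
        for s in table
        if include_synonymous or s.ref_aa != s.alt_aa
    ]
    counts = pd.Series(labels).value_counts()
    counts.name = "n_sites"
    return counts


# ---------------------------------------------------------------------------
# achievability checks (64-codon search)
# ---------------------------------------------------------------------------

def achievable_codons(ref_aa: str, alt_aa: str, codon_pos: int) -> list[str]:
    """Codons with C at ``codon_pos`` realising ``ref_aa``→``alt_aa`` by one edit."""
    out = []
    for codon in map("".join, product(_BASES, repeat=3)):
        if codon[codon_pos - 1] != "C" or translate_codon(codon) != ref_aa:
            continue
        if apply_edit(codon, codon_pos).alt_aa == alt_aa:
            out.append(codon)
    return sorted(out)


def achievable_with_coedits(
    ref_aa: str, alt_aa: str, codon_pos: int, coedited_positions: Iterable[int] = ()
) -> list[str]:
    """Like :func:`achievable_codons`, but editing co-listed Cs jointly.

    Validated catalogs occasionally print, for each of two edited sites
    in the same codon, the amino-acid change produced by editing *both*
    (e.g. CCx→UUx giving P→F across a pair of rows).  Here the focal
    position and every position in ``coedited_positions`` that carries a
    C are edited together before translating.
    """
    positions = {codon_pos, *coedited_positions}
    if not positions <= {1, 2, 3}:
        raise ValidationError(f"codon positions outside 1..3: {positions}")
    out = []
    for codon in map("".join, product(_BASES, repeat=3)):
        if codon[codon_pos - 1] != "C" or translate_codon(codon) != ref_aa:
            continue
        edited = list(codon)
        for p in positions:
            if edited[p - 1] == "C":
                edited[p - 1] = "T"
        if translate_codon("".join(edited)) == alt_aa:
            out.append(codon)
    return sorted(out)
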