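"""Domain types and file I/O for organellar C-to-U RNA-editing analysis.

The central objects are :class:`GenomeRecord` (an organelle genome),
:class:`GeneModel` (a stranded, possibly multi-segment CDS/tRNA/rRNA
feature), :class:`EditSite` (one validated or called C-to-U event with
genome and spliced-CDS coordinates plus its codon-level effect) and
:class:`SiteTable` (a collection of sites with a provenance tag).

Two validated-site catalogs for the tea plant ship with the package
(``load_table1`` for the chloroplast, 38 sites over 22 genes;
``load_table2`` for the mitochondrion, 139 sites over 22 genes); they are
transcribed verbatim from the published tables, including a handful of
internally inconsistent rows which are preserved as printed and surfaced
by the consistency checks in :mod:`orgredit.effect_annotator`.

Coordinate conventions: genome positions are 1-based inclusive (GFF3
style); CDS positions are 1-based on the spliced transcript with position
1 the first base of the start codon, so an ``C701``-style token means the
701st transcript base carries the edited C. The standard genetic code
(translation table 1) is used for both organelles and stop is written
``X`` to match the catalogs' ``R→X`` notation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OrgreditError",
    "ParseError",
    "ValidationError",
    "GenomeRecord",
    "GeneModel",
    "EditSite",
    "SiteTable",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "load_site_table",
    "write_site_table",
    "load_table1",
    "load_table2",
    "transcript_sequence",
    "translate_codon",
    "reverse_complement",
    "classify_effect",
    "infer_strands",
]

VALID_BASES = frozenset("ACGTN")
ORGANELLES = ("chloroplast", "mitochondrion")
FEATURE_CLASSES = ("CDS", "tRNA", "rRNA")
EFFECTS = ("synonymous", "missense", "stop_gain", "start_gain")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_AA_CHANGE_RE = re.compile(r"^([A-Z])(\d+)(?:→|->)([A-Z])(\d+)$")
_EDITED_NT_RE = re.compile(r"^([ACGT])(\d+)$")


class OrgreditError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(OrgreditError):
    """A file could not be parsed (message names the offending line)."""


class ValidationError(OrgreditError):
    """Input violated a documented invariant or precondition."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard code; stop is rendered ``X``."""
    if len(codon) != 3 or any(b not in "ACGTU" for b in codon.upper()):
        raise ValidationError(f"not a codon: {codon!r}")
    aa = str(Seq(codon.upper().replace("U", "T")).translate(table=1))
    return "X" if aa == "*" else aa


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeRecord:
    """One organelle genome sequence (upper-case, alphabet ACGTN)."""

    id: str
    sequence: str
    organelle: str = "chloroplast"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("genome record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"genome {self.id!r}: empty sequence")
        if self.organelle not in ORGANELLES:
            raise ValidationError(f"unknown organelle {self.organelle!r}")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValidationError(
                f"genome {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at a 1-based genome position."""
        if not 1 <= pos <= len(self.sequence):
            raise ValidationError(
                f"position {pos} outside genome {self.id!r} (1..{len(self)})"
            )
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene feature made of 1-based inclusive genome segments.

    ``segments`` are stored in transcription order: ascending genome
    coordinate on the + strand, descending on the − strand.  ``complete``
    marks a CDS that includes both the start and the stop codon, in which
    case its spliced length must be divisible by 3.
    """

    gene_id: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    feature_class: str = "CDS"
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown feature class "
                f"{self.feature_class!r}"
            )
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        if not segs:
            raise ValidationError(f"gene {self.gene_id!r}: no segments")
        for a, b in segs:
            if a > b or a < 1:
                raise ValidationError(
                    f"gene {self.gene_id!r}: bad segment ({a}, {b})"
                )
        ordered = sorted(segs)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 <= b1:
                raise ValidationError(
                    f"gene {self.gene_id!r}: overlapping segments "
                    f"({a1},{b1}) and ({a2},{b2})"
                )
        # normalize to transcription order
        segs = tuple(ordered if self.strand == "+" else ordered[::-1])
        object.__setattr__(self, "segments", segs)
        if self.feature_class == "CDS" and self.complete and len(self) % 3:
            raise ValidationError(
                f"gene {self.gene_id!r}: complete CDS length {len(self)} "
                "not divisible by 3"
            )

    def __len__(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    def transcript_index(self, genome_pos: int) -> Optional[int]:
        """1-based position on the spliced transcript, or None if outside."""
        offset = 0
        for a, b in self.segments:
            if a <= genome_pos <= b:
                local = (genome_pos - a) if self.strand == "+" else (b - genome_pos)
                return offset + local + 1
            offset += b - a + 1
        return None

    def genome_position(self, transcript_pos: int) -> int:
        """Genome coordinate of a 1-based transcript position."""
        if not 1 <= transcript_pos <= len(self):
            raise ValidationError(
                f"gene {self.gene_id!r}: transcript position {transcript_pos} "
                f"outside 1..{len(self)}"
            )
        offset = transcript_pos - 1
        for a, b in self.segments:
            width = b - a + 1
            if offset < width:
                return a + offset if self.strand == "+" else b - offset
            offset -= width
        raise AssertionError("unreachable")


def transcript_sequence(genome: GenomeRecord, gene: GeneModel) -> str:
    """Spliced transcript-strand sequence of a gene.

    Segments are extracted from the genome, reverse-complemented for −
    strand genes, and concatenated in transcription order.
    """
    parts = []
    for a, b in gene.segments:
        if b > len(genome) or a < 1:
            raise ValidationError(
                f"gene {gene.gene_id!r}: segment ({a},{b}) outside genome "
                f"{genome.id!r} (length {len(genome)})"
            )
        chunk = genome.sequence[a - 1 : b]
        parts.append(chunk if gene.strand == "+" else reverse_complement(chunk))
    return "".join(parts)


# ---------------------------------------------------------------------------
# edit sites
# ---------------------------------------------------------------------------

def classify_effect(
    ref_aa: str, alt_aa: str, codon_index: Optional[int], alt_codon: Optional[str]
) -> str:
    """Effect class of a C→U edit from its amino-acid pair.

    stop_gain when the edit creates a stop; start_gain when it creates an
    ATG at codon 1 (ACG→AUG); synonymous when the amino acid is unchanged;
    missense otherwise.  stop_loss cannot arise: no stop codon contains C.
    """
    if alt_aa == "X" and ref_aa != "X":
        return "stop_gain"
    if codon_index == 1 and (alt_codon == "ATG" or (ref_aa, alt_aa) == ("T", "M")):
        return "start_gain"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


@dataclass(frozen=True)
class EditSite:
    """One C-to-U editing event on a coding transcript.

    ``cds_pos`` is the 1-based position of the edited C on the spliced
    transcript; ``codon_position`` must satisfy ``((cds_pos-1) % 3) + 1``.
    ``ref_codon``/``alt_codon`` are populated when the genome is available;
    catalog rows parsed from TSV carry only the amino-acid pair.
    ``codon_index`` is the amino-acid number as printed in the source
    table; for a few catalog rows it disagrees with ``(cds_pos-1)//3 + 1``
    and is deliberately not cross-validated here.
    """

    gene_id: str
    genome_pos: int
    cds_pos: int
    codon_index: int
    codon_position: int
    ref_aa: str
    alt_aa: str
    effect: str
    organelle: str = "chloroplast"
    ref_base: str = "C"
    alt_base: str = "T"
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_base != "C":
            raise ValidationError(
                f"{self.gene_id} {self.genome_pos}: edited base must be C, "
                f"got {self.ref_base!r}"
            )
        if self.alt_base not in ("T", "U"):
            raise ValidationError(
                f"{self.gene_id} {self.genome_pos}: alt base must be T/U"
            )
        if self.cds_pos < 1:
            raise ValidationError("cds_pos must be >= 1")
        expected = (self.cds_pos - 1) % 3 + 1
        if self.codon_position != expected:
            raise ValidationError(
                f"{self.gene_id} C{self.cds_pos}: codon_position "
                f"{self.codon_position} inconsistent with cds_pos "
                f"(expected {expected})"
            )
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        if self.organelle not in ORGANELLES:
            raise ValidationError(f"unknown organelle {self.organelle!r}")
        if self.ref_codon is not None:
            if self.alt_codon is None:
                raise ValidationError("ref_codon given without alt_codon")
            p = self.codon_position - 1
            if self.ref_codon[p] != "C" or self.alt_codon[p] != "T":
                raise ValidationError(
                    f"{self.gene_id} C{self.cds_pos}: codons "
                    f"{self.ref_codon}->{self.alt_codon} are not a C→T edit "
                    f"at codon position {self.codon_position}"
                )
            if any(
                self.ref_codon[i] != self.alt_codon[i]
                for i in range(3)
                if i != p
            ):
                raise ValidationError(
                    f"{self.gene_id} C{self.cds_pos}: codons differ outside "
                    f"position {self.codon_position}"
                )
            if (
                translate_codon(self.ref_codon) != self.ref_aa
                or translate_codon(self.alt_codon) != self.alt_aa
            ):
                raise ValidationError(
                    f"{self.gene_id} C{self.cds_pos}: amino acids do not "
                    f"match codons {self.ref_codon}->{self.alt_codon}"
                )

    @property
    def aa_change(self) -> str:
        return (
            f"{self.ref_aa}{self.codon_index}→{self.alt_aa}{self.codon_index}"
        )


@dataclass
class SiteTable:
    """An ordered collection of edit sites with a provenance tag.

    ``inconsistencies`` records rows whose printed annotation disagreed
    with recomputation at load time (reported, never silently fixed).
    """

    rows: list[EditSite]
    provenance: str
    inconsistencies: list[str] = field(default_factory=list)

    PROVENANCES = ("paper_table_1", "paper_table_2", "called", "simulated")

    def __post_init__(self) -> None:
        if self.provenance not in self.PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        seen: set[tuple[int, str]] = set()
        for row in self.rows:
            key = (row.genome_pos, row.gene_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate site {row.gene_id}:{row.genome_pos}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def genes(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row.gene_id not in out:
                out.append(row.gene_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [s.gene_id for s in self.rows],
                "genome_position": [s.genome_pos for s in self.rows],
                "edited_nucleotide": [f"C{s.cds_pos}" for s in self.rows],
                "amino_acid_change": [s.aa_change for s in self.rows],
                "editing_type": ["C→T"] * len(self.rows),
                "position_in_codon": [s.codon_position for s in self.rows],
                "effect": [s.effect for s in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path, organelle: str = "chloroplast") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects (upper-cased)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1 is not a FASTA header")
    records = [
        GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), organelle=organelle)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_gff(path) -> list[GeneModel]:
    """Read CDS/tRNA/rRNA gene models from a GFF3 file.

    Multi-segment CDS features sharing a Parent (or ID) are grouped into
    one :class:`GeneModel`; segment ordering and validation (strand,
    overlap, frame completeness) happen in the GeneModel constructor.
    A ``partial=true`` attribute marks an incomplete CDS, lifting the
    length-divisible-by-3 requirement.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from exc

    grouped: dict[tuple[str, str], dict] = {}
    for ftype in FEATURE_CLASSES:
        for feat in db.features_of_type(ftype):
            if feat.strand not in "+-":
                raise ValidationError(
                    f"{path}: feature {feat.id!r} has unknown strand "
                    f"{feat.strand!r}"
                )
            name = (
                feat.attributes.get("Parent", [None])[0]
                or feat.attributes.get("gene", [None])[0]
                or feat.attributes.get("ID", [feat.id])[0]
            )
            # create_unique may suffix duplicated IDs with _1, _2 ...
            name = re.sub(r"_\d+$", "", name)
            key = (name, ftype)
            entry = grouped.setdefault(
                key, {"strand": feat.strand, "segments": [], "partial": False}
            )
            if entry["strand"] != feat.strand:
                raise ValidationError(
                    f"{path}: gene {name!r} mixes strands"
                )
            entry["segments"].append((feat.start, feat.end))
            if feat.attributes.get("partial", ["false"])[0].lower() == "true":
                entry["partial"] = True

    genes = [
        GeneModel(
            gene_id=name,
            strand=entry["strand"],
            segments=tuple(entry["segments"]),
            feature_class=ftype,
            complete=not entry["partial"],
        )
        for (name, ftype), entry in grouped.items()
    ]
    return genes


def write_gff(genes: Sequence[GeneModel], path, source: str = "orgredit") -> None:
    """Write gene models as minimal GFF3 (one line per segment)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.gene_id};Parent={gene.gene_id}"
            if not gene.complete:
                attrs += ";partial=true"
            for a, b in sorted(gene.segments):
                fh.write(
                    "\t".join(
                        [
                            "genome",
                            source,
                            gene.feature_class,
                            str(a),
                            str(b),
                            ".",
                            gene.strand,
                            "0" if gene.feature_class == "CDS" else ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# site tables (TSV)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "gene",
    "genome_position",
    "edited_nucleotide",
    "amino_acid_change",
    "position_in_codon",
)


def load_site_table(path, provenance: str, organelle: Optional[str] = None) -> SiteTable:
    """Load a TSV site table (the validated-catalog column layout).

    ``edited_nucleotide`` tokens like ``C701`` are split into the reference
    base (must be C) and the spliced-CDS position.  The printed
    position-in-codon column is cross-checked against
    ``((cds_pos-1) % 3) + 1``; any mismatch is recorded verbatim in the
    returned table's ``inconsistencies`` list (the recomputed value is
    what the EditSite carries, since its invariants demand it).
    """
    if organelle is None:
        organelle = "mitochondrion" if provenance == "paper_table_2" else "chloroplast"
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    rows: list[EditSite] = []
    notes: list[str] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        m = _EDITED_NT_RE.match(str(rec.edited_nucleotide))
        if not m:
            raise ParseError(
                f"{path} line {i}: bad edited_nucleotide "
                f"{rec.edited_nucleotide!r}"
            )
        ref_base, cds_pos = m.group(1), int(m.group(2))
        if ref_base != "C":
            raise ValidationError(
                f"{path} line {i}: edited nucleotide is {ref_base}, not C"
            )
        printed = int(rec.position_in_codon)
        if printed not in (1, 2, 3):
            raise ValidationError(
                f"{path} line {i}: position_in_codon {printed} outside 1..3"
            )
        computed = (cds_pos - 1) % 3 + 1
        if printed != computed:
            notes.append(
                f"line {i} ({rec.gene} C{cds_pos}): printed codon position "
                f"{printed}, recomputed {computed}"
            )
        m2 = _AA_CHANGE_RE.match(str(rec.amino_acid_change))
        if not m2:
            raise ParseError(
                f"{path} line {i}: bad amino_acid_change "
                f"{rec.amino_acid_change!r}"
            )
        ref_aa, codon_index, alt_aa = m2.group(1), int(m2.group(2)), m2.group(3)
        rows.append(
            EditSite(
                gene_id=str(rec.gene),
                genome_pos=int(rec.genome_position),
                cds_pos=cds_pos,
                codon_index=codon_index,
                codon_position=computed,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                effect=classify_effect(ref_aa, alt_aa, codon_index, None),
                organelle=organelle,
            )
        )
    return SiteTable(rows=rows, provenance=provenance, inconsistencies=notes)


def write_site_table(table: SiteTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def _load_bundled(name: str, provenance: str) -> SiteTable:
    with resources.as_file(resources.files("orgredit") / "data" / name) as p:
        return load_site_table(p, provenance)


def load_table1() -> SiteTable:
    """Bundled validated chloroplast catalog (38 sites, 22 genes)."""
    return _load_bundled("table1_chloroplast.tsv", "paper_table_1")


def load_table2() -> SiteTable:
    """Bundled validated mitochondrial catalog (139 sites, 22 genes)."""
    return _load_bundled("table2_mitochondria.tsv", "paper_table_2")


def infer_strands(table: SiteTable) -> dict[str, str]:
    """Heuristically infer per-gene strand from a site catalog.

    The catalogs give genome and transcript coordinates but no strand.
    For genes with at least two sites, genome position increasing with
    cds_pos implies '+', decreasing implies '-'.  Genes with one site, or
    with a non-monotone relation, map to '?'.  This is metadata inference,
    never used for computation on the catalogs themselves.
    """
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for site in table:
        by_gene.setdefault(site.gene_id, []).append((site.cds_pos, site.genome_pos))
    out: dict[str, str] = {}
    for gene, pairs in by_gene.items():
        if len(pairs) < 2:
            out[gene] = "?"
            continue
        pairs.sort()
        deltas = [
            (g2 > g1) - (g2 < g1)
            for (_, g1), (_, g2) in zip(pairs, pairs[1:])
        ]
        if all(d > 0 for d in deltas):
            out[gene] = "+"
        elif all(d < 0 for d in deltas):
            out[gene] = "-"
        else:
            out[gene] = "?"
    return out
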