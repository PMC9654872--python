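"""Flanking-base context around editing sites and window export.

All windows are taken in transcript coordinates: splice junctions and
strand are resolved once by :func:`orgredit.orgdata.transcript_sequence`,
because editing factors bind the transcript, not the genome strand.
Sites whose window would cross a transcript boundary contribute only
their available positions; the per-position denominator of the context
matrix tracks this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .orgdata import (
    GeneModel,
    GenomeRecord,
    SiteTable,
    ValidationError,
    transcript_sequence,
)

__all__ = [
    "Window",
    "ContextMatrix",
    "flanking_window",
    "context_matrix",
    "export_windows",
]

BASES = ("A", "C", "G", "T")
CONTEXT_POSITIONS = tuple(p for p in range(-5, 6) if p != 0)


@dataclass(frozen=True)
class Window:
    """A transcript-strand window around one edited site."""

    sequence: str
    truncated: bool
    # how many requested upstream positions were actually available
    upstream_used: int
    downstream_used: int


def flanking_window(
    genome: GenomeRecord,
    gene: GeneModel,
    cds_pos: int,
    upstream: int,
    downstream: int,
    include_site: bool = True,
    allow_truncation: bool = False,
) -> Window:
    """Extract a transcript-strand window around ``cds_pos``.

    ``upstream``/``downstream`` count bases on either side of the edited
    position; the edited base itself is included only when
    ``include_site`` is set (centered windows include it, upstream-only
    exports do not).  Windows reaching past the transcript ends raise
    unless ``allow_truncation`` is set, in which case the available part
    is returned and flagged.
    """
    tx = transcript_sequence(genome, gene)
    if not 1 <= cds_pos <= len(tx):
        raise ValidationError(
            f"gene {gene.gene_id!r}: cds_pos {cds_pos} outside transcript "
            f"1..{len(tx)}"
        )
    lo = cds_pos - upstream
    hi = cds_pos + downstream
    truncated = lo < 1 or hi > len(tx)
    if truncated and not allow_truncation:
        raise ValidationError(
            f"gene {gene.gene_id!r}: window {lo}..{hi} around C{cds_pos} "
            f"crosses transcript bounds 1..{len(tx)} "
            "(pass allow_truncation=True to accept a shorter window)"
        )
    lo_c = max(lo, 1)
    hi_c = min(hi, len(tx))
    seq = tx[lo_c - 1 : cds_pos - 1]
    if include_site:
        seq += tx[cds_pos - 1]
    seq += tx[cds_pos:hi_c]
    return Window(
        sequence=seq,
        truncated=truncated,
        upstream_used=cds_pos - lo_c,
        downstream_used=hi_c - cds_pos,
    )


@dataclass
class ContextMatrix:
    """Per-position base frequencies at offsets −5..−1, +1..+5.

    ``counts`` and ``freq`` are DataFrames indexed by offset with columns
    A/C/G/T; ``n`` is the per-offset number of contributing sites (the
    truncation-aware denominator); ``n_sites`` the number of sites used.
    """

    counts: pd.DataFrame
    freq: pd.DataFrame
    n: pd.Series
    n_sites: int

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out["n"] = self.n
        out.to_csv(path, sep="\t", index_label="position")


def _gene_index(genes: Sequence[GeneModel]) -> dict[str, GeneModel]:
    return {g.gene_id: g for g in genes}


def context_matrix(
    sites: SiteTable,
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
) -> ContextMatrix:
    """Tally flanking bases at offsets −5..+5 (offset 0 excluded)."""
    if len(sites) == 0:
        raise ValidationError("context matrix of an empty site set")
    by_id = _gene_index(genes)
    counts = pd.DataFrame(
        0, index=list(CONTEXT_POSITIONS), columns=list(BASES), dtype=int
    )
    tx_cache: dict[str, str] = {}
    for site in sites:
        gene = by_id.get(site.gene_id)
        if gene is None:
            raise ValidationError(f"site gene {site.gene_id!r} not in gene set")
        tx = tx_cache.get(gene.gene_id)
        if tx is None:
            tx = tx_cache[gene.gene_id] = transcript_sequence(genome, gene)
        for offset in CONTEXT_POSITIONS:
            pos = site.cds_pos + offset
            if 1 <= pos <= len(tx):
                base = tx[pos - 1]
                if base in counts.columns:
                    counts.loc[offset, base] += 1
    n = counts.sum(axis=1)
    if (n == 0).any():
        # offsets where no site contributed stay all-zero with n=0
        freq = counts.div(n.replace(0, 1), axis=0).astype(float)
    else:
        freq = counts.div(n, axis=0)
    return ContextMatrix(counts=counts, freq=freq, n=n, n_sites=len(sites))


def export_windows(
    sites: SiteTable,
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    mode: str,
    path: Optional[str] = None,
) -> list[SeqRecord]:
    """Export per-site FASTA windows for external motif tools.

    ``mode='upstream25'`` gives the 25 bases 5′ of the edited C (site
    excluded); ``mode='centered51'`` gives positions −25..+25 including
    the site.  Records are named ``gene:cds_pos``; truncated windows are
    flagged in the description.  When ``path`` is given the records are
    also written as FASTA.
    """
    if mode == "upstream25":
        up, down, include = 25, 0, False
    elif mode == "centered51":
        up, down, include = 25, 25, True
    else:
        raise ValidationError(f"unknown window mode {mode!r}")
    by_id = _gene_index(genes)
    records = []
    for site in sites:
        gene = by_id.get(site.gene_id)
        if gene is None:
            raise ValidationError(f"site gene {site.gene_id!r} not in gene set")
        win = flanking_window(
            genome,
            gene,
            site.cds_pos,
            upstream=up,
            downstream=down,
            include_site=include,
            allow_truncation=True,
        )
        desc = "truncated" if win.truncated else ""
        records.append(
            SeqRecord(
                Seq(win.sequence),
                id=f"{site.gene_id}:{site.cds_pos}",
                description=desc,
            )
        )
    if path is not None:
        seqio_write(records, str(path), "fasta")
    return records
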