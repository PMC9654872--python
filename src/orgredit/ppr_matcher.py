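"""PPR-code-based prediction of editing-factor / target-site interactions.

Pentatricopeptide-repeat (PPR) proteins of the PLS subclass recognise
RNA in a modular fashion: each ~35-residue P/L/S motif binds one
nucleotide, and the identity-determining residues of the motif — here
the 2nd, 5th and last — form an empirical "PPR code" that maps to a base
preference.  This module turns an ordered list of motif codes into a
position weight matrix (one column per nucleotide-specifying motif,
N→C order mapping onto the target 5′→3′), scans 51-nt windows centered
on editing sites with summed log-odds scores against an i.i.d.
background, and converts scores to exact p-values by dynamic programming
over a discretized score lattice (the classical exact-scan approach).

E/E+/DYW motifs belong to the deaminase arm of the protein and
contribute no PWM column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .context_profile import export_windows
from .orgdata import (
    GeneModel,
    GenomeRecord,
    ParseError,
    SiteTable,
    ValidationError,
)

__all__ = [
    "PprMotif",
    "PprProtein",
    "PprCodeTable",
    "PwmModel",
    "ScanHit",
    "extract_codes",
    "build_pwm",
    "scan_window",
    "pwm_pvalue",
    "predict_interactions",
    "read_motif_table",
    "write_interactions",
]

MOTIF_CLASSES = ("P", "P1", "P2", "L", "L1", "L2", "S", "S1", "S2", "E", "E+", "DYW")
NUCLEOTIDE_SPECIFYING = frozenset(
    {"P", "P1", "P2", "L", "L1", "L2", "S", "S1", "S2"}
)
BASES = ("A", "C", "G", "T")  # internal alphabet; U is accepted and mapped to T
_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["U"] = _BASE_INDEX["T"]


@dataclass(frozen=True)
class PprMotif:
    """One PPR motif reduced to its code residues (positions 2, 5, last)."""

    motif_class: str
    residue_2: str
    residue_5: str
    residue_last: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValidationError(f"unknown motif class {self.motif_class!r}")
        for res in (self.residue_2, self.residue_5, self.residue_last):
            if res not in _AA_LETTERS:
                raise ValidationError(f"invalid amino-acid letter {res!r}")

    @property
    def specifies_nucleotide(self) -> bool:
        return self.motif_class in NUCLEOTIDE_SPECIFYING

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.residue_2, self.residue_5, self.residue_last)


@dataclass(frozen=True)
class PprProtein:
    """Ordered (N→C) motif codes of one PLS-class PPR protein."""

    protein_id: str
    motifs: tuple[PprMotif, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", tuple(self.motifs))
        if not any(m.specifies_nucleotide for m in self.motifs):
            raise ValidationError(
                f"protein {self.protein_id!r}: no nucleotide-specifying "
                "(P/L/S) motif"
            )


def extract_codes(
    protein_id: str, motif_sequences: Sequence[tuple[str, str]]
) -> PprProtein:
    """Reduce (motif_class, amino-acid sequence) pairs to code residues.

    The 2nd, 5th and last residues of each motif sequence are extracted,
    preserving N→C order; motifs shorter than 5 residues are an error.
    """
    motifs = []
    for motif_class, seq in motif_sequences:
        seq = seq.strip().upper()
        if len(seq) < 5:
            raise ValidationError(
                f"protein {protein_id!r}: motif sequence {seq!r} shorter "
                "than 5 residues"
            )
        motifs.append(
            PprMotif(
                motif_class=motif_class,
                residue_2=seq[1],
                residue_5=seq[4],
                residue_last=seq[-1],
            )
        )
    return PprProtein(protein_id=protein_id, motifs=tuple(motifs))


def _as_prob_vector(values, context: str) -> np.ndarray:
    vec = np.asarray(values, dtype=float)
    if vec.shape != (4,):
        raise ValidationError(f"{context}: need 4 probabilities")
    if (vec < 0).any():
        raise ValidationError(f"{context}: negative probability")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{context}: probabilities sum to {vec.sum()}")
    return vec


@dataclass
class PprCodeTable:
    """PPR code → base preference, with triple/pair/single fallback.

    Keys are the code residues (2nd, 5th, last); lookup tries the full
    triple, then (5th, last), then the last residue alone, then the
    background.  Vectors are probabilities over A/C/G/U.  The bundled
    tests use synthetic tables only; a transcription of a published code
    dataset can be supplied as TSV with columns
    ``res2  res5  res_last  pA  pC  pG  pU`` where ``.`` marks an unused
    key column (pair and single entries) and a row of three ``.`` gives
    the background.
    """

    triples: dict = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)
    singles: dict = field(default_factory=dict)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.triples = {
            k: _as_prob_vector(v, f"triple {k}") for k, v in self.triples.items()
        }
        self.pairs = {
            k: _as_prob_vector(v, f"pair {k}") for k, v in self.pairs.items()
        }
        self.singles = {
            k: _as_prob_vector(v, f"single {k}") for k, v in self.singles.items()
        }
        self.background = _as_prob_vector(self.background, "background")
        if (self.background <= 0).any():
            raise ValidationError("background must be strictly positive")

    def __len__(self) -> int:
        return len(self.triples) + len(self.pairs) + len(self.singles)

    def lookup(self, motif: PprMotif) -> np.ndarray:
        """Base preference for one motif (triple → pair → single → background)."""
        vec = self.triples.get(motif.triple)
        if vec is None:
            vec = self.pairs.get((motif.residue_5, motif.residue_last))
        if vec is None:
            vec = self.singles.get(motif.residue_last)
        if vec is None:
            vec = self.background
        return vec

    @classmethod
    def from_tsv(cls, path) -> "PprCodeTable":
        path = Path(path)
        if not path.exists():
            raise ParseError(f"{path}: no such file")
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = ["res2", "res5", "res_last", "pA", "pC", "pG", "pU"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        triples, pairs, singles = {}, {}, {}
        background = None
        for i, row in enumerate(df.itertuples(index=False), start=2):
            vec = [float(row.pA), float(row.pC), float(row.pG), float(row.pU)]
            keys = (row.res2, row.res5, row.res_last)
            blank = tuple(k in (".", "") for k in keys)
            if blank == (True, True, True):
                background = vec
            elif blank == (True, True, False):
                singles[row.res_last] = vec
            elif blank == (True, False, False):
                pairs[(row.res5, row.res_last)] = vec
            elif blank == (False, False, False):
                triples[keys] = vec
            else:
                raise ParseError(f"{path} line {i}: unsupported key pattern")
        kwargs = dict(triples=triples, pairs=pairs, singles=singles)
        if background is not None:
            kwargs["background"] = background
        return cls(**kwargs)

    def to_tsv(self, path) -> None:
        rows = []
        for (r2, r5, rl), v in self.triples.items():
            rows.append([r2, r5, rl, *v])
        for (r5, rl), v in self.pairs.items():
            rows.append([".", r5, rl, *v])
        for rl, v in self.singles.items():
            rows.append([".", ".", rl, *v])
        rows.append([".", ".", ".", *self.background])
        pd.DataFrame(
            rows, columns=["res2", "res5", "res_last", "pA", "pC", "pG", "pU"]
        ).to_csv(path, sep="\t", index=False)


class PwmModel:
    """Position weight matrix with log-odds scoring and exact p-values.

    ``probs`` has one row per nucleotide-specifying motif (after
    pseudocount and renormalisation), columns A/C/G/U.  Scores are summed
    log-odds in bits against the background.  P-values — the probability
    that an i.i.d. background sequence of length L scores at least as
    high — are computed by dynamic programming over a discretized score
    lattice; the lattice step is chosen so that the total rounding slack
    is at most ``discretization_bound`` bits, and the DP rounds
    conservatively (the reported p never undercuts the exact one).
    """

    #: lattice resolution: number of steps across the total score range
    LATTICE_STEPS = 100_000

    def __init__(
        self,
        probs,
        background=None,
        pseudocount: float = 0.0,
        protein_id: str = "",
    ) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValidationError("PWM must have shape (L >= 1, 4)")
        if pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        probs = probs + pseudocount
        row_sums = probs.sum(axis=1, keepdims=True)
        if (row_sums <= 0).any():
            raise ValidationError("PWM row sums to zero")
        self.probs = probs / row_sums
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM columns failed to normalise")
        self.background = _as_prob_vector(
            np.full(4, 0.25) if background is None else background, "background"
        )
        if (self.background <= 0).any():
            raise ValidationError("background must be strictly positive")
        self.pseudocount = float(pseudocount)
        self.protein_id = protein_id
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probs) - np.log2(self.background)
        self._lattice: Optional[tuple[float, int, np.ndarray]] = None

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    # -- exact p-value machinery -------------------------------------------

    def _score_lattice(self) -> tuple[float, int, np.ndarray]:
        """(step, min_int, tail) where tail[j] = P(score_int >= min_int + j)."""
        if self._lattice is not None:
            return self._lattice
        llr = self.log_odds
        finite = np.isfinite(llr)
        if not finite.any(axis=1).all():
            raise ValidationError("a PWM row has no finite log-odds entry")
        span = float(
            sum(
                llr[i][finite[i]].max() - llr[i][finite[i]].min()
                for i in range(self.length)
            )
        )
        step = max(span, 1e-9) / self.LATTICE_STEPS
        ints = np.where(finite, np.rint(llr / step), 0).astype(np.int64)
        mins = np.array(
            [ints[i][finite[i]].min() for i in range(self.length)]
        )
        maxs = np.array(
            [ints[i][finite[i]].max() for i in range(self.length)]
        )
        dist = np.zeros(int((maxs - mins).sum()) + 1)
        dist[0] = 1.0
        used = 1
        for i in range(self.length):
            width = int(maxs[i] - mins[i])
            new = np.zeros(used + width)
            for b in range(4):
                if not finite[i, b]:
                    continue  # -inf path: mass drops below every finite score
                shift = int(ints[i, b] - mins[i])
                new[shift : shift + used] += dist[:used] * self.background[b]
            dist, used = new, used + width
        tail = np.cumsum(dist[::-1])[::-1]
        self._lattice = (step, int(mins.sum()), tail)
        return self._lattice

    @property
    def discretization_bound(self) -> float:
        """Maximum total score slack introduced by lattice rounding (bits)."""
        step, _, _ = self._score_lattice()
        return step * self.length

    def pvalue(self, score: float) -> float:
        """P(background sequence of length L scores >= ``score``).

        Conservative under discretization: the true tail probability at
        ``score`` is never larger than the value returned; it is at least
        the exact tail at ``score - discretization_bound``.
        """
        if not math.isfinite(score):
            raise ValidationError("score must be finite")
        step, min_int, tail = self._score_lattice()
        # shift by half a lattice unit per position so rounding can only
        # lower the threshold (never miss achievable sequences)
        t = math.ceil(score / step - 0.5 * self.length - 1e-9) - min_int
        if t <= 0:
            return float(tail[0])
        if t >= len(tail):
            return 0.0
        return float(tail[t])

    def max_score(self) -> float:
        llr = np.where(np.isfinite(self.log_odds), self.log_odds, -np.inf)
        return float(llr.max(axis=1).sum())


def build_pwm(
    protein: PprProtein,
    codes: PprCodeTable,
    pseudocount: float = 0.01,
) -> PwmModel:
    """Compose a protein's base-preference matrix from a code table.

    One PWM column per nucleotide-specifying motif, in N→C order
    (mapping onto the target 5′→3′); E/E+/DYW motifs are skipped.  Each
    motif's vector comes from the code table's triple → pair → single →
    background fallback; the pseudocount is added and rows renormalised.
    """
    if len(codes) == 0:
        raise ValidationError("empty code table")
    rows = [
        codes.lookup(m) for m in protein.motifs if m.specifies_nucleotide
    ]
    if not rows:
        raise ValidationError(
            f"protein {protein.protein_id!r}: no nucleotide-specifying motif"
        )
    return PwmModel(
        np.vstack(rows),
        background=codes.background,
        pseudocount=pseudocount,
        protein_id=protein.protein_id,
    )


@dataclass(frozen=True)
class ScanHit:
    protein_id: str
    target_id: str
    offset: int  # 0-based match start within the window
    score: float  # bits
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def _encode(window: str) -> np.ndarray:
    window = window.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in window], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"invalid base {exc.args[0]!r} in window") from exc


def scan_window(
    pwm: PwmModel,
    window: str,
    threshold_p: float = 1e-4,
    target_id: str = "",
) -> list[ScanHit]:
    """Score every forward offset of ``window`` against the PWM.

    Returns hits with p-value ≤ ``threshold_p``, sorted by p ascending
    and ties broken by leftmost offset.
    """
    idx = _encode(window)
    L = pwm.length
    if len(idx) < L:
        raise ValidationError(
            f"window length {len(idx)} shorter than PWM length {L}"
        )
    hits = []
    for offset in range(len(idx) - L + 1):
        score = float(pwm.log_odds[np.arange(L), idx[offset : offset + L]].sum())
        if not math.isfinite(score):
            continue  # a zero-probability base under the PWM: no hit
        p = pwm.pvalue(score)
        if p <= threshold_p:
            hits.append(
                ScanHit(
                    protein_id=pwm.protein_id,
                    target_id=target_id,
                    offset=offset,
                    score=score,
                    p_value=p,
                )
            )
    hits.sort(key=lambda h: (h.p_value, h.offset))
    return hits


def pwm_pvalue(pwm: PwmModel, score: float) -> float:
    """Exact tail probability of ``score`` under the background (see PwmModel)."""
    return pwm.pvalue(score)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


@dataclass
class InteractionResult:
    """Interaction table plus the per-protein target-count summary."""

    table: pd.DataFrame
    summary: pd.DataFrame
    n_targets_hit: int
    n_proteins_hit: int


_TABLE_COLUMNS = [
    "protein_id",
    "target_id",
    "offset",
    "score_bits",
    "p_value",
    "q_value",
]


def predict_interactions(
    proteins: Sequence[PprProtein],
    codes: PprCodeTable,
    sites: SiteTable,
    genome: GenomeRecord,
    genes: Sequence[GeneModel],
    threshold_p: float = 1e-4,
    pseudocount: float = 0.01,
) -> InteractionResult:
    """Scan every protein against every site's 51-nt centered window.

    Per (protein, site) pair the best (lowest-p) hit is retained when its
    raw p-value is ≤ ``threshold_p``; Benjamini–Hochberg q-values over
    all scanned pairs are attached as an extra column but do not drive
    the filtering.  The summary bins proteins by how many target windows
    they hit ({1, 2, 3, 4, ≥5}).
    """
    windows = export_windows(sites, genome, genes, mode="centered51")
    best_rows = []
    for protein in proteins:
        pwm = build_pwm(protein, codes, pseudocount=pseudocount)
        for record in windows:
            hits = scan_window(
                pwm, str(record.seq), threshold_p=1.0, target_id=record.id
            )
            if not hits:
                continue
            best = hits[0]
            best_rows.append(
                {
                    "protein_id": protein.protein_id,
                    "target_id": record.id,
                    "offset": best.offset,
                    "score_bits": best.score,
                    "p_value": best.p_value,
                }
            )
    if not best_rows:
        empty = pd.DataFrame(columns=_TABLE_COLUMNS)
        summary = pd.DataFrame(
            {"n_proteins": [0] * 5, "fraction": [0.0] * 5},
            index=["1", "2", "3", "4", ">=5"],
        )
        return InteractionResult(empty, summary, 0, 0)

    frame = pd.DataFrame(best_rows)
    frame["q_value"] = _bh_qvalues(frame["p_value"].to_numpy())
    frame = frame[frame["p_value"] <= threshold_p].reset_index(drop=True)
    frame = frame[_TABLE_COLUMNS]

    per_protein = frame.groupby("protein_id")["target_id"].nunique()
    bins = {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
    for count in per_protein:
        bins[str(count) if count < 5 else ">=5"] += 1
    total = max(len(per_protein), 1)
    summary = pd.DataFrame(
        {
            "n_proteins": list(bins.values()),
            "fraction": [v / total for v in bins.values()],
        },
        index=list(bins.keys()),
    )
    return InteractionResult(
        table=frame,
        summary=summary,
        n_targets_hit=frame["target_id"].nunique(),
        n_proteins_hit=len(per_protein),
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_motif_table(path) -> list[PprProtein]:
    """Read a PPR motif TSV.

    Columns: ``protein_id, motif_index, motif_class`` plus either
    ``motif_sequence`` or explicit ``residue_2, residue_5, residue_last``.
    Returns one protein per id, motifs ordered by ``motif_index``.
    An empty table yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    df = pd.read_csv(path, sep="\t", dtype=str)
    base_cols = ["protein_id", "motif_index", "motif_class"]
    missing = [c for c in base_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    explicit = {"residue_2", "residue_5", "residue_last"} <= set(df.columns)
    if not explicit and "motif_sequence" not in df.columns:
        raise ParseError(
            f"{path}: need motif_sequence or residue_2/residue_5/residue_last"
        )
    proteins = []
    for protein_id, group in df.groupby("protein_id", sort=False):
        group = group.sort_values("motif_index", key=lambda s: s.astype(int))
        if explicit:
            motifs = tuple(
                PprMotif(
                    motif_class=row.motif_class,
                    residue_2=row.residue_2,
                    residue_5=row.residue_5,
                    residue_last=row.residue_last,
                )
                for row in group.itertuples(index=False)
            )
            proteins.append(PprProtein(protein_id=str(protein_id), motifs=motifs))
        else:
            proteins.append(
                extract_codes(
                    str(protein_id),
                    [
                        (row.motif_class, row.motif_sequence)
                        for row in group.itertuples(index=False)
                    ],
                )
            )
    return proteins


def write_interactions(result: InteractionResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)
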