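"""Per-site editing-level quantification.

The editing level (extent) of a site is the fraction of transcript
molecules carrying the edit.  From a Sanger chromatogram it is estimated
as the T peak height over the sum of the C and T peak heights; from read
counts it is T/(T+C) with a Wilson 95% confidence interval attached.
Measurements across sites and samples are tabulated into a site × sample
matrix; qualitative bins mirroring the usual narrative labels (<10%,
~30%, ~50%, >80%, ~100%) are available as convenience annotations and
are never used in computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .orgdata import ParseError, ValidationError

__all__ = [
    "EditingLevelMeasurement",
    "level_from_peaks",
    "level_from_counts",
    "level_table",
    "qualitative_bin",
    "read_peaks",
]


@dataclass(frozen=True)
class EditingLevelMeasurement:
    gene_id: str
    cds_pos: int
    sample_id: str
    method: str  # 'peaks' or 'reads'
    numerator: float  # T evidence
    denominator: float  # T + C evidence
    level: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("peaks", "reads"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.denominator <= 0:
            raise ValidationError("denominator must be positive")
        if not 0.0 <= self.level <= 1.0:
            raise ValidationError("level outside [0, 1]")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError("one-sided confidence interval")
        if self.ci_low is not None and not (
            self.ci_low <= self.level <= self.ci_high
        ):
            raise ValidationError("interval does not contain the level")

    @property
    def site_id(self) -> str:
        return f"{self.gene_id}:{self.cds_pos}"


def level_from_peaks(
    h_T: float,
    h_C: float,
    gene_id: str = "",
    cds_pos: int = 0,
    sample_id: str = "",
) -> EditingLevelMeasurement:
    """Editing level from chromatogram peak heights: T/(T+C)."""
    if h_T < 0 or h_C < 0:
        raise ValidationError("peak heights must be non-negative")
    if h_T + h_C == 0:
        raise ValidationError(
            "both C and T peaks are zero: editing level undefined"
        )
    return EditingLevelMeasurement(
        gene_id=gene_id,
        cds_pos=cds_pos,
        sample_id=sample_id,
        method="peaks",
        numerator=float(h_T),
        denominator=float(h_T + h_C),
        level=h_T / (h_T + h_C),
    )


def level_from_counts(
    n_T: int,
    n_C: int,
    gene_id: str = "",
    cds_pos: int = 0,
    sample_id: str = "",
    alpha: float = 0.05,
) -> EditingLevelMeasurement:
    """Editing level from read counts with a Wilson score interval."""
    if n_T != int(n_T) or n_C != int(n_C):
        raise ValidationError("read counts must be integers")
    n_T, n_C = int(n_T), int(n_C)
    if n_T < 0 or n_C < 0:
        raise ValidationError("read counts must be non-negative")
    total = n_T + n_C
    if total < 1:
        raise ValidationError("zero total reads: editing level undefined")
    low, high = proportion_confint(n_T, total, alpha=alpha, method="wilson")
    return EditingLevelMeasurement(
        gene_id=gene_id,
        cds_pos=cds_pos,
        sample_id=sample_id,
        method="reads",
        numerator=float(n_T),
        denominator=float(total),
        level=n_T / total,
        ci_low=float(low),
        ci_high=float(high),
    )


def qualitative_bin(level: float) -> str:
    """Narrative label for a level; annotation only, never computed with."""
    if not 0.0 <= level <= 1.0:
        raise ValidationError("level outside [0, 1]")
    if level < 0.10:
        return "<10%"
    if level < 0.40:
        return "~30%"
    if level < 0.65:
        return "~50%"
    if level < 0.95:
        return ">80%"
    return "~100%"


def level_table(
    measurements: Iterable[EditingLevelMeasurement],
    bins: bool = False,
) -> pd.DataFrame:
    """Site × sample matrix of editing levels (NaN where unmeasured).

    Duplicate (site, sample, method) entries are an error.  With
    ``bins=True`` the cells carry qualitative labels instead of numbers.
    """
    measurements = list(measurements)
    seen = set()
    for m in measurements:
        key = (m.site_id, m.sample_id, m.method)
        if key in seen:
            raise ValidationError(f"duplicate measurement {key}")
        seen.add(key)
    frame = pd.DataFrame(
        {
            "site": [m.site_id for m in measurements],
            "sample": [m.sample_id for m in measurements],
            "level": [m.level for m in measurements],
        }
    )
    if frame.empty:
        return pd.DataFrame()
    matrix = frame.pivot(index="site", columns="sample", values="level")
    if bins:
        matrix = matrix.map(
            lambda v: qualitative_bin(v) if pd.notna(v) else pd.NA
        )
    return matrix


def read_peaks(path) -> list[EditingLevelMeasurement]:
    """Read a peaks TSV (gene, cds_pos, sample, h_A, h_C, h_G, h_T)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = ["gene", "cds_pos", "sample", "h_C", "h_T"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                level_from_peaks(
                    h_T=float(row.h_T),
                    h_C=float(row.h_C),
                    gene_id=str(row.gene),
                    cds_pos=int(row.cds_pos),
                    sample_id=str(row.sample),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out
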