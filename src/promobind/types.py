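"""Core domain types for promoter-binding analysis.

Coordinate conventions
----------------------
All genomic coordinates are 0-based, half-open (BED convention).  A TSS
``position`` is the coordinate of the first transcribed base.  Offsets
relative to a TSS are strand-aware and signed: negative values lie
upstream of the gene, positive values downstream, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TSSRecord",
    "Peak",
    "SignalTrack",
    "ExpressionRecord",
    "GenomeSequence",
    "relative_offset",
]

_VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class TSSRecord:
    """A gene's transcription start site.

    Parameters
    ----------
    gene_id : str
        Non-empty gene identifier.
    chrom : str
        Chromosome name.
    position : int
        0-based coordinate of the first transcribed base.
    strand : str
        ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.position < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.position}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Peak:
    """A called binding interval with its center and log2 signal.

    ``center`` is ``floor((start + end) / 2)``; even-width ties resolve
    by floor.  The center, not the interval ends, is the unit used for
    promoter-window membership and peak-peak distances.
    """

    chrom: str
    start: int
    end: int
    signal: float = 0.0
    factor: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's log2 expression value."""

    gene_id: str
    expression: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


class SignalTrack:
    """Probe-level log2 signal measurements, ordered within chromosome.

    Stores one (chrom, position, value) triple per probe.  Positions must
    be strictly increasing within each chromosome.
    """

    def __init__(self, chroms: Iterable[str], positions: Iterable[int], values: Iterable[float]):
        df = pd.DataFrame(
            {
                "chrom": pd.Series(list(chroms), dtype=str),
                "position": np.asarray(list(positions), dtype=np.int64),
                "value": np.asarray(list(values), dtype=np.float64),
            }
        )
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
        self._df = df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignalTrack":
        return cls(df["chrom"], df["position"], df["value"])

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def by_chrom(self) -> Dict[str, pd.DataFrame]:
        return {str(c): sub.reset_index(drop=True) for c, sub in self._df.groupby("chrom", sort=False)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return self._df.equals(other._df)


_ALLOWED_BASES = frozenset("ACGTNacgtn")


class GenomeSequence:
    """Per-chromosome nucleotide strings with lowercase soft-masking.

    The alphabet is {A, C, G, T, N} in either case; lowercase marks
    repeat-masked (soft-masked) sequence per the UCSC convention.
    """

    def __init__(self, sequences: Mapping[str, str], validate: bool = True):
        if validate:
            for chrom, seq in sequences.items():
                bad = set(seq) - _ALLOWED_BASES
                if bad:
                    raise ValueError(
                        f"chromosome {chrom} contains bases outside ACGTN: {sorted(bad)!r}"
                    )
        self._seqs = dict(sequences)

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def items(self):
        return self._seqs.items()

    def region(self, chrom: str, start: int, end: int) -> str:
        """Extract [start, end), raising if out of chromosome bounds."""
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"region {chrom}:{start}-{end} out of bounds (length {len(seq)})"
            )
        return seq[start:end]


def relative_offset(peak_center: int, tss: TSSRecord, chrom: str | None = None) -> int:
    """Strand-aware signed offset of a position from a TSS.

    Negative offsets are upstream of the gene on either strand:
    plus strand  -> center - position
    minus strand -> position - center

    ``chrom`` (if given) must match the TSS chromosome.
    """
    if chrom is not None and chrom != tss.chrom:
        raise ValueError(f"chromosome mismatch: {chrom} vs {tss.chrom}")
    if tss.strand == "+":
        return int(peak_center) - tss.position
    return tss.position - int(peak_center)
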