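"""Readers and writers for the interchange formats.

BED-like peaks (chrom, start, end[, score]), bedGraph-like signal
(chrom, start, end, value; single-position probes use end = start + 1),
tab-separated TSS and expression tables, and soft-masked FASTA via
Biopython.  All downstream modules consume the parsed domain types;
nothing re-parses files.
"""

from __future__ import annotations

from typing import Dict, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionRecord, GenomeSequence, Peak, SignalTrack, TSSRecord

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_signal",
    "write_signal",
    "read_tss",
    "write_tss",
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
]


def _split(line: str) -> List[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_peaks(path, factor: str = "") -> List[Peak]:
    """Parse a BED-like peak file into peaks labeled with ``factor``.

    Columns: chrom, start, end and an optional log2-score column; a
    missing score is read as 0.0.  Malformed lines (non-integer
    coordinates, end <= start) raise with the offending line number.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = _split(line)
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            signal = float(fields[3]) if len(fields) > 3 else 0.0
            peaks.append(Peak(chrom=chrom, start=start, end=end, signal=signal, factor=factor))
    return peaks


def write_peaks(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.signal:g}\n")


def read_signal(path) -> SignalTrack:
    """Parse a bedGraph-like track; probe position is the interval start."""
    chroms, positions, values = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = _split(line)
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                start = int(fields[1])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
            chroms.append(fields[0])
            positions.append(start)
            values.append(value)
    return SignalTrack(chroms, positions, values)


def write_signal(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t{row.value:g}\n")


def read_tss(path) -> List[TSSRecord]:
    """Parse a TSS table: gene_id, chrom, position, strand."""
    records: List[TSSRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(
                    TSSRecord(
                        gene_id=fields[0], chrom=fields[1], position=int(fields[2]), strand=fields[3]
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_tss(records, path) -> None:
    with open(path, "w") as fh:
        for t in records:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.position}\t{t.strand}\n")


def read_expression(path) -> List[ExpressionRecord]:
    """Parse an expression table: gene_id, log2 expression.

    A duplicated gene_id is an error (one record per gene).
    """
    seen: Dict[str, int] = {}
    records: List[ExpressionRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene_id = fields[0]
            if gene_id in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r} (first at line {seen[gene_id]})"
                )
            seen[gene_id] = lineno
            records.append(ExpressionRecord(gene_id=gene_id, expression=float(fields[1])))
    return records


def write_expression(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.expression:g}\n")


def read_fasta(path) -> GenomeSequence:
    """Read a soft-masked FASTA; case is preserved (lowercase = repeat)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")
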