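"""Fixed-motif scanning and k-mer enrichment.

Exact-match scanning of short recognition motifs (homeodomain TAATCC
family, E-box CACGTG) over soft-masked genome sequence, motif-density
profiles anchored on TSSs or peak centers, motif frequency against gene
expression in fixed-size peak bins, and an iterative exhaustive k-mer
enrichment search over foreground/background sequence sets with
round-by-round masking of the winning k-mer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import GenomeSequence, Peak, TSSRecord, relative_offset

__all__ = [
    "MotifSet",
    "MotifDensityProfile",
    "EnrichedKmer",
    "default_motif_set",
    "scan_motif",
    "motif_density_profile",
    "motif_frequency_vs_expression",
    "kmer_enrichment_iterative",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifSet:
    """Named groups of exact recognition sequences.

    ``motifs`` maps a group name (e.g. "OTX2") to its member sequences.
    ``scan_both_strands`` also matches reverse complements (reported at
    the forward coordinate of their first base); ``respect_softmask``
    skips matches overlapping lowercase (repeat-masked) bases.
    """

    motifs: Dict[str, Tuple[str, ...]]
    scan_both_strands: bool = True
    respect_softmask: bool = False

    def __post_init__(self) -> None:
        for name, seqs in self.motifs.items():
            if not seqs:
                raise ValueError(f"motif group {name!r} is empty")
            for s in seqs:
                if not s or set(s) - set("ACGT"):
                    raise ValueError(
                        f"motif {s!r} in group {name!r} must be non-empty uppercase ACGT"
                    )

    def sequences(self) -> List[str]:
        return [s for seqs in self.motifs.values() for s in seqs]


def default_motif_set(**kwargs) -> MotifSet:
    """OTX2 homeodomain motifs plus the canonical E-box."""
    return MotifSet(
        motifs={"OTX2": ("TAATCC", "TAAGCC", "TAATCT"), "E-box": ("CACGTG",)}, **kwargs
    )


@dataclass
class MotifDensityProfile:
    """Per-bin motif presence around an anchor set.

    ``percent`` is the percentage of anchors whose bin window contains
    at least one occurrence; ``count_per_bp`` is total occurrences per
    anchor per bp (the normalized-count variant of the same curve).
    """

    anchor: str                       # "TSS" or "peak_center"
    window: Tuple[int, int]
    bin_width: int
    percent: Dict[str, np.ndarray]    # per motif sequence
    count_per_bp: Dict[str, np.ndarray]
    n_anchors: int
    masked: bool

    @property
    def bin_centers(self) -> np.ndarray:
        lo = self.window[0]
        n = (self.window[1] - lo) // self.bin_width
        return lo + self.bin_width * np.arange(n) + self.bin_width / 2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for motif, pct in self.percent.items():
            for c, p, d in zip(self.bin_centers, pct, self.count_per_bp[motif]):
                rows.append(
                    {"motif": motif, "bin_center": c, "percent": p, "count_per_bp": d}
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichedKmer:
    """One round's winning k-mer of the iterative enrichment search."""

    sequence: str
    length: int
    fg_count: int
    bg_count: int
    score: float      # log2 pseudocounted relative-frequency ratio
    round_index: int


def _find_occurrences(seq: str, motif: str, respect_softmask: bool) -> List[int]:
    upper = seq.upper()
    k = len(motif)
    out = []
    start = 0
    while True:
        i = upper.find(motif, start)
        if i == -1:
            break
        if not (respect_softmask and any(c.islower() for c in seq[i : i + k])):
            out.append(i)
        start = i + 1
    return out


def scan_motif(seq: str, motif_set: MotifSet) -> Dict[str, List[int]]:
    """All exact occurrence positions of each motif sequence in ``seq``.

    Overlapping matches are allowed.  With both-strand scanning the
    reverse complement is matched too and mapped to the forward
    coordinate of its first base; palindromes count once per position.
    Soft-mask handling per the motif set's flag.
    """
    result: Dict[str, List[int]] = {}
    for motif in motif_set.sequences():
        positions = set(_find_occurrences(seq, motif, motif_set.respect_softmask))
        if motif_set.scan_both_strands:
            rc = revcomp(motif)
            if rc != motif:
                positions.update(_find_occurrences(seq, rc, motif_set.respect_softmask))
        result[motif] = sorted(positions)
    return result


def motif_density_profile(
    genome: GenomeSequence,
    anchors: Sequence[Union[TSSRecord, Peak]],
    motif_set: Optional[MotifSet] = None,
    window: Tuple[int, int] = (-5000, 3000),
    bin_width: int = 50,
    masked: bool = False,
) -> MotifDensityProfile:
    """Motif density per 50 bp bin of distance to the anchors.

    TSS anchors use strand-aware signed offsets over ``window``; peak
    centers use unsigned offsets, folding the two flanks together over
    ``[0, window[1])``.  An occurrence is binned by its first base.
    Windows are clipped at chromosome ends.
    """
    if not anchors:
        raise ValueError("anchor set is empty")
    if motif_set is None:
        motif_set = default_motif_set()
    motif_set = MotifSet(
        motifs=motif_set.motifs,
        scan_both_strands=motif_set.scan_both_strands,
        respect_softmask=masked,
    )
    is_tss = isinstance(anchors[0], TSSRecord)
    if is_tss:
        lo, hi = window
    else:
        lo, hi = 0, window[1]
    if (hi - lo) % bin_width:
        raise ValueError("window must be a multiple of bin width")
    n_bins = (hi - lo) // bin_width

    presence = {m: np.zeros(n_bins, dtype=np.int64) for m in motif_set.sequences()}
    counts = {m: np.zeros(n_bins, dtype=np.int64) for m in motif_set.sequences()}

    for anchor in anchors:
        if is_tss:
            pos, chrom, strand = anchor.position, anchor.chrom, anchor.strand
            if strand == "+":
                a, b = pos + lo, pos + hi
            else:
                a, b = pos - hi + 1, pos - lo + 1
        else:
            pos, chrom, strand = anchor.center, anchor.chrom, "+"
            a, b = pos - window[1] + 1, pos + window[1]
        seq_len = len(genome[chrom])
        a_cl, b_cl = max(a, 0), min(b, seq_len)
        if b_cl <= a_cl:
            continue
        region = genome.region(chrom, a_cl, b_cl)
        hits = scan_motif(region, motif_set)
        for motif, positions in hits.items():
            seen = set()
            for p in positions:
                abs_pos = a_cl + p
                if is_tss:
                    off = relative_offset(abs_pos, anchor)
                else:
                    off = abs(abs_pos - pos)
                if not (lo <= off < hi):
                    continue
                b_idx = (off - lo) // bin_width
                counts[motif][b_idx] += 1
                seen.add(b_idx)
            for b_idx in seen:
                presence[motif][b_idx] += 1

    n = len(anchors)
    return MotifDensityProfile(
        anchor="TSS" if is_tss else "peak_center",
        window=(lo, hi),
        bin_width=bin_width,
        percent={m: 100.0 * v / n for m, v in presence.items()},
        count_per_bp={m: v / (n * bin_width) for m, v in counts.items()},
        n_anchors=n,
        masked=masked,
    )


def motif_frequency_vs_expression(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    expression: Mapping[str, float],
    peak_gene: Mapping[int, str],
    motif_set: Optional[MotifSet] = None,
    bin_size: int = 400,
) -> pd.DataFrame:
    """Motif frequency and mean expression per expression-sorted peak bin.

    ``peak_gene`` maps peak index (into ``peaks``) to its gene; peaks
    without a mapped gene or without an expression value are dropped and
    logged.  Peaks are stably sorted by ascending gene expression and
    binned per ``bin_size``; the final partial bin is kept and flagged.
    Frequency is the fraction of peaks in the bin containing >=1
    occurrence of the motif within the peak interval.
    """
    if motif_set is None:
        motif_set = default_motif_set()
    usable: List[Tuple[float, Peak]] = []
    n_dropped = 0
    for i, pk in enumerate(peaks):
        gene = peak_gene.get(i)
        if gene is None or gene not in expression:
            n_dropped += 1
            continue
        usable.append((expression[gene], pk))
    if n_dropped:
        logger.info("%d peaks without mapped expression dropped", n_dropped)
    if not usable:
        raise ValueError("no peaks with mapped expression")
    order = np.argsort([e for e, _ in usable], kind="stable")

    has_motif: Dict[str, List[bool]] = {m: [] for m in motif_set.sequences()}
    exprs = []
    for idx in order:
        e, pk = usable[idx]
        exprs.append(e)
        region = genome.region(pk.chrom, max(pk.start, 0), min(pk.end, len(genome[pk.chrom])))
        hits = scan_motif(region, motif_set)
        for m in has_motif:
            has_motif[m].append(bool(hits[m]))
    exprs_arr = np.asarray(exprs)

    rows = []
    n = len(exprs)
    for b, start in enumerate(range(0, n, bin_size)):
        end = min(start + bin_size, n)
        row = {
            "bin": b,
            "n_peaks": end - start,
            "partial": end - start < bin_size,
            "mean_expression": float(exprs_arr[start:end].mean()),
        }
        for m, flags in has_motif.items():
            row[f"freq_{m}"] = float(np.mean(flags[start:end]))
        rows.append(row)
    return pd.DataFrame(rows)


def _count_kmers(
    seqs: Sequence[str], lengths: Sequence[int]
) -> Tuple[Dict[int, Dict[str, int]], Dict[int, Dict[str, int]], Dict[int, int]]:
    """Exhaustive k-mer counts; windows containing non-ACGT characters
    are skipped.

    Returns per-length dicts of (a) both-strand counts keyed by the
    canonical orientation (lexicographic min of a k-mer and its reverse
    complement — the two always tie under double-strand counting), and
    (b) forward-strand-only counts keyed by literal k-mer, plus the
    per-length total both-strand window counts.
    """
    canon: Dict[int, Dict[str, int]] = {k: {} for k in lengths}
    forward: Dict[int, Dict[str, int]] = {k: {} for k in lengths}
    totals: Dict[int, int] = {k: 0 for k in lengths}
    valid = set("ACGT")
    for seq in seqs:
        up = seq.upper()
        for strand, s in enumerate((up, revcomp(up))):
            for k in lengths:
                d = canon[k]
                f = forward[k]
                for i in range(len(s) - k + 1):
                    w = s[i : i + k]
                    if set(w) <= valid:
                        c = min(w, revcomp(w))
                        d[c] = d.get(c, 0) + 1
                        totals[k] += 1
                        if strand == 0:
                            f[w] = f.get(w, 0) + 1
    return canon, forward, totals


def kmer_enrichment_iterative(
    foreground: Sequence[str],
    background: Sequence[str],
    lengths: Sequence[int] = (6, 7, 8),
    rounds: int = 15,
    pseudocount: float = 1.0,
) -> List[EnrichedKmer]:
    """Iterative exhaustive k-mer enrichment with masking.

    Each round counts every k-mer (both strands, all requested lengths)
    in foreground and background and scores reverse-complement k-mer
    classes by the log2 ratio of pseudocounted relative frequencies —
    under double-strand counting a k-mer and its reverse complement tie
    exactly, so the class is the scoring unit.  The top class wins (ties
    broken lexicographically on the canonical orientation) and is
    reported in the orientation more frequent on the foreground forward
    strand.  Its occurrences in either orientation are then replaced by
    N in the foreground and the search repeats for the given number of
    rounds; an exhausted foreground stops early with a warning.  The
    background is never masked.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    fg = [s.upper() for s in foreground]
    bg = [s.upper() for s in background]
    bg_counts, _, bg_totals = _count_kmers(bg, lengths)

    results: List[EnrichedKmer] = []
    for round_index in range(1, rounds + 1):
        fg_counts, fg_forward, fg_totals = _count_kmers(fg, lengths)
        best: Optional[Tuple[float, str]] = None
        for k in lengths:
            fgT = fg_totals[k]
            bgT = bg_totals[k]
            if fgT == 0:
                continue
            for w, c in fg_counts[k].items():
                score = float(
                    np.log2(
                        ((c + pseudocount) / (fgT + pseudocount))
                        / ((bg_counts[k].get(w, 0) + pseudocount) / (bgT + pseudocount))
                    )
                )
                if best is None or score > best[0] or (score == best[0] and w < best[1]):
                    best = (score, w)
        if best is None:
            warnings.warn(
                f"foreground exhausted after {round_index - 1} rounds", stacklevel=2
            )
            break
        score, canonical = best
        k = len(canonical)
        rc = revcomp(canonical)
        fwd = fg_forward[k]
        winner = rc if fwd.get(rc, 0) > fwd.get(canonical, 0) else canonical
        results.append(
            EnrichedKmer(
                sequence=winner,
                length=k,
                fg_count=fg_counts[k][canonical],
                bg_count=bg_counts[k].get(canonical, 0),
                score=score,
                round_index=round_index,
            )
        )
        fg = [_mask_kmer(s, winner) for s in fg]
    return results


def _mask_kmer(seq: str, kmer: str) -> str:
    """Replace every occurrence of ``kmer`` and its reverse complement
    with N (overlapping occurrences handled left to right)."""
    k = len(kmer)
    targets = {kmer, revcomp(kmer)}
    chars = list(seq)
    for t in targets:
        start = 0
        while True:
            i = seq.find(t, start)
            if i == -1:
                break
            chars[i : i + k] = "N" * k
            start = i + 1
    # second target must be searched on the original string, so apply
    # masks on a copy of positions rather than the mutated sequence
    return "".join(chars)
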