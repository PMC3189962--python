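"""Peak-to-promoter assignment and co-binding classification.

A promoter is "bound" by a factor when at least one peak center lies
within +/-2000 bp of its TSS (both endpoints inclusive).  OTX2-bound
promoters split into single (exactly one peak) and multiple (two or
more); crossing with the MYC flag yields the four co-binding classes,
plus MYC-only and unbound promoters outside them.  Enrichment of MYC
among multiple-OTX2 promoters is scored with an exact upper-tail
hypergeometric probability computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .types import Peak, TSSRecord

__all__ = [
    "PromoterBindingSummary",
    "ClassTable",
    "assign_binding",
    "classify_promoters",
    "hypergeometric_enrichment",
    "hypergeometric_point_probability",
]

DEFAULT_HALF_WINDOW = 2000

COBIND_CLASSES = ("single-MYC", "single+MYC", "multi-MYC", "multi+MYC", "MYC-only", "unbound")


@dataclass(frozen=True)
class PromoterBindingSummary:
    """Per-promoter binding state derived from peak assignments."""

    gene_id: str
    n_otx2_peaks: int
    myc_bound: bool

    @property
    def otx2_class(self) -> str:
        if self.n_otx2_peaks == 0:
            return "none"
        return "single" if self.n_otx2_peaks == 1 else "multiple"

    @property
    def cobind_class(self) -> str:
        if self.n_otx2_peaks == 0:
            return "MYC-only" if self.myc_bound else "unbound"
        stem = "single" if self.n_otx2_peaks == 1 else "multi"
        return f"{stem}{'+' if self.myc_bound else '-'}MYC"


@dataclass
class ClassTable:
    """Contingency counts with percentages on their natural denominators.

    Percentages: OTX2-bound, MYC-bound and co-bound are fractions of all
    promoters; single and multiple are fractions of OTX2-bound; MYC
    within single / within multiple are fractions of those subclasses.
    """

    total: int
    otx2_bound: int
    single: int
    multiple: int
    myc_bound: int
    cobound: int
    myc_and_single: int
    myc_and_multiple: int

    def __post_init__(self) -> None:
        if self.single + self.multiple != self.otx2_bound:
            raise ValueError("single + multiple must equal OTX2-bound")
        if self.myc_and_single > self.single or self.myc_and_multiple > self.multiple:
            raise ValueError("joint cells exceed their margins")

    def percentages(self) -> Dict[str, float]:
        """Full-precision percentages; 0 when a denominator is empty."""

        def pct(a: int, b: int) -> float:
            return 100.0 * a / b if b else 0.0

        return {
            "otx2_bound": pct(self.otx2_bound, self.total),
            "single_of_bound": pct(self.single, self.otx2_bound),
            "multiple_of_bound": pct(self.multiple, self.otx2_bound),
            "myc_bound": pct(self.myc_bound, self.total),
            "cobound": pct(self.cobound, self.total),
            "myc_within_single": pct(self.myc_and_single, self.single),
            "myc_within_multiple": pct(self.myc_and_multiple, self.multiple),
        }

    def report(self) -> Dict[str, float]:
        """Percentages rounded to one decimal for reporting."""
        return {k: round(v, 1) for k, v in self.percentages().items()}

    def enrichment_p(self) -> float:
        """Upper-tail hypergeometric P for MYC among multiple-OTX2
        promoters against the all-promoter background."""
        return hypergeometric_enrichment(
            self.total, self.myc_bound, self.multiple, self.myc_and_multiple
        )


def assign_binding(
    peaks: Sequence[Peak],
    tss_set: Sequence[TSSRecord],
    half_window: int = DEFAULT_HALF_WINDOW,
) -> Dict[str, List[Peak]]:
    """Assign each peak to every promoter whose TSS lies within
    ``half_window`` of the peak center (offset in [-w, +w], inclusive).

    Returns gene_id -> list of assigned peaks (every promoter present,
    possibly with an empty list).  A peak may land on several promoters.
    """
    out: Dict[str, List[Peak]] = {t.gene_id: [] for t in tss_set}
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for t in tss_set:
        by_chrom.setdefault(t.chrom, []).append((t.position, t.gene_id))
    arrays = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        arrays[chrom] = (
            np.asarray([p for p, _ in entries], dtype=np.int64),
            [g for _, g in entries],
        )
    for pk in peaks:
        if pk.chrom not in arrays:
            continue
        pos, genes = arrays[pk.chrom]
        c = pk.center
        i0 = np.searchsorted(pos, c - half_window, side="left")
        i1 = np.searchsorted(pos, c + half_window, side="right")
        for j in range(i0, i1):
            out[genes[j]].append(pk)
    return out


def classify_promoters(
    otx2_assignments: Dict[str, List[Peak]],
    myc_assignments: Dict[str, List[Peak]],
    tss_set: Sequence[TSSRecord],
) -> Tuple[List[PromoterBindingSummary], ClassTable]:
    """Build per-promoter summaries and the co-binding contingency table."""
    summaries = [
        PromoterBindingSummary(
            gene_id=t.gene_id,
            n_otx2_peaks=len(otx2_assignments.get(t.gene_id, ())),
            myc_bound=bool(myc_assignments.get(t.gene_id)),
        )
        for t in tss_set
    ]
    single = sum(1 for s in summaries if s.otx2_class == "single")
    multiple = sum(1 for s in summaries if s.otx2_class == "multiple")
    myc = sum(1 for s in summaries if s.myc_bound)
    cobound = sum(1 for s in summaries if s.myc_bound and s.n_otx2_peaks > 0)
    table = ClassTable(
        total=len(summaries),
        otx2_bound=single + multiple,
        single=single,
        multiple=multiple,
        myc_bound=myc,
        cobound=cobound,
        myc_and_single=sum(1 for s in summaries if s.cobind_class == "single+MYC"),
        myc_and_multiple=sum(1 for s in summaries if s.cobind_class == "multi+MYC"),
    )
    return summaries, table


def _log_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for the hypergeometric(N, K, n) law, via gammaln."""
    k = np.asarray(k, dtype=np.int64)
    return (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def _check_hypergeom_args(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= k <= n <= N):
        raise ValueError(f"require 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValueError(f"require k <= K <= N, got k={k}, K={K}, N={N}")


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Exact one-sided enrichment probability P(X >= k).

    X counts successes in a sample of ``n`` drawn without replacement
    from a population of ``N`` containing ``K`` successes.  The tail
    includes the observed count and is summed in log space so that
    extreme values (down to ~1e-300) remain accurate.
    """
    _check_hypergeom_args(N, K, n, k)
    upper = min(n, K)
    ks = np.arange(k, upper + 1)
    if ks.size == 0:
        return 0.0
    return float(np.exp(logsumexp(_log_pmf(ks, N, K, n))))


def hypergeometric_point_probability(N: int, K: int, n: int, k: int) -> float:
    """Exact point probability P(X = k) (the spreadsheet HYPGEOMDIST
    convention, reported by some studies in place of the tail)."""
    _check_hypergeom_args(N, K, n, k)
    return float(np.exp(_log_pmf(np.asarray([k]), N, K, n))[0])
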