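"""TSS-anchored aggregate binding profiles.

TSS list hygiene (minimum-spacing filter), mean-signal and
percent-bound-per-bin curves over a window around the TSS, mode
detection on binned profiles, and per-promoter heatmap matrices.

Binning convention: bins are half-open ``[x, x + bin_width)`` labeled by
their center ``x + bin_width/2``; offset 0 lies in the bin ``[0, bin_width)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import Peak, SignalTrack, TSSRecord

__all__ = [
    "BinnedProfile",
    "PromoterMatrix",
    "filter_tss",
    "mean_signal_profile",
    "peak_frequency_profile",
    "find_profile_modes",
    "promoter_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-5000, 3000)


@dataclass
class BinnedProfile:
    """A per-bin aggregate over TSS-relative offsets.

    ``values`` holds one number per bin (NaN where no data fell in the
    bin); ``kind`` is ``"mean_signal"`` or ``"percent_bound"``;
    ``n_informative`` counts the contributing items per bin.
    """

    window: Tuple[int, int]
    bin_width: int
    values: np.ndarray
    kind: str
    n_promoters: int
    n_informative: np.ndarray

    @property
    def n_bins(self) -> int:
        return (self.window[1] - self.window[0]) // self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        lo = self.window[0]
        return lo + self.bin_width * np.arange(self.n_bins) + self.bin_width / 2

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "value": self.values,
                "n_informative": self.n_informative,
            }
        )


@dataclass
class PromoterMatrix:
    """Per-promoter binned signal, rows sorted by an explicit key."""

    gene_ids: List[str]
    sort_values: np.ndarray
    matrix: np.ndarray            # promoters x bins, NaN = missing
    window: Tuple[int, int]
    bin_width: int

    def to_frame(self):
        import pandas as pd

        lo = self.window[0]
        cols = lo + self.bin_width * np.arange(self.matrix.shape[1]) + self.bin_width // 2
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=cols)


def _check_window(window: Tuple[int, int], bin_width: int) -> None:
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    if (hi - lo) % bin_width:
        raise ValueError(f"window {window} is not a multiple of bin width {bin_width}")


def filter_tss(tss_list: Sequence[TSSRecord], min_spacing: int = 150) -> List[TSSRecord]:
    """Drop alternative TSSs closer than ``min_spacing`` to the previous
    retained TSS of the same gene.

    Each gene's TSSs are scanned per chromosome in genomic order; a TSS
    is kept iff its distance to the last retained TSS of that gene is at
    least ``min_spacing``.  Output preserves the input order.
    """
    kept = set()
    groups: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for i, t in enumerate(tss_list):
        groups.setdefault((t.gene_id, t.chrom), []).append((t.position, i))
    for _, entries in groups.items():
        entries.sort()
        last: Optional[int] = None
        for pos, i in entries:
            if last is None or pos - last >= min_spacing:
                kept.add(i)
                last = pos
    return [t for i, t in enumerate(tss_list) if i in kept]


def _tss_arrays(tss_set: Sequence[TSSRecord]) -> Dict[str, Dict[str, np.ndarray]]:
    """Per chromosome: sorted positions, matching promoter indices and
    strand flags (+1 / -1)."""
    out: Dict[str, Dict[str, List]] = {}
    for i, t in enumerate(tss_set):
        d = out.setdefault(t.chrom, {"pos": [], "idx": [], "sgn": []})
        d["pos"].append(t.position)
        d["idx"].append(i)
        d["sgn"].append(1 if t.strand == "+" else -1)
    arrays = {}
    for chrom, d in out.items():
        pos = np.asarray(d["pos"], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        arrays[chrom] = {
            "pos": pos[order],
            "idx": np.asarray(d["idx"], dtype=np.int64)[order],
            "sgn": np.asarray(d["sgn"], dtype=np.int64)[order],
        }
    return arrays


def _per_promoter_bins(
    track: SignalTrack,
    tss_set: Sequence[TSSRecord],
    window: Tuple[int, int],
    bin_width: int,
):
    """Yield (promoter index, bin indices, probe values) for every probe
    falling in a promoter's strand-aware window."""
    lo, hi = window
    by_chrom_tss: Dict[str, List[int]] = {}
    for i, t in enumerate(tss_set):
        by_chrom_tss.setdefault(t.chrom, []).append(i)
    for chrom, sub in track.by_chrom().items():
        pos = sub["position"].to_numpy()
        val = sub["value"].to_numpy()
        for i in by_chrom_tss.get(chrom, ()):
            t = tss_set[i]
            if t.strand == "+":
                # probe p at offset p - position in [lo, hi)
                i0 = np.searchsorted(pos, t.position + lo, side="left")
                i1 = np.searchsorted(pos, t.position + hi, side="left")
                offs = pos[i0:i1] - t.position
            else:
                # offset position - p in [lo, hi)  <=>  p in (pos-hi, pos-lo]
                i0 = np.searchsorted(pos, t.position - hi, side="right")
                i1 = np.searchsorted(pos, t.position - lo, side="right")
                offs = t.position - pos[i0:i1]
            if i1 > i0:
                yield i, (offs - lo) // bin_width, val[i0:i1]


def mean_signal_profile(
    track: SignalTrack,
    tss_set: Sequence[TSSRecord],
    window: Tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = 50,
    per_promoter_mean: bool = False,
) -> BinnedProfile:
    """Mean log2 signal per bin of strand-aware TSS offset.

    Pools all (probe, promoter) assignments across promoters by default;
    ``per_promoter_mean=True`` averages per-promoter means instead.
    Bins with no probes are NaN.
    """
    _check_window(window, bin_width)
    n_bins = (window[1] - window[0]) // bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    if per_promoter_mean:
        # mean of per-promoter bin means
        prom_sums: Dict[int, np.ndarray] = {}
        prom_counts: Dict[int, np.ndarray] = {}
        for i, bins, vals in _per_promoter_bins(track, tss_set, window, bin_width):
            s = prom_sums.setdefault(i, np.zeros(n_bins))
            c = prom_counts.setdefault(i, np.zeros(n_bins, dtype=np.int64))
            np.add.at(s, bins, vals)
            np.add.at(c, bins, 1)
        for i, s in prom_sums.items():
            c = prom_counts[i]
            has = c > 0
            sums[has] += s[has] / c[has]
            counts[has] += 1
    else:
        for _, bins, vals in _per_promoter_bins(track, tss_set, window, bin_width):
            np.add.at(sums, bins, vals)
            np.add.at(counts, bins, 1)
    values = np.full(n_bins, np.nan)
    has = counts > 0
    values[has] = sums[has] / counts[has]
    return BinnedProfile(
        window=tuple(window),
        bin_width=bin_width,
        values=values,
        kind="mean_signal",
        n_promoters=len(tss_set),
        n_informative=counts,
    )


def peak_frequency_profile(
    peaks: Sequence[Peak],
    tss_set: Sequence[TSSRecord],
    window: Tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = 50,
) -> BinnedProfile:
    """Percentage of promoters with >=1 peak center per offset bin.

    A promoter with several peak centers in one bin counts once in that
    bin; values are percentages of ``len(tss_set)``.
    """
    _check_window(window, bin_width)
    lo, hi = window
    n_bins = (hi - lo) // bin_width
    arrays = _tss_arrays(tss_set)
    pairs = set()
    for pk in peaks:
        d = arrays.get(pk.chrom)
        if d is None:
            continue
        c = pk.center
        pos, idx, sgn = d["pos"], d["idx"], d["sgn"]
        # plus strand: offset c - pos in [lo, hi) -> pos in (c - hi, c - lo]
        i0 = np.searchsorted(pos, c - hi, side="right")
        i1 = np.searchsorted(pos, c - lo, side="right")
        for j in range(i0, i1):
            if sgn[j] == 1:
                pairs.add((int(idx[j]), int((c - pos[j] - lo) // bin_width)))
        # minus strand: offset pos - c in [lo, hi) -> pos in [c + lo, c + hi)
        i0 = np.searchsorted(pos, c + lo, side="left")
        i1 = np.searchsorted(pos, c + hi, side="left")
        for j in range(i0, i1):
            if sgn[j] == -1:
                pairs.add((int(idx[j]), int((pos[j] - c - lo) // bin_width)))
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, b in pairs:
        counts[b] += 1
    n = len(tss_set)
    values = 100.0 * counts / n if n else np.full(n_bins, np.nan)
    return BinnedProfile(
        window=tuple(window),
        bin_width=bin_width,
        values=np.asarray(values, dtype=float),
        kind="percent_bound",
        n_promoters=n,
        n_informative=counts,
    )


def find_profile_modes(profile: BinnedProfile, min_prominence: Optional[float] = None) -> List[float]:
    """Local maxima of a binned profile, as bin-center offsets.

    A mode is a bin (or plateau of equal bins) strictly higher than its
    informative neighbors; boundary maxima count.  Plateau ties resolve
    to the bin nearest the TSS.  Modes with prominence below
    ``min_prominence`` (default: 10% of the profile's range) are
    discarded.  Missing bins never form modes and behave as lower
    neighbors.
    """
    v = np.asarray(profile.values, dtype=float)
    informative = ~np.isnan(v)
    if informative.sum() == 0:
        raise ValueError("profile has no informative bins")
    if informative.sum() < 3:
        raise ValueError("profile needs >=3 informative bins for mode detection")
    if min_prominence is None:
        rng = np.nanmax(v) - np.nanmin(v)
        min_prominence = 0.1 * rng
    work = np.where(informative, v, -np.inf)
    centers = profile.bin_centers
    n = len(work)

    modes: List[float] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and work[j + 1] == work[i]:
            j += 1
        left_lower = i == 0 or work[i - 1] < work[i]
        right_lower = j == n - 1 or work[j + 1] < work[i]
        if np.isfinite(work[i]) and left_lower and right_lower:
            peak_val = work[i]
            # prominence: drop to the higher of the two bases, each base
            # being the minimum between the peak and the next higher
            # value (or the window edge)
            bases = []
            for direction, start in ((-1, i - 1), (1, j + 1)):
                base = None
                k = start
                while 0 <= k < n:
                    x = work[k]
                    if np.isfinite(x):
                        base = x if base is None else min(base, x)
                        if x > peak_val:
                            break
                    k += direction
                if base is not None:
                    bases.append(base)
            prominence = peak_val - max(bases) if bases else 0.0
            if prominence >= min_prominence:
                plateau = centers[i : j + 1]
                modes.append(float(plateau[np.argmin(np.abs(plateau))]))
        i = j + 1
    return sorted(modes)


def promoter_matrix(
    track: SignalTrack,
    tss_set: Sequence[TSSRecord],
    sort_key: Mapping[str, float],
    window: Tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = 50,
    min_informative_bins: int = 100,
) -> PromoterMatrix:
    """Per-promoter binned mean signal, rows sorted descending by key.

    Promoters with no sort key are excluded and logged; promoters with
    at most ``min_informative_bins`` informative bins are excluded (the
    filter requires strictly more).  Equal keys preserve input order
    (stable sort).
    """
    _check_window(window, bin_width)
    n_bins = (window[1] - window[0]) // bin_width
    n = len(tss_set)
    sums = np.zeros((n, n_bins))
    counts = np.zeros((n, n_bins), dtype=np.int64)
    for i, bins, vals in _per_promoter_bins(track, tss_set, window, bin_width):
        np.add.at(sums[i], bins, vals)
        np.add.at(counts[i], bins, 1)
    keep_idx: List[int] = []
    for i, t in enumerate(tss_set):
        if t.gene_id not in sort_key:
            logger.warning("promoter %s has no sort key; excluded from matrix", t.gene_id)
            continue
        if (counts[i] > 0).sum() > min_informative_bins:
            keep_idx.append(i)
    keys = np.asarray([sort_key[tss_set[i].gene_id] for i in keep_idx], dtype=float)
    order = np.argsort(-keys, kind="stable")
    rows = [keep_idx[o] for o in order]
    matrix = np.full((len(rows), n_bins), np.nan)
    for r, i in enumerate(rows):
        has = counts[i] > 0
        matrix[r, has] = sums[i, has] / counts[i, has]
    return PromoterMatrix(
        gene_ids=[tss_set[i].gene_id for i in rows],
        sort_values=keys[order],
        matrix=matrix,
        window=tuple(window),
        bin_width=bin_width,
    )
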