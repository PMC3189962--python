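"""Observed vs expected OTX2-MYC peak-center distances.

For promoters carrying exactly one OTX2 peak plus MYC binding, the
observed statistic is the distance from the OTX2 center to the nearest
MYC center.  The expected (null) distribution re-draws each OTX2 peak
offset uniformly over the +/-2000 bp binding window, keeping MYC peaks
and per-promoter peak counts fixed, and pools several randomizations.
Per distance range, a 2x2 Fisher exact test compares observed against
expected membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact

from .classes import DEFAULT_HALF_WINDOW, PromoterBindingSummary
from .types import Peak, TSSRecord

__all__ = [
    "DistanceResult",
    "DEFAULT_RANGES",
    "observed_distances",
    "randomized_null",
    "range_enrichment",
]

DEFAULT_RANGES: Tuple[Tuple[float, float], ...] = (
    (0, 200),
    (200, 400),
    (400, 800),
    (800, 1600),
    (1600, float("inf")),
)


@dataclass
class DistanceResult:
    """Per-range observed vs expected distance fractions with Fisher p."""

    observed: np.ndarray
    null: np.ndarray
    ranges: Tuple[Tuple[float, float], ...]
    observed_pct: np.ndarray
    expected_pct: np.ndarray
    p_values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "range_lo": [r[0] for r in self.ranges],
                "range_hi": [r[1] for r in self.ranges],
                "observed_pct": self.observed_pct,
                "expected_pct": self.expected_pct,
                "fisher_p": self.p_values,
            }
        )


def _single_myc_promoters(
    summaries: Sequence[PromoterBindingSummary],
    otx2_assignments: Dict[str, List[Peak]],
    myc_assignments: Dict[str, List[Peak]],
):
    for s in summaries:
        if s.cobind_class != "single+MYC":
            continue
        otx2 = otx2_assignments.get(s.gene_id, [])
        myc = myc_assignments.get(s.gene_id, [])
        if len(otx2) != 1:
            raise ValueError(
                f"promoter {s.gene_id} classified single but has {len(otx2)} OTX2 peaks"
            )
        if not myc:
            raise ValueError(f"promoter {s.gene_id} flagged MYC-bound but has no MYC peaks")
        yield s.gene_id, otx2[0].center, np.asarray([p.center for p in myc], dtype=np.int64)


def observed_distances(
    summaries: Sequence[PromoterBindingSummary],
    otx2_assignments: Dict[str, List[Peak]],
    myc_assignments: Dict[str, List[Peak]],
) -> np.ndarray:
    """|OTX2 center - nearest MYC center| per single+MYC promoter."""
    out = [
        int(np.min(np.abs(myc_centers - otx2_center)))
        for _, otx2_center, myc_centers in _single_myc_promoters(
            summaries, otx2_assignments, myc_assignments
        )
    ]
    return np.asarray(out, dtype=np.int64)


def randomized_null(
    summaries: Sequence[PromoterBindingSummary],
    otx2_assignments: Dict[str, List[Peak]],
    myc_assignments: Dict[str, List[Peak]],
    tss_set: Sequence[TSSRecord],
    R: int = 3,
    seed: int = 0,
    half_window: int = DEFAULT_HALF_WINDOW,
) -> np.ndarray:
    """Pooled null distances over ``R`` randomizations.

    Each randomization re-draws every OTX2 peak offset uniformly over
    [-half_window, +half_window] around its promoter's TSS (MYC peaks
    fixed, peak counts preserved) and recomputes the nearest-MYC
    distances for the single+MYC promoters.  Deterministic given seed.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    tss_pos = {t.gene_id: t.position for t in tss_set}
    entries = list(_single_myc_promoters(summaries, otx2_assignments, myc_assignments))
    pooled: List[int] = []
    for _ in range(R):
        for gene_id, _, myc_centers in entries:
            offset = rng.uniform(-half_window, half_window)
            center = int(round(tss_pos[gene_id] + offset))
            pooled.append(int(np.min(np.abs(myc_centers - center))))
    return np.asarray(pooled, dtype=np.int64)


def range_enrichment(
    observed: np.ndarray,
    null: np.ndarray,
    ranges: Sequence[Tuple[float, float]] = DEFAULT_RANGES,
) -> DistanceResult:
    """Per-range observed vs expected fractions with two-sided Fisher p.

    Ranges must partition [0, inf) as consecutive half-open intervals.
    The null pool is scaled to the observed total (rounded) so each
    Fisher table is integer-valued.
    """
    observed = np.asarray(observed)
    null = np.asarray(null)
    if observed.size == 0 or null.size == 0:
        raise ValueError("observed and null distance sets must be non-empty")
    ranges = tuple((float(lo), float(hi)) for lo, hi in ranges)
    if not ranges:
        raise ValueError("empty range set")
    if ranges[0][0] != 0 or ranges[-1][1] != float("inf"):
        raise ValueError("ranges must start at 0 and end at infinity")
    for (_, a), (b, _) in zip(ranges, ranges[1:]):
        if a != b:
            raise ValueError("ranges must be consecutive half-open intervals")

    n_obs = observed.size
    n_null = null.size
    obs_pct, exp_pct, ps = [], [], []
    for lo, hi in ranges:
        obs_in = int(np.sum((observed >= lo) & (observed < hi)))
        null_in = int(np.sum((null >= lo) & (null < hi)))
        exp_in = int(round(null_in / n_null * n_obs))
        table = [[obs_in, n_obs - obs_in], [exp_in, n_obs - exp_in]]
        ps.append(float(fisher_exact(table, alternative="two-sided")[1]))
        obs_pct.append(100.0 * obs_in / n_obs)
        exp_pct.append(100.0 * null_in / n_null)
    return DistanceResult(
        observed=observed,
        null=null,
        ranges=ranges,
        observed_pct=np.asarray(obs_pct),
        expected_pct=np.asarray(exp_pct),
        p_values=np.asarray(ps),
    )
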