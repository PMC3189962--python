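"""Synthetic promoter/ChIP datasets with the statistical structure the
analysis pipeline assumes.

The generator emulates a promoter-array experiment for two transcription
factors: a homeodomain factor (OTX2) whose peak offsets around the TSS
follow a two-component bimodal mixture (upstream and downstream modes),
and a bHLH factor (MYC) whose peaks center on the TSS.  Per promoter it
draws bound status, peak multiplicity, class-conditional MYC co-binding,
expression coupled to the co-binding class, probe-level signal tracks,
and genome sequence with TAATCC-family motifs depleted near the TSS,
E-boxes enriched at the TSS, and soft-masked Alu-like repeats rich in
TAATCC.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import ExpressionRecord, GenomeSequence, Peak, SignalTrack, TSSRecord

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "generate_fixture_from_counts"]

# Co-binding classes a promoter can be planted into.
CLASSES = ("unbound", "MYC-only", "single-MYC", "single+MYC", "multi-MYC", "multi+MYC")

_PROMOTERS_PER_CHROM = 1000
_TSS_SPACING = 10_000          # bp between consecutive TSSs; > window width, no overlap
_FIRST_TSS = 6_000             # leaves room for the -5000 flank
_WINDOW = (-5000, 3000)        # profiled promoter window


@dataclass
class SyntheticConfig:
    """Generative parameters.

    Default probabilities reproduce the promoter-array fractions the
    pipeline is designed around: 45.4% of promoters OTX2-bound, 40.2% of
    bound promoters with multiple peaks, MYC co-binding in 63.8% of
    multi-peak and 48.7% of single-peak promoters, and a 51.5% marginal
    MYC rate (the unbound-promoter MYC probability is solved from that
    marginal).  Offset-mixture means sit at -250 and +650 bp.
    """

    n_promoters: int = 25_064
    seed: int = 0

    p_otx2_bound: float = 0.454
    p_multi_given_bound: float = 0.402
    # extra peaks beyond 2 for "multiple" promoters: truncated geometric
    geom_extra_p: float = 0.45
    max_peaks: int = 5

    otx2_offset_means: Tuple[float, float] = (-250.0, 650.0)
    otx2_offset_sds: Tuple[float, float] = (150.0, 200.0)
    otx2_offset_weights: Tuple[float, float] = (0.5, 0.5)
    otx2_offset_law: str = "mixture"      # or "uniform" (uniform on +/-2000)

    myc_offset_mean: float = 0.0
    myc_offset_sd: float = 200.0
    couple_myc_to_otx2: bool = False      # MYC offset = OTX2 offset + N(0, coupling_sd)
    coupling_sd: float = 150.0

    p_myc_given_multi: float = 0.638
    p_myc_given_single: float = 0.487
    p_myc_marginal: float = 0.515
    p_myc_given_no_otx2: Optional[float] = None   # solved from marginal if None

    peak_width: int = 500
    signal_mean: float = 2.5
    signal_sd: float = 0.8
    probe_spacing: int = 100
    probe_noise_sd: float = 0.3

    # per-class mean log2 expression, common sd
    expression_class_means: Dict[str, float] = field(
        default_factory=lambda: {
            "unbound": 5.0,
            "MYC-only": 6.0,
            "single-MYC": 5.8,
            "single+MYC": 6.3,
            "multi-MYC": 6.0,
            "multi+MYC": 7.5,
        }
    )
    expression_sd: float = 1.0

    # motif placement law (per-bp Poisson rates on top of random background)
    taatcc_rate_per_bp: float = 1 / 500
    taatcc_depletion_factor: float = 0.2
    taatcc_depletion_halfwidth: int = 500
    ebox_rate_per_bp: float = 1 / 1000
    ebox_enrichment_factor: float = 5.0
    ebox_enrichment_halfwidth: int = 250
    repeat_density: float = 1.0           # expected Alu-like insertions per promoter
    repeat_length: int = 300

    include_signal: bool = True
    include_sequence: bool = True

    def __post_init__(self) -> None:
        for name in (
            "p_otx2_bound",
            "p_multi_given_bound",
            "p_myc_given_multi",
            "p_myc_given_single",
            "p_myc_marginal",
            "geom_extra_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.otx2_offset_weights) - 1.0) > 1e-9:
            raise ValueError("otx2_offset_weights must sum to 1")
        if self.otx2_offset_law not in ("mixture", "uniform"):
            raise ValueError("otx2_offset_law must be 'mixture' or 'uniform'")

    def solve_p_myc_given_no_otx2(self) -> float:
        """Solve P(MYC | no OTX2) so the MYC marginal hits ``p_myc_marginal``.

        Law of total probability over the three planted OTX2 states.
        Raises if the configured conditionals make the marginal infeasible.
        """
        if self.p_myc_given_no_otx2 is not None:
            v = self.p_myc_given_no_otx2
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p_myc_given_no_otx2 must be in [0,1], got {v}")
            return v
        p_multi = self.p_otx2_bound * self.p_multi_given_bound
        p_single = self.p_otx2_bound * (1 - self.p_multi_given_bound)
        p_none = 1 - self.p_otx2_bound
        if p_none == 0:
            bound_part = p_single * self.p_myc_given_single + p_multi * self.p_myc_given_multi
            if abs(bound_part - self.p_myc_marginal) > 1e-9:
                raise ValueError("marginal P(MYC) infeasible with p_otx2_bound = 1")
            return 0.0
        v = (
            self.p_myc_marginal
            - p_single * self.p_myc_given_single
            - p_multi * self.p_myc_given_multi
        ) / p_none
        if not 0.0 <= v <= 1.0:
            raise ValueError(
                f"solved p_myc_given_no_otx2 = {v:.4f} outside [0,1]; "
                "marginal MYC probability infeasible under the class conditionals"
            )
        return v

    def motif_rate(self, offset: np.ndarray, kind: str) -> np.ndarray:
        """The configured per-bp placement rate at TSS offset(s); the
        independent oracle for planted-density tests."""
        offset = np.asarray(offset, dtype=float)
        if kind == "taatcc":
            base, factor, hw = (
                self.taatcc_rate_per_bp,
                self.taatcc_depletion_factor,
                self.taatcc_depletion_halfwidth,
            )
            return np.where(np.abs(offset) < hw, base * factor, base)
        if kind == "ebox":
            base = self.ebox_rate_per_bp
            tri = np.maximum(0.0, 1 - np.abs(offset) / self.ebox_enrichment_halfwidth)
            return base * (1 + (self.ebox_enrichment_factor - 1) * tri)
        raise ValueError(f"unknown motif kind {kind!r}")


@dataclass
class SyntheticDataset:
    """The generated bundle: TSS table, peak calls per factor, probe
    tracks, expression, genome, and the planted per-promoter truth."""

    tss: List[TSSRecord]
    otx2_peaks: List[Peak]
    myc_peaks: List[Peak]
    signal: Dict[str, Optional[SignalTrack]]
    expression: List[ExpressionRecord]
    genome: Optional[GenomeSequence]
    truth: pd.DataFrame  # gene_id, class, n_otx2_peaks, myc_bound

    def write(self, outdir) -> None:
        from pathlib import Path

        from . import io as pio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_tss(self.tss, out / "tss.tsv")
        pio.write_peaks(self.otx2_peaks, out / "otx2_peaks.bed")
        pio.write_peaks(self.myc_peaks, out / "myc_peaks.bed")
        pio.write_expression(self.expression, out / "expression.tsv")
        for factor, track in self.signal.items():
            if track is not None:
                pio.write_signal(track, out / f"{factor.lower()}_signal.bedgraph")
        if self.genome is not None:
            pio.write_fasta(self.genome, out / "genome.fa")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _tss_layout(n: int, rng: Optional[np.random.Generator]) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Chromosome names, positions and strands for n promoters; one
    chromosome per 1000 promoters, TSSs spaced widely enough that the
    profiled windows never overlap."""
    idx = np.arange(n)
    chrom_idx = idx // _PROMOTERS_PER_CHROM
    within = idx % _PROMOTERS_PER_CHROM
    chroms = [f"chr{c + 1}" for c in chrom_idx]
    positions = _FIRST_TSS + within * _TSS_SPACING
    if rng is None:
        strands = np.where(idx % 2 == 0, "+", "-")
    else:
        strands = np.where(rng.random(n) < 0.5, "+", "-")
    return chroms, positions.astype(np.int64), strands


def _offset_to_abs(position: int, strand: str, offset: float) -> int:
    return int(round(position + offset if strand == "+" else position - offset))


def _make_peak(chrom: str, position: int, strand: str, offset: float, width: int, signal: float, factor: str) -> Peak:
    center = _offset_to_abs(position, strand, offset)
    start = center - width // 2
    return Peak(chrom=chrom, start=start, end=start + width, signal=float(signal), factor=factor)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset under ``config``.

    Per promoter: bound ~ Bernoulli(p_otx2_bound); bound promoters carry
    a single peak or, with p_multi_given_bound, 2 + truncated-geometric
    extra peaks (max ``max_peaks``); OTX2 offsets come from the bimodal
    mixture (or uniform on +/-2000); the MYC flag is drawn from the
    class-conditional probabilities and places one TSS-centered (or
    OTX2-coupled) MYC peak; expression is the class mean plus Gaussian
    noise; probe tracks are Gaussian bumps at peak centers plus noise;
    sequence is uniform-random ACGT with planted motifs following the
    configured TSS-offset rate law and soft-masked repeat insertions.
    """
    cfg = config
    p_myc_none = cfg.solve_p_myc_given_no_otx2()   # raises before any output
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_promoters

    chroms, positions, strands = _tss_layout(n, rng)
    gene_ids = [f"G{i:06d}" for i in range(n)]
    tss = [
        TSSRecord(gene_ids[i], chroms[i], int(positions[i]), str(strands[i]))
        for i in range(n)
    ]

    bound = rng.random(n) < cfg.p_otx2_bound
    multi = bound & (rng.random(n) < cfg.p_multi_given_bound)
    single = bound & ~multi

    # peak counts: 1 for single; 2 + truncated geometric for multi
    n_peaks = np.zeros(n, dtype=int)
    n_peaks[single] = 1
    n_multi = int(multi.sum())
    if n_multi:
        extra_max = cfg.max_peaks - 2
        j = np.arange(extra_max + 1)
        pmf = (1 - cfg.geom_extra_p) ** j
        pmf = pmf / pmf.sum()
        n_peaks[multi] = 2 + rng.choice(j, size=n_multi, p=pmf)

    # class-conditional MYC flags
    u = rng.random(n)
    myc = np.where(multi, u < cfg.p_myc_given_multi,
                   np.where(single, u < cfg.p_myc_given_single, u < p_myc_none))

    classes = np.full(n, "unbound", dtype=object)
    classes[~bound & myc] = "MYC-only"
    classes[single & ~myc] = "single-MYC"
    classes[single & myc] = "single+MYC"
    classes[multi & ~myc] = "multi-MYC"
    classes[multi & myc] = "multi+MYC"

    def draw_otx2_offsets(k: int) -> np.ndarray:
        if cfg.otx2_offset_law == "uniform":
            return rng.uniform(-2000, 2000, size=k)
        comp = rng.choice(2, size=k, p=np.asarray(cfg.otx2_offset_weights))
        means = np.asarray(cfg.otx2_offset_means)[comp]
        sds = np.asarray(cfg.otx2_offset_sds)[comp]
        return rng.normal(means, sds)

    otx2_peaks: List[Peak] = []
    myc_peaks: List[Peak] = []
    otx2_offsets_by_promoter: List[np.ndarray] = []
    for i in range(n):
        k = n_peaks[i]
        offs = draw_otx2_offsets(k) if k else np.empty(0)
        otx2_offsets_by_promoter.append(offs)
        sigs = rng.normal(cfg.signal_mean, cfg.signal_sd, size=k)
        for o, s in zip(offs, sigs):
            otx2_peaks.append(
                _make_peak(chroms[i], positions[i], strands[i], o, cfg.peak_width, s, "OTX2")
            )
        if myc[i]:
            if cfg.couple_myc_to_otx2 and k:
                base = offs[rng.integers(k)]
                m_off = float(np.clip(base + rng.normal(0, cfg.coupling_sd), -2000, 2000))
            else:
                m_off = rng.normal(cfg.myc_offset_mean, cfg.myc_offset_sd)
            myc_peaks.append(
                _make_peak(
                    chroms[i], positions[i], strands[i], m_off, cfg.peak_width,
                    rng.normal(cfg.signal_mean, cfg.signal_sd), "MYC",
                )
            )

    expression = [
        ExpressionRecord(
            gene_ids[i],
            float(rng.normal(cfg.expression_class_means[classes[i]], cfg.expression_sd)),
        )
        for i in range(n)
    ]

    signal: Dict[str, Optional[SignalTrack]] = {"OTX2": None, "MYC": None}
    if cfg.include_signal:
        signal["OTX2"] = _signal_track(cfg, rng, chroms, positions, strands, otx2_peaks)
        signal["MYC"] = _signal_track(cfg, rng, chroms, positions, strands, myc_peaks)

    genome = _genome(cfg, rng, chroms, positions, strands) if cfg.include_sequence else None

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "n_otx2_peaks": n_peaks,
            "myc_bound": myc,
        }
    )
    return SyntheticDataset(
        tss=tss,
        otx2_peaks=otx2_peaks,
        myc_peaks=myc_peaks,
        signal=signal,
        expression=expression,
        genome=genome,
        truth=truth,
    )


def _signal_track(cfg, rng, chroms, positions, strands, peaks) -> SignalTrack:
    """Probe measurements over each promoter window: Gaussian bumps of
    amplitude = peak signal (sd = peak_width / 4) plus Gaussian noise."""
    by_prom: Dict[int, List[Peak]] = {}
    # peaks were produced promoter by promoter; recover the promoter index
    # by position arithmetic (windows never overlap)
    pos_lookup: Dict[Tuple[str, int], int] = {}
    for i, (c, p) in enumerate(zip(chroms, positions)):
        pos_lookup[(c, int(p) // _TSS_SPACING)] = i
    for pk in peaks:
        i = pos_lookup[(pk.chrom, pk.center // _TSS_SPACING)]
        by_prom.setdefault(i, []).append(pk)

    sigma = cfg.peak_width / 4
    all_chrom, all_pos, all_val = [], [], []
    lo, hi = _WINDOW
    for i in range(len(positions)):
        pos, strand = int(positions[i]), strands[i]
        if strand == "+":
            grid = np.arange(pos + lo, pos + hi, cfg.probe_spacing)
        else:
            grid = np.arange(pos - hi, pos - lo, cfg.probe_spacing)
        vals = rng.normal(0, cfg.probe_noise_sd, size=grid.size)
        for pk in by_prom.get(i, ()):
            vals += pk.signal * np.exp(-((grid - pk.center) ** 2) / (2 * sigma**2))
        all_chrom.extend([chroms[i]] * grid.size)
        all_pos.append(grid)
        all_val.append(vals)
    return SignalTrack(
        all_chrom,
        np.concatenate(all_pos) if all_pos else [],
        np.concatenate(all_val) if all_val else [],
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_OTX2_MOTIFS = (b"TAATCC", b"TAAGCC", b"TAATCT")
_EBOX = b"CACGTG"


def _genome(cfg, rng, chroms, positions, strands) -> GenomeSequence:
    """Uniform-random sequence with motifs planted at the configured
    TSS-offset rates and lowercase Alu-like insertions carrying TAATCC."""
    n = len(positions)
    chrom_names = list(dict.fromkeys(chroms))
    chrom_n = {c: 0 for c in chrom_names}
    for c in chroms:
        chrom_n[c] += 1
    chrom_len = {c: _FIRST_TSS + chrom_n[c] * _TSS_SPACING + _WINDOW[1] + 1000 for c in chrom_names}

    buffers: Dict[str, bytearray] = {}
    for c in chrom_names:
        raw = _BASES[rng.integers(0, 4, size=chrom_len[c], dtype=np.uint8)]
        buffers[c] = bytearray(raw.tobytes())

    lo, hi = _WINDOW

    def plant(buf: bytearray, abs_pos: int, motif: bytes) -> None:
        if 0 <= abs_pos and abs_pos + len(motif) <= len(buf):
            buf[abs_pos : abs_pos + len(motif)] = motif

    for i in range(n):
        buf = buffers[chroms[i]]
        pos, strand = int(positions[i]), strands[i]

        def to_abs(off: float) -> int:
            return _offset_to_abs(pos, strand, off)

        # TAATCC family: piecewise-constant Poisson placement, depleted
        # within the core around the TSS
        hw = cfg.taatcc_depletion_halfwidth
        base = cfg.taatcc_rate_per_bp
        segments = [
            (lo, -hw, base),
            (-hw, hw, base * cfg.taatcc_depletion_factor),
            (hw, hi, base),
        ]
        for seg_lo, seg_hi, rate in segments:
            seg_lo, seg_hi = max(seg_lo, lo), min(seg_hi, hi)
            if seg_hi <= seg_lo:
                continue
            count = rng.poisson(rate * (seg_hi - seg_lo))
            for off in rng.uniform(seg_lo, seg_hi, size=count):
                plant(buf, to_abs(off), _OTX2_MOTIFS[rng.integers(len(_OTX2_MOTIFS))])

        # E-box: uniform base rate plus a triangular bump peaking at the
        # TSS (rate law in SyntheticConfig.motif_rate)
        count = rng.poisson(cfg.ebox_rate_per_bp * (hi - lo))
        for off in rng.uniform(lo, hi, size=count):
            plant(buf, to_abs(off), _EBOX)
        ehw = cfg.ebox_enrichment_halfwidth
        extra = rng.poisson(cfg.ebox_rate_per_bp * (cfg.ebox_enrichment_factor - 1) * ehw)
        for off in rng.triangular(-ehw, 0, ehw, size=extra):
            plant(buf, to_abs(off), _EBOX)

        # soft-masked Alu-like repeats outside the depletion core
        for _ in range(rng.poisson(cfg.repeat_density)):
            side = rng.random() < 0.5
            hw = cfg.taatcc_depletion_halfwidth
            off = rng.uniform(lo, -hw - cfg.repeat_length) if side else rng.uniform(hw, hi - cfg.repeat_length)
            rep = _BASES[rng.integers(0, 4, size=cfg.repeat_length, dtype=np.uint8)].tobytes().lower()
            rep_arr = bytearray(rep)
            for j in sorted(rng.choice(cfg.repeat_length - 6, size=2, replace=False)):
                rep_arr[j : j + 6] = b"taatcc"
            plant(buf, to_abs(off) if strand == "+" else to_abs(off) - cfg.repeat_length, bytes(rep_arr))

    return GenomeSequence({c: buffers[c].decode("ascii") for c in chrom_names}, validate=False)


def generate_fixture_from_counts(counts: Dict[str, int]) -> SyntheticDataset:
    """Deterministic fixture with exactly the stated contingency counts.

    ``counts`` keys: total, single, multi, myc_total, myc_and_single,
    myc_and_multi.  The fixture plants 1 OTX2 peak per single promoter,
    2 per multi promoter, and one TSS-centered MYC peak per MYC-bound
    promoter, all centers within +/-2000 bp of the TSS.  Inconsistent
    counts raise before any output.
    """
    total = counts["total"]
    single = counts["single"]
    multi = counts["multi"]
    myc_total = counts["myc_total"]
    myc_and_single = counts["myc_and_single"]
    myc_and_multi = counts["myc_and_multi"]

    if min(total, single, multi, myc_total, myc_and_single, myc_and_multi) < 0:
        raise ValueError("counts must be non-negative")
    if single + multi > total:
        raise ValueError("single + multi exceeds total promoters")
    if myc_and_single > single:
        raise ValueError("myc_and_single exceeds single")
    if myc_and_multi > multi:
        raise ValueError("myc_and_multi exceeds multi")
    if myc_total > total:
        raise ValueError("myc_total exceeds total")
    myc_only = myc_total - myc_and_single - myc_and_multi
    if myc_only < 0:
        raise ValueError("myc_total smaller than its joint cells")
    if myc_only > total - single - multi:
        raise ValueError("MYC-only promoters exceed unbound promoters")

    chroms, positions, strands = _tss_layout(total, rng=None)
    gene_ids = [f"G{i:06d}" for i in range(total)]
    tss = [TSSRecord(gene_ids[i], chroms[i], int(positions[i]), str(strands[i])) for i in range(total)]

    width = 500
    otx2_peaks: List[Peak] = []
    myc_peaks: List[Peak] = []
    classes = []
    n_otx2 = np.zeros(total, dtype=int)
    myc_flags = np.zeros(total, dtype=bool)

    for i in range(total):
        pos, strand, chrom = int(positions[i]), str(strands[i]), chroms[i]
        if i < multi:
            n_otx2[i] = 2
            otx2_peaks.append(_make_peak(chrom, pos, strand, -250, width, 2.0, "OTX2"))
            otx2_peaks.append(_make_peak(chrom, pos, strand, 650, width, 2.0, "OTX2"))
            myc_flags[i] = i < myc_and_multi
        elif i < multi + single:
            n_otx2[i] = 1
            otx2_peaks.append(_make_peak(chrom, pos, strand, -250, width, 2.0, "OTX2"))
            myc_flags[i] = (i - multi) < myc_and_single
        else:
            myc_flags[i] = (i - multi - single) < myc_only
        if myc_flags[i]:
            myc_peaks.append(_make_peak(chrom, pos, strand, 0, width, 2.0, "MYC"))
        if n_otx2[i] >= 2:
            classes.append("multi+MYC" if myc_flags[i] else "multi-MYC")
        elif n_otx2[i] == 1:
            classes.append("single+MYC" if myc_flags[i] else "single-MYC")
        else:
            classes.append("MYC-only" if myc_flags[i] else "unbound")

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "class": classes, "n_otx2_peaks": n_otx2, "myc_bound": myc_flags}
    )
    return SyntheticDataset(
        tss=tss,
        otx2_peaks=otx2_peaks,
        myc_peaks=myc_peaks,
        signal={"OTX2": None, "MYC": None},
        expression=[],
        genome=None,
        truth=truth,
    )
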