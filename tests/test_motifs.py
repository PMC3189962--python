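import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import linregress

from promobind import (
    GenomeSequence,
    MotifSet,
    Peak,
    SyntheticConfig,
    TSSRecord,
    default_motif_set,
    generate_dataset,
    kmer_enrichment_iterative,
    motif_density_profile,
    motif_frequency_vs_expression,
    scan_motif,
)
from promobind.motifs import revcomp


def mk_set(*motifs, both=True, mask=False):
    return MotifSet(motifs={"m": tuple(motifs)}, scan_both_strands=both, respect_softmask=mask)


def naive_scan(seq, motif, both_strands, respect_softmask):
    """Independent substring-search oracle."""
    hits = set()
    targets = {motif}
    if both_strands:
        targets.add(revcomp(motif))
    upper = seq.upper()
    k = len(motif)
    for t in targets:
        for i in range(len(seq) - k + 1):
            if upper[i : i + k] == t:
                if respect_softmask and any(c.islower() for c in seq[i : i + k]):
                    continue
                hits.add(i)
    return sorted(hits)


class TestScanMotif:
    def test_forward_match(self):
        assert scan_motif("GGTAATCCA", mk_set("TAATCC"))["TAATCC"] == [2]

    def test_reverse_complement_match(self):
        assert scan_motif("GGATTA", mk_set("TAATCC"))["TAATCC"] == [0]

    def test_strand_scanning_disabled(self):
        assert scan_motif("GGATTA", mk_set("TAATCC", both=False))["TAATCC"] == []

    def test_softmask_semantics(self):
        assert scan_motif("ggtaatcca", mk_set("TAATCC", mask=True))["TAATCC"] == []
        assert scan_motif("ggtaatcca", mk_set("TAATCC", mask=False))["TAATCC"] == [2]

    def test_palindrome_counted_once(self):
        assert scan_motif("ACACGTGT", mk_set("CACGTG"))["CACGTG"] == [1]

    def test_overlapping_matches_allowed(self):
        assert scan_motif("AAAAAA", mk_set("AAAA", both=False))["AAAA"] == [0, 1, 2]

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            mk_set("TAAT CC")
        with pytest.raises(ValueError):
            MotifSet(motifs={"m": ()})

    @settings(deadline=None, max_examples=150)
    @given(
        seq=st.text(alphabet="ACGTacgt", min_size=0, max_size=2000),
        motif=st.sampled_from(["TAATCC", "TAAGCC", "TAATCT", "CACGTG", "AT", "ACGT"]),
        both=st.booleans(),
        mask=st.booleans(),
    )
    def test_equals_naive_substring_oracle(self, seq, motif, both, mask):
        got = scan_motif(seq, mk_set(motif, both=both, mask=mask))[motif]
        assert got == naive_scan(seq, motif, both, mask)

    @settings(deadline=None, max_examples=60)
    @given(seq=st.text(alphabet="ACGTacgt", min_size=0, max_size=500))
    def test_masked_counts_never_exceed_unmasked(self, seq):
        masked = scan_motif(seq, mk_set("TAATCC", mask=True))["TAATCC"]
        unmasked = scan_motif(seq, mk_set("TAATCC", mask=False))["TAATCC"]
        assert set(masked) <= set(unmasked)
        if seq == seq.upper():
            assert masked == unmasked


class TestDensityProfile:
    def test_planted_at_fixed_offset(self):
        rng = np.random.default_rng(0)
        n = 40
        chrom = "chr1"
        seq = list("".join(rng.choice(list("ACG"), 500000)))  # no T: no spurious TAATCC
        tl = []
        for i in range(n):
            pos = 10000 + 10000 * i
            tl.append(TSSRecord(f"G{i}", chrom, pos, "+"))
            seq[pos - 275 : pos - 275 + 6] = list("TAATCC")
        genome = GenomeSequence({chrom: "".join(seq)}, validate=False)
        prof = motif_density_profile(genome, tl, mk_set("TAATCC"), window=(-500, 500))
        v = dict(zip(prof.bin_centers, prof.percent["TAATCC"]))
        assert v[-275.0] == 100.0
        assert sum(x for c, x in v.items() if c != -275.0) == 0.0

    def test_minus_strand_offsets(self):
        chrom = "chr1"
        seq = list("A" * 30000)
        pos = 15000
        # on the minus strand, genomic position pos + 275 is offset -275
        seq[pos + 275 - 5 : pos + 275 + 1] = list("GGATTA")  # revcomp(TAATCC)
        genome = GenomeSequence({chrom: "".join(seq)}, validate=False)
        tl = [TSSRecord("G1", chrom, pos, "-")]
        prof = motif_density_profile(genome, tl, mk_set("TAATCC"), window=(-500, 500))
        v = dict(zip(prof.bin_centers, prof.percent["TAATCC"]))
        assert v[-275.0] == 100.0

    def test_anchor_order_invariance(self, small_genome_dataset):
        _, ds = small_genome_dataset
        sub = ds.tss[:300]
        a = motif_density_profile(ds.genome, sub, window=(-1000, 1000))
        b = motif_density_profile(ds.genome, sub[::-1], window=(-1000, 1000))
        for m in a.percent:
            np.testing.assert_allclose(a.percent[m], b.percent[m])

    def test_planted_depletion_and_enrichment_recovered(self, small_genome_dataset):
        """The generator's configured placement law is recovered: the
        TAATCC-family profile dips inside the depletion core with higher
        flanks, and the E-box profile peaks within one bin of the TSS."""
        cfg, ds = small_genome_dataset
        prof = motif_density_profile(ds.genome, ds.tss, masked=True)
        centers = prof.bin_centers
        fam = sum(prof.percent[m] for m in ("TAATCC", "TAAGCC", "TAATCT"))
        core = np.abs(centers) < cfg.taatcc_depletion_halfwidth
        flank = np.abs(centers) >= 1000
        assert fam[core].mean() < fam[flank].mean()
        assert abs(centers[np.argmin(fam)]) <= cfg.taatcc_depletion_halfwidth
        ebox = prof.percent["CACGTG"]
        assert abs(centers[np.argmax(ebox)]) <= 50

    def test_repeat_mask_lowers_taatcc_flanks(self, small_genome_dataset):
        """Soft-masked Alu-like insertions carry TAATCC: unmasked scans
        see more family occurrences outside the core than masked scans."""
        cfg, ds = small_genome_dataset
        sub = ds.tss[:800]
        masked = motif_density_profile(ds.genome, sub, masked=True)
        unmasked = motif_density_profile(ds.genome, sub, masked=False)
        centers = masked.bin_centers
        flank = np.abs(centers) >= 1000
        assert unmasked.percent["TAATCC"][flank].mean() > masked.percent["TAATCC"][flank].mean()

    def test_peak_center_anchors_use_unsigned_offsets(self):
        chrom = "chr1"
        seq = list("A" * 20000)
        seq[10000 - 120 : 10000 - 114] = list("CACGTG")
        seq[10000 + 114 : 10000 + 120] = list("CACGTG")
        genome = GenomeSequence({chrom: "".join(seq)}, validate=False)
        pk = Peak(chrom, 9950, 10050, 1.0)  # center 10000
        prof = motif_density_profile(genome, [pk], mk_set("CACGTG"), window=(0, 500))
        v = dict(zip(prof.bin_centers, prof.percent["CACGTG"]))
        assert v[125.0] == 100.0  # both flanks fold into |offset| bin [100,150)

    def test_empty_anchor_set_rejected(self, small_genome_dataset):
        _, ds = small_genome_dataset
        with pytest.raises(ValueError):
            motif_density_profile(ds.genome, [])


class TestFrequencyVsExpression:
    def _genome_and_peaks(self, n_peaks, motif_in_first=None, seed=0):
        rng = np.random.default_rng(seed)
        chrom = "chr1"
        seq = list("".join(rng.choice(list("ACG"), 1000 * n_peaks + 2000)))
        peaks, peak_gene, expr = [], {}, {}
        for i in range(n_peaks):
            start = 500 + 1000 * i
            peaks.append(Peak(chrom, start, start + 200, 1.0))
            gene = f"G{i}"
            peak_gene[i] = gene
            expr[gene] = float(i)  # expression increases with index
            if motif_in_first is not None and i < motif_in_first:
                seq[start + 50 : start + 56] = list("TAATCC")
        genome = GenomeSequence({chrom: "".join(seq)}, validate=False)
        return genome, peaks, peak_gene, expr

    def test_planted_low_expression_motif(self):
        genome, peaks, peak_gene, expr = self._genome_and_peaks(800, motif_in_first=400)
        df = motif_frequency_vs_expression(peaks, genome, expr, peak_gene, mk_set("TAATCC"))
        assert df["freq_m" if False else "freq_TAATCC"].tolist() == [1.0, 0.0]
        assert not df["partial"].any()

    def test_partial_final_bin_flagged(self):
        genome, peaks, peak_gene, expr = self._genome_and_peaks(399)
        df = motif_frequency_vs_expression(peaks, genome, expr, peak_gene, mk_set("TAATCC"))
        assert len(df) == 1 and bool(df["partial"].iloc[0])
        assert df["n_peaks"].iloc[0] == 399

    def test_unmapped_peaks_dropped(self):
        genome, peaks, peak_gene, expr = self._genome_and_peaks(401)
        del peak_gene[0]
        df = motif_frequency_vs_expression(peaks, genome, expr, peak_gene, mk_set("TAATCC"))
        assert df["n_peaks"].sum() == 400

    def test_independence_gives_flat_slope(self):
        """With motif placement independent of expression, the per-bin
        frequency-vs-expression regression slope is not significantly
        non-zero in most replicates."""
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genome, peaks, peak_gene, expr = self._genome_and_peaks(1200, seed=seed)
            # plant motif in a random 30% of peaks, independent of expression
            seq = list(genome["chr1"])
            for i in rng.choice(1200, 360, replace=False):
                start = 500 + 1000 * int(i)
                seq[start + 50 : start + 56] = list("TAATCC")
            genome = GenomeSequence({"chr1": "".join(seq)}, validate=False)
            df = motif_frequency_vs_expression(peaks, genome, expr, peak_gene, mk_set("TAATCC"))
            res = linregress(df["mean_expression"], df["freq_TAATCC"])
            sig += res.pvalue < 0.05
        assert sig <= 3


class TestKmerEnrichment:
    def _random_seqs(self, rng, n, length):
        return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]

    def test_identical_fg_bg_scores_zero_lexicographic_winner(self, rng):
        seqs = self._random_seqs(rng, 10, 120)
        res = kmer_enrichment_iterative(seqs, list(seqs), rounds=1)
        assert res[0].score == pytest.approx(0.0, abs=1e-12)
        # oracle: with all scores tied at 0, the winning revcomp class is
        # the lexicographically smallest canonical k-mer present, reported
        # in its forward-strand-majority orientation
        present = set()
        fwd = {}
        for s in seqs:
            for strand, t in enumerate((s, revcomp(s))):
                for k in (6, 7, 8):
                    for i in range(len(t) - k + 1):
                        w = t[i : i + k]
                        present.add(min(w, revcomp(w)))
                        if strand == 0:
                            fwd[w] = fwd.get(w, 0) + 1
        canonical = min(present)
        rc = revcomp(canonical)
        expected = rc if fwd.get(rc, 0) > fwd.get(canonical, 0) else canonical
        assert res[0].sequence == expected

    def test_planted_motif_wins_round_one(self, rng):
        fg = []
        for i, s in enumerate(self._random_seqs(rng, 60, 200)):
            if i % 2 == 0:
                j = int(rng.integers(0, 194))
                s = s[:j] + "TAATCC" + s[j + 6 :]
            fg.append(s)
        # background free of the motif on both strands
        bg = [
            s.replace("TAATCC", "CCCCCC").replace("GGATTA", "CCCCCC")
            for s in self._random_seqs(rng, 60, 200)
        ]
        res = kmer_enrichment_iterative(fg, bg, rounds=1)
        assert res[0].sequence == "TAATCC"
        assert res[0].round_index == 1
        assert res[0].score > 1.0

    def test_two_planted_motifs_recovered_in_rate_order(self, rng):
        fg = []
        for i, s in enumerate(self._random_seqs(rng, 80, 200)):
            if i % 5 < 4:  # 80%
                j = int(rng.integers(0, 180))
                s = s[:j] + "TAATCC" + s[j + 6 :]
            if i % 5 < 2:  # 40%
                s = "CACGTG" + s[6:]
            fg.append(s)
        bg = [
            s.replace("TAATCC", "AAAAAA").replace("GGATTA", "AAAAAA")
            .replace("CACGTG", "AAAAAA")
            for s in self._random_seqs(rng, 80, 200)
        ]
        res = kmer_enrichment_iterative(fg, bg, rounds=2)
        assert [r.sequence for r in res] == ["TAATCC", "CACGTG"]

    def test_masking_removes_winner_from_later_rounds(self, rng):
        fg = ["TAATCCTAATCC" + s for s in self._random_seqs(rng, 20, 100)]
        bg = self._random_seqs(rng, 20, 112)
        res = kmer_enrichment_iterative(fg, bg, rounds=3)
        later = {r.sequence for r in res[1:]}
        assert "TAATCC" not in later

    def test_deterministic(self, rng):
        fg = self._random_seqs(rng, 15, 150)
        bg = self._random_seqs(rng, 15, 150)
        a = kmer_enrichment_iterative(fg, bg, rounds=4)
        b = kmer_enrichment_iterative(fg, bg, rounds=4)
        assert a == b

    def test_exhausted_foreground_stops_early(self):
        fg = ["TAATCCGG"]
        bg = ["ACGTACGTACGT"]
        with pytest.warns(UserWarning, match="exhausted"):
            res = kmer_enrichment_iterative(fg, bg, lengths=(8,), rounds=15)
        assert len(res) < 15

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment_iterative([], ["ACGT"])
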