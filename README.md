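# promobind

TSS-anchored promoter binding landscapes from ChIP-on-chip data.

`promobind` is a small analysis library for studying *where* transcription
factors sit within promoter regions. It was built around a two-factor
setting — the homeodomain factor OTX2 and the bHLH factor MYC in
medulloblastoma cells — in which OTX2 shows an unusual **bimodal** binding
distribution around transcription start sites (modes near −250 bp and
+650 bp), while MYC shows the common single TSS-centered peak. The package
provides the full analysis chain for this kind of question:

- **TSS-anchored profiles** — mean log2 signal and percent-of-promoters-bound
  per 50 bp bin over a −5000..+3000 bp window, with TSS list hygiene
  (alternative TSSs closer than 150 bp to the previous retained one are
  dropped), mode detection, and expression-sorted per-promoter matrices.
- **Co-binding classification** — a promoter is *bound* when a peak center
  falls within ±2000 bp of its TSS (inclusive). OTX2-bound promoters split
  into *single* (one peak) and *multiple* (two or more), crossed with the
  MYC flag into four co-binding classes. Enrichment of MYC among
  multiple-OTX2 promoters is scored with an exact upper-tail hypergeometric
  probability, `P(X ≥ k)`, computed in log space so tails near 1e-80
  remain accurate.
- **Peak-distance randomization test** — for single-OTX2/MYC-bound
  promoters, observed |OTX2 center − nearest MYC center| distances are
  compared against a null in which OTX2 offsets are redrawn uniformly over
  the ±2000 bp window (3 randomizations pooled by default), with two-sided
  Fisher exact tests per distance range.
- **Motif analysis** — exact scanning of the OTX2 motifs
  (TAATCC/TAAGCC/TAATCT) and the E-box (CACGTG) on soft-masked sequence,
  density-vs-TSS and density-vs-peak-center profiles, motif frequency
  against expression in 400-peak bins, and an iterative exhaustive k-mer
  (k = 6–8) enrichment search with round-by-round masking of the winner.
- **Expression integration** — rank-quintile expression categories,
  percent-bound curves per category and class, and Welch t-tests of the
  multi-OTX2+MYC class against the others.
- **A synthetic data generator** (`SyntheticConfig`, `generate_dataset`)
  that emulates the statistical structure of such an experiment — bimodal
  OTX2 offsets, TSS-centered MYC, class-conditional co-binding solved
  against a target MYC marginal, class-coupled expression, probe tracks,
  and genome sequence with TSS-depleted TAATCC, TSS-enriched E-boxes and
  soft-masked Alu-like repeats — so every stage is testable without any
  external download. `generate_fixture_from_counts` builds deterministic
  fixtures realizing an exact contingency table.

Input formats are the plain interchange ones: BED-like peaks, bedGraph-like
probe signal, TSV tables for TSSs and log2 expression, and soft-masked
FASTA (lowercase = repeat).

## Worked example

Classify a 25,064-promoter fixture constructed from an exact contingency
table (11,389 OTX2-bound of which 4,578 carry multiple peaks; 12,906
MYC-bound; 2,923 / 3,317 MYC within multiple / single):

```python
import promobind as pb

counts = dict(total=25064, single=6811, multi=4578,
              myc_total=12906, myc_and_single=3317, myc_and_multi=2923)
ds = pb.generate_fixture_from_counts(counts)
otx2 = pb.assign_binding(ds.otx2_peaks, ds.tss)
myc = pb.assign_binding(ds.myc_peaks, ds.tss)
summaries, table = pb.classify_promoters(otx2, myc, ds.tss)
print(table.report())
print(f"{table.enrichment_p():.3g}")
```

prints

```
{'otx2_bound': 45.4, 'single_of_bound': 59.8, 'multiple_of_bound': 40.2,
 'myc_bound': 51.5, 'cobound': 24.9, 'myc_within_single': 48.7,
 'myc_within_multiple': 63.8}
1.51e-77
```

i.e. 45.4% of promoters are OTX2-bound, 40.2% of those carry two or more
peaks, and MYC co-binds 63.8% of the multiple-peak versus 48.7% of the
single-peak promoters — an enrichment with upper-tail hypergeometric
probability 1.5e-77 (the point probability `P(X = k)`, the spreadsheet
HYPGEOMDIST convention, is 7.0e-78).

Profile a synthetic dataset at the default study conditions and detect
binding modes:

```python
cfg = pb.SyntheticConfig(seed=1)          # 25,064 promoters
sim = pb.generate_dataset(cfg)
prof = pb.peak_frequency_profile(sim.otx2_peaks, sim.tss)
print(pb.find_profile_modes(prof))        # [-225.0, 625.0]
myc_prof = pb.peak_frequency_profile(sim.myc_peaks, sim.tss)
print(pb.find_profile_modes(myc_prof))    # [-25.0]
```

The OTX2 percent-bound curve is bimodal with modes within one 50 bp bin of
the planted −250/+650 bp mixture means; the MYC curve has a single mode at
the TSS. (Mode offsets are bin centers, so the exact values move by ±25 bp
between seeds.)

A thin CLI mirrors the library: `promobind simulate | profile | classify |
dist | motifs | expression` (see `promobind --help`).

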