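# scfrag

Downstream analysis of **salivary cell-free DNA (ScfDNA)** fragmentomics for
two-group (e.g. cancer vs. non-cancer) cohort studies: insert-size profile
jaggedness, short/long fragment scores over a 1-Mb genome grid, 4-mer end
motifs, G-quadruplex prevalence, mitochondrial and microbial read fractions,
and a statistics + PCA/clustering integration layer — together with a
synthetic cohort simulator that makes the whole pipeline testable without
sequencing data.

Salivary cfDNA differs from plasma cfDNA: alongside the mononucleosomal
~167 bp fragment population it carries an ultrashort (< 100 bp) population
with pronounced ~10 bp periodicity, plus abundant oral-microbiome reads.
This package quantifies those signals per sample and compares them across
cohorts.

## Core quantities

* **Peak–valley index** — for the insert-size histogram (y = % reads per
  integer fragment length), local extrema are found with a lookahead/delta
  scan (`lookahead = 1`, `delta = 0.0001`, no smoothing), and the index is

  &nbsp;&nbsp;&nbsp;&nbsp;I = Σᵢ (Pᵢ − Vᵢ) / n

  where Pᵢ is the i-th peak height, Vᵢ the first valley to its right, and n
  the number of paired peaks.  It measures the "jaggedness" of the sub-100 bp
  10-bp comb; histograms with no extrema get I = 0.

* **Fragment score** — the count ratio of short fragments, length ∈ [35, 100),
  to mononucleosome-range fragments, length ∈ [100, 250], globally per sample
  and per 1-Mb bin (GRCh38 chr1–chr22 tile into 2,887 such bins).

* **End-motif profile** — frequencies of the 256 4-mers at the 5' end of each
  fragment's sequenced strand, summarised by Shannon entropy in bits
  (0 … 8 for k = 4); plus the percent of fragments carrying a canonical
  G-quadruplex motif `G{3,}(N{1,7}G{3,}){3}` on either strand.

* **Compartment fractions** — % mitochondrial fragments (chrM/MT) and %
  microbial reads from a taxonomic classification table, with rank-level
  relative abundances and Shannon alpha diversity (natural log).

* **Group statistics** — per-feature Welch t tests (unpooled variances),
  multiplicity handled by the two-stage step-up adaptive FDR of Benjamini,
  Krieger & Yekutieli at Q = 0.05 (q values are rejection-threshold infima),
  AUROC by the Mann–Whitney identity, and an integration layer that runs
  centered/unit-variance PCA (SVD, deterministic signs) and hierarchical
  clustering over the discovered features.

## Worked example

```python
import scfrag as sf

cfg = sf.preset("noncancer_like", n_fragments=20_000, seed=7)
sample, manifest = sf.simulate_sample(cfg, sample_id="demo")
for name, value in sf.sample_scalar_metrics(sample).items():
    print(f"{name:22s} {value:.4f}")
```

prints

```
peak_valley_index      0.2783
fragment_score         2.2510
mito_fraction_pct      4.8276
motif_entropy_bits     7.9658
g4_prevalence_pct      11.8141
```

The jagged "noncancer-like" preset yields a clearly positive peak–valley
index (deep 10-bp comb below 100 bp) and a fragment score above 2 (short
fragments outnumber mononucleosomal ones roughly 2:1 — the generating
mixture implies 2.34, and the estimate sits within sampling error of it).
The mitochondrial percent estimates the preset's 5 % truth; motif entropy
near 8 bits reflects a near-uniform end-motif spectrum, and ~12 % of
fragments carry a planted G-quadruplex motif.

The same pipeline is exposed as a CLI over fragment BED/BAM files:

```bash
scfrag simulate --out cohort --seed 1 --n-per-group 10
scfrag profile cohort/B1.fragments.bed --out out_profile
scfrag compare  --manifest cohort/cohort_manifest.tsv --out out_compare
scfrag integrate --manifest cohort/cohort_manifest.tsv --out out_pca
```

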