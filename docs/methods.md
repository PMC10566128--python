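# Methods

This note documents the models, conventions and numerical choices behind
`scfrag`, and what the synthetic cohort does and does not establish.

## Fragment model and coordinates

A fragment is one aligned cfDNA molecule: contig, 0-based half-open
interval, strand, and optionally the sequenced-strand sequence (5'→3').
All internal coordinates are BED-convention; BAM positions are converted on
read.  For paired BAM input only proper, primary, non-duplicate pairs are
used, and the fragment is the alignment span of the pair (leftmost start to
rightmost end), never the TLEN field — this stays correct for merged-read
inputs.  The default length window is [35, 300] bp, the range over which
insert-size profiles are plotted and compared.  Mitochondrial contigs are
recognised by name (`chrM` or `MT`).  Fragments on contigs absent from the
genome model are kept but excluded from binned analyses (with a warning).

The genome model ships GRCh38 chr1–chr22 + chrM lengths.  Binning tiles
each contig with consecutive half-open 1-Mb bins including the final
partial bin, giving Σ ceil(L/1 Mb) = 2,887 autosomal bins.  A fragment
belongs to the bin containing its **start** coordinate — a deterministic
rule that makes per-bin counts conserve the autosomal total exactly.

## Insert-size profile and the peak–valley index

The histogram assigns each in-range fragment to its integer length;
heights are % of in-range fragments, so the profile sums to 100.  No
smoothing is applied anywhere: smoothing would erase the ~10 bp comb the
index is designed to measure.

Extrema come from a lookahead/delta scan (the classic 1-D peak detector):
the running maximum is a candidate peak, confirmed when the series falls
more than `delta` below it and stays below it across the next `lookahead`
points; valleys are symmetric; the first confirmed extremum is discarded as
an initialisation artefact, so confirmed extrema strictly alternate and
series endpoints are never extrema.  Defaults are `lookahead = 1`,
`delta = 0.0001` on the raw % series.  Plateaus yield a single extremum at
the plateau's first point.  The implementation is checked against an
independent step-by-step transcription of the same procedure on random
series, including tied/plateau inputs.

The index is Σ(Pᵢ − Vᵢ)/n over peaks paired with the first confirmed valley
at larger x; peaks with no right valley are unpaired and excluded, and
n is the number of pairs.  Extremum-free histograms get index 0 (not NaN)
so cohort statistics never propagate missing values.  One caveat is
documented deliberately: because the detector skips the confirming sample
when it switches search direction, a confirmed valley on a steep rising
shoulder (e.g. the flank of the 167 bp mode) can sit slightly **above** the
preceding minor peak, so individual pair differences are not strictly
non-negative — on jagged profiles the index itself is robustly positive and
the vast majority of pairs drop.

## Fragment scores, coverage and compartments

The fragment score is count([35, 100)) / count([100, 250]), using autosomal
fragments; boundary conventions are fixed (100 counts long, 35 short,
lengths outside both windows count in neither) and the windows are
configurable.  Per-bin scores use the same windows within each 1-Mb bin;
bins with a zero long-count are flagged undefined (NaN) and excluded from
group tests rather than raising.  Bin coverage is each bin's % share of
binned fragments.  The mitochondrial fraction is 100·n_mito/n_total.

## End motifs and G-quadruplexes

The end motif is the first k = 4 bases at the 5' end of the sequenced
strand, one end per fragment (read 1 for pairs); fragments with N in the
first k bases or shorter than k are skipped and tallied.  All 4ᵏ = 256
categories are enumerated and zero-filled.  Entropy is Shannon entropy in
bits (base 2), giving the interpretable 0–8 range for k = 4; per-motif
−p·log₂p terms are exported so cross-sample aggregations can be built
downstream.  G-quadruplex prevalence is the % of fragments matching
`G{3,}(N{1,7}G{3,}){3}` on either the sequence or its reverse complement —
the canonical four-tract/1–7-base-loop definition, exposed as a pattern
parameter.

## Microbial metrics

Classification is consumed as a table (sample, semicolon-delimited lineage
over superkingdom→species, count); reads the classifier maps back to the
host are tracked separately and excluded from taxon math.  Rank-level
relative abundances are per-sample normalised; alpha diversity is the
Shannon index with **natural** log (the ecological convention), while motif
entropy uses log₂ — each follows its field.  Microbial fraction is
reported against both the classified-read denominator and, when an
unclassified remainder is supplied, the total-read denominator.

## Group statistics

Every per-feature test is Welch's unequal-variance t (two-sided,
Welch–Satterthwaite df); variances are never pooled across features or
groups.  When both groups are constant and equal the test is degenerate and
p = 1 by convention.  Multiplicity uses the two-stage step-up adaptive FDR
(stage 1: BH at Q′ = Q/(1+Q), estimating m₀ = m − r₁; stage 2: BH at
Q′·m/m₀; r₁ = 0 rejects none, r₁ = m rejects all).  The normative output is
the flag vector; the reported q value is the smallest Q at which a feature
would be rejected, computed exactly by scanning the stage-1 breakpoints.
Two properties worth knowing: the rejection set grows with Q, and the
procedure does **not** always contain plain BH at the same Q (stage 1 runs
at the deflated level, so a p value rejected by BH exactly at threshold can
leave stage 1 empty) — it does contain BH at Q/(1+Q).  AUROC is computed by
the Mann–Whitney identity with midranks for ties.  Features with missing
or undefined values are excluded from testing and listed.

## Integration

Feature bundles (fragmentomic scalars, per-bin coverage and scores, motif
frequencies, microbial metrics) are joined on the sample set with
per-column provenance.  PCA centers and (by default) unit-variance scales
columns, decomposes by SVD, and fixes component signs by making each
component's largest-magnitude loading positive; constant columns are
dropped with a warning under scaling.  Hierarchical clustering defaults to
correlation distance with average linkage on the scaled matrix; leaf order
is deterministic (scipy tie-breaking by input order) and trees export as
Newick.  Feature selection for the integration layer can be "all" or the
FDR discoveries.

## Synthetic cohorts

The simulator generates the statistical structure the pipeline measures,
not sequence-level realism.  Per sample:

* **Lengths** — mixture of (i) a comb over [35, 100] bp: cosine modulation
  of period 10 bp and trough-to-peak depth `comb_depth`; (ii) a Gaussian
  mononucleosomal component (mean 167 bp, sd 10 bp); (iii) a uniform
  background over [35, 300].  The exact mixture pmf is available in closed
  form, so the implied fragment score is an analytic truth.
* **Positions** — multinomial over the 1-Mb bins (weights ∝ bin width, the
  terminal bin of each chromosome multiplied by `telomere_enrichment`),
  uniform within the bin.
* **Mitochondrial fragments** — binomial fraction of human fragments with a
  Gamma length law (shape 8, scale 10 → mode 70 bp).
* **Sequences** — the 5' 4-mer follows a per-sample multinomial drawn from a
  group-specific Dirichlet over the 256 motifs; a telomeric-repeat
  G-quadruplex (GGGTTAGGGTTAGGGTTAGGG) is planted into a `g4_plant_rate`
  fraction of fragments and rejection-sampled out of the remainder, so the
  plant rate is the exact population prevalence.
* **Microbial reads** — a binomial fraction of classified reads, spread over
  a fixed 12-taxon oral panel by a Dirichlet-multinomial.

Everything is deterministic given the seed; cohorts derive per-sample seeds
from the master seed by a fixed rule and a JSON manifest records every
generating parameter and realized count.

The two presets encode the cohort phenomenology the analysis targets:
`noncancer_like` is jagged (comb depth 0.85), short-enriched (short weight
0.62), telomere-enriched (3×), G4-richer (12 %), microbially more diverse;
`gc_like` ("gastric-cancer-like") carries the extra 167 bp mononucleosomal
component (weight 0.38), more mitochondrial (10 % vs 5 %) and microbial
(35 % vs 25 %) signal, and a skewed, lower-entropy end-motif spectrum
(GG-started motifs over-weighted).  These defaults are the package's
standing study conditions for tests; they were chosen once from the
qualitative group contrasts the analysis is meant to detect.

**What passing tests show — and don't.**  Estimator-consistency tests show
the pipeline recovers the generator's truth under the stated sampling laws
(binomial/multinomial/Dirichlet); cohort tests show the statistics layer
detects effects of the planted kind and sign at 10 + 10 samples and
20,000 fragments per sample (a desk-scale stand-in for real sequencing
depth).  They do not establish effect sizes, p values or AUROCs for real
saliva cohorts: real data carry GC and mappability structure, correlated
bins, sequencing error, classifier noise and batch effects that the
generator intentionally omits.

## Numerical choices and degenerate inputs

* Empty histograms, samples without sequences, single-class AUROC labels,
  sub-2-per-group tests, and empty discovery selections raise informative
  errors; undefined per-bin scores and zero-genome-fraction O/E ratios are
  NaN-flagged instead.
* Problem sizes in the test-suite and acceptance script (20,000 fragments
  per sample, 10 + 10 samples; 100,000 fragments for consistency checks)
  are the package's chosen desk-scale defaults; all scale linearly.
* Peak annotation assigns each peak to the highest-priority category
  overlapping its midpoint (promoter > 5'UTR > exon > intron > 3'UTR > TTS
  > intergenic, configurable); promoters/TTS windows default to ±1 kb of
  the TSS/TES when built from BED12 gene models.

## Known limitations

* No GC-correction, mappability weighting, or copy-number analysis.
* Peak calling and taxonomic classification are consumed as inputs
  (narrowPeak, taxa TSV), never re-implemented.
* Gene models are accepted as BED12 (or per-category BEDs); GFF3 is not
  parsed.
* The element-centered coverage profile uses mean-1 normalisation
  ("relative coverage"); other normalisations in the literature are not
  reproduced.
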