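"""Two-group synthetic cfDNA cohort generator with a truth manifest.

The generator emulates the statistical structure a salivary cfDNA cohort
presents to the downstream analysis — not sequence-level realism.  Per
sample it draws:

* fragment lengths from a three-part mixture: a 10-bp periodic comb over
  35–100 bp (sub-mononucleosomal "jaggedness", depth tunable), a Gaussian
  mononucleosomal component at ~167 bp, and a uniform background over
  35–300 bp;
* genomic positions uniform within 1-Mb bins after reweighting the terminal
  (telomeric) bin of each chromosome arm;
* mitochondrial fragments (binomial fraction) with a Gamma length law whose
  mode sits at ~70 bp;
* sequences whose first four bases follow a per-sample multinomial drawn
  from a group-specific Dirichlet over the 256 end motifs, with a canonical
  G-quadruplex motif planted into a known fraction of fragments (and
  rejection-sampled out of the rest, so the plant rate is the exact truth);
* a microbial read count (binomial fraction of classified reads) spread over
  a fixed panel of oral taxa by a Dirichlet-multinomial.

Every generating parameter and realized count is recorded in a JSON-able
truth manifest so tests can compare estimator output against simulator
truth under the stated sampling law.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .end_motif import enumerate_motifs, has_gquad
from .fragments_io import (
    GenomeModel,
    SampleFragments,
    make_bins,
    write_fragments_bed,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
G4_PLANT = "GGGTTAGGGTTAGGGTTAGGG"  # telomeric-repeat quadruplex, 21 nt

#: Fixed oral-microbiome taxon panel (7-rank lineages, superkingdom→species).
TAXA_PANEL = [
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;Streptococcus mitis",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus fermentum",
    "Bacteria;Firmicutes;Negativicutes;Veillonellales;Veillonellaceae;Veillonella;Veillonella parvula",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pasteurellales;Pasteurellaceae;Haemophilus;Haemophilus parainfluenzae",
    "Bacteria;Proteobacteria;Betaproteobacteria;Neisseriales;Neisseriaceae;Neisseria;Neisseria flavescens",
    "Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Micrococcaceae;Rothia;Rothia mucilaginosa",
    "Bacteria;Actinobacteria;Actinomycetia;Actinomycetales;Actinomycetaceae;Actinomyces;Actinomyces oris",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella;Prevotella melaninogenica",
    "Bacteria;Fusobacteria;Fusobacteriia;Fusobacteriales;Fusobacteriaceae;Fusobacterium;Fusobacterium nucleatum",
    "Bacteria;Fusobacteria;Fusobacteriia;Fusobacteriales;Leptotrichiaceae;Leptotrichia;Leptotrichia buccalis",
    "Bacteria;Firmicutes;Bacilli;Bacillales;Gemellaceae;Gemella;Gemella haemolysans",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Porphyromonadaceae;Porphyromonas;Porphyromonas gingivalis",
]


@dataclass
class SimConfig:
    """Generating parameters for one sample (or one group's preset)."""

    n_fragments: int = 20_000          # target human fragment count
    group: str = "A"
    comb_depth: float = 0.5            # trough-to-peak modulation, 0..1
    comb_period: int = 10              # bp
    short_weight: float = 0.5          # comb component over [35, 100]
    mono_weight: float = 0.25          # Gaussian at mono_mean
    background_weight: float = 0.25    # uniform over [lo, hi]
    mono_mean: float = 167.0
    mono_sd: float = 10.0
    length_lo: int = 35
    length_hi: int = 300
    mito_fraction: float = 0.05        # of human fragments
    mito_gamma_shape: float = 8.0      # mode (shape-1)*scale = 70 bp
    mito_gamma_scale: float = 10.0
    microbial_fraction: float = 0.25   # of classified reads
    telomere_enrichment: float = 1.0   # weight multiplier, terminal bins
    g4_plant_rate: float = 0.10
    motif_dirichlet: np.ndarray | float = 30.0   # scalar → symmetric over 256
    taxa_dirichlet: np.ndarray | None = None     # over TAXA_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([self.short_weight, self.mono_weight, self.background_weight])
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"mixture weights must be >=0 and sum to 1, got {w}")
        for name in ("comb_depth", "mito_fraction", "microbial_fraction", "g4_plant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if np.isscalar(self.motif_dirichlet):
            self.motif_dirichlet = np.full(256, float(self.motif_dirichlet))
        else:
            self.motif_dirichlet = np.asarray(self.motif_dirichlet, dtype=float)
            if self.motif_dirichlet.shape != (256,):
                raise ValueError("motif_dirichlet needs 256 concentrations")
        if self.taxa_dirichlet is None:
            self.taxa_dirichlet = np.full(len(TAXA_PANEL), 5.0)
        else:
            self.taxa_dirichlet = np.asarray(self.taxa_dirichlet, dtype=float)
            if self.taxa_dirichlet.shape != (len(TAXA_PANEL),):
                raise ValueError(f"taxa_dirichlet needs {len(TAXA_PANEL)} concentrations")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["motif_dirichlet"] = np.asarray(self.motif_dirichlet).tolist()
        d["taxa_dirichlet"] = np.asarray(self.taxa_dirichlet).tolist()
        return d


def length_pmf(config: SimConfig) -> np.ndarray:
    """Exact pmf of the human fragment-length mixture on lo..hi."""
    lo, hi = config.length_lo, config.length_hi
    L = np.arange(lo, hi + 1)
    # comb over [35, 100]: cosine modulation with peaks every comb_period bp
    comb = np.where(
        (L >= lo) & (L <= 100),
        1.0 + config.comb_depth * np.cos(2 * np.pi * (L - 40) / config.comb_period),
        0.0,
    )
    comb = comb / comb.sum() if comb.sum() > 0 else comb
    mono = np.exp(-0.5 * ((L - config.mono_mean) / config.mono_sd) ** 2)
    mono /= mono.sum()
    bg = np.full(L.size, 1.0 / L.size)
    pmf = (
        config.short_weight * comb
        + config.mono_weight * mono
        + config.background_weight * bg
    )
    return pmf / pmf.sum()


def expected_fragment_score(config: SimConfig) -> float:
    """Truth value of the short/long ratio implied by the length mixture."""
    pmf = length_pmf(config)
    L = np.arange(config.length_lo, config.length_hi + 1)
    p_short = pmf[(L >= 35) & (L < 100)].sum()
    p_long = pmf[(L >= 100) & (L <= 250)].sum()
    return float(p_short / p_long)


def _bin_weights(genome: GenomeModel, telomere_enrichment: float):
    bins = make_bins(genome, genome.autosomes)
    w = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    first_last = np.zeros(len(bins), dtype=bool)
    for contig in genome.autosomes:
        idx = np.flatnonzero((bins["contig"] == contig).to_numpy())
        first_last[idx[0]] = True
        first_last[idx[-1]] = True
    w[first_last] *= telomere_enrichment
    return bins, w / w.sum()


def _random_seq_codes(rng: np.random.Generator, total: int) -> np.ndarray:
    return rng.integers(0, 4, size=total, dtype=np.int64)


def _draw_sequences(
    rng: np.random.Generator,
    lengths: np.ndarray,
    motif_probs: np.ndarray,
    g4_plant_rate: float,
) -> tuple[list[str], int]:
    """Sequences with Dirichlet-multinomial 5' 4-mers and exact G4 planting.

    Fragments not selected for planting are rejection-sampled until G4-free,
    so the plant rate is the exact population prevalence.
    """
    motifs = enumerate_motifs(4)
    n = len(lengths)
    motif_idx = rng.choice(256, size=n, p=motif_probs)
    plant = rng.random(n) < g4_plant_rate
    seqs: list[str] = []
    n_planted = 0
    for i in range(n):
        length = int(lengths[i])
        while True:
            body = _BASES[rng.integers(0, 4, size=max(length - 4, 0))].tobytes().decode()
            seq = motifs[motif_idx[i]] + body
            if plant[i] and length >= 4 + len(G4_PLANT):
                pos = int(rng.integers(4, length - len(G4_PLANT) + 1))
                seq = seq[:pos] + G4_PLANT + seq[pos + len(G4_PLANT):]
                n_planted += 1
                break
            if plant[i]:
                # too short to plant: fall through as unplanted, G4-free
                plant[i] = False
            if not has_gquad(seq):
                break
        seqs.append(seq)
    return seqs, n_planted


def simulate_sample(
    config: SimConfig,
    sample_id: str | None = None,
    genome: GenomeModel | None = None,
    with_sequences: bool = True,
) -> tuple[SampleFragments, dict]:
    """Draw one sample's fragments; return them with the truth manifest."""
    genome = genome or GenomeModel.grch38()
    rng = np.random.default_rng(config.seed)
    if sample_id is None:
        sample_id = f"{config.group}_{config.seed}"

    # classified-read bookkeeping: microbial share of classified reads
    f = config.microbial_fraction
    n_classified = int(round(config.n_fragments / (1.0 - f))) if f < 1 else config.n_fragments
    n_microbial = int(rng.binomial(n_classified, f))
    n_human = n_classified - n_microbial
    n_mito = int(rng.binomial(n_human, config.mito_fraction))
    n_nuclear = n_human - n_mito

    # nuclear lengths from the mixture pmf
    pmf = length_pmf(config)
    L_axis = np.arange(config.length_lo, config.length_hi + 1)
    nuc_lengths = rng.choice(L_axis, size=n_nuclear, p=pmf)

    # nuclear positions: bin by telomere-reweighted multinomial, uniform within
    bins, w = _bin_weights(genome, config.telomere_enrichment)
    bin_idx = rng.choice(len(bins), size=n_nuclear, p=w)
    bstart = bins["start"].to_numpy()[bin_idx]
    bend = bins["end"].to_numpy()[bin_idx]
    starts = bstart + (rng.random(n_nuclear) * (bend - bstart)).astype(np.int64)
    contigs = bins["contig"].to_numpy()[bin_idx]
    contig_len = np.array([genome.lengths[c] for c in contigs])
    starts = np.minimum(starts, contig_len - nuc_lengths)  # clamp at contig end
    ends = starts + nuc_lengths

    # mitochondrial fragments: Gamma length law, mode ~70 bp
    mito_lengths = np.clip(
        np.round(rng.gamma(config.mito_gamma_shape, config.mito_gamma_scale, n_mito)),
        config.length_lo,
        config.length_hi,
    ).astype(np.int64)
    mito_starts = (
        rng.random(n_mito) * (genome.lengths["chrM"] - mito_lengths)
    ).astype(np.int64)

    all_contigs = np.concatenate([contigs, np.full(n_mito, "chrM", dtype=object)])
    all_starts = np.concatenate([starts, mito_starts])
    all_ends = np.concatenate([ends, mito_starts + mito_lengths])
    strands = np.where(rng.random(n_human) < 0.5, "+", "-").astype(object)

    manifest: dict = {
        "sample_id": sample_id,
        "config": config.to_jsonable(),
        "n_classified": n_classified,
        "n_microbial": n_microbial,
        "n_human": n_human,
        "n_mito": n_mito,
        "truth": {
            "microbial_fraction_pct": 100.0 * f,
            "mito_fraction_pct": 100.0 * config.mito_fraction,
            "expected_fragment_score": expected_fragment_score(config),
            "g4_prevalence_pct": 100.0 * config.g4_plant_rate,
            "telomere_enrichment": config.telomere_enrichment,
        },
    }

    seqs = None
    if with_sequences:
        motif_probs = rng.dirichlet(config.motif_dirichlet)
        all_lengths = all_ends - all_starts
        seqs, n_planted = _draw_sequences(
            rng, all_lengths, motif_probs, config.g4_plant_rate
        )
        p = motif_probs[motif_probs > 0]
        manifest["truth"]["motif_probs"] = motif_probs.tolist()
        manifest["truth"]["motif_entropy_bits"] = float(-(p * np.log2(p)).sum())
        manifest["n_g4_planted"] = n_planted

    order = np.lexsort((all_ends, all_starts, all_contigs.astype(str)))
    sample = SampleFragments(
        sample_id,
        all_contigs[order],
        all_starts[order],
        all_ends[order],
        strands[order],
        [seqs[i] for i in order] if seqs is not None else None,
    )
    counts = {c: int((sample.contig == c).sum()) for c in np.unique(sample.contig)}
    manifest["per_contig_counts"] = counts
    return sample, manifest


def simulate_taxa(
    config: SimConfig, n_reads: int, sample_id: str, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str, int]], dict]:
    """Dirichlet-multinomial taxa counts over the fixed panel.

    Returns rows ``(sample_id, lineage, count)`` plus a truth record with the
    drawn composition and the Dirichlet mean.
    """
    rng = rng or np.random.default_rng(config.seed + 7_777)
    alpha = np.asarray(config.taxa_dirichlet, dtype=float)
    probs = rng.dirichlet(alpha)
    counts = rng.multinomial(n_reads, probs)
    rows = [
        (sample_id, lineage, int(c))
        for lineage, c in zip(TAXA_PANEL, counts)
    ]
    truth = {
        "composition": probs.tolist(),
        "dirichlet_mean": (alpha / alpha.sum()).tolist(),
        "n_reads": int(n_reads),
    }
    return rows, truth


def simulate_cohort(
    config_A: SimConfig,
    config_B: SimConfig,
    n_per_group: int,
    out_dir: str | os.PathLike,
    master_seed: int | None = None,
    with_sequences: bool = True,
) -> dict:
    """Write a full two-group cohort (fragment BEDs + taxa TSV + manifest).

    Per-sample seeds derive from the master seed by a fixed rule
    (master*1000 + sample index), so a fixed master seed yields
    byte-identical output files.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if master_seed is None:
        master_seed = config_A.seed
    manifest: dict = {
        "master_seed": int(master_seed),
        "n_per_group": n_per_group,
        "samples": {},
    }
    taxa_rows: list[tuple[str, str, int]] = []
    sample_files: dict[str, str] = {}
    groups: dict[str, str] = {}
    idx = 0
    for group, cfg in (("A", config_A), ("B", config_B)):
        for j in range(n_per_group):
            c = copy.deepcopy(cfg)
            c.group = group
            c.seed = int(master_seed) * 1000 + idx
            sid = f"{group}{j + 1}"
            sample, m = simulate_sample(c, sample_id=sid, with_sequences=with_sequences)
            bed = os.path.join(out_dir, f"{sid}.fragments.bed")
            write_fragments_bed(sample, bed)
            rng = np.random.default_rng(c.seed + 7_777)
            rows, taxa_truth = simulate_taxa(c, m["n_microbial"], sid, rng)
            taxa_rows.extend(rows)
            m["taxa_truth"] = taxa_truth
            manifest["samples"][sid] = m
            sample_files[sid] = bed
            groups[sid] = group
            idx += 1

    taxa_path = os.path.join(out_dir, "taxa.tsv")
    with open(taxa_path, "w") as fh:
        fh.write("sample\tlineage\tcount\n")
        for sid, lineage, count in taxa_rows:
            fh.write(f"{sid}\t{lineage}\t{count}\n")
    manifest["taxa_file"] = taxa_path
    manifest["fragment_files"] = sample_files
    manifest["groups"] = groups
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_file"] = man_path
    return manifest


# -- presets ----------------------------------------------------------------

def _cancer_motif_alpha() -> np.ndarray:
    """Skewed end-motif concentrations: GG-started motifs over-represented."""
    alpha = np.full(256, 30.0)
    for i, motif in enumerate(enumerate_motifs(4)):
        if motif.startswith("GG"):
            alpha[i] = 90.0
    return alpha


#: Group presets mirroring the cohort phenomenology the analysis targets:
#: the non-cancer-like group is jagged (deep sub-100 bp comb), short-enriched,
#: telomere-enriched, G4-richer and microbially diverse; the cancer-like group
#: carries the extra ~167 bp mononucleosomal peak, more mitochondrial and
#: microbial reads, and a skewed (lower-entropy) end-motif spectrum.
def preset(name: str, n_fragments: int = 20_000, seed: int = 0) -> SimConfig:
    if name == "gc_like":
        return SimConfig(
            n_fragments=n_fragments,
            group="A",
            comb_depth=0.25,
            short_weight=0.40,
            mono_weight=0.38,
            background_weight=0.22,
            mito_fraction=0.10,
            microbial_fraction=0.35,
            telomere_enrichment=1.0,
            g4_plant_rate=0.08,
            motif_dirichlet=_cancer_motif_alpha(),
            taxa_dirichlet=np.array(
                [18.0, 10.0, 2.0, 1.5, 3.0, 12.0, 2.5, 3.0, 2.0, 2.0, 2.5, 2.0]
            ),
            seed=seed,
        )
    if name == "noncancer_like":
        return SimConfig(
            n_fragments=n_fragments,
            group="B",
            comb_depth=0.85,
            short_weight=0.62,
            mono_weight=0.12,
            background_weight=0.26,
            mito_fraction=0.05,
            microbial_fraction=0.25,
            telomere_enrichment=3.0,
            g4_plant_rate=0.12,
            motif_dirichlet=np.full(256, 30.0),
            taxa_dirichlet=np.array(
                [6.0, 3.0, 10.0, 8.0, 5.0, 4.0, 6.0, 5.0, 4.0, 4.0, 4.0, 4.0]
            ),
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}; choose gc_like or noncancer_like")


def file_sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
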