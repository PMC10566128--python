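"""Annotation of externally called fragment-pileup peaks.

Peak calling is consumed, not performed: peaks arrive as ENCODE narrowPeak
(10 columns) or plain BED.  Each peak is assigned to exactly one genomic
element category — the highest-priority category overlapping its midpoint —
with priority promoter > 5'UTR > exon > intron > 3'UTR > TTS > intergenic
(the conventional annotator hierarchy; configurable).  Derived metrics:
peaks-per-read, per-category observed/expected ratios against the genome
fraction each category occupies, and element-center relative-coverage
profiles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .fragments_io import GenomeModel, SampleFragments

DEFAULT_PRIORITY = ["promoter", "5UTR", "exon", "intron", "3UTR", "TTS", "intergenic"]


@dataclass
class PeakSet:
    """Called peaks for one sample (contig, start, end, optional summit offset)."""

    peaks: pd.DataFrame  # columns: contig, start, end, [summit]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if (self.peaks["end"] <= self.peaks["start"]).any():
            raise ValueError("peak end must exceed start")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.peaks["start"] + self.peaks["end"]) // 2).to_numpy()


def load_narrowpeak(path: str | os.PathLike, sample_id: str = "") -> PeakSet:
    """Read ENCODE narrowPeak (10 col) or BED3+ peaks."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            summit = int(parts[9]) if len(parts) >= 10 and parts[9] not in ("", ".") else -1
            rows.append((contig, start, end, summit))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "summit"])
    if not sample_id:
        sample_id = os.path.basename(os.fspath(path)).rsplit(".", 1)[0]
    return PeakSet(peaks=df, sample_id=sample_id)


@dataclass
class ElementAnnotation:
    """Genomic element intervals per category, with genome fractions.

    ``intervals[category]`` is a per-contig interval tree whose payloads are
    gene labels; ``genome_fraction[category]`` is the merged-bp share of the
    genome the category covers (before priority resolution, so fractions may
    sum past 1 where categories overlap).
    """

    categories: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    intervals: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)
    genome_fraction: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def _merged_bp(tree_by_contig: Mapping[str, IntervalTree]) -> int:
        total = 0
        for tree in tree_by_contig.values():
            t = IntervalTree(tree)
            t.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in t)
        return total

    @classmethod
    def from_intervals(
        cls,
        by_category: Mapping[str, Sequence[tuple[str, int, int, str]]],
        genome: GenomeModel,
        priority: Sequence[str] = DEFAULT_PRIORITY,
    ) -> "ElementAnnotation":
        """Build from ``{category: [(contig, start, end, gene), ...]}``."""
        trees: dict[str, dict[str, IntervalTree]] = {}
        for cat, ivs in by_category.items():
            per_contig: dict[str, IntervalTree] = {}
            for contig, start, end, gene in ivs:
                per_contig.setdefault(contig, IntervalTree()).addi(start, end, gene)
            trees[cat] = per_contig
        genome_bp = sum(genome.lengths.values())
        fractions = {
            cat: cls._merged_bp(trees.get(cat, {})) / genome_bp for cat in priority
        }
        covered = [c for c in priority if c != "intergenic"]
        fractions["intergenic"] = max(0.0, 1.0 - sum(fractions[c] for c in covered))
        return cls(categories=list(priority), intervals=trees, genome_fraction=fractions)

    @classmethod
    def from_category_beds(
        cls,
        bed_by_category: Mapping[str, str | os.PathLike],
        genome: GenomeModel,
        priority: Sequence[str] = DEFAULT_PRIORITY,
    ) -> "ElementAnnotation":
        """Build from one BED file per category (4th column = gene label)."""
        by_cat: dict[str, list[tuple[str, int, int, str]]] = {}
        for cat, path in bed_by_category.items():
            ivs = []
            with open(path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith(("#", "track")):
                        continue
                    parts = line.split("\t")
                    gene = parts[3] if len(parts) > 3 else ""
                    ivs.append((parts[0], int(parts[1]), int(parts[2]), gene))
            by_cat[cat] = ivs
        return cls.from_intervals(by_cat, genome, priority)

    @classmethod
    def from_gene_bed12(
        cls,
        path: str | os.PathLike,
        genome: GenomeModel,
        promoter_flank: int = 1000,
        tts_flank: int = 1000,
        priority: Sequence[str] = DEFAULT_PRIORITY,
    ) -> "ElementAnnotation":
        """Derive element categories from gene models in BED12.

        Promoter = TSS ± ``promoter_flank``; TTS window = transcription end
        ± ``tts_flank``; exons from the block structure, introns between
        blocks; UTRs = exonic bp outside the thick (CDS) region, split into
        5'/3' by strand.
        """
        by_cat: dict[str, list[tuple[str, int, int, str]]] = {
            c: [] for c in priority if c != "intergenic"
        }
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                p = line.split("\t")
                contig, start, end = p[0], int(p[1]), int(p[2])
                gene = p[3] if len(p) > 3 else ""
                strand = p[5] if len(p) > 5 else "+"
                thick_s = int(p[6]) if len(p) > 6 else start
                thick_e = int(p[7]) if len(p) > 7 else end
                if len(p) > 11:
                    sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in p[11].rstrip(",").split(",")]
                    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                else:
                    exons = [(start, end)]
                tss = start if strand == "+" else end
                tts = end if strand == "+" else start
                by_cat["promoter"].append(
                    (contig, max(0, tss - promoter_flank), tss + promoter_flank, gene)
                )
                by_cat["TTS"].append(
                    (contig, max(0, tts - tts_flank), tts + tts_flank, gene)
                )
                for es, ee in exons:
                    by_cat["exon"].append((contig, es, ee, gene))
                    # UTR portions: exonic bp outside the CDS
                    if es < thick_s:
                        utr = (contig, es, min(ee, thick_s), gene)
                        by_cat["5UTR" if strand == "+" else "3UTR"].append(utr)
                    if ee > thick_e:
                        utr = (contig, max(es, thick_e), ee, gene)
                        by_cat["3UTR" if strand == "+" else "5UTR"].append(utr)
                for (es0, ee0), (es1, _ee1) in zip(exons[:-1], exons[1:]):
                    if es1 > ee0:
                        by_cat["intron"].append((contig, ee0, es1, gene))
        return cls.from_intervals(by_cat, genome, priority)


def annotate_peaks(
    peaks: PeakSet, ann: ElementAnnotation
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each peak to one category by midpoint + priority.

    Returns ``(category_counts, per_gene)`` where ``category_counts`` covers
    every category (zero-filled) and sums to ``n_peaks``, and ``per_gene``
    tallies gene assignments for the promoter/exon/intron categories.
    """
    known_contigs = set()
    for per_contig in ann.intervals.values():
        known_contigs |= set(per_contig)
    peak_contigs = set(peaks.peaks["contig"])
    if known_contigs and not (peak_contigs & known_contigs):
        raise ValueError(
            f"no peak contig matches the annotation: peaks on {sorted(peak_contigs)}, "
            f"annotation on {sorted(known_contigs)}"
        )
    counts = dict.fromkeys(ann.categories, 0)
    gene_rows: list[tuple[str, str]] = []
    mids = peaks.midpoints
    contigs = peaks.peaks["contig"].to_numpy()
    for contig, mid in zip(contigs, mids):
        assigned = "intergenic"
        gene = ""
        for cat in ann.categories:
            if cat == "intergenic":
                continue
            tree = ann.intervals.get(cat, {}).get(contig)
            if tree is None:
                continue
            hits = tree[int(mid)]
            if hits:
                assigned = cat
                gene = sorted(iv.data for iv in hits)[0]
                break
        counts[assigned] += 1
        if assigned in ("promoter", "exon", "intron") and gene:
            gene_rows.append((gene, assigned))
    per_gene = (
        pd.DataFrame(gene_rows, columns=["gene", "category"])
        .value_counts()
        .rename("n_peaks")
        .reset_index()
        if gene_rows
        else pd.DataFrame(columns=["gene", "category", "n_peaks"])
    )
    return pd.Series(counts, name="n_peaks"), per_gene


def peaks_per_read(peaks: PeakSet, sample: SampleFragments) -> float:
    """Ratio of called peaks to total fragments."""
    if sample.n_total == 0:
        raise ValueError("sample has no fragments")
    return peaks.n_peaks / sample.n_total


def observed_expected(
    category_counts: pd.Series, ann: ElementAnnotation
) -> pd.Series:
    """Per-category O/E: observed peak share over the category's genome share.

    Categories with zero genome fraction get NaN (undefined).
    """
    total = category_counts.sum()
    if total <= 0:
        raise ValueError("no peaks to compare")
    out = {}
    for cat in ann.categories:
        gf = ann.genome_fraction.get(cat, 0.0)
        obs = category_counts.get(cat, 0) / total
        out[cat] = obs / gf if gf > 0 else float("nan")
    return pd.Series(out, name="obs_over_exp")


def element_coverage_profile(
    sample: SampleFragments,
    centers: Sequence[tuple[str, int]],
    flank: int = 1000,
) -> pd.DataFrame:
    """Mean per-base fragment coverage around element centers, mean-normalised.

    For offsets −flank..+flank the coverage of each window is averaged over
    centers and scaled so the profile's mean is 1 ("relative coverage").
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not centers:
        raise ValueError("need at least one center")
    # per contig: sorted starts and sorted ends → coverage by counting rule
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for contig in np.unique(sample.contig):
        m = sample.contig == contig
        starts[contig] = np.sort(sample.start[m])
        ends[contig] = np.sort(sample.end[m])
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(offsets.size, dtype=float)
    for contig, center in centers:
        pos = center + offsets
        if contig not in starts:
            continue
        cov = (
            np.searchsorted(starts[contig], pos, side="right")
            - np.searchsorted(ends[contig], pos, side="right")
        )
        acc += cov
    acc /= len(centers)
    mean = acc.mean()
    if mean == 0:
        raise ValueError("no fragment coverage within any center window")
    return pd.DataFrame({"offset": offsets, "relative_coverage": acc / mean})
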