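"""Fragment-level I/O and the genome model.

A *fragment* is one aligned cell-free DNA molecule: a half-open genomic
interval on a named contig, with its length, strand, and (optionally) the
sequenced-strand sequence.  All coordinates are 0-based half-open (BED
convention); BAM's internal coordinates are converted on read.

The :class:`GenomeModel` carries contig lengths (GRCh38 chr1–chr22 + chrM
constants are bundled) and the 1-Mb bin grid used for karyogram-style
coverage and per-bin fragmentomic scores.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GRCh38 primary-assembly contig lengths (bp) for the autosomes and the
#: mitochondrial genome.
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrM": 16_569,
}

#: Contig names recognised as mitochondrial (both common dialects).
MITO_NAMES = frozenset({"chrM", "MT"})

#: Contig names recognised as autosomal.
AUTOSOME_NAMES = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
)

DEFAULT_LENGTH_RANGE = (35, 300)


class FragmentFileError(ValueError):
    """Raised for unreadable or malformed fragment files."""


@dataclass(frozen=True)
class Fragment:
    """One aligned cfDNA molecule.

    ``start``/``end`` are 0-based half-open; ``seq``, when present, is the
    sequenced strand read 5'→3' and has length ``end - start``.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.seq is not None and len(self.seq) != self.length:
            raise ValueError(
                f"sequence length {len(self.seq)} != fragment length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_mito(self) -> bool:
        return self.contig in MITO_NAMES


class SampleFragments:
    """Ordered collection of fragments for one sample.

    Stored column-wise (numpy arrays) for fast vectorised metrics; iteration
    yields :class:`Fragment` objects in coordinate order.
    """

    def __init__(
        self,
        sample_id: str,
        contigs: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        strands: Sequence[str] | None = None,
        seqs: Sequence[str | None] | None = None,
    ) -> None:
        n = len(starts)
        if not (len(contigs) == len(ends) == n):
            raise ValueError("column lengths differ")
        self.sample_id = sample_id
        self.contig = np.asarray(contigs, dtype=object)
        self.start = np.asarray(starts, dtype=np.int64)
        self.end = np.asarray(ends, dtype=np.int64)
        if np.any(self.end <= self.start):
            bad = int(np.argmax(self.end <= self.start))
            raise ValueError(
                f"fragment end must exceed start at record {bad}: "
                f"{self.contig[bad]}:{self.start[bad]}-{self.end[bad]}"
            )
        if strands is None:
            self.strand = np.full(n, "+", dtype=object)
        else:
            self.strand = np.asarray(strands, dtype=object)
        self.seqs: list[str | None] | None = list(seqs) if seqs is not None else None
        if self.seqs is not None and len(self.seqs) != n:
            raise ValueError("seqs length differs from fragment count")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_fragments(cls, sample_id: str, fragments: Iterable[Fragment]) -> "SampleFragments":
        frs = list(fragments)
        return cls(
            sample_id,
            [f.contig for f in frs],
            [f.start for f in frs],
            [f.end for f in frs],
            [f.strand for f in frs],
            [f.seq for f in frs] if any(f.seq is not None for f in frs) else None,
        )

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[Fragment]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Fragment:
        return Fragment(
            contig=str(self.contig[i]),
            start=int(self.start[i]),
            end=int(self.end[i]),
            strand=str(self.strand[i]),
            seq=self.seqs[i] if self.seqs is not None else None,
        )

    # -- derived columns ---------------------------------------------------
    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def is_mito(self) -> np.ndarray:
        return np.isin(self.contig, list(MITO_NAMES))

    @property
    def is_autosomal(self) -> np.ndarray:
        return np.isin(self.contig, list(AUTOSOME_NAMES))

    @property
    def n_total(self) -> int:
        return len(self)

    @property
    def n_mito(self) -> int:
        return int(self.is_mito.sum())

    @property
    def n_autosomal(self) -> int:
        return int(self.is_autosomal.sum())

    def subset(self, mask: np.ndarray, sample_id: str | None = None) -> "SampleFragments":
        idx = np.flatnonzero(mask)
        return SampleFragments(
            sample_id or self.sample_id,
            self.contig[idx],
            self.start[idx],
            self.end[idx],
            self.strand[idx],
            [self.seqs[i] for i in idx] if self.seqs is not None else None,
        )

    def sort(self) -> "SampleFragments":
        """Return a copy in coordinate order (contig name, start, end)."""
        order = np.lexsort((self.end, self.start, self.contig.astype(str)))
        return SampleFragments(
            self.sample_id,
            self.contig[order],
            self.start[order],
            self.end[order],
            self.strand[order],
            [self.seqs[i] for i in order] if self.seqs is not None else None,
        )


@dataclass
class GenomeModel:
    """Contig lengths plus the bin size of the genome-wide grid."""

    lengths: dict[str, int] = field(default_factory=lambda: dict(GRCH38_LENGTHS))
    bin_size: int = 1_000_000

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"contig {name} has non-positive length {length}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @classmethod
    def grch38(cls, bin_size: int = 1_000_000) -> "GenomeModel":
        return cls(dict(GRCH38_LENGTHS), bin_size)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, bin_size: int = 1_000_000) -> "GenomeModel":
        df = pd.read_csv(path, sep="\t", header=None, names=["contig", "length"])
        return cls(dict(zip(df["contig"].astype(str), df["length"].astype(int))), bin_size)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c in AUTOSOME_NAMES]

    def n_bins(self, contig: str) -> int:
        return math.ceil(self.lengths[contig] / self.bin_size)

    def __contains__(self, contig: str) -> bool:
        return contig in self.lengths


def make_bins(
    genome: GenomeModel, contigs: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tile contigs with consecutive half-open bins of ``genome.bin_size`` bp.

    The final partial bin of each contig is included, so a contig of length
    L contributes ceil(L / bin_size) bins.  Returns a DataFrame with columns
    ``contig``, ``start``, ``end`` in the given contig order.
    """
    if contigs is None:
        contigs = genome.autosomes
    contigs = list(contigs)
    if not contigs:
        raise ValueError("empty contig list")
    missing = [c for c in contigs if c not in genome]
    if missing:
        raise KeyError(f"contigs absent from genome model: {missing}")
    rows: list[tuple[str, int, int]] = []
    B = genome.bin_size
    for contig in contigs:
        L = genome.lengths[contig]
        for k in range(math.ceil(L / B)):
            rows.append((contig, k * B, min((k + 1) * B, L)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _load_bed(path: str | os.PathLike) -> list[Fragment]:
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentFileError(
                    f"{path}:{lineno}: expected >=3 tab-separated BED fields, "
                    f"got {len(parts)}: {line!r}"
                )
            try:
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentFileError(f"{path}:{lineno}: bad coordinates: {line!r}") from exc
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
            seq = parts[6] if len(parts) > 6 and parts[6] else None
            try:
                frags.append(Fragment(contig, start, end, strand, seq))
            except ValueError as exc:
                raise FragmentFileError(f"{path}:{lineno}: {exc}") from exc
    return frags


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_bam(path: str | os.PathLike, min_mapq: int) -> list[Fragment]:
    import pysam

    frags: list[Fragment] = []
    pending: dict[str, "pysam.AlignedSegment"] = {}
    try:
        af = pysam.AlignmentFile(os.fspath(path), "rb", check_sq=False)
    except (ValueError, OSError) as exc:
        raise FragmentFileError(f"cannot open BAM {path}: {exc}") from exc
    with af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    continue
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = read
                    continue
                # fragment = alignment span of the pair, not TLEN
                start = min(read.reference_start, mate.reference_start)
                end = max(read.reference_end, mate.reference_end)
                r1 = read if read.is_read1 else mate
                seq = r1.query_sequence
                if seq is not None and r1.is_reverse:
                    seq = reverse_complement(seq)
                # motif end = 5' of read 1; fragment seq only kept when the
                # pair fully overlaps (merged-style); else None
                span_seq = seq if seq is not None and len(seq) == end - start else None
                frags.append(
                    Fragment(
                        read.reference_name,
                        start,
                        end,
                        "-" if r1.is_reverse else "+",
                        span_seq,
                    )
                )
            else:
                seq = read.query_sequence
                if seq is not None and read.is_reverse:
                    seq = reverse_complement(seq)
                if seq is not None and len(seq) != read.reference_end - read.reference_start:
                    seq = None  # indels: span and read length disagree
                frags.append(
                    Fragment(
                        read.reference_name,
                        read.reference_start,
                        read.reference_end,
                        "-" if read.is_reverse else "+",
                        seq,
                    )
                )
    return frags


def load_fragments(
    path: str | os.PathLike,
    format: str = "auto",
    min_mapq: int = 0,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    sample_id: str | None = None,
    genome: GenomeModel | None = None,
) -> SampleFragments:
    """Load fragments from a BAM or fragment-BED file.

    Fragments with mapping quality below ``min_mapq`` (BAM only) or with
    length outside ``length_range`` (inclusive bounds) are dropped.  Output
    order is coordinate order.  Fragments on contigs absent from ``genome``
    (when given) are retained but a warning is logged — binned analyses skip
    them downstream.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FragmentFileError(f"no such file: {path}")
    lo, hi = length_range
    if lo < 1:
        raise ValueError("length_range lower bound must be >= 1")
    if format == "auto":
        format = "bam" if path.endswith((".bam", ".sam", ".cram")) else "bed"
    if format == "bam":
        frags = _load_bam(path, min_mapq)
    elif format == "bed":
        frags = _load_bed(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    frags = [f for f in frags if lo <= f.length <= hi]
    frags.sort(key=lambda f: (f.contig, f.start, f.end))
    if sample_id is None:
        sample_id = os.path.basename(path).rsplit(".", 1)[0]
    sample = SampleFragments.from_fragments(sample_id, frags)
    if genome is not None and len(sample):
        unknown = sorted(set(sample.contig) - set(genome.lengths))
        if unknown:
            logger.warning(
                "sample %s: %d contigs absent from genome model (kept, excluded "
                "from binning): %s", sample_id, len(unknown), unknown
            )
    return sample


def write_fragments_bed(sample: SampleFragments, path: str | os.PathLike) -> None:
    """Write BED6 (+ optional 7th sequence column); name=frag index, score=length."""
    with open(path, "w") as fh:
        for i in range(len(sample)):
            fields = [
                str(sample.contig[i]),
                str(int(sample.start[i])),
                str(int(sample.end[i])),
                f"{sample.sample_id}_f{i}",
                str(int(sample.end[i] - sample.start[i])),
                str(sample.strand[i]),
            ]
            if sample.seqs is not None and sample.seqs[i] is not None:
                fields.append(sample.seqs[i])
            fh.write("\t".join(fields) + "\n")


def write_fragments_bam(
    sample: SampleFragments, path: str | os.PathLike, genome: GenomeModel
) -> None:
    """Write fragments as unpaired alignments to a coordinate-sorted BAM.

    Sequences are stored SAM-style (forward genome strand); reads without a
    sequence get ``*``.  Header contigs come from the genome model.
    """
    import pysam

    contigs = list(genome.lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.lengths[c]} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    srt = sample.sort()
    with pysam.AlignmentFile(os.fspath(path), "wb", header=header) as out:
        for i in range(len(srt)):
            a = pysam.AlignedSegment()
            a.query_name = f"{srt.sample_id}_f{i}"
            a.reference_id = tid[str(srt.contig[i])]
            a.reference_start = int(srt.start[i])
            a.mapping_quality = 60
            length = int(srt.end[i] - srt.start[i])
            a.cigarstring = f"{length}M"
            a.flag = 16 if srt.strand[i] == "-" else 0
            seq = srt.seqs[i] if srt.seqs is not None else None
            if seq is not None:
                a.query_sequence = reverse_complement(seq) if srt.strand[i] == "-" else seq
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
            out.write(a)
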