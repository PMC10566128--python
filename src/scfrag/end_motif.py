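"""Fragment end motifs, Shannon entropy and G-quadruplex prevalence.

The *end motif* of a fragment is the first k nucleotides (default k = 4,
256 categories) at its 5' end on the sequenced strand; the distribution of
end motifs across a sample reflects the cleavage preferences of the
nucleases that produced the fragments.  Motif diversity is summarised by
Shannon entropy in bits (0 for a single motif, 2k for the uniform
distribution over 4^k motifs).

G-quadruplex (G4) prevalence is the percent of fragments whose sequence, on
either strand, contains a canonical quadruplex-forming motif: four runs of
three or more guanines separated by loops of 1–7 bases.
"""

from __future__ import annotations

import itertools
import os
import re
from dataclasses import dataclass, field

import numpy as np

from .fragments_io import SampleFragments, reverse_complement

#: Canonical quadruplex-forming pattern: G≥3 tracts, loops of 1–7 bases, ×4.
G4_PATTERN = r"G{3,}(?:[ACGTN]{1,7}G{3,}){3}"
_G4_RE = re.compile(G4_PATTERN)


def enumerate_motifs(k: int = 4) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order (ACGT alphabet)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@dataclass
class MotifProfile:
    k: int
    counts: dict[str, int]                    # zero-filled over all 4^k motifs
    n_skipped: int = 0                        # fragments with N or short seq
    freqs: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError("motif profile has no counted fragments")
        self.freqs = {m: c / total for m, c in self.counts.items()}

    @property
    def entropy_bits(self) -> float:
        return motif_entropy(self)

    @property
    def per_motif_entropy(self) -> dict[str, float]:
        """Per-motif −p·log2(p) terms (0 for absent motifs)."""
        return {
            m: (-p * np.log2(p) if p > 0 else 0.0) for m, p in self.freqs.items()
        }

    def to_tsv(self, path: str | os.PathLike) -> None:
        pme = self.per_motif_entropy
        with open(path, "w") as fh:
            fh.write("motif\tcount\tfreq\tneg_p_log2_p\n")
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\t{self.freqs[m]:.10g}\t{pme[m]:.10g}\n")


def motif_profile(sample: SampleFragments, k: int = 4) -> MotifProfile:
    """Count the 5'-end k-mer of each sequenced fragment.

    One end per fragment (the 5' end of the sequenced strand / read 1).
    Fragments whose sequence is missing, shorter than k, or carries N within
    the first k bases are skipped and tallied in ``n_skipped``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sample.seqs is None or all(s is None for s in sample.seqs):
        raise ValueError("motif profiling requires sequences")
    counts = dict.fromkeys(enumerate_motifs(k), 0)
    skipped = 0
    for seq in sample.seqs:
        if seq is None or len(seq) < k:
            skipped += 1
            continue
        motif = seq[:k].upper()
        if motif in counts:
            counts[motif] += 1
        else:
            skipped += 1  # N or non-ACGT in the first k bases
    if sum(counts.values()) == 0:
        raise ValueError("motif profiling requires sequences")
    return MotifProfile(k=k, counts=counts, n_skipped=skipped)


def motif_entropy(profile: MotifProfile) -> float:
    """Shannon entropy of the motif frequency vector, in bits."""
    p = np.array([v for v in profile.freqs.values() if v > 0])
    return float(-(p * np.log2(p)).sum())


def has_gquad(seq: str, pattern: re.Pattern = _G4_RE) -> bool:
    """True if the sequence or its reverse complement matches the G4 motif."""
    seq = seq.upper()
    return bool(pattern.search(seq) or pattern.search(reverse_complement(seq)))


def gquad_prevalence(sample: SampleFragments, pattern: str = G4_PATTERN) -> float:
    """Percent of sequenced fragments carrying ≥1 canonical G4 motif."""
    if sample.seqs is None or all(s is None for s in sample.seqs):
        raise ValueError("G-quadruplex scanning requires sequences")
    rx = re.compile(pattern)
    seqs = [s for s in sample.seqs if s is not None]
    n_pos = sum(has_gquad(s, rx) for s in seqs)
    return 100.0 * n_pos / len(seqs)
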