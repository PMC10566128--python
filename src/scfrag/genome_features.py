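"""Binned genome coverage, fragment scores and mitochondrial fraction.

The *fragment score* is the ratio of short fragments (35–100 bp, below the
mononucleosomal range) to mononucleosome-protected fragments (100–250 bp),
computed globally per sample or per 1-Mb bin.  Boundary convention: length
100 counts as long, length 35 as short; lengths outside both windows count
in neither (half-open short window [35, 100), closed long window [100, 250]).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .fragments_io import SampleFragments

SHORT_RANGE = (35, 100)   # [lo, hi) — half-open
LONG_RANGE = (100, 250)   # [lo, hi] — closed


def _short_long_masks(
    lengths: np.ndarray,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    s_lo, s_hi = short_range
    l_lo, l_hi = long_range
    if not (s_lo < s_hi <= l_lo < l_hi):
        raise ValueError("short range must lie strictly below the long range")
    short = (lengths >= s_lo) & (lengths < s_hi)
    long = (lengths >= l_lo) & (lengths <= l_hi)
    return short, long


def bin_coverage(sample: SampleFragments, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin fragment counts, coverage % and short/long fragment scores.

    A fragment belongs to the bin containing its *start* coordinate.  Only
    fragments on contigs present in ``bins`` are counted; ``coverage_pct``
    is each bin's share (in %) of those fragments, so it sums to 100.
    Bins whose long-fragment count is zero get ``fragment_score = NaN``
    (undefined, excluded from group tests downstream).
    """
    contigs = list(dict.fromkeys(bins["contig"]))
    in_bins = np.isin(sample.contig, contigs)
    if not in_bins.any():
        raise ValueError("no fragments on binned contigs")
    sub = sample.subset(in_bins)
    lengths = sub.lengths
    short, long = _short_long_masks(lengths)

    # bin width inferred per contig from the grid (uniform except final bin)
    out = bins.copy()
    n_frag = np.zeros(len(bins), dtype=np.int64)
    n_short = np.zeros(len(bins), dtype=np.int64)
    n_long = np.zeros(len(bins), dtype=np.int64)
    bin_size = int((bins["end"] - bins["start"]).max())
    # row index of each contig's first bin
    first_row = {c: int(bins.index[bins["contig"] == c][0]) for c in contigs}
    n_bins_per = {c: int((bins["contig"] == c).sum()) for c in contigs}
    for c in contigs:
        cmask = sub.contig == c
        if not cmask.any():
            continue
        k = sub.start[cmask] // bin_size
        k = np.clip(k, 0, n_bins_per[c] - 1)
        base = first_row[c]
        n_frag[base : base + n_bins_per[c]] += np.bincount(k, minlength=n_bins_per[c])
        n_short[base : base + n_bins_per[c]] += np.bincount(
            k[short[cmask]], minlength=n_bins_per[c]
        )
        n_long[base : base + n_bins_per[c]] += np.bincount(
            k[long[cmask]], minlength=n_bins_per[c]
        )
    out["n_fragments"] = n_frag
    out["coverage_pct"] = 100.0 * n_frag / n_frag.sum()
    out["n_short"] = n_short
    out["n_long"] = n_long
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(n_long > 0, n_short / np.maximum(n_long, 1), np.nan)
    out["fragment_score"] = score
    return out


def fragment_score(
    sample: SampleFragments,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    autosomal_only: bool = True,
) -> float:
    """Global short/long count ratio; NaN when the long count is zero."""
    lengths = sample.lengths
    if autosomal_only:
        lengths = lengths[sample.is_autosomal]
    short, long = _short_long_masks(lengths, short_range, long_range)
    n_long = int(long.sum())
    if n_long == 0:
        return float("nan")
    return float(short.sum() / n_long)


def mito_fraction(sample: SampleFragments) -> float:
    """Percent of fragments on the mitochondrial contig."""
    if sample.n_total == 0:
        raise ValueError("sample has no fragments")
    return 100.0 * sample.n_mito / sample.n_total


def write_bin_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """BED3 + metric columns, tab-separated."""
    table.to_csv(path, sep="\t", index=False)
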