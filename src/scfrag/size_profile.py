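"""Insert-size histogram, local-extrema detection and the peak–valley index.

The peak–valley index quantifies the "jaggedness" of a cfDNA insert-size
profile: sub-100 bp fragments show a comb with ~10 bp periodicity (nuclease
access along the nucleosome surface), and the mean drop from each peak to
the valley immediately to its right summarises how pronounced that comb is.

Extrema are found with a lookahead/delta scan over the raw percent series
(no smoothing — smoothing would erase the 10 bp comb): the running maximum
is a candidate peak, confirmed once the series falls more than ``delta``
below it and stays below it over the next ``lookahead`` points; valleys are
symmetric.  Confirmed extrema alternate, and trailing unconfirmed candidates
are never emitted, so endpoints cannot be extrema.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .fragments_io import SampleFragments


@dataclass
class SizeHistogram:
    """Percent-of-reads by fragment length over ``lengths[0]..lengths[-1]``."""

    lengths: np.ndarray  # consecutive integers lo..hi
    pct: np.ndarray      # % of in-range fragments per length
    n_source: int        # fragments counted (in range)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.pct = np.asarray(self.pct, dtype=float)
        if self.lengths.shape != self.pct.shape:
            raise ValueError("lengths and pct must align")
        if self.n_source > 0 and not math.isclose(self.pct.sum(), 100.0, abs_tol=1e-9):
            raise ValueError(f"pct must sum to 100, got {self.pct.sum()!r}")

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("length\tpct\n")
            for length, p in zip(self.lengths, self.pct):
                fh.write(f"{length}\t{p:.10g}\n")


@dataclass
class PeakValleySet:
    """Confirmed peaks/valleys of a histogram plus peak→right-valley pairs."""

    peaks: list[tuple[int, float]] = field(default_factory=list)
    valleys: list[tuple[int, float]] = field(default_factory=list)
    pairs: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        """Number of paired peaks."""
        return len(self.pairs)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "peaks": [[int(x), float(y)] for x, y in self.peaks],
            "valleys": [[int(x), float(y)] for x, y in self.valleys],
            "pairs": [[float(p), float(v)] for p, v in self.pairs],
            "n": self.n,
            "peak_valley_index": peak_valley_index(self),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_histogram(sample: SampleFragments, lo: int = 35, hi: int = 300) -> SizeHistogram:
    """Histogram of fragment lengths as % of in-range reads.

    Lengths outside ``[lo, hi]`` are excluded from both numerator and
    denominator, matching an insert-size plot restricted to that range.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if len(sample) == 0:
        raise ValueError("empty histogram: sample has no fragments")
    lens = sample.lengths
    in_range = lens[(lens >= lo) & (lens <= hi)]
    if in_range.size == 0:
        raise ValueError(f"empty histogram: no fragments with length in [{lo}, {hi}]")
    counts = np.bincount(in_range - lo, minlength=hi - lo + 1)
    pct = 100.0 * counts / counts.sum()
    return SizeHistogram(np.arange(lo, hi + 1), pct, int(in_range.size))


def peakdetect(
    y: np.ndarray, x: np.ndarray, lookahead: int = 1, delta: float = 0.0001
) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Lookahead/delta local-extrema scan over a 1-D series.

    Returns ``(max_peaks, min_peaks)`` as lists of ``(x, y)``.  A running
    maximum becomes a confirmed peak when the series drops below it by more
    than ``delta`` and no point in the following ``lookahead`` positions
    reaches it again; minima are symmetric.  The first confirmed extremum is
    discarded as a boundary artefact of the running max/min initialisation,
    so confirmed extrema strictly alternate and endpoints are never emitted.
    Plateaus yield a single extremum at the plateau's first point.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    if y.shape != x.shape:
        raise ValueError("x and y must have the same shape")
    if lookahead < 1:
        raise ValueError("lookahead must be >= 1")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    length = len(y)
    if length < 2 * lookahead + 1:
        raise ValueError(f"series too short: need > {2 * lookahead} points, got {length}")

    max_peaks: list[tuple[int, float]] = []
    min_peaks: list[tuple[int, float]] = []
    dump: list[bool] = []  # True where the hit was a maximum

    mn, mx = np.inf, -np.inf
    mnpos = mxpos = x[0]
    for index in range(length - lookahead):
        yi, xi = y[index], x[index]
        if yi > mx:
            mx, mxpos = yi, xi
        if yi < mn:
            mn, mnpos = yi, xi

        if yi < mx - delta and mx != np.inf:
            if y[index : index + lookahead].max() < mx:
                max_peaks.append((mxpos, mx))
                dump.append(True)
                mx, mn = np.inf, np.inf
                if index + lookahead >= length:
                    break
                continue

        if yi > mn + delta and mn != -np.inf:
            if y[index : index + lookahead].min() > mn:
                min_peaks.append((mnpos, mn))
                dump.append(False)
                mn, mx = -np.inf, -np.inf
                if index + lookahead >= length:
                    break
                continue

    # drop the false hit on the first value of the series
    if dump:
        if dump[0]:
            max_peaks.pop(0)
        else:
            min_peaks.pop(0)
    return max_peaks, min_peaks


def detect_extrema(
    hist: SizeHistogram, lookahead: int = 1, delta: float = 0.0001
) -> PeakValleySet:
    """Find histogram peaks/valleys and pair each peak with its right valley.

    Peaks without a confirmed valley at larger x are excluded from pairs.
    """
    peaks, valleys = peakdetect(hist.pct, hist.lengths, lookahead, delta)
    pairs: list[tuple[float, float]] = []
    vx = np.array([v[0] for v in valleys])
    for px, py in peaks:
        right = np.searchsorted(vx, px, side="right")
        if right < len(valleys):
            pairs.append((py, valleys[right][1]))
    return PeakValleySet(peaks=peaks, valleys=valleys, pairs=pairs)


def peak_valley_index(pv: PeakValleySet) -> float:
    """Mean peak-minus-right-valley drop, Σ(P_i − V_i)/n over paired peaks.

    Returns 0.0 (not NaN) for extremum-free histograms so cohort statistics
    never propagate NaN.
    """
    if pv.n == 0:
        return 0.0
    return float(sum(p - v for p, v in pv.pairs) / pv.n)
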