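"""Independent reference implementations used only to check the package.

Each oracle is a deliberately plain transcription of the published
procedure it checks (list-based, step-by-step), kept free of any code from
the implementation under test.
"""

from __future__ import annotations

import math


def peakdetect_reference(y_axis, x_axis, lookahead=1, delta=0.0001):
    """Literal transcription of the classic lookahead/delta peak detector."""
    max_peaks = []
    min_peaks = []
    dump = []
    length = len(y_axis)
    mn, mx = float("inf"), float("-inf")
    mnpos = mxpos = None
    for index in range(length - lookahead):
        x = x_axis[index]
        y = y_axis[index]
        if y > mx:
            mx = y
            mxpos = x
        if y < mn:
            mn = y
            mnpos = x

        # look for a maximum
        if y < mx - delta and mx != float("inf"):
            if max(y_axis[index : index + lookahead]) < mx:
                max_peaks.append((mxpos, mx))
                dump.append(True)
                mx = float("inf")
                mn = float("inf")
                continue

        # look for a minimum
        if y > mn + delta and mn != float("-inf"):
            if min(y_axis[index : index + lookahead]) > mn:
                min_peaks.append((mnpos, mn))
                dump.append(False)
                mn = float("-inf")
                mx = float("-inf")
                continue

    # remove the false hit on the first value
    if dump:
        if dump[0]:
            max_peaks.pop(0)
        else:
            min_peaks.pop(0)
    return max_peaks, min_peaks


def bh_reject_reference(pvals, alpha):
    """Benjamini–Hochberg step-up by explicit enumeration."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    k = 0
    for rank, i in enumerate(indexed, start=1):
        if pvals[i] <= alpha * rank / m:
            k = rank
    rejected = [False] * m
    for i in indexed[:k]:
        rejected[i] = True
    return rejected


def bky_two_stage_reference(pvals, Q):
    """Two-stage step-up adaptive FDR by direct transcription.

    Stage 1: BH at Q' = Q/(1+Q) giving r1 rejections.  r1 == 0 → reject
    none; r1 == m → reject all; otherwise stage 2 is BH at Q'·m/(m−r1).
    """
    m = len(pvals)
    q_prime = Q / (1.0 + Q)
    stage1 = bh_reject_reference(pvals, q_prime)
    r1 = sum(stage1)
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    return bh_reject_reference(pvals, q_prime * m / (m - r1))


def auroc_pairs_reference(scores, labels):
    """AUROC by brute-force pair counting (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def welch_reference(x, y):
    """Textbook Welch t with Welch–Satterthwaite df and two-sided p."""
    from scipy.stats import t as t_dist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def shannon_entropy_bits_reference(freqs):
    return -sum(p * math.log2(p) for p in freqs if p > 0)
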