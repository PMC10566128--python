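"""Two-group statistics: Welch t tests, two-stage adaptive FDR, AUROC.

Multiple-feature testing follows the two-stage step-up procedure of
Benjamini, Krieger & Yekutieli (adaptive FDR): stage 1 runs Benjamini–
Hochberg at the deflated level Q' = Q/(1+Q) to estimate the number of true
nulls m0 = m − r1; stage 2 re-runs BH at Q'·m/m0.  The procedure's
normative output is the set of rejection flags; the q value reported for
each feature is the smallest Q at which that feature would be rejected
(rejection-threshold infimum), which keeps volcano axes continuous.

Every per-feature test is an unpooled Welch t ("multiple t tests without
assuming consistent SD"): variances are never pooled across features or
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FeatureMatrix:
    """Samples × named features with a binary group label per sample."""

    values: pd.DataFrame          # index = sample ids, columns = features
    groups: pd.Series             # index = sample ids, values in {"A", "B"}
    provenance: dict[str, str] = field(default_factory=dict)  # feature → module

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = list(self.values.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {"A", "B"}
        if bad:
            raise ValueError(f"group labels must be 'A' or 'B', got {sorted(bad)}")
        if self.values.columns.duplicated().any():
            dupes = list(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicate feature names: {dupes}")

    def complete(self) -> "FeatureMatrix":
        """Copy without features that are undefined (NaN) in any sample."""
        keep = self.values.columns[self.values.notna().all()]
        return FeatureMatrix(
            values=self.values[keep],
            groups=self.groups,
            provenance={k: v for k, v in self.provenance.items() if k in keep},
        )

    def split(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        col = self.values[feature]
        a = col[self.groups == "A"].to_numpy(dtype=float)
        b = col[self.groups == "B"].to_numpy(dtype=float)
        return a, b


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p).

    NaNs are dropped with a warning.  When both groups have zero variance
    and equal means the test is degenerate and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        warnings.warn("NaN values dropped from Welch t input", stacklevel=2)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf,
                float(len(x) + len(y) - 2), 0.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    # Welch–Satterthwaite df
    nx, ny = len(x), len(y)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level alpha."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = sorted_p <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


def bky_reject(p: np.ndarray, Q: float = 0.05) -> np.ndarray:
    """Two-stage Benjamini–Krieger–Yekutieli step-up rejection flags."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    q_prime = Q / (1.0 + Q)
    stage1 = _bh_reject(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return _bh_reject(p, q_prime * m / (m - r1))


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p values: feature i is BH-rejected at level a iff adj_i <= a."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def bky_fdr(p: np.ndarray, Q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage BKY q values and discovery flags at level ``Q``.

    The flag vector is the procedure's normative output; the q value of
    feature i is the smallest level (capped at 1) at which i would be
    rejected.  It is found exactly by scanning the stage-1 breakpoints:
    with u = Q/(1+Q), the stage-1 rejection count r1 = #{BH-adjusted p
    <= u} is piecewise constant in u, and inside each piece feature i is
    rejected iff its BH-adjusted p <= u*m/(m-r1), so the infimum over each
    piece has closed form.
    """
    p = np.asarray(p, dtype=float)
    flags = bky_reject(p, Q)
    m = len(p)
    c = _bh_adjusted(p)
    u_max = 0.5  # Q = 1 corresponds to u = Q/(1+Q) = 0.5
    breakpoints = np.unique(c)
    q = np.ones(m)
    for j, u_lo in enumerate(breakpoints):
        if u_lo > u_max:
            break
        r1 = int((c <= u_lo).sum())
        u_hi = breakpoints[j + 1] if j + 1 < len(breakpoints) else np.inf
        u_hi = min(u_hi, u_max + 1e-15)
        if r1 == m:
            u_star = np.full(m, u_lo)
            feasible = np.full(m, u_lo <= u_max)
        else:
            u_star = np.maximum(u_lo, c * (m - r1) / m)
            feasible = (u_star < u_hi) & (u_star <= u_max)
        q_cand = np.where(feasible, u_star / (1.0 - u_star), 1.0)
        q = np.minimum(q, q_cand)
    return np.minimum(q, 1.0), flags


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC = P(score_pos > score_neg) + ½·P(tie), by the Mann–Whitney identity.

    ``labels`` is binary; 1 marks the positive (cancer) group.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compare_features(
    matrix: FeatureMatrix, Q: float = 0.05, min_per_group: int = 2
) -> pd.DataFrame:
    """Per-feature Welch t + joint BKY FDR; the volcano table.

    Features with any missing value, or fewer than ``min_per_group``
    finite values in either group, are excluded from testing and listed
    with ``tested = False``.
    """
    rows = []
    testable: list[str] = []
    for feat in matrix.values.columns:
        a, b = matrix.split(feat)
        ok = (
            np.isfinite(a).all()
            and np.isfinite(b).all()
            and len(a) >= min_per_group
            and len(b) >= min_per_group
        )
        if ok:
            t, df, pval = welch_t(a, b)
            rows.append((feat, a.mean(), b.mean(), a.mean() - b.mean(),
                         t, df, pval, True, len(a), len(b)))
            testable.append(feat)
        else:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, False, int(np.isfinite(a).sum()),
                         int(np.isfinite(b).sum())))
    if not testable:
        raise ValueError("no testable features")
    out = pd.DataFrame(
        rows,
        columns=["feature", "mean_A", "mean_B", "difference", "t", "df", "p",
                 "tested", "n_A", "n_B"],
    ).set_index("feature")
    q, flags = bky_fdr(out.loc[testable, "p"].to_numpy(), Q=Q)
    out["q"] = np.nan
    out["discovery"] = False
    out.loc[testable, "q"] = q
    out.loc[testable, "discovery"] = flags
    return out.reset_index()
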